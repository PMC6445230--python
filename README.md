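# npsid

Identification of new psychoactive substances (NPS) from unit-resolution
LC–MS/MS evidence, without reference standards.

## The problem

Forensic toxicology laboratories routinely face seized powders containing
compounds for which no reference standard, no library spectrum and no
accurate-mass instrument is available. On a triple-quadrupole (QQQ)
instrument only integer m/z values are measured, so the molecular formula
of an unknown cannot be read off the mass directly. It can, however, be
*deduced* by combining several independent pieces of unit-resolution
evidence. `npsid` implements that deduction as a reusable, tested
pipeline:

1. **Precursor determination** — MS1 scans at a decreasing series of
   in-source fragmentor voltages (110/90/70/40 eV) let the intact
   protonated molecule [M+H]⁺ re-emerge from in-source fragmentation; the
   called precursor is the highest-m/z ion whose abundance peaks at a
   low-to-interior voltage.
2. **Isotope-pattern element exclusion** — the A+2 elements S, Cl and Br
   each contribute a large, element-specific M+2 line (≈4.4%, ≈32% and
   ≈97% of M+0 per atom). If the measured M+2 falls below half the
   single-atom contribution, the element is excluded.
3. **Nitrogen rule and unsaturation** — an even neutral nominal mass
   forces an even nitrogen count; aromatic marker fragments (phenyl
   C₆H₅⁺ at 77, tropylium C₇H₇⁺ at 91, phenylvinyl C₈H₇⁺ at 103) force
   RDBE = C − (H+halogens)/2 + N/2 + 1 ≥ 4 and minimum C/H counts.
4. **Constrained formula enumeration** — all elemental compositions with
   the target nominal mass inside the evidence-derived bounds.
5. **Fragment/neutral-loss annotation** — each product ion is explained
   as an even-electron cation subformula of [M+H]⁺ and/or a named neutral
   loss (NH₃ −17, H₂O −18, CH₅N −31, ...); the intensity-weighted
   explained fraction scores each candidate.
6. **Candidate ranking and database resolution** — composite score
   0.3·isotope-fit + 0.5·fragment-coverage + 0.2·database-hit against a
   packaged table of ~50 NPS and common drugs; same-formula isomers are
   reported together as an ambiguity set (formula-level identification —
   separating AMT from 5-IT requires an orthogonal technique such as NMR).

A synthetic-data module simulates the whole acquisition (isotope
clusters, voltage-dependent in-source fragmentation, CE-dependent product
spectra, lognormal intensity noise) so every stage is testable end to end
without instrument data.

## Worked example

The canonical case: an unknown at [M+H]⁺ = 175 with isotope cluster
175:100 / 176:9.8 / 177:0.7 (relative %) and fragments 77/91/103/158.

```sh
$ npsid isotopes exclude --cluster 100,9.8,0.7
S   excluded   measured (M+2)/(M+0) = 0.0070 vs single-atom S contribution 0.0447 (threshold 0.0224): excluded
Cl  excluded   measured (M+2)/(M+0) = 0.0070 vs single-atom Cl contribution 0.3200 (threshold 0.1600): excluded
Br  excluded   measured (M+2)/(M+0) = 0.0070 vs single-atom Br contribution 0.9728 (threshold 0.4864): excluded
```

No M+2 signal: S, Cl and Br are out. The neutral mass 174 is even, so the
nitrogen count is even; the 103 fragment implies C ≥ 8, H ≥ 7 and at
least one benzene ring (RDBE ≥ 4). Enumerating under those constraints:

```sh
$ npsid enumerate --mass 174 --bounds C=8:15,H=7:20,N=2:4,O=0:2,F=0:1 \
      --n-parity even --min-rdbe 4
C10H7FN2    RDBE=8
C10H10N2O   RDBE=7
C9H10N4     RDBE=7
C11H14N2    RDBE=6
```

Exactly four formulas survive. Running the full pipeline on simulated
scans of the same compound ranks them by the combined evidence:

```sh
$ npsid simulate --compound AMT --seed 1 --noise 0.02 --out sim/
$ npsid identify --ms1 sim/AMT_ms1_f110.csv --ms1 sim/AMT_ms1_f90.csv \
      --ms1 sim/AMT_ms1_f70.csv --ms1 sim/AMT_ms1_f40.csv \
      --ms2 sim/AMT_ms2_ce10.csv --ms2 sim/AMT_ms2_ce20.csv \
      --ms2 sim/AMT_ms2_ce30.csv --ms2 sim/AMT_ms2_ce40.csv
1. C11H14N2 score=1.000 db=[5-IT, AMT]
2. C10H10N2O score=0.800 db=[-]
3. C10H7FN2 score=0.800 db=[-]
4. C9H10N4 score=0.800 db=[-]
```

C₁₁H₁₄N₂ wins: all four candidates explain the fragment list (coverage
1.0) and fit the isotope cluster, but only C₁₁H₁₄N₂ resolves in the
compound table — to the isomer ambiguity set {AMT, 5-IT}, which is as far
as mass spectrometry alone can go.

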