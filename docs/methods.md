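# Methods

## Scope and assumptions

`npsid` identifies small organic molecules at the *formula* level from
unit-resolution (integer m/z) electrospray LC–MS/MS data. Assumptions
baked into the model:

* **Even-electron chemistry.** The precursor is the protonated molecule
  [M+H]⁺; radical cations, adducts ([M+Na]⁺, dimers) and multiply
  charged species are out of scope. Fragments are even-electron cations
  that may retain the ionizing proton (+1 H allowance over the neutral
  composition) with no further hydrogen rearrangement modelled.
* **Supported elements** H, C, N, O, F, S, Cl, Br, I — the element space
  of drug-like small molecules. The packaged isotope table
  (`data/elements.csv`, v1) carries NIST standard masses/abundances and
  is cross-checked in the test suite against an independent source
  (pyteomics). Iodine uses the standard 126.9045 Da / nominal 127.
* **Unit resolution throughout.** Nominal mass = Σ count × mass number
  of the most abundant isotope (Br → 79, so the bromine doublet sits at
  274/276 for protonated bk-2C-B). The electron mass is ignored at
  nominal resolution and subtracted per charge in exact-mass mode.

## Stage-by-stage model

### Precursor selection

Candidate ions are the integer-binned peaks of the *lowest*-voltage MS1
scan with isotope satellites removed (a peak 1–2 Da above a stronger
peak is an isotope line, not an ion). The call is the highest-m/z
candidate whose abundance-vs-voltage argmax lies at or below the median
scanned voltage. The "≤ median" form, rather than "lowest voltage",
matters: below the in-source optimum overall ion transmission also
falls, so the true [M+H]⁺ typically peaks at an *interior* voltage
(70 eV on the default 110/90/70/40 grid). Ties in abundance resolve to
the lower voltage; candidate ties resolve to higher m/z (in-source
fragments are always lighter than their precursor). How a real analyst
distinguishes [M+H]⁺ from a high-mass adduct is not observable at unit
resolution; the monotone-survival heuristic is this module's
operationalization, and a user-supplied precursor m/z overrides it.

### A+2 exclusion

For each of S, Cl, Br the minimal expected (M+2)/(M+0) contribution of
one atom comes from the isotope table (0.0447, 0.320, 0.973). An element
is excluded iff the measured ratio is below **0.5 ×** that contribution.
The 0.5 safety factor is chosen to tolerate the ±50%-scale intensity
error of a QQQ while still cleanly separating a sub-1% measured M+2 from
sulfur's 4.4%: property tests confirm no false exclusion over simulated
clusters of S/Cl/Br-containing formulas at the default noise. The
measured M+1 is deliberately **not** used for carbon-count estimation:
single-quadrupole-resolution M+1 intensities are unreliable at the
~30% level on real instruments, so carbon bounds come from fragment
evidence instead.

### Nitrogen rule and constraint derivation

Even neutral nominal mass ⇒ even N count (valid over the supported
element set). Derived constraints, in order: target = precursor − 1;
aromatic marker fragments (77/91/103) raise min RDBE to 4; the 103
marker (C₈H₇⁺) forces C ≥ 8 and H ≥ 7; an ammonia loss
([M+H]⁺ − 17) marks a primary amine, so N ≥ 1 raised to the
nitrogen-rule parity; A+2 exclusions collapse bounds to (0,0); iodine is
dropped when target − 127 cannot fund the minimum carbon budget at
12 Da/C.

Default upper bounds are the generic small-NPS search space C ≤ 15,
H ≤ 20, N ≤ 4, O ≤ 2, F ≤ 1, extended with S ≤ 1, Cl ≤ 2, Br ≤ 2,
I ≤ 1 so that the *exclusion rules*, not the bounds, are what remove
those elements when the evidence warrants. There is no algorithm behind
"feasible atom ratios" at unit resolution — the bounds are configuration,
fully overridable per run.

### Enumeration

Production route: iterate the non-hydrogen element grid and solve H by
mass closure (exact at nominal resolution; a small tolerance window of H
counts in exact mode). Independent oracle: flat nested loops over every
element range with the same filters, used only in tests
(`brute_force_enumerate`); the two are asserted set-equal on random
instances. Output order is deterministic: descending RDBE, then Hill
string. Exact-mass mode (Da or ppm tolerance) supports HRMS inputs but
nominal mode is the default.

### Fragment annotation

For each fragment, *all* cation subformulas of [M+H]⁺ within the mass
tolerance (default 0.5 Da) and with RDBE ≥ 0.5 become assignments; a
unique-choice heuristic was deliberately rejected because at unit
resolution several chemically sensible formulas can share one integer
mass, and any single-pick rule (max RDBE, fewest heteroatoms,
mass-proportional scaling) demonstrably picks the wrong diagnostic ion
for at least one canonical case. Named neutral losses attach when the
complement left by an ion exactly equals a loss-table entry. The
packaged loss table ships H₂O 18, NH₃ 17, CH₅N 31, CO 28, HCN 27,
CH₃ 15 (radical, flagged) and C₂H₄ 28 and is user-extensible. The
printed tropylium composition in some sources ("C₇H₆⁺" at 91) is
mass-inconsistent (C₇H₆ = 90); the canonical C₇H₇⁺ is used.

Explanation coverage is the intensity-weighted fraction of fragment
signal with ≥ 1 assignment. It is monotone in the loss table and equals
the brute-force subformula oracle's verdict by construction (tested).

### Ranking and database

Composite = 0.3·isotope-fit + 0.5·coverage + 0.2·(DB hit), ties broken
by lower |RDBE − 6| then Hill string. Fragment evidence gets the largest
weight because it is what actually discriminates isobaric candidates;
the isotope score (cosine of the M+0..+2 vectors) mainly confirms the
hard exclusions; a database hit is a soft bonus — absence from the table
never eliminates a candidate, since NPS are by definition often novel.
The packaged table (`data/nps_compounds.csv`, v1, ~52 records) is a
frozen curated snapshot: tryptamines, benzofurans, phenethylamines,
cathinones, piperazines and common drugs of abuse. Identification stops
at the formula + isomer ambiguity set (e.g. C₁₁H₁₄N₂ → {AMT, 5-IT}).

## Synthetic data: what it does and does not emulate

The generator reproduces the statistical structure the pipeline
*assumes*: exact multinomial isotope clusters of [M+H]⁺; logistic
precursor survival in fragmentor voltage (midpoint 90 eV, width 15 eV)
times an ion-transmission factor falling linearly below 60 eV, which
places the precursor optimum at the interior voltage 70 eV; logistic
survival in collision energy (midpoint 20 eV, width 8 eV) with template
fragments growing as (1 − survival); multiplicative lognormal intensity
noise (default σ = 0.05, no m/z noise at unit resolution). Seeds are
explicit everywhere; no global random state. Quantitative in-source
fragmentation yields are instrument- and compound-specific and not
available here, so the logistic parameters are free simulation knobs,
chosen once for the interior-optimum behaviour, not empirical claims.

Not emulated: compound-specific fragmentation chemistry (templates are
compositional: applicable neutral losses plus aromatic marker ions that
fit the composition), fragment-ion isotope satellites, chromatography,
matrix ions, detector saturation, and CE-dependent *relative* fragment
intensities. Passing the synthetic benchmark therefore shows the
pipeline correctly inverts its own generative assumptions — not that it
handles every artifact of real instrument data.

The 20-case recovery benchmark samples compounds whose formulas are (a)
inside the default bounds and (b) not nominal-mass-degenerate with a
different in-bounds database formula (e.g. methamphetamine C₁₀H₁₅N and
cathinone C₉H₁₁NO, both 149). Two distinct same-mass database formulas
are genuinely undecidable at unit resolution without compound-specific
spectral libraries; the benchmark measures pipeline recovery, not that
irreducible ambiguity. Thirty-six eligible records (27 distinct
formulas) remain.

## Numerical choices

* Isotope patterns: per-element distributions convolved by binary
  exponentiation; prune threshold default 1e-6 (relative to base line),
  renormalized after pruning. Verified against explicit isotopologue
  enumeration to 1e-9 for all ≤5-atom formulas.
* Fragment mass tolerance 0.5 Da (unit resolution); exact mode default
  0.005 Da unless overridden.
* Cluster normalization fixes MH+0 = 100; a missing M+2 entry is treated
  as 0 with a warning.
* Degenerate inputs: empty spectra are retained with a warning; an
  all-zero spectrum cannot be normalized (error); contradictory bounds
  enumerate to an empty list, reported as "no candidates" (CLI exit 2).
* Problem sizes: the default benchmark is 20 cases; property tests use
  100 random enumeration instances, 200 simulated exclusion clusters and
  100 noise realizations for the precursor-call rate — sizes at which
  the checked quantities are already stable.

## Known limitations

* Formula-level only: no structure elucidation, no SMILES/InChI.
* Nominal-mass enumeration cannot separate isobars closer than 1 Da;
  exact-mass mode requires HRMS input.
* The A+2 rule tests single-atom thresholds; it cannot count atoms
  (Cl₂ vs Cl is left to the isotope-fit score).
* The precursor heuristic assumes the precursor survives at the lowest
  voltage; extreme in-source fragmentation that fully destroys [M+H]⁺
  yields a "no precursor" result requiring a manual override.
* mzML/vendor formats are not read; the exchange formats are the CSV
  dialect and a minimal MSP record.
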