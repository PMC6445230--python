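# npsid element table v1 (NIST standard isotope masses and abundances)
# columns: symbol,mass_number,exact_mass,abundance
symbol,mass_number,exact_mass,abundance
H,1,1.0078250319,0.999885
H,2,2.0141017779,0.000115
C,12,12.0000000000,0.9893
C,13,13.0033548378,0.0107
N,14,14.0030740052,0.99636
N,15,15.0001088984,0.00364
O,16,15.9949146221,0.99757
O,17,16.9991315000,0.00038
O,18,17.9991604000,0.00205
F,19,18.9984031630,1.0
S,32,31.9720707300,0.9499
S,33,32.9714585400,0.0075
S,34,33.9678668100,0.0425
S,36,35.9670808800,0.0001
Cl,35,34.9688527100,0.7576
Cl,37,36.9659026000,0.2424
Br,79,78.9183376100,0.5069
Br,81,80.9162906900,0.4931
I,127,126.9044730000,1.0
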