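# Proton CSDA ranges in liquid water at selected kinetic energies.
# Source: NIST PSTAR stopping-power and range tables for liquid water,
# https://physics.nist.gov/PhysRefData/Star/Text/PSTAR.html (retrieved 2026-09).
# csda_range_g_per_cm2 is numerically equal to range in cm of unit-density water.
energy_MeV,csda_range_g_per_cm2
50,2.227
60,3.093
70,4.080
80,5.184
90,6.398
100,7.718
125,11.46
150,15.77
175,20.68
200,25.96
225,31.76
250,37.94
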