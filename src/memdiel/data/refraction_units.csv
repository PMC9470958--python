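# Group-contribution molar refractions (cm^3/mol) of the chemical units of
# a phosphatidylcholine lipid at the three standard wavelengths (nm).
unit,R_468_3,R_589_3,R_653_3
CH3,5.719,5.653,5.636
CH2,4.695,4.647,4.624
COO,6.261,6.200,6.173
C,2.601,2.591,2.572
H,1.043,1.028,1.026
PO4,10.821,10.769,10.733
N,2.820,2.744,2.698
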