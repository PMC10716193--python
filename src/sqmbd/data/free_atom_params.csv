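# Free-atom reference parameters for the Tkatchenko-Scheffler scaling step.
# alpha0: static dipole polarizability (Bohr^3), Chu & Dalgarno (2004) /
#   TS reference set; C60: homoatomic dispersion coefficient (Ha*Bohr^6);
# rvdw0: free-atom van der Waals radius (Bohr), from the TS reference set.
element,alpha0,c60,rvdw0
H,4.50,6.50,3.10
C,12.00,46.60,3.59
N,7.40,24.20,3.34
O,5.40,15.60,3.19
F,3.80,9.52,3.04
P,25.00,185.00,4.50
S,19.60,134.00,4.03
Cl,15.00,94.60,3.71
Se,28.90,210.00,4.21
Br,20.00,162.00,3.93
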