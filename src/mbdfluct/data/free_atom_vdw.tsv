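# Free-atom van der Waals reference data (Hartree atomic units).
# alpha0: static dipole polarizability (Bohr^3)
# c6: homoatomic dispersion coefficient (Ha Bohr^6)
# rvdw: free-atom van der Waals radius (Bohr)
# element	alpha0	c6	rvdw
H	4.500	6.50	3.10
He	1.38	1.46	2.65
C	12.00	46.6	3.59
N	7.40	24.2	3.34
O	5.40	15.6	3.19
F	3.80	9.52	3.04
Ne	2.67	6.38	2.91
Si	37.00	305.0	4.20
P	25.00	185.0	4.01
S	19.60	134.0	3.86
Cl	15.00	94.6	3.71
Ar	11.10	64.3	3.55
Br	20.00	162.0	3.93
I	35.00	385.0	4.17
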