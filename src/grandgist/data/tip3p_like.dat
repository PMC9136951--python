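# Rigid three-site water model (TIP3P-like parameters).
# Units: Å, e, kJ/mol.  Local frame: O at origin, H atoms in the xy-plane,
# dipole along +y.  O-H 0.9572 Å, H-O-H 104.52 deg.
name TIP3P-like
rho0 0.0329
# site  kind           x          y         z       charge    sigma     epsilon
site  water_oxygen    0.000000   0.000000  0.0     -0.834    3.15061   0.6364
site  water_hydrogen  0.756950   0.585882  0.0      0.417    0.0       0.0
site  water_hydrogen -0.756950   0.585882  0.0      0.417    0.0       0.0
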