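# Rigid four-site water model (TIP4P-like parameters) with a massless
# charge-carrying virtual site M on the H-O-H bisector, 0.15 Å from O.
# Units: Å, e, kJ/mol.
name TIP4P-like
rho0 0.0332
# site  kind           x          y         z       charge    sigma     epsilon
site  water_oxygen    0.000000   0.000000  0.0      0.0      3.15365   0.6480
site  water_hydrogen  0.756950   0.585882  0.0      0.52     0.0       0.0
site  water_hydrogen -0.756950   0.585882  0.0      0.52     0.0       0.0
site  water_virtual   0.000000   0.150000  0.0     -1.04     0.0       0.0
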