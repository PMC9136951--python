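# Single-site neutral Lennard-Jones probe "water" for toy cavity systems:
# keeps grand-canonical titrations interpretable (one well = one water)
# while exercising the full rigid-molecule machinery.
name LJ-probe
rho0 0.0329
# site  kind           x    y    z    charge   sigma    epsilon
site  water_oxygen    0.0  0.0  0.0   0.0     3.150    0.650
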