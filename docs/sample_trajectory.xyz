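4
P=4 n_atoms=1 time_index=0 timestep=0.5 length_unit=angstrom beta=1.0 hbar=1.0
H 0 0 0.111328125 0.03125 0.046875
H 0 1 0.099609375 0.01953125 0.0703125
H 0 2 0.083984375 -0.068359375 -0.111328125
H 0 3 -0.05078125 -0.0546875 0.09375
4
P=4 n_atoms=1 time_index=1 timestep=0.5 length_unit=angstrom beta=1.0 hbar=1.0
H 0 0 0.103515625 -0.125 0
H 0 1 0.080078125 -0.09375 0.07421875
H 0 2 -0.095703125 -0.0078125 0.080078125
H 0 3 -0.048828125 -0.0390625 -0.056640625
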