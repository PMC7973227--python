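# Trajectory file format

## Bead extended-XYZ dialect (`.xyz`)

One block per snapshot:

```
<n_atoms * P>                      # number of coordinate lines that follow
P=<int> n_atoms=<int> time_index=<int> timestep=<float> length_unit=<label> beta=<float> hbar=<float> [box="Lx Ly Lz"]
<atom_type> <atom_id> <bead_index> <x> <y> <z>
...
```

- Every atom contributes exactly `P` consecutive-or-interleaved lines per
  block; `bead_index` runs 0..P−1 and encodes the cyclic ring order.
- `length_unit` is a label (e.g. `angstrom`, `bohr`); the package never
  converts units, all radii and distances inherit this unit.
- `box` is optional; when present, frames are unwrapped (chained
  minimum-image from bead 0) before any shape analysis.
- Coordinates are written with 17 significant digits so that
  read(write(T)) reproduces them to better than 1e−12.
- `atom_id` identifies an atom across snapshots and must keep a constant
  `atom_type`.

A 1-atom, P=4, N=2 example lives at [`sample_trajectory.xyz`](sample_trajectory.xyz).

## Columnar CSV

The same content as a flat table, for spreadsheet/pandas workflows:

```
# P=4 timestep=0.5 length_unit=angstrom beta=1.0 hbar=1.0
time_index,atom_id,atom_type,bead_index,x,y,z
...
```

The leading comment line carries the configuration. `read_trajectory(path,
format="csv")` / `write_trajectory(traj, path, format="csv")` handle it.

## Derived outputs

- Barcodes: JSON `{dimension, bars: [[birth, death], ...], truncated:
  [bool, ...], r_max}` with `"inf"` for the essential component's death.
- Betti sequences: CSV rows `atom_id, time_index, h(r_0), ..., h(r_M)`.
- WD series: CSV `atom_id, t, wd` (entry t compares snapshots t and t+1).
- PCA scores: CSV `pc1, pc2, ..., class`.
- PT windows: CSV `h_atom_id, t_start, t_end, label, donor, acceptor`.
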