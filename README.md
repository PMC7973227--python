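# ringtop

Topological shape analysis of path-integral ring polymers.

In imaginary-time path-integral simulations (PIMD, RPMD, TRPMD) every atom
is represented by a closed "ring polymer" of P beads; its spatial spread
encodes the quantum uncertainty of the atom's position. Classical shape
metrics — gyration radius R_g, the gyration tensor with asphericity b,
acylindricity c and shape anisotropy κ², bead-distance distributions, the
imaginary-time mean-square displacement — summarize the *instantaneous*
spread. `ringtop` adds the *time-fluctuation of shape*: each bead cloud is
summarized by the β₁ barcode of its Vietoris–Rips filtration (loops born
and filled as a ball of radius r grows at every bead), the barcode becomes
a Betti sequence h(r) and then a probability distribution over intersection
counts 0..B₁, adjacent snapshots are compared with the 1-D Wasserstein
(earth mover's) distance under the bin cost d_ij = |i−j|,

    WD = [wd_{1,2}  wd_{2,3}  ...  wd_{N-1,N}],

and sliding-window Fourier spectra of the WD series, reduced by PCA,
fingerprint how violently an atom's delocalization fluctuates. Atom
populations with different nuclear quantum behavior — a delocalized vs a
localized species, or proton-transferring vs inert hydrogens — separate in
these fingerprints even when their static R_g values are indistinguishable.

The package is aimed at practitioners of path-integral simulation who want
to *identify* atoms with interesting quantum behavior before committing to
a reaction coordinate: the library computes every stage, a CLI drives the
standard pipelines, and a seeded synthetic generator makes the whole thing
testable without any trajectory download.

## Worked example

```python
import numpy as np
import ringtop as rt
from ringtop import persistence as ph, transport as tr, synthetic as syn

# one loop: born when neighboring balls touch (r = 1/2),
# filled at the diagonal (r = sqrt(2)/2)
bc = rt.vr_barcode(rt.make_toy_cloud("unit_square"))
print("square bars:", bc.bars)

# earth mover's distance between two Betti distributions, cost |i-j|
K = np.array([0.1, 0.2, 0.2, 0.5]); L = np.array([0.0, 0.4, 0.4, 0.2])
print("WD:", rt.wasserstein_lp(K, L).total_cost)

# a small two-population fixture: loose (A) vs tight (B) ring polymers
spec = syn.glass_spec(seed=0, n_atoms=4, n_snapshots=120)
traj = syn.make_two_population_trajectory(spec)
dists, b1 = ph.trajectory_betti_distributions(traj)
vecs = {a: tr.wd_series(dists[a], atom_id=a) for a in traj.atom_ids}
summary = tr.wd_population_summary(
    {c: [vecs[a] for a in traj.atoms_of_type(c)] for c in "AB"})
print(f"B1 = {b1}")
print(f"mean WD: A = {summary.means['A']:.4f}, B = {summary.means['B']:.4f}")
print(f"histogram overlap = {summary.overlap:.3f}")
```

prints

```
square bars: [[0.5        0.70710678]]
WD: 0.49999999999999983
B1 = 9
mean WD: A = 0.0393, B = 0.0023
histogram overlap = 0.023
```

The unit square's single loop lives on the radius interval [1/2, √2/2].
The WD of 0.5 decomposes into three moves — 0.1 mass over one bin, 0.1
over two bins, 0.2 over one bin (0.1 + 0.2 + 0.2). In the fixture, the
loose population's shape changes roughly 17× more per snapshot than the
tight one's (0.039 vs 0.002 in bin-distance units), and the two WD
histograms barely overlap (2.3%) — the contrast the fluctuation metrics
are designed to expose.

## Command line

```sh
ringtop simulate --preset glass --seed 1 --out run/     # synthetic fixture
ringtop static   --traj run/trajectory.xyz --out run/   # R_g, b, c, kappa^2, iMSD
ringtop barcode  --traj run/trajectory.xyz --out run/   # barcodes + Betti sequences
ringtop wd-series --traj run/trajectory.xyz --out run/  # per-atom WD vectors
ringtop spectra  --traj run/trajectory.xyz --out run/ --plot
ringtop label-pt --traj run/trajectory.xyz --out run/   # PT / non-PT windows
```

All commands accept `--config params.yaml` (radius grid, window width,
cutoffs) and write CSV/JSON; the trajectory dialect is documented in
[docs/format.md](docs/format.md) and the models in
[docs/methods.md](docs/methods.md).

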