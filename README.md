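# gamdkit

Toy-scale Gaussian-accelerated Langevin sampling and trajectory analysis.

The package implements, on analytic potentials and synthetic trajectories
with known ground truth, the complete computational pipeline of a
boosted-dynamics conformational study:

- **`gamdkit.toy_systems`** — synthetic inputs with exact references:
  quartic double wells and 2-D multi-well surfaces with closed-form
  Boltzmann densities, protein-like ensembles with planted collective
  modes (known covariance eigenstructure), two-state ensembles with known
  populations, hydrogen-bond fixtures with exact geometry, and multi-model
  PDB / XYZ trajectory I/O.
- **`gamdkit.gamd`** — BAOAB Langevin integration in conventional and
  boosted mode.  The boost adds `dV = k/2 (E - V)^2` below a threshold
  energy `E`, with `(E, k, k0)` derived from the conventional run's
  potential-energy statistics (`Vmax`, `Vmin`, `Vavg`, `sigma_V`) under
  either the lower-bound (`E = Vmax`) or upper-bound (`E = Vmin + 1/k`)
  rule, controlled by the user ceiling `sigma0`.
- **`gamdkit.reweighting`** — unbiased probability densities and
  potentials of mean force over 1–2 reaction coordinates via
  exponential-average or second-order cumulant reweighting of the
  per-frame boost, plus watershed-based energy-basin detection
  (basins labeled `EB1`, `EB2`, … by ascending free energy).
- **`gamdkit.structure_metrics`** — Kabsch superposition, RMSD series,
  RMSF / ΔRMSF about the iteratively aligned mean, radius of gyration,
  distance reaction coordinates, and peak-reporting probability
  distributions.  Selections use a small mini-language
  (`"name CA"`, `"protein and not element H"`, `"resid 30-40"`).
- **`gamdkit.collective_motions`** — PCA of the aligned-coordinate
  covariance (1/n normalization) with variance fractions, porcupine-style
  mode export, and dynamic cross-correlation maps in [-1, 1].
- **`gamdkit.interaction_network`** — geometric hydrogen bonds
  (D–A distance < 3.5 Å **and** acceptor–H–donor angle > 120°, both
  strict) with percent occupancy, salt-bridge / ion-coordination distance
  series, ring- and group-centroid distances, and manifest-driven
  interaction tables.

Units are fixed package-wide: Å, ps, kcal/mol, amu, K
(`kT = 0.0019872041 · T`). Indices are 0-based in the API and 1-based in
files and CLI output.

## CLI

All functionality is exposed through the `gamdkit` entry point:

```bash
# generate a double-well spec and sample it with a boost
gamdkit synth --kind double-well --out dw.yaml
gamdkit simulate --potential dw.yaml --mode gamd --sigma0 2.4 \
    --steps 2000000 --stride 100 --seed 1 --mass 1.0 --out traj.tsv

# reweighted free-energy profile + basins
gamdkit fel --table traj.tsv --rc1 x1 --method cumulant2 --out fel.tsv

# synthetic ensembles and their analyses
gamdkit synth --kind planted --n-particles 30 --n-frames 5000 --out t.pdb
gamdkit pca --traj t.pdb --n-modes 6 --scree scree.tsv --porcupine mode1.pdb
gamdkit dccm --traj t.pdb --out dccm.tsv
gamdkit metrics --traj t.pdb --measure rmsf --select "name CA" --out rmsf.tsv

# interaction occupancies from a manifest
gamdkit synth --kind hbond-fixture --n-frames 1000 --out hb.pdb
gamdkit interactions --traj hb.pdb --manifest manifest.yaml --out table.tsv
```

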