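# asdkit

Trajectory analysis for protein-stabilized amorphous solid dispersions:
given a molecular trajectory (periodic orthorhombic box) and a topology with
donor/acceptor annotations, the package computes

* **hydrogen-bond networks** — geometric detection (0.35 nm / 30°, both
  angle-vertex conventions), boolean existence matrices, strict
  occupancy-threshold stability classification (>80% protein–drug, >50%
  otherwise), breadth-first "generation" tracing of drug molecules from the
  protein, and per-residue bond rankings with a >10% major-contributor flag;
* **contact shells** — per-molecule minimal distances to the protein (both
  center-of-mass and nearest-atom definitions), 0.4 nm-wide shell indices,
  first-drug-shell flags, minimal-distance histograms, second-layer
  fractions, and radial distribution functions;
* **mobility** — unwrapped per-molecule center-of-mass paths, protein-frame
  motion subtraction, FFT-based mean-squared displacements, Einstein-relation
  diffusivity fits (reported in 10⁻⁹ cm²/s), group means (by shell, by
  bonding status, with exclusion sets), cumulative diffusivity-contribution
  curves with the 90%-crossing level, and 1/5/10 Å displacement classes;
* **composition planning** — integer molecule counts from target weight
  fractions (dry and 5 wt%-water schemes, 15-entry reference grid);
* **synthetic data** — a Brownian-dynamics generator with planted ground
  truth (assigned diffusivities, harmonic tethers, protein drift, exact
  scheduled H-bond occupancies, two-layer shell fixtures) so every analysis
  stage can be validated without any MD engine.

Supported on-disk formats are plain text: multi-frame GRO, an extended-XYZ
dialect (`Lattice=...` / `Time=...` header, coordinates in nm), and a
tab-separated topology sidecar. Internal units are nm / ps / Da.

## CLI

All functionality is reachable through the `asd` command:

```sh
# plan a composition
asd plan --drug-wt 47.5 --water-wt 5 --n-protein 4

# the 15-entry reference composition grid
asd grid

# generate synthetic data with planted ground truth
asd synth --preset two-layer --seed 7 --out traj.extxyz --top top.tsv --truth truth.json
asd synth --preset brownian --seed 1 --n-drug 20 --n-frames 500 --drug-d 0.5 \
    --out traj.extxyz --top top.tsv

# individual stages
asd shells   --traj traj.extxyz --top top.tsv --out shells.tsv
asd hbond    --traj traj.extxyz --top top.tsv --window last:200 --out hbonds/
asd mobility --traj traj.extxyz --top top.tsv --fit 0.1:0.5 --out mobility.tsv

# full pipeline from one declarative config
asd run --config run.yaml
```

A minimal `run.yaml`:

```yaml
traj_path: traj.extxyz
top_path: top.tsv
window: "last:2000"
out_dir: out
```

`asd run` writes a shell table, existence matrix (+ JSON index), stable-bond
set, generation assignments, residue ranking, per-molecule diffusivity
records, group summaries, distance and diffusivity histograms, a
shell × bonding-status cross-tabulation, and a `manifest.json` echoing every
parameter. Exit codes: 0 success, 2 config error, 3 stage failure.

## Layout

```
src/asdkit/
  model.py        core types, minimum-image geometry, unwrapping
  io.py           GRO / extended-XYZ / topology-sidecar readers and writers
  composition.py  weight-fraction -> molecule-count planner
  synthetic.py    Brownian generator with planted ground truth
  hbond.py        detection, existence matrices, stability, generations
  spatial.py      minimal distances, shells, layers, RDF
  mobility.py     MSD, diffusivity fits, grouping, displacement classes
  pipeline.py     one-config orchestration
  cli.py          the `asd` command
```
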