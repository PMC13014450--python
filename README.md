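# thermotraj

Analysis toolkit for comparing the thermal stability of proteins from
molecular-dynamics trajectories, built around the descriptor set used in
hyperthermophile/mesophile CheY comparisons (TmY vs EcY):

- **Global descriptors** — Kabsch superposition and RMSD, radius of
  gyration, and the smooth-switching fraction of native contacts
  (β = 5 Å⁻¹, λ = 1.8, 4.5 Å heavy-atom cutoff, sequence separation > 3).
- **Local descriptors** — per-residue RMSF, a self-contained DSSP-style
  secondary-structure assignment (H/G/I/E/B/T/C) with the three-class
  collapse {H,G,I}→α, {E}→β, rest→coil, element persistence, and
  Ile/Leu/Val composition per class.
- **Interactions** — geometric hydrogen bonds (donor–acceptor ≤ 3.5 Å,
  angle at the donor ≤ 30°; HBpp/HBps modes), salt bridges (min
  basic-N/acidic-O distance ≤ 4.0 Å), replica-averaged frequencies,
  stability classes (high ≥ 0.75, moderate ≥ 0.50, low ≥ 0.30,
  negligible below), formed-pair filtering (mean ≥ 0.30),
  dyad/triad/tetrad network motifs, and non-native bridge emergence.
- **Replica statistics** — pooled series (3 × 10,001 frames → 30,003
  values), Tukey boxplot summaries, and percent-change arithmetic.
- **Synthetic generators** — seeded toy structures (ideal helix,
  antiparallel hairpin, extended strand, mini α/β fold with engineered
  charge pairs) and trajectories with known ground truth (rigid motion,
  Gaussian fluctuation, monotone expansion, prescribed contact
  fractions, engineered protein–water hydrogen bonds) so every analysis
  stage has a desk-scale parameter-recovery test.

Structures and trajectories are read and written as (multi-model) PDB;
lengths are Å internally and nm in reports.

## CLI

```sh
thermotraj synth helix --n-residues 12 --out helix.pdb
thermotraj synth trajectory helix.pdb --mode fluctuation --n-frames 100 --out traj.pdb
thermotraj rmsd traj.pdb --selection ca --out rmsd.csv
thermotraj gyrate traj.pdb
thermotraj qnative traj.pdb
thermotraj rmsf traj.pdb
thermotraj hbonds traj.pdb --mode pp
thermotraj saltbridges rep1.pdb rep2.pdb rep3.pdb --classify --networks nets.json
thermotraj ss traj.pdb --content-out content.csv
thermotraj report config.yaml
```

`report` runs the full per-protein, per-temperature pipeline from a YAML
config (see `thermotraj.aggregate.run_pipeline` for the schema) and
emits descriptor CSVs, pooled summary tables, SS content, hydrogen-bond
counts, salt-bridge frequencies with networks, a comparison table and a
run log of every threshold used.

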