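# nucleofold

Quantitative analysis of nucleosome-array architecture from 3D nucleosome
pose models, and a coarse-grained mesoscale Monte Carlo simulator of
chromatin fibers with irregular linker-length profiles.

The package covers the full pipeline used to compare immature (PN1) and
mature (PN56) retina chromatin:

- **`synth`** — calibrated synthetic-data generators: linker-length
  mixtures matched to the published PN1/PN56 statistics (means 30.7/42.6
  bp, SDs 24.1/22.6 bp, negative-linker fractions 10.7%/3.2%), 3D array
  scenes with traced open-DNA paths, contact-injected scenes with known
  ground truth, and fiber templates for the simulator.
- **`stereology`** — per-nucleosome descriptors: center-to-center distance
  D to the next nucleosome, distance N to the nearest nucleosome in 3D,
  bend angle alpha, plane angles beta and para (folded to [0, 90]);
  boundary and unresolved-linker exclusion rules; stacked-nucleosome
  fractions; per-sample summaries with Welch-t / KS tests.
- **`linkers`** — open-DNA tracing calculus: traced polyline length O (bp
  at 0.34 nm/bp), peels S/E, signed linker length L = O − S − E,
  constrained core length C = 146 − S − E per core, per-array averages,
  NRL estimates, and C-vs-L correlation checks.
- **`contacts`** — nearest-neighbour contact classification into i±k /
  trans / none categories at the 11 nm threshold (trans confirmed by the
  28 nm terminal-distance rule), fold changes between crosslinked and
  control spectra, and the same classification applied to simulated
  ensembles.
- **`mesoscale`** — rigid nucleosome cores with surface pseudo-charges,
  histone-tail chains and linker-histone beads; linker DNA at 3.0 nm bead
  spacing (8.8 bp/bead, `round(bp / 8.8235)` beads per linker); harmonic
  stretch, discrete worm-like-chain bending, Debye–Hückel electrostatics
  (monovalent screening `0.304/sqrt(c[M])` nm; implicit Mg via a DNA–DNA
  screening override and 50→30 nm persistence length), soft capped
  excluded volume, zero-linker 3 nm springs; Metropolis sampling with
  bead / rigid-core / pivot / crankshaft moves and burn-in auto-tuning.
- **`sim_observables`** — packing ratio (nucleosomes per 11 nm of
  principal fiber axis), i±k interaction profiles from the full pairwise
  contact matrix, linker-DNA stem indices (pairs of mean bead positions
  < 2.5 nm; eligibility requires both linkers > 26 bp), fan-plot
  positional distributions in the core body frame, and tail-partner
  fractions.

## CLI

```bash
nucleofold synth --sample PN1 --n-arrays 50 --seed 11 --out-dir out
nucleofold stereology --poses out/PN1_poses.tsv --out-dir out
nucleofold linkers --poses out/PN1_poses.tsv --paths out/PN1_paths.tsv --out-dir out
nucleofold contacts --poses out/PN1_poses.tsv --out-dir out
nucleofold simulate --sample PN56 --replicates 2 --frames 200 --out-dir out
nucleofold analyze-sim --sample PN56 --replicates 3 --frames 100 --out-dir out
```

Global flags: `--config` (YAML; see `nucleofold.io_model.RunConfig` for
the schema and defaults), `--seed`, `--out-dir`, `--log-level`.  Tables
are UTF-8 TSV; simulated ensembles are written as multi-model PDB files
(one MODEL per configuration, pseudo-atoms typed by bead kind);
summaries are JSON.

## File formats

- **pose tables** (`*_poses.tsv`): `sample_id, tomogram_id, array_id,
  nuc_index, x_nm, y_nm, z_nm, nx, ny, nz, near_boundary,
  linker_to_next_resolved`.  Chain indices are 1-based; linker *i*
  connects nucleosomes *i* and *i + 1*; plane normals are unit vectors.
- **path tables** (`*_paths.tsv`): `array_id, linker_index, S_bp, E_bp,
  resolved, points` with the polyline serialized as
  `x,y,z;x,y,z;...` in nm.
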