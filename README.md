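# ciliaxis

Filament-level post-processing for subtomogram-averaged microtubule data.
The package implements the analysis stages that sit downstream of
subtomogram alignment/classification of continuous filaments (basal-body
triplet and axonemal doublet microtubules):

- **Continuity-constrained pose correction** — per-filament RANSAC over
  per-axis polynomials in segment index detects gross misalignments,
  corrects isolated outliers by trajectory interpolation, and discards
  filaments that fail wholesale (`ciliaxis.trajectory_ransac`).
- **Longitudinal class mapping** — arc-length back-tracking of classified
  segments, per-region per-class binned histograms, the weighted-average
  transition statistic `L = Σ j·Nj / Σ Nj` (converted to nm via bin
  centers), per-organelle dot maps, and a run-length permutation test for
  assembly cooperativity (`ciliaxis.longitudinal_mapping`).
- **Lattice geometry** — Kabsch superposition of paired point models, the
  inter-protofilament rotation angle, inner-junction width RMSD after
  superposing on a reference protofilament, and occupancy periodicity /
  register detection on 8-nm base repeats (`ciliaxis.lattice_geometry`).
- **Synthetic data** — deterministic generators for nine-filament barrels,
  pose corruption with planted outliers, logistic class-label fields,
  binary occupancy tracks, and protofilament lattices with prescribed
  junction angles, so every stage is testable without external data
  (`ciliaxis.synthetic_data`).
- **Domain types and I/O** — segment records (nm, scalar-first unit
  quaternions), filaments, region/bin specs, point models (Å); canonical
  CSV/TSV and STAR particle tables (RELION-style tags accepted on read),
  PDB or CSV point models (`ciliaxis.core_model`).
- **Pipeline driver** — `simulate → ransac → map → geometry` with a
  deterministic JSON report (`ciliaxis.pipeline`).

## CLI

```sh
# synthetic ground truth, labels, corruption
ciliaxis simulate barrel --n-filaments 9 --length 450 --out truth.csv
ciliaxis simulate labels --in truth.csv --center 130 --out labeled.csv
ciliaxis simulate corrupt --in labeled.csv --outlier-fraction 0.1 --out noisy.csv

# continuity correction (writes corrected poses with arc-length s_nm)
ciliaxis ransac --in noisy.csv --out corrected.csv --report qc.csv

# histograms, weighted-average positions, per-organelle dot maps
ciliaxis map --in corrected.csv --out histograms.csv --maps maps.csv

# geometry
ciliaxis simulate lattice --n-pf 13 --out models.csv
ciliaxis geometry angle --models models.csv
ciliaxis geometry width --model1 a.csv --model2 b.csv
ciliaxis simulate occupancy --length 960 --period 48 --out occ.csv
ciliaxis geometry period --in occ.csv

# full pipeline with a YAML config
ciliaxis run --config config.yaml --out outdir
```

## Conventions worth knowing

- Pose noise sigmas are RMS magnitudes of the 3-D perturbation (per-axis
  sigma is `sigma/√3`).
- Bins are half-open with the final bin closed; `L_nm` uses the bin-center
  convention `start + (L − 0.5)·width`.
- Inter-protofilament angles are reported unsigned in [0°, 180°]; the
  handedness (counter-clockwise positive viewed from the plus end) is
  available via `inter_pf_angle_signed`.
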