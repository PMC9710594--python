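# codes-scoring

Scoring and classification of protein–protein docking decoys: CAPRI-style
quality assessment, consensus interface features, balanced/capped dataset
construction, and a class-weighted random-forest classifier with forward
feature selection.

## What it does

* **structure_io** — reads two-body complexes from PDB with an explicit
  receptor/ligand chain partition (auto-partition: larger body = receptor);
  HETATM/waters excluded, altlocs collapsed to highest occupancy.
* **geometry** — residue contacts (5 Å), interface residues (10 Å), clash
  counting (3 Å, heavy atoms, strict `<`), Kabsch superposition and RMSD.
* **capri** — fnat, L-rms (ligand backbone RMSD after receptor fit), I-rms
  (native-interface backbone RMSD after interface fit), the four-level
  quality classification (configurable thresholds), and the per-target
  mean + 2·SD clash screen.
* **features** — consensus contact score (mean ensemble frequency of a
  decoy's contacts), 21 residue-class contact counts, buried surface area
  (Shrake–Rupley, total/polar/apolar), non-interacting-surface composition,
  plus ingestion/cleaning (>30 % missing → drop; per-target mean imputation)
  and z-score normalization of external feature tables.
* **datasets** — balanced (1:1 per target) and capped-unbalanced
  (3000/target, ≤600 correct) manifests; deterministic benchmark-tag and
  repeated-random target-level splits; per-target PRNG substreams.
* **classifier** — random forest with class weights applied as sample
  weights (defaults: 100 trees, min-split 10, weights 1.2/0.1),
  importance-driven forward feature selection, coordinate-wise tuning,
  vote-fraction scoring and decoy ranking.
* **evaluation** — per-class precision/recall/accuracy/F1/MCC and top-N
  success reports with the acceptable/medium/high tier breakdown.
* **synthetic** — seeded toy complexes and rigid-body-perturbed decoy
  ensembles with planted quality tiers and clash outliers, plus feature
  tables with stated class-conditional Gaussians; the offline test surface
  for everything above.

## CLI

```sh
codes simulate --seed 5 --targets 2 --out sim/
codes assess --native sim/T000/native.pdb --decoys sim/T000/decoys \
    --receptor A --ligand B --target T000 --out T000.tsv
codes featurize --decoys sim/T000/decoys --receptor A --ligand B \
    --target T000 --out feats_T000.tsv
codes build-dataset --assessment T000.tsv --assessment T001.tsv \
    --scheme balanced --seed 3 --out bal.tsv
codes train --manifest bal.tsv --features feats.tsv \
    --validation-targets T001 --select-threshold 0.01 --out model/
codes rank --model model/ --features feats.tsv --out ranking.tsv
codes evaluate --model model/ --manifest bal.tsv --features feats.tsv \
    --out report.json
```

Every command writes a `run_manifest.json` (config + SHA-256) next to its
artifacts, and all sampling is reproducible from the given seed.

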