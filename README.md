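# apoescreen

Screening analytics for **ApoE4 structure correctors** — small molecules that
bind the Trp34 pocket of apolipoprotein E4 (the strongest genetic risk factor
for late-onset Alzheimer's disease) and flip its Trp34 sidechain back to the
benign, ApoE3-like "flip-in" orientation.

The package is written for computational chemists running ensemble
virtual screens: it implements the rank-aggregation, triage and geometric
analytics around the docking/shape/MD engines, together with seeded synthetic
generators for every input class, so the whole pipeline is testable without
any engine or database download.

## The core statistic

Docking a library against an ensemble of ApoE structures shows a sign
pattern: binding ranks on **holo**-ApoE4 structures (stabilizer-bound, pocket
open) correlate *positively* with experimental affinity, while ranks on
**free**-ApoE4 structures (Trp34 flipped out, pocket closed) correlate
*negatively*. The consensus score rewards compounds on the right side of both
signals:

```
consensus = mean(rank on holo-ApoE4) / mean(rank on free-ApoE4)      (lower = better)
```

Around it the package provides:

- `geometry.triage_structures` — receptor shortlisting (X-ray ≤ 2 Å,
  non-mutant, Trp34 orientation consistent with isoform);
- `consensus.build_consensus_table`, `correlation_diagnostics`,
  `enrichment` — rank aggregation and its diagnostics against (censored) Kd;
- `consensus.combine_shape_queries`, `intersect_hitlists`, `kd_triage` —
  shape-screening combination, hitlist intersection, binding-table triage;
- `interactions.detect_hbonds` / `detect_pi_stacking` / `pocket_occupancy` /
  `build_checklist` — geometric interaction checklists on coordinates;
- `geometry.classify_flip`, `chi_angles`, `kabsch_superpose`, `rmsd_series`,
  `flip_fraction` — Trp34 flip classification and trajectory observables;
- `synthetic.gen_screen` / `build_pose_complex` / `gen_flip_trajectory` —
  seeded generators emulating the docking screen, toy pocket poses and
  two-state flip trajectories;
- `io` — Vina-style logs, censoring-aware Kd tables ("<5", ">100",
  "No binding"), PDB coordinates, score/checklist tables.

## Worked example

Rank the eight known ApoE4 stabilizers (bundled benchmark: PubChem CIDs with
their docking ranks against the six-structure ensemble and NMR Kd values):

```python
from apoescreen import datasets
from apoescreen.consensus import (build_consensus_table, consensus_frame,
                                  correlation_diagnostics, intersect_hitlists)

matrix = datasets.load_known_ligand_ranks()          # 8 ligands x 6 structures
table = consensus_frame(build_consensus_table(matrix))
print(table.to_string(index=False))
```

```
ligand_id  avg_holo_rank  avg_free_rank  consensus_score  consensus_rank
155557185        43.0000       512.0000           0.0840          1.0000
155563897        39.0000       407.0000           0.0958          2.0000
155511476       103.0000       800.5000           0.1287          3.0000
155552638        92.5000       662.0000           0.1397          4.0000
155538646       132.0000       701.5000           0.1882          5.0000
137796780        55.0000       270.0000           0.2037          6.0000
 83673143       793.0000      1011.0000           0.7844          7.0000
155530661       545.5000       194.5000           2.8046          8.0000
```

The ratio of average holo rank to average free rank orders the compounds by
affinity almost perfectly: the strongest binders (Kd ≤ 8 µM: 155557185,
155511476, 155538646) head the list, the non-binding 900 µM fragment
(83673143) and the outlier 155530661 fall to the bottom. Against the measured
Kd values the consensus score is near-perfectly concordant:

```python
kd = [r for r in datasets.load_known_ligand_kd() if r.ligand_id != "83673143"]
print(correlation_diagnostics(matrix, kd, method="pearson").consensus)
# 0.9940632792654913
print(intersect_hitlists(datasets.DOCKING_TOP25, datasets.SHAPE_TOP25, n=25))
# ['193679']
```

193679 is Isobavachin, the prenylated flavonoid that the combined
docking/shape screen singles out as the one compound in both top-25 lists.

A full synthetic pipeline run (screen simulation → consensus → shape
combination → intersection → interaction checklist → trajectory analytics):

```sh
apoescreen run --seed 7 --out demo-run/
# completed 6 stages in 0.53 s; report at demo-run/report.json
```

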