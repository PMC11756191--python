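# tadfuse

Two-condition Hi-C comparison for studying 3D-genome reorganisation during
malignant transformation — the setting where an indolent B-cell leukaemia
(CLL-like) sample and its transformed aggressive-lymphoma (DLBCL-like)
counterpart are profiled by chromosome conformation capture and the analyst
asks: *what changed in the chromatin architecture, and which differentially
expressed genes sit where it changed?*

The package covers the full analysis stack at three scales, plus expression
integration:

* **Matrix scale** — ICE (iterative-correction) balancing with a mad-max
  coverage filter, expected-by-distance and observed/expected (O/E)
  transforms, contact-probability curves `P(s)` with log-log slope fitting
  and detection of the distance where two conditions' curves cross, matrix
  coarsening (100 kb → 1 Mb) and per-pair `log2` differential maps.
* **Compartment scale** — A/B compartment eigenvector (leading eigenvector
  `E1` of the per-chromosome Pearson correlation of O/E rows, sign-anchored
  to an orientation track), StableAA / StableBB / SwitchAB / SwitchBA
  classification between conditions, saddle plots over genome-wide `E1`
  quantiles, and AA/BB/AB compartment strengths
  `overall = log2(AA·BB/AB²)`.
* **TAD scale** — diamond insulation scores
  `score(i) = log2(diamond mean / chromosomal geometric mean)`, boundary
  calling at strong local minima, tiling TAD segmentation, intra- vs
  inter-TAD contact ratios, aggregate TAD analysis (rescaled average
  domain pile-up), and **TAD-fusion detection**: condition-2 domains that
  span several condition-1 domains whose separating boundary disappeared.
* **Integration** — map a differential-expression gene (DEG) table by TSS
  onto the bin axis, classify every gene as *boundary* / *merged-TAD* /
  *other*, report the all/up/down boundary fractions and the UPG^TAD /
  DWG^TAD gene sets, and test enrichment with hypergeometric 2×2 tables
  (Haldane-corrected odds ratios, Benjamini–Hochberg q-values).

Because patient Hi-C and scRNA-seq data of this kind are typically not
deposited, the package ships a first-class **synthetic-data generator**:
contact matrices with power-law distance decay, an aperiodic A/B
checkerboard, TAD blocks, and a derived "transformed" condition with
planted TAD fusions, compartment switches, TAD compaction, a steeper decay
exponent and boosted B–B contacts — all with machine-readable ground truth,
so every stage is testable end to end.

## Worked example

Run the default synthetic transformation analysis (4 × 50 Mb chromosomes at
100 kb bins, 10⁷ expected cis contacts, 4 planted TAD fusions, 40 planted
compartment switches, 2000 DEGs with 5-fold up-gene enrichment in fused
TADs):

```bash
tadfuse run --outdir out --seed 1
# fusion events: 4; crossover: 635777.2899593043; boundary DEG fraction: 0.045
```

`out/report.json` then contains, among other metrics (seed 1):

| metric | value | meaning |
| --- | --- | --- |
| `ps_crossover_bp` | `635777` | the two `P(s)` curves cross at ≈ 0.64 Mb; the transformed condition is higher on the proximal side (gained short-range contacts) |
| `bb_strength_change` | `+0.216` | B–B saddle-corner strength increased in condition 2 |
| `fusion_count` / `lost_boundary_count` | `4` / `4` | all planted fusions recovered |
| `insulation_change_at_lost_boundaries` | `+0.687` | insulation rises where boundaries were lost |
| `intra_inter_ratio_condition1/2` | `5.65 → 10.34` | TAD compaction: more intra-, fewer inter-TAD contacts |
| `upg_tad_odds_ratio` | `5.25` | recovered enrichment of up-genes in merged TADs (planted odds 5) |

Individual stages are also exposed as subcommands operating on plain-text
files (bins/pixels TSV, bedGraph, BED):
`tadfuse simulate | balance | ps-curve | compartments | saddle | switches |
insulation | tads | fusions | ata | diff-matrix | integrate | run`.

The library surface mirrors the CLI; see the API in `tadfuse/__init__.py`
and the model documentation in `docs/methods.md`.

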