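# Methods

## The generative model

The simulator produces per-chromosome cis contact matrices over uniform
bins (lengths must divide the bin size evenly; no ragged terminal bins).
The expected count at bin pair (i, j), i ≠ j, is

```
λ_ij = K · |i−j|^(−α)
         · (1 + δ_c · [same compartment and |i−j| ≥ d_min])
         · (1 + δ_t · [same TAD])
         · f_BB^([both bins B and |i−j| ≥ d_min])
```

with `K` chosen so that the genome-wide expected cis total equals the
configured depth. Observed counts are independent Poisson draws on the
upper triangle, mirrored (exact symmetry, zero diagonal — self-ligation
signal at d = 0 is never simulated or analysed). Poisson noise is the
simplest model consistent with count data; overdispersion is out of scope.
Only cis matrices are simulated; whole-genome views are block-diagonal
mosaics and trans contacts are a non-goal.

Model parameters, defaults, and rationale:

| parameter | default | meaning |
| --- | --- | --- |
| `decay_exponent` α | 1.0 | power-law distance decay, the canonical fractal-globule value |
| `compartment_delta` δ_c | 0.6 | contact bonus for same-compartment pairs |
| `compartment_min_dist` d_min | 20 bins (2 Mb) | compartment terms act only at long range; see below |
| `tad_delta` δ_t | 1.0 | within-TAD contact bonus (2× over background) |
| `depth` | 10⁷ | expected genome-wide cis count for the default 2000-bin genome |
| `n_tads_per_chrom` | 10 | ~5 Mb TADs on 50 Mb chromosomes |
| `min_tad_bins` | 5 (0.5 Mb) | minimum planted TAD span |
| `compartment_block_len` | 10 bins (1 Mb) | approximate A/B block length |

**Why the distance gate (`d_min`)?** Compartmentalisation in real contact
maps is a long-range, O/E-level pattern; near the diagonal the map is
dominated by TADs and distance decay. An ungated checkerboard term puts a
sharp contact step at every A/B block edge at *all* distances, and every
block edge then presents as a TAD boundary to any insulation-based caller
— hundreds of "boundaries" that no real map would show. Gating the
compartment (and B–B) factors to separations ≥ 2 Mb leaves the insulation
window (±0.5 Mb) governed by the TAD term alone while the eigenvector and
saddle analyses, which integrate over all distances, see the checkerboard
essentially unchanged.

**Why aperiodic compartment blocks?** Block lengths are drawn uniformly
from [L/2, 3L/2] around the target length L with a random phase and random
starting label per chromosome. A strictly periodic checkerboard aliases
with genomic distance: at separations that are multiples of the period
*every* pair is same-compartment, which contaminates the expected-by-
distance denominator and makes saddle corner strengths non-monotone in
δ_c. Irregular blocks (as in real genomes) keep the same-label fraction
flat in distance; with them, compartment strength is strictly increasing
over δ_c ∈ {0.2, 0.4, 0.6, 0.8} and eigenvector recovery is exact on
noise-free input.

**Why a minimum planted TAD size?** Boundaries drawn uniformly can fall
closer together than the insulation window; a domain narrower than the
window is unresolvable by construction (and sub-0.5 Mb TADs are not a
feature of real maps at 100 kb resolution). Planted boundaries therefore
keep every TAD ≥ `min_tad_bins`.

The derived second condition removes `n_fusions` boundaries (recorded as
fusion events), flips `n_switches` compartment labels (recorded with
direction), divides δ_t by (1 − attenuation) to emulate TAD compaction,
and can steepen the decay exponent (`decay_increase`) and boost B–B pairs
(`bb_boost`) — together these plant the transformation phenotype the
pipeline is designed to detect: gained proximal / lost distal contacts,
stronger B–B compartment interaction, compacted TADs, and merged domains.

The DEG generator places down-genes uniformly over bins and up-genes with
sampling odds ω on bins whose structural category is *merged-TAD*
(category computed from planted geometry with the same flank convention
the classifier uses). Placing on category rather than on the raw fused
interval makes the (direction × merged-TAD) odds ratio identify ω exactly;
genes that would land on boundary-flank bins inside a fused TAD would
otherwise be reclassified and bias the recovered OR downward. TSSs are
uniform within the chosen bin, |log2FC| ~ folded N(2, 0.5), adjusted p
drawn below 0.05 (tables are assumed pre-filtered; the filter is
re-asserted on input with a logged drop count).

### What the simulator does not emulate

Overdispersed (negative-binomial) counts, trans contacts, restriction-
fragment geometry, read-level artefacts, copy-number effects, unmappable
regions, and loop-level (punctate) structure. Passing tests demonstrate
that the *operations* recover planted structure under Poisson sampling at
realistic depth — not that the pipeline is robust to every artefact of
patient-derived libraries.

## Analysis choices

**Balancing.** ICE per chromosome: `W ← W/(s_i s_j)` with
`s = rowsum/mean(rowsum)` until max |s−1| < 1e−5 (≤ 200 iterations;
non-convergence flags and warns rather than fails). Low-coverage bins are
masked by a mad-max rule — zero marginal, fewer than `min_nnz` nonzero
pixels, or log marginal more than 5 MADs below the genome-wide median —
with the cutoff floored at a two-fold drop below the median so that
near-uniform coverage (e.g. noise-free expectation input) masks nothing.
Masked bins carry zero rows in counts and NaN in O/E; every downstream
mean skips them.

**P(s).** Entries over unmasked cis pairs (i < j) are normalised to unit
total; distances are pooled genome-wide into log-spaced bins and each bin
stores the geometric mean probability of its positive pairs together with
the realised geometric-mean pair distance. Slopes are fitted by least
squares in log10–log10 against the realised distances (an exact power law
then yields its exponent exactly); the default fit excludes the first
diagonal (d = 1 bin), which in real libraries is dominated by short-range
artefacts. The crossover of two curves on identical distance bins is the
first sign change of log2(a/b), linearly interpolated in log10-distance.

**Compartments.** Per chromosome, E1 is the leading eigenvector of the
Pearson correlation matrix of unmasked O/E rows (correlation, not raw O/E:
scale-free and standard), sign-oriented against an orientation track (the
simulator provides the planted indicator plus N(0, 0.3²) noise, standing
in for GC/gene density) and scaled to unit variance. E1 = 0 or masked →
NA, excluded from switches and saddles. Chromosomes with < 10 usable bins
get an all-NA track with a warning. Saddles rank bins genome-wide (E1
computed per chromosome), trim 2% from each tail, form 20 equal-occupancy
groups and average O/E over cis group pairs; corner blocks of 20% of the
groups give AA/BB/AB strengths and `overall = log2(AA·BB/AB²)`.

**Insulation and TADs.** The diamond at bin i spans rows (i−w..i−1) ×
columns (i..i+w−1), w = 5 bins (0.5 Mb): it measures contact across the
gap between bins i−1 and i, so a boundary b (separating bins b−1 and b)
produces its unique insulation minimum exactly at index b. (The variant
that excludes bin i on both sides yields an exact two-bin plateau at b−1
and b on noise-free input, making the called position ambiguous.) Scores
are log2 of the diamond mean over the chromosome's geometric mean of
diamond means (geometric: robust to heavy-tailed rows). Boundary strength
is the mean score of the two flanking w/2 half-windows minus the score at
i; boundaries are local minima with strength ≥ 0.1, plateaus resolved to
the leftmost bin, chromosome-edge bins never called. Segmentations tile
each chromosome; intervals < 3 bins are merged by dropping their
weaker (higher-insulation) delimiting boundary. Aggregate TAD analysis
rescales each TAD window (plus half-TAD flanks, windows clipped at
chromosome ends are skipped) to 30 × 30 by bilinear interpolation and
averages elementwise ignoring NaN.

**Fusion detection.** A condition-2 TAD [s, e) is a fusion if s and e each
match a condition-1 boundary or chromosome end within ±1 bin and it
contains at least one condition-1 interior boundary with no condition-2
boundary within ±1 bin. The *merged-TAD interval* used for gene
classification is the fused TAD minus its first and last bin (terminal
boundary bins), so the boundary and merged-TAD gene categories cannot
collide at the fusion edges.

**DEG integration.** Genes are located by TSS (whole-gene-body overlap
would break the mutually exclusive category partition). The boundary set
defaults to the union over both conditions (either condition's set is
selectable); a gene is *boundary* if its bin is within ±1 bin of any
boundary, else *merged-TAD* if inside a merged interval, else *other* —
boundary takes precedence, so the three categories partition the genes.
Condition 1 is fixed as the untransformed (CLL-like) state throughout;
SwitchAB therefore means A in condition 1 and B in condition 2.
Enrichment is tested per (direction × category) 2×2 table with the
hypergeometric upper tail; odds ratios use the Haldane–Anscombe 0.5
correction when a cell is zero, with Woolf 95% CIs; q-values are
Benjamini–Hochberg across the four emitted tables only (stated in the
output — the family is deliberately small).

**Differential maps.** Conditions are depth-normalised to equal unit cis
totals over jointly unmasked bins before any comparison. Differential
matrices are log2 ratios (not subtractions — the choice is flagged since
either reading is defensible) with pseudocount 1e−6 × the mean unmasked
entry averaged over both normalised inputs, making the result exactly
antisymmetric under argument swap. Whole-genome differential heatmaps are
produced at 1 Mb by coarsening the 100 kb matrices ×10 (remainder bins
pool into the final coarse bin, recorded in metadata).

## Numerical conventions

Coordinates are 0-based half-open everywhere; distances are reported in bp
at bin-centre resolution. Matrices are validated symmetric to 1e−9. All
text writers emit full-precision float reprs so round trips are lossless.
Every source of randomness flows from one top-level seed via SHA-256
stage-name substreams (`stage_seed(seed, name)`), keeping reruns
byte-identical and all derived seeds below 2³¹.

## Problem sizes

The default configuration analyses 4 × 500 bins (4 × 50 Mb at 100 kb) at
depth 10⁷, where the full pipeline runs in a few seconds; recovery studies
in the test suite use 500-bin chromosomes at depths 10⁶–10⁷ and 100-seed
replicate sets for the enrichment statistics. These sizes were chosen so
that planted-parameter recovery operates in the same regime the analyses
target (≈ 10–100 expected counts per near-diagonal pixel) while the whole
suite stays interactive.

## Known limitations

* The insulation caller assumes TADs at least as wide as its window; no
  hierarchical/nested domain calling, directionality index, or loop-anchor
  analysis.
* Sub-compartments (A1/A2/B1–B4) are not called.
* The eigenvector sign requires an orientation track; with a flat or
  adversarial track, A/B labels can flip per chromosome.
* Fusion detection is deliberately conservative (anchor matching within
  tolerance); boundary shifts larger than the tolerance register as a
  lost-plus-gained boundary pair rather than a fusion.
* The enrichment q-values correct only across the four emitted tables; a
  genome-wide scan would need a wider family.
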