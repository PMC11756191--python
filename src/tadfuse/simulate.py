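"""Paired-condition Hi-C simulator with fully known planted structure.

The generative model emulates the features a two-condition (leukaemia ->
transformed-lymphoma style) comparison measures: power-law distance decay,
an A/B compartment checkerboard, TAD blocks, and — in the derived second
condition — TAD fusions (lost boundaries), compartment switches, TAD
compaction, a steeper decay exponent and stronger B–B contacts.  A DEG
table generator plants an enrichment of upregulated genes inside the
fused-TAD intervals.

Expected cis count at bin pair (i, j), i != j, within one chromosome:

    lambda_ij = K * |i - j|**(-alpha)
                  * (1 + delta_c * [same compartment AND |i-j| >= d_min])
                  * (1 + delta_t * [same TAD])
                  * bb_factor**[both bins in B AND |i-j| >= d_min]

with K a global constant chosen so the expected genome-wide cis total
equals ``depth``.  The compartment terms are gated to separations of at
least ``compartment_min_dist`` bins (default 20, i.e. 2 Mb at 100 kb)
because compartmentalisation is a long-range feature of real contact
maps; the TAD-scale neighbourhood is governed by the TAD term alone.  Observed counts are independent Poisson draws on the
upper triangle, mirrored to keep the matrix exactly symmetric; the
diagonal (d = 0, self-ligation) is never simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome import GenomeSpec, GenomicBinTable, ValidationError
from .matrix import ContactMatrix


@dataclass
class PlantedTruth:
    """Ground-truth structure behind a simulated condition.

    ``compartment_labels`` is one 'A'/'B' per global bin;
    ``tad_boundaries`` maps chromosome -> sorted interior boundary bin
    indices (chromosome-local; boundary b separates bins b-1 and b).
    ``fusion_events`` and ``switch_bins`` are only populated on a derived
    second condition and record what changed relative to condition 1.
    """

    compartment_labels: np.ndarray
    tad_boundaries: dict[str, list[int]]
    decay_exponent: float
    compartment_delta: float
    tad_delta: float
    depth: float
    bb_factor: float = 1.0
    compartment_min_dist: int = 20
    fusion_events: list[tuple[str, int]] = field(default_factory=list)
    switch_bins: list[tuple[int, str]] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.compartment_labels = np.asarray(self.compartment_labels, dtype=object)
        if self.decay_exponent <= 0:
            raise ValidationError("decay exponent must be positive")
        if self.compartment_delta < 0 or self.tad_delta < 0:
            raise ValidationError("compartment/TAD deltas must be >= 0")

    def to_json(self) -> str:
        d = asdict(self)
        d["compartment_labels"] = list(self.compartment_labels)
        d["fusion_events"] = [[c, int(b)] for c, b in self.fusion_events]
        d["switch_bins"] = [[int(i), s] for i, s in self.switch_bins]
        d["tad_boundaries"] = {c: [int(b) for b in bs] for c, bs in self.tad_boundaries.items()}
        return json.dumps(d, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        d["compartment_labels"] = np.array(d["compartment_labels"], dtype=object)
        d["fusion_events"] = [(c, int(b)) for c, b in d["fusion_events"]]
        d["switch_bins"] = [(int(i), s) for i, s in d["switch_bins"]]
        return cls(**d)


def generate_genome(spec: GenomeSpec, n_tads_per_chrom: int,
                    compartment_block_len: int, seed: int,
                    decay_exponent: float = 1.0, compartment_delta: float = 0.6,
                    tad_delta: float = 1.0, depth: float = 1e7,
                    min_tad_bins: int = 5,
                    compartment_min_dist: int = 20) -> PlantedTruth:
    """Plant TAD boundaries and an alternating A/B compartment pattern.

    Each chromosome is partitioned into exactly ``n_tads_per_chrom``
    contiguous TADs by interior boundaries drawn uniformly at random
    subject to every TAD spanning at least ``min_tad_bins`` bins —
    domains narrower than the insulation analysis window are not
    resolvable and do not occur at realistic TAD scales (at a 100 kb
    working resolution the default keeps every TAD >= 0.5 Mb).
    Compartment labels alternate
    in blocks of ``compartment_block_len`` bins with a random phase and
    random starting label per chromosome.  Deterministic for a fixed seed.
    The intensity parameters (decay exponent, compartment and TAD contact
    bonuses, expected cis depth) are stored on the returned truth.
    """
    if n_tads_per_chrom < 1:
        raise ValidationError("n_tads_per_chrom must be >= 1")
    if compartment_block_len < 1:
        raise ValidationError("compartment_block_len must be >= 1")
    rng = np.random.default_rng(seed)
    labels = np.empty(spec.n_bins, dtype=object)
    boundaries: dict[str, list[int]] = {}
    table = spec.bins()
    for chrom in spec.chrom_names:
        off, nb = table.chrom_span(chrom)
        k = n_tads_per_chrom - 1
        g = max(1, min_tad_bins)
        hi = nb - g - (k - 1) * g
        if nb < n_tads_per_chrom * g or (k > 0 and hi - g + 1 < k):
            raise ValidationError(
                f"{chrom!r}: {nb} bins cannot hold {n_tads_per_chrom} TADs "
                f"of >= {g} bins")
        if k > 0:
            # sample sorted distinct offsets, then spread them g bins apart
            # so every TAD (including the terminal ones) spans >= g bins
            ys = np.sort(rng.choice(np.arange(g, hi + 1), size=k, replace=False))
            boundaries[chrom] = [int(y + i * g) for i, y in enumerate(ys)]
        else:
            boundaries[chrom] = []
        # alternating blocks of approximately the requested length: lengths
        # are drawn around the target so the pattern is aperiodic (a strictly
        # periodic checkerboard aliases with genomic distance and distorts
        # O/E contrast in a way real compartment maps do not show)
        lo_len = max(1, int(np.ceil(compartment_block_len / 2)))
        hi_len = max(lo_len, int(np.floor(3 * compartment_block_len / 2)))
        cur = rng.choice(np.array(["A", "B"], dtype=object))
        pos = int(rng.integers(0, lo_len))  # random phase: first block truncated
        lab = np.empty(nb, dtype=object)
        first_len = int(rng.integers(lo_len, hi_len + 1)) - pos
        lab[:max(first_len, 0)] = cur
        pos = max(first_len, 0)
        while pos < nb:
            cur = "B" if cur == "A" else "A"
            length = int(rng.integers(lo_len, hi_len + 1))
            lab[pos:pos + length] = cur
            pos += length
        labels[off:off + nb] = lab
    return PlantedTruth(labels, boundaries, decay_exponent=decay_exponent,
                        compartment_delta=compartment_delta, tad_delta=tad_delta,
                        depth=depth, compartment_min_dist=compartment_min_dist,
                        seed=seed)


def _tad_index(truth: PlantedTruth, table: GenomicBinTable, chrom: str) -> np.ndarray:
    """Per-bin TAD id (chromosome-local) implied by the boundary list."""
    _, nb = table.chrom_span(chrom)
    bounds = truth.tad_boundaries.get(chrom, [])
    tid = np.zeros(nb, dtype=int)
    for b in bounds:
        tid[b:] += 1
    return tid


def expected_contacts(truth: PlantedTruth, spec: GenomeSpec) -> ContactMatrix:
    """Noise-free expectation matrix lambda of the generative model."""
    if truth.decay_exponent <= 0:
        raise ValidationError("decay exponent must be positive")
    if truth.depth <= 0:
        raise ValidationError("depth must be positive")
    table = spec.bins()
    blocks: dict[str, np.ndarray] = {}
    unscaled_total = 0.0
    for chrom in spec.chrom_names:
        off, nb = table.chrom_span(chrom)
        idx = np.arange(nb)
        d = np.abs(idx[:, None] - idx[None, :]).astype(float)
        with np.errstate(divide="ignore"):
            lam = d ** (-truth.decay_exponent)
        np.fill_diagonal(lam, 0.0)
        lab = truth.compartment_labels[off:off + nb]
        same_comp = lab[:, None] == lab[None, :]
        # compartmentalisation is a long-range signal: the same-compartment
        # bonus applies only beyond compartment_min_dist bins, leaving the
        # TAD-scale (insulation-window) neighbourhood to the TAD term
        far = d >= truth.compartment_min_dist
        lam *= 1.0 + truth.compartment_delta * (same_comp & far)
        tid = _tad_index(truth, table, chrom)
        lam *= 1.0 + truth.tad_delta * (tid[:, None] == tid[None, :])
        if truth.bb_factor != 1.0:
            both_b = (lab[:, None] == "B") & (lab[None, :] == "B")
            lam *= np.where(both_b & far, truth.bb_factor, 1.0)
        blocks[chrom] = lam
        unscaled_total += lam.sum()
    k = truth.depth / unscaled_total
    for chrom in blocks:
        blocks[chrom] *= k
    return ContactMatrix(table, blocks, balanced=False)


def simulate_contacts(truth: PlantedTruth, spec: GenomeSpec, seed: int) -> ContactMatrix:
    """Poisson-sampled raw counts around the model expectation.

    Upper-triangle entries are drawn independently and mirrored, so the
    output is exactly symmetric with a zero diagonal; two calls with the
    same seed are identical.
    """
    expect = expected_contacts(truth, spec)
    rng = np.random.default_rng(seed)
    blocks: dict[str, np.ndarray] = {}
    for chrom in spec.chrom_names:
        lam = expect.blocks[chrom]
        n = lam.shape[0]
        iu, ju = np.triu_indices(n, k=1)
        draws = rng.poisson(lam[iu, ju]).astype(float)
        blk = np.zeros((n, n))
        blk[iu, ju] = draws
        blk[ju, iu] = draws
        blocks[chrom] = blk
    return ContactMatrix(expect.bins, blocks, balanced=False)


def derive_condition_two(truth: PlantedTruth, n_fusions: int, n_switches: int,
                         insulation_attenuation: float, seed: int,
                         decay_increase: float = 0.0,
                         bb_boost: float = 1.0) -> PlantedTruth:
    """Derive the transformed condition from a condition-1 truth.

    Removes ``n_fusions`` randomly chosen interior boundaries (recorded as
    fusion events), flips ``n_switches`` randomly chosen bin labels
    (recorded with direction AB or BA), and divides the TAD contact bonus
    by (1 - attenuation) at the retained boundaries to emulate TAD
    compaction.  ``decay_increase`` steepens the distance-decay exponent
    and ``bb_boost`` multiplies B–B pair intensity, emulating the gained
    proximal and B-compartment contacts of the transformed cells.
    """
    if not 0 <= insulation_attenuation < 1:
        raise ValidationError("insulation_attenuation must be in [0, 1)")
    all_bounds = [(c, b) for c, bs in truth.tad_boundaries.items() for b in bs]
    if n_fusions > len(all_bounds):
        raise ValidationError(
            f"requested {n_fusions} fusions but only {len(all_bounds)} boundaries exist")
    n_bins = truth.compartment_labels.size
    if n_switches > n_bins:
        raise ValidationError("more switches than bins")
    rng = np.random.default_rng(seed)
    lost_idx = rng.choice(len(all_bounds), size=n_fusions, replace=False) if n_fusions else []
    fusion_events = sorted((all_bounds[i] for i in lost_idx), key=lambda t: (t[0], t[1]))
    lost = set(fusion_events)
    boundaries2 = {c: [b for b in bs if (c, b) not in lost]
                   for c, bs in truth.tad_boundaries.items()}
    labels2 = truth.compartment_labels.copy()
    switch_bins: list[tuple[int, str]] = []
    if n_switches:
        flip = rng.choice(n_bins, size=n_switches, replace=False)
        for i in sorted(int(x) for x in flip):
            if labels2[i] == "A":
                labels2[i] = "B"
                switch_bins.append((i, "AB"))
            else:
                labels2[i] = "A"
                switch_bins.append((i, "BA"))
    return PlantedTruth(
        labels2, boundaries2,
        decay_exponent=truth.decay_exponent + decay_increase,
        compartment_delta=truth.compartment_delta,
        tad_delta=truth.tad_delta / (1.0 - insulation_attenuation),
        depth=truth.depth,
        bb_factor=truth.bb_factor * bb_boost,
        compartment_min_dist=truth.compartment_min_dist,
        fusion_events=fusion_events,
        switch_bins=switch_bins,
        seed=seed,
    )


def orientation_track(truth: PlantedTruth, noise_sd: float = 0.3,
                      seed: int = 0) -> np.ndarray:
    """Per-bin orientation signal standing in for GC / gene density.

    Planted compartment indicator (+1 for A, -1 for B) plus Gaussian noise;
    used only to fix the sign of the compartment eigenvector.
    """
    rng = np.random.default_rng(seed)
    base = np.where(truth.compartment_labels == "A", 1.0, -1.0)
    return base + rng.normal(0.0, noise_sd, size=base.size)


# ---------------------------------------------------------------------------
# Fused-TAD geometry and DEG tables
# ---------------------------------------------------------------------------

def fused_intervals(truth2: PlantedTruth, spec: GenomeSpec) -> list[tuple[str, int, int]]:
    """Merged-TAD bin intervals implied by the planted fusion events.

    For each lost boundary, the enclosing condition-2 TAD is the interval
    between the surrounding retained boundaries (or chromosome ends); the
    merged-TAD interval excludes the first and last bin of that TAD (the
    terminal boundary bins).  Overlapping events collapse to one interval.
    Returned as chromosome-local half-open (chrom, start_bin, end_bin).
    """
    table = spec.bins()
    out: set[tuple[str, int, int]] = set()
    for chrom, b in truth2.fusion_events:
        _, nb = table.chrom_span(chrom)
        bounds = truth2.tad_boundaries.get(chrom, [])
        left = max([0] + [x for x in bounds if x <= b])
        right = min([nb] + [x for x in bounds if x > b])
        s, e = left + 1, right - 1
        if e > s:
            out.add((chrom, s, e))
    return sorted(out)


def truth_fusion_events(truth2: PlantedTruth, spec: GenomeSpec) -> list:
    """Planted fusion events as TadFusionEvent objects (ground truth).

    Lost boundaries sharing one enclosing condition-2 TAD collapse into a
    single event, mirroring what fusion detection reports.
    """
    from .tads import TadFusionEvent

    table = spec.bins()
    grouped: dict[tuple[str, int, int], list[int]] = {}
    for chrom, b in truth2.fusion_events:
        _, nb = table.chrom_span(chrom)
        bounds = truth2.tad_boundaries.get(chrom, [])
        left = max([0] + [x for x in bounds if x <= b])
        right = min([nb] + [x for x in bounds if x > b])
        grouped.setdefault((chrom, left, right), []).append(b)
    events = []
    for (chrom, left, right), lost in sorted(grouped.items()):
        b1 = sorted(set(truth2.tad_boundaries.get(chrom, [])) | set(lost))
        _, nb = table.chrom_span(chrom)
        edges = [0] + b1 + [nb]
        merged = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)
                  if edges[i] >= left and edges[i + 1] <= right]
        events.append(TadFusionEvent(chrom, sorted(lost), merged, (left, right)))
    return events


@dataclass
class SyntheticDegTruth:
    """Planted per-gene placement and structural category."""

    gene: list[str]
    bin_id: list[int]
    direction: list[str]
    category: list[str]          # boundary | merged_tad | other
    enrichment_odds: float
    flank: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.gene, "bin_id": self.bin_id,
                             "direction": self.direction, "category": self.category})


def _bin_categories(truth1: PlantedTruth, truth2: PlantedTruth, spec: GenomeSpec,
                    flank: int) -> np.ndarray:
    """Per-bin structural category from planted geometry.

    Boundary = within +/- flank bins of any boundary of either condition
    (union); merged_tad = inside a fused-TAD interval and not boundary;
    otherwise other.  Matches the downstream classification convention.
    """
    table = spec.bins()
    cat = np.full(spec.n_bins, "other", dtype=object)
    for chrom, s, e in fused_intervals(truth2, spec):
        off, _ = table.chrom_span(chrom)
        cat[off + s:off + e] = "merged_tad"
    union: dict[str, set[int]] = {}
    for t in (truth1, truth2):
        for chrom, bs in t.tad_boundaries.items():
            union.setdefault(chrom, set()).update(bs)
    for chrom, bs in union.items():
        off, nb = table.chrom_span(chrom)
        for b in bs:
            lo, hi = max(0, b - flank), min(nb, b + flank + 1)
            cat[off + lo:off + hi] = "boundary"
    return cat


def simulate_deg_table(truth_pair: tuple[PlantedTruth, PlantedTruth], spec: GenomeSpec,
                       n_genes: int, frac_up: float, enrichment_odds: float,
                       seed: int, flank: int = 1,
                       ) -> tuple[pd.DataFrame, SyntheticDegTruth]:
    """Differential-expression gene table with planted structural enrichment.

    Down-genes are placed uniformly over bins.  Up-genes are placed with
    sampling odds ``enrichment_odds`` (omega >= 1) on merged-TAD bins
    relative to all other bins, so the odds ratio of the 2x2 table
    (direction x merged-TAD membership) equals omega exactly in
    expectation.  TSSs are uniform within the chosen bin, |log2FC| is
    drawn from N(2, 0.5) folded positive, and adjusted p-values are drawn
    below the conventional 0.05 cutoff.
    """
    if n_genes < 0:
        raise ValidationError("n_genes must be >= 0")
    if enrichment_odds < 1:
        raise ValidationError("enrichment_odds must be >= 1")
    if not 0 <= frac_up <= 1:
        raise ValidationError("frac_up must be in [0, 1]")
    truth1, truth2 = truth_pair
    table = spec.bins()
    rng = np.random.default_rng(seed)
    cat = _bin_categories(truth1, truth2, spec, flank)
    cols = ["gene", "chrom", "tss", "log2fc", "padj", "direction"]
    if n_genes == 0:
        empty = pd.DataFrame(columns=cols)
        return empty, SyntheticDegTruth([], [], [], [], enrichment_odds, flank)

    n_up = int(round(n_genes * frac_up))
    n_down = n_genes - n_up
    w_up = np.where(cat == "merged_tad", enrichment_odds, 1.0)
    w_up = w_up / w_up.sum()
    up_bins = rng.choice(spec.n_bins, size=n_up, p=w_up)
    down_bins = rng.choice(spec.n_bins, size=n_down)
    bins_all = np.concatenate([up_bins, down_bins])
    directions = np.array(["up"] * n_up + ["down"] * n_down, dtype=object)
    order = rng.permutation(n_genes)
    bins_all, directions = bins_all[order], directions[order]

    genes, chroms, tsss, l2fc, padj = [], [], [], [], []
    for g in range(n_genes):
        b = int(bins_all[g])
        chrom = table.chroms[b]
        start, end = int(table.starts[b]), int(table.ends[b])
        genes.append(f"gene{g:05d}")
        chroms.append(chrom)
        tsss.append(int(rng.integers(start, end)))
        mag = abs(rng.normal(2.0, 0.5))
        l2fc.append(mag if directions[g] == "up" else -mag)
        padj.append(float(rng.uniform(1e-8, 0.049)))
    degs = pd.DataFrame({"gene": genes, "chrom": chroms, "tss": tsss,
                         "log2fc": l2fc, "padj": padj, "direction": list(directions)})
    truth = SyntheticDegTruth(genes, [int(b) for b in bins_all], list(directions),
                              [str(cat[b]) for b in bins_all], enrichment_odds, flank)
    return degs, truth
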