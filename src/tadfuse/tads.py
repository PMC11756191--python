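"""Insulation scores, TAD segmentation, aggregate TAD analysis and
cross-condition TAD-fusion detection.

The insulation score at bin i is the mean balanced contact inside the
w x w diamond spanning (i-w..i-1) x (i+1..i+w), log2-normalised to the
chromosome's geometric mean; TAD boundaries are local insulation minima
whose prominence (boundary strength) exceeds a threshold.  A TAD fusion
is a condition-2 TAD that spans two or more condition-1 TADs whose
separating boundary disappeared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomicBinTable, ValidationError
from .matrix import ContactMatrix


@dataclass
class InsulationTrack:
    """Per-bin diamond insulation with boundary-strength annotations.

    ``raw`` is the diamond mean (NaN near chromosome edges, at masked
    windows and where the diamond is empty); ``score`` is
    log2(raw / per-chromosome geometric mean of raw); ``strength`` is the
    dip prominence used for boundary calling.
    """

    bins: GenomicBinTable
    raw: np.ndarray
    score: np.ndarray
    strength: np.ndarray
    window: int


def insulation_score(m: ContactMatrix, window: int = 5) -> InsulationTrack:
    """Diamond-window insulation of a balanced matrix.

    The diamond at bin i spans rows (i-w .. i-1) x columns (i .. i+w-1):
    it measures contact across the gap between bins i-1 and i, so the
    score indexes boundaries in the same convention as segmentations
    (boundary b separates bins b-1 and b) and a planted boundary produces
    its insulation minimum exactly at b rather than on a two-bin plateau.
    Defined only where the full diamond fits inside the chromosome.  The
    boundary strength at bin i is the mean of the score over the two
    flanking half-windows (w//2 bins each) minus the score at i — the
    depth of the local dip.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    if not m.balanced:
        raise ValidationError("insulation_score expects a balanced matrix")
    n = m.bins.n_bins
    raw = np.full(n, np.nan)
    score = np.full(n, np.nan)
    strength = np.full(n, np.nan)
    for chrom in m.bins.chrom_names:
        off, nb = m.bins.chrom_span(chrom)
        if nb <= 2 * window:
            warnings.warn(f"{chrom}: too short for insulation window {window}",
                          RuntimeWarning)
            continue
        blk = m.blocks[chrom]
        valid = ~m.chrom_mask(chrom)
        r = np.full(nb, np.nan)
        for i in range(window, nb - window + 1):
            rows = np.arange(i - window, i)
            cols = np.arange(i, i + window)
            ok = np.outer(valid[rows], valid[cols])
            if ok.any():
                sub = blk[np.ix_(rows, cols)]
                vals = sub[ok]
                vals = vals[np.isfinite(vals)]
                if vals.size:
                    r[i] = vals.mean()
        defined = np.isfinite(r) & (r > 0)
        if not defined.any():
            continue
        gmean = np.exp(np.log(r[defined]).mean())
        s = np.full(nb, np.nan)
        s[defined] = np.log2(r[defined] / gmean)
        h = max(1, window // 2)
        st = np.full(nb, np.nan)
        for i in range(nb):
            if not np.isfinite(s[i]):
                continue
            left = s[max(0, i - h):i]
            right = s[i + 1:i + h + 1]
            left = left[np.isfinite(left)]
            right = right[np.isfinite(right)]
            if left.size and right.size:
                st[i] = 0.5 * (left.mean() + right.mean()) - s[i]
        raw[off:off + nb] = r
        score[off:off + nb] = s
        strength[off:off + nb] = st
    return InsulationTrack(m.bins, raw, score, strength, window)


def call_boundaries(track: InsulationTrack, strength_min: float = 0.1
                    ) -> dict[str, list[int]]:
    """Local insulation minima with strength >= ``strength_min``.

    Plateau minima resolve to their leftmost bin; the first and last
    defined bin of a chromosome are never called.  Returns
    chromosome-local boundary bin indices.
    """
    out: dict[str, list[int]] = {}
    for chrom in track.bins.chrom_names:
        sl = track.bins.chrom_slice(chrom)
        s = track.score[sl]
        st = track.strength[sl]
        defined = np.flatnonzero(np.isfinite(s))
        bounds: list[int] = []
        if defined.size >= 3:
            vals = s[defined]
            for k in range(1, defined.size - 1):
                if vals[k - 1] == vals[k]:
                    continue   # plateau: only its leftmost bin may be called
                if vals[k - 1] <= vals[k]:
                    continue   # not lower than the left side
                jj = k + 1
                while jj < defined.size and vals[jj] == vals[k]:
                    jj += 1
                if jj >= defined.size or vals[jj] <= vals[k]:
                    continue
                i = defined[k]
                if np.isfinite(st[i]) and st[i] >= strength_min:
                    bounds.append(int(i))
        out[chrom] = bounds
    return out


@dataclass
class TadSegmentation:
    """Half-open TAD intervals tiling each chromosome exactly."""

    bins: GenomicBinTable
    intervals: dict[str, list[tuple[int, int]]]   # chromosome-local bin coords

    def __post_init__(self) -> None:
        for chrom, ivs in self.intervals.items():
            _, nb = self.bins.chrom_span(chrom)
            pos = 0
            for s, e in ivs:
                if s != pos or e <= s:
                    raise ValidationError(f"{chrom}: intervals do not tile (at {s})")
                pos = e
            if pos != nb:
                raise ValidationError(f"{chrom}: intervals end at {pos}, expected {nb}")

    def boundaries(self, chrom: str) -> list[int]:
        """Interior boundaries implied by the intervals."""
        return [e for _, e in self.intervals[chrom][:-1]]

    def n_tads(self) -> int:
        return sum(len(v) for v in self.intervals.values())


def segment_tads(boundaries: dict[str, list[int]], bins: GenomicBinTable,
                 min_tad: int = 3,
                 insulation: InsulationTrack | None = None) -> TadSegmentation:
    """Turn boundary lists into a tiling segmentation, merging slivers.

    Consecutive boundaries plus the chromosome ends delimit intervals; any
    interval shorter than ``min_tad`` bins is merged with a neighbour by
    dropping one of its two delimiting boundaries — the one with the
    higher (weaker) insulation score when a track is supplied, otherwise
    the one adjoining the smaller neighbour.
    """
    intervals: dict[str, list[tuple[int, int]]] = {}
    for chrom in bins.chrom_names:
        off, nb = bins.chrom_span(chrom)
        bs = sorted(set(boundaries.get(chrom, [])))
        if any(b <= 0 or b >= nb for b in bs):
            raise ValidationError(f"{chrom}: boundaries must be interior")

        def score_of(b: int) -> float:
            if insulation is None:
                return 0.0
            v = insulation.score[off + b]
            return float(v) if np.isfinite(v) else np.inf

        changed = True
        while changed:
            changed = False
            edges = [0] + bs + [nb]
            for i in range(len(edges) - 1):
                if edges[i + 1] - edges[i] < min_tad and len(bs) > 0:
                    left_b = edges[i] if i > 0 else None
                    right_b = edges[i + 1] if i < len(edges) - 2 else None
                    if left_b is None and right_b is None:
                        break
                    if left_b is None:
                        drop = right_b
                    elif right_b is None:
                        drop = left_b
                    elif insulation is not None:
                        drop = left_b if score_of(left_b) >= score_of(right_b) else right_b
                    else:
                        # merge into the smaller neighbour
                        left_sz = edges[i] - edges[i - 1]
                        right_sz = edges[i + 2] - edges[i + 1]
                        drop = left_b if left_sz <= right_sz else right_b
                    bs.remove(drop)
                    changed = True
                    break
        edges = [0] + bs + [nb]
        intervals[chrom] = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    return TadSegmentation(bins, intervals)


def intra_inter_ratio(m: ContactMatrix, seg: TadSegmentation) -> dict[str, float]:
    """Mean within-TAD vs adjacent-TAD contact and their ratio.

    Intra averages all unmasked pairs (i < j) inside a TAD; inter averages
    pairs spanning two *adjacent* TADs at separations up to the larger of
    the two TAD spans.  A zero inter mean yields a NaN ratio (flagged).
    """
    if not m.bins.same_axis(seg.bins):
        raise ValidationError("segmentation on a different bin table")
    intra_s = intra_n = inter_s = inter_n = 0.0
    for chrom in m.bins.chrom_names:
        blk = m.blocks[chrom]
        valid = ~m.chrom_mask(chrom)
        ivs = seg.intervals[chrom]
        for s, e in ivs:
            for i in range(s, e):
                if not valid[i]:
                    continue
                for j in range(i + 1, e):
                    if valid[j] and np.isfinite(blk[i, j]):
                        intra_s += blk[i, j]
                        intra_n += 1
        for (s1, e1), (s2, e2) in zip(ivs[:-1], ivs[1:]):
            span = max(e1 - s1, e2 - s2)
            for i in range(s1, e1):
                if not valid[i]:
                    continue
                for j in range(s2, e2):
                    if valid[j] and j - i <= span and np.isfinite(blk[i, j]):
                        inter_s += blk[i, j]
                        inter_n += 1
    intra = intra_s / intra_n if intra_n else float("nan")
    inter = inter_s / inter_n if inter_n else float("nan")
    ratio = intra / inter if inter_n and inter > 0 else float("nan")
    return {"intra_mean": intra, "inter_mean": inter, "ratio": ratio,
            "n_intra_pairs": int(intra_n), "n_inter_pairs": int(inter_n)}


def _bilinear_resize(mat: np.ndarray, target: int) -> np.ndarray:
    """Bilinear interpolation of a square matrix onto target x target,
    mapping the corner samples onto the corner samples."""
    n = mat.shape[0]
    if n == target:
        return mat.copy()
    if n == 1:
        return np.full((target, target), mat[0, 0])
    xs = np.linspace(0, n - 1, target)
    i0 = np.clip(np.floor(xs).astype(int), 0, n - 2)
    frac = xs - i0
    out = np.empty((target, target))
    for a in range(target):
        ra, fa = i0[a], frac[a]
        row = mat[ra] * (1 - fa) + mat[ra + 1] * fa
        out[a] = row[i0] * (1 - frac) + row[i0 + 1] * frac
    return out


def aggregate_tads(oe: ContactMatrix, seg: TadSegmentation, target_size: int = 30,
                   flank_frac: float = 0.5, min_tad_bins: int = 3) -> np.ndarray:
    """Average rescaled O/E pile-up over TADs (aggregate TAD analysis).

    Each TAD window (the TAD plus a half-TAD flank on each side, clipped
    at chromosome ends) is rescaled to ``target_size`` squared by bilinear
    interpolation and the windows are averaged elementwise, ignoring NaN.
    TADs shorter than ``min_tad_bins`` are skipped.
    """
    if target_size < 5:
        raise ValidationError("target_size must be >= 5")
    acc = np.zeros((target_size, target_size))
    cnt = np.zeros((target_size, target_size))
    for chrom in oe.bins.chrom_names:
        _, nb = oe.bins.chrom_span(chrom)
        blk = oe.blocks[chrom]
        for s, e in seg.intervals[chrom]:
            L = e - s
            if L < min_tad_bins:
                continue
            f = int(round(L * flank_frac))
            lo, hi = s - f, e + f
            if lo < 0 or hi > nb:
                continue
            win = blk[lo:hi, lo:hi]
            resized = _bilinear_resize(win, target_size)
            ok = np.isfinite(resized)
            acc[ok] += resized[ok]
            cnt[ok] += 1
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)


@dataclass
class TadFusionEvent:
    """A condition-2 TAD spanning several condition-1 TADs."""

    chrom: str
    lost_boundaries: list[int]                 # condition-1 boundaries gone in condition 2
    merged_from: list[tuple[int, int]] = field(default_factory=list)
    fused_interval: tuple[int, int] = (0, 0)   # the enclosing condition-2 TAD

    def merged_bin_interval(self) -> tuple[int, int]:
        """Merged-TAD interval used for gene classification: the fused
        condition-2 TAD minus its first and last (terminal boundary) bins."""
        s, e = self.fused_interval
        return (s + 1, e - 1)


def detect_fusions(seg1: TadSegmentation, seg2: TadSegmentation,
                   tol: int = 1) -> list[TadFusionEvent]:
    """Find condition-2 TADs produced by merging condition-1 TADs.

    A condition-2 TAD [s, e) is a fusion when (a) s and e each coincide
    with a condition-1 boundary or chromosome end within ``tol`` bins,
    and (b) it contains at least one condition-1 interior boundary with
    no condition-2 boundary within ``tol`` bins (a lost boundary).  All
    lost boundaries and the merged condition-1 TADs are recorded.
    """
    if not seg1.bins.same_axis(seg2.bins):
        raise ValidationError("segmentations on different bin tables")
    events: list[TadFusionEvent] = []
    for chrom in seg1.bins.chrom_names:
        _, nb = seg1.bins.chrom_span(chrom)
        b1 = seg1.boundaries(chrom)
        b2 = seg2.boundaries(chrom)
        anchors1 = [0] + b1 + [nb]
        for s, e in seg2.intervals[chrom]:
            if min((abs(s - a) for a in anchors1), default=tol + 1) > tol:
                continue
            if min((abs(e - a) for a in anchors1), default=tol + 1) > tol:
                continue
            lost = [b for b in b1
                    if s + tol < b < e - tol
                    and min((abs(b - c) for c in b2), default=tol + 1) > tol]
            if not lost:
                continue
            merged = [(ts, te) for ts, te in seg1.intervals[chrom]
                      if ts >= s - tol and te <= e + tol]
            events.append(TadFusionEvent(chrom, sorted(lost), merged, (s, e)))
    return events
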