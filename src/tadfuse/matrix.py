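"""Contact-matrix model and matrix-level operations.

A :class:`ContactMatrix` holds one symmetric dense block per chromosome
(cis contacts only) over a shared :class:`~tadfuse.genome.GenomicBinTable`.
Operations here cover ICE balancing, distance-decay expectation, the O/E
transform, contact-probability P(s) curves with crossover detection,
coarsening, and two-condition differential log-ratio matrices.

Masked bins (zero or near-zero coverage) carry zeros in count/balanced
matrices and NaN in O/E and differential matrices; every operation skips
them when averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomicBinTable, ValidationError

SYMMETRY_TOL = 1e-9


@dataclass
class ContactMatrix:
    """Per-chromosome symmetric cis contact blocks over a bin table.

    Attributes
    ----------
    bins : GenomicBinTable
        Bin axis shared by all blocks.
    blocks : dict[str, np.ndarray]
        One dense symmetric (n_c, n_c) float array per chromosome.
    balanced : bool
        True after ICE correction.
    bias : np.ndarray | None
        Per-bin multiplicative bias (global length), NaN at masked bins;
        present iff ``balanced``.
    mask : np.ndarray
        Boolean, True for bins excluded from analysis.
    is_oe : bool
        True for observed/expected matrices (NaN marks undefined entries).
    converged : bool
        Balancing convergence flag (meaningful iff ``balanced``).
    meta : dict
        Free-form provenance (e.g. coarsening factor).
    """

    bins: GenomicBinTable
    blocks: dict[str, np.ndarray]
    balanced: bool = False
    bias: np.ndarray | None = None
    mask: np.ndarray | None = None
    is_oe: bool = False
    converged: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.zeros(self.bins.n_bins, dtype=bool)
        for chrom in self.bins.chrom_names:
            _, nb = self.bins.chrom_span(chrom)
            blk = self.blocks[chrom]
            if blk.shape != (nb, nb):
                raise ValidationError(f"{chrom!r}: block shape {blk.shape} != ({nb}, {nb})")
            finite = np.isfinite(blk)
            asym = np.abs(np.where(finite & finite.T, blk - blk.T, 0.0)).max(initial=0.0)
            if asym > SYMMETRY_TOL:
                raise ValidationError(f"{chrom!r}: asymmetry {asym:.3e} exceeds {SYMMETRY_TOL}")

    # -- helpers -----------------------------------------------------------
    def chrom_mask(self, chrom: str) -> np.ndarray:
        return self.mask[self.bins.chrom_slice(chrom)]

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            self.bins,
            {c: b.copy() for c, b in self.blocks.items()},
            balanced=self.balanced,
            bias=None if self.bias is None else self.bias.copy(),
            mask=self.mask.copy(),
            is_oe=self.is_oe,
            converged=self.converged,
            meta=dict(self.meta),
        )

    def total(self) -> float:
        """Sum over unmasked cis entries (both triangles, diagonal once)."""
        tot = 0.0
        for chrom in self.bins.chrom_names:
            blk = self.blocks[chrom]
            valid = ~self.chrom_mask(chrom)
            sub = blk[np.ix_(valid, valid)]
            tot += np.nansum(sub)
        return float(tot)

    def max_asymmetry(self) -> float:
        worst = 0.0
        for blk in self.blocks.values():
            finite = np.isfinite(blk)
            both = finite & finite.T
            if both.any():
                worst = max(worst, float(np.abs((blk - blk.T)[both]).max()))
        return worst


def matrix_from_dense(bins: GenomicBinTable, dense_by_chrom: dict[str, np.ndarray],
                      **kw) -> ContactMatrix:
    """Convenience constructor from float arrays (copies, symmetrizes check)."""
    blocks = {c: np.asarray(a, dtype=float).copy() for c, a in dense_by_chrom.items()}
    return ContactMatrix(bins, blocks, **kw)


# ---------------------------------------------------------------------------
# ICE balancing
# ---------------------------------------------------------------------------

def _coverage_mask(m: ContactMatrix, mad_max: float, min_nnz: int) -> np.ndarray:
    """Low-coverage bin filter (mad-max rule).

    A bin is excluded when its marginal is zero, when it has fewer than
    ``min_nnz`` nonzero pixels, or when its log marginal falls more than
    ``mad_max`` median absolute deviations below the genome-wide median
    of the nonzero log marginals."""
    marginals = np.zeros(m.bins.n_bins)
    nnz = np.zeros(m.bins.n_bins)
    for chrom in m.bins.chrom_names:
        sl = m.bins.chrom_slice(chrom)
        blk = m.blocks[chrom]
        marginals[sl] = blk.sum(axis=1)
        nnz[sl] = (blk > 0).sum(axis=1)
    mask = marginals <= 0
    positive = marginals[~mask]
    if positive.size and mad_max > 0:
        logm = np.log(positive)
        med = np.median(logm)
        mad = np.median(np.abs(logm - med))
        # floor the cutoff at a two-fold drop below the median so that
        # near-uniform coverage (tiny MAD) never masks ordinary bins
        cutoff = med - max(mad_max * mad, np.log(2.0))
        with np.errstate(divide="ignore"):
            mask |= np.where(marginals > 0, np.log(np.maximum(marginals, 1e-300)),
                             -np.inf) < cutoff
    mask |= nnz < min_nnz
    return mask


def ice_balance(m: ContactMatrix, max_iter: int = 200, tol: float = 1e-5,
                mad_max: float = 5.0, min_nnz: int = 1) -> ContactMatrix:
    """Iterative correction (ICE) of a raw contact matrix, per chromosome.

    Each chromosome block is rescaled as W <- W / (s_i s_j) with
    s = rowsum / mean(rowsum over unmasked bins), iterated until the
    maximum relative row-sum deviation drops below ``tol`` or ``max_iter``
    is reached (non-convergence sets a flag and warns, it is not an error).
    The accumulated per-bin bias vector is stored on the result.
    """
    if m.balanced:
        raise ValidationError("matrix is already balanced")
    mask = m.mask | _coverage_mask(m, mad_max, min_nnz)
    if mask.all():
        raise ValidationError("all bins masked: matrix has no usable coverage")

    bias = np.ones(m.bins.n_bins)
    blocks: dict[str, np.ndarray] = {}
    converged_all = True
    for chrom in m.bins.chrom_names:
        sl = m.bins.chrom_slice(chrom)
        valid = ~mask[sl]
        blk = m.blocks[chrom].astype(float).copy()
        blk[~valid, :] = 0.0
        blk[:, ~valid] = 0.0
        if valid.sum() == 0:
            blocks[chrom] = blk
            continue
        b = np.ones(valid.sum())
        sub = blk[np.ix_(valid, valid)]
        converged = False
        for _ in range(max_iter):
            rows = sub.sum(axis=1)
            s = rows / rows.mean()
            s[s == 0] = 1.0
            sub /= np.outer(s, s)
            b *= s
            if np.abs(s - 1.0).max() < tol:
                converged = True
                break
        if not converged:
            converged_all = False
        blk[np.ix_(valid, valid)] = sub
        blocks[chrom] = blk
        chrom_bias = np.full(valid.size, np.nan)
        chrom_bias[valid] = b
        bias[sl] = chrom_bias
    bias[mask] = np.nan
    if not converged_all:
        warnings.warn("ICE did not converge on every chromosome", RuntimeWarning)
    return ContactMatrix(m.bins, blocks, balanced=True, bias=bias, mask=mask,
                         converged=converged_all, meta=dict(m.meta))


# ---------------------------------------------------------------------------
# Expected-by-distance and O/E
# ---------------------------------------------------------------------------

@dataclass
class ExpectedProfile:
    """Per-chromosome mean contact at each bin separation d = 1..n-1.

    Entries at separations with no unmasked pair are NaN (missing).
    """

    bins: GenomicBinTable
    profiles: dict[str, np.ndarray]


def expected_by_distance(m: ContactMatrix) -> ExpectedProfile:
    """Mean over unmasked pairs of each off-diagonal, per chromosome."""
    profiles: dict[str, np.ndarray] = {}
    for chrom in m.bins.chrom_names:
        blk = m.blocks[chrom]
        valid = ~m.chrom_mask(chrom)
        n = blk.shape[0]
        prof = np.full(max(n - 1, 0), np.nan)
        for d in range(1, n):
            pair_ok = valid[:-d] & valid[d:]
            if pair_ok.any():
                prof[d - 1] = np.diagonal(blk, d)[pair_ok].mean()
        profiles[chrom] = prof
    return ExpectedProfile(m.bins, profiles)


def observed_over_expected(m: ContactMatrix, expected: ExpectedProfile | None = None
                           ) -> ContactMatrix:
    """O/E transform: entry (i, j) divided by the chromosome mean at
    separation |i - j|.  Masked bins and separations with missing expected
    become NaN; the diagonal is NaN (d = 0 is never analysed)."""
    if expected is None:
        expected = expected_by_distance(m)
    if not m.bins.same_axis(expected.bins):
        raise ValidationError("expected profile computed on a different bin table")
    blocks: dict[str, np.ndarray] = {}
    for chrom in m.bins.chrom_names:
        blk = m.blocks[chrom]
        n = blk.shape[0]
        prof = expected.profiles[chrom]
        out = np.full((n, n), np.nan)
        for d in range(1, n):
            e = prof[d - 1]
            if np.isfinite(e) and e > 0:
                idx = np.arange(n - d)
                out[idx, idx + d] = blk[idx, idx + d] / e
                out[idx + d, idx] = out[idx, idx + d]
        valid = ~m.chrom_mask(chrom)
        out[~valid, :] = np.nan
        out[:, ~valid] = np.nan
        blocks[chrom] = out
    return ContactMatrix(m.bins, blocks, balanced=m.balanced, bias=None,
                         mask=m.mask.copy(), is_oe=True, meta=dict(m.meta))


# ---------------------------------------------------------------------------
# Contact-probability curve P(s)
# ---------------------------------------------------------------------------

@dataclass
class ContactCurve:
    """Genome-wide contact probability versus genomic separation.

    Per-pair contact probabilities (entries normalised to unit total over
    unmasked cis pairs, i < j) are pooled into log-spaced distance bins;
    each bin stores the geometric mean probability over its positive pairs
    and both the nominal bin centre and the realised geometric-mean pair
    distance (bp).
    """

    edges_bp: np.ndarray        # len k+1
    centers_bp: np.ndarray      # geometric centres of the edges, len k
    mean_dist_bp: np.ndarray    # realised GM pair distance, NaN if empty
    prob: np.ndarray            # GM probability, NaN if no positive pair
    n_pairs: np.ndarray         # pairs contributing to the GM
    bins_per_decade: int
    from_balanced: bool

    def defined(self) -> np.ndarray:
        return np.isfinite(self.prob) & (self.prob > 0)


def contact_probability_curve(m: ContactMatrix, bins_per_decade: int = 8) -> ContactCurve:
    """P(s): pooled, log-binned geometric-mean contact probability.

    Distances are bin-centre separations in bp; probabilities are matrix
    entries divided by the total over all unmasked cis pairs so the
    genome-wide cis probability mass is 1.
    """
    if bins_per_decade < 1:
        raise ValidationError("bins_per_decade must be >= 1")
    bin_size = m.bins.bin_size
    dists: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for chrom in m.bins.chrom_names:
        blk = m.blocks[chrom]
        valid = ~m.chrom_mask(chrom)
        n = blk.shape[0]
        iu, ju = np.triu_indices(n, k=1)
        ok = valid[iu] & valid[ju]
        v = blk[iu[ok], ju[ok]]
        finite = np.isfinite(v)
        dists.append((ju[ok][finite] - iu[ok][finite]).astype(float) * bin_size)
        vals.append(v[finite])
    dist = np.concatenate(dists) if dists else np.array([])
    val = np.concatenate(vals) if vals else np.array([])
    if dist.size == 0:
        raise ValidationError("no unmasked cis pairs")
    total = val.sum()
    if total <= 0:
        raise ValidationError("matrix total is zero")
    prob_pair = val / total

    lo = np.log10(dist.min())
    hi = np.log10(dist.max())
    k = max(1, int(np.ceil((hi - lo) * bins_per_decade)))
    edges = np.logspace(lo, lo + k / bins_per_decade, k + 1)
    edges[-1] = max(edges[-1], dist.max() * (1 + 1e-12))
    which = np.clip(np.searchsorted(edges, dist, side="right") - 1, 0, k - 1)

    prob = np.full(k, np.nan)
    mean_d = np.full(k, np.nan)
    npairs = np.zeros(k, dtype=int)
    pos = prob_pair > 0
    for b in range(k):
        sel = (which == b) & pos
        cnt = int(sel.sum())
        npairs[b] = cnt
        if cnt:
            prob[b] = np.exp(np.log(prob_pair[sel]).mean())
            mean_d[b] = np.exp(np.log(dist[sel]).mean())
    centers = np.sqrt(edges[:-1] * edges[1:])
    return ContactCurve(edges, centers, mean_d, prob, npairs, bins_per_decade,
                        from_balanced=m.balanced)


def fit_decay_slope(curve: ContactCurve, min_dist_bp: float | None = None,
                    max_dist_bp: float | None = None) -> float:
    """Least-squares slope of log10(P) vs log10(s) over defined curve bins.

    Fits against the realised geometric-mean pair distance of each bin, so
    an exact power law yields its exponent exactly.
    """
    ok = curve.defined() & np.isfinite(curve.mean_dist_bp)
    if min_dist_bp is not None:
        ok &= curve.mean_dist_bp >= min_dist_bp
    if max_dist_bp is not None:
        ok &= curve.mean_dist_bp <= max_dist_bp
    if ok.sum() < 2:
        raise ValidationError("fewer than two defined curve bins in fit range")
    x = np.log10(curve.mean_dist_bp[ok])
    y = np.log10(curve.prob[ok])
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def crossover_distance(a: ContactCurve, b: ContactCurve) -> float | None:
    """Smallest distance where log2(a/b) changes sign.

    The two curves must share distance-bin edges.  The crossing point is
    linearly interpolated in log10-distance between the flanking bin
    centres; returns None when the ratio never changes sign.
    """
    if a.edges_bp.shape != b.edges_bp.shape or not np.allclose(a.edges_bp, b.edges_bp):
        raise ValidationError("curves are on different distance bins")
    ok = a.defined() & b.defined()
    x = np.log10(a.centers_bp[ok])
    r = np.log2(a.prob[ok] / b.prob[ok])
    if r.size < 2:
        return None
    sign = np.sign(r)
    nz = np.flatnonzero(sign != 0)
    for a_idx, b_idx in zip(nz[:-1], nz[1:]):
        if sign[a_idx] == sign[b_idx]:
            continue
        if b_idx > a_idx + 1:
            # the ratio is exactly zero between the two signed points
            return float(10 ** x[a_idx + 1])
        frac = r[a_idx] / (r[a_idx] - r[b_idx])
        return float(10 ** (x[a_idx] + frac * (x[b_idx] - x[a_idx])))
    return None


# ---------------------------------------------------------------------------
# Coarsening and differential matrices
# ---------------------------------------------------------------------------

def coarsen(m: ContactMatrix, factor: int) -> ContactMatrix:
    """Sum counts within factor x factor blocks (e.g. 100 kb -> 1 Mb).

    Chromosomes whose bin count is not a multiple of ``factor`` pool the
    remainder bins into the final coarse bin; the output bin table then
    carries a wider terminal bin and the factor is recorded in ``meta``.
    """
    if factor < 1:
        raise ValidationError("factor must be >= 1")
    if factor == 1:
        return m.copy()
    chroms, starts, ends = [], [], []
    blocks: dict[str, np.ndarray] = {}
    masks = []
    for chrom in m.bins.chrom_names:
        sl = m.bins.chrom_slice(chrom)
        blk = m.blocks[chrom]
        n = blk.shape[0]
        nc = max(1, n // factor)
        # boundaries of coarse bins in fine-bin units; remainder -> last bin
        cuts = [i * factor for i in range(nc)] + [n]
        out = np.zeros((nc, nc))
        for p in range(nc):
            for q in range(nc):
                out[p, q] = np.nansum(blk[cuts[p]:cuts[p + 1], cuts[q]:cuts[q + 1]])
        blocks[chrom] = out
        fine_starts = m.bins.starts[sl]
        fine_ends = m.bins.ends[sl]
        for p in range(nc):
            chroms.append(chrom)
            starts.append(fine_starts[cuts[p]])
            ends.append(fine_ends[cuts[p + 1] - 1])
        cmask = m.chrom_mask(chrom)
        masks.extend(bool(cmask[cuts[p]:cuts[p + 1]].all()) for p in range(nc))
    table = GenomicBinTable(np.array(chroms, dtype=object), np.array(starts),
                            np.array(ends), m.bins.bin_size * factor, ragged_end=True)
    meta = dict(m.meta)
    meta["coarsen_factor"] = meta.get("coarsen_factor", 1) * factor
    return ContactMatrix(table, blocks, balanced=m.balanced, bias=None,
                         mask=np.array(masks, dtype=bool), is_oe=m.is_oe, meta=meta)


def depth_normalize(a: ContactMatrix, b: ContactMatrix) -> tuple[ContactMatrix, ContactMatrix]:
    """Scale both matrices to unit total over jointly unmasked cis entries."""
    if not a.bins.same_axis(b.bins):
        raise ValidationError("matrices are on different bin tables")
    mask = a.mask | b.mask
    out = []
    for m in (a, b):
        tot = 0.0
        for chrom in m.bins.chrom_names:
            valid = ~mask[m.bins.chrom_slice(chrom)]
            tot += np.nansum(m.blocks[chrom][np.ix_(valid, valid)])
        if tot <= 0:
            raise ValidationError("matrix total is zero after joint masking")
        c = m.copy()
        for chrom in c.bins.chrom_names:
            c.blocks[chrom] = c.blocks[chrom] / tot
        c.mask = mask.copy()
        out.append(c)
    return out[0], out[1]


def differential_matrix(a: ContactMatrix, b: ContactMatrix,
                        pseudocount: float | None = None) -> ContactMatrix:
    """Signed per-pair log2 ratio of two depth-normalised matrices.

    Both inputs must be balanced on the same bin table; they are first
    scaled to equal (unit) cis totals over the joint unmasked bins.  The
    pseudocount defaults to 1e-6 times the mean jointly-unmasked entry
    (averaged over the two normalised matrices, so the result is exactly
    antisymmetric under argument swap).  Masked pairs are NaN.
    """
    if not (a.balanced and b.balanced):
        raise ValidationError("differential_matrix requires balanced inputs")
    an, bn = depth_normalize(a, b)
    mask = an.mask
    if pseudocount is None:
        s = cnt = 0.0
        for chrom in an.bins.chrom_names:
            valid = ~mask[an.bins.chrom_slice(chrom)]
            for mm in (an, bn):
                sub = mm.blocks[chrom][np.ix_(valid, valid)]
                s += np.nansum(sub)
                cnt += np.isfinite(sub).sum()
        pseudocount = 1e-6 * (s / cnt if cnt else 1.0)
    blocks: dict[str, np.ndarray] = {}
    for chrom in an.bins.chrom_names:
        ratio = np.log2((an.blocks[chrom] + pseudocount) / (bn.blocks[chrom] + pseudocount))
        valid = ~mask[an.bins.chrom_slice(chrom)]
        ratio[~valid, :] = np.nan
        ratio[:, ~valid] = np.nan
        blocks[chrom] = ratio
    meta = {"pseudocount": pseudocount}
    return ContactMatrix(an.bins, blocks, balanced=True, bias=None, mask=mask.copy(),
                         is_oe=False, meta=meta)
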