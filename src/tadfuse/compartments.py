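"""A/B compartment calling, switch classification and saddle analysis.

Compartments are called per chromosome from the leading eigenvector (E1)
of the Pearson correlation matrix of the O/E contact map; the sign of E1
is anchored to an orientation track (GC content, gene density, or the
simulator's planted indicator) so that positive E1 = compartment A.
Two-condition comparisons classify each bin as StableAA, StableBB,
SwitchAB or SwitchBA, and saddle plots average O/E over E1-quantile pairs
to quantify AA/BB/AB interaction strength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomicBinTable, ValidationError
from .matrix import ContactMatrix

MIN_BINS_PER_CHROM = 10
SWITCH_CATEGORIES = ("StableAA", "StableBB", "SwitchAB", "SwitchBA", "NA")


@dataclass
class CompartmentTrack:
    """Per-bin compartment eigenvector and A/B label.

    E1 is NaN on masked bins and on chromosomes too short to analyse;
    label is 'A' iff E1 > 0, 'B' iff E1 < 0, else 'NA'.
    """

    bins: GenomicBinTable
    e1: np.ndarray
    labels: np.ndarray

    @classmethod
    def from_e1(cls, bins: GenomicBinTable, e1: np.ndarray) -> "CompartmentTrack":
        labels = np.full(e1.size, "NA", dtype=object)
        labels[np.isfinite(e1) & (e1 > 0)] = "A"
        labels[np.isfinite(e1) & (e1 < 0)] = "B"
        return cls(bins, e1, labels)


def compartment_eigenvector(oe: ContactMatrix, orientation: np.ndarray) -> CompartmentTrack:
    """E1 from the per-chromosome Pearson correlation of O/E rows.

    For each chromosome the correlation matrix of the unmasked O/E rows is
    eigendecomposed; the eigenvector of the largest eigenvalue is oriented
    so its correlation with ``orientation`` is non-negative and scaled to
    unit variance.  Chromosomes with fewer than 10 usable bins get an
    all-NaN track (with a warning).
    """
    if not oe.is_oe:
        raise ValidationError("compartment_eigenvector expects an O/E matrix")
    orientation = np.asarray(orientation, dtype=float)
    if orientation.size != oe.bins.n_bins:
        raise ValidationError("orientation track length does not match bin table")
    e1 = np.full(oe.bins.n_bins, np.nan)
    for chrom in oe.bins.chrom_names:
        sl = oe.bins.chrom_slice(chrom)
        blk = oe.blocks[chrom]
        valid = ~oe.chrom_mask(chrom)
        # rows must also have variation: all-NaN or constant rows break corrcoef
        sub = blk[np.ix_(valid, valid)]
        usable = np.isfinite(sub).sum(axis=1) >= 2
        if usable.sum() < MIN_BINS_PER_CHROM:
            warnings.warn(f"{chrom}: fewer than {MIN_BINS_PER_CHROM} usable bins, "
                          "compartment track left undefined", RuntimeWarning)
            continue
        sub = sub[np.ix_(usable, usable)]
        filled = np.where(np.isfinite(sub), sub, np.nanmean(sub))
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(filled)
        corr = np.nan_to_num(corr, nan=0.0)
        vals, vecs = np.linalg.eigh(corr)
        v = vecs[:, -1]
        local = np.full(valid.size, np.nan)
        local[np.flatnonzero(valid)[usable]] = v
        ref = orientation[sl]
        ok = np.isfinite(local) & np.isfinite(ref)
        if ok.sum() >= 2 and np.std(local[ok]) > 0 and np.std(ref[ok]) > 0:
            r = np.corrcoef(local[ok], ref[ok])[0, 1]
            if r < 0:
                local = -local
        sd = np.nanstd(local)
        if sd > 0:
            local = local / sd
        e1[sl] = local
    return CompartmentTrack.from_e1(oe.bins, e1)


def classify_switches(t1: CompartmentTrack, t2: CompartmentTrack) -> pd.DataFrame:
    """Per-bin two-condition category (StableAA/StableBB/SwitchAB/SwitchBA).

    Category is the cross-tabulation of the two label tracks; any bin with
    an NA label in either condition is NA.  Returns a frame with columns
    ``bin_id``, ``label1``, ``label2``, ``category``.
    """
    if not t1.bins.same_axis(t2.bins):
        raise ValidationError("tracks are on different bin tables")
    l1, l2 = t1.labels, t2.labels
    cat = np.full(l1.size, "NA", dtype=object)
    cat[(l1 == "A") & (l2 == "A")] = "StableAA"
    cat[(l1 == "B") & (l2 == "B")] = "StableBB"
    cat[(l1 == "A") & (l2 == "B")] = "SwitchAB"
    cat[(l1 == "B") & (l2 == "A")] = "SwitchBA"
    return pd.DataFrame({"bin_id": np.arange(l1.size), "label1": l1,
                         "label2": l2, "category": cat})


def switch_counts(table: pd.DataFrame) -> dict[str, int]:
    counts = table["category"].value_counts()
    return {c: int(counts.get(c, 0)) for c in SWITCH_CATEGORIES}


@dataclass
class SaddleMatrix:
    """Mean O/E over bin pairs grouped by genome-wide E1 quantile.

    Row/column 0 holds the lowest-E1 (strongest B) group; the last holds
    the strongest A group.  Cells with no contributing pair are NaN.
    """

    values: np.ndarray
    counts: np.ndarray
    q: int
    trim: float


def _quantile_groups(track: CompartmentTrack, mask: np.ndarray, q: int,
                     trim: float) -> np.ndarray:
    """Genome-wide equal-occupancy E1 groups; -1 marks excluded bins."""
    group = np.full(track.e1.size, -1, dtype=int)
    usable = np.flatnonzero(np.isfinite(track.e1) & (track.e1 != 0) & ~mask)
    if usable.size == 0:
        return group
    order = usable[np.argsort(track.e1[usable], kind="stable")]
    n_trim = int(np.floor(trim * order.size))
    kept = order[n_trim:order.size - n_trim] if n_trim else order
    if kept.size < q:
        return group
    # equal-occupancy split by rank
    splits = np.array_split(kept, q)
    for g, idx in enumerate(splits):
        group[idx] = g
    return group


def saddle(oe: ContactMatrix, track: CompartmentTrack, q: int = 20,
           trim: float = 0.02) -> SaddleMatrix:
    """Q x Q average O/E over genome-wide E1-quantile pairs.

    Bins are ranked by E1 across all chromosomes, the extreme ``trim``
    fraction is dropped from each tail, and the remainder is split into
    ``q`` equal-occupancy groups.  Cell (p, r) averages O/E over all
    unmasked cis pairs with one bin in group p and the other in group r
    (d = 0 excluded); the result is symmetric by construction.
    """
    if q < 2:
        raise ValidationError("q must be >= 2")
    if not oe.bins.same_axis(track.bins):
        raise ValidationError("track and matrix are on different bin tables")
    group = _quantile_groups(track, oe.mask, q, trim)
    sums = np.zeros((q, q))
    counts = np.zeros((q, q), dtype=int)
    for chrom in oe.bins.chrom_names:
        sl = oe.bins.chrom_slice(chrom)
        g = group[sl]
        blk = oe.blocks[chrom]
        has = np.flatnonzero(g >= 0)
        if has.size < 2:
            continue
        sub = blk[np.ix_(has, has)]
        gg = g[has]
        finite = np.isfinite(sub)
        np.fill_diagonal(finite, False)
        gi = np.repeat(gg, has.size).reshape(has.size, has.size)
        gj = gi.T
        flat_idx = (gi * q + gj)[finite]
        np.add.at(sums.reshape(-1), flat_idx, sub[finite])
        np.add.at(counts.reshape(-1), flat_idx, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return SaddleMatrix(values, counts, q, trim)


def compartment_strength(s: SaddleMatrix, corner_frac: float = 0.2) -> dict[str, float]:
    """AA/BB/AB corner means of a saddle and the overall log2 strength.

    AA averages the top-E1 corner block, BB the bottom corner, AB the two
    anti-diagonal corners; overall = log2(AA * BB / AB**2).
    """
    k = int(round(s.q * corner_frac))
    if k < 1:
        raise ValidationError("q * corner_frac must be >= 1")
    v = s.values
    bb = float(np.nanmean(v[:k, :k]))
    aa = float(np.nanmean(v[s.q - k:, s.q - k:]))
    ab = float(np.nanmean(np.concatenate([v[:k, s.q - k:].ravel(),
                                          v[s.q - k:, :k].ravel()])))
    overall = float(np.log2(aa * bb / ab ** 2)) if aa > 0 and bb > 0 and ab > 0 else float("nan")
    return {"AA": aa, "BB": bb, "AB": ab, "overall": overall}


def differential_saddle(s1: SaddleMatrix, s2: SaddleMatrix) -> np.ndarray:
    """Elementwise log2(s1 / s2); exactly antisymmetric under swap."""
    if s1.q != s2.q:
        raise ValidationError("saddles have different Q")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.log2(s1.values / s2.values)
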