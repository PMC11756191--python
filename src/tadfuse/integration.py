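"""Integration of differential-expression gene lists with TAD structure.

Each gene is located by its TSS in the genomic bin table and classified
as ``boundary`` (within a flank of any TAD boundary of either condition),
``merged_tad`` (inside a fused-TAD interval) or ``other``; the boundary
category takes precedence so the three categories partition the genes.
Summary fractions mirror the standard all / upregulated / downregulated
split, and 2x2 enrichment tables (direction x category) are tested with
the hypergeometric upper tail and Benjamini–Hochberg correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .genome import GenomicBinTable, ValidationError
from .tads import TadFusionEvent

log = logging.getLogger(__name__)

DEG_COLUMNS = ["gene", "chrom", "tss", "log2fc", "padj", "direction"]
PADJ_CUTOFF = 0.05


def validate_deg_table(degs: pd.DataFrame) -> pd.DataFrame:
    """Check the DEG-table contract and re-assert the significance filter.

    Direction must match the sign of log2FC; genes with adjusted p at or
    above 0.05 are dropped with a logged count (tables are assumed to be
    pre-filtered, the filter is only re-asserted here).
    """
    missing = [c for c in DEG_COLUMNS if c not in degs.columns]
    if missing:
        raise ValidationError(f"DEG table missing columns {missing}")
    degs = degs.copy()
    bad_dir = ~(
        ((degs["direction"] == "up") & (degs["log2fc"] > 0))
        | ((degs["direction"] == "down") & (degs["log2fc"] < 0))
    )
    if bad_dir.any():
        raise ValidationError(
            f"{int(bad_dir.sum())} genes have direction inconsistent with log2fc sign")
    if ((degs["padj"] < 0) | (degs["padj"] > 1)).any():
        raise ValidationError("adjusted p-values outside [0, 1]")
    keep = degs["padj"] < PADJ_CUTOFF
    n_drop = int((~keep).sum())
    if n_drop:
        log.warning("dropping %d genes with padj >= %.2f", n_drop, PADJ_CUTOFF)
    return degs.loc[keep].reset_index(drop=True)


def map_genes_to_bins(degs: pd.DataFrame, bins: GenomicBinTable
                      ) -> tuple[pd.DataFrame, int]:
    """Assign each gene to the bin whose half-open interval holds its TSS.

    Genes on chromosomes absent from the bin table are skipped with a
    logged warning; the skip count is returned alongside the mapped table
    (extra column ``bin_id``).
    """
    known = set(bins.chrom_names)
    rows = []
    skipped = 0
    for rec in degs.itertuples(index=False):
        if rec.chrom not in known:
            skipped += 1
            continue
        rows.append(bins.bin_id(rec.chrom, int(rec.tss)))
    if skipped:
        log.warning("skipped %d genes on chromosomes absent from the bin table", skipped)
    mapped = degs.loc[degs["chrom"].isin(known)].reset_index(drop=True).copy()
    mapped["bin_id"] = rows
    return mapped, skipped


@dataclass
class DegTadClassification:
    """Per-gene structural category plus the headline summary fractions."""

    table: pd.DataFrame            # gene, direction, bin_id, category
    fraction_boundary_all: float
    fraction_boundary_up: float
    fraction_boundary_down: float
    upg_tad: list[str] = field(default_factory=list)   # upregulated genes in merged TADs
    dwg_tad: list[str] = field(default_factory=list)
    n_skipped: int = 0

    def counts(self) -> dict[str, int]:
        vc = self.table["category"].value_counts()
        return {c: int(vc.get(c, 0)) for c in ("boundary", "merged_tad", "other")}


def classify_degs(degs: pd.DataFrame, bins: GenomicBinTable,
                  boundary_bins: dict[str, list[int]], flank: int = 1,
                  fusions: list[TadFusionEvent] | None = None,
                  validate: bool = True) -> DegTadClassification:
    """Classify DEGs as boundary / merged_tad / other.

    ``boundary_bins`` maps chromosome to chromosome-local boundary bin
    indices (normally the union over both conditions); a gene is
    ``boundary`` when its bin lies within ±``flank`` bins of any of them.
    ``merged_tad`` requires the bin to lie inside a fusion event's
    merged interval (the fused TAD minus its terminal bins) and applies
    only where the boundary rule does not; everything else is ``other``.
    """
    if validate:
        degs = validate_deg_table(degs)
    mapped, skipped = map_genes_to_bins(degs, bins)
    cat = np.full(bins.n_bins, "other", dtype=object)
    for ev in fusions or []:
        off, _ = bins.chrom_span(ev.chrom)
        s, e = ev.merged_bin_interval()
        if e > s:
            cat[off + s:off + e] = "merged_tad"
    for chrom, bs in boundary_bins.items():
        off, nb = bins.chrom_span(chrom)
        for b in bs:
            lo, hi = max(0, b - flank), min(nb, b + flank + 1)
            cat[off + lo:off + hi] = "boundary"

    table = mapped[["gene", "direction", "bin_id"]].copy()
    table["category"] = [cat[b] for b in table["bin_id"]]

    def frac(sub: pd.DataFrame) -> float:
        return float((sub["category"] == "boundary").mean()) if len(sub) else float("nan")

    up = table[table["direction"] == "up"]
    down = table[table["direction"] == "down"]
    return DegTadClassification(
        table=table,
        fraction_boundary_all=frac(table),
        fraction_boundary_up=frac(up),
        fraction_boundary_down=frac(down),
        upg_tad=sorted(up.loc[up["category"] == "merged_tad", "gene"]),
        dwg_tad=sorted(down.loc[down["category"] == "merged_tad", "gene"]),
        n_skipped=skipped,
    )


def _odds_ratio(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """OR with Haldane–Anscombe 0.5 correction and a Woolf 95% CI."""
    if min(a, b, c, d) == 0:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a2, b2, c2, d2 = a, b, c, d
    orr = (a2 * d2) / (b2 * c2)
    se = np.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
    lo = orr * np.exp(-1.959963984540054 * se)
    hi = orr * np.exp(1.959963984540054 * se)
    return float(orr), float(lo), float(hi)


def enrichment_test(cls: DegTadClassification) -> pd.DataFrame:
    """Direction x category 2x2 enrichment over the classified genes.

    For each (direction in {up, down}) x (category in {boundary,
    merged_tad}) the table is (a) direction & category, (b) direction &
    not, (c) other direction & category, (d) other direction & not.
    p is the hypergeometric upper tail P(X >= a) for drawing the
    direction's genes from the classified universe; q is BH-adjusted
    across the four emitted tables.
    """
    t = cls.table
    n_total = len(t)
    rows = []
    for direction in ("up", "down"):
        in_dir = t["direction"] == direction
        for category in ("boundary", "merged_tad"):
            in_cat = t["category"] == category
            a = int((in_dir & in_cat).sum())
            b = int((in_dir & ~in_cat).sum())
            c = int((~in_dir & in_cat).sum())
            d = int((~in_dir & ~in_cat).sum())
            orr, lo, hi = _odds_ratio(a, b, c, d)
            k_cat = a + c
            n_draw = a + b
            p = float(hypergeom.sf(a - 1, n_total, k_cat, n_draw)) if n_total else float("nan")
            rows.append({"direction": direction, "category": category,
                         "a": a, "b": b, "c": c, "d": d,
                         "odds_ratio": orr, "ci_low": lo, "ci_high": hi, "p": p})
    out = pd.DataFrame(rows)
    if len(out) and out["p"].notna().all():
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["q"] = np.nan
    return out
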