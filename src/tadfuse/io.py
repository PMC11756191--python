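"""Text-first readers and writers for the interchange formats.

Contact matrices travel as a bins TSV (chrom, start, end) plus an
upper-triangle pixels TSV (bin1_id, bin2_id, count) in the cooler-style
COO dialect; per-bin tracks as bedGraph; TADs and boundaries as BED;
curves, saddles and gene tables as TSV; planted truth and run reports as
JSON.  All coordinates are 0-based half-open and floats are written at
full precision so round trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomicBinTable, ValidationError
from .matrix import ContactCurve, ContactMatrix
from .tads import TadFusionEvent, TadSegmentation


# ---------------------------------------------------------------------------
# bins + pixels
# ---------------------------------------------------------------------------

def write_contact_table(m: ContactMatrix, bins_path, pixels_path) -> None:
    """Write the bin table and the nonzero upper-triangle pixels."""
    m.bins.to_dataframe().to_csv(bins_path, sep="\t", index=False)
    with open(pixels_path, "w") as fh:
        fh.write("bin1_id\tbin2_id\tcount\n")
        for chrom in m.bins.chrom_names:
            off, nb = m.bins.chrom_span(chrom)
            blk = m.blocks[chrom]
            iu, ju = np.triu_indices(nb)
            vals = blk[iu, ju]
            keep = np.isfinite(vals) & (vals != 0)
            for i, j, v in zip(iu[keep], ju[keep], vals[keep]):
                fh.write(f"{off + i}\t{off + j}\t{float(v)!r}\n")


def read_contact_table(bins_path, pixels_path) -> ContactMatrix:
    """Materialise a symmetric matrix from bins + pixels TSV files.

    Duplicate pixels (including an (i, j)/(j, i) pair) are summed; an
    out-of-range bin id is a hard error reporting the offending line; a
    non-uniform bin width in the bins table is a hard error; a pixel
    joining two chromosomes is rejected (matrices here are cis-only).
    """
    bins_df = pd.read_csv(bins_path, sep="\t")
    table = GenomicBinTable.from_dataframe(bins_df)
    widths = (table.ends - table.starts)
    if not np.all(widths == table.bin_size):
        raise ValidationError(f"{bins_path}: non-uniform bin widths")
    n = table.n_bins
    chrom_of = table.chroms
    blocks = {c: np.zeros((table.chrom_span(c)[1],) * 2) for c in table.chrom_names}
    with open(pixels_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["bin1_id", "bin2_id", "count"]:
            raise ValidationError(f"{pixels_path}: expected header bin1_id/bin2_id/count")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            try:
                i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
            except (ValueError, IndexError) as exc:
                raise ValidationError(f"{pixels_path}:{lineno}: malformed pixel") from exc
            if not (0 <= i < n and 0 <= j < n):
                raise ValidationError(
                    f"{pixels_path}:{lineno}: bin id out of range (n={n})")
            if chrom_of[i] != chrom_of[j]:
                raise ValidationError(
                    f"{pixels_path}:{lineno}: trans pixel {i},{j} not supported")
            chrom = chrom_of[i]
            off, _ = table.chrom_span(chrom)
            a, b = i - off, j - off
            blocks[chrom][a, b] += v
            if a != b:
                blocks[chrom][b, a] += v
    return ContactMatrix(table, blocks, balanced=False)


# ---------------------------------------------------------------------------
# tracks and intervals
# ---------------------------------------------------------------------------

def write_bedgraph(bins: GenomicBinTable, values: np.ndarray, path) -> None:
    """Per-bin real track; NaN bins are skipped."""
    with open(path, "w") as fh:
        for chrom, start, end, v in zip(bins.chroms, bins.starts, bins.ends, values):
            if np.isfinite(v):
                fh.write(f"{chrom}\t{start}\t{end}\t{float(v)!r}\n")


def read_bedgraph(bins: GenomicBinTable, path) -> np.ndarray:
    """Read a bedGraph onto the bin axis (NaN where absent).

    Each record must coincide with one bin of the table.
    """
    out = np.full(bins.n_bins, np.nan)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, end, val = line.rstrip("\n").split("\t")[:4]
            try:
                b = bins.bin_id(chrom, int(start))
            except (KeyError, ValidationError) as exc:
                raise ValidationError(f"{path}:{lineno}: interval not on bin axis") from exc
            if int(bins.starts[b]) != int(start) or int(bins.ends[b]) != int(end):
                raise ValidationError(f"{path}:{lineno}: interval does not match a bin")
            out[b] = float(val)
    return out


def write_tads_bed(seg: TadSegmentation, path) -> None:
    bs = seg.bins.bin_size
    with open(path, "w") as fh:
        for chrom, ivs in seg.intervals.items():
            for k, (s, e) in enumerate(ivs):
                fh.write(f"{chrom}\t{s * bs}\t{e * bs}\tTAD_{chrom}_{k}\n")


def write_boundaries_bed(boundaries: dict[str, list[int]], bins: GenomicBinTable,
                         path) -> None:
    bs = bins.bin_size
    with open(path, "w") as fh:
        for chrom, blist in boundaries.items():
            for b in blist:
                fh.write(f"{chrom}\t{b * bs}\t{(b + 1) * bs}\tboundary_{chrom}_{b}\n")


def write_fusions_tsv(events: list[TadFusionEvent], bins: GenomicBinTable, path) -> None:
    bs = bins.bin_size
    with open(path, "w") as fh:
        fh.write("chrom\tfused_start_bp\tfused_end_bp\tlost_boundaries_bp\tn_merged_tads\n")
        for ev in events:
            s, e = ev.fused_interval
            lost = ",".join(str(b * bs) for b in ev.lost_boundaries)
            fh.write(f"{ev.chrom}\t{s * bs}\t{e * bs}\t{lost}\t{len(ev.merged_from)}\n")


# ---------------------------------------------------------------------------
# curves, saddles, DEG tables, JSON
# ---------------------------------------------------------------------------

def write_curve_tsv(curve: ContactCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write("distance_bp\tmean_pair_distance_bp\tprob\tn_pairs\n")
        for c, md, p, n in zip(curve.centers_bp, curve.mean_dist_bp,
                               curve.prob, curve.n_pairs):
            fh.write(f"{float(c)!r}\t{float(md)!r}\t{float(p)!r}\t{int(n)}\n")


def write_matrix_tsv(values: np.ndarray, path) -> None:
    """Small dense matrix (saddle, ATA, coarse differential) as TSV."""
    with open(path, "w") as fh:
        for row in np.atleast_2d(values):
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_matrix_tsv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", ndmin=2)


def write_deg_table(degs: pd.DataFrame, path) -> None:
    degs.to_csv(path, sep="\t", index=False)


def read_deg_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
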