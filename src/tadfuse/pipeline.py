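"""End-to-end pipeline: simulate (or load) -> balance -> P(s) ->
compartments -> TADs -> fusions -> DEG integration -> JSON report.

All randomness derives from one top-level seed through stage-name-hashed
substreams, so a rerun with the same configuration and seed reproduces
every output byte for byte.  The report stores only relative paths and
no timestamps for the same reason.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as tio
from .genome import GenomeSpec, ValidationError
from .matrix import (ContactMatrix, coarsen, contact_probability_curve,
                     crossover_distance, differential_matrix, expected_by_distance,
                     fit_decay_slope, ice_balance, observed_over_expected)
from .compartments import (compartment_eigenvector, classify_switches,
                           compartment_strength, differential_saddle, saddle,
                           switch_counts)
from .tads import (aggregate_tads, call_boundaries, detect_fusions,
                   insulation_score, intra_inter_ratio, segment_tads)
from .integration import classify_degs, enrichment_test
from .simulate import (derive_condition_two, generate_genome, orientation_track,
                       simulate_contacts, simulate_deg_table)

log = logging.getLogger(__name__)

__version__ = "0.1.0"


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    """Full parameter set of a run; YAML-serialisable with defaults.

    The working resolution (100 kb) is used for compartments and TADs;
    the coarse resolution (1 Mb) only for the whole-genome differential
    heatmap, so the working bin size must divide the coarse one.
    """

    chrom_names: list[str] = field(default_factory=lambda: ["chr1", "chr2", "chr3", "chr4"])
    chrom_lengths: list[int] = field(default_factory=lambda: [50_000_000] * 4)
    bin_size: int = 100_000
    coarse_bin_size: int = 1_000_000
    # simulation (condition 1)
    n_tads_per_chrom: int = 10
    compartment_block_len: int = 10
    decay_exponent: float = 1.0
    compartment_delta: float = 0.6
    tad_delta: float = 1.0
    depth: float = 1e7
    compartment_min_dist_bins: int = 20
    orientation_noise_sd: float = 0.3
    # condition-2 derivation
    n_fusions: int = 4
    n_switches: int = 40
    insulation_attenuation: float = 0.3
    decay_increase: float = 0.25
    bb_boost: float = 1.3
    # DEG simulation
    n_genes: int = 2000
    frac_up: float = 0.5
    enrichment_odds: float = 5.0
    # analysis parameters
    ice_tol: float = 1e-5
    ice_max_iter: int = 200
    mad_max: float = 5.0
    bins_per_decade: int = 8
    saddle_quantiles: int = 20
    saddle_trim: float = 0.02
    corner_frac: float = 0.2
    insulation_window: int = 5
    boundary_strength_min: float = 0.1
    min_tad_bins: int = 3
    fusion_tol_bins: int = 1
    deg_flank_bins: int = 1
    ata_target_size: int = 30
    pseudocount: float | None = None
    seed: int = 1

    def __post_init__(self) -> None:
        if self.coarse_bin_size % self.bin_size != 0:
            raise ValidationError("working bin size must divide the coarse bin size")

    def genome_spec(self) -> GenomeSpec:
        return GenomeSpec(tuple(self.chrom_names), tuple(self.chrom_lengths), self.bin_size)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _analysis_stack(raw: ContactMatrix, cfg: PipelineConfig):
    """Balance, expected profile, O/E for one condition."""
    bal = ice_balance(raw, max_iter=cfg.ice_max_iter, tol=cfg.ice_tol,
                      mad_max=cfg.mad_max)
    exp = expected_by_distance(bal)
    oe = observed_over_expected(bal, exp)
    return bal, oe


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute every stage in dependency order and write a run report.

    On a stage failure the report marks the stage failed, downstream
    stages are skipped, and the failure is re-raised by the CLI as a
    nonzero exit; metrics for skipped stages are explicitly null with a
    reason.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": asdict(cfg),
        "stages": {},
        "metrics": {},
        "outputs": {},
    }
    metrics = report["metrics"]
    outputs = report["outputs"]
    stage_order = ["simulate", "balance", "ps_curve", "compartments",
                   "tads", "fusions", "integrate"]
    current = {"stage": stage_order[0]}

    def begin(stage: str) -> None:
        current["stage"] = stage

    def done(stage: str, **params) -> None:
        report["stages"][stage] = {"status": "ok", "parameters": params}

    try:
        return _run_stages(cfg, outdir, report, metrics, outputs, begin, done)
    except Exception as exc:
        failed = current["stage"]
        report["stages"][failed] = {"status": "failed", "error": str(exc)}
        for stage in stage_order[stage_order.index(failed) + 1:]:
            report["stages"][stage] = {"status": "skipped",
                                       "reason": f"upstream stage {failed} failed"}
        tio.write_json(report, outdir / "report.json")
        raise StageFailure(failed, str(exc)) from exc


class StageFailure(RuntimeError):
    """A pipeline stage failed; the report records which and why."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _run_stages(cfg, outdir, report, metrics, outputs, begin, done) -> dict:
    spec = cfg.genome_spec()

    # --- simulate -------------------------------------------------------
    begin("simulate")
    truth1 = generate_genome(
        spec, cfg.n_tads_per_chrom, cfg.compartment_block_len,
        seed=stage_seed(cfg.seed, "genome"),
        decay_exponent=cfg.decay_exponent, compartment_delta=cfg.compartment_delta,
        tad_delta=cfg.tad_delta, depth=cfg.depth,
        compartment_min_dist=cfg.compartment_min_dist_bins)
    truth2 = derive_condition_two(
        truth1, cfg.n_fusions, cfg.n_switches, cfg.insulation_attenuation,
        seed=stage_seed(cfg.seed, "condition2"),
        decay_increase=cfg.decay_increase, bb_boost=cfg.bb_boost)
    raw1 = simulate_contacts(truth1, spec, seed=stage_seed(cfg.seed, "contacts1"))
    raw2 = simulate_contacts(truth2, spec, seed=stage_seed(cfg.seed, "contacts2"))
    orient = orientation_track(truth1, cfg.orientation_noise_sd,
                               seed=stage_seed(cfg.seed, "orientation"))
    degs, deg_truth = simulate_deg_table(
        (truth1, truth2), spec, cfg.n_genes, cfg.frac_up, cfg.enrichment_odds,
        seed=stage_seed(cfg.seed, "degs"), flank=cfg.deg_flank_bins)

    bins = spec.bins()
    (outdir / "condition1").mkdir(exist_ok=True)
    (outdir / "condition2").mkdir(exist_ok=True)
    for name, raw, truth in (("condition1", raw1, truth1), ("condition2", raw2, truth2)):
        tio.write_contact_table(raw, outdir / name / "bins.tsv", outdir / name / "pixels.tsv")
        (outdir / name / "truth.json").write_text(truth.to_json())
    tio.write_bedgraph(bins, orient, outdir / "orientation.bedgraph")
    tio.write_deg_table(degs, outdir / "degs.tsv")
    tio.write_deg_table(deg_truth.to_frame(), outdir / "degs_truth.tsv")
    outputs["degs"] = "degs.tsv"
    outputs["orientation"] = "orientation.bedgraph"
    done("simulate", n_fusions=cfg.n_fusions, n_switches=cfg.n_switches,
         depth=cfg.depth, n_genes=cfg.n_genes)

    # --- balance + coarse differential ---------------------------------
    begin("balance")
    bal1, oe1 = _analysis_stack(raw1, cfg)
    bal2, oe2 = _analysis_stack(raw2, cfg)
    factor = cfg.coarse_bin_size // cfg.bin_size
    diff_fine = differential_matrix(bal1, bal2, pseudocount=cfg.pseudocount)
    coarse1 = coarsen(raw1, factor)
    coarse2 = coarsen(raw2, factor)
    cb1 = ice_balance(coarse1, max_iter=cfg.ice_max_iter, tol=cfg.ice_tol,
                      mad_max=cfg.mad_max)
    cb2 = ice_balance(coarse2, max_iter=cfg.ice_max_iter, tol=cfg.ice_tol,
                      mad_max=cfg.mad_max)
    diff_coarse = differential_matrix(cb1, cb2, pseudocount=cfg.pseudocount)
    for chrom in bins.chrom_names:
        tio.write_matrix_tsv(diff_coarse.blocks[chrom],
                             outdir / f"diff_matrix_coarse_{chrom}.tsv")
    metrics["ice_converged"] = bool(bal1.converged and bal2.converged)
    metrics["masked_bins_condition1"] = int(bal1.mask.sum())
    metrics["masked_bins_condition2"] = int(bal2.mask.sum())
    del diff_fine  # fine differential is recomputable; coarse one is reported
    done("balance", tol=cfg.ice_tol, max_iter=cfg.ice_max_iter,
         mad_max=cfg.mad_max, coarsen_factor=factor)

    # --- P(s) curves and crossover --------------------------------------
    begin("ps_curve")
    curve1 = contact_probability_curve(bal1, cfg.bins_per_decade)
    curve2 = contact_probability_curve(bal2, cfg.bins_per_decade)
    tio.write_curve_tsv(curve1, outdir / "ps_curve_condition1.tsv")
    tio.write_curve_tsv(curve2, outdir / "ps_curve_condition2.tsv")
    metrics["ps_slope_condition1"] = fit_decay_slope(curve1, min_dist_bp=2 * cfg.bin_size)
    metrics["ps_slope_condition2"] = fit_decay_slope(curve2, min_dist_bp=2 * cfg.bin_size)
    xo = crossover_distance(curve2, curve1)
    metrics["ps_crossover_bp"] = xo
    if xo is not None:
        # condition 2 gains proximal contacts iff its curve is higher below the crossover
        below = curve2.defined() & curve1.defined() & (curve2.centers_bp < xo)
        metrics["condition2_higher_below_crossover"] = bool(
            below.any() and np.all(curve2.prob[below] >= curve1.prob[below]))
    else:
        metrics["condition2_higher_below_crossover"] = None
    done("ps_curve", bins_per_decade=cfg.bins_per_decade)

    # --- compartments ----------------------------------------------------
    begin("compartments")
    track1 = compartment_eigenvector(oe1, orient)
    track2 = compartment_eigenvector(oe2, orient)
    tio.write_bedgraph(bins, track1.e1, outdir / "condition1" / "e1.bedgraph")
    tio.write_bedgraph(bins, track2.e1, outdir / "condition2" / "e1.bedgraph")
    switches = classify_switches(track1, track2)
    switches.to_csv(outdir / "switches.tsv", sep="\t", index=False)
    metrics["switch_counts"] = switch_counts(switches)
    s1 = saddle(oe1, track1, cfg.saddle_quantiles, cfg.saddle_trim)
    s2 = saddle(oe2, track2, cfg.saddle_quantiles, cfg.saddle_trim)
    tio.write_matrix_tsv(s1.values, outdir / "saddle_condition1.tsv")
    tio.write_matrix_tsv(s2.values, outdir / "saddle_condition2.tsv")
    tio.write_matrix_tsv(differential_saddle(s2, s1), outdir / "saddle_differential.tsv")
    st1 = compartment_strength(s1, cfg.corner_frac)
    st2 = compartment_strength(s2, cfg.corner_frac)
    metrics["compartment_strength_condition1"] = st1
    metrics["compartment_strength_condition2"] = st2
    metrics["bb_strength_change"] = st2["BB"] - st1["BB"]
    done("compartments", q=cfg.saddle_quantiles, trim=cfg.saddle_trim,
         corner_frac=cfg.corner_frac)

    # --- TADs ------------------------------------------------------------
    begin("tads")
    ins1 = insulation_score(bal1, cfg.insulation_window)
    ins2 = insulation_score(bal2, cfg.insulation_window)
    tio.write_bedgraph(bins, ins1.score, outdir / "condition1" / "insulation.bedgraph")
    tio.write_bedgraph(bins, ins2.score, outdir / "condition2" / "insulation.bedgraph")
    b1 = call_boundaries(ins1, cfg.boundary_strength_min)
    b2 = call_boundaries(ins2, cfg.boundary_strength_min)
    seg1 = segment_tads(b1, bins, cfg.min_tad_bins, ins1)
    seg2 = segment_tads(b2, bins, cfg.min_tad_bins, ins2)
    tio.write_boundaries_bed(b1, bins, outdir / "condition1" / "boundaries.bed")
    tio.write_boundaries_bed(b2, bins, outdir / "condition2" / "boundaries.bed")
    tio.write_tads_bed(seg1, outdir / "condition1" / "tads.bed")
    tio.write_tads_bed(seg2, outdir / "condition2" / "tads.bed")
    metrics["boundary_count_condition1"] = sum(len(v) for v in b1.values())
    metrics["boundary_count_condition2"] = sum(len(v) for v in b2.values())
    rr1 = intra_inter_ratio(bal1, seg1)
    rr2 = intra_inter_ratio(bal2, seg2)
    metrics["intra_inter_condition1"] = rr1
    metrics["intra_inter_condition2"] = rr2
    metrics["intra_inter_ratio_change"] = rr2["ratio"] - rr1["ratio"]
    ata1 = aggregate_tads(oe1, seg1, cfg.ata_target_size)
    ata2 = aggregate_tads(oe2, seg2, cfg.ata_target_size)
    tio.write_matrix_tsv(ata1, outdir / "ata_condition1.tsv")
    tio.write_matrix_tsv(ata2, outdir / "ata_condition2.tsv")
    with np.errstate(invalid="ignore", divide="ignore"):
        tio.write_matrix_tsv(np.log2(ata2 / ata1), outdir / "ata_differential.tsv")
    done("tads", window=cfg.insulation_window, strength_min=cfg.boundary_strength_min,
         min_tad=cfg.min_tad_bins, ata_target=cfg.ata_target_size)

    # --- fusions ---------------------------------------------------------
    begin("fusions")
    fusions = detect_fusions(seg1, seg2, cfg.fusion_tol_bins)
    tio.write_fusions_tsv(fusions, bins, outdir / "fusions.tsv")
    metrics["fusion_count"] = len(fusions)
    lost = [(ev.chrom, b) for ev in fusions for b in ev.lost_boundaries]
    metrics["lost_boundary_count"] = len(lost)
    if lost:
        deltas = []
        for chrom, b in lost:
            off, _ = bins.chrom_span(chrom)
            d = ins2.score[off + b] - ins1.score[off + b]
            if np.isfinite(d):
                deltas.append(d)
        metrics["insulation_change_at_lost_boundaries"] = (
            float(np.mean(deltas)) if deltas else None)
    else:
        metrics["insulation_change_at_lost_boundaries"] = None
    done("fusions", tol=cfg.fusion_tol_bins)

    # --- integrate -------------------------------------------------------
    begin("integrate")
    union: dict[str, list[int]] = {}
    for chrom in bins.chrom_names:
        union[chrom] = sorted(set(b1.get(chrom, [])) | set(b2.get(chrom, [])))
    cls = classify_degs(degs, bins, union, cfg.deg_flank_bins, fusions)
    cls.table.to_csv(outdir / "deg_classification.tsv", sep="\t", index=False)
    enrich = enrichment_test(cls)
    enrich.to_csv(outdir / "deg_enrichment.tsv", sep="\t", index=False)
    metrics["deg_boundary_fraction_all"] = cls.fraction_boundary_all
    metrics["deg_boundary_fraction_up"] = cls.fraction_boundary_up
    metrics["deg_boundary_fraction_down"] = cls.fraction_boundary_down
    metrics["deg_category_counts"] = cls.counts()
    metrics["upg_tad"] = cls.upg_tad
    metrics["dwg_tad"] = cls.dwg_tad
    up_merged = enrich[(enrich["direction"] == "up") & (enrich["category"] == "merged_tad")]
    metrics["upg_tad_odds_ratio"] = float(up_merged["odds_ratio"].iloc[0])
    metrics["upg_tad_or_ci"] = [float(up_merged["ci_low"].iloc[0]),
                                float(up_merged["ci_high"].iloc[0])]
    metrics["upg_tad_q"] = float(up_merged["q"].iloc[0])
    done("integrate", flank=cfg.deg_flank_bins, boundary_set="union")

    outputs["report"] = "report.json"
    tio.write_json(report, outdir / "report.json")
    return report
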