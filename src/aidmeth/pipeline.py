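"""End-to-end orchestration: normalize -> test -> DMRs -> candidates, plus
the qPCR/expression branch, from one YAML-able config.

Every stage output is a plain TSV so intermediates stay inspectable and
diffable; each run writes a metadata record (config hash, seed, package
version) next to the outputs, and rerunning with an identical config
reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .bmiq import normalize_matrix
from .dmr import candidates_to_frame, dmr_heatmap_table, dmrs_to_frame, write_dmr_bed
from .io import (
    read_beta_matrix, read_ct_table, read_design, read_expression_matrix,
    read_manifest, write_beta_matrix,
)
from .mvp import PairedMethylationModel, summarize_global
from .qpcr import classify_aid_expressor, ddct_fold_change, delta_ct
from .reanalysis import (
    TwoGroupExpressionModel, UnimodalMarkerError, bimodal_split, correlation_screen,
)

__all__ = ["PipelineConfig", "run_methylation_pipeline", "run_expression_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run.  Thresholds default to the
    analysis regime: MVPs at raw p<0.05 (and 0.001 reported), DMRs of >=3
    MVPs per 1 kb window, candidates with >=2 hypomethylated regulatory
    MVPs, expression FDR 0.05, 3-fold ΔΔCt flag, AICDA Ct cutoff 32."""

    out_dir: str = "results"
    betas: str | None = None
    manifest: str | None = None
    design: str | None = None
    ct_table: str | None = None
    expression: str | None = None

    skip_bmiq: bool = False
    scale: str = "beta"
    p_mvp: float = 0.05
    p_strict: float = 0.001
    window_bp: int = 1000
    min_mvps: int = 3
    min_hypo_regulatory: int = 2
    fdr: float = 0.05
    ddct_flag_threshold: float = 3.0
    aid_ct_threshold: float = 32.0
    reference_gene: str = "GAPDH"
    calibrator_condition: str = "GFP"
    marker_gene: str = "AICDA"
    candidate_genes: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val, lo, hi in [("p_mvp", self.p_mvp, 0, 1), ("p_strict", self.p_strict, 0, 1),
                                  ("fdr", self.fdr, 0, 1)]:
            if not (lo < val <= hi):
                raise ValueError(f"{name} must lie in ({lo}, {hi}]")
        if self.window_bp < 1 or self.min_mvps < 1 or self.min_hypo_regulatory < 0:
            raise ValueError("window/min-MVP parameters must be positive")
        if self.ddct_flag_threshold <= 1:
            raise ValueError("ddct_flag_threshold must exceed 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "candidate_genes" in raw and raw["candidate_genes"] is not None:
            raw["candidate_genes"] = tuple(raw["candidate_genes"])
        return cls(**raw)

    def config_hash(self) -> str:
        fields = dataclasses.asdict(self)
        fields.pop("out_dir")  # hash the analysis, not where it lands
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_metadata(cfg: PipelineConfig, out: Path, stage: str) -> None:
    record = {"stage": stage, "config_hash": cfg.config_hash(), "seed": cfg.seed,
              "version": __version__}
    (out / f"{stage}.meta.json").write_text(json.dumps(record, sort_keys=True) + "\n")


def run_methylation_pipeline(cfg: PipelineConfig) -> dict[str, object]:
    """normalize -> mvp -> dmr -> candidates -> summaries.

    Returns the in-memory bundle and writes TSVs under ``cfg.out_dir``.
    """
    if not (cfg.betas and cfg.manifest and cfg.design):
        raise ValueError("methylation pipeline needs betas, manifest and design paths")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("reading inputs")
    betas = read_beta_matrix(cfg.betas)
    manifest = read_manifest(cfg.manifest)
    design = read_design(cfg.design, betas)

    log.info("stage normalize (skip_bmiq=%s)", cfg.skip_bmiq)
    try:
        norm = normalize_matrix(betas, manifest, skip=cfg.skip_bmiq, seed=cfg.seed)
    except Exception as exc:
        raise RuntimeError(f"stage 'normalize' failed: {exc}") from exc
    write_beta_matrix(norm, out / "betas.normalized.tsv")

    log.info("stage mvp (scale=%s)", cfg.scale)
    try:
        results = PairedMethylationModel(norm, design, manifest, scale=cfg.scale).fit()
    except Exception as exc:
        raise RuntimeError(f"stage 'mvp' failed: {exc}") from exc
    annotated = results.annotated_table()
    annotated.to_csv(out / "mvps.tsv", sep="\t", na_rep="NA")

    log.info("stage dmr")
    try:
        dmrs = results.call_dmrs(cfg.p_mvp, cfg.window_bp, cfg.min_mvps)
    except Exception as exc:
        raise RuntimeError(f"stage 'dmr' failed: {exc}") from exc
    dmrs_to_frame(dmrs).to_csv(out / "dmrs.tsv", sep="\t", index=False)
    write_dmr_bed(dmrs, out / "dmrs.bed")

    log.info("stage candidates")
    try:
        candidates = results.candidate_genes(
            cfg.p_mvp, cfg.window_bp, cfg.min_mvps, cfg.min_hypo_regulatory)
    except Exception as exc:
        raise RuntimeError(f"stage 'candidates' failed: {exc}") from exc
    candidates_to_frame(candidates).to_csv(out / "candidate_genes.tsv", sep="\t", index=False)

    log.info("stage summaries")
    summary = summarize_global(norm, manifest, design)
    summary.to_csv(out / "global_summary.tsv", sep="\t", index=False, na_rep="NA")
    heatmap = dmr_heatmap_table(dmrs, norm, design)
    heatmap.to_csv(out / "dmr_heatmap.tsv", sep="\t", na_rep="NA")
    (out / "mvp_summary.txt").write_text(
        results.summary((cfg.p_mvp, cfg.p_strict)) + "\n")
    _write_metadata(cfg, out, "methylation")

    return {
        "results": results,
        "mvps": annotated,
        "dmrs": dmrs,
        "candidates": candidates,
        "global_summary": summary,
        "heatmap": heatmap,
    }


def run_expression_pipeline(cfg: PipelineConfig) -> dict[str, object]:
    """qPCR quantification (ΔΔCt folds + AID screening) and cohort reanalysis."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, object] = {}

    if cfg.ct_table:
        log.info("stage qpcr")
        try:
            ct = read_ct_table(cfg.ct_table)
            dct = delta_ct(ct, cfg.reference_gene)
            conditions = list(dict.fromkeys(dct["condition"]))
            if cfg.calibrator_condition in conditions and len(conditions) > 1:
                cal = dct[dct["condition"] == cfg.calibrator_condition]
                folds = []
                for cond in conditions:
                    if cond == cfg.calibrator_condition:
                        continue
                    f = ddct_fold_change(dct[dct["condition"] == cond], cal,
                                         cfg.ddct_flag_threshold)
                    f.insert(1, "condition", cond)
                    folds.append(f)
                fold_table = pd.concat(folds, ignore_index=True) if folds else pd.DataFrame()
                fold_table.to_csv(out / "ddct_folds.tsv", sep="\t", index=False, na_rep="NA")
                bundle["folds"] = fold_table
            # screening: AID expressor classification from AICDA Ct
            aicda = dct[dct["gene"] == cfg.marker_gene]
            screening = aicda.assign(aid_class=[
                classify_aid_expressor(ct_, cfg.aid_ct_threshold) for ct_ in aicda["ct"]
            ])
            screening.to_csv(out / "aid_screening.tsv", sep="\t", index=False, na_rep="NA")
            bundle["delta_ct"] = dct
            bundle["screening"] = screening
        except Exception as exc:
            raise RuntimeError(f"stage 'qpcr' failed: {exc}") from exc

    if cfg.expression:
        log.info("stage reanalysis")
        try:
            expr = read_expression_matrix(cfg.expression)
            genes = list(cfg.candidate_genes) or None
            try:
                split = bimodal_split(expr, cfg.marker_gene, method="antimode")
                de = TwoGroupExpressionModel(expr, split, genes=genes).fit(fdr=cfg.fdr)
                de.table.to_csv(out / "reanalysis_de.tsv", sep="\t", na_rep="NA")
                (out / "reanalysis_summary.txt").write_text(de.summary() + "\n")
                bundle["split"] = split
                bundle["de"] = de
            except UnimodalMarkerError:
                log.warning("marker not bimodal; falling back to correlation screen")
                corr, (r2_min, r2_max) = correlation_screen(expr, cfg.marker_gene, genes)
                corr.to_csv(out / "reanalysis_correlation.tsv", sep="\t", na_rep="NA")
                bundle["correlation"] = corr
                bundle["r2_range"] = (r2_min, r2_max)
        except Exception as exc:
            raise RuntimeError(f"stage 'reanalysis' failed: {exc}") from exc

    _write_metadata(cfg, out, "expression")
    return bundle
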