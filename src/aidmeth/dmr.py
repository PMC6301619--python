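"""Windowed DMR calling and the candidate-gene filter cascade.

A differentially methylated region (DMR) is defined operationally: any
window of ``window_bp`` (default 1000 bp, inclusive of both endpoints)
containing at least ``min_mvps`` MVPs is a *qualifying window*; maximal
unions of overlapping qualifying windows, trimmed to their outermost member
MVPs, are emitted as DMRs.  Chained overlaps can therefore produce regions
longer than a single window — the per-window constraint, not the merged
span, carries the "3 MVPs in 1 kb" rule.

Candidate genes are the genes touched by any DMR that (a) are not
pseudogenes and (b) are supported by at least ``min_hypo_regulatory``
hypomethylated member MVPs sitting in a regulatory/transcribed feature
(TSS1500, TSS200, 5'UTR, 1st exon, gene body or 3'UTR).  A gene supported
by several DMRs pools its hypomethylated regulatory MVPs across them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .io import BetaMatrix, Manifest, PairedDesign, ValidationError

__all__ = [
    "DMR",
    "CandidateGene",
    "REGULATORY_FEATURES",
    "call_dmrs",
    "select_candidates",
    "dmr_heatmap_table",
    "dmrs_to_frame",
    "candidates_to_frame",
    "write_dmr_bed",
]

#: Features counting as regulatory/transcribed for the hypomethylation filter.
#: TSS200 and 1stExon are included because they fall within the positional
#: criterion (<=1500 bp upstream of the TSS / inside the transcript) even
#: though the manifest categories are disjoint.
REGULATORY_FEATURES = frozenset({"TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR"})


@dataclass
class DMR:
    """A called region: >=3 member MVPs, coordinates 1-based inclusive."""

    chromosome: str
    start: int
    end: int
    probe_ids: list[str]
    member_deltas: dict[str, float]  # probe id -> delta beta
    n_hypo: int
    n_hyper: int
    genes: frozenset[str]
    features_hit: dict[str, frozenset[str]]  # gene -> features of hypomethylated members

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def n_mvps(self) -> int:
        return len(self.probe_ids)


@dataclass
class CandidateGene:
    """A gene surviving (or failing) the filter cascade, with provenance."""

    gene: str
    supporting_dmrs: list[DMR] = field(default_factory=list)
    n_hypo_regulatory: int = 0
    excluded_reason: str | None = None  # pseudogene | insufficient_hypo | feature_mismatch

    @property
    def retained(self) -> bool:
        return self.excluded_reason is None


def call_dmrs(
    mvps: pd.DataFrame,
    manifest: Manifest,
    window_bp: int = 1000,
    min_mvps: int = 3,
    p_max: float = 0.05,
) -> list[DMR]:
    """Call DMRs from an MVP table (must carry ``p`` and ``delta_beta``).

    The result is deterministic, sorted by (chromosome, start), and
    invariant to the input row order.  Every member MVP satisfies
    ``p < p_max``.
    """
    if window_bp < 1 or min_mvps < 1:
        raise ValueError("window_bp and min_mvps must be positive")
    if (mvps["p"] >= p_max).any():
        raise ValidationError(f"call_dmrs expects MVPs pre-filtered to p < {p_max}")
    mdf = manifest.df
    missing = [pid for pid in mvps.index if pid not in mdf.index]
    if missing:
        raise ValidationError(f"MVPs without manifest positions: {missing[:5]}")

    ann = mdf.reindex(mvps.index)
    table = mvps.assign(chrom=ann["chrom"], pos=ann["pos"].astype(int))

    dmrs: list[DMR] = []
    for chrom, sub in table.groupby("chrom", sort=True):
        sub = sub.sort_values(["pos", "delta_beta"], kind="mergesort")
        pos = sub["pos"].to_numpy()
        n = len(pos)
        # qualifying cores: runs of min_mvps consecutive MVPs fitting one window
        cores: list[tuple[int, int]] = []
        for i in range(n - min_mvps + 1):
            j = i + min_mvps - 1
            if pos[j] - pos[i] <= window_bp - 1:  # inclusive span <= window_bp
                cores.append((i, j))
        if not cores:
            continue
        # union of overlapping member-index intervals
        merged: list[list[int]] = [list(cores[0])]
        for lo, hi in cores[1:]:
            if lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        for lo, hi in merged:
            members = sub.iloc[lo:hi + 1]
            dmrs.append(_build_dmr(chrom, members, mdf))
    return dmrs


def _build_dmr(chrom: str, members: pd.DataFrame, mdf: pd.DataFrame) -> DMR:
    hypo = members["delta_beta"] < 0
    genes: set[str] = set()
    features_hit: dict[str, set[str]] = {}
    for pid in members.index:
        row = mdf.loc[pid]
        genes.update(row["genes"])
        if members.loc[pid, "delta_beta"] < 0:
            for g in row["genes"]:
                features_hit.setdefault(g, set()).add(row["feature"])
    return DMR(
        chromosome=chrom,
        start=int(members["pos"].min()),
        end=int(members["pos"].max()),
        probe_ids=list(members.index),
        member_deltas={pid: float(members.loc[pid, "delta_beta"]) for pid in members.index},
        n_hypo=int(hypo.sum()),
        n_hyper=int((~hypo).sum()),
        genes=frozenset(genes),
        features_hit={g: frozenset(f) for g, f in features_hit.items()},
    )


def select_candidates(
    dmrs: list[DMR],
    manifest: Manifest,
    min_hypo_regulatory: int = 2,
    regulatory_features: frozenset[str] = REGULATORY_FEATURES,
) -> list[CandidateGene]:
    """Apply the filter cascade to every gene touched by a DMR.

    Exclusion reasons: ``pseudogene`` (flagged on the manifest),
    ``feature_mismatch`` (enough hypomethylated MVPs, but too few in
    regulatory features) or ``insufficient_hypo``.  Output is sorted by
    gene symbol; retained candidates come with their supporting DMRs.
    """
    mdf = manifest.df
    per_gene: dict[str, CandidateGene] = {}
    hypo_reg: dict[str, int] = {}
    hypo_total: dict[str, int] = {}
    for dmr in dmrs:
        for gene in dmr.genes:
            per_gene.setdefault(gene, CandidateGene(gene=gene)).supporting_dmrs.append(dmr)
        for pid in dmr.probe_ids:
            if dmr.member_deltas[pid] >= 0:
                continue
            row = mdf.loc[pid]
            for gene in row["genes"]:
                hypo_total[gene] = hypo_total.get(gene, 0) + 1
                if row["feature"] in regulatory_features:
                    hypo_reg[gene] = hypo_reg.get(gene, 0) + 1

    is_pseudo: dict[str, bool] = {}
    for gene in per_gene:
        rows = mdf[[gene in g for g in mdf["genes"]]]
        is_pseudo[gene] = bool(rows["is_pseudogene"].any())

    out = []
    for gene in sorted(per_gene):
        cand = per_gene[gene]
        cand.n_hypo_regulatory = hypo_reg.get(gene, 0)
        if is_pseudo[gene]:
            cand.excluded_reason = "pseudogene"
        elif cand.n_hypo_regulatory >= min_hypo_regulatory:
            cand.excluded_reason = None
        elif hypo_total.get(gene, 0) >= min_hypo_regulatory:
            cand.excluded_reason = "feature_mismatch"
        else:
            cand.excluded_reason = "insufficient_hypo"
        out.append(cand)
    return out


def dmr_heatmap_table(
    dmrs: list[DMR], betas: BetaMatrix, design: PairedDesign
) -> pd.DataFrame:
    """Per-patient delta-beta matrix of DMR member MVPs (Fig-style heatmap input).

    Rows are member probes (grouped per DMR with region / gene labels),
    columns are patients, values are per-patient treatment-minus-control
    beta differences.
    """
    design.validate_against(betas)
    rows = []
    index = []
    labels = []
    for k, dmr in enumerate(dmrs):
        region = f"{dmr.chromosome}:{dmr.start}-{dmr.end}"
        genes = ";".join(sorted(dmr.genes))
        for pid in dmr.probe_ids:
            ctrl = betas.values.loc[pid, list(design.control_samples)].to_numpy(float)
            trt = betas.values.loc[pid, list(design.treatment_samples)].to_numpy(float)
            rows.append(trt - ctrl)
            index.append(pid)
            labels.append((region, genes))
    out = pd.DataFrame(rows, index=pd.Index(index, name="probe_id"), columns=design.patients)
    out.insert(0, "dmr", [r for r, _ in labels])
    out.insert(1, "genes", [g for _, g in labels])
    return out


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "chrom": d.chromosome, "start": d.start, "end": d.end, "span": d.span,
            "n_mvps": d.n_mvps, "n_hypo": d.n_hypo, "n_hyper": d.n_hyper,
            "genes": ";".join(sorted(d.genes)), "probe_ids": ";".join(d.probe_ids),
        }
        for d in dmrs
    ])


def candidates_to_frame(candidates: list[CandidateGene]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "gene": c.gene,
            "retained": int(c.retained),
            "n_hypo_regulatory": c.n_hypo_regulatory,
            "n_supporting_dmrs": len(c.supporting_dmrs),
            "excluded_reason": c.excluded_reason or "",
        }
        for c in candidates
    ])


def write_dmr_bed(dmrs: list[DMR], path: str | Path) -> None:
    """Export DMRs as BED (0-based half-open, converted from 1-based inclusive)."""
    with open(path, "w") as fh:
        for d in dmrs:
            name = ";".join(sorted(d.genes)) or "."
            fh.write(f"{d.chromosome}\t{d.start - 1}\t{d.end}\t{name}\t{d.n_mvps}\n")
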