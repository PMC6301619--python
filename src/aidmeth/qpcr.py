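"""qPCR relative quantification: 2^-ΔCt screening, 2^-ΔΔCt fold changes,
AID-expressor classification and the bacterial mutator-frequency statistic.

Conventions
-----------
* Technical replicates are averaged on the Ct scale before any ΔCt.
* ΔCt = Ct(gene) - Ct(reference) per sample; 2^-ΔCt is the relative
  expression used for patient screening.  Targets with "Undetermined" Ct
  are reported at the sentinel 10^-11 with ``detected = False``.
* ΔΔCt = ΔCt(treated) - ΔCt(calibrator); fold = 2^-ΔΔCt.  Undetected
  genes are dropped from fold changes (not imputed) — the sentinel applies
  to screening output only.
* A sample is a non-AID-expressor iff its AICDA Ct is undetermined or
  strictly above the threshold (default 32 cycles).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "UNDETECTED_SENTINEL",
    "CtMeasurement",
    "average_replicates",
    "delta_ct",
    "ddct_fold_change",
    "classify_aid_expressor",
    "mutation_frequency",
]

log = logging.getLogger(__name__)

UNDETECTED_SENTINEL = 1e-11  # reported relative expression for undetermined Ct


@dataclass(frozen=True)
class CtMeasurement:
    """One well: sample, gene and threshold cycle (None = undetermined)."""

    sample_id: str
    gene: str
    ct: float | None
    condition: str = ""

    def __post_init__(self) -> None:
        if self.ct is not None and not (0 < self.ct <= 50):
            raise ValueError(f"Ct must lie in (0, 50], got {self.ct}")


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table.copy()
    return pd.DataFrame([
        {"sample_id": m.sample_id, "condition": m.condition, "gene": m.gene, "ct": m.ct}
        for m in table
    ]).astype({"ct": float})


def average_replicates(table) -> pd.DataFrame:
    """Mean Ct over technical replicates of (sample, condition, gene).

    A grouped measurement is undetected only if *all* replicates are; the
    mean is otherwise taken over the detected replicates.
    """
    df = _as_frame(table)
    if "condition" not in df.columns:
        df["condition"] = ""
    return (
        df.groupby(["sample_id", "condition", "gene"], as_index=False, sort=True)["ct"]
        .mean()
    )


def delta_ct(table, reference_gene: str) -> pd.DataFrame:
    """Per-(sample, condition, gene) ΔCt and 2^-ΔCt relative expression.

    Raises if the reference gene is missing or undetected in any sample.
    Undetected targets propagate: ΔCt is missing and the relative
    expression is the 10^-11 sentinel with ``detected = False``.
    """
    df = average_replicates(table)
    ref = df[df["gene"] == reference_gene].set_index(["sample_id", "condition"])["ct"]
    groups = df[["sample_id", "condition"]].drop_duplicates()
    for _, row in groups.iterrows():
        key = (row.sample_id, row.condition)
        if key not in ref.index or pd.isna(ref.loc[key]):
            raise ValueError(
                f"reference gene {reference_gene!r} undetected or absent in sample "
                f"{row.sample_id!r} (condition {row.condition!r})"
            )
    tgt = df[df["gene"] != reference_gene].copy()
    ref_ct = ref.loc[list(zip(tgt["sample_id"], tgt["condition"]))].to_numpy()
    tgt["delta_ct"] = tgt["ct"].to_numpy() - ref_ct
    tgt["detected"] = tgt["ct"].notna()
    tgt["rel_expr"] = np.where(tgt["detected"], np.power(2.0, -tgt["delta_ct"]), UNDETECTED_SENTINEL)
    return tgt[["sample_id", "condition", "gene", "ct", "delta_ct", "rel_expr", "detected"]]


def ddct_fold_change(
    treated: pd.DataFrame,
    calibrator: pd.DataFrame,
    flag_threshold: float = 3.0,
) -> pd.DataFrame:
    """2^-ΔΔCt fold change of each (sample, gene) versus the calibrator.

    Both inputs are :func:`delta_ct` frames.  Genes undetected in either
    condition are dropped (with a log warning for genes missing from the
    calibrator); ``exceeds_flag`` marks folds beyond ``flag_threshold``-fold
    up or down.
    """
    if flag_threshold <= 1:
        raise ValueError("flag_threshold must exceed 1")
    cal = calibrator[calibrator["detected"]].set_index(["sample_id", "gene"])["delta_ct"]
    rows = []
    for r in treated.itertuples(index=False):
        key = (r.sample_id, r.gene)
        if key not in cal.index:
            log.warning("gene %s missing/undetected in calibrator for sample %s; skipped",
                        r.gene, r.sample_id)
            continue
        if not r.detected:
            continue
        ddct = r.delta_ct - cal.loc[key]
        fold = 2.0 ** (-ddct)
        rows.append({
            "sample_id": r.sample_id, "gene": r.gene, "ddct": ddct, "fold": fold,
            "exceeds_flag": bool(fold > flag_threshold or fold < 1.0 / flag_threshold),
        })
    return pd.DataFrame(rows, columns=["sample_id", "gene", "ddct", "fold", "exceeds_flag"])


def classify_aid_expressor(ct_aicda: float | None, threshold: float = 32.0) -> str:
    """AID-expressor call from the AICDA Ct.

    ``non_expressor`` iff the Ct is undetermined or strictly above the
    threshold; a Ct exactly at the threshold counts as an expressor.
    """
    if ct_aicda is None or (isinstance(ct_aicda, float) and np.isnan(ct_aicda)):
        return "non_expressor"
    return "non_expressor" if ct_aicda > threshold else "expressor"


def mutation_frequency(counts: pd.DataFrame) -> tuple[pd.DataFrame, float, float]:
    """Mutator-assay frequencies: Rif-resistant / total clones, per clone.

    ``counts`` needs columns clone_id, rif_resistant, total.  Returns the
    per-clone table plus the mean and sample standard deviation across
    clones.
    """
    df = counts.copy()
    required = {"clone_id", "rif_resistant", "total"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts table missing columns: {sorted(required - set(df.columns))}")
    if (df["total"] <= 0).any():
        raise ValueError("total clone counts must be positive")
    if ((df["rif_resistant"] < 0) | (df["rif_resistant"] > df["total"])).any():
        raise ValueError("rif_resistant must lie in [0, total]")
    df["frequency"] = df["rif_resistant"] / df["total"]
    mean = float(df["frequency"].mean())
    sd = float(df["frequency"].std(ddof=1)) if len(df) > 1 else 0.0
    return df, mean, sd
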