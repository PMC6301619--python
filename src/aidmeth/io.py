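"""Tabular formats shared by every pipeline stage.

One canonical TSV dialect throughout: tab separated, UTF-8, ``.`` decimal,
``NA`` for missing values.  All genomic coordinates are 1-based point
coordinates (the CpG site); windows are inclusive of both endpoints.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_CATEGORIES",
    "CGI_CATEGORIES",
    "ProbeAnnotation",
    "Manifest",
    "BetaMatrix",
    "PairedDesign",
    "ValidationError",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_manifest",
    "write_manifest",
    "read_design",
    "write_design",
    "read_ct_table",
    "write_ct_table",
    "read_expression_matrix",
    "write_expression_matrix",
]

#: Gene-feature categories relative to a transcript, as on the EPIC manifest.
FEATURE_CATEGORIES = ("TSS1500", "TSS200", "1stExon", "5UTR", "Body", "3UTR", "IGR")

#: Probe position classes relative to CpG islands.
CGI_CATEGORIES = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

MISSING = "NA"


class ValidationError(ValueError):
    """Raised when an input file or in-memory table violates its contract."""


@dataclass(frozen=True)
class ProbeAnnotation:
    """One manifest row: where a probe sits and what it annotates.

    ``position`` is the 1-based coordinate of the interrogated CpG.
    ``genes`` may be empty (intergenic probes); a probe listing several
    genes contributes to every one of them downstream.
    """

    probe_id: str
    chromosome: str
    position: int
    design_type: str  # "I" or "II"
    genes: frozenset[str] = frozenset()
    feature: str = "IGR"
    cgi_relation: str = "OpenSea"
    is_pseudogene: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"probe {self.probe_id}: position must be >= 1")
        if self.design_type not in ("I", "II"):
            raise ValidationError(
                f"probe {self.probe_id}: design_type must be 'I' or 'II', got {self.design_type!r}"
            )
        if self.feature not in FEATURE_CATEGORIES:
            raise ValidationError(
                f"probe {self.probe_id}: feature {self.feature!r} not in {FEATURE_CATEGORIES}"
            )
        if self.cgi_relation not in CGI_CATEGORIES:
            raise ValidationError(
                f"probe {self.probe_id}: cgi_relation {self.cgi_relation!r} not in {CGI_CATEGORIES}"
            )


class Manifest:
    """An ordered collection of :class:`ProbeAnnotation`, sorted by (chromosome, position).

    Iterating yields annotations; ``manifest.df`` exposes the underlying
    frame (indexed by probe id) for vectorised access.
    """

    COLUMNS = ("probe_id", "chrom", "pos", "design_type", "genes", "feature",
               "cgi_relation", "is_pseudogene")

    def __init__(self, annotations: Iterable[ProbeAnnotation]):
        records = sorted(annotations, key=lambda a: (a.chromosome, a.position))
        seen: set[str] = set()
        for a in records:
            if a.probe_id in seen:
                raise ValidationError(f"duplicate probe id in manifest: {a.probe_id}")
            seen.add(a.probe_id)
        self._records: list[ProbeAnnotation] = records
        self._df = pd.DataFrame(
            {
                "chrom": [a.chromosome for a in records],
                "pos": [a.position for a in records],
                "design_type": [a.design_type for a in records],
                "genes": [a.genes for a in records],
                "feature": [a.feature for a in records],
                "cgi_relation": [a.cgi_relation for a in records],
                "is_pseudogene": [a.is_pseudogene for a in records],
            },
            index=pd.Index([a.probe_id for a in records], name="probe_id"),
        )

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ProbeAnnotation]:
        return iter(self._records)

    def __getitem__(self, probe_id: str) -> ProbeAnnotation:
        idx = self._df.index.get_loc(probe_id)
        return self._records[idx]

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self._df.index

    def subset(self, probe_ids: Sequence[str]) -> "Manifest":
        wanted = set(probe_ids)
        return Manifest(a for a in self._records if a.probe_id in wanted)


@dataclass
class BetaMatrix:
    """Probe x sample beta values in [0, 1]; NaN marks a missing cell."""

    values: pd.DataFrame  # index = probe ids, columns = sample ids

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids: {dups[:5]}")
        if df.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        arr = df.to_numpy(dtype=float)
        bad = np.where(~np.isnan(arr) & ((arr < 0) | (arr > 1)))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValidationError(
                f"beta value {arr[i, j]} outside [0, 1] at probe "
                f"{df.index[i]!r}, sample {df.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class PairedDesign:
    """Per-patient (control, treatment) sample pairing."""

    pairs: tuple[tuple[str, str, str], ...]  # (patient, control_sample, treatment_sample)

    def __post_init__(self) -> None:
        patients = [p for p, _, _ in self.pairs]
        if len(set(patients)) != len(patients):
            dup = [p for p in patients if patients.count(p) > 1][0]
            raise ValidationError(f"patient listed twice in design: {dup}")
        samples = [s for _, c, t in self.pairs for s in (c, t)]
        if len(set(samples)) != len(samples):
            raise ValidationError("a sample is used more than once in the design")

    @property
    def patients(self) -> list[str]:
        return [p for p, _, _ in self.pairs]

    @property
    def control_samples(self) -> list[str]:
        return [c for _, c, _ in self.pairs]

    @property
    def treatment_samples(self) -> list[str]:
        return [t for _, _, t in self.pairs]

    def validate_against(self, betas: BetaMatrix) -> None:
        missing = [s for s in self.control_samples + self.treatment_samples
                   if s not in betas.values.columns]
        if missing:
            raise ValidationError(f"design references samples absent from matrix: {missing}")

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# readers / writers


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    """Read a beta-value TSV (first column probe ids, header row sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING], keep_default_na=False)
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric beta value in {path}: {exc}") from exc
    return BetaMatrix(df)


def write_beta_matrix(betas: BetaMatrix, path: str | Path) -> None:
    betas.values.to_csv(path, sep="\t", na_rep=MISSING, index_label="probe_id")


def _parse_genes(raw: object) -> frozenset[str]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return frozenset()
    text = str(raw).strip()
    if not text or text == MISSING:
        return frozenset()
    return frozenset(g.strip() for g in text.split(";") if g.strip())


def read_manifest(path: str | Path) -> Manifest:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING], keep_default_na=False)
    required = set(Manifest.COLUMNS)
    if not required.issubset(df.columns):
        raise ValidationError(f"manifest missing columns: {sorted(required - set(df.columns))}")
    annotations = []
    for row in df.itertuples(index=False):
        annotations.append(
            ProbeAnnotation(
                probe_id=row.probe_id,
                chromosome=row.chrom,
                position=int(row.pos),
                design_type=row.design_type,
                genes=_parse_genes(row.genes),
                feature=row.feature,
                cgi_relation=row.cgi_relation,
                is_pseudogene=str(row.is_pseudogene).strip().lower() in ("1", "true", "yes"),
            )
        )
    return Manifest(annotations)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    rows = []
    for a in manifest:
        rows.append({
            "probe_id": a.probe_id,
            "chrom": a.chromosome,
            "pos": a.position,
            "design_type": a.design_type,
            "genes": ";".join(sorted(a.genes)),
            "feature": a.feature,
            "cgi_relation": a.cgi_relation,
            "is_pseudogene": int(a.is_pseudogene),
        })
    pd.DataFrame(rows, columns=list(Manifest.COLUMNS)).to_csv(path, sep="\t", index=False)


def read_design(path: str | Path, betas: BetaMatrix | None = None) -> PairedDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"patient", "control_sample", "treatment_sample"}
    if not required.issubset(df.columns):
        raise ValidationError(f"design missing columns: {sorted(required - set(df.columns))}")
    design = PairedDesign(tuple(
        (r.patient, r.control_sample, r.treatment_sample) for r in df.itertuples(index=False)
    ))
    if betas is not None:
        design.validate_against(betas)
    return design


def write_design(design: PairedDesign, path: str | Path) -> None:
    pd.DataFrame(
        list(design.pairs), columns=["patient", "control_sample", "treatment_sample"]
    ).to_csv(path, sep="\t", index=False)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct table: sample_id, condition, gene, ct.

    'Undetermined' or 'NA' Ct cells become NaN (undetected).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING, "Undetermined"],
                     keep_default_na=False)
    required = {"sample_id", "condition", "gene", "ct"}
    if not required.issubset(df.columns):
        raise ValidationError(f"Ct table missing columns: {sorted(required - set(df.columns))}")
    df = df.copy()
    df["ct"] = df["ct"].astype(float)
    detected = df["ct"].notna()
    if ((df.loc[detected, "ct"] <= 0) | (df.loc[detected, "ct"] > 50)).any():
        raise ValidationError("Ct values must lie in (0, 50] (50-cycle protocol)")
    return df[["sample_id", "condition", "gene", "ct"]]


def write_ct_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", na_rep=MISSING, index=False)


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample log2-expression TSV (first column gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING], keep_default_na=False)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    df = df.astype(float)
    if not np.isfinite(df.to_numpy()).all():
        raise ValidationError("expression matrix must be finite")
    return df


def write_expression_matrix(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", na_rep=MISSING, index_label="gene")
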