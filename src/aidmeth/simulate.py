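"""Synthetic EPIC-array, expression-cohort and qPCR data generators.

Everything the pipeline consumes can be simulated here with the statistical
structure the analysis assumes: three-state beta-value mixtures
(unmethylated / hemimethylated / methylated), Type II probe compression
toward 0.5, a paired per-patient control/treatment design, planted
per-probe delta-beta effects bounded at ±0.20, planted clusters of >=3
affected probes within 1 kb near annotated gene features, and a cohort
expression matrix with one bimodally expressed marker gene.

Determinism: all draws come from ``numpy.random.default_rng`` streams
derived from the config seed, so a fixed config reproduces byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import (
    CGI_CATEGORIES,
    FEATURE_CATEGORIES,
    BetaMatrix,
    Manifest,
    PairedDesign,
    ProbeAnnotation,
)

__all__ = [
    "PlantedDMR",
    "SimulationConfig",
    "CtExperiment",
    "simulate_manifest",
    "simulate_paired_betas",
    "simulate_expression_cohort",
    "simulate_ct_table",
]

MAX_PLANTED_DELTA = 0.20  # the analysis regime: per-probe changes at most +/-20%


@dataclass(frozen=True)
class PlantedDMR:
    """A planted cluster of affected probes: >=3 probes within <=1000 bp."""

    chromosome: str
    anchor: int              # 1-based position of the first probe
    n_probes: int
    span: int                # inclusive bp from first to last probe
    delta_beta: float
    gene: str = ""
    feature: str = "TSS1500"
    is_pseudogene: bool = False

    def __post_init__(self) -> None:
        if self.n_probes < 3:
            raise ValueError("a planted DMR needs >= 3 probes")
        if self.span > 1000 or self.span < self.n_probes:
            raise ValueError("planted DMR span must be in [n_probes, 1000] bp")
        if abs(self.delta_beta) > MAX_PLANTED_DELTA + 1e-12:
            raise ValueError(f"|delta_beta| must be <= {MAX_PLANTED_DELTA}")
        if self.feature not in FEATURE_CATEGORIES:
            raise ValueError(f"unknown feature {self.feature!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic EPIC experiment.

    Defaults emulate the real design: 4 patients, a mostly-Type-II EPIC
    chip, a methylome that is bimodal with state means near 0.1 / 0.5 /
    0.9, mild Type II compression, and paired-replicate noise applied on
    the logit(beta) scale.
    """

    n_probes: int = 10_000
    n_patients: int = 4
    frac_type2: float = 0.84
    state_weights: tuple[float, float, float] = (0.35, 0.15, 0.50)
    state_shapes: tuple[tuple[float, float], ...] = ((2.0, 18.0), (10.0, 10.0), (18.0, 2.0))
    type2_compression: float = 0.25
    planted_mvp_effects: tuple[tuple[tuple[int, ...], float], ...] = ()
    planted_dmrs: tuple[PlantedDMR, ...] = ()
    noise_sd_logit: float = 0.25
    frac_genic: float = 0.6
    frac_pseudogene: float = 0.05
    n_chromosomes: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 10:
            raise ValueError("n_probes must be >= 10")
        if not (0 <= self.frac_type2 <= 1):
            raise ValueError("frac_type2 must be in [0, 1]")
        if abs(sum(self.state_weights) - 1.0) > 1e-12:
            raise ValueError("state_weights must sum to 1 (within 1e-12)")
        if any(a <= 0 or b <= 0 for a, b in self.state_shapes):
            raise ValueError("state shape parameters must be positive")
        if not (0 <= self.type2_compression <= 1):
            raise ValueError("type2_compression must be in [0, 1]")
        if self.noise_sd_logit < 0:
            raise ValueError("noise_sd_logit must be >= 0")
        if not (0 <= self.frac_pseudogene <= 1 and 0 <= self.frac_genic <= 1):
            raise ValueError("fractions must be in [0, 1]")
        for probes, delta in self.planted_mvp_effects:
            if abs(delta) > MAX_PLANTED_DELTA + 1e-12:
                raise ValueError(f"|planted delta_beta| must be <= {MAX_PLANTED_DELTA}")
            if any(i < 0 or i >= self.n_probes for i in probes):
                raise ValueError("planted MVP probe index out of range")


def _background_probe_id(i: int) -> str:
    return f"cg{i:08d}"


def _dmr_probe_id(k: int, j: int) -> str:
    return f"cgDMR{k:02d}{j:03d}"


def simulate_manifest(cfg: SimulationConfig) -> Manifest:
    """Generate a probe manifest: background probes plus planted DMR probes.

    Background probe ids encode the generation index (``cg%08d``) so that
    planted per-probe effects referenced by index in the config can be
    resolved after sorting; planted DMR probes get ``cgDMR<k><j>`` ids.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    chroms = [f"chr{c + 1}" for c in range(cfg.n_chromosomes)]
    chrom_of = rng.integers(0, cfg.n_chromosomes, size=cfg.n_probes)
    gaps = rng.integers(500, 5000, size=cfg.n_probes)

    annotations: list[ProbeAnnotation] = []
    pseudo_flags: dict[str, bool] = {}
    positions: dict[int, int] = {c: 0 for c in range(cfg.n_chromosomes)}
    for i in range(cfg.n_probes):
        c = int(chrom_of[i])
        positions[c] += int(gaps[i])
        pos = positions[c]
        genic = rng.random() < cfg.frac_genic
        if genic:
            gene = f"GENE_{chroms[c]}_{pos // 50_000}"
            if gene not in pseudo_flags:
                pseudo_flags[gene] = bool(rng.random() < cfg.frac_pseudogene)
            genes = frozenset({gene})
            feature = FEATURE_CATEGORIES[rng.integers(0, 6)]  # genic categories
            pseudo = pseudo_flags[gene]
        else:
            genes = frozenset()
            feature = "IGR"
            pseudo = False
        annotations.append(ProbeAnnotation(
            probe_id=_background_probe_id(i),
            chromosome=chroms[c],
            position=pos,
            design_type="II" if rng.random() < cfg.frac_type2 else "I",
            genes=genes,
            feature=feature,
            cgi_relation=CGI_CATEGORIES[rng.integers(0, len(CGI_CATEGORIES))],
            is_pseudogene=pseudo,
        ))

    for k, dmr in enumerate(cfg.planted_dmrs):
        offsets = np.linspace(0, dmr.span - 1, dmr.n_probes).round().astype(int)
        offsets = np.unique(offsets)
        if len(offsets) < dmr.n_probes:  # extremely tight spans: force distinct
            offsets = np.arange(dmr.n_probes)
        gene = dmr.gene or f"DMRGENE{k}"
        for j, off in enumerate(offsets):
            annotations.append(ProbeAnnotation(
                probe_id=_dmr_probe_id(k, j),
                chromosome=dmr.chromosome,
                position=dmr.anchor + int(off),
                design_type="II" if rng.random() < cfg.frac_type2 else "I",
                genes=frozenset({gene}),
                feature=dmr.feature,
                cgi_relation="Island",
                is_pseudogene=dmr.is_pseudogene,
            ))
    return Manifest(annotations)


def planted_delta_map(cfg: SimulationConfig) -> dict[str, float]:
    """Probe id -> planted treatment-minus-control beta shift."""
    out: dict[str, float] = {}
    for probes, delta in cfg.planted_mvp_effects:
        for i in probes:
            out[_background_probe_id(i)] = delta
    for k, dmr in enumerate(cfg.planted_dmrs):
        for j in range(dmr.n_probes):
            out[_dmr_probe_id(k, j)] = dmr.delta_beta
    return out


def simulate_paired_betas(
    cfg: SimulationConfig, manifest: Manifest
) -> tuple[BetaMatrix, PairedDesign]:
    """Simulate the paired control/treatment beta matrix for a manifest.

    Per probe: a baseline beta drawn from the three-state mixture (shared
    across patients and between a patient's two samples); the treatment
    sample adds the planted delta-beta (clamped to [0, 1]); Type II probes
    are compressed toward 0.5; finally independent Gaussian noise on the
    logit scale is applied per sample and back-transformed, which keeps
    values inside (0, 1) without clamping the noise itself.
    """
    expected = {a.probe_id for a in simulate_manifest(cfg)}
    if {a.probe_id for a in manifest} != expected:
        raise ValueError("manifest does not match this SimulationConfig")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    probes = [a.probe_id for a in manifest]
    n = len(probes)
    weights = np.asarray(cfg.state_weights)
    states = rng.choice(3, size=n, p=weights)
    shapes = np.asarray(cfg.state_shapes)
    baseline = rng.beta(shapes[states, 0], shapes[states, 1])

    deltas = planted_delta_map(cfg)
    delta_vec = np.array([deltas.get(p, 0.0) for p in probes])
    is2 = np.array([a.design_type == "II" for a in manifest])

    ctrl_mean = baseline
    trt_mean = np.clip(baseline + delta_vec, 0.0, 1.0)
    c = cfg.type2_compression
    ctrl_mean = np.where(is2, 0.5 + (1.0 - c) * (ctrl_mean - 0.5), ctrl_mean)
    trt_mean = np.where(is2, 0.5 + (1.0 - c) * (trt_mean - 0.5), trt_mean)

    eps = 1e-6
    cols: dict[str, np.ndarray] = {}
    pairs = []
    sample_order: list[str] = []
    for p in range(cfg.n_patients):
        patient = f"P{p + 1}"
        for cond, mean in (("ctrl", ctrl_mean), ("aid", trt_mean)):
            sid = f"{patient}_{cond}"
            if cfg.noise_sd_logit > 0:
                z = logit(np.clip(mean, eps, 1 - eps))
                z = z + rng.normal(0.0, cfg.noise_sd_logit, size=n)
                cols[sid] = expit(z)
            else:
                cols[sid] = mean.copy()
            sample_order.append(sid)
        pairs.append((patient, f"{patient}_ctrl", f"{patient}_aid"))

    df = pd.DataFrame(cols, index=pd.Index(probes, name="probe_id"), columns=sample_order)
    return BetaMatrix(df), PairedDesign(tuple(pairs))


def simulate_expression_cohort(
    n_samples: int,
    n_genes: int,
    marker_bimodal: tuple[float, float, float] = (4.0, 8.0, 0.3),
    seed: int = 0,
    marker_gene: str = "AICDA",
    planted_association: dict[str, float] | None = None,
    noise_sd: float = 0.5,
) -> pd.DataFrame:
    """Simulate a log2 expression cohort with one bimodal marker gene.

    ``marker_bimodal`` is (low-group mean, high-group mean, high fraction).
    ``planted_association`` maps gene names to log2 effects added to the
    marker-high samples, planting a real group difference for those genes.
    The high-group sample ids are recorded in ``.attrs['high_samples']``.
    """
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    low, high, frac = marker_bimodal
    if not (0 < frac < 1):
        raise ValueError("high fraction must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    if marker_gene not in genes:
        genes = [marker_gene] + genes[: n_genes - 1]

    is_high = rng.random(n_samples) < frac
    base = rng.normal(7.0, 1.5, size=len(genes))
    vals = base[:, None] + rng.normal(0.0, noise_sd, size=(len(genes), n_samples))
    df = pd.DataFrame(vals, index=pd.Index(genes, name="gene"), columns=samples)
    df.loc[marker_gene] = np.where(is_high, high, low) + rng.normal(0.0, noise_sd, n_samples)
    for gene, effect in (planted_association or {}).items():
        if gene not in df.index:
            raise ValueError(f"planted gene {gene!r} not in the matrix")
        df.loc[gene] = df.loc[gene].to_numpy() + effect * is_high
    df.attrs["high_samples"] = [s for s, h in zip(samples, is_high) if h]
    return df


@dataclass(frozen=True)
class CtExperiment:
    """Descriptor of a qPCR experiment for :func:`simulate_ct_table`.

    ``conditions[0]`` is the calibrator (e.g. the GFP-transfected
    condition).  ``base_delta_ct`` is each gene's true ΔCt versus the
    reference gene in the calibrator condition.
    """

    samples: tuple[str, ...]
    genes: tuple[str, ...]
    reference_gene: str = "GAPDH"
    conditions: tuple[str, ...] = ("GFP", "AID-GFP")
    reference_ct: float = 18.0
    base_delta_ct: float = 6.0
    undetected_genes: tuple[str, ...] = ()
    aicda_ct: float | None = None   # force a specific AICDA Ct (above/below 32)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.reference_gene in self.undetected_genes:
            raise ValueError("the reference gene cannot be undetected")


def simulate_ct_table(
    design: CtExperiment,
    true_fold_changes: dict[str, float],
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a Ct table realising the configured true fold changes.

    In the calibrator condition every gene sits at its base ΔCt; in a
    treated condition gene g's ΔCt is shifted by -log2(fold_g), so the
    downstream 2^-ΔΔCt recovers ``true_fold_changes`` exactly at zero
    noise.  Genes in ``undetected_genes`` are emitted with missing Ct
    (non-detection flag).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    rows = []
    for sample in design.samples:
        for ci, cond in enumerate(design.conditions):
            ref_ct = design.reference_ct + rng.normal(0, design.noise_sd)
            rows.append({"sample_id": sample, "condition": cond,
                         "gene": design.reference_gene, "ct": ref_ct})
            for gene in design.genes:
                if gene == design.reference_gene:
                    continue
                if gene in design.undetected_genes:
                    rows.append({"sample_id": sample, "condition": cond,
                                 "gene": gene, "ct": np.nan})
                    continue
                dct = design.base_delta_ct
                if ci > 0:
                    fold = true_fold_changes.get(gene, 1.0)
                    if fold <= 0:
                        raise ValueError("true fold changes must be positive")
                    dct = dct - np.log2(fold)
                ct = ref_ct + dct + rng.normal(0, design.noise_sd)
                if gene == "AICDA" and design.aicda_ct is not None:
                    ct = design.aicda_ct
                rows.append({"sample_id": sample, "condition": cond, "gene": gene, "ct": ct})
    return pd.DataFrame(rows, columns=["sample_id", "condition", "gene", "ct"])
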