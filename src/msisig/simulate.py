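"""Synthetic study generator with the statistical structure the pipeline assumes.

A cohort has three latent classes: MSI tumours carrying a dominant expression
program over the informative genes, an MSI-like subgroup of hospital-MSS
tumours sharing that program at attenuated strength, and MSS tumours.
Hospital assessment sees only the MSI / MSS dichotomy and errs at a small
rate.  Companion generators emit a kinome-panel variant table with
class-dependent per-gene mutation rates (plus labelled decoy records that
violate the inclusion filters), exponential distant-metastasis-free survival
with a protective hazard ratio for signature-positive classes, and technical
replicate hybridizations with day and operator offsets.

Everything is driven by a single integer seed: identical configuration and
seed give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import (
    MSI,
    MSI_LIKE,
    MSS,
    VARIANT_COLUMNS,
    ExpressionMatrix,
    validate_clinical_table,
    validate_variant_table,
)

__all__ = [
    "GeneratorConfig",
    "CohortTruth",
    "simulate_cohort",
    "simulate_variants",
    "simulate_survival",
    "simulate_replicates",
    "default_panel",
]

TYMS_GENE = "TYMS"


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohorts.

    Defaults emulate the development setting: 276 samples at 11% MSI
    prevalence, 64 informative genes out of 1000 shifted by two within-class
    standard deviations (0.6x in the MSI-like subgroup, which makes up 10%
    of hospital-MSS tumours), a 615-gene mutation panel with per-gene
    mutation rates of 8.2% / 6.4% / 1.6% for MSI / MSI-like / MSS, a
    protective hazard ratio of 0.25 for signature-positive tumours against a
    20% ten-year event rate in MSS, and 5% technical noise.
    """

    n_samples: int = 276
    prevalence_msi: float = 0.11
    prevalence_msi_like_among_mss: float = 0.10
    n_genes: int = 1000
    n_informative: int = 64
    effect_size_msi: float = 2.0  # mean shift in units of gene SD
    effect_attenuation_msi_like: float = 0.6
    gene_sd: float = 1.0
    tech_noise_sd: float = 0.05
    hospital_error_rate: float = 0.02
    mut_rate_msi: float = 0.082
    mut_rate_msi_like: float = 0.064
    mut_rate_mss: float = 0.016
    hazard_ratio_positive: float = 0.25
    event_rate_mss: float = 0.2  # 10-year event fraction in the MSS stratum
    horizon_years: float = 10.0
    panel_size: int = 615
    decoy_fraction: float = 0.2
    tyms_shift_msi: float = 0.4
    tyms_shift_msi_like: float = 0.3
    braf_mutant_rate: dict = field(
        default_factory=lambda: {MSI: 0.64, MSI_LIKE: 0.17, MSS: 0.02}
    )
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.prevalence_msi,
            self.prevalence_msi_like_among_mss,
            self.hospital_error_rate,
            self.mut_rate_msi,
            self.mut_rate_msi_like,
            self.mut_rate_mss,
            self.event_rate_mss,
            self.decoy_fraction,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValidationError("probabilities must lie in [0, 1]")
        if self.n_informative > self.n_genes:
            raise ValidationError("n_informative exceeds n_genes")
        if min(self.n_samples, self.n_genes, self.panel_size) <= 0:
            raise ValidationError("sizes must be positive")
        if self.gene_sd <= 0 or self.tech_noise_sd < 0:
            raise ValidationError("noise scales must be positive")
        if self.hazard_ratio_positive < 0 or self.horizon_years <= 0:
            raise ValidationError("hazard ratio and horizon must be nonnegative/positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort, for recovery checks."""

    latent_class: np.ndarray  # per-sample, values MSS / MSI_LIKE / MSI
    informative_genes: list
    effect_signs: np.ndarray  # per informative gene, +1 or -1


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _spawn(rng: np.random.Generator) -> np.random.Generator:
    return np.random.default_rng(int(rng.integers(2**31)))


def default_panel(size: int = 615) -> list:
    return [f"KIN{i:04d}" for i in range(1, size + 1)]


def simulate_cohort(config: GeneratorConfig, seed: int | None = None):
    """Draw a full cohort: expression, clinical annotation and latent truth.

    Returns ``(ExpressionMatrix, clinical DataFrame, CohortTruth)``.  The
    expression matrix holds the informative-gene program plus a TYMS gene
    with class-dependent up-regulation; the clinical table carries the
    error-prone hospital MSI label, stage, BRAF status and DMFS follow-up
    from :func:`simulate_survival`.
    """
    config.validate()
    rng = _rng(config.seed if seed is None else seed)
    n = config.n_samples

    u = rng.random(n)
    latent = np.where(
        u < config.prevalence_msi,
        MSI,
        np.where(u < config.prevalence_msi + (1 - config.prevalence_msi) * config.prevalence_msi_like_among_mss,
                 MSI_LIKE, MSS),
    )

    gene_ids = [f"G{j:05d}" for j in range(1, config.n_genes + 1)] + [TYMS_GENE]
    informative = [gene_ids[j] for j in range(config.n_informative)]
    # Up/down direction is a fixed property of each program gene, shared by
    # every cohort drawn from the same configuration (else a signature frozen
    # on one cohort could not transfer to another).
    signs = np.where(np.arange(config.n_informative) % 2 == 0, 1.0, -1.0)

    values = rng.normal(0.0, config.gene_sd, size=(n, config.n_genes + 1))
    shift = np.zeros((n, config.n_informative))
    shift[latent == MSI] = config.effect_size_msi * config.gene_sd
    shift[latent == MSI_LIKE] = (
        config.effect_attenuation_msi_like * config.effect_size_msi * config.gene_sd
    )
    values[:, : config.n_informative] += shift * signs
    values[latent == MSI, -1] += config.tyms_shift_msi
    values[latent == MSI_LIKE, -1] += config.tyms_shift_msi_like

    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    matrix = ExpressionMatrix(sample_ids, gene_ids, values, {"scale": "log2"})

    hospital = np.where(latent == MSI, "MSI", "MSS")
    flip = rng.random(n) < config.hospital_error_rate
    hospital = np.where(flip, np.where(hospital == "MSI", "MSS", "MSI"), hospital)

    braf_rate = np.array([config.braf_mutant_rate[c] for c in latent])
    braf = np.where(rng.random(n) < braf_rate, "mutant", "wildtype")

    times, events = simulate_survival(latent, config, rng=_spawn(rng))

    clinical = validate_clinical_table(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "msi_hospital": hospital,
                "stage": "II",
                "braf": braf,
                "dmfs_years": times,
                "dmfs_event": events,
            }
        )
    )
    truth = CohortTruth(latent, informative, signs)
    return matrix, clinical, truth


def simulate_survival(latent_classes, config: GeneratorConfig, rng=None, seed: int | None = None):
    """Exponential DMFS times with administrative censoring at the horizon.

    The baseline hazard is set so the MSS stratum reaches the configured
    10-year event fraction; signature-positive classes (MSI, MSI-like) have
    their hazard multiplied by ``hazard_ratio_positive``.  Returns
    ``(times, events)``.
    """
    config.validate()
    if rng is None:
        rng = _rng(config.seed if seed is None else seed)
    latent = np.asarray(latent_classes)
    n = len(latent)
    base_rate = -np.log1p(-config.event_rate_mss) / config.horizon_years
    rate = np.where(latent == MSS, base_rate, base_rate * config.hazard_ratio_positive)
    with np.errstate(divide="ignore"):
        raw = np.where(rate > 0, rng.exponential(1.0, n) / np.where(rate > 0, rate, 1.0), np.inf)
    times = np.minimum(raw, config.horizon_years)
    events = (raw <= config.horizon_years).astype(int)
    return times, events


def _true_variant(rng: np.random.Generator) -> dict:
    """One record guaranteed to survive the inclusion filters."""
    coverage = max(10, int(rng.negative_binomial(10, 10.0 / 90.0)))  # mean ~80
    vaf = rng.beta(4, 6)
    vc = int(np.clip(rng.binomial(coverage, vaf), 5, coverage))
    fwd = int(np.clip(rng.binomial(vc, 0.5), 1, vc - 1))
    return {
        "coverage": coverage,
        "variant_count": vc,
        "fwd_variant_count": fwd,
        "rev_variant_count": vc - fwd,
        "consequence": "coding_change",
        "in_normal_panel": False,
    }


def _decoy_variant(rng: np.random.Generator) -> dict:
    """One record violating exactly one inclusion filter."""
    rec = _true_variant(rng)
    mode = rng.integers(5)
    if mode == 0:  # low coverage
        rec["coverage"] = int(rng.integers(5, 10))
        vc = min(rec["variant_count"], rec["coverage"])
        rec["variant_count"] = vc
        fwd = int(np.clip(rec["fwd_variant_count"], 1, vc - 1)) if vc >= 2 else vc
        rec["fwd_variant_count"] = fwd
        rec["rev_variant_count"] = vc - fwd
    elif mode == 1:  # low variant support
        vc = int(rng.integers(2, 5))
        fwd = int(rng.integers(1, vc))
        rec.update(variant_count=vc, fwd_variant_count=fwd, rev_variant_count=vc - fwd)
    elif mode == 2:  # single-strand detection
        rec["fwd_variant_count"] = rec["variant_count"]
        rec["rev_variant_count"] = 0
    elif mode == 3:  # non-coding consequence
        rec["consequence"] = "other"
    else:  # germline
        rec["in_normal_panel"] = True
    return rec


def simulate_variants(
    latent_classes,
    config: GeneratorConfig,
    panel=None,
    seed: int | None = None,
    sample_ids=None,
):
    """Kinome-panel variant records for each sample.

    Each panel gene is mutated with its class rate; mutated genes emit 1-3
    records that pass every inclusion filter.  On top, a
    ``decoy_fraction``-sized fraction of additional records each violate one
    filter, so downstream filtering is exercised.  Returns
    ``(VariantTable DataFrame, decoy flags)`` with flags aligned to rows.
    """
    config.validate()
    rng = _rng(config.seed + 1 if seed is None else seed)
    latent = np.asarray(latent_classes)
    if panel is None:
        panel = default_panel(config.panel_size)
    panel = list(panel)
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(1, len(latent) + 1)]
    rate_by_class = {MSI: config.mut_rate_msi, MSI_LIKE: config.mut_rate_msi_like, MSS: config.mut_rate_mss}

    rows: list[dict] = []
    decoy: list[bool] = []
    for sid, cls in zip(sample_ids, latent):
        mutated = np.flatnonzero(rng.random(len(panel)) < rate_by_class[cls])
        for j in mutated:
            for _ in range(int(rng.integers(1, 4))):
                rec = _true_variant(rng)
                rec.update(sample_id=sid, gene_id=panel[j], position=int(rng.integers(1, 10_000)))
                rows.append(rec)
                decoy.append(False)
        n_decoys = rng.binomial(len(panel), rate_by_class[cls] * config.decoy_fraction)
        for j in rng.choice(len(panel), size=n_decoys, replace=False):
            rec = _decoy_variant(rng)
            rec.update(sample_id=sid, gene_id=panel[int(j)], position=int(rng.integers(10_000, 20_000)))
            rows.append(rec)
            decoy.append(True)
    table = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return validate_variant_table(table), np.asarray(decoy, dtype=bool)


def simulate_replicates(
    matrix: ExpressionMatrix,
    tech_noise_sd: float,
    n_days: int = 1,
    n_operators: int = 1,
    day_sd: float = 0.02,
    operator_sd: float = 0.02,
    seed: int | None = None,
) -> list:
    """Replicate hybridizations of the same biological samples.

    One replicate matrix per (day, operator) combination: the original values
    plus per-cell Gaussian technical noise and small additive day and
    operator offsets.  With zero noise the replicates equal the input.
    """
    rng = _rng(seed)
    day_offsets = rng.normal(0.0, day_sd, n_days) if day_sd > 0 else np.zeros(n_days)
    op_offsets = rng.normal(0.0, operator_sd, n_operators) if operator_sd > 0 else np.zeros(n_operators)
    replicates = []
    for d in range(n_days):
        for o in range(n_operators):
            noise = rng.normal(0.0, tech_noise_sd, matrix.values.shape) if tech_noise_sd > 0 else 0.0
            values = matrix.values + noise + day_offsets[d] + op_offsets[o]
            meta = dict(matrix.metadata)
            meta.update(replicate_day=d, replicate_operator=o)
            replicates.append(ExpressionMatrix(matrix.sample_ids, matrix.gene_ids, values, meta))
    return replicates
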