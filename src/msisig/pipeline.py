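"""End-to-end synthetic study: develop, freeze, validate the signature.

This ties the modules together the way the study design does: gene selection
and threshold optimization on a development cohort against hospital MSI
labels, classification of development and validation cohorts, and the
downstream mutation-frequency, survival and technical-reproducibility
analyses.  It exists so that one seeded call reproduces the whole analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import classifier, evaluation, gene_selection, mutation, survival
from .io_formats import MSS, ExpressionMatrix, SignatureModel, msi_binary_labels
from .simulate import (
    GeneratorConfig,
    default_panel,
    simulate_cohort,
    simulate_replicates,
    simulate_variants,
)

__all__ = ["StudyResult", "run_study", "develop_signature"]

# Cross-validation repeats for the synthetic studies.  The full design uses
# 1000 repeats; 50 gives selection frequencies stable enough for a cohort of
# a few hundred samples while keeping a complete study run interactive.
DEFAULT_CV_REPEATS = 50


@dataclass
class StudyResult:
    """Everything a full synthetic study produces."""

    model: SignatureModel
    dev_calls: pd.DataFrame
    val_calls: pd.DataFrame
    dev_labels: np.ndarray
    val_labels: np.ndarray
    dev_report: evaluation.PerformanceReport
    val_report: evaluation.PerformanceReport
    auc_dev: float
    auc_dev_ci: tuple
    auc_latent: float
    gene_recovery: float
    mutation_means: dict
    mutation_t: float
    mutation_p: float
    cox: survival.CoxResult
    logrank_chi2: float
    logrank_p: float
    tyms: dict
    replicate_r2: float
    replicate_concordance: float
    truth_dev: object
    truth_val: object


def develop_signature(
    matrix: ExpressionMatrix,
    hospital_labels: np.ndarray,
    n_repeats: int = DEFAULT_CV_REPEATS,
    n_folds: int = 10,
    signature_size: int = 64,
    seed: int | None = None,
) -> SignatureModel:
    """Select genes by repeated CV, build centroids, optimize both thresholds."""
    _, selected = gene_selection.cv_frequency_selection(
        matrix,
        hospital_labels,
        n_folds=n_folds,
        n_repeats=n_repeats,
        signature_size=signature_size,
        seed=seed,
    )
    model = classifier.build_centroids(matrix, hospital_labels, selected)
    idx = classifier.msi_index_matrix(matrix, model)["index"].to_numpy()
    primary = evaluation.optimize_primary_threshold(idx, hospital_labels)
    pos = idx >= primary
    if len(np.unique(hospital_labels[pos])) == 2:
        secondary = evaluation.optimize_secondary_threshold(idx[pos], hospital_labels[pos])
        secondary = max(secondary, primary)
    else:
        secondary = primary
    model = model.with_thresholds(primary, secondary)
    model.provenance.update(cv_repeats=n_repeats, seed=seed)
    return model


def run_study(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    n_repeats: int = DEFAULT_CV_REPEATS,
    n_validation: int = 263,
    n_variant_samples: int = 73,
) -> StudyResult:
    """Run the complete synthetic study from one seed.

    Generates a development cohort, develops and freezes the signature
    against hospital labels, classifies an independent validation cohort,
    and runs the mutation-frequency, survival, TYMS and replicate analyses.
    """
    if config is None:
        config = GeneratorConfig()
    config = replace(config, seed=seed)
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(2**31))  # noqa: E731

    # development cohort and frozen signature
    dev_expr, dev_clin, dev_truth = simulate_cohort(config, seed=sub())
    dev_labels = msi_binary_labels(dev_clin).to_numpy()
    model = develop_signature(dev_expr, dev_labels, n_repeats=n_repeats, seed=sub())
    dev_calls = classifier.classify_matrix(dev_expr, model)
    dev_idx = dev_calls["index"].to_numpy()
    dev_report = evaluation.performance_report(dev_idx, dev_labels, model.threshold_primary)
    auc_dev, auc_dev_ci = evaluation.roc_auc(dev_idx, dev_labels, n_boot=500, seed=sub())
    latent_pos = (dev_truth.latent_class != MSS).astype(int)
    auc_latent, _ = evaluation.roc_auc(dev_idx, latent_pos, n_boot=10, seed=sub())
    recovered = set(model.gene_ids) & set(dev_truth.informative_genes)
    gene_recovery = len(recovered) / len(dev_truth.informative_genes)

    # mutation frequency on a sequenced subset of the development cohort
    seq = slice(0, n_variant_samples)
    seq_ids = dev_expr.sample_ids[seq]
    variants, _ = simulate_variants(
        dev_truth.latent_class[seq], config, seed=sub(), sample_ids=seq_ids
    )
    kept = mutation.filter_variants(variants)
    freqs = mutation.mutation_frequency(kept, default_panel(config.panel_size), sample_ids=seq_ids)
    call_by_sample = dev_calls.set_index("sample_id")["call"]
    seq_groups = np.where(call_by_sample.loc[seq_ids].to_numpy() == MSS, "MSS", "positive")
    mut_t, mut_p, mut_means = mutation.compare_groups(
        freqs["frequency"].to_numpy(), seq_groups, "positive", "MSS"
    )
    by_call = pd.Series(freqs["frequency"].to_numpy(), index=call_by_sample.loc[seq_ids]).groupby(level=0).mean()
    mutation_means = {**{k: float(v) for k, v in by_call.items()}, **mut_means}

    # validation cohort: classification, survival, TYMS
    val_config = replace(config, n_samples=n_validation)
    val_expr, val_clin, val_truth = simulate_cohort(val_config, seed=sub())
    val_labels = msi_binary_labels(val_clin).to_numpy()
    val_calls = classifier.classify_matrix(val_expr, model)
    val_idx = val_calls["index"].to_numpy()
    val_report = evaluation.performance_report(val_idx, val_labels, model.threshold_primary)

    positive = (val_calls["call"] != MSS).astype(int).to_numpy()
    times = val_clin["dmfs_years"].to_numpy()
    events = val_clin["dmfs_event"].to_numpy().astype(int)
    cox = survival.cox_hr(times, events, positive, horizon=config.horizon_years)
    chi2, logrank_p, _ = survival.logrank_test(times, events, val_calls["call"].to_numpy())
    tyms = survival.tyms_comparison(val_expr, val_calls["call"].to_numpy())

    # technical reproducibility of the frozen read-out
    (replicate,) = simulate_replicates(dev_expr, config.tech_noise_sd, seed=sub())
    rep_calls = classifier.classify_matrix(replicate, model)
    r = np.corrcoef(dev_idx, rep_calls["index"].to_numpy())[0, 1]
    concordance = float(
        np.mean((dev_calls["call"] != MSS).to_numpy() == (rep_calls["call"] != MSS).to_numpy())
    )

    return StudyResult(
        model=model,
        dev_calls=dev_calls,
        val_calls=val_calls,
        dev_labels=dev_labels,
        val_labels=val_labels,
        dev_report=dev_report,
        val_report=val_report,
        auc_dev=auc_dev,
        auc_dev_ci=auc_dev_ci,
        auc_latent=auc_latent,
        gene_recovery=gene_recovery,
        mutation_means=mutation_means,
        mutation_t=mut_t,
        mutation_p=mut_p,
        cox=cox,
        logrank_chi2=chi2,
        logrank_p=logrank_p,
        tyms=tyms,
        replicate_r2=float(r**2),
        replicate_concordance=concordance,
        truth_dev=dev_truth,
        truth_val=val_truth,
    )
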