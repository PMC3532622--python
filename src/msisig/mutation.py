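"""Mutation-frequency analysis over a fixed capture panel.

Candidate variants are filtered with the study's inclusion rules (coverage,
variant-read support, both-strand detection, protein-coding consequence,
absence from the normal panel); per-sample mutation frequency is the
fraction of distinct panel genes carrying at least one surviving variant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io_formats import validate_variant_table

__all__ = ["filter_variants", "mutation_frequency", "compare_groups"]

MIN_COVERAGE = 10
MIN_VARIANT_COUNT = 5


def filter_variants(
    table: pd.DataFrame,
    min_coverage: int = MIN_COVERAGE,
    min_variant_count: int = MIN_VARIANT_COUNT,
) -> pd.DataFrame:
    """Apply the variant inclusion criteria; idempotent, may return empty.

    A record survives when coverage >= 10, variant reads >= 5, the variant is
    seen on both strands (>= 1 read each), its consequence changes the coding
    sequence, and it is absent from the normal panel (germline removal).
    """
    table = validate_variant_table(table)
    if len(table) == 0:
        return table
    keep = (
        (table["coverage"] >= min_coverage)
        & (table["variant_count"] >= min_variant_count)
        & (table["fwd_variant_count"] >= 1)
        & (table["rev_variant_count"] >= 1)
        & (table["consequence"] == "coding_change")
        & (~table["in_normal_panel"])
    )
    return table.loc[keep].reset_index(drop=True)


def mutation_frequency(filtered: pd.DataFrame, panel, sample_ids=None) -> pd.DataFrame:
    """Per-sample fraction of panel genes mutated.

    Multiple variants in one gene count the gene once.  ``sample_ids``, when
    given, fixes the output rows (samples without surviving variants get
    frequency 0); otherwise only samples present in the table are reported.
    Variants in genes outside the panel raise.
    """
    panel = list(panel)
    panel_set = set(panel)
    if len(panel_set) != len(panel):
        raise ValidationError("panel contains duplicate genes")
    outside = sorted(set(filtered["gene_id"]) - panel_set) if len(filtered) else []
    if outside:
        raise ValidationError(f"variants in genes outside the panel: {outside}")
    if sample_ids is None:
        sample_ids = sorted(set(filtered["sample_id"])) if len(filtered) else []
    counts = (
        filtered.groupby("sample_id")["gene_id"].nunique() if len(filtered) else pd.Series(dtype=int)
    )
    n_mut = np.array([int(counts.get(s, 0)) for s in sample_ids])
    return pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "n_genes_mutated": n_mut,
            "panel_size": len(panel),
            "frequency": n_mut / len(panel),
        }
    )


def compare_groups(frequencies, groups, group_a, group_b):
    """Two-sided Student t-test of per-sample mutation frequencies.

    Returns ``(t, p, means)`` where ``means`` maps each group label to its
    mean frequency.  Each group needs at least two samples.
    """
    frequencies = np.asarray(frequencies, dtype=float)
    groups = np.asarray(groups)
    a = frequencies[groups == group_a]
    b = frequencies[groups == group_b]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError(
            f"need >= 2 samples per group, got {len(a)} ({group_a}) and {len(b)} ({group_b})"
        )
    means = {group_a: float(a.mean()), group_b: float(b.mean())}
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate: no within-group variability
        if a.mean() == b.mean():
            return 0.0, 1.0, means
        t = np.inf if a.mean() > b.mean() else -np.inf
        return float(t), 0.0, means
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), means
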