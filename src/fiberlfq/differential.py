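"""Paired contrasts and the fold-change/p-value fusion significance score.

All contrasts are paired through the subject: the fiber contrast compares
slow vs fast pools of the same subject at PRE, the training contrasts
compare POST vs PRE within a fiber type, and the interaction contrast is
the per-subject difference of the two training responses,

    (slow_POST - slow_PRE) - (fast_POST - fast_PRE).

Each contrast reduces to a one-sample t-test on per-subject log2
differences.  Proteins are then ranked by a fusion score that combines
biological relevance (fold change) with statistical significance:

    pi = |log2FC| * (-log10 p),        s = 10^(-pi),

so s lives on a p-like scale (s = p exactly when |log2FC| = 1, s = 1 when
log2FC = 0) and a single cutoff s <= 0.05 defines the regulated set.  The
score demands both a large fold change and a small p value, which protects
against false discoveries from tiny but consistent shifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnalysisConfig, AnnotationMap
from .preprocess import LogMatrix, QuantStatus, classify_exclusive, valid_value_filter

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300

CONTRASTS = ("fiber_PRE", "training_slow", "training_fast", "interaction")

#: (plus, minus) group pairs per contrast; the interaction is the
#: difference of the two training contrasts.
_CONTRAST_GROUPS: dict[str, list[tuple[str, str]]] = {
    "fiber_PRE": [("slow", "PRE"), ("fast", "PRE")],
    "training_slow": [("slow", "POST"), ("slow", "PRE")],
    "training_fast": [("fast", "POST"), ("fast", "PRE")],
    "interaction": [("slow", "POST"), ("slow", "PRE"), ("fast", "POST"), ("fast", "PRE")],
}


class DegenerateVarianceError(ValueError):
    """All paired differences are identical; the t statistic is undefined."""


def contrast_groups(contrast: str) -> list[tuple[str, str]]:
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; choose from {CONTRASTS}")
    return list(_CONTRAST_GROUPS[contrast])


def paired_differences(m: LogMatrix, contrast: str) -> pd.DataFrame:
    """Per-subject paired log2 differences, proteins x subjects.

    Subjects missing any sample the contrast requires are dropped with a
    warning; fewer than two remaining subjects is an error.
    """
    groups = contrast_groups(contrast)
    design = m.design
    per_subject: dict[str, pd.Series] = {}
    for subj in design.subjects:
        samples = {g: design.sample_for(subj, *g) for g in groups}
        if any(s is None for s in samples.values()):
            logger.warning(
                "subject %s lacks a sample required by contrast %s; dropped",
                subj, contrast,
            )
            continue
        if contrast == "interaction":
            d = (
                m.values[samples[("slow", "POST")]]
                - m.values[samples[("slow", "PRE")]]
                - m.values[samples[("fast", "POST")]]
                + m.values[samples[("fast", "PRE")]]
            )
        else:
            plus, minus = groups
            d = m.values[samples[plus]] - m.values[samples[minus]]
        per_subject[subj] = d
    if len(per_subject) < 2:
        raise ValueError(
            f"contrast {contrast!r} has {len(per_subject)} usable subject(s); need >= 2"
        )
    return pd.DataFrame(per_subject, index=m.values.index)


def paired_t_test(diffs: np.ndarray | pd.Series) -> tuple[float, float, float, int, float]:
    """One-sample t-test of paired differences against zero.

    Returns (mean difference, SD of differences, t, df, two-sided p).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    if d.size < 2:
        raise ValueError(f"need >= 2 finite differences, got {d.size}")
    dbar = float(np.mean(d))
    s_d = float(np.std(d, ddof=1))
    if s_d == 0.0:
        raise DegenerateVarianceError("zero variance of paired differences")
    n = d.size
    t = dbar / (s_d / np.sqrt(n))
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    return dbar, s_d, float(t), df, p


def pi_value(log2fc: float, p: float) -> float:
    """pi = |log2FC| * (-log10 p), with p clamped below at 1e-300."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must lie in (0, 1], got {p}")
    return float(abs(log2fc) * (-np.log10(max(p, P_FLOOR))))


def pi_significance_score(log2fc: float, p: float) -> float:
    """Fusion score s = 10^(-|log2FC| * (-log10 p)), on a p-like scale.

    Equivalent closed forms at the anchors are returned exactly: s = p when
    |log2FC| = 1 and s = 1 when log2FC = 0.  Clamped below at 1e-300 so
    extreme scores stay strictly positive.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must lie in (0, 1], got {p}")
    if log2fc == 0.0:
        return 1.0
    if abs(log2fc) == 1.0:
        return max(p, P_FLOOR)
    return float(max(10.0 ** (-pi_value(log2fc, p)), P_FLOOR))


def run_contrast(
    m: LogMatrix,
    contrast: str,
    config: AnalysisConfig | None = None,
    status: QuantStatus | None = None,
) -> pd.DataFrame:
    """Differential table for one contrast on an imputed matrix.

    Proteins enter a comparison when they carry at least ``min_valid``
    observed values in one of the contrast's groups; the interaction
    contrast additionally requires quantification in both fiber types
    (fiber-exclusive proteins are excluded from it).

    Output columns: protein_group_id, contrast, log2fc, sd_diff, n, t, df,
    p, pi, sig_score, regulated, direction.
    """
    config = config or AnalysisConfig()
    groups = contrast_groups(contrast)
    retained, _ = valid_value_filter(
        m, groups, config.min_valid, config.valid_fraction_mode, config.valid_fraction
    )
    if contrast == "interaction":
        if status is None:
            status = classify_exclusive(m, config.min_valid)
        retained &= status.proteins_with("both")
    diffs = paired_differences(m, contrast)
    rows = []
    order = [pid for pid in m.values.index if pid in retained]
    for pid in order:
        d = diffs.loc[pid]
        try:
            dbar, s_d, t, df, p = paired_t_test(d)
        except DegenerateVarianceError:
            dbar = float(np.mean(d))
            s_d, t, df = 0.0, np.nan, len(d) - 1
            # A perfectly constant nonzero shift is treated as maximal
            # evidence; a constant zero difference as no evidence.
            p = 1.0 if dbar == 0.0 else P_FLOOR
        pi = pi_value(dbar, p)
        s = pi_significance_score(dbar, p)
        rows.append(
            (
                pid, contrast, dbar, s_d, df + 1, t, df, p, pi, s,
                bool(s <= config.sig_cutoff),
                int(np.sign(dbar)),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_group_id", "contrast", "log2fc", "sd_diff", "n", "t",
            "df", "p", "pi", "sig_score", "regulated", "direction",
        ],
    )


def regulated_set(result: pd.DataFrame) -> set[str]:
    return set(result.loc[result["regulated"], "protein_group_id"])


def regulated_overlap(
    res_a: pd.DataFrame,
    res_b: pd.DataFrame,
    annotation: AnnotationMap | None = None,
    namespace: str | None = None,
    term: str | None = None,
    accession_lists: dict[str, Iterable[str]] | None = None,
) -> dict:
    """Set arithmetic on two regulated sets, optionally term-annotated.

    Returns counts of proteins regulated only in A, only in B and in both,
    plus — when an annotation term is supplied — the fraction of the
    overlap carrying that term.
    """
    a, b = regulated_set(res_a), regulated_set(res_b)
    both = a & b
    out = {
        "a_only": len(a - b),
        "b_only": len(b - a),
        "both": len(both),
    }
    if annotation is not None and term is not None:
        def has_term(pid: str) -> bool:
            accs = accession_lists.get(pid, [pid]) if accession_lists else [pid]
            return (namespace, term) in annotation.terms_for(accs)

        annotated = sum(has_term(pid) for pid in both)
        out["annotated_in_both"] = annotated
        out["annotated_fraction"] = annotated / len(both) if both else 0.0
    return out
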