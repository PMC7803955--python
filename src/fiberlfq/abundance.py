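"""Percentage protein abundance, category aggregation and within-subject ANOVA.

Abundance shares are descriptions of the raw LFQ signal, so they are
computed on non-imputed intensities with missing treated as zero in the
sums: a protein's percent abundance in a sample is its LFQ intensity
divided by the summed LFQ intensities of all proteins in that sample.
Category abundances (e.g. "GOCC mitochondrion", glycolysis, TCA cycle,
OXPHOS, TIM/TOM) sum the member proteins' percents.

Isoform families whose members share most of their sequence (myosin heavy
chains, AMPK subunits) are quantified from peptides unique to a single
family member; peptides mapping to two or more members are excluded.

Group-level responses (category percents, isoform percents) in the 2x2
fiber x training layout are tested with a two-factor repeated-measures
ANOVA in which each effect is tested against its own effect-by-subject
error term, followed by Tukey's studentized-range post hoc on the four
cell means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnnotationMap, PeptideTable, ProteinGroupTable, SampleDesign

CELLS = [("slow", "PRE"), ("slow", "POST"), ("fast", "PRE"), ("fast", "POST")]


# ---------------------------------------------------------------------------
# Percent abundance
# ---------------------------------------------------------------------------


def percent_abundance(table: ProteinGroupTable) -> pd.DataFrame:
    """Per-protein per-sample percent of summed LFQ intensity.

    a[i, j] = 100 * I[i, j] / sum_k I[k, j], with missing treated as zero.
    Missing cells report 0%.
    """
    vals = table.intensities.fillna(0.0)
    totals = vals.sum(axis=0)
    empty = totals[totals == 0.0]
    if len(empty):
        raise ValueError(f"sample(s) with no observed intensity: {list(empty.index)}")
    return 100.0 * vals / totals


def category_percent_abundance(
    table: ProteinGroupTable,
    annotation: AnnotationMap,
    categories: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Summed member percents per (namespace, term) category and sample.

    Membership joins through any accession of the protein group.  Rows are
    the requested categories plus ``ALL`` (always 100%); an empty category
    yields 0%.
    """
    percents = percent_abundance(table)
    acc_lists = {
        pid: table.accessions_of(pid) for pid in table.protein_group_ids
    }
    rows = {}
    for ns, term in categories:
        members = annotation.group_members(ns, term, acc_lists)
        members = [pid for pid in percents.index if pid in members]
        rows[f"{ns}:{term}"] = percents.loc[members].sum(axis=0)
    rows["ALL"] = percents.sum(axis=0)
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Isoform quantification from unique peptides
# ---------------------------------------------------------------------------


def isoform_percent_from_unique_peptides(
    peptides: PeptideTable, family: Sequence[str]
) -> pd.DataFrame:
    """Isoform share of a sequence family from family-unique peptides.

    A peptide counts as unique when it maps to exactly one family member
    (mappings to accessions outside the family are ignored for the
    uniqueness decision within the family).  Per isoform and sample,
    percent = 100 * summed unique-peptide intensity of the isoform /
    summed unique-peptide intensity of the whole family.  Samples with no
    family unique-peptide signal get NaN.
    """
    family = list(family)
    if len(family) < 2:
        raise ValueError("an isoform family needs at least 2 members")
    fam = set(family)
    owner: dict[str, str] = {}
    for _, row in peptides.info.iterrows():
        hits = fam.intersection(row["mapped_accessions"].split(";"))
        if len(hits) == 1:
            owner[row["peptide_id"]] = next(iter(hits))
    zero_unique = [iso for iso in family if iso not in set(owner.values())]
    if zero_unique:
        warnings.warn(
            f"isoform(s) without unique peptides: {zero_unique}; "
            "their share is reported as 0",
            stacklevel=2,
        )
    samples = peptides.intensities.columns
    sums = pd.DataFrame(0.0, index=family, columns=samples)
    for pid, iso in owner.items():
        sums.loc[iso] += peptides.intensities.loc[pid].fillna(0.0)
    totals = sums.sum(axis=0)
    if not owner or (totals == 0.0).all():
        warnings.warn("no unique-peptide signal in the family", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 100.0 * sums / totals
    out[out.columns[totals == 0.0]] = np.nan
    return out


# ---------------------------------------------------------------------------
# Two-factor repeated-measures ANOVA (2x2 within-subject)
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    """Within-subject 2x2 decomposition for one response.

    ``table`` rows: fiber, exercise, interaction, each with SS, df, MS, F,
    p and its own error term (SS_err, df_err, MS_err = effect-by-subject
    mean square).  ``cell_means`` indexed by "fiber_time".  ``degenerate``
    flags responses with zero error variance (F undefined).
    """

    table: pd.DataFrame
    cell_means: pd.Series
    n_subjects: int
    degenerate: bool
    cells: pd.DataFrame  # subjects x 4 cells, for post hoc use


def rm_anova_2x2(values: pd.Series, design: SampleDesign) -> AnovaResult:
    """Classical 2x2 repeated-measures decomposition of a per-sample response.

    Each main effect and the interaction is tested against its own
    subject-interaction error term with df = (1, n-1).
    """
    subjects = design.subjects
    n = len(subjects)
    if n < 3:
        raise ValueError(f"need >= 3 subjects, got {n}")
    y = np.empty((n, 2, 2))  # subject x fiber(slow,fast) x time(PRE,POST)
    for i, s in enumerate(subjects):
        for j, f in enumerate(("slow", "fast")):
            for k, t in enumerate(("PRE", "POST")):
                sid = design.sample_for(s, f, t)
                if sid is None or sid not in values.index or pd.isna(values[sid]):
                    raise ValueError(f"incomplete 2x2 cell for subject {s!r}: ({f}, {t})")
                y[i, j, k] = values[sid]
    g = y.mean()
    subj = y.mean(axis=(1, 2))
    fib = y.mean(axis=(0, 2))
    tim = y.mean(axis=(0, 1))
    cell = y.mean(axis=0)  # fiber x time
    sf = y.mean(axis=2)  # subject x fiber
    st = y.mean(axis=1)  # subject x time

    ss_subj = 4.0 * np.sum((subj - g) ** 2)
    ss_fib = 2.0 * n * np.sum((fib - g) ** 2)
    ss_tim = 2.0 * n * np.sum((tim - g) ** 2)
    ss_fs = 2.0 * np.sum((sf - fib[None, :] - subj[:, None] + g) ** 2)
    ss_ts = 2.0 * np.sum((st - tim[None, :] - subj[:, None] + g) ** 2)
    ss_int = n * np.sum((cell - fib[:, None] - tim[None, :] + g) ** 2)
    ss_tot = np.sum((y - g) ** 2)
    ss_fts = ss_tot - ss_subj - ss_fib - ss_tim - ss_fs - ss_ts - ss_int

    dfe = n - 1
    rows = []
    degenerate = False
    for name, ss, ss_err in (
        ("fiber", ss_fib, ss_fs),
        ("exercise", ss_tim, ss_ts),
        ("interaction", ss_int, ss_fts),
    ):
        ms, ms_err = ss / 1.0, ss_err / dfe
        if ms_err <= 0.0:
            degenerate = True
            f_stat, p = (0.0, np.nan) if ss == 0 else (np.inf, 0.0)
        else:
            f_stat = ms / ms_err
            p = float(stats.f.sf(f_stat, 1, dfe))
        rows.append((name, ss, 1, ms, ss_err, dfe, ms_err, f_stat, p))
    table = pd.DataFrame(
        rows,
        columns=["effect", "SS", "df", "MS", "SS_err", "df_err", "MS_err", "F", "p"],
    ).set_index("effect")
    cell_means = pd.Series(
        {f"{f}_{t}": cell[j, k] for j, f in enumerate(("slow", "fast"))
         for k, t in enumerate(("PRE", "POST"))}
    )
    cells = pd.DataFrame(
        {f"{f}_{t}": y[:, j, k] for j, f in enumerate(("slow", "fast"))
         for k, t in enumerate(("PRE", "POST"))},
        index=subjects,
    )
    return AnovaResult(table, cell_means, n, degenerate, cells)


def tukey_posthoc(anova: AnovaResult) -> pd.DataFrame:
    """Tukey studentized-range comparisons of the four cell means.

    q = |mean difference| / sqrt(MS_err / n), adjusted p from the
    studentized-range distribution with k = 4 means and df = n - 1.  The
    2x2 within design has no single pooled error, so each pair uses the
    error term matching the factors it crosses: the fiber-by-subject MS
    for pairs differing only in fiber, the exercise-by-subject MS for
    pairs differing only in time, and the pooled within-subject error for
    diagonal pairs.  ``p_unadjusted`` is the two-sided t probability of
    the same statistic (q / sqrt(2)).
    """
    tab = anova.table
    n, dfe = anova.n_subjects, anova.n_subjects - 1
    ms_fs = tab.loc["fiber", "MS_err"]
    ms_ts = tab.loc["exercise", "MS_err"]
    ms_pooled = (
        tab.loc["fiber", "SS_err"]
        + tab.loc["exercise", "SS_err"]
        + tab.loc["interaction", "SS_err"]
    ) / (3 * dfe)
    if min(ms_fs, ms_ts, ms_pooled) <= 0.0:
        raise ValueError("degenerate error mean square; post hoc undefined")
    names = list(anova.cell_means.index)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            fa, ta = a.rsplit("_", 1)
            fb, tb = b.rsplit("_", 1)
            if fa != fb and ta == tb:
                ms_err = ms_fs
            elif fa == fb and ta != tb:
                ms_err = ms_ts
            else:
                ms_err = ms_pooled
            diff = anova.cell_means[a] - anova.cell_means[b]
            q = abs(diff) / np.sqrt(ms_err / n)
            p_adj = float(stats.studentized_range.sf(q, 4, dfe))
            p_un = float(2.0 * stats.t.sf(q / np.sqrt(2.0), dfe))
            rows.append((a, b, diff, q, p_adj, p_un))
    return pd.DataFrame(
        rows, columns=["cell_a", "cell_b", "mean_diff", "q", "p_adjusted", "p_unadjusted"]
    )


def category_anova(
    category_table: pd.DataFrame, design: SampleDesign
) -> dict[str, AnovaResult]:
    """RM-ANOVA per category row of a category-percent table."""
    out = {}
    for cat in category_table.index:
        if cat == "ALL":
            continue
        out[cat] = rm_anova_2x2(category_table.loc[cat], design)
    return out
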