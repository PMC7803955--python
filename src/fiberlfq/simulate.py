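"""Synthetic fiber-type proteomics experiments with known ground truth.

The generator emulates the statistical structure of a paired endurance
training study on pooled slow- and fast-twitch muscle fibers: a handful of
subjects sampled in a complete 2x2 within-subject layout (fiber type x
PRE/POST), on the order of two thousand quantifiable protein groups, a
long-tailed abundance distribution in which the ten most abundant
(sarcomeric-like) proteins carry about half the total signal, and
abundance-dependent missingness (a cell is more likely to go unquantified
the closer the protein sits to the detection limit).

The model is additive on the log2 scale.  For protein i, subject s, fiber f
and timepoint t the log2 intensity is

    x = log2(base_i) + u_s + fiber_i * [f = slow]
        + train_{i,f} * [t = POST] + eps,

with subject effects u_s ~ N(0, between_subject_sd) shared across all of a
subject's samples (this creates the pairing the paired tests exploit) and
residual noise eps ~ N(0, within_subject_sd).  Planted effect sizes and the
terms coupled to them are emitted as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    AnnotationMap,
    PeptideTable,
    ProteinGroupTable,
    SampleDesign,
    write_annotations,
    write_peptides,
    write_protein_groups,
    write_sample_design,
)

EFFECT_CLASSES = ("none", "fiber", "training_slow", "training_fast", "interaction")


@dataclass
class SimConfig:
    """Study-condition parameters of the simulator.

    ``n_subjects`` = 5 and ``n_proteins`` = 2200 mirror the scale of a
    five-subject paired fiber-pool study with ~2200 quantifiable groups;
    ``top10_share`` = 0.5 makes the ten most abundant proteins carry half
    the summed signal.  Effect counts set how many proteins receive a
    planted fiber difference, a training response in each fiber, or a
    fiber-specific (interaction) training response; ``effect_size_log2`` is
    the planted |log2 fold change|.  ``missing_target`` is the overall
    fraction of missing cells, realised through a logistic
    abundance-dependent detection model with slope ``missing_slope`` per
    log2 unit.
    """

    n_subjects: int = 5
    n_proteins: int = 2200
    top10_share: float = 0.50
    base_mean_log2: float = 20.0
    base_sd_log2: float = 2.0
    within_subject_sd: float = 0.5
    between_subject_sd: float = 0.3
    n_fiber_effects: int = 300
    n_training_effects_slow: int = 150
    n_training_effects_fast: int = 110
    n_interaction_effects: int = 80
    effect_size_log2: float = 1.0
    missing_target: float = 0.25
    missing_slope: float = 0.8
    n_terms: int = 30
    term_size: int = 40
    effect_term_coupling: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.top10_share < 1:
            raise ValueError("top10_share must lie in (0, 1)")
        if not 0 <= self.missing_target < 1:
            raise ValueError("missing_target must lie in [0, 1)")
        total_effects = (
            self.n_fiber_effects
            + self.n_training_effects_slow
            + self.n_training_effects_fast
            + self.n_interaction_effects
        )
        if total_effects > self.n_proteins:
            raise ValueError(
                f"effect counts ({total_effects}) exceed n_proteins ({self.n_proteins})"
            )


@dataclass
class GroundTruth:
    """Planted per-protein effects, the acceptance surface for recovery tests.

    ``true_interaction_log2fc`` always equals
    ``true_training_log2fc_slow - true_training_log2fc_fast`` exactly.
    ``effect_class`` records which planting pool the protein came from.
    """

    table: pd.DataFrame  # indexed by protein_group_id

    def __post_init__(self) -> None:
        t = self.table
        diff = t["true_training_log2fc_slow"] - t["true_training_log2fc_fast"]
        if not np.array_equal(
            diff.to_numpy(), t["true_interaction_log2fc"].to_numpy()
        ):
            raise ValueError("interaction must equal slow - fast training effect")

    def proteins_in_class(self, effect_class: str) -> set[str]:
        t = self.table
        return set(t.index[t["effect_class"] == effect_class])

    def write(self, path) -> Path:
        path = Path(path)
        self.table.reset_index().to_csv(path, sep="\t", index=False, float_format="%.17g")
        return path

    @classmethod
    def read(cls, path) -> "GroundTruth":
        df = pd.read_csv(path, sep="\t").set_index("protein_group_id")
        return cls(df)


# ---------------------------------------------------------------------------
# Abundance backbone
# ---------------------------------------------------------------------------


def sample_base_abundances(
    n_proteins: int,
    top10_share: float,
    base_mean_log2: float = 20.0,
    base_sd_log2: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Linear-scale baseline abundances with a dominant top-10.

    The non-top tail is log2-normal; ten dominant proteins are then placed
    as a geometric cascade scaled so their summed intensity is exactly
    ``top10_share`` of the total.  Returned sorted descending.
    """
    if n_proteins < 11:
        raise ValueError("need at least 11 proteins to define a top-10 share")
    if not 0 < top10_share < 1:
        raise ValueError(f"infeasible top10_share {top10_share}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    tail = 2.0 ** rng.normal(base_mean_log2, base_sd_log2, size=n_proteins - 10)
    tail_sum = tail.sum()
    top_sum = tail_sum * top10_share / (1.0 - top10_share)
    # Geometric cascade (ratio 0.7) echoes the steep rank-abundance curve of
    # sarcomeric proteins.
    cascade = 0.7 ** np.arange(10)
    top = top_sum * cascade / cascade.sum()
    vec = np.concatenate([top, np.sort(tail)[::-1]])
    return vec


def realized_top10_share(abundances: np.ndarray) -> float:
    srt = np.sort(np.asarray(abundances, dtype=float))[::-1]
    return float(srt[:10].sum() / srt.sum())


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------


def _expected_missing(a: float, b: float, x: np.ndarray) -> float:
    with np.errstate(over="ignore"):
        p_obs = 1.0 / (1.0 + np.exp(-(a + b * x)))
    return float(np.mean(1.0 - p_obs))


def apply_missingness(
    matrix: pd.DataFrame,
    b: float,
    missing_target: float,
    seed: int | np.random.Generator = 0,
    a: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Apply abundance-dependent (MNAR) missingness to a log2 matrix.

    Each cell with log2 intensity x stays observed with probability
    logistic(a + b*x).  When ``a`` is not given it is calibrated by
    bisection so the expected missing fraction equals ``missing_target``.
    Returns (matrix with NaN, boolean missing mask, intercept a).
    """
    if b <= 0:
        raise ValueError("detection slope b must be > 0")
    if not 0 <= missing_target < 1:
        raise ValueError("missing_target must lie in [0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = matrix.to_numpy(dtype=float)
    if missing_target == 0:
        mask = pd.DataFrame(False, index=matrix.index, columns=matrix.columns)
        return matrix.copy(), mask, np.inf
    if a is None:
        flat = x.ravel()
        lo, hi = -b * flat.max() - 50.0, -b * flat.min() + 50.0
        lo_frac = _expected_missing(lo, b, flat)
        hi_frac = _expected_missing(hi, b, flat)
        if not hi_frac <= missing_target <= lo_frac:
            raise ValueError(
                f"missing_target {missing_target} unreachable; achievable "
                f"range is [{hi_frac:.4f}, {lo_frac:.4f}]"
            )
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if _expected_missing(mid, b, flat) > missing_target:
                lo = mid
            else:
                hi = mid
        a = 0.5 * (lo + hi)
    with np.errstate(over="ignore"):
        p_obs = 1.0 / (1.0 + np.exp(-(a + b * x)))
    missing = rng.random(x.shape) >= p_obs
    mask = pd.DataFrame(missing, index=matrix.index, columns=matrix.columns)
    out = matrix.mask(mask)
    return out, mask, float(a)


# ---------------------------------------------------------------------------
# Isoform families
# ---------------------------------------------------------------------------

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _random_sequence(rng: np.random.Generator, length: int = 12) -> str:
    return "".join(rng.choice(_AA, size=length))


def generate_isoform_family(
    isoform_ids: Sequence[str],
    mixing: pd.DataFrame,
    n_unique_peptides: int = 6,
    n_shared_peptides: int = 4,
    noise_sd: float = 0.0,
    total_signal: float = 1e9,
    seed: int | np.random.Generator = 0,
    peptide_prefix: str = "pep",
) -> PeptideTable:
    """Peptide-level data for a family of sequence-similar isoforms.

    ``mixing``: isoforms x samples matrix of proportions, each column
    summing to 1 (e.g. myosin heavy chain composition per fiber pool).
    Unique peptides map to exactly one isoform and their intensity is
    proportional to that isoform's mixing proportion times a per-peptide
    response factor; shared peptides map to two isoforms and carry their
    summed signal.  ``noise_sd`` is multiplicative log2 noise.
    """
    if list(mixing.index) != list(isoform_ids):
        raise ValueError("mixing rows must match isoform_ids")
    if n_unique_peptides < 1:
        raise ValueError(
            "every isoform needs at least one unique peptide to be quantifiable"
        )
    col_sums = mixing.sum(axis=0)
    if not np.allclose(col_sums, 1.0, atol=1e-9):
        raise ValueError("mixing proportions must sum to 1 per sample")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows = []
    intens = {}
    k = 0
    for iso in isoform_ids:
        # Peptides respond unevenly, but responses are normalised to a
        # common per-isoform sum so summed unique-peptide intensity stays
        # proportional to the isoform's mixing fraction.
        responses = 2.0 ** rng.normal(0.0, 0.3, size=n_unique_peptides)
        responses *= n_unique_peptides / responses.sum()
        for response in responses:
            pid = f"{peptide_prefix}{k:03d}"
            k += 1
            signal = total_signal * mixing.loc[iso] * response
            if noise_sd > 0:
                signal = signal * 2.0 ** rng.normal(0.0, noise_sd, size=len(signal))
            rows.append((pid, _random_sequence(rng), iso))
            intens[pid] = signal.to_numpy()
    n_iso = len(isoform_ids)
    for _ in range(n_shared_peptides):
        pid = f"{peptide_prefix}{k:03d}"
        k += 1
        pair = rng.choice(n_iso, size=2, replace=False)
        accs = ";".join(isoform_ids[i] for i in sorted(pair))
        response = 2.0 ** rng.normal(0.0, 0.3)
        signal = total_signal * mixing.iloc[sorted(pair)].sum(axis=0) * response
        if noise_sd > 0:
            signal = signal * 2.0 ** rng.normal(0.0, noise_sd, size=len(signal))
        rows.append((pid, _random_sequence(rng), accs))
        intens[pid] = signal.to_numpy()
    info = pd.DataFrame(rows, columns=["peptide_id", "sequence", "mapped_accessions"])
    inten = pd.DataFrame(intens, index=mixing.columns).T
    inten.index = pd.Index(info["peptide_id"], name="peptide_id")
    return PeptideTable(info, inten)


# ---------------------------------------------------------------------------
# Full experiment
# ---------------------------------------------------------------------------


def _make_design(n_subjects: int) -> SampleDesign:
    rows = []
    for s in range(1, n_subjects + 1):
        for f in ("slow", "fast"):
            for t in ("PRE", "POST"):
                rows.append((f"{f}_{t}_S{s}", f"S{s}", f, t))
    return SampleDesign(
        pd.DataFrame(rows, columns=["sample_id", "subject_id", "fiber_type", "timepoint"])
    )


def _assign_effects(cfg: SimConfig, rng: np.random.Generator, ids: list[str]) -> GroundTruth:
    n = cfg.n_proteins
    fiber = np.zeros(n)
    train_s = np.zeros(n)
    train_f = np.zeros(n)
    klass = np.array(["none"] * n, dtype=object)
    total = (
        cfg.n_fiber_effects
        + cfg.n_training_effects_slow
        + cfg.n_training_effects_fast
        + cfg.n_interaction_effects
    )
    # Effects are planted outside the top-10 backbone so the dominant
    # sarcomeric-like proteins stay comparable across groups.
    chosen = rng.choice(np.arange(10, n), size=total, replace=False)
    e = cfg.effect_size_log2
    pos = 0

    def take(k):
        nonlocal pos
        sel = chosen[pos:pos + k]
        pos += k
        return sel

    sel = take(cfg.n_fiber_effects)
    fiber[sel] = rng.choice([-e, e], size=len(sel))
    klass[sel] = "fiber"
    sel = take(cfg.n_training_effects_slow)
    train_s[sel] = rng.choice([-e, e], size=len(sel))
    klass[sel] = "training_slow"
    sel = take(cfg.n_training_effects_fast)
    train_f[sel] = rng.choice([-e, e], size=len(sel))
    klass[sel] = "training_fast"
    sel = take(cfg.n_interaction_effects)
    # Fiber-specific training response: the full effect lands in one fiber
    # only, so the interaction contrast sees +-e.
    which_slow = rng.random(len(sel)) < 0.5
    signs = rng.choice([-e, e], size=len(sel))
    train_s[sel[which_slow]] = signs[which_slow]
    train_f[sel[~which_slow]] = signs[~which_slow]
    klass[sel] = "interaction"

    table = pd.DataFrame(
        {
            "true_fiber_log2fc": fiber,
            "true_training_log2fc_slow": train_s,
            "true_training_log2fc_fast": train_f,
            "true_interaction_log2fc": train_s - train_f,
            "effect_class": klass,
        },
        index=pd.Index(ids, name="protein_group_id"),
    )
    return GroundTruth(table)


def _assign_annotations(
    cfg: SimConfig, rng: np.random.Generator, truth: GroundTruth
) -> AnnotationMap:
    """Terms with configurable coupling to the planted effect classes.

    A few named terms mimic categories a muscle proteome would show —
    "mitochondrion" biased toward training-upregulated proteins,
    "sarcomere" toward fiber-different ones — with a fraction
    ``effect_term_coupling`` of members drawn from the coupled class and
    the remainder drawn at random.  The remaining terms are uncoupled.
    """
    t = truth.table
    ids = np.array(t.index)
    up_training = ids[
        (t["true_training_log2fc_slow"] > 0) | (t["true_training_log2fc_fast"] > 0)
    ]
    fiber_diff = ids[t["true_fiber_log2fc"] != 0]
    interaction = ids[np.array(t["effect_class"] == "interaction")]
    coupled = [
        ("GOCC", "mitochondrion", up_training),
        ("Keyword", "Mitochondrion", up_training),
        ("GOBP", "metabolic process", up_training),
        ("GOCC", "sarcomere", fiber_diff),
        ("GOBP", "muscle contraction", fiber_diff),
        ("Keyword", "Secreted", interaction),
    ]
    entries = []
    c = cfg.effect_term_coupling
    for ns, term, pool in coupled:
        n_from_pool = min(int(round(c * cfg.term_size)), len(pool))
        sel = list(rng.choice(pool, size=n_from_pool, replace=False))
        rest = np.setdiff1d(ids, sel)
        sel += list(rng.choice(rest, size=cfg.term_size - n_from_pool, replace=False))
        entries += [(acc, ns, term) for acc in sel]
    namespaces = ("GOBP", "GOCC", "GOMF", "KEGG", "Keyword")
    for j in range(max(0, cfg.n_terms - len(coupled))):
        ns = namespaces[j % len(namespaces)]
        term = f"term_{j:02d}"
        sel = rng.choice(ids, size=min(cfg.term_size, len(ids)), replace=False)
        entries += [(acc, ns, term) for acc in sel]
    return AnnotationMap(pd.DataFrame(entries, columns=["accession", "namespace", "term"]))


_MYH_MIXING = {
    # Pool composition per fiber type: slow pools are dominated by MYH7
    # (~90%); fast pools split ~80/20 between MYH2 (IIa) and MYH1 (IIx).
    "slow": (0.90, 0.08, 0.02),
    "fast": (0.02, 0.78, 0.20),
}


def _myh_family(design: SampleDesign, rng: np.random.Generator) -> PeptideTable:
    isoforms = ["MYH7", "MYH2", "MYH1"]
    cols = {}
    for _, row in design.table.iterrows():
        cols[row["sample_id"]] = _MYH_MIXING[row["fiber_type"]]
    mixing = pd.DataFrame(cols, index=isoforms)
    return generate_isoform_family(
        isoforms, mixing, n_unique_peptides=6, n_shared_peptides=4,
        noise_sd=0.1, seed=rng, peptide_prefix="MYHpep",
    )


def generate_experiment(
    cfg: SimConfig,
) -> tuple[ProteinGroupTable, PeptideTable, SampleDesign, AnnotationMap, GroundTruth]:
    """Simulate one complete paired fiber-type training experiment."""
    rng = np.random.default_rng(cfg.seed)
    design = _make_design(cfg.n_subjects)
    ids = [f"P{i:05d}" for i in range(cfg.n_proteins)]
    base = sample_base_abundances(
        cfg.n_proteins, cfg.top10_share, cfg.base_mean_log2, cfg.base_sd_log2, rng
    )
    truth = _assign_effects(cfg, rng, ids)
    t = truth.table
    log_base = np.log2(base)
    subj_eff = {s: rng.normal(0.0, cfg.between_subject_sd) for s in design.subjects}
    cols = {}
    for _, row in design.table.iterrows():
        x = log_base + subj_eff[row["subject_id"]]
        if row["fiber_type"] == "slow":
            x = x + t["true_fiber_log2fc"].to_numpy()
            if row["timepoint"] == "POST":
                x = x + t["true_training_log2fc_slow"].to_numpy()
        else:
            if row["timepoint"] == "POST":
                x = x + t["true_training_log2fc_fast"].to_numpy()
        x = x + rng.normal(0.0, cfg.within_subject_sd, size=cfg.n_proteins)
        cols[row["sample_id"]] = x
    log_matrix = pd.DataFrame(cols, index=pd.Index(ids, name="protein_group_id"))
    log_missing, _, _ = apply_missingness(
        log_matrix, cfg.missing_slope, cfg.missing_target, rng
    )
    intensities = 2.0 ** log_missing
    meta = pd.DataFrame(
        {
            "accessions": [f"{i};{i}-2" for i in ids],
            "gene_name": [f"GENE{j}" for j in range(cfg.n_proteins)],
            "unique_peptides": rng.integers(1, 30, size=cfg.n_proteins),
        },
        index=intensities.index,
    )
    proteins = ProteinGroupTable(intensities, meta, design)
    annotation = _assign_annotations(cfg, rng, truth)
    peptides = _myh_family(design, rng)
    return proteins, peptides, design, annotation, truth


def write_experiment(
    out_dir,
    proteins: ProteinGroupTable,
    peptides: PeptideTable,
    design: SampleDesign,
    annotation: AnnotationMap,
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write a simulated experiment in the same formats the readers accept."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return {
        "protein_groups": write_protein_groups(proteins, out_dir / "protein_groups.tsv"),
        "peptides": write_peptides(peptides, out_dir / "peptides.tsv"),
        "design": write_sample_design(design, out_dir / "design.csv"),
        "annotations": write_annotations(annotation, out_dir / "annotations.tsv"),
        "ground_truth": truth.write(out_dir / "ground_truth.tsv"),
    }
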