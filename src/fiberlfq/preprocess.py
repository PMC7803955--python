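"""Log transform, valid-value filtering, fiber exclusivity and imputation.

Label-free intensities are analysed on the log2 scale.  Missing values are
assumed to be missing-not-at-random (abundances below the detection limit),
so they are filled by drawing from a Gaussian that is narrowed to a
fraction ``w`` of the observed spread and shifted ``d`` observed standard
deviations below the observed mean — the classic downshift imputation used
for LFQ matrices.  Defaults are w = 0.3 and d = 1.0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import AnalysisConfig, ProteinGroupTable, SampleDesign

Group = tuple[str, str]  # (fiber_type, timepoint)

STATUS_BOTH = "both"
STATUS_EXCLUSIVE_SLOW = "exclusive_slow"
STATUS_EXCLUSIVE_FAST = "exclusive_fast"
STATUS_INSUFFICIENT = "insufficient"


class DegenerateColumnError(ValueError):
    """A column to be imputed has too few observed values to define sigma."""


@dataclass
class LogMatrix:
    """Proteins x samples log2 intensities with an imputation audit trail.

    ``values`` may contain NaN before imputation and is complete after;
    ``imputed`` flags cells that were missing and have been filled.  Cells
    that are neither imputed nor NaN are observed quantifications.
    """

    values: pd.DataFrame
    design: SampleDesign
    imputed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.values.columns) != self.design.sample_ids:
            raise ValueError("matrix columns must match design sample_ids")
        if self.imputed is None:
            self.imputed = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )

    @property
    def observed(self) -> pd.DataFrame:
        """True where a cell holds a real (non-imputed) quantification."""
        return self.values.notna() & ~self.imputed

    def group_valid_counts(self, groups: Iterable[Group] | None = None) -> pd.DataFrame:
        """Observed-value counts per protein per (fiber, time) group."""
        groups = list(groups) if groups is not None else self.design.groups
        obs = self.observed
        out = {}
        for f, t in groups:
            cols = self.design.samples_in(f, t)
            if not cols:
                raise ValueError(f"group {(f, t)} has no samples in the design")
            out[f"{f}_{t}"] = obs[cols].sum(axis=1)
        return pd.DataFrame(out, index=self.values.index)


def log2_transform(table: ProteinGroupTable) -> LogMatrix:
    """Log2 of linear intensities; missing stays missing."""
    vals = table.intensities
    arr = vals.to_numpy(dtype=float)
    if np.nanmin(arr, initial=0.0) < 0:
        raise ValueError("negative intensity cannot be log-transformed")
    return LogMatrix(np.log2(vals), table.design)


@dataclass
class QuantStatus:
    """Per-protein fiber-exclusivity classification.

    A protein is *exclusive* to a fiber type when it reaches ``min_valid``
    observed values in at least one group of that fiber type and in none of
    the other's; *both* when each fiber type has a qualifying group;
    *insufficient* otherwise.
    """

    status: pd.Series
    group_counts: pd.DataFrame
    min_valid: int

    def proteins_with(self, status: str) -> set[str]:
        return set(self.status.index[self.status == status])

    def counts(self) -> dict[str, int]:
        return self.status.value_counts().to_dict()


def classify_exclusive(m: LogMatrix, min_valid: int = 3) -> QuantStatus:
    """Classify proteins as quantified in both fiber types or only one."""
    fibers = m.design.fiber_types
    if "slow" not in fibers or "fast" not in fibers:
        raise ValueError("design must contain both slow and fast fiber samples")
    counts = m.group_valid_counts()
    slow_cols = [c for c in counts.columns if c.startswith("slow_")]
    fast_cols = [c for c in counts.columns if c.startswith("fast_")]
    slow_ok = (counts[slow_cols] >= min_valid).any(axis=1)
    fast_ok = (counts[fast_cols] >= min_valid).any(axis=1)
    status = pd.Series(STATUS_INSUFFICIENT, index=counts.index, name="status")
    status[slow_ok & fast_ok] = STATUS_BOTH
    status[slow_ok & ~fast_ok] = STATUS_EXCLUSIVE_SLOW
    status[fast_ok & ~slow_ok] = STATUS_EXCLUSIVE_FAST
    return QuantStatus(status, counts, min_valid)


def valid_value_filter(
    m: LogMatrix,
    groups: Sequence[Group],
    min_valid: int = 3,
    fraction_mode: bool = False,
    fraction: float = 0.5,
) -> tuple[set[str], pd.DataFrame]:
    """Proteins admissible for a comparison over ``groups``.

    Default rule: retained iff at least ``min_valid`` observed values in at
    least one of the comparison's groups.  ``fraction_mode`` instead keeps
    proteins observed in at least ``fraction`` of all samples.
    """
    counts = m.group_valid_counts(groups)
    if fraction_mode:
        obs_frac = m.observed.mean(axis=1)
        keep = obs_frac >= fraction
    else:
        keep = (counts >= min_valid).any(axis=1)
    return set(counts.index[keep]), counts


@dataclass
class ImputationParams:
    """Per-column Gaussian parameters actually used for imputation."""

    table: pd.DataFrame  # columns: mu, sigma, n_observed, n_imputed
    shift: float
    width: float
    scope: str
    seed: int


def impute_gaussian_downshift(
    m: LogMatrix,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
    width: float | None = None,
    shift: float | None = None,
    scope: str | None = None,
) -> tuple[LogMatrix, ImputationParams]:
    """Fill missing cells from a downshifted, narrowed Gaussian.

    For target column j with observed mean mu_j and SD sigma_j (ddof=1,
    observed cells only), each missing cell receives an independent draw
    from Normal(mu_j - d*sigma_j, (w*sigma_j)^2).  ``scope='global'`` uses
    whole-matrix moments instead.  Observed cells are never altered.
    """
    config = config or AnalysisConfig()
    w = config.impute_width if width is None else width
    d = config.impute_shift if shift is None else shift
    scope = scope or config.impute_scope
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    vals = m.values.copy()
    imputed = m.imputed.copy()
    missing_by_col = vals.isna()
    params_rows = {}
    if scope == "global":
        flat = vals.to_numpy().ravel()
        flat = flat[~np.isnan(flat)]
        if flat.size < 2:
            raise DegenerateColumnError("matrix has fewer than 2 observed values")
        g_mu, g_sigma = float(np.mean(flat)), float(np.std(flat, ddof=1))
    for col in vals.columns:
        miss = missing_by_col[col]
        n_miss = int(miss.sum())
        obs = vals.loc[~miss, col].to_numpy()
        if scope == "global":
            mu, sigma = g_mu, g_sigma
        else:
            if n_miss and obs.size < 2:
                raise DegenerateColumnError(
                    f"sample {col!r} has {obs.size} observed values; "
                    "cannot estimate an imputation distribution"
                )
            mu = float(np.mean(obs)) if obs.size else np.nan
            sigma = float(np.std(obs, ddof=1)) if obs.size >= 2 else np.nan
        if n_miss:
            draws = rng.normal(mu - d * sigma, w * sigma, size=n_miss)
            vals.loc[miss, col] = draws
            imputed.loc[miss, col] = True
        params_rows[col] = (mu, sigma, int((~miss).sum()), n_miss)
    params = ImputationParams(
        pd.DataFrame(
            params_rows, index=["mu", "sigma", "n_observed", "n_imputed"]
        ).T,
        shift=d,
        width=w,
        scope=scope,
        seed=seed,
    )
    return LogMatrix(vals, m.design, imputed), params


def imputation_audit(before: LogMatrix, after: LogMatrix) -> pd.DataFrame:
    """Long-format record of every imputed cell (protein, sample, value)."""
    filled = after.imputed & ~before.imputed
    rows = []
    for col in filled.columns:
        idx = filled.index[filled[col]]
        for pid in idx:
            rows.append((pid, col, after.values.at[pid, col]))
    return pd.DataFrame(rows, columns=["protein_group_id", "sample_id", "imputed_value"])
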