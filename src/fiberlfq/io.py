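"""Domain types and tabular I/O.

The on-disk dialect follows MaxQuant's ``proteinGroups.txt`` conventions:
tab-separated text, one ``LFQ intensity <sample>`` column per sample, and a
semicolon-separated accession list in ``Majority protein IDs``.  MaxQuant
writes ``0`` for proteins it could not quantify in a run, so a zero (or
empty) intensity is normalised to missing (NaN) on read.

The experimental design is a small CSV mapping each sample to a subject, a
fiber type (``slow``/``fast``/``whole``) and a timepoint (``PRE``/``POST``);
a "group" throughout the package is a (fiber_type, timepoint) pair.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

FIBER_TYPES = ("slow", "fast", "whole")
TIMEPOINTS = ("PRE", "POST")
NAMESPACES = ("GOCC", "GOBP", "GOMF", "KEGG", "Keyword")

LFQ_PREFIX = "LFQ intensity "
MAJORITY_COL = "Majority protein IDs"


class FormatError(ValueError):
    """A required column, value or enum member is missing or malformed."""


class DesignError(ValueError):
    """The sample design violates the paired 2x2 layout constraints."""


# ---------------------------------------------------------------------------
# Sample design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleDesign:
    """Sample -> (subject, fiber type, timepoint) mapping.

    ``table`` has columns sample_id, subject_id, fiber_type, timepoint, one
    row per sample.  At most one sample may occupy a given
    (subject, fiber_type, timepoint) cell.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "subject_id", "fiber_type", "timepoint"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise FormatError(f"design table lacks column(s): {missing}")
        t = self.table.reset_index(drop=True)[required].astype(
            {"sample_id": str, "subject_id": str}
        )
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise DesignError(f"duplicate sample_id(s): {dup}")
        bad_f = sorted(set(t["fiber_type"]) - set(FIBER_TYPES))
        if bad_f:
            raise FormatError(
                f"unknown fiber_type value(s) {bad_f}; allowed: {list(FIBER_TYPES)}"
            )
        bad_t = sorted(set(t["timepoint"]) - set(TIMEPOINTS))
        if bad_t:
            raise FormatError(
                f"unknown timepoint value(s) {bad_t}; allowed: {list(TIMEPOINTS)}"
            )
        cell = t[["subject_id", "fiber_type", "timepoint"]]
        if cell.duplicated().any():
            dup = cell[cell.duplicated()].values.tolist()
            raise DesignError(f"more than one sample per design cell: {dup}")
        object.__setattr__(self, "table", t)

    # -- basic views --------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def subjects(self) -> list[str]:
        return sorted(self.table["subject_id"].unique())

    @property
    def n(self) -> int:
        """Number of subjects."""
        return len(self.subjects)

    @property
    def fiber_types(self) -> list[str]:
        return [f for f in FIBER_TYPES if f in set(self.table["fiber_type"])]

    @property
    def groups(self) -> list[tuple[str, str]]:
        """(fiber_type, timepoint) pairs present in the design."""
        seen = self.table[["fiber_type", "timepoint"]].drop_duplicates()
        return [tuple(r) for r in seen.itertuples(index=False)]

    def samples_in(self, fiber_type: str, timepoint: str) -> list[str]:
        t = self.table
        m = (t["fiber_type"] == fiber_type) & (t["timepoint"] == timepoint)
        return t.loc[m, "sample_id"].tolist()

    def sample_for(self, subject_id: str, fiber_type: str, timepoint: str) -> str | None:
        t = self.table
        m = (
            (t["subject_id"] == subject_id)
            & (t["fiber_type"] == fiber_type)
            & (t["timepoint"] == timepoint)
        )
        hits = t.loc[m, "sample_id"]
        return None if hits.empty else hits.iloc[0]

    def is_complete(self, fiber_types: Sequence[str] = ("slow", "fast")) -> bool:
        """True if every subject has a sample in every fiber x time cell."""
        for s in self.subjects:
            for f in fiber_types:
                for tp in TIMEPOINTS:
                    if self.sample_for(s, f, tp) is None:
                        return False
        return True


def read_sample_design(path: str | os.PathLike) -> SampleDesign:
    """Read a design CSV with columns sample,subject,fiber_type,timepoint."""
    df = pd.read_csv(path, dtype=str)
    rename = {"sample": "sample_id", "subject": "subject_id"}
    df = df.rename(columns=rename)
    return SampleDesign(df)


def write_sample_design(design: SampleDesign, path: str | os.PathLike) -> Path:
    out = design.table.rename(
        columns={"sample_id": "sample", "subject_id": "subject"}
    )
    path = Path(path)
    out.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Protein groups
# ---------------------------------------------------------------------------


@dataclass
class ProteinGroupTable:
    """Protein groups x samples intensity matrix with identifiers.

    ``intensities``: linear LFQ units, NaN for missing, indexed by
    protein_group_id (the first majority accession), columns exactly the
    design's sample_ids.  ``meta``: per-group accession tuple, gene name and
    unique-peptide count, same index.
    """

    intensities: pd.DataFrame
    meta: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        if list(self.intensities.columns) != self.design.sample_ids:
            raise FormatError(
                "intensity columns do not match design sample_ids"
            )
        if self.intensities.index.duplicated().any():
            dup = self.intensities.index[self.intensities.index.duplicated()]
            raise FormatError(f"duplicate protein_group_id(s): {list(dup)}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise FormatError("negative intensity encountered")
        # MaxQuant writes 0 for non-quantified entries: normalise to NaN.
        self.intensities = self.intensities.astype(float).replace(0.0, np.nan)

    @property
    def protein_group_ids(self) -> list[str]:
        return list(self.intensities.index)

    def accessions_of(self, protein_group_id: str) -> tuple[str, ...]:
        return tuple(self.meta.loc[protein_group_id, "accessions"].split(";"))


def read_protein_groups(path: str | os.PathLike, design: SampleDesign) -> ProteinGroupTable:
    """Parse a MaxQuant-style proteinGroups TSV against a sample design."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if MAJORITY_COL not in df.columns:
        raise FormatError(f'missing required column "{MAJORITY_COL}"')
    for sid in design.sample_ids:
        if LFQ_PREFIX + sid not in df.columns:
            raise FormatError(f'missing required column "{LFQ_PREFIX}{sid}"')
    ids = df[MAJORITY_COL].str.split(";").str[0]
    if ids.duplicated().any():
        raise FormatError(
            f"duplicate leading accession(s): {sorted(ids[ids.duplicated()])}"
        )
    inten = pd.DataFrame(index=pd.Index(ids, name="protein_group_id"))
    for sid in design.sample_ids:
        col = pd.to_numeric(df[LFQ_PREFIX + sid], errors="coerce")
        inten[sid] = col.to_numpy()
    meta = pd.DataFrame(
        {
            "accessions": df[MAJORITY_COL].to_numpy(),
            "gene_name": df.get("Gene names", pd.Series([""] * len(df))).fillna("").to_numpy(),
            "unique_peptides": pd.to_numeric(
                df.get("Unique peptides", pd.Series([0] * len(df))), errors="coerce"
            )
            .fillna(0)
            .astype(int)
            .to_numpy(),
        },
        index=inten.index,
    )
    return ProteinGroupTable(inten, meta, design)


def write_protein_groups(table: ProteinGroupTable, path: str | os.PathLike) -> Path:
    out = pd.DataFrame({MAJORITY_COL: table.meta["accessions"]})
    out["Gene names"] = table.meta["gene_name"]
    out["Unique peptides"] = table.meta["unique_peptides"]
    for sid in table.design.sample_ids:
        out[LFQ_PREFIX + sid] = table.intensities[sid].fillna(0.0)
    path = Path(path)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# Peptides
# ---------------------------------------------------------------------------


@dataclass
class PeptideTable:
    """Peptides x samples intensities with accession mappings.

    ``info``: peptide_id, sequence, mapped_accessions (semicolon string,
    non-empty).  ``intensities``: linear units, NaN missing, indexed by
    peptide_id.
    """

    info: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        if self.info["sequence"].duplicated().any():
            raise FormatError("duplicate peptide sequences")
        if (self.info["mapped_accessions"].str.len() == 0).any():
            raise FormatError("peptide with empty accession mapping")
        self.intensities = self.intensities.astype(float).replace(0.0, np.nan)

    def mapped(self, peptide_id: str) -> tuple[str, ...]:
        row = self.info.set_index("peptide_id").loc[peptide_id]
        return tuple(row["mapped_accessions"].split(";"))


def read_peptides(path: str | os.PathLike) -> PeptideTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("peptide_id", "sequence", "mapped_accessions"):
        if col not in df.columns:
            raise FormatError(f'missing required column "{col}"')
    sample_cols = [c for c in df.columns if c.startswith(LFQ_PREFIX)]
    info = df[["peptide_id", "sequence", "mapped_accessions"]].copy()
    inten = pd.DataFrame(index=pd.Index(df["peptide_id"], name="peptide_id"))
    for c in sample_cols:
        inten[c[len(LFQ_PREFIX):]] = pd.to_numeric(df[c], errors="coerce").to_numpy()
    return PeptideTable(info, inten)


def write_peptides(peptides: PeptideTable, path: str | os.PathLike) -> Path:
    out = peptides.info.copy()
    for sid in peptides.intensities.columns:
        out[LFQ_PREFIX + sid] = peptides.intensities[sid].fillna(0.0).to_numpy()
    path = Path(path)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


@dataclass
class AnnotationMap:
    """Accession -> {(namespace, term)} relation, deduplicated.

    A protein group carries a term if *any* of its member accessions does
    (members of a group share peptide evidence).
    """

    entries: pd.DataFrame  # columns: accession, namespace, term

    def __post_init__(self) -> None:
        bad = sorted(set(self.entries["namespace"]) - set(NAMESPACES))
        if bad:
            raise FormatError(
                f"unknown namespace(s) {bad}; allowed: {list(NAMESPACES)}"
            )
        self.entries = (
            self.entries[["accession", "namespace", "term"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.entries)

    def terms_for(self, accessions: Iterable[str]) -> set[tuple[str, str]]:
        acc = set(accessions)
        hit = self.entries[self.entries["accession"].isin(acc)]
        return set(map(tuple, hit[["namespace", "term"]].itertuples(index=False)))

    def members(self, namespace: str, term: str) -> set[str]:
        e = self.entries
        m = (e["namespace"] == namespace) & (e["term"] == term)
        return set(e.loc[m, "accession"])

    def terms(self, namespace: str | None = None) -> list[tuple[str, str]]:
        e = self.entries
        if namespace is not None:
            e = e[e["namespace"] == namespace]
        return sorted(set(map(tuple, e[["namespace", "term"]].itertuples(index=False))))

    def group_members(
        self, namespace: str, term: str, accession_lists: Mapping[str, Iterable[str]]
    ) -> set[str]:
        """Protein-group ids whose accession list intersects the term members."""
        members = self.members(namespace, term)
        return {
            gid for gid, accs in accession_lists.items() if members.intersection(accs)
        }


def read_annotations(path: str | os.PathLike) -> AnnotationMap:
    df = pd.read_csv(
        path, sep="\t", dtype=str, header=0,
    )
    for col in ("accession", "namespace", "term"):
        if col not in df.columns:
            raise FormatError(f'missing required column "{col}"')
    return AnnotationMap(df)


def write_annotations(annotation: AnnotationMap, path: str | os.PathLike) -> Path:
    path = Path(path)
    annotation.entries.sort_values(["namespace", "term", "accession"]).to_csv(
        path, sep="\t", index=False
    )
    return path


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Tunable knobs of the statistical pipeline.

    min_valid
        Minimum number of quantified values required in at least one
        experimental group for a protein to enter a comparison (default 3).
    sig_cutoff
        Significance-score threshold; proteins with s <= sig_cutoff are
        called regulated (default 0.05).
    impute_width, impute_shift
        Width (as a fraction of the observed SD) and downshift (in observed
        SDs) of the Gaussian used for missing-value imputation; defaults
        0.3 and 1.0 — a narrowed, left-shifted normal mimicking abundances
        below the detection limit.
    impute_scope
        ``per_column`` (each sample's own mean/SD; Perseus convention) or
        ``global`` (whole-matrix moments).
    """

    min_valid: int = 3
    valid_fraction_mode: bool = False
    valid_fraction: float = 0.5
    sig_cutoff: float = 0.05
    impute_width: float = 0.3
    impute_shift: float = 1.0
    impute_scope: str = "per_column"
    cluster_fisher_fdr: float = 0.02
    enrich_fdr: float = 0.05
    n_clusters: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.sig_cutoff < 1:
            raise ValueError("sig_cutoff must lie in (0, 1)")
        if self.impute_width <= 0:
            raise ValueError("impute_width must be > 0")
        if self.impute_shift < 0:
            raise ValueError("impute_shift must be >= 0")
        if self.min_valid < 1:
            raise ValueError("min_valid must be >= 1")
        if self.impute_scope not in ("per_column", "global"):
            raise ValueError("impute_scope must be 'per_column' or 'global'")

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise FormatError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**known)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


# ---------------------------------------------------------------------------
# Generic result writing
# ---------------------------------------------------------------------------


def write_results(
    tables: Mapping[str, pd.DataFrame], out_dir: str | os.PathLike
) -> dict[str, Path]:
    """Write result DataFrames as TSVs with deterministic row order.

    Rows are sorted by protein_group_id and then contrast when those columns
    exist; otherwise by all columns left to right.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        sort_cols = [
            c for c in ("protein_group_id", "contrast") if c in df.columns
        ] or list(df.columns)
        ordered = df.sort_values(sort_cols, kind="mergesort") if len(df) else df
        path = out_dir / f"{name}.tsv"
        ordered.to_csv(path, sep="\t", index=False, float_format="%.17g")
        paths[name] = path
    return paths
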