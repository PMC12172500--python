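"""Typed containers and I/O for abundance tables and cohort metadata.

The central object is :class:`AbundanceTable`, a samples x taxa matrix of
relative abundances with a kingdom tag (bacteria / fungi) per taxon and a
taxonomic level for the whole table.  Cohort metadata records, per sample,
the subject it came from, the scalp region (T = frontal, H = occipital),
the subject's age in years, and the clinical stage on the Hamilton-Norwood
scale (Healthy, AGA3, AGA5, AGA7).

Tables are plain TSV: first column ``sample_id``, remaining columns taxa.
Lines starting with ``#`` are treated as comments so that pipeline outputs
can carry a provenance header.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STAGES: tuple[str, ...] = ("Healthy", "AGA3", "AGA5", "AGA7")
REGIONS: tuple[str, ...] = ("T", "H")
KINGDOMS: tuple[str, ...] = ("bacteria", "fungi")
LEVELS: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: tolerance on row sums for a table to count as normalized
NORM_TOL = 1e-9

AGE_MIN, AGE_MAX = 20, 60


class FormatError(ValueError):
    """Raised when an input file or table violates the format contract."""


def stage_index(stage: str) -> int:
    """Severity rank of a clinical stage (0 = Healthy ... 3 = AGA7)."""
    try:
        return STAGES.index(stage)
    except ValueError:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}") from None


def age_bin(age: int | float, width: int = 5) -> str:
    """Deterministic 5-year age-bin label, e.g. ``[25,30)``.

    Bins are closed-open; the right edge of the final bin is closed at 60,
    so ages 55-60 all map to ``[55,60]``.
    """
    if not (AGE_MIN <= age <= AGE_MAX):
        raise ValueError(f"age {age} outside supported range [{AGE_MIN},{AGE_MAX}]")
    lo = AGE_MIN + width * int((age - AGE_MIN) // width)
    if lo >= AGE_MAX - width:  # final bin absorbs the closed right edge
        lo = AGE_MAX - width
        return f"[{lo},{AGE_MAX}]"
    return f"[{lo},{lo + width})"


def age_bin_center(label: str) -> float:
    """Midpoint of an :func:`age_bin` label."""
    lo, hi = label.strip("[]()").split(",")
    return (float(lo) + float(hi)) / 2.0


@dataclass
class AbundanceTable:
    """Samples x taxa relative-abundance matrix.

    Parameters
    ----------
    data:
        DataFrame with sample ids as the index and taxon ids as columns.
        Values are non-negative relative abundances.
    kingdoms:
        Either a single kingdom name applied to every taxon, or a mapping
        taxon id -> kingdom.
    level:
        Taxonomic level of the columns (one of :data:`LEVELS`).
    """

    data: pd.DataFrame
    kingdoms: pd.Series = field(repr=False)
    level: str = "genus"

    def __init__(
        self,
        data: pd.DataFrame,
        kingdoms: str | Mapping[str, str] | pd.Series,
        level: str = "genus",
    ):
        data = data.copy()
        data.index = data.index.astype(str)
        data.index.name = "sample_id"
        data.columns = data.columns.astype(str)
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon ids: {dups}")
        values = data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise FormatError("non-finite abundance values")
        if (values < 0).any():
            raise FormatError("negative abundance values")
        if isinstance(kingdoms, str):
            if kingdoms not in KINGDOMS:
                raise ValueError(f"unknown kingdom {kingdoms!r}")
            kingdoms = pd.Series(kingdoms, index=data.columns)
        else:
            kingdoms = pd.Series(kingdoms).astype(str)
            missing = data.columns.difference(kingdoms.index)
            if len(missing):
                raise ValueError(f"kingdom tag missing for taxa: {list(missing)}")
            kingdoms = kingdoms.reindex(data.columns)
            bad = set(kingdoms.unique()) - set(KINGDOMS)
            if bad:
                raise ValueError(f"unknown kingdoms {sorted(bad)}")
        if level not in LEVELS:
            raise ValueError(f"unknown taxonomic level {level!r}")
        self.data = data.astype(float)
        self.kingdoms = kingdoms
        self.level = level

    # -- basic accessors ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def is_normalized(self, tol: float = NORM_TOL) -> bool:
        sums = self.values.sum(axis=1)
        return bool(np.all(np.abs(sums - 1.0) <= tol))

    def normalize(self) -> "AbundanceTable":
        """Return a copy with each row renormalized to sum 1.

        Zero-sum rows cannot be normalized and raise a :class:`FormatError`
        naming the offending samples.
        """
        sums = self.values.sum(axis=1)
        zero = sums <= 0
        if zero.any():
            bad = [s for s, z in zip(self.sample_ids, zero) if z]
            raise FormatError(f"zero-sum sample(s): {bad}")
        return AbundanceTable(self.data.div(sums, axis=0), self.kingdoms, self.level)

    def subset(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return AbundanceTable(self.data.loc[list(sample_ids)], self.kingdoms, self.level)

    def sorted_taxa(self) -> "AbundanceTable":
        """Copy with columns in lexicographic order (deterministic output)."""
        cols = sorted(self.data.columns)
        return AbundanceTable(self.data[cols], self.kingdoms[cols], self.level)


@dataclass
class CohortMetadata:
    """Per-sample cohort annotations with pairing structure.

    ``df`` is indexed by sample id and has columns ``subject_id``,
    ``region``, ``age``, ``stage`` and the derived ``age_bin``.
    """

    df: pd.DataFrame

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        if df.index.name != "sample_id" and "sample_id" in df.columns:
            df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        df.index.name = "sample_id"
        required = {"subject_id", "region", "age", "stage"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"metadata missing columns: {sorted(missing)}")
        if df.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")
        df["subject_id"] = df["subject_id"].astype(str)
        df["age"] = df["age"].astype(int)
        df["age_bin"] = [age_bin(a) for a in df["age"]]
        self.df = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.df["subject_id"]))

    def stages(self) -> pd.Series:
        return self.df["stage"]

    def groups(self) -> pd.Series:
        """Subject id per sample — the grouping unit for leakage-safe splits."""
        return self.df["subject_id"]

    def subset(self, sample_ids: Sequence[str]) -> "CohortMetadata":
        return CohortMetadata(self.df.loc[list(sample_ids)])

    def samples_of_stage(self, stage: str) -> list[str]:
        return list(self.df.index[self.df["stage"] == stage])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_abundance_table(
    path: str | Path,
    kingdom: str,
    level: str = "genus",
    orientation: str = "samples",
) -> AbundanceTable:
    """Read a TSV abundance table and renormalize rows to sum 1.

    ``orientation='samples'`` (default) expects samples in rows; pass
    ``orientation='taxa'`` for a transposed file.  A square table is
    ambiguous and must carry an explicit orientation flag — the default is
    accepted but never silently guessed the other way.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if orientation not in ("samples", "taxa"):
        raise ValueError("orientation must be 'samples' or 'taxa'")
    if orientation == "taxa":
        df = df.T
    table = AbundanceTable(df, kingdom, level)
    return table.normalize()


def write_abundance_table(
    table: AbundanceTable, path: str | Path, header: str | None = None
) -> None:
    """Write a table as TSV with lexicographic taxon order.

    ``header`` (optional) is written as a leading ``#`` comment line.
    """
    out = table.sorted_taxa().data
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        out.to_csv(fh, sep="\t", lineterminator="\n")


def read_metadata(path: str | Path) -> CohortMetadata:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    return CohortMetadata(df)


def write_metadata(
    meta: CohortMetadata, path: str | Path, header: str | None = None
) -> None:
    cols = ["subject_id", "region", "age", "stage", "age_bin"]
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        meta.df[cols].to_csv(fh, sep="\t", lineterminator="\n")


_RANK_PREFIXES = tuple(f"{r[0]}__" for r in LEVELS)


def read_lineages(path: str | Path) -> pd.DataFrame:
    """Read a lineage TSV (taxon_id + one column per rank).

    ``g__``/``s__``-style rank prefixes are tolerated and stripped.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).set_index("taxon_id")
    for col in df.columns:
        df[col] = df[col].str.replace(r"^[a-z]__", "", regex=True)
    return df


def write_lineages(lineages: pd.DataFrame, path: str | Path) -> None:
    lineages.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def merge_kingdoms(
    bacterial: AbundanceTable,
    fungal: AbundanceTable,
    renormalize: bool = True,
) -> AbundanceTable:
    """Concatenate a bacterial and a fungal table over the same samples.

    Each input must be row-normalized.  The concatenated rows sum to 2;
    with ``renormalize=True`` (default) they are rescaled to sum 1, giving
    the two kingdoms equal mass per sample so that neither the kingdom with
    more taxa nor the deeper-sequenced one dominates downstream distances.
    """
    for name, t in (("bacterial", bacterial), ("fungal", fungal)):
        if not t.is_normalized(tol=1e-6):
            raise ValueError(f"{name} table is not row-normalized")
    sb, sf = set(bacterial.sample_ids), set(fungal.sample_ids)
    if sb != sf:
        diff = sorted(sb.symmetric_difference(sf))
        raise ValueError(f"sample sets differ between kingdoms: {diff}")
    shared = set(bacterial.taxon_ids) & set(fungal.taxon_ids)
    f_data = fungal.data.loc[bacterial.sample_ids]
    if shared:  # same genus name in both kingdoms: disambiguate
        f_data = f_data.rename(
            columns={t: f"{t} (fungi)" for t in shared}
        )
    merged = pd.concat([bacterial.data, f_data], axis=1)
    kingdoms = pd.concat(
        [
            pd.Series("bacteria", index=bacterial.data.columns),
            pd.Series("fungi", index=f_data.columns),
        ]
    )
    if renormalize:
        merged = merged.div(merged.sum(axis=1), axis=0)
    if bacterial.level != fungal.level:
        raise ValueError(
            f"level mismatch: {bacterial.level} vs {fungal.level}"
        )
    return AbundanceTable(merged, kingdoms, bacterial.level)


def aggregate_to_level(
    table: AbundanceTable, lineages: pd.DataFrame, level: str
) -> AbundanceTable:
    """Sum abundances of taxa sharing the same name at a coarser rank.

    Taxa unnamed at the target rank are pooled into ``unclassified_<kingdom>``.
    Aggregating a table to its own level is the identity.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    if level == table.level:
        return table
    if LEVELS.index(level) > LEVELS.index(table.level):
        raise ValueError(
            f"cannot refine {table.level}-level table to {level} level"
        )
    missing = [t for t in table.taxon_ids if t not in lineages.index]
    if missing:
        raise ValueError(f"no lineage entry for taxa: {missing}")
    new_cols: dict[str, list[str]] = {}
    new_kingdom: dict[str, str] = {}
    names = lineages[level] if level in lineages.columns else pd.Series(dtype=str)
    for taxon in table.taxon_ids:
        kingdom = table.kingdoms[taxon]
        name = names.get(taxon) if len(names) else None
        if name is None or (isinstance(name, float) and math.isnan(name)) or name == "":
            name = f"unclassified_{kingdom}"
        name = str(name)
        key = name
        if key in new_kingdom and new_kingdom[key] != kingdom:
            key = f"{name} ({kingdom})"
        new_cols.setdefault(key, []).append(taxon)
        new_kingdom[key] = kingdom
    agg = pd.DataFrame(
        {key: table.data[cols].sum(axis=1) for key, cols in new_cols.items()},
        index=table.data.index,
    )
    return AbundanceTable(agg, new_kingdom, level)


def validate_cohort(
    tables: AbundanceTable | Iterable[AbundanceTable],
    metadata: CohortMetadata,
) -> list[dict]:
    """Cross-check tables against metadata; returns a list of violations.

    Report-only: each violation is a dict with ``kind``, a human-readable
    ``message`` and the ids involved.  An empty list means the cohort is
    internally consistent.
    """
    if isinstance(tables, AbundanceTable):
        tables = [tables]
    violations: list[dict] = []
    meta_ids = set(metadata.sample_ids)
    for i, table in enumerate(tables):
        tab_ids = set(table.sample_ids)
        for sid in sorted(tab_ids - meta_ids):
            violations.append(
                {"kind": "sample_not_in_metadata", "sample_id": sid, "table": i,
                 "message": f"sample {sid} in table {i} absent from metadata"}
            )
        for sid in sorted(meta_ids - tab_ids):
            violations.append(
                {"kind": "sample_not_in_table", "sample_id": sid, "table": i,
                 "message": f"sample {sid} in metadata absent from table {i}"}
            )
        sums = table.values.sum(axis=1)
        for sid, s in zip(table.sample_ids, sums):
            if abs(s - 1.0) > 1e-6:
                violations.append(
                    {"kind": "not_normalized", "sample_id": sid, "table": i,
                     "message": f"sample {sid} row sums to {s:.6g}"}
                )
    df = metadata.df
    for sid, row in df.iterrows():
        if row["region"] not in REGIONS:
            violations.append(
                {"kind": "bad_region", "sample_id": sid,
                 "message": f"sample {sid} has region {row['region']!r}"}
            )
        if row["stage"] not in STAGES:
            violations.append(
                {"kind": "bad_stage", "sample_id": sid,
                 "message": f"sample {sid} has stage {row['stage']!r}"}
            )
    for subj, grp in df.groupby("subject_id"):
        if len(grp) > 2:
            violations.append(
                {"kind": "too_many_samples", "subject_id": subj,
                 "message": f"subject {subj} has {len(grp)} samples"}
            )
        regions = list(grp["region"])
        if len(regions) != len(set(regions)):
            violations.append(
                {"kind": "duplicate_region", "subject_id": subj,
                 "message": f"subject {subj} has two samples from one region"}
            )
        for col in ("age", "stage"):
            if grp[col].nunique() > 1:
                violations.append(
                    {"kind": f"inconsistent_{col}", "subject_id": subj,
                     "message": f"subject {subj} has conflicting {col} values"}
                )
    return violations
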