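"""Domain tables and their TSV serialization.

All tables are thin wrappers around :class:`pandas.DataFrame` that enforce
the schema invariants of the pipeline at construction time.  Files are
tab-separated UTF-8 with a header row and ``NA`` for missing values, so
every artifact is diff-able and round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import ClassVar, Iterable, Sequence

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "DM")
CELL_TYPES = ("neuron", "OPC", "OL", "astrocyte", "NSC", "astrocyte_precursor")
STAGES = ("precursor", "intermediate", "differentiated")
EVENT_CATEGORIES = (
    "cassette",
    "multi_exon",
    "mutually_exclusive",
    "acceptor_switch",
    "donor_switch",
)
#: categories describing exon inclusion blocks (single, multi, mutually excl.)
EXON_CATEGORIES = ("cassette", "multi_exon", "mutually_exclusive")

NA_REP = "NA"


class SchemaError(ValueError):
    """A required column is missing or an enum value is out of range."""


class TableValueError(ValueError):
    """A cell violates a value invariant (sign, integrality, positivity)."""


class UniquenessError(ValueError):
    """A column that must be unique contains duplicates."""


def _require_columns(df: pd.DataFrame, columns: Iterable[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing}")


def _require_unique(df: pd.DataFrame, column: str, name: str) -> None:
    dup = df[column][df[column].duplicated()]
    if len(dup):
        raise UniquenessError(
            f"{name}: duplicate {column} value(s): {sorted(set(dup))[:5]}"
        )


def _require_enum(df: pd.DataFrame, column: str, allowed: Sequence[str], name: str) -> None:
    bad = sorted(set(df[column]) - set(allowed))
    if bad:
        raise SchemaError(
            f"{name}: column {column!r} contains value(s) {bad} "
            f"not in allowed set {list(allowed)}"
        )


def _require_nonneg_int(df: pd.DataFrame, columns: Iterable[str], name: str) -> None:
    for col in columns:
        values = df[col]
        if values.isna().any():
            row = values.index[values.isna()][0]
            raise TableValueError(f"{name}: missing count at row {row}, column {col!r}")
        arr = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
            bad = values.index[arr != np.floor(arr)][0]
            raise TableValueError(
                f"{name}: non-integer count at row {bad}, column {col!r}"
            )
        if np.any(arr < 0):
            bad = values.index[arr < 0][0]
            raise TableValueError(
                f"{name}: negative count at row {bad}, column {col!r}"
            )


@dataclass
class SampleSheet:
    """Sample metadata: genotype, cell type, differentiation stage, replicate."""

    df: pd.DataFrame

    REQUIRED: ClassVar[tuple[str, ...]] = (
        "sample_id",
        "genotype",
        "cell_type",
        "stage",
        "replicate",
    )

    def __post_init__(self) -> None:
        name = type(self).__name__
        _require_columns(self.df, self.REQUIRED, name)
        _require_unique(self.df, "sample_id", name)
        _require_enum(self.df, "genotype", GENOTYPES, name)
        _require_enum(self.df, "cell_type", CELL_TYPES, name)
        _require_enum(self.df, "stage", STAGES, name)
        reps = np.asarray(self.df["replicate"], dtype=float)
        if np.any(reps < 1) or np.any(reps != np.floor(reps)):
            raise TableValueError(f"{name}: replicate must be a positive integer")
        self.df = self.df.reset_index(drop=True)
        self.df["replicate"] = self.df["replicate"].astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    def select(
        self,
        genotype: str | None = None,
        cell_type: str | None = None,
        stage: str | None = None,
    ) -> list[str]:
        """Sample ids matching every given (non-None) criterion."""
        mask = pd.Series(True, index=self.df.index)
        for col, val in (
            ("genotype", genotype),
            ("cell_type", cell_type),
            ("stage", stage),
        ):
            if val is not None:
                mask &= self.df[col] == val
        return list(self.df.loc[mask, "sample_id"])

    def write(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, na_rep=NA_REP)

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str},
                               keep_default_na=False, na_values=[NA_REP]))


@dataclass
class GeneCountTable:
    """Gene-level read counts, one integer column per sample."""

    df: pd.DataFrame  # columns: gene_id + sample columns

    def __post_init__(self) -> None:
        name = type(self).__name__
        _require_columns(self.df, ["gene_id"], name)
        _require_unique(self.df, "gene_id", name)
        if not self.samples:
            raise SchemaError(f"{name}: no sample columns present")
        _require_nonneg_int(self.df, self.samples, name)
        self.df = self.df.reset_index(drop=True)
        self.df[self.samples] = self.df[self.samples].astype(np.int64)

    @property
    def samples(self) -> list[str]:
        return [c for c in self.df.columns if c != "gene_id"]

    @property
    def gene_ids(self) -> pd.Series:
        return self.df["gene_id"]

    def matrix(self) -> pd.DataFrame:
        """Counts indexed by gene_id (genes x samples)."""
        return self.df.set_index("gene_id")[self.samples]

    def check_samples(self, sheet: SampleSheet) -> None:
        if set(self.samples) != set(sheet.sample_ids):
            raise SchemaError(
                "GeneCountTable: sample columns do not match the sample sheet"
            )

    def write(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, na_rep=NA_REP)

    @classmethod
    def read(cls, path: str | Path) -> "GeneCountTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"gene_id": str},
                               keep_default_na=False, na_values=[NA_REP]))


@dataclass
class SplicingEventTable:
    """Per-event inclusion/exclusion read counts with an event category.

    Sample columns come in pairs ``inc_<sample>`` / ``exc_<sample>``.
    Optional BED-convention coordinates (0-based half-open, explicit strand)
    are carried through but never computed on.
    """

    df: pd.DataFrame

    COORD_COLUMNS: ClassVar[tuple[str, ...]] = ("chrom", "start", "end", "strand")

    def __post_init__(self) -> None:
        name = type(self).__name__
        _require_columns(self.df, ["event_id", "gene_id", "category"], name)
        _require_unique(self.df, "event_id", name)
        _require_enum(self.df, "category", EVENT_CATEGORIES, name)
        inc = {c[4:] for c in self.df.columns if c.startswith("inc_")}
        exc = {c[4:] for c in self.df.columns if c.startswith("exc_")}
        if inc != exc:
            raise SchemaError(
                f"{name}: unpaired inclusion/exclusion columns for samples "
                f"{sorted(inc.symmetric_difference(exc))}"
            )
        if not inc:
            raise SchemaError(f"{name}: no sample count columns present")
        count_cols = [f"{p}_{s}" for s in sorted(inc) for p in ("inc", "exc")]
        _require_nonneg_int(self.df, count_cols, name)
        self.df = self.df.reset_index(drop=True)
        self.df[count_cols] = self.df[count_cols].astype(np.int64)

    @property
    def samples(self) -> list[str]:
        return sorted(c[4:] for c in self.df.columns if c.startswith("inc_"))

    @property
    def has_coordinates(self) -> bool:
        return all(c in self.df.columns for c in self.COORD_COLUMNS)

    def inclusion(self, samples: Sequence[str] | None = None) -> pd.DataFrame:
        samples = list(samples) if samples is not None else self.samples
        out = self.df[[f"inc_{s}" for s in samples]].copy()
        out.columns = samples
        out.index = self.df["event_id"]
        return out

    def exclusion(self, samples: Sequence[str] | None = None) -> pd.DataFrame:
        samples = list(samples) if samples is not None else self.samples
        out = self.df[[f"exc_{s}" for s in samples]].copy()
        out.columns = samples
        out.index = self.df["event_id"]
        return out

    def write(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, na_rep=NA_REP)

    def write_bed(self, path: str | Path, events: Sequence[str] | None = None) -> None:
        """Export event coordinates as BED6 (requires coordinate columns)."""
        if not self.has_coordinates:
            raise SchemaError("SplicingEventTable: no coordinate columns to export")
        df = self.df
        if events is not None:
            df = df[df["event_id"].isin(set(events))]
        bed = df[["chrom", "start", "end", "event_id"]].copy()
        bed["score"] = 0
        bed["strand"] = df["strand"]
        bed.to_csv(path, sep="\t", index=False, header=False)

    @classmethod
    def read(cls, path: str | Path) -> "SplicingEventTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"event_id": str, "gene_id": str},
                               keep_default_na=False, na_values=[NA_REP]))


@dataclass
class PhosphoSiteTable:
    """Phosphosite label-free intensities; missingness is explicit (NA)."""

    df: pd.DataFrame  # columns: site_id, protein_id + sample columns

    def __post_init__(self) -> None:
        name = type(self).__name__
        _require_columns(self.df, ["site_id", "protein_id"], name)
        _require_unique(self.df, "site_id", name)
        if not self.samples:
            raise SchemaError(f"{name}: no sample columns present")
        values = self.df[self.samples].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any(values <= 0):
                raise TableValueError(
                    f"{name}: intensities must be strictly positive when present "
                    "(never zero-coded)"
                )
        self.df = self.df.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return [c for c in self.df.columns if c not in ("site_id", "protein_id")]

    def matrix(self) -> pd.DataFrame:
        return self.df.set_index("site_id")[self.samples]

    def write(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, na_rep=NA_REP)

    @classmethod
    def read(cls, path: str | Path) -> "PhosphoSiteTable":
        df = pd.read_csv(
            path, sep="\t", dtype={"site_id": str, "protein_id": str},
            keep_default_na=False, na_values=[NA_REP],
        )
        return cls(df)


@dataclass
class FociTable:
    """Per-nucleus ribonuclear foci counts."""

    df: pd.DataFrame  # columns: cell_id, cell_type, genotype, foci_count

    def __post_init__(self) -> None:
        name = type(self).__name__
        _require_columns(self.df, ["cell_id", "cell_type", "genotype", "foci_count"], name)
        _require_unique(self.df, "cell_id", name)
        _require_enum(self.df, "cell_type", CELL_TYPES, name)
        _require_enum(self.df, "genotype", GENOTYPES, name)
        _require_nonneg_int(self.df, ["foci_count"], name)
        self.df = self.df.reset_index(drop=True)
        self.df["foci_count"] = self.df["foci_count"].astype(np.int64)

    def write(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, na_rep=NA_REP)

    @classmethod
    def read(cls, path: str | Path) -> "FociTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"cell_id": str},
                               keep_default_na=False, na_values=[NA_REP]))


@dataclass
class SimulationTruth:
    """Planted effect labels emitted by every generator.

    One row per planted (or null) feature: ``feature_id``, ``layer``
    (expression/splicing/phospho/foci), ``label`` and the planted
    ``effect`` size on the layer's natural scale (log2 fold change,
    delta-PSI points, ...).
    """

    df: pd.DataFrame

    LABELS: ClassVar[tuple[str, ...]] = (
        "null",
        "de_up",
        "de_down",
        "splice_up",
        "splice_down",
        "differentiation_up",
        "differentiation_down",
        "immature_shift",
        "mature_shift",
        "phospho_up",
        "phospho_down",
        "genotype_exclusive",
    )

    def __post_init__(self) -> None:
        name = type(self).__name__
        _require_columns(self.df, ["feature_id", "layer", "label", "effect"], name)
        self.df = self.df.reset_index(drop=True)

    def features(self, *labels: str) -> set[str]:
        """Feature ids carrying any of the given labels."""
        mask = self.df["label"].isin(labels)
        return set(self.df.loc[mask, "feature_id"])

    def write(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, na_rep=NA_REP)

    @classmethod
    def read(cls, path: str | Path) -> "SimulationTruth":
        return cls(pd.read_csv(path, sep="\t", dtype={"feature_id": str},
                               keep_default_na=False, na_values=[NA_REP]))


TABLE_TYPES = {
    "samples": SampleSheet,
    "counts": GeneCountTable,
    "events": SplicingEventTable,
    "phospho": PhosphoSiteTable,
    "foci": FociTable,
    "truth": SimulationTruth,
}


def read_table(path: str | Path, schema: type) -> object:
    """Read and validate a table of the given schema from a TSV file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return schema.read(path)


def write_table(table: object, path: str | Path) -> Path:
    """Write a validated table to TSV; inverse of :func:`read_table`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.write(path)
    return path
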