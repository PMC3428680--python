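"""Abundance and trait tables: parsing, alignment and preprocessing.

The pipeline starts from an OTU-by-sample abundance table (rows = OTUs,
columns = samples) and an optional sample-by-trait table of numeric
environmental variables.  Preprocessing follows the usual co-occurrence
workflow: counts are converted to relative abundance per sample, rare OTUs
are removed by a prevalence filter, and each remaining OTU profile is
standardized to mean 0 / variance 1 so that downstream Pearson correlations
reduce to scaled inner products.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "StandardizedTable",
    "TraitTable",
    "ParseError",
    "AlignmentError",
    "read_tables",
    "read_abundance",
    "read_traits",
    "to_relative_abundance",
    "prevalence_filter",
    "standardize_rows",
]


class ParseError(ValueError):
    """A table file could not be interpreted as a numeric matrix."""


class AlignmentError(ValueError):
    """Abundance and trait tables share no samples."""


@dataclass
class AbundanceTable:
    """OTU x sample matrix of non-negative abundances.

    ``stage`` tracks the preprocessing state: ``raw`` (counts or arbitrary
    non-negative values), ``relative`` (each sample column sums to 1) or
    ``filtered`` (prevalence-filtered relative abundances).
    """

    otu_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match identifier lists")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicate OTU identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if np.isnan(self.values).any():
            raise ValueError("missing values are not permitted in abundance tables")
        if (self.values < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.stage not in ("raw", "relative", "filtered"):
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.otu_ids, columns=self.sample_ids)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "OTU"
        df.to_csv(path, sep="\t")


@dataclass
class StandardizedTable:
    """Row-standardized OTU profiles (mean 0, variance 1 per row).

    The population denominator (divide by n, not n-1) is used; the choice
    cancels in every Pearson correlation computed downstream.
    """

    otu_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    row_means: np.ndarray
    row_sds: np.ndarray

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.otu_ids, columns=self.sample_ids)

    def subset(self, otu_ids: list[str]) -> "StandardizedTable":
        """Row subset preserving the requested order."""
        pos = {o: i for i, o in enumerate(self.otu_ids)}
        missing = [o for o in otu_ids if o not in pos]
        if missing:
            raise KeyError(f"OTUs not in table: {missing[:5]}")
        idx = [pos[o] for o in otu_ids]
        return StandardizedTable(
            otu_ids=list(otu_ids),
            sample_ids=list(self.sample_ids),
            values=self.values[idx],
            row_means=self.row_means[idx],
            row_sds=self.row_sds[idx],
        )


@dataclass
class TraitTable:
    """Sample x trait matrix of numeric environmental variables.

    Missing values are permitted (NaN) and handled pairwise downstream.
    """

    sample_ids: list[str]
    trait_names: list[str]
    values: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.trait_names)):
            raise ValueError("values shape does not match identifier lists")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.trait_names)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "Sample"
        df.to_csv(path, sep="\t")

    def standardize(self) -> "TraitTable":
        """Column-standardize traits (mean 0, sd 1, NaN-aware, population sd)."""
        v = self.values.copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mu = np.nanmean(v, axis=0)
            sd = np.nanstd(v, axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        out = (v - mu) / sd_safe
        out[:, sd == 0] = np.nan
        if (sd == 0).any():
            bad = [t for t, s in zip(self.trait_names, sd) if s == 0]
            warnings.warn(f"constant traits set to NaN after standardization: {bad}")
        return TraitTable(list(self.sample_ids), list(self.trait_names), out, standardized=True)

    def align_to(self, sample_ids: list[str]) -> "TraitTable":
        """Restrict to the given samples, in the given order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        shared = [s for s in sample_ids if s in pos]
        if not shared:
            raise AlignmentError("no samples shared between abundance and trait tables")
        if len(shared) < len(self.sample_ids) or len(shared) < len(sample_ids):
            warnings.warn(
                "sample mismatch between abundance and trait tables; "
                f"using the {len(shared)} shared samples"
            )
        idx = [pos[s] for s in shared]
        return TraitTable(shared, list(self.trait_names), self.values[idx], self.standardized)


def _read_matrix(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise ParseError(f"{what} file {path} has no data rows")
    if df.shape[1] == 0:
        raise ParseError(f"{what} file {path} has no data columns")
    num = df.apply(pd.to_numeric, errors="coerce")
    # pandas encodes missing cells as NaN already; flag cells that were
    # present but non-numeric
    bad = num.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric value {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r} in {path}"
        )
    num.index = num.index.astype(str)
    num.columns = num.columns.astype(str)
    return num


def read_abundance(path: str | Path) -> AbundanceTable:
    """Read a tab-delimited OTU x sample table (first column = OTU ids)."""
    df = _read_matrix(path, "abundance")
    return AbundanceTable(list(df.index), list(df.columns), df.to_numpy(float))


def read_traits(path: str | Path) -> TraitTable:
    """Read a tab-delimited sample x trait table (first column = sample ids)."""
    df = _read_matrix(path, "trait")
    return TraitTable(list(df.index), list(df.columns), df.to_numpy(float))


def read_tables(
    abundance_path: str | Path, trait_path: str | Path | None = None
) -> tuple[AbundanceTable, TraitTable | None]:
    """Read abundance (and optionally trait) tables and align their samples.

    Samples are aligned by identifier intersection, order taken from the
    abundance table; mismatches emit a warning.
    """
    table = read_abundance(abundance_path)
    traits = None
    if trait_path is not None:
        traits = read_traits(trait_path).align_to(table.sample_ids)
    return table, traits


def to_relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Divide each sample column by its sum so columns sum to 1."""
    if table.stage != "raw":
        raise ValueError(f"expected a raw table, got stage={table.stage!r}")
    sums = table.values.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        names = [table.sample_ids[i] for i in zero]
        raise ValueError(f"all-zero sample column(s): {names}")
    return AbundanceTable(
        list(table.otu_ids), list(table.sample_ids), table.values / sums, stage="relative"
    )


def prevalence_filter(table: AbundanceTable, min_samples: int) -> AbundanceTable:
    """Keep OTUs detected (strictly positive) in at least ``min_samples`` samples."""
    if min_samples < 1:
        raise ValueError("min_samples must be a positive integer")
    if min_samples > table.n_samples:
        raise ValueError(
            f"min_samples={min_samples} exceeds the number of samples ({table.n_samples})"
        )
    prevalence = (table.values > 0).sum(axis=1)
    keep = np.flatnonzero(prevalence >= min_samples)
    if keep.size < 3:
        raise ValueError(
            f"prevalence filter retains {keep.size} OTUs; at least 3 are required "
            "for correlation analysis"
        )
    return AbundanceTable(
        [table.otu_ids[i] for i in keep],
        list(table.sample_ids),
        table.values[keep],
        stage="filtered",
    )


def standardize_rows(table: AbundanceTable) -> StandardizedTable:
    """Standardize each OTU profile to mean 0 and variance 1 (population sd).

    Zero-variance rows cannot be standardized and are dropped with a warning.
    """
    v = table.values
    means = v.mean(axis=1)
    sds = v.std(axis=1)  # population denominator
    keep = np.flatnonzero(sds > 0)
    if keep.size < len(table.otu_ids):
        dropped = [table.otu_ids[i] for i in np.flatnonzero(sds == 0)]
        warnings.warn(f"dropped {len(dropped)} constant OTU profile(s): {dropped[:5]}")
    x = (v[keep] - means[keep, None]) / sds[keep, None]
    return StandardizedTable(
        otu_ids=[table.otu_ids[i] for i in keep],
        sample_ids=list(table.sample_ids),
        values=x,
        row_means=means[keep],
        row_sds=sds[keep],
    )
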