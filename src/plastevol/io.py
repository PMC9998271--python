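"""Core data containers and file I/O for the expression-plasticity pipeline.

The experiment this package models is a replicated ecotype contrast: two
geographic pairs of populations (a zinc-tolerant mine population T and its
nearest zinc-sensitive coastal population S), each grown clonally under a
control and a zinc treatment.  Counts are gene-level RNA-seq integers; the
design table records which population/treatment/genotype each sample is.

Counts are stored genes x samples.  All tabular I/O is plain TSV.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CountMatrix",
    "SampleDesign",
    "AnalysisConfig",
    "read_counts",
    "write_counts",
    "read_design",
    "filter_low_counts",
    "PlastevolError",
    "ValidationError",
    "ParseError",
]

#: population -> (pair, ecotype).  S = sensitive/coastal, T = tolerant/mine.
POPULATIONS: Mapping[str, tuple[str, str]] = {
    "S1": ("P1", "S"),
    "T1": ("P1", "T"),
    "S2": ("P2", "S"),
    "T2": ("P2", "T"),
}
TREATMENTS = ("C", "Z")  # control, zinc


class PlastevolError(Exception):
    """Base class for all package errors."""


class ValidationError(PlastevolError):
    """An input violates a structural invariant."""


class ParseError(PlastevolError):
    """A file could not be parsed into a valid container."""


class CountMatrix:
    """Gene x sample matrix of non-negative integer RNA-seq counts.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by gene id, columns by sample id, integer values.

    Invariants (checked on construction): unique gene and sample ids,
    no negative entries, integral values.
    """

    def __init__(self, data: pd.DataFrame):
        if data.shape[0] == 0:
            raise ValidationError("no genes found")
        if data.index.duplicated().any():
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if data.columns.duplicated().any():
            dupes = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
        arr = data.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ParseError("counts must be numeric integers")
        if np.any(arr < 0):
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count for gene {data.index[g]!r}, sample {data.columns[s]!r}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            if np.any(arr != np.floor(arr)) or np.any(~np.isfinite(arr)):
                g, s = np.argwhere((arr != np.floor(arr)) | ~np.isfinite(arr))[0]
                raise ParseError(
                    f"non-integer count for gene {data.index[g]!r}, "
                    f"sample {data.columns[s]!r}"
                )
            data = data.astype(np.int64)
        self.data = data

    # -- accessors ---------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, s = self.data.shape
        return f"<CountMatrix {g} genes x {s} samples>"

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        path = Path(path)
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except pd.errors.EmptyDataError:
            raise ParseError(f"{path}: no genes found") from None
        if df.shape[0] == 0:
            raise ParseError(f"{path}: no genes found")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        for col in df.columns:
            if df[col].dtype == object:
                bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
                raise ParseError(
                    f"{path}: non-integer count for gene {bad[0]!r}, sample {col!r}"
                )
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    # -- operations --------------------------------------------------------
    def filter_low_counts(self, min_total: int = 10) -> "CountMatrix":
        """Drop genes whose total count across all samples is below ``min_total``.

        ``min_total=0`` is the identity.  Gene order is preserved; the
        operation is idempotent.  An all-filtered matrix is returned as an
        (invalid-downstream but representable) empty frame.
        """
        if min_total < 0:
            raise ValidationError("min_total must be >= 0")
        keep = self.data.sum(axis=1) >= min_total
        obj = object.__new__(CountMatrix)  # bypass the no-genes check: empty is legal here
        obj.data = self.data.loc[keep]
        return obj


class SampleDesign:
    """Validated per-sample factor table.

    Columns: sample, population, treatment, individual, plus derived pair and
    ecotype (and an optional, unused tank column).  Clones of each genotype
    ("individual") must appear under both treatments of exactly one
    population, and every population x treatment cell needs >= 2 samples so
    dispersions are estimable.
    """

    REQUIRED = ("sample", "population", "treatment", "individual")

    def __init__(self, table: pd.DataFrame):
        df = table.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"design table missing columns: {missing}")
        for c in self.REQUIRED:
            df[c] = df[c].astype(str)
        if df["sample"].duplicated().any():
            raise ValidationError("duplicate sample ids in design")
        unknown = sorted(set(df["population"]) - set(POPULATIONS))
        if unknown:
            raise ValidationError(
                f"unknown population label(s) {unknown}; expected {sorted(POPULATIONS)}"
            )
        bad_trt = sorted(set(df["treatment"]) - set(TREATMENTS))
        if bad_trt:
            raise ValidationError(
                f"unknown treatment label(s) {bad_trt}; expected {TREATMENTS}"
            )
        df["pair"] = df["population"].map(lambda p: POPULATIONS[p][0])
        df["ecotype"] = df["population"].map(lambda p: POPULATIONS[p][1])
        if "tank" not in df.columns:
            df["tank"] = ""

        # each individual: both treatments, one population
        for ind, sub in df.groupby("individual"):
            if sub["population"].nunique() != 1:
                raise ValidationError(
                    f"individual {ind!r} appears in more than one population"
                )
            if set(sub["treatment"]) != set(TREATMENTS):
                raise ValidationError(
                    f"individual {ind!r} present in only one treatment; clones must "
                    "be paired across control and zinc"
                )
        cell = df.groupby(["population", "treatment"]).size()
        thin = cell[cell < 2]
        if len(thin):
            raise ValidationError(
                f"population x treatment cells with <2 samples: {list(thin.index)}"
            )
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample"])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleDesign":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def samples_for(
        self,
        population: str | Iterable[str] | None = None,
        ecotype: str | None = None,
        treatment: str | None = None,
        pair: str | None = None,
    ) -> list[str]:
        """Sample ids matching the given factor levels (AND-combined)."""
        df = self.table
        m = pd.Series(True, index=df.index)
        if population is not None:
            pops = [population] if isinstance(population, str) else list(population)
            m &= df["population"].isin(pops)
        if ecotype is not None:
            m &= df["ecotype"] == ecotype
        if treatment is not None:
            m &= df["treatment"] == treatment
        if pair is not None:
            m &= df["pair"] == pair
        return list(df.loc[m, "sample"])

    def restrict(self, samples: Iterable[str]) -> "SampleDesign":
        keep = set(samples)
        return SampleDesign(self.table[self.table["sample"].isin(keep)])


@dataclass
class AnalysisConfig:
    """Thresholds and knobs shared across the pipeline.

    fdr_threshold
        BH-adjusted p-value cut for every differential-expression call.
    overshoot_ratio
        The |EC|/|PC| boundary between overshooting and reversion when EC
        counteracts PC (default 0.5).
    bootstrap_reps
        Parametric-bootstrap replicates per gene.
    bootstrap_support_threshold
        Minimum fraction of replicates agreeing with the point classification
        for a call to "pass" the bootstrap.
    low_count_min
        Genes with total count below this across all samples are removed.
    dispersion_shrink_weight
        Weight (0..1) pulling per-gene log dispersion toward the fitted
        mean-dispersion trend.
    boundary_tie
        Category assigned when |EC| equals exactly overshoot_ratio * |PC|.
    shared_lp_bootstrap
        If True, use the naive bootstrap that reuses one sensitive-zinc draw
        in both PC and EC (biased; kept for comparison).
    """

    fdr_threshold: float = 0.05
    overshoot_ratio: float = 0.5
    bootstrap_reps: int = 100
    bootstrap_support_threshold: float = 0.95
    low_count_min: int = 10
    rng_seed: int = 0
    dispersion_shrink_weight: float = 0.5
    boundary_tie: str = "reversion"
    shared_lp_bootstrap: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise ValidationError("fdr_threshold must be in (0, 1)")
        if not 0 < self.bootstrap_support_threshold <= 1:
            raise ValidationError("bootstrap_support_threshold must be in (0, 1]")
        if self.overshoot_ratio <= 0:
            raise ValidationError("overshoot_ratio must be positive")
        if self.bootstrap_reps < 1:
            raise ValidationError("bootstrap_reps must be a positive integer")
        if self.low_count_min < 0:
            raise ValidationError("low_count_min must be >= 0")
        if not 0 <= self.dispersion_shrink_weight <= 1:
            raise ValidationError("dispersion_shrink_weight must be in [0, 1]")
        if self.boundary_tie not in ("reversion", "overshooting", "unclassified"):
            raise ValidationError(
                "boundary_tie must be reversion, overshooting or unclassified"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# module-level convenience functions (thin wrappers over the classes)
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> CountMatrix:
    """Read a genes-in-rows TSV count table (first column = gene ids)."""
    return CountMatrix.from_tsv(path)


def write_counts(m: CountMatrix, path: str | Path) -> None:
    m.to_tsv(path)


def read_design(path: str | Path) -> SampleDesign:
    """Read and validate a sample design TSV (sample/population/treatment/individual)."""
    return SampleDesign.from_tsv(path)


def filter_low_counts(m: CountMatrix, min_total: int = 10) -> CountMatrix:
    return m.filter_low_counts(min_total)
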