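"""Count-table and metadata handling.

Reads taxa-by-sample count tables and per-sample metadata from delimited
text, validates them, applies prevalence filtering, and performs the
left-censoring transform: a zero read count is not imputed but recorded as
an observation censored below the detection limit ``d`` (1 for integer
sequencing counts).  Every downstream model consumes the resulting
:class:`CensoredCountTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "CountTable",
    "SampleMetadata",
    "CovariateDesign",
    "CensoredCountTable",
    "read_count_table",
    "read_metadata",
    "align_metadata",
    "filter_by_prevalence",
    "censor",
]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)


@dataclass
class CountTable:
    """A taxa-by-sample matrix of non-negative integer read counts."""

    counts: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.sample_ids, "sample")
        arr = self.counts
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        bad = ~np.isfinite(arr.astype(float)) | (arr < 0) | (arr != np.floor(arr))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid count {arr[i, j]!r} at taxon {self.taxon_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r} (must be a non-negative integer)"
            )
        self.counts = arr.astype(np.int64)
        empty = np.flatnonzero(self.counts.sum(axis=0) == 0)
        if empty.size:
            names = [self.sample_ids[j] for j in empty]
            raise ValidationError(f"samples with zero library size: {names}")

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def prevalence(self) -> np.ndarray:
        """Fraction of samples in which each taxon has a nonzero count."""
        return (self.counts > 0).mean(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index_label="taxon_id")


@dataclass
class SampleMetadata:
    """Per-sample covariate table keyed by sample identifier."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.table, pd.DataFrame):
            self.table = pd.DataFrame(self.table)
        _check_unique([str(s) for s in self.table.index], "sample")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.table.index]


@dataclass
class CovariateDesign:
    """Design matrix with a leading intercept and a recorded tested column.

    ``tested_index`` points at the condition covariate whose coefficient the
    likelihood-ratio test targets.
    """

    matrix: np.ndarray
    columns: list[str]
    tested_index: int = 1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.columns):
            raise ValidationError("design matrix / column mismatch")
        if not (0 < self.tested_index < self.matrix.shape[1]):
            raise ValidationError("tested_index out of range")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]


@dataclass
class CensoredCountTable:
    """Counts with zeros replaced by censoring proxies.

    ``proxies`` holds y* (zeros replaced by the detection limit d),
    ``indicators`` holds delta (0 exactly where the raw count was zero) and
    ``raw_library_sizes`` the per-sample totals of the raw counts.  Raw
    counts are recoverable as ``proxies * indicators``.
    """

    proxies: np.ndarray
    indicators: np.ndarray
    detection_limit: float
    raw_library_sizes: np.ndarray
    taxon_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.proxies = np.asarray(self.proxies, dtype=float)
        self.indicators = np.asarray(self.indicators, dtype=np.int8)
        self.raw_library_sizes = np.asarray(self.raw_library_sizes, dtype=float)
        if self.detection_limit <= 0:
            raise ValidationError("detection limit must be positive")
        if (self.proxies <= 0).any():
            raise ValidationError("censoring proxies must be strictly positive")

    @property
    def n_taxa(self) -> int:
        return self.proxies.shape[0]

    @property
    def n_samples(self) -> int:
        return self.proxies.shape[1]

    @property
    def raw_counts(self) -> np.ndarray:
        return self.proxies * self.indicators


def _read_delimited(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    if delimiter is None:
        suffixes = {s.lower() for s in path.suffixes}
        if ".tsv" in suffixes or ".tab" in suffixes or ".txt" in suffixes:
            delimiter = "\t"
        elif ".csv" in suffixes:
            delimiter = ","
    if delimiter is None:
        return pd.read_csv(path, sep=None, engine="python", index_col=0)
    return pd.read_csv(path, sep=delimiter, index_col=0)


def read_count_table(
    path: str | Path,
    orientation: str = "taxa-rows",
    delimiter: str | None = None,
) -> CountTable:
    """Read a count table from delimited text (optionally gzipped).

    Parameters
    ----------
    orientation
        ``"taxa-rows"`` (rows are taxa, the canonical layout) or
        ``"samples-rows"`` (the transpose).  There is no silent
        auto-detection: transposed count tables are a classic silent bug.
    delimiter
        Field separator; inferred from the extension (``.tsv``/``.csv``) or
        sniffed when omitted.
    """
    if orientation not in ("taxa-rows", "samples-rows"):
        raise ValidationError(
            "orientation must be 'taxa-rows' or 'samples-rows', "
            f"got {orientation!r}"
        )
    df = _read_delimited(path, delimiter)
    if orientation == "samples-rows":
        df = df.T
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            if len(bad):
                raise ValidationError(
                    f"non-numeric entry {bad.iloc[0]!r} at row {bad.index[0]!r}, "
                    f"column {col!r} in {path}"
                )
    return CountTable(df.to_numpy(), list(df.index), list(df.columns))


def read_metadata(path: str | Path, delimiter: str | None = None) -> SampleMetadata:
    """Read a sample metadata table keyed by its first column."""
    return SampleMetadata(_read_delimited(path, delimiter))


def align_metadata(
    ct: CountTable,
    md: SampleMetadata | pd.DataFrame,
    condition_name: str,
    covariate_names: Sequence[str] = (),
) -> CovariateDesign:
    """Build the covariate design aligned to the count table's samples.

    The design has a leading intercept, the condition variable as its
    tested column (index 1) and optional numeric covariates appended.
    """
    table = md.table if isinstance(md, SampleMetadata) else md
    table = table.copy()
    table.index = table.index.map(str)
    missing = [s for s in ct.sample_ids if s not in table.index]
    if missing:
        raise ValidationError(f"samples absent from metadata: {missing}")
    used = [condition_name, *covariate_names]
    for name in used:
        if name not in table.columns:
            raise ValidationError(f"metadata column not found: {name!r}")
    sub = table.loc[ct.sample_ids, used]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValidationError(f"missing values in metadata columns {bad}; not imputed")
    values = sub.to_numpy(dtype=float)
    if np.ptp(values[:, 0]) == 0:
        raise ValidationError(f"condition {condition_name!r} is constant across samples")
    design = np.column_stack([np.ones(len(sub)), values])
    return CovariateDesign(design, ["intercept", *used], tested_index=1)


def filter_by_prevalence(ct: CountTable, min_prevalence: float) -> CountTable:
    """Drop taxa whose prevalence is strictly below ``min_prevalence``.

    Taxa exactly at the cutoff are kept (the filter removes strictly lower
    prevalence only).
    """
    if not 0 <= min_prevalence <= 1:
        raise ValidationError("min_prevalence must lie in [0, 1]")
    keep = ct.prevalence() >= min_prevalence
    if not keep.any():
        raise ValidationError("prevalence filter removed every taxon")
    idx = np.flatnonzero(keep)
    return CountTable(
        ct.counts[idx],
        [ct.taxon_ids[i] for i in idx],
        list(ct.sample_ids),
    )


def censor(ct: CountTable, d: float = 1.0) -> CensoredCountTable:
    """Apply the left-censoring transform at detection limit ``d``.

    Zero counts become proxies equal to ``d`` with censoring indicator 0;
    positive counts pass through with indicator 1.  Raw library sizes are
    recorded before proxying.
    """
    if d <= 0:
        raise ValidationError(f"detection limit must be positive, got {d}")
    counts = ct.counts.astype(float)
    indicators = (counts > 0).astype(np.int8)
    proxies = np.where(indicators == 1, counts, float(d))
    return CensoredCountTable(
        proxies=proxies,
        indicators=indicators,
        detection_limit=float(d),
        raw_library_sizes=ct.library_sizes.astype(float),
        taxon_ids=list(ct.taxon_ids),
        sample_ids=list(ct.sample_ids),
    )
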