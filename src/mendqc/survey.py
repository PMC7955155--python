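"""Cohort-level statistics over per-dataset read-type compositions.

Operates on survey tables with one row per RNA-seq dataset carrying the
pair counts (total, mapped, duplicate, MEND) from which the hierarchical
fractions are derived:

    unmapped fraction   = (total - mapped) / total
    duplicate fraction  = duplicates / mapped
    non-exonic fraction = 1 - MEND / (mapped - duplicates)
    MEND fraction       = MEND / total

All survey counts are in read pairs.  Unmapped counts are taken as
total - mapped, the aligner-log convention; the alignment-file pipeline
counts unmapped records directly, and both paths populate the same
record type.

The module also provides median/IQR summaries (quantile method
configurable), Spearman rank correlation between depth and duplicate
fraction, threshold censuses, and the MEND-based sequencing-depth
recommendation arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DatasetRecord",
    "SurveySummary",
    "CensusPredicate",
    "DEFAULT_CENSUS",
    "compute_fractions",
    "summarize",
    "spearman_rho",
    "census",
    "mend_recommendation",
    "read_survey_table",
    "records_to_frame",
]

FRACTION_COLUMNS = ("unmapped_frac", "dup_frac", "nonexonic_frac", "mend_frac")

#: numpy quantile methods exposed to the user
QUANTILE_METHODS = ("linear", "lower", "nearest")


@dataclass(frozen=True)
class DatasetRecord:
    """One survey row: pair counts and (optionally) derived fractions."""

    dataset_id: str
    cohort: str
    total_pairs: int
    mapped_pairs: int
    duplicate_pairs: int
    mend_pairs: int
    unmapped_frac: float | None = None
    dup_frac: float | None = None
    nonexonic_frac: float | None = None
    mend_frac: float | None = None

    def validate(self) -> None:
        if min(self.total_pairs, self.mapped_pairs, self.duplicate_pairs, self.mend_pairs) < 0:
            raise ValueError(f"{self.dataset_id}: negative count")
        if self.mapped_pairs > self.total_pairs:
            raise ValueError(f"{self.dataset_id}: mapped > total")
        if self.duplicate_pairs > self.mapped_pairs:
            raise ValueError(f"{self.dataset_id}: duplicates > mapped")
        if self.mend_pairs > self.mapped_pairs - self.duplicate_pairs:
            raise ValueError(f"{self.dataset_id}: MEND > mapped - duplicates")


def compute_fractions(rec: DatasetRecord) -> DatasetRecord:
    """Derive the four hierarchical fractions from a record's counts.

    Any 0/0 is defined as 0.  Count-invariant violations reject the row
    with a ValueError naming the dataset.
    """
    rec.validate()

    def frac(num: float, den: float) -> float:
        return num / den if den else 0.0

    nondup = rec.mapped_pairs - rec.duplicate_pairs
    return replace(
        rec,
        unmapped_frac=frac(rec.total_pairs - rec.mapped_pairs, rec.total_pairs),
        dup_frac=frac(rec.duplicate_pairs, rec.mapped_pairs),
        nonexonic_frac=1.0 - frac(rec.mend_pairs, nondup) if nondup else 0.0,
        mend_frac=frac(rec.mend_pairs, rec.total_pairs),
    )


@dataclass(frozen=True)
class CensusPredicate:
    """A strict threshold comparison on one survey column.

    ``op`` is ">" or "<"; an optional ``where`` predicate restricts the
    census to a sub-population (e.g. datasets above a depth threshold).
    """

    name: str
    column: str
    op: str
    threshold: float
    where: "CensusPredicate | None" = None

    def mask(self, frame: pd.DataFrame) -> pd.Series:
        col = frame[self.column]
        m = col > self.threshold if self.op == ">" else col < self.threshold
        if self.where is not None:
            m = m & self.where.mask(frame)
        return m


#: The survey census reported in the field: high-duplicate, high-non-exonic
#: and high-unmapped dataset counts, plus low-MEND datasets among those
#: meeting the 30M-mapped-pairs depth guideline.
_DEEP = CensusPredicate("mapped_gt_30M", "mapped_pairs", ">", 30e6)
DEFAULT_CENSUS: tuple[CensusPredicate, ...] = (
    CensusPredicate("dup_frac_gt_50pct", "dup_frac", ">", 0.5),
    CensusPredicate("nonexonic_frac_gt_50pct", "nonexonic_frac", ">", 0.5),
    CensusPredicate("unmapped_frac_gt_25pct", "unmapped_frac", ">", 0.25),
    _DEEP,
    CensusPredicate("deep_and_mend_lt_25pct", "mend_frac", "<", 0.25, where=_DEEP),
    CensusPredicate("deep_and_mend_lt_50pct", "mend_frac", "<", 0.5, where=_DEEP),
    CensusPredicate("deep_and_mend_lt_10pct", "mend_frac", "<", 0.10, where=_DEEP),
)


@dataclass
class SurveySummary:
    """Median/quartile summaries per fraction, cohort medians, censuses."""

    n_datasets: int
    stats: pd.DataFrame  # index: column; columns: min, q1, median, q3, max
    cohort_medians: pd.DataFrame  # index: cohort; columns: fractions
    census_counts: dict[str, int]

    def to_json_dict(self) -> dict:
        return {
            "n_datasets": self.n_datasets,
            "stats": {
                col: {k: float(v) for k, v in row.items()}
                for col, row in self.stats.iterrows()
            },
            "cohort_medians": {
                str(c): {k: float(v) for k, v in row.items()}
                for c, row in self.cohort_medians.iterrows()
            },
            "census": dict(self.census_counts),
        }


def records_to_frame(records: Iterable[DatasetRecord]) -> pd.DataFrame:
    """Records (fractions filled in if absent) as a DataFrame."""
    rows = []
    for rec in records:
        if rec.mend_frac is None:
            rec = compute_fractions(rec)
        rows.append(rec.__dict__)
    return pd.DataFrame(rows)


def summarize(
    records: Iterable[DatasetRecord] | pd.DataFrame,
    quantile_method: str = "linear",
    census_predicates: Sequence[CensusPredicate] = DEFAULT_CENSUS,
    extra_columns: Sequence[str] = ("total_pairs",),
) -> SurveySummary:
    """Median, quartiles and extrema per fraction column, plus censuses.

    ``quantile_method`` selects how quartiles interpolate between order
    statistics (numpy's linear / lower / nearest).
    """
    if quantile_method not in QUANTILE_METHODS:
        raise ValueError(f"quantile_method must be one of {QUANTILE_METHODS}")
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if frame.empty:
        raise ValueError("cannot summarize an empty survey table")
    cols = [c for c in (*FRACTION_COLUMNS, *extra_columns) if c in frame.columns]
    rows = {}
    for col in cols:
        v = frame[col].to_numpy(dtype=float)
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method=quantile_method)
        rows[col] = {"min": v.min(), "q1": q1, "median": med, "q3": q3, "max": v.max()}
    stats_frame = pd.DataFrame.from_dict(rows, orient="index")
    cohort_medians = frame.groupby("cohort")[list(FRACTION_COLUMNS)].median()
    counts = census(frame, census_predicates)
    return SurveySummary(
        n_datasets=len(frame),
        stats=stats_frame,
        cohort_medians=cohort_medians,
        census_counts=counts,
    )


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mean ranks for ties).

    Requires at least 3 paired values; zero rank variance in either
    variable makes the coefficient undefined and raises ValueError.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("spearman_rho needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman_rho undefined: zero rank variance")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def census(
    records: Iterable[DatasetRecord] | pd.DataFrame,
    predicates: Sequence[CensusPredicate],
) -> dict[str, int]:
    """Count records satisfying each (strict) threshold predicate."""
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    return {p.name: int(p.mask(frame).sum()) for p in predicates}


def mend_recommendation(
    mapped_target: float, typical_unmapped: float, mend_fraction_of_total: float
) -> float:
    """MEND-read depth equivalent to a mapped-read depth guideline.

    Converts a guideline stated in mapped reads into MEND reads: the total
    depth implied by the guideline (mapped target plus the typical unmapped
    count that accompanies it) times the typical MEND fraction of total.
    """
    if mapped_target <= 0 or typical_unmapped < 0:
        raise ValueError("mapped_target must be > 0 and typical_unmapped >= 0")
    if not 0 < mend_fraction_of_total <= 1:
        raise ValueError("mend_fraction_of_total must be in (0, 1]")
    return (mapped_target + typical_unmapped) * mend_fraction_of_total


# ---------------------------------------------------------------------------
# table I/O

DEFAULT_COLUMN_MAP = {
    "dataset_id": "dataset_id",
    "cohort": "cohort",
    "total_pairs": "total",
    "mapped_pairs": "mapped",
    "duplicate_pairs": "duplicates",
    "mend_pairs": "mend",
}


def read_survey_table(
    path: str,
    column_map: dict[str, str] | None = None,
    on_invalid: str = "skip",
    log: Callable[[str], None] | None = None,
) -> list[DatasetRecord]:
    """Load a TSV/CSV survey table into validated records with fractions.

    ``column_map`` maps our field names to the file's header names (extra
    metadata columns are ignored).  Invalid rows are skipped with a logged
    reason (``on_invalid='skip'``) or raise (``'raise'``).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    sep = "," if str(path).endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep)
    missing = [src for src in cmap.values() if src not in frame.columns]
    if missing:
        raise ValueError(
            f"survey table is missing columns {missing}; available: {list(frame.columns)}"
        )
    records: list[DatasetRecord] = []
    for _, row in frame.iterrows():
        rec = DatasetRecord(
            dataset_id=str(row[cmap["dataset_id"]]),
            cohort=str(row[cmap["cohort"]]),
            total_pairs=int(row[cmap["total_pairs"]]),
            mapped_pairs=int(row[cmap["mapped_pairs"]]),
            duplicate_pairs=int(row[cmap["duplicate_pairs"]]),
            mend_pairs=int(row[cmap["mend_pairs"]]),
        )
        try:
            records.append(compute_fractions(rec))
        except ValueError as exc:
            if on_invalid == "raise":
                raise
            if log is not None:
                log(f"skipping row: {exc}")
    return records
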