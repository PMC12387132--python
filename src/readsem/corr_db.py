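"""Long-format correlation database: types, validation, filtering, bucketing.

The unit of analysis is one observed subtest-pair Pearson correlation tied
to the correlation matrix (sample) it came from.  This module loads the
three CSV tables (records, subtest classifications, matrix metadata),
validates them against the type invariants, applies the inclusion filters
(no clinical samples, no same-subtest cross-version correlations, subgroup
matrices preferred over a battery's full-sample matrix), and maps each
surviving record to its unordered construct-pair bucket, dropping records
that involve a poor indicator of a broad ability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from readsem.consensus import CONSTRUCTS

VALID_BROAD_CODES = frozenset(CONSTRUCTS)
VALID_QUALITY = frozenset({"good", "poor"})
VALID_SAMPLE_KINDS = frozenset({"normative", "concurrent_validity", "clinical"})


class DatabaseError(ValueError):
    """Validation failure in the correlation database."""


@dataclass(frozen=True)
class SubtestClassification:
    """CHC classification of one subtest within a battery."""

    subtest_id: str
    battery: str
    broad_code: str
    narrow_code: str
    indicator_quality: str

    def __post_init__(self) -> None:
        if self.broad_code not in VALID_BROAD_CODES:
            raise DatabaseError(
                f"subtest {self.subtest_id!r}: unknown broad code {self.broad_code!r}"
            )
        if self.indicator_quality not in VALID_QUALITY:
            raise DatabaseError(
                f"subtest {self.subtest_id!r}: indicator quality must be "
                f"'good' or 'poor', got {self.indicator_quality!r}"
            )


@dataclass(frozen=True)
class MatrixMeta:
    """Metadata for one correlation matrix (one sample)."""

    matrix_id: str
    battery: str
    sample_kind: str
    group_label: str
    default_N: int
    supersedes_matrix_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.sample_kind not in VALID_SAMPLE_KINDS:
            raise DatabaseError(
                f"matrix {self.matrix_id!r}: unknown sample kind {self.sample_kind!r}"
            )
        if self.default_N < 4:
            raise DatabaseError(
                f"matrix {self.matrix_id!r}: default N must be >= 4 "
                f"(Fisher-z variance needs N-3 > 0), got {self.default_N}"
            )


@dataclass(frozen=True)
class CorrelationRecord:
    """One observed subtest-pair correlation.

    ``subtest_a``/``subtest_b`` are canonicalized to lexicographic order so
    that A-B and B-A form a single key.  ``bucket`` is filled by
    :func:`bucket_pairs` with the unordered construct-pair key.
    """

    matrix_id: str
    subtest_a: str
    subtest_b: str
    N: int
    r: float
    same_subtest_cross_version: bool = False
    bucket: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.subtest_a == self.subtest_b:
            raise DatabaseError(
                f"matrix {self.matrix_id!r}: self-correlation of {self.subtest_a!r}"
            )
        if not abs(self.r) < 1:
            raise DatabaseError(
                f"matrix {self.matrix_id!r}, pair ({self.subtest_a!r}, "
                f"{self.subtest_b!r}): |r| must be < 1, got {self.r}"
            )
        if self.N < 4:
            raise DatabaseError(
                f"matrix {self.matrix_id!r}, pair ({self.subtest_a!r}, "
                f"{self.subtest_b!r}): N must be >= 4, got {self.N}"
            )
        if self.subtest_a > self.subtest_b:  # canonicalize pair order
            a, b = self.subtest_b, self.subtest_a
            object.__setattr__(self, "subtest_a", a)
            object.__setattr__(self, "subtest_b", b)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.matrix_id, self.subtest_a, self.subtest_b)


@dataclass
class CorrelationDatabase:
    """Validated records plus their classification and matrix metadata."""

    records: list[CorrelationRecord]
    classifications: dict[str, SubtestClassification]
    matrices: dict[str, MatrixMeta]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ExclusionLog:
    """Counts of records removed, by reason."""

    counts: dict[str, int] = field(default_factory=dict)

    def add(self, reason: str) -> None:
        self.counts[reason] = self.counts.get(reason, 0) + 1

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _parse_supersedes(raw: object) -> tuple[str, ...]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return ()
    text = str(raw).strip()
    if not text:
        return ()
    return tuple(part.strip() for part in text.split(";") if part.strip())


def load_classifications(path: str | Path) -> dict[str, SubtestClassification]:
    df = pd.read_csv(path, dtype=str)
    out: dict[str, SubtestClassification] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        cls = SubtestClassification(
            subtest_id=row.subtest_id,
            battery=row.battery,
            broad_code=row.broad,
            narrow_code=row.narrow,
            indicator_quality=row.quality,
        )
        if cls.subtest_id in out:
            raise DatabaseError(
                f"{path}, row {row_no}: duplicate subtest id {cls.subtest_id!r}"
            )
        out[cls.subtest_id] = cls
    return out


def load_matrices(path: str | Path) -> dict[str, MatrixMeta]:
    df = pd.read_csv(path, dtype=str)
    out: dict[str, MatrixMeta] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        meta = MatrixMeta(
            matrix_id=row.matrix_id,
            battery=row.battery,
            sample_kind=row.sample_kind,
            group_label=row.group_label,
            default_N=int(row.default_n),
            supersedes_matrix_ids=_parse_supersedes(
                getattr(row, "supersedes_matrix_ids", None)
            ),
        )
        if meta.matrix_id in out:
            raise DatabaseError(
                f"{path}, row {row_no}: duplicate matrix id {meta.matrix_id!r}"
            )
        out[meta.matrix_id] = meta
    return out


def load_database(
    records_path: str | Path,
    classifications_path: str | Path,
    matrices_path: str | Path,
) -> CorrelationDatabase:
    """Load and validate the three CSV tables into a database object.

    Every record is checked against the type invariants, pair order is
    canonicalized, missing per-pair N falls back to the matrix default, and
    duplicate (matrix, pair) triples are rejected with their row number.
    """
    classifications = load_classifications(classifications_path)
    matrices = load_matrices(matrices_path)

    df = pd.read_csv(records_path)
    records: list[CorrelationRecord] = []
    seen: set[tuple[str, str, str]] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        matrix_id = str(row.matrix_id)
        if matrix_id not in matrices:
            raise DatabaseError(
                f"{records_path}, row {row_no}: unknown matrix id {matrix_id!r}"
            )
        for subtest in (row.subtest_a, row.subtest_b):
            if str(subtest) not in classifications:
                raise DatabaseError(
                    f"{records_path}, row {row_no}: unknown subtest id {subtest!r}"
                )
        n_raw = getattr(row, "n", None)
        N = matrices[matrix_id].default_N if pd.isna(n_raw) else int(n_raw)
        flag_raw = getattr(row, "same_subtest_cross_version", False)
        flag = (
            bool(flag_raw)
            if not isinstance(flag_raw, str)
            else flag_raw.strip().lower() in {"true", "1", "yes"}
        )
        try:
            rec = CorrelationRecord(
                matrix_id=matrix_id,
                subtest_a=str(row.subtest_a),
                subtest_b=str(row.subtest_b),
                N=N,
                r=float(row.r),
                same_subtest_cross_version=flag,
            )
        except DatabaseError as err:
            raise DatabaseError(f"{records_path}, row {row_no}: {err}") from None
        if rec.key in seen:
            raise DatabaseError(
                f"{records_path}, row {row_no}: duplicate correlation for "
                f"matrix {rec.matrix_id!r}, pair ({rec.subtest_a!r}, {rec.subtest_b!r})"
            )
        seen.add(rec.key)
        records.append(rec)
    return CorrelationDatabase(records, classifications, matrices)


def apply_inclusion_filters(
    db: CorrelationDatabase,
) -> tuple[list[CorrelationRecord], ExclusionLog]:
    """Apply the sample-level inclusion filters.

    Removes records from clinical samples, records flagged as the same
    subtest across test versions, and records from any full-sample matrix
    that is superseded by age/grade-subgroup matrices (metadata-driven via
    ``supersedes_matrix_ids``).  Returns surviving records and a log
    counting each exclusion reason; record counts are conserved.
    """
    superseded: set[str] = set()
    for meta in db.matrices.values():
        superseded.update(meta.supersedes_matrix_ids)

    kept: list[CorrelationRecord] = []
    log = ExclusionLog()
    for rec in db.records:
        kind = db.matrices[rec.matrix_id].sample_kind
        if kind == "clinical":
            log.add("clinical_sample")
        elif rec.same_subtest_cross_version:
            log.add("same_subtest_cross_version")
        elif rec.matrix_id in superseded:
            log.add("superseded_by_subgroups")
        else:
            kept.append(rec)
    return kept, log


def bucket_pairs(
    records: list[CorrelationRecord],
    classifications: dict[str, SubtestClassification],
) -> tuple[list[CorrelationRecord], ExclusionLog]:
    """Annotate records with their unordered construct-pair bucket.

    Records where either subtest is a poor indicator of its broad ability
    are dropped (reason ``poor_indicator``).  The bucket key is invariant
    to subtest order; within-construct pairs (e.g. Gc-Gc) are retained.
    """
    kept: list[CorrelationRecord] = []
    log = ExclusionLog()
    for rec in records:
        for subtest in (rec.subtest_a, rec.subtest_b):
            if subtest not in classifications:
                raise DatabaseError(f"unclassified subtest {subtest!r}")
        ca = classifications[rec.subtest_a]
        cb = classifications[rec.subtest_b]
        if ca.indicator_quality == "poor" or cb.indicator_quality == "poor":
            log.add("poor_indicator")
            continue
        bucket = tuple(sorted((ca.broad_code, cb.broad_code)))
        kept.append(replace(rec, bucket=bucket))
    return kept, log
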