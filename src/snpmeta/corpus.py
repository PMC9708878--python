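"""Study-level data model and table I/O for case-control genotype counts.

A *study* is one case-control comparison at one biallelic site: three genotype
counts per arm (common homozygote, heterozygote, variant homozygote) plus
etiology and provenance metadata.  A :class:`StudyCorpus` is an ordered,
uniquely-keyed collection of such studies — the unit every downstream analysis
(HWE filtering, contrast construction, pooling) consumes.

Tables are plain TSV/CSV with one study per row; three bundled fixtures
transcribe published genotype tables for the TGF-beta1 -509C/T, codon 10 and
codon 25 polymorphisms in chronic liver disease.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Sequence

from .errors import (
    DuplicateStudyError,
    FixtureLookupError,
    RowParseError,
    SchemaError,
)

log = logging.getLogger(__name__)

#: Etiology labels recognised for chronic liver disease subgrouping.
DISEASE_LABELS = ("HCC", "Cirrhosis", "CHB", "CHC", "AIH", "ALD", "PBC")

REQUIRED_COLUMNS = (
    "study_id",
    "polymorphism",
    "disease",
    "case_aa",
    "case_ab",
    "case_bb",
    "ctrl_aa",
    "ctrl_ab",
    "ctrl_bb",
    "allele_common",
    "allele_variant",
)

_COUNT_COLUMNS = ("case_aa", "case_ab", "case_bb", "ctrl_aa", "ctrl_ab", "ctrl_bb")

FIXTURES = {
    "tgfb1_509": "tgfb1_509.tsv",
    "tgfb1_codon10": "tgfb1_codon10.tsv",
    "tgfb1_codon25": "tgfb1_codon25.tsv",
}


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one arm: common hom, het, variant hom."""

    n_aa: int
    n_ab: int
    n_bb: int

    def __post_init__(self) -> None:
        for name in ("n_aa", "n_ab", "n_bb"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        """Number of individuals in the arm."""
        return self.n_aa + self.n_ab + self.n_bb

    @property
    def allele_common(self) -> int:
        """Count of common alleles (a): 2*hom + het."""
        return 2 * self.n_aa + self.n_ab

    @property
    def allele_variant(self) -> int:
        """Count of variant alleles (b): 2*hom + het."""
        return 2 * self.n_bb + self.n_ab

    @property
    def monomorphic(self) -> bool:
        """True when only one allele is observed in the arm."""
        return self.allele_common == 0 or self.allele_variant == 0


@dataclass(frozen=True)
class StudyRecord:
    """One case-control study arm-pair with metadata."""

    study_id: str
    polymorphism: str
    disease: str
    case: GenotypeCounts
    control: GenotypeCounts
    allele_labels: tuple[str, str] = ("A", "B")
    country: str = ""
    ethnicity: str = ""
    genotyping_method: str = ""
    sex: str = ""
    nos_score: int | None = None
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValueError("study_id must be non-empty")
        if not self.polymorphism:
            raise ValueError("polymorphism must be non-empty")
        if self.disease not in DISEASE_LABELS:
            raise ValueError(
                f"disease {self.disease!r} not one of {DISEASE_LABELS}"
            )


@dataclass(frozen=True)
class StudyCorpus:
    """Ordered collection of studies with unique ids."""

    records: tuple[StudyRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.study_id in seen:
                raise DuplicateStudyError(f"duplicate study_id {r.study_id!r}")
            seen.add(r.study_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.records)

    def __getitem__(self, study_id: str) -> StudyRecord:
        for r in self.records:
            if r.study_id == study_id:
                return r
        raise KeyError(study_id)

    def subset(self, study_ids: Sequence[str]) -> "StudyCorpus":
        wanted = set(study_ids)
        return replace(
            self, records=tuple(r for r in self.records if r.study_id in wanted)
        )

    def without(self, study_id: str) -> "StudyCorpus":
        return replace(
            self, records=tuple(r for r in self.records if r.study_id != study_id)
        )

    def partition(self, key: str = "disease") -> dict[str, "StudyCorpus"]:
        """Partition records by a metadata field, preserving input order."""
        groups: dict[str, list[StudyRecord]] = {}
        for r in self.records:
            groups.setdefault(getattr(r, key), []).append(r)
        return {
            label: replace(self, records=tuple(rs)) for label, rs in groups.items()
        }


@dataclass(frozen=True)
class CountTotals:
    """Corpus-level sample tallies."""

    k: int
    n_case_total: int
    n_control_total: int


def aggregate_counts(corpus: StudyCorpus) -> CountTotals:
    """Sum arm sizes over a corpus."""
    return CountTotals(
        k=len(corpus),
        n_case_total=sum(r.case.n for r in corpus),
        n_control_total=sum(r.control.n for r in corpus),
    )


def _parse_count(value: str, column: str, row_number: int) -> int:
    try:
        v = int(value)
    except (TypeError, ValueError):
        raise RowParseError(
            f"row {row_number}: column {column!r} is not an integer: {value!r}"
        ) from None
    if v < 0:
        raise RowParseError(f"row {row_number}: column {column!r} is negative: {v}")
    return v


def _record_from_row(row: Mapping[str, str], row_number: int) -> StudyRecord:
    counts = {c: _parse_count(row[c], c, row_number) for c in _COUNT_COLUMNS}
    nos_raw = (row.get("nos_score") or "").strip()
    extra = {
        k: v
        for k, v in row.items()
        if k not in REQUIRED_COLUMNS
        and k not in ("country", "ethnicity", "genotyping_method", "sex", "nos_score")
        and v not in (None, "")
    }
    try:
        return StudyRecord(
            study_id=row["study_id"].strip(),
            polymorphism=row["polymorphism"].strip(),
            disease=row["disease"].strip(),
            case=GenotypeCounts(counts["case_aa"], counts["case_ab"], counts["case_bb"]),
            control=GenotypeCounts(counts["ctrl_aa"], counts["ctrl_ab"], counts["ctrl_bb"]),
            allele_labels=(row["allele_common"].strip(), row["allele_variant"].strip()),
            country=(row.get("country") or "").strip(),
            ethnicity=(row.get("ethnicity") or "").strip(),
            genotyping_method=(row.get("genotyping_method") or "").strip(),
            sex=(row.get("sex") or "").strip(),
            nos_score=int(nos_raw) if nos_raw else None,
            extra=extra,
        )
    except ValueError as exc:
        raise RowParseError(f"row {row_number}: {exc}") from exc


def read_study_table(path: str | Path, dialect: str = "tsv") -> StudyCorpus:
    """Read a study table from TSV (default) or CSV.

    The header must name every required column; extra columns are carried
    through in ``StudyRecord.extra``.
    """
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    path = Path(path)
    delim = "\t" if dialect == "tsv" else ","
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise SchemaError(
                f"{path.name}: missing required column(s): {', '.join(missing)}"
            )
        records = [
            _record_from_row(row, i) for i, row in enumerate(reader, start=2)
        ]
    return StudyCorpus(records=tuple(records), provenance=str(path))


def write_corpus(corpus: StudyCorpus, path: str | Path, dialect: str = "tsv") -> None:
    """Write a corpus back to the standard table schema (lossless round-trip)."""
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    path = Path(path)
    delim = "\t" if dialect == "tsv" else ","
    meta_cols = ("country", "ethnicity", "genotyping_method", "sex", "nos_score")
    extra_cols = sorted({k for r in corpus for k in r.extra})
    header = list(REQUIRED_COLUMNS) + list(meta_cols) + extra_cols
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(header)
        for r in corpus:
            row = [
                r.study_id,
                r.polymorphism,
                r.disease,
                r.case.n_aa,
                r.case.n_ab,
                r.case.n_bb,
                r.control.n_aa,
                r.control.n_ab,
                r.control.n_bb,
                r.allele_labels[0],
                r.allele_labels[1],
                r.country,
                r.ethnicity,
                r.genotyping_method,
                r.sex,
                "" if r.nos_score is None else r.nos_score,
            ]
            row += [r.extra.get(c, "") for c in extra_cols]
            writer.writerow(row)


def load_fixture(polymorphism: str) -> StudyCorpus:
    """Load one of the bundled genotype tables.

    Valid names: ``tgfb1_509`` (25 study-disease rows), ``tgfb1_codon10``
    (18 rows), ``tgfb1_codon25`` (20 rows).
    """
    try:
        filename = FIXTURES[polymorphism]
    except KeyError:
        raise FixtureLookupError(
            f"unknown fixture {polymorphism!r}; valid names: "
            + ", ".join(sorted(FIXTURES))
        ) from None
    ref = resources.files("snpmeta.data").joinpath(filename)
    with resources.as_file(ref) as p:
        corpus = read_study_table(p, dialect="tsv")
    return replace(corpus, provenance=f"bundled fixture {polymorphism}")


def check_number_columns(corpus: StudyCorpus, numbers: Mapping[str, tuple[int, int]]) -> list[str]:
    """Compare genotype-row sums against externally stated arm sizes.

    Returns the list of study_ids whose sums disagree; each disagreement is
    logged at warning level (the genotype sums remain authoritative).
    """
    bad = []
    for r in corpus:
        if r.study_id not in numbers:
            continue
        n_case, n_ctrl = numbers[r.study_id]
        if (r.case.n, r.control.n) != (n_case, n_ctrl):
            log.warning(
                "study %s: stated arm sizes %d/%d disagree with genotype sums %d/%d; "
                "genotype sums win",
                r.study_id, n_case, n_ctrl, r.case.n, r.control.n,
            )
            bad.append(r.study_id)
    return bad
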