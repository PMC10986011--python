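"""Domain types and file IO for read-level methylation haplotype data.

Conventions
-----------
All genomic coordinates are 0-based half-open (BED convention). A CpG site is
located by the position of its C on the forward strand. Haplotype files follow
an mHap-style 6-column TSV dialect::

    chrom <TAB> start <TAB> end <TAB> pattern <TAB> count <TAB> strand

where ``pattern`` is a string over {0, 1} (0 = unmethylated, 1 = methylated),
one character per covered CpG in genomic order on the forward strand, and
``count`` is the read multiplicity. Files may be gzip-compressed (suffix
``.gz``). Reads from the reverse strand are assumed to have been projected to
forward-strand CpG coordinates by the upstream methylation extractor; the
strand column is carried through but ignored by all downstream measurements.
"""

from __future__ import annotations

import csv
import gzip
import io as _stdio
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

logger = logging.getLogger(__name__)

_PATTERN_RE = re.compile(r"^[01]+$")

LABELS = ("BTN", "MTN")
COHORTS = ("discovery", "validation", "test")


class FormatError(ValueError):
    """A malformed record in an input file; the message names the offending line."""


class CpGSite(NamedTuple):
    """A single CpG, identified by the forward-strand position of its C."""

    chrom: str
    pos: int


def chrom_sort_key(chrom: str) -> tuple:
    """Natural chromosome ordering: chr1 < chr2 < ... < chr10 < chrX."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    return (1, 0, name)


@dataclass(frozen=True, slots=True)
class HaplotypeRecord:
    """One read-level methylation haplotype.

    ``pattern`` holds one character per reference CpG falling in
    ``[start, end)``, in genomic order.
    """

    chrom: str
    start: int
    end: int
    pattern: str
    count: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(f"record {self.chrom}:{self.start}-{self.end}: end <= start")
        if not _PATTERN_RE.match(self.pattern):
            raise FormatError(
                f"record {self.chrom}:{self.start}-{self.end}: pattern {self.pattern!r} "
                "contains characters outside {0,1}"
            )
        if self.count < 1:
            raise FormatError(
                f"record {self.chrom}:{self.start}-{self.end}: count must be >= 1, got {self.count}"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(
                f"record {self.chrom}:{self.start}-{self.end}: bad strand {self.strand!r}"
            )

    @property
    def sort_key(self) -> tuple:
        return (chrom_sort_key(self.chrom), self.start, self.end, self.pattern, self.strand)


@dataclass(frozen=True, slots=True)
class Region:
    """A genomic interval, 0-based half-open, optionally named."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(f"region {self.chrom}:{self.start}-{self.end}: end <= start")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(slots=True)
class SampleMeta:
    """Clinical metadata for one enrolled patient sample.

    ``label`` is the pathology-confirmed class (BTN = benign thyroid nodule,
    MTN = malignant thyroid nodule) or ``None`` when unknown; ``tirads`` is
    the ACR TI-RADS ultrasonography category (1-5); ``size_mm`` is the nodule
    maximum diameter in millimetres.
    """

    sample_id: str
    label: str | None = None
    cohort: str = "discovery"
    age: float | None = None
    sex: str | None = None
    tirads: int | None = None
    size_mm: float | None = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"sample {self.sample_id}: label must be one of {LABELS}, got {self.label!r}")
        if self.cohort not in COHORTS:
            raise ValueError(f"sample {self.sample_id}: cohort must be one of {COHORTS}, got {self.cohort!r}")
        if self.sex is not None and self.sex not in ("F", "M"):
            raise ValueError(f"sample {self.sample_id}: sex must be F or M, got {self.sex!r}")
        if self.tirads is not None and not 1 <= int(self.tirads) <= 5:
            raise ValueError(f"sample {self.sample_id}: tirads must be in 1..5, got {self.tirads}")
        if self.size_mm is not None and not self.size_mm > 0:
            raise ValueError(f"sample {self.sample_id}: size_mm must be > 0, got {self.size_mm}")


@dataclass(slots=True)
class Cohort:
    """Samples plus their per-sample haplotype collections."""

    samples: list[SampleMeta]
    haplotypes: dict[str, list[HaplotypeRecord]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValueError(f"duplicate sample ids: {sorted(dup)}")
        unknown = set(self.haplotypes) - set(ids)
        if unknown:
            raise ValueError(f"haplotypes supplied for unknown samples: {sorted(unknown)}")
        for s in self.samples:
            if s.cohort == "discovery" and s.label is None:
                raise ValueError(f"discovery sample {s.sample_id} lacks a pathology label")

    def split(self, cohort: str) -> list[SampleMeta]:
        return [s for s in self.samples if s.cohort == cohort]

    def meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


# ---------------------------------------------------------------------------
# haplotype files
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _count_sites_in(reference_sites: Sequence[CpGSite], chrom: str, start: int, end: int) -> int:
    # reference_sites must be sorted by (chrom, pos); linear scan is fine at
    # fixture scale, callers with large references pre-index via bisect
    return sum(1 for s in reference_sites if s.chrom == chrom and start <= s.pos < end)


def read_haplotype_file(
    path: str | Path,
    reference_sites: Sequence[CpGSite] | None = None,
) -> list[HaplotypeRecord]:
    """Read an mHap-style TSV into a canonically sorted record list.

    Lines starting with ``#`` or ``track`` and blank lines are skipped.
    When ``reference_sites`` is given, each record's pattern length is checked
    against the number of reference CpGs in its interval.

    Raises
    ------
    FormatError
        On any malformed line, naming the line number.
    """
    records: list[HaplotypeRecord] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 tab-separated fields, got {len(fields)}")
            try:
                rec = HaplotypeRecord(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    pattern=fields[3],
                    count=int(fields[4]),
                    strand=fields[5],
                )
            except (FormatError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if reference_sites is not None:
                n_sites = _count_sites_in(reference_sites, rec.chrom, rec.start, rec.end)
                if n_sites != len(rec.pattern):
                    raise FormatError(
                        f"{path}:{lineno}: pattern length {len(rec.pattern)} does not match "
                        f"{n_sites} reference CpGs in {rec.chrom}:{rec.start}-{rec.end}"
                    )
            records.append(rec)
    records.sort(key=lambda r: r.sort_key)
    return records


def write_haplotype_file(records: Iterable[HaplotypeRecord], path: str | Path) -> None:
    """Write records as mHap-style TSV, sorted by (chrom, start)."""
    recs = sorted(records, key=lambda r: r.sort_key)
    with _open_text(path, "wt") as fh:
        for r in recs:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.pattern}\t{r.count}\t{r.strand}\n")


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

_SHEET_COLUMNS = ("sample_id", "label", "cohort", "age", "sex", "tirads", "size_mm")


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read a CSV/TSV sample sheet with header into typed :class:`SampleMeta`.

    Missing values are empty fields, never sentinel numbers. The delimiter is
    sniffed from the header line (tab wins over comma when both present).
    """
    path = Path(path)
    with _open_text(path) as fh:
        text = fh.read()
    if not text.strip():
        return []
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.DictReader(_stdio.StringIO(text), delimiter=delim)
    missing_cols = set(_SHEET_COLUMNS) - set(reader.fieldnames or ())
    if missing_cols:
        raise FormatError(f"{path}: sample sheet missing columns {sorted(missing_cols)}")

    def _opt(v: str | None) -> str | None:
        v = (v or "").strip()
        return v or None

    samples: list[SampleMeta] = []
    seen: set[str] = set()
    for lineno, row in enumerate(reader, start=2):
        sid = _opt(row["sample_id"])
        if sid is None:
            raise FormatError(f"{path}:{lineno}: empty sample_id")
        if sid in seen:
            raise FormatError(f"{path}:{lineno}: duplicate sample_id {sid!r}")
        seen.add(sid)
        age = _opt(row["age"])
        tirads = _opt(row["tirads"])
        size_mm = _opt(row["size_mm"])
        try:
            samples.append(
                SampleMeta(
                    sample_id=sid,
                    label=_opt(row["label"]),
                    cohort=_opt(row["cohort"]) or "discovery",
                    age=float(age) if age is not None else None,
                    sex=_opt(row["sex"]),
                    tirads=int(tirads) if tirads is not None else None,
                    size_mm=float(size_mm) if size_mm is not None else None,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return samples


def write_sample_sheet(samples: Iterable[SampleMeta], path: str | Path) -> None:
    """Write samples as a TSV sheet; missing values become empty fields."""
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(_SHEET_COLUMNS) + "\n")
        for s in samples:
            def _fmt(v) -> str:
                if v is None:
                    return ""
                if isinstance(v, float) and math.isnan(v):
                    return ""
                return str(v)

            fh.write(
                "\t".join(
                    _fmt(v)
                    for v in (s.sample_id, s.label, s.cohort, s.age, s.sex, s.tirads, s.size_mm)
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED regions and CpG site lists
# ---------------------------------------------------------------------------

def read_regions_bed(path: str | Path) -> list[Region]:
    """Read a BED3/BED4 file of regions (0-based half-open, no merging)."""
    regions: list[Region] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED fields")
            try:
                regions.append(
                    Region(
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        name=fields[3] if len(fields) > 3 else "",
                    )
                )
            except (FormatError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    regions.sort(key=lambda r: (chrom_sort_key(r.chrom), r.start, r.end))
    return regions


def write_regions_bed(regions: Iterable[Region], path: str | Path) -> None:
    regs = sorted(regions, key=lambda r: (chrom_sort_key(r.chrom), r.start, r.end))
    with _open_text(path, "wt") as fh:
        for r in regs:
            if r.name:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def read_sites_bed(path: str | Path) -> list[CpGSite]:
    """Read a reference CpG set from BED (one site per line, start = C position)."""
    sites = [CpGSite(r.chrom, r.start) for r in read_regions_bed(path)]
    sites.sort(key=lambda s: (chrom_sort_key(s.chrom), s.pos))
    if len(set(sites)) != len(sites):
        raise FormatError(f"{path}: duplicate CpG sites")
    return sites


def write_sites_bed(sites: Iterable[CpGSite], path: str | Path) -> None:
    ordered = sorted(set(sites), key=lambda s: (chrom_sort_key(s.chrom), s.pos))
    with _open_text(path, "wt") as fh:
        for s in ordered:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\n")
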