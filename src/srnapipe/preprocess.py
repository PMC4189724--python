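"""Raw-read cleaning, unique-tag collapsing and size distributions.

Every raw read is assigned to exactly one removal category or survives as a
clean 18-30 nt insert.  Categories are evaluated in a fixed order: quality,
3' adapter presence, empty insert, 5' adapter contamination, polyA, length.
A read must be adapter-trimmed before its insert length can be judged, which
fixes the relative order of the adapter and length rules.

"High quality" is not defined by upstream conventions, so the package
documents its own rule: a read is low quality when its mean Phred score is
below ``min_mean_quality`` or more than ``max_n_fraction`` of its bases are
N.  Both knobs are recorded in the cleaning report header.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

#: Removal-category keys in report order.
REPORT_CATEGORIES = (
    "adapter3_null",
    "insert_null",
    "adapter5_contaminants",
    "smaller_than_18nt",
    "polyA",
    "clean_reads",
)

MIN_TAG_LENGTH = 18
MAX_TAG_LENGTH = 30


def round2(value: float) -> float:
    """Round half up to two decimals (table-style percentages)."""
    return math.floor(value * 100 + 0.5) / 100.0


@dataclass
class CleaningReport:
    """Per-library read accounting in the shape of a removal-statistics table."""

    total_reads: int = 0
    high_quality: int = 0
    adapter3_null: int = 0
    insert_null: int = 0
    adapter5_contaminants: int = 0
    smaller_than_18nt: int = 0
    polyA: int = 0
    clean_reads: int = 0
    params: dict = field(default_factory=dict)

    def category_counts(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in REPORT_CATEGORIES}

    def percentages(self) -> dict[str, float]:
        """Each category as a percent of high-quality reads, two decimals."""
        if self.high_quality == 0:
            return {name: 0.0 for name in REPORT_CATEGORIES}
        return {
            name: round2(100.0 * count / self.high_quality)
            for name, count in self.category_counts().items()
        }

    def conserved(self) -> bool:
        """Removal categories plus clean reads partition the high-quality reads."""
        return self.high_quality == sum(self.category_counts().values())

    @classmethod
    def from_counts(
        cls,
        total_reads: int,
        high_quality: int,
        removals: Mapping[str, int],
        clean_reads: int | None = None,
    ) -> "CleaningReport":
        """Build a report from externally tabulated counts.

        When ``clean_reads`` is omitted it is derived from the conservation
        invariant: high-quality reads minus all removal categories.
        """
        removal_total = sum(removals.get(k, 0) for k in REPORT_CATEGORIES[:-1])
        if clean_reads is None:
            clean_reads = high_quality - removal_total
        return cls(
            total_reads=total_reads,
            high_quality=high_quality,
            clean_reads=clean_reads,
            **{k: removals.get(k, 0) for k in REPORT_CATEGORIES[:-1]},
        )

    def to_rows(self) -> list[tuple[str, int, str]]:
        pct = self.percentages()
        rows = [("total_reads", self.total_reads, ""), ("high_quality", self.high_quality, "100%")]
        rows += [
            (name, count, f"{pct[name]:.2f}%")
            for name, count in self.category_counts().items()
        ]
        return rows


@dataclass
class CleanTag:
    """A unique clean sRNA sequence with per-library counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not MIN_TAG_LENGTH <= n <= MAX_TAG_LENGTH:
            raise ValueError(f"tag length {n} outside [{MIN_TAG_LENGTH}, {MAX_TAG_LENGTH}]")
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"bad tag alphabet in {self.sequence!r}")
        if self.counts and not any(c > 0 for c in self.counts.values()):
            raise ValueError("tag observed in no library")

    def total(self) -> int:
        return sum(self.counts.values())


def _mean_phred(qual: str) -> float:
    return sum(ord(c) - 33 for c in qual) / len(qual)


def _is_polya(insert: str, min_run: int, min_fraction: float) -> bool:
    if "A" * min_run not in insert:
        return False
    return insert.count("A") / len(insert) >= min_fraction


def _find_adapter(seq: str, adapter_prefix: str, max_start: int) -> int:
    """Leftmost start of the adapter prefix, restricted to plausible inserts."""
    pos = seq.find(adapter_prefix)
    if pos == -1 or pos > max_start:
        return -1
    return pos


def clean_reads(
    reads: Iterable[tuple[str, str, str]],
    adapter3: str,
    adapter5: str,
    *,
    min_mean_quality: float = 20.0,
    max_n_fraction: float = 0.1,
    adapter_match_len: int = 6,
    polya_min_run: int = 6,
    polya_min_fraction: float = 0.7,
    min_length: int = MIN_TAG_LENGTH,
    max_length: int = MAX_TAG_LENGTH,
) -> tuple[Counter, CleaningReport]:
    """Clean one library of raw reads.

    Parameters
    ----------
    reads:
        Iterable of ``(name, sequence, phred33_quality)`` triples.
    adapter3, adapter5:
        Ligated adapter sequences; the first ``adapter_match_len`` bases of
        each are matched exactly.

    Returns
    -------
    (tag_counts, report):
        ``tag_counts`` maps each clean insert sequence to its read count;
        the report satisfies the conservation invariant.
    """
    if not adapter3 or not adapter5:
        raise ValueError("both 3' and 5' adapter sequences are required")
    if len(adapter3) < adapter_match_len or len(adapter5) < adapter_match_len:
        raise ValueError(f"adapters must provide >= {adapter_match_len} bases")
    a3 = adapter3[:adapter_match_len].upper()
    a5 = adapter5[:adapter_match_len].upper()
    report = CleaningReport(
        params={
            "min_mean_quality": min_mean_quality,
            "max_n_fraction": max_n_fraction,
            "adapter_match_len": adapter_match_len,
            "polya_min_run": polya_min_run,
            "polya_min_fraction": polya_min_fraction,
            "min_length": min_length,
            "max_length": max_length,
            "adapter3": adapter3,
            "adapter5": adapter5,
        }
    )
    tags: Counter = Counter()
    for _name, seq, qual in reads:
        seq = seq.upper()
        report.total_reads += 1
        if _mean_phred(qual) < min_mean_quality or seq.count("N") / len(seq) > max_n_fraction:
            continue  # low quality: excluded before the high-quality accounting
        report.high_quality += 1
        pos = _find_adapter(seq, a3, max_start=max_length)
        if pos == -1:
            report.adapter3_null += 1
            continue
        insert = seq[:pos]
        if not insert:
            report.insert_null += 1
            continue
        if insert.startswith(a5):
            report.adapter5_contaminants += 1
            continue
        if _is_polya(insert, polya_min_run, polya_min_fraction):
            report.polyA += 1
            continue
        if len(insert) < min_length:
            report.smaller_than_18nt += 1
            continue
        report.clean_reads += 1
        tags[insert] += 1
    return tags, report


def collapse_libraries(per_library: Mapping[str, Mapping[str, int]]) -> list[CleanTag]:
    """Merge per-library tag counters into a unified :class:`CleanTag` list."""
    libraries = list(per_library)
    sequences = sorted({seq for counts in per_library.values() for seq in counts})
    return [
        CleanTag(seq, {lib: int(per_library[lib].get(seq, 0)) for lib in libraries})
        for seq in sequences
    ]


def size_distribution(
    tags, unit: str = "total", library: str | None = None
) -> dict[int, float]:
    """Length -> fraction over 18-30 nt, on a unique-tag or count-weighted basis.

    ``tags`` is either a ``{sequence: count}`` mapping or a list of
    :class:`CleanTag`; with the latter, ``library`` restricts counting to one
    library.
    """
    if unit not in ("unique", "total"):
        raise ValueError(f"unit must be 'unique' or 'total', got {unit!r}")
    weights: dict[int, float] = {n: 0.0 for n in range(MIN_TAG_LENGTH, MAX_TAG_LENGTH + 1)}
    grand = 0.0
    items: Iterable[tuple[str, int]]
    if isinstance(tags, Mapping):
        items = tags.items()
    else:
        items = (
            (t.sequence, t.counts.get(library, 0) if library else t.total()) for t in tags
        )
    for seq, count in items:
        if count <= 0:
            continue
        w = 1 if unit == "unique" else count
        weights[len(seq)] += w
        grand += w
    if grand == 0:
        raise ValueError("empty tag set")
    return {n: w / grand for n, w in weights.items()}
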