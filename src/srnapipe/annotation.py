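"""Exact genome mapping and hierarchical classification of clean tags.

Tags are matched to the genome with zero mismatches on both strands.  Each
unique tag then receives exactly one category from the fixed priority

    miRNA > rRNA > tRNA > snRNA > snoRNA > repeat >
    exon_sense > exon_antisense > intron_sense > intron_antisense > unannotated

Known-miRNA assignment is sequence-level (exact identity with a mature
reference entry after U/T normalisation) and does not require a genome hit;
all interval-based categories require one.  Tags hitting several loci are
counted once per category, with every locus retained in the records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from srnapipe.preprocess import CleanTag, round2
from srnapipe.seqs import Feature, revcomp, to_dna

#: Composition categories in report (table) order.
CATEGORIES = (
    "exon_antisense",
    "exon_sense",
    "intron_antisense",
    "intron_sense",
    "miRNA",
    "rRNA",
    "repeat",
    "snRNA",
    "snoRNA",
    "tRNA",
    "unannotated",
)

#: Interval feature classes in classification priority order.
_INTERVAL_PRIORITY = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "exon", "intron")


@dataclass
class GenomeHit:
    """One perfect genomic occurrence of a tag (1-based inclusive)."""

    tag: str
    scaffold: str
    start: int
    end: int
    strand: str
    mismatches: int = 0


@dataclass
class AnnotationRecord:
    tag: str
    category: str
    reference_id: str | None = None
    hits: list = field(default_factory=list)


def map_tags(
    tags: Sequence[CleanTag], genome: Mapping[str, str]
) -> dict[str, list[GenomeHit]]:
    """All exact occurrences of each tag on both genome strands.

    Returns ``{tag sequence: [GenomeHit, ...]}``; tags without hits map to an
    empty list (flagged unmapped).
    """
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    hits: dict[str, list[GenomeHit]] = {}
    for tag in tags:
        seq = tag.sequence
        found: list[GenomeHit] = []
        rc = revcomp(seq)
        for name, scaffold in genome.items():
            for query, strand in ((seq, "+"), (rc, "-")):
                pos = scaffold.find(query)
                while pos != -1:
                    found.append(
                        GenomeHit(seq, name, pos + 1, pos + len(seq), strand)
                    )
                    pos = scaffold.find(query, pos + 1)
        found.sort(key=lambda h: (h.scaffold, h.start, h.strand))
        hits[seq] = found
    return hits


def identify_known_mirnas(
    tags: Sequence[CleanTag], mature_reference: Mapping[str, str]
) -> dict[str, dict[str, int]]:
    """Per-miRNA count table from exact mature-sequence matches.

    A tag is assigned to a known miRNA iff it equals the mature reference
    sequence exactly after U/T normalisation; counts are per-library sums
    over assigned tags.  ``mature_reference`` may also be an iterable of
    ``(id, sequence)`` pairs, in which case duplicate ids are rejected.
    """
    items = (
        list(mature_reference.items())
        if isinstance(mature_reference, Mapping)
        else list(mature_reference)
    )
    ids = [ref_id for ref_id, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate reference ids")
    by_seq: dict[str, list[str]] = {}
    for ref_id, ref_seq in items:
        by_seq.setdefault(to_dna(ref_seq), []).append(ref_id)
    table: dict[str, dict[str, int]] = {}
    for tag in tags:
        for ref_id in by_seq.get(tag.sequence, ()):
            row = table.setdefault(ref_id, {})
            for lib, count in tag.counts.items():
                row[lib] = row.get(lib, 0) + count
    return table


def _interval_category(
    hits: Iterable[GenomeHit], features_by_scaffold: Mapping[str, list[Feature]]
) -> tuple[str, str] | None:
    """Best interval-based category over all hits, with its reference id."""
    best: tuple[int, int, str, str] | None = None  # (class rank, sense rank, ref, cat)
    for hit in hits:
        for feat in features_by_scaffold.get(hit.scaffold, ()):
            if not feat.overlaps(hit.scaffold, hit.start, hit.end):
                continue
            rank = _INTERVAL_PRIORITY.index(feat.cls)
            if feat.cls in ("exon", "intron"):
                sense = 0 if hit.strand == feat.strand else 1
                category = f"{feat.cls}_{'sense' if sense == 0 else 'antisense'}"
            else:
                sense = 0
                category = feat.cls
            key = (rank, sense, feat.name, category)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    return best[3], best[2]


@dataclass
class CompositionReport:
    """Per-library unique/total composition over the annotation categories."""

    libraries: list[str]
    unique: dict[str, dict[str, int]]  # category -> library -> unique tags
    total: dict[str, dict[str, int]]  # category -> library -> reads
    mapped_unique: dict[str, int] = field(default_factory=dict)
    mapped_total: dict[str, int] = field(default_factory=dict)

    def library_totals(self, kind: str = "total") -> dict[str, int]:
        table = self.total if kind == "total" else self.unique
        return {
            lib: sum(table[cat][lib] for cat in CATEGORIES) for lib in self.libraries
        }

    def percentages(self, kind: str = "total") -> dict[str, dict[str, float]]:
        """Category percentages of each library's grand total, two decimals."""
        table = self.total if kind == "total" else self.unique
        totals = self.library_totals(kind)
        return {
            cat: {
                lib: round2(100.0 * table[cat][lib] / totals[lib]) if totals[lib] else 0.0
                for lib in self.libraries
            }
            for cat in CATEGORIES
        }

    def to_rows(self) -> list[list]:
        pct_u = self.percentages("unique")
        pct_t = self.percentages("total")
        totals_u = self.library_totals("unique")
        totals_t = self.library_totals("total")
        rows: list[list] = [["Total"]]
        for lib in self.libraries:
            rows[0] += [totals_u[lib], "100%", totals_t[lib], "100%"]
        if self.mapped_unique:
            # genome-matching subset alongside the all-clean totals
            row: list = ["Mapped"]
            for lib in self.libraries:
                row += [self.mapped_unique[lib], "", self.mapped_total[lib], ""]
            rows.append(row)
        for cat in CATEGORIES:
            row: list = [cat]
            for lib in self.libraries:
                row += [
                    self.unique[cat][lib],
                    f"{pct_u[cat][lib]:.2f}%",
                    self.total[cat][lib],
                    f"{pct_t[cat][lib]:.2f}%",
                ]
            rows.append(row)
        return rows


def classify(
    tags: Sequence[CleanTag],
    hits: Mapping[str, list[GenomeHit]],
    mature_reference: Mapping[str, str],
    features: Iterable[Feature],
) -> tuple[list[AnnotationRecord], CompositionReport]:
    """Assign one category per tag and tabulate the composition.

    ``features`` supplies the interval annotation (ncRNA loci, repeats,
    exons, introns); miRNA-class features are ignored here because known
    miRNAs are matched at sequence level and novel-precursor loci are, by
    definition, unannotated at this stage.
    """
    mature_seqs = {to_dna(s) for s in mature_reference.values()}
    mature_ids = {to_dna(s): i for i, s in sorted(mature_reference.items(), reverse=True)}
    features_by_scaffold: dict[str, list[Feature]] = {}
    for feat in features:
        if feat.cls in _INTERVAL_PRIORITY:
            features_by_scaffold.setdefault(feat.scaffold, []).append(feat)

    libraries = sorted({lib for tag in tags for lib in tag.counts})
    unique = {cat: {lib: 0 for lib in libraries} for cat in CATEGORIES}
    total = {cat: {lib: 0 for lib in libraries} for cat in CATEGORIES}
    mapped_unique = {lib: 0 for lib in libraries}
    mapped_total = {lib: 0 for lib in libraries}
    records = []
    for tag in tags:
        tag_hits = hits.get(tag.sequence, [])
        ref_id: str | None = None
        if tag.sequence in mature_seqs:
            category = "miRNA"
            ref_id = mature_ids[tag.sequence]
        else:
            assignment = _interval_category(tag_hits, features_by_scaffold) if tag_hits else None
            if assignment is None:
                category = "unannotated"
            else:
                category, ref_id = assignment
        records.append(AnnotationRecord(tag.sequence, category, ref_id, list(tag_hits)))
        for lib, count in tag.counts.items():
            if count > 0:
                unique[category][lib] += 1
                total[category][lib] += count
                if tag_hits:
                    mapped_unique[lib] += 1
                    mapped_total[lib] += count
    report = CompositionReport(
        libraries=libraries,
        unique=unique,
        total=total,
        mapped_unique=mapped_unique,
        mapped_total=mapped_total,
    )
    return records, report
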