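"""Nucleotide-sequence primitives shared across pipeline stages.

All genomic coordinates in the package are 1-based and inclusive, written
``scaffold:start:end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")

DNA_ALPHABET = frozenset("ACGT")
RNA_ALPHABET = frozenset("ACGU")

#: Annotation feature classes understood by the pipeline.
FEATURE_CLASSES = (
    "known_mirna",
    "novel_mirna_precursor",
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "repeat",
    "exon",
    "intron",
)


def revcomp(seq: str) -> str:
    """Reverse complement (DNA output; U treated as T)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_dna(seq: str) -> str:
    """Uppercase and normalise U -> T."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Uppercase and normalise T -> U."""
    return seq.upper().replace("T", "U")


def validate_nucleotides(seq: str, *, allow_n: bool = False) -> str:
    """Return the DNA-normalised sequence, raising on foreign characters."""
    norm = to_dna(seq)
    allowed = DNA_ALPHABET | ({"N"} if allow_n else set())
    bad = set(norm) - allowed
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)!r}")
    return norm


@dataclass
class Feature:
    """One planted or annotated genomic feature (1-based inclusive coords)."""

    name: str
    scaffold: str
    start: int
    end: int
    strand: str
    cls: str
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad coordinates for {self.name}: {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.cls not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.cls!r}")

    @property
    def locus(self) -> str:
        return f"{self.scaffold}:{self.start}:{self.end}"

    def sequence(self, scaffolds: dict) -> str:
        """Feature sequence on its own strand."""
        sub = scaffolds[self.scaffold][self.start - 1 : self.end]
        return sub if self.strand == "+" else revcomp(sub)

    def overlaps(self, scaffold: str, start: int, end: int) -> bool:
        return scaffold == self.scaffold and start <= self.end and self.start <= end


def overlap_length(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Length of the intersection of two 1-based inclusive intervals (0 if disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)
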