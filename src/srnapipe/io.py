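"""Plain-text format plumbing: FASTA, FASTQ, GFF3 and TSV reports.

Parsing of FASTA/FASTQ is delegated to Biopython; writers emit deterministic
byte-stable text so that pipeline reruns under a fixed seed are comparable
with ``diff``.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from srnapipe.seqs import Feature


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> ordered {id: uppercase sequence}."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path, records: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality string) per read."""
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        qual = "".join(chr(q + 33) for q in quals)
        yield rec.id, str(rec.seq).upper(), qual


def write_fastq(path, reads: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def write_collapsed_fasta(path, tag_counts: dict[str, int], prefix: str = "tag") -> None:
    """Collapsed unique-tag FASTA with ``>tag_N_count`` headers."""
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(
            sorted(tag_counts.items(), key=lambda kv: (-kv[1], kv[0])), start=1
        ):
            fh.write(f">{prefix}_{i}_x{count}\n{seq}\n")


def read_collapsed_fasta(path) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        count = int(rec.id.rsplit("_x", 1)[1]) if "_x" in rec.id else 1
        seq = str(rec.seq).upper()
        counts[seq] = counts.get(seq, 0) + count
    return counts


def write_gff3(path, features: Iterable[Feature], source: str = "srnapipe") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            attrs = ";".join(
                [f"ID={feat.name}"] + [f"{k}={v}" for k, v in sorted(feat.attrs.items())]
            )
            fh.write(
                "\t".join(
                    [
                        feat.scaffold,
                        source,
                        feat.cls,
                        str(feat.start),
                        str(feat.end),
                        ".",
                        feat.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> list[Feature]:
    features = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = {}
            for item in cols[8].split(";"):
                if "=" in item:
                    key, value = item.split("=", 1)
                    attrs[key] = value
            features.append(
                Feature(
                    name=attrs.pop("ID", f"{cols[0]}:{cols[3]}-{cols[4]}"),
                    scaffold=cols[0],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6] if cols[6] in "+-" else "+",
                    cls=cols[2],
                    attrs=attrs,
                )
            )
    return features


def write_tsv(path, header: list[str], rows: Iterable[Iterable]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for row in rows:
            writer.writerow(list(row))


def read_tsv(path) -> tuple[list[str], list[list[str]]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = list(reader)
    if not rows:
        raise ValueError(f"empty TSV: {path}")
    return rows[0], rows[1:]


def ensure_dir(path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    return path
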