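"""Toy genome and three-library sRNA read simulator with recorded ground truth.

The generator plants known-miRNA loci, novel hairpin precursors, ncRNA
features, repeats and exon/intron intervals on random scaffolds, then samples
reads multinomially from planted tags plus artifact classes (low-quality,
missing 3' adapter, empty insert, 5'-adapter contamination, short inserts,
polyA).  Every planted tag, its class, its per-library expected fraction and
every artifact fraction are recorded in a manifest so each downstream stage
can be checked against exact truth.

All coordinates are 1-based inclusive.  Reads are 36 nt, Phred+33, with a
two-level quality model (high/low); adapters are fixed, recorded defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from srnapipe import io
from srnapipe.fold import dotbracket_to_pairs, fold_hairpin, pairs_to_partner
from srnapipe.seqs import Feature, revcomp

READ_LENGTH = 36
HIGH_QUALITY_CHAR = "I"  # Phred 40
LOW_QUALITY_CHAR = "#"  # Phred 2

DEFAULT_ADAPTER3 = "TCGTATGCCGTCTTCTGCTTG"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"

ARTIFACT_CATEGORIES = (
    "low_quality",
    "adapter3_null",
    "insert_null",
    "adapter5_contaminant",
    "short_insert",
    "polyA",
)


class CapacityError(ValueError):
    """Feature demand exceeds what the configured scaffolds can hold."""


@dataclass
class SynthConfig:
    """Generator settings; every field is a free parameter of the simulation."""

    n_scaffolds: int = 4
    scaffold_length: int = 60_000
    n_known_mirnas: int = 12
    n_novel_precursors: int = 6
    n_rrna: int = 4
    n_trna: int = 4
    n_snrna: int = 2
    n_snorna: int = 2
    n_repeats: int = 3
    n_exons: int = 4
    n_introns: int = 4
    n_noise_tags: int = 25
    n_transcripts: int = 4
    transcript_length: int = 800
    libraries: tuple = ("SD8", "C5", "LD3")
    control: str = "SD8"
    depths: dict = field(default_factory=dict)
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    #: log2 fold changes (treatment vs control) planted on the first known miRNAs
    planted_log2fc: tuple = (1.0, -1.0, 2.0, -2.0)
    #: read-mass fraction given to a planted changed miRNA in the control library
    changed_mirna_fraction: float = 0.008
    artifact_fractions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.depths:
            self.depths = {lib: 100_000 for lib in self.libraries}
        if not self.artifact_fractions:
            self.artifact_fractions = {
                "low_quality": 0.004,
                "adapter3_null": 0.0006,
                "insert_null": 0.0002,
                "adapter5_contaminant": 0.0018,
                "short_insert": 0.012,
                "polyA": 0.0002,
            }
        if self.control not in self.libraries:
            raise ValueError(f"control {self.control!r} not among libraries")
        unknown = set(self.artifact_fractions) - set(ARTIFACT_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown artifact categories: {sorted(unknown)}")
        if sum(self.artifact_fractions.values()) > 1:
            raise ValueError("artifact fractions sum beyond 1")
        if len(self.planted_log2fc) > self.n_known_mirnas:
            raise ValueError("more planted fold changes than known miRNAs")


@dataclass
class ToyGenome:
    scaffolds: dict[str, str]
    features: list[Feature]

    def feature_sequence(self, feature: Feature) -> str:
        return feature.sequence(self.scaffolds)

    def mature_reference(self) -> dict[str, str]:
        """miRBase-style mature reference derived from planted known miRNAs."""
        return {
            f.name: f.attrs["mature"]
            for f in self.features
            if f.cls == "known_mirna"
        }

    def ncrna_reference(self) -> dict[str, dict[str, str]]:
        out: dict[str, dict[str, str]] = {}
        for f in self.features:
            if f.cls in ("rRNA", "tRNA", "snRNA", "snoRNA"):
                out.setdefault(f.cls, {})[f.name] = self.feature_sequence(f)
        return out

    def occurrences(self, seq: str) -> int:
        """Occurrences of ``seq`` in the genome counting both strands."""
        total = 0
        rc = revcomp(seq)
        for scaffold in self.scaffolds.values():
            for query in (seq, rc) if rc != seq else (seq,):
                pos = scaffold.find(query)
                while pos != -1:
                    total += 1
                    pos = scaffold.find(query, pos + 1)
        return total

    def validate(self) -> None:
        for f in self.features:
            if f.scaffold not in self.scaffolds:
                raise ValueError(f"{f.name}: unknown scaffold {f.scaffold}")
            if f.end > len(self.scaffolds[f.scaffold]):
                raise ValueError(f"{f.name}: feature beyond scaffold end")


@dataclass
class TagTruth:
    name: str
    sequence: str
    cls: str
    feature: str
    fractions: dict[str, float]


@dataclass
class GroundTruthManifest:
    libraries: list[str]
    control: str
    depths: dict[str, int]
    adapter3: str
    adapter5: str
    artifact_fractions: dict[str, float]
    tags: list[TagTruth]
    fold_changes: dict[str, dict[str, float]] = field(default_factory=dict)
    target_truth: list = field(default_factory=list)

    def validate(self) -> None:
        art = sum(self.artifact_fractions.values())
        for lib in self.libraries:
            total = art + sum(t.fractions.get(lib, 0.0) for t in self.tags)
            if total > 1 + 1e-9:
                raise ValueError(f"{lib}: fractions sum to {total:.4f} > 1")
            if any(t.fractions.get(lib, 0.0) < 0 for t in self.tags):
                raise ValueError("negative tag fraction")

    def expected_counts(self, lib: str) -> dict[str, float]:
        depth = self.depths[lib]
        return {t.sequence: depth * t.fractions.get(lib, 0.0) for t in self.tags}

    def class_fractions(self, lib: str) -> dict[str, float]:
        out: dict[str, float] = {}
        for t in self.tags:
            out[t.cls] = out.get(t.cls, 0.0) + t.fractions.get(lib, 0.0)
        return out


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _tag_forbidden(tag: str, a3p: str, a5p: str) -> bool:
    """Motifs that would divert a planted tag into a removal category."""
    return a3p in tag or tag.startswith(a5p) or "A" * 6 in tag


class _Placer:
    """Non-overlapping feature placement with a separation margin."""

    def __init__(self, rng: np.random.Generator, scaffolds: dict[str, str], margin: int = 30):
        self.rng = rng
        self.names = list(scaffolds)
        self.lengths = {k: len(v) for k, v in scaffolds.items()}
        self.occupied: dict[str, list[tuple[int, int]]] = {k: [] for k in scaffolds}
        self.margin = margin

    def place(self, length: int, tries: int = 300) -> tuple[str, int]:
        for _ in range(tries):
            name = self.names[self.rng.integers(len(self.names))]
            limit = self.lengths[name] - length
            if limit < 1:
                continue
            start = int(self.rng.integers(1, limit + 1))
            end = start + length - 1
            if all(
                end + self.margin < s or start - self.margin > e
                for s, e in self.occupied[name]
            ):
                self.occupied[name].append((start, end))
                return name, start
        raise CapacityError(
            f"could not place a feature of {length} nt; "
            "reduce feature counts or enlarge scaffolds"
        )


def _mature_arm_paired(precursor: str, mature: str) -> int:
    """Paired mature bases in the MFE structure of the bare precursor."""
    structure, _ = fold_hairpin(precursor)
    partner = pairs_to_partner(len(precursor), dotbracket_to_pairs(structure))
    offset = precursor.find(mature)
    lo, hi = offset, offset + len(mature)
    return sum(
        1 for k in range(lo, hi) if partner[k] != -1 and not lo <= partner[k] < hi
    )


def _design_precursor(
    rng: np.random.Generator, a3p: str, a5p: str, arm: str
) -> tuple[str, str]:
    """A hairpin precursor with a perfect extended stem and its mature arm."""
    for _ in range(50):
        length = int(rng.choice([20, 21, 21, 22, 22, 23]))
        first = "T" if rng.random() < 0.85 else _random_seq(rng, 1)
        mature = first + _random_seq(rng, length - 1)
        if _tag_forbidden(mature, a3p, a5p):
            continue
        ext = _random_seq(rng, 10)
        loop = _random_seq(rng, 12)
        top = ext + (mature if arm == "5p" else revcomp(mature))
        precursor = top + loop + revcomp(top)
        if a3p in precursor or "A" * 6 in precursor:
            continue
        if precursor.count(mature) != 1:
            continue
        if _mature_arm_paired(precursor, mature) >= 16:
            return precursor, mature
    raise RuntimeError("failed to design a folding precursor")


def generate_toy_genome(config: SynthConfig, seed: int) -> ToyGenome:
    """Random scaffolds with planted features; deterministic for (config, seed)."""
    rng = np.random.default_rng([int(seed), 0])
    a3p, a5p = config.adapter3[:6], config.adapter5[:6]
    scaffolds = {
        f"scaffold_{i + 1}": _random_seq(rng, config.scaffold_length)
        for i in range(config.n_scaffolds)
    }
    placer = _Placer(rng, scaffolds)
    features: list[Feature] = []

    def overwrite(scaffold: str, start: int, seq: str) -> None:
        s = scaffolds[scaffold]
        scaffolds[scaffold] = s[: start - 1] + seq + s[start - 1 + len(seq) :]

    for i in range(config.n_known_mirnas):
        for _ in range(50):
            mature = _random_seq(rng, 21)
            if not _tag_forbidden(mature, a3p, a5p):
                break
        else:  # pragma: no cover
            raise RuntimeError("failed to design a mature sequence")
        scaffold, start = placer.place(len(mature))
        overwrite(scaffold, start, mature)
        features.append(
            Feature(
                name=f"syn-miR{i + 1:03d}",
                scaffold=scaffold,
                start=start,
                end=start + len(mature) - 1,
                strand="+",
                cls="known_mirna",
                attrs={"mature": mature},
            )
        )
    for i in range(config.n_novel_precursors):
        arm = "5p" if i % 2 == 0 else "3p"
        precursor, mature = _design_precursor(rng, a3p, a5p, arm)
        scaffold, start = placer.place(len(precursor))
        overwrite(scaffold, start, precursor)
        offset = precursor.find(mature)
        features.append(
            Feature(
                name=f"syn-nov{i + 1:03d}",
                scaffold=scaffold,
                start=start,
                end=start + len(precursor) - 1,
                strand="+",
                cls="novel_mirna_precursor",
                attrs={
                    "mature": mature,
                    "arm": arm,
                    "mature_start": start + offset,
                    "mature_end": start + offset + len(mature) - 1,
                },
            )
        )
    interval_plan = [
        ("rRNA", config.n_rrna, (100, 150)),
        ("tRNA", config.n_trna, (70, 90)),
        ("snRNA", config.n_snrna, (80, 120)),
        ("snoRNA", config.n_snorna, (70, 100)),
        ("repeat", config.n_repeats, (150, 250)),
        ("exon", config.n_exons, (150, 300)),
        ("intron", config.n_introns, (150, 300)),
    ]
    for cls, count, (lo, hi) in interval_plan:
        for i in range(count):
            length = int(rng.integers(lo, hi + 1))
            scaffold, start = placer.place(length)
            strand = "-" if cls in ("exon", "intron") and i % 2 else "+"
            features.append(
                Feature(
                    name=f"syn-{cls}{i + 1:02d}",
                    scaffold=scaffold,
                    start=start,
                    end=start + length - 1,
                    strand=strand,
                    cls=cls,
                )
            )
    genome = ToyGenome(scaffolds=scaffolds, features=features)
    genome.validate()
    return genome


def _pick_fragment(
    rng: np.random.Generator,
    genome: ToyGenome,
    feature: Feature,
    a3p: str,
    a5p: str,
    used: set[str],
    antisense: bool = False,
) -> str:
    seq = genome.feature_sequence(feature)
    for _ in range(100):
        length = int(rng.integers(20, 25))
        if length >= len(seq):
            continue
        offset = int(rng.integers(0, len(seq) - length + 1))
        frag = seq[offset : offset + length]
        if antisense:
            frag = revcomp(frag)
        if _tag_forbidden(frag, a3p, a5p) or frag in used:
            continue
        if genome.occurrences(frag) != 1:
            continue
        return frag
    raise RuntimeError(f"could not draw a usable fragment from {feature.name}")


def build_manifest(
    genome: ToyGenome, config: SynthConfig, seed: int
) -> GroundTruthManifest:
    """Assign per-library expected fractions to planted tags.

    Fold changes are exact by construction: a leftover "noise" class of
    unmappable tags absorbs the per-library slack so all fractions sum to 1.
    """
    rng = np.random.default_rng([int(seed), 1])
    a3p, a5p = config.adapter3[:6], config.adapter5[:6]
    libs = list(config.libraries)
    tags: list[TagTruth] = []
    fold_changes: dict[str, dict[str, float]] = {}
    used: set[str] = set()

    known = [f for f in genome.features if f.cls == "known_mirna"]
    for i, feat in enumerate(known):
        mature = feat.attrs["mature"]
        used.add(mature)
        if i < len(config.planted_log2fc):
            fc = config.planted_log2fc[i]
            base = config.changed_mirna_fraction
            fracs = {
                lib: base if lib == config.control else base * 2.0**fc for lib in libs
            }
            fold_changes[feat.name] = {
                lib: (0.0 if lib == config.control else fc) for lib in libs
            }
        else:
            base = float(rng.uniform(0.001, 0.006))
            fracs = {lib: base for lib in libs}
        tags.append(TagTruth(feat.name, mature, "mirna", feat.name, fracs))

    novel = [f for f in genome.features if f.cls == "novel_mirna_precursor"]
    for i, feat in enumerate(novel):
        mature = feat.attrs["mature"]
        used.add(mature)
        # stage-specific presence patterns; every novel mature clears the
        # read-count screen (> 5 reads) in at least one library
        pattern = i % 3
        base = float(rng.uniform(3e-4, 8e-4))
        fracs = {}
        for j, lib in enumerate(libs):
            if pattern == 0:
                fracs[lib] = base
            elif pattern == 1:
                fracs[lib] = base if j == i % len(libs) else 0.0
            else:
                fracs[lib] = base * (1 + j)
        tags.append(TagTruth(feat.name, mature, "novel_mirna", feat.name, fracs))
        if i == 0:  # one observed star arm exercises the star-detection path
            precursor = genome.feature_sequence(feat)
            offset = precursor.find(mature)
            if feat.attrs["arm"] == "5p":
                star = revcomp(precursor[offset : offset + len(mature)])
            else:
                star = revcomp(mature)
            if not _tag_forbidden(star, a3p, a5p) and star not in used:
                used.add(star)
                tags.append(
                    TagTruth(
                        f"{feat.name}*",
                        star,
                        "novel_star",
                        feat.name,
                        {lib: fracs[lib] * 0.2 for lib in libs},
                    )
                )

    fragment_plan = {
        "rRNA": (2, 0.20),
        "tRNA": (2, 0.05),
        "snRNA": (1, 0.006),
        "snoRNA": (1, 0.006),
        "repeat": (2, 0.02),
        "exon": (2, 0.02),
        "intron": (1, 0.01),
    }
    for cls, (per_feature, class_mass) in fragment_plan.items():
        feats = [f for f in genome.features if f.cls == cls]
        if not feats:
            continue
        n_frags = per_feature * len(feats)
        weights = rng.dirichlet(np.ones(n_frags) * 4.0)
        idx = 0
        for feat in feats:
            for rep in range(per_feature):
                antisense = cls in ("exon", "intron") and rep % 2 == 1
                frag = _pick_fragment(rng, genome, feat, a3p, a5p, used, antisense)
                used.add(frag)
                truth_cls = cls
                if cls in ("exon", "intron"):
                    truth_cls = f"{cls}_{'antisense' if antisense else 'sense'}"
                frac = float(class_mass * weights[idx])
                tags.append(
                    TagTruth(
                        f"{feat.name}.f{rep + 1}",
                        frag,
                        truth_cls,
                        feat.name,
                        {lib: frac for lib in libs},
                    )
                )
                idx += 1

    # unmappable noise absorbs the remaining read mass per library
    noise_seqs = []
    while len(noise_seqs) < config.n_noise_tags:
        cand = _random_seq(rng, int(rng.integers(20, 25)))
        if _tag_forbidden(cand, a3p, a5p) or cand in used:
            continue
        if genome.occurrences(cand) != 0:
            continue
        used.add(cand)
        noise_seqs.append(cand)
    noise_weights = rng.dirichlet(np.ones(len(noise_seqs)) * 4.0)
    art_sum = sum(config.artifact_fractions.values())
    planted_sums = {
        lib: sum(t.fractions.get(lib, 0.0) for t in tags) for lib in libs
    }
    noise_tags = []
    for k, seq in enumerate(noise_seqs):
        fracs = {}
        for lib in libs:
            slack = 1.0 - art_sum - planted_sums[lib]
            if slack <= 0:
                raise ValueError(f"{lib}: planted fractions leave no noise mass")
            fracs[lib] = float(slack * noise_weights[k])
        noise_tags.append(TagTruth(f"noise{k + 1:03d}", seq, "noise", "", fracs))
    tags.extend(noise_tags)

    manifest = GroundTruthManifest(
        libraries=libs,
        control=config.control,
        depths=dict(config.depths),
        adapter3=config.adapter3,
        adapter5=config.adapter5,
        artifact_fractions=dict(config.artifact_fractions),
        tags=tags,
        fold_changes=fold_changes,
    )
    manifest.validate()
    return manifest


def generate_transcripts(
    genome: ToyGenome, config: SynthConfig, seed: int
) -> tuple[dict[str, str], list[dict]]:
    """Toy transcripts with planted perfect target sites of novel matures."""
    rng = np.random.default_rng([int(seed), 2])
    novel = [f for f in genome.features if f.cls == "novel_mirna_precursor"]
    transcripts: dict[str, str] = {}
    truth: list[dict] = []
    for i in range(config.n_transcripts):
        tid = f"toyT{i + 1:03d}"
        seq = _random_seq(rng, config.transcript_length)
        if novel:
            feat = novel[i % len(novel)]
            site = revcomp(feat.attrs["mature"])
            pos = int(rng.integers(50, config.transcript_length - len(site) - 50))
            seq = seq[:pos] + site + seq[pos + len(site) :]
            truth.append(
                {
                    "mirna": feat.name,
                    "mature": feat.attrs["mature"],
                    "transcript": tid,
                    "start": pos + 1,
                    "end": pos + len(site),
                }
            )
        transcripts[tid] = seq
    return transcripts, truth


@dataclass
class SimulationResult:
    reads: dict[str, list[tuple[str, str, str]]]
    tag_counts: dict[str, dict[str, int]]
    artifact_counts: dict[str, dict[str, int]]


def sample_tag_counts(
    manifest: GroundTruthManifest, library: str, seed: int
) -> tuple[dict[str, int], dict[str, int]]:
    """Multinomial category counts for one library, without building reads."""
    depth = manifest.depths[library]
    if depth <= 0:
        raise ValueError(f"{library}: zero or negative depth")
    rng = np.random.default_rng([int(seed), 3, manifest.libraries.index(library)])
    probs = [t.fractions.get(library, 0.0) for t in manifest.tags]
    probs += [manifest.artifact_fractions.get(c, 0.0) for c in ARTIFACT_CATEGORIES]
    p = np.asarray(probs, dtype=float)
    p = p / p.sum()
    counts = rng.multinomial(depth, p)
    tag_counts = {
        t.sequence: int(c) for t, c in zip(manifest.tags, counts) if c > 0
    }
    artifact_counts = {
        cat: int(c)
        for cat, c in zip(ARTIFACT_CATEGORIES, counts[len(manifest.tags) :])
    }
    return tag_counts, artifact_counts


def _read_from_insert(rng: np.random.Generator, insert: str, adapter3: str) -> str:
    read = insert + adapter3
    if len(read) < READ_LENGTH:
        read += _random_seq(rng, READ_LENGTH - len(read))
    return read[:READ_LENGTH]


def _artifact_read(
    rng: np.random.Generator, category: str, adapter3: str, adapter5: str
) -> tuple[str, str]:
    a3p, a5p = adapter3[:6], adapter5[:6]
    qual = HIGH_QUALITY_CHAR * READ_LENGTH
    if category == "low_quality":
        seq = _read_from_insert(rng, _random_seq(rng, 22), adapter3)
        return seq, LOW_QUALITY_CHAR * READ_LENGTH
    if category == "adapter3_null":
        while True:
            seq = _random_seq(rng, READ_LENGTH)
            if a3p not in seq:
                return seq, qual
    if category == "insert_null":
        return _read_from_insert(rng, "", adapter3), qual
    if category == "adapter5_contaminant":
        while True:
            insert = a5p + _random_seq(rng, 8)
            seq = _read_from_insert(rng, insert, adapter3)
            if seq.find(a3p) == len(insert):
                return seq, qual
    if category == "short_insert":
        while True:
            insert = _random_seq(rng, int(rng.integers(10, 18)))
            if _tag_forbidden(insert, a3p, a5p) or insert.count("A") / len(insert) >= 0.7:
                continue
            return _read_from_insert(rng, insert, adapter3), qual
    if category == "polyA":
        return _read_from_insert(rng, "A" * 20, adapter3), qual
    raise ValueError(f"unknown artifact category {category!r}")


def simulate_libraries(
    genome: ToyGenome, manifest: GroundTruthManifest, seed: int
) -> SimulationResult:
    """Sample all libraries; read counts equal the configured depths exactly."""
    del genome  # reads are built from the manifest's tag sequences
    reads: dict[str, list[tuple[str, str, str]]] = {}
    tag_counts: dict[str, dict[str, int]] = {}
    artifact_counts: dict[str, dict[str, int]] = {}
    for lib_index, lib in enumerate(manifest.libraries):
        tcounts, acounts = sample_tag_counts(manifest, lib, seed)
        rng = np.random.default_rng([int(seed), 4, lib_index])
        lib_reads: list[tuple[str, str, str]] = []
        for truth in manifest.tags:
            count = tcounts.get(truth.sequence, 0)
            if count == 0:
                continue
            seq = _read_from_insert(rng, truth.sequence, manifest.adapter3)
            qual = HIGH_QUALITY_CHAR * READ_LENGTH
            for _ in range(count):
                lib_reads.append((f"{lib}_{len(lib_reads) + 1}_{truth.cls}", seq, qual))
        for category in ARTIFACT_CATEGORIES:
            for _ in range(acounts.get(category, 0)):
                seq, qual = _artifact_read(
                    rng, category, manifest.adapter3, manifest.adapter5
                )
                lib_reads.append((f"{lib}_{len(lib_reads) + 1}_{category}", seq, qual))
        order = rng.permutation(len(lib_reads))
        reads[lib] = [lib_reads[i] for i in order]
        tag_counts[lib] = tcounts
        artifact_counts[lib] = acounts
    return SimulationResult(reads, tag_counts, artifact_counts)


def write_dataset(
    outdir,
    genome: ToyGenome,
    manifest: GroundTruthManifest,
    result: SimulationResult,
    transcripts: dict[str, str] | None = None,
) -> dict[str, Path]:
    """Write the full synthetic dataset as plain-text files."""
    outdir = io.ensure_dir(outdir)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fa"
    io.write_fasta(paths["genome"], genome.scaffolds)
    paths["features"] = outdir / "features.gff3"
    io.write_gff3(paths["features"], genome.features)
    paths["mature_ref"] = outdir / "mature_mirnas.fa"
    io.write_fasta(paths["mature_ref"], genome.mature_reference())
    for cls, records in genome.ncrna_reference().items():
        key = f"ref_{cls}"
        paths[key] = outdir / f"{cls}.fa"
        io.write_fasta(paths[key], records)
    for lib, lib_reads in result.reads.items():
        key = f"reads_{lib}"
        paths[key] = outdir / f"{lib}.fastq"
        io.write_fastq(paths[key], lib_reads)
    if transcripts:
        paths["transcripts"] = outdir / "transcripts.fa"
        io.write_fasta(paths["transcripts"], transcripts)
    paths["manifest"] = outdir / "manifest.tsv"
    header = ["name", "sequence", "class", "feature"] + [
        f"frac_{lib}" for lib in manifest.libraries
    ] + [f"sampled_{lib}" for lib in manifest.libraries]
    rows = []
    for t in manifest.tags:
        rows.append(
            [t.name, t.sequence, t.cls, t.feature]
            + [f"{t.fractions.get(lib, 0.0):.3e}" for lib in manifest.libraries]
            + [result.tag_counts[lib].get(t.sequence, 0) for lib in manifest.libraries]
        )
    io.write_tsv(paths["manifest"], header, rows)
    return paths
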