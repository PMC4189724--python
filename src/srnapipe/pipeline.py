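"""End-to-end orchestration: synth -> clean -> annotate -> novel -> diffexpr -> targets.

A single :class:`PipelineConfig` carries every path, adapter and threshold;
each documented paper-gap decision surfaces here as a named key with its
default.  ``run_pipeline`` executes the stages in order, writes all TSV/GFF3
reports plus a JSON run manifest (package version, seed, thresholds) and
aborts with the failing stage's name on any error.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

import srnapipe
from srnapipe import annotation, diffexpr, hairpin, io, preprocess, synth, targets
from srnapipe.seqs import Feature


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    seed: int = 1
    libraries: tuple = ("SD8", "C5", "LD3")
    control: str = "SD8"
    # input paths; when absent the synthetic generator provides them
    genome_fasta: str | None = None
    reads_fastq: dict = field(default_factory=dict)  # library -> path
    mature_fasta: str | None = None
    features_gff3: str | None = None
    transcripts_fasta: str | None = None
    adapter3: str = synth.DEFAULT_ADAPTER3
    adapter5: str = synth.DEFAULT_ADAPTER5
    synthetic: dict = field(default_factory=dict)  # SynthConfig overrides
    # cleaning thresholds
    min_mean_quality: float = 20.0
    max_n_fraction: float = 0.1
    adapter_match_len: int = 6
    polya_min_run: int = 6
    polya_min_fraction: float = 0.7
    # hairpin thresholds
    flank: int = 150
    cluster_gap: int = 30
    min_mature: int = 20
    max_mature: int = 23
    min_count: int = 5
    min_paired: int = 16
    max_bulge: int = 4
    max_mfe: float = -18.0
    # differential expression thresholds
    p_threshold: float = 0.01
    fc_threshold: float = 1.0
    bh_correct: bool = False
    # target prediction
    target_cutoff: float = 4.0

    def validate(self) -> None:
        if self.control not in self.libraries:
            raise ValueError(
                f"control {self.control!r} not among libraries {self.libraries}"
            )
        if not 0 <= self.polya_min_fraction <= 1:
            raise ValueError("polya_min_fraction outside [0, 1]")
        if self.max_mfe > 0:
            raise ValueError("max_mfe must be <= 0")
        if self.min_mature > self.max_mature:
            raise ValueError("min_mature > max_mature")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold outside (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "libraries" in data:
            data["libraries"] = tuple(data["libraries"])
        return cls(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return a bundle of output paths and key tables."""
    config.validate()
    outdir = io.ensure_dir(config.outdir)
    bundle: dict = {"outdir": outdir}
    stage = "synth"
    try:
        if config.genome_fasta is None:
            scfg = synth.SynthConfig(
                libraries=tuple(config.libraries),
                control=config.control,
                adapter3=config.adapter3,
                adapter5=config.adapter5,
                **config.synthetic,
            )
            genome = synth.generate_toy_genome(scfg, config.seed)
            manifest = synth.build_manifest(genome, scfg, config.seed)
            transcripts, _target_truth = synth.generate_transcripts(
                genome, scfg, config.seed
            )
            sim = synth.simulate_libraries(genome, manifest, config.seed)
            paths = synth.write_dataset(outdir / "synth", genome, manifest, sim, transcripts)
            scaffolds = genome.scaffolds
            features = genome.features
            mature_ref = genome.mature_reference()
            reads_paths = {lib: paths[f"reads_{lib}"] for lib in config.libraries}
            bundle["synth_paths"] = paths
            bundle["manifest"] = manifest
        else:
            scaffolds = io.read_fasta(config.genome_fasta)
            features = io.read_gff3(config.features_gff3) if config.features_gff3 else []
            mature_ref = io.read_fasta(config.mature_fasta) if config.mature_fasta else {}
            transcripts = (
                io.read_fasta(config.transcripts_fasta)
                if config.transcripts_fasta
                else {}
            )
            reads_paths = dict(config.reads_fastq)
            missing = [lib for lib in config.libraries if lib not in reads_paths]
            if missing:
                raise ValueError(f"no FASTQ supplied for libraries {missing}")

        stage = "clean"
        per_lib_tags = {}
        reports = {}
        for lib in config.libraries:
            tags, report = preprocess.clean_reads(
                io.read_fastq(reads_paths[lib]),
                config.adapter3,
                config.adapter5,
                min_mean_quality=config.min_mean_quality,
                max_n_fraction=config.max_n_fraction,
                adapter_match_len=config.adapter_match_len,
                polya_min_run=config.polya_min_run,
                polya_min_fraction=config.polya_min_fraction,
            )
            per_lib_tags[lib] = tags
            reports[lib] = report
            io.write_collapsed_fasta(outdir / f"{lib}.collapsed.fa", tags)
        _write_cleaning_tsv(outdir / "cleaning_report.tsv", reports, config.libraries)
        clean_tags = preprocess.collapse_libraries(per_lib_tags)
        totals = {lib: reports[lib].clean_reads for lib in config.libraries}
        bundle["cleaning_reports"] = reports
        bundle["clean_tags"] = clean_tags

        stage = "annotate"
        hits = annotation.map_tags(clean_tags, scaffolds)
        records, composition = annotation.classify(clean_tags, hits, mature_ref, features)
        known_counts = annotation.identify_known_mirnas(clean_tags, mature_ref)
        io.write_tsv(
            outdir / "composition.tsv",
            ["category"]
            + [f"{lib}_{k}" for lib in composition.libraries for k in ("unique", "unique_pct", "total", "total_pct")],
            composition.to_rows(),
        )
        io.write_tsv(
            outdir / "known_mirna_counts.tsv",
            ["mirna"] + list(config.libraries),
            [
                [mid] + [counts.get(lib, 0) for lib in config.libraries]
                for mid, counts in sorted(known_counts.items())
            ],
        )
        bundle["records"] = records
        bundle["composition"] = composition
        bundle["known_counts"] = known_counts

        stage = "novel"
        unannotated = {r.tag for r in records if r.category == "unannotated" and r.hits}
        unann_hits = [h for r in records if r.tag in unannotated for h in r.hits]
        windows = hairpin.extract_candidates(
            unann_hits, scaffolds, flank=config.flank, cluster_gap=config.cluster_gap
        )
        tag_counts = {t.sequence: t.counts for t in clean_tags}
        candidates = [
            hairpin.build_candidate(w, scaffolds, tag_counts) for w in windows
        ]
        accepted = hairpin.screen_candidates(
            candidates,
            min_mature=config.min_mature,
            max_mature=config.max_mature,
            min_count=config.min_count,
            min_paired=config.min_paired,
            max_bulge=config.max_bulge,
            max_mfe=config.max_mfe,
        )
        _write_novel_outputs(outdir, accepted, config.libraries)
        bundle["candidates"] = candidates
        bundle["accepted_novel"] = accepted

        stage = "diffexpr"
        novel_counts = {
            f"nov-{i + 1:03d}": c.mature_counts for i, c in enumerate(accepted)
        }
        all_counts = {**known_counts, **novel_counts}
        if all_counts:
            counts_df = pd.DataFrame.from_dict(all_counts, orient="index").fillna(0)
            for lib in config.libraries:
                if lib not in counts_df.columns:
                    counts_df[lib] = 0
            counts_df = counts_df[list(config.libraries)].astype(int)
            expression = diffexpr.compare_libraries(
                counts_df,
                {k: float(v) for k, v in totals.items()},
                config.control,
                p_threshold=config.p_threshold,
                fc_threshold=config.fc_threshold,
                bh_correct=config.bh_correct,
            )
        else:
            expression = pd.DataFrame()
        expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
        bundle["expression"] = expression

        stage = "targets"
        if transcripts and accepted:
            mirnas = {
                f"nov-{i + 1:03d}": c.mature for i, c in enumerate(accepted)
            }
            target_hits = targets.scan_transcriptome(
                mirnas, transcripts, cutoff=config.target_cutoff
            )
            _write_target_tsv(outdir / "targets.tsv", target_hits)
            bundle["target_hits"] = target_hits
    except Exception as exc:
        raise StageError(stage, exc) from exc

    run_manifest = {
        "version": srnapipe.__version__,
        "seed": config.seed,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in asdict(config).items()
        },
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2, sort_keys=True, default=str)
    bundle["run_manifest"] = run_manifest
    return bundle


def _write_cleaning_tsv(path, reports, libraries) -> None:
    header = ["type"] + [f"{lib}_{c}" for lib in libraries for c in ("count", "percent")]
    row_names = [name for name, _c, _p in next(iter(reports.values())).to_rows()]
    rows = []
    for i, name in enumerate(row_names):
        row = [name]
        for lib in libraries:
            _n, count, pct = reports[lib].to_rows()[i]
            row += [count, pct]
        rows.append(row)
    io.write_tsv(path, header, rows)


def _write_novel_outputs(outdir, accepted, libraries) -> None:
    io.write_tsv(
        outdir / "novel_mirnas.tsv",
        ["mirna", "mature", "location", "mfe", "structure"]
        + [f"count_{lib}" for lib in libraries],
        [
            [
                f"nov-{i + 1:03d}",
                c.mature,
                c.window.locus,
                f"{c.mfe:.2f}",
                c.structure,
            ]
            + [c.mature_counts.get(lib, 0) for lib in libraries]
            for i, c in enumerate(accepted)
        ],
    )
    feats = []
    for i, c in enumerate(accepted):
        feats.append(
            Feature(
                name=f"nov-{i + 1:03d}",
                scaffold=c.window.scaffold,
                start=c.window.start,
                end=c.window.end,
                strand=c.window.strand,
                cls="novel_mirna_precursor",
                attrs={"mature": c.mature, "mfe": f"{c.mfe:.2f}"},
            )
        )
    io.write_gff3(outdir / "novel_mirnas.gff3", feats)


def _write_target_tsv(path, target_hits) -> None:
    rows = []
    for mid, hits in sorted(target_hits.items()):
        for aln in hits:
            try:
                cleavage = "{}..{}".format(*aln.predicted_cleavage())
            except ValueError:
                cleavage = "indeterminate"
            rows.append(
                [
                    mid,
                    aln.transcript_id,
                    aln.start,
                    aln.end,
                    f"{aln.score:.2f}",
                    cleavage,
                ]
            )
    io.write_tsv(
        path,
        ["mirna", "transcript", "site_start", "site_end", "score", "cleavage"],
        rows,
    )
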