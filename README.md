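# srnapipe

A small-RNA-seq analysis toolkit covering the classic three-library workflow:

1. **synth** — generate a toy genome, reference sets and three FASTQ
   libraries with planted, manifest-recorded ground truth (known miRNAs with
   planted fold changes, novel hairpin precursors, ncRNA fragments,
   degradation products, unmappable noise, and the usual read artifacts).
2. **clean** — convert raw reads into clean 18–30 nt tags through a fixed
   sequence of removal categories (quality, missing 3' adapter, empty
   insert, 5'-adapter contamination, polyA, length), with a conservation-
   checked accounting report and size distributions.
3. **annotate** — exact-match genome mapping on both strands and
   hierarchical classification (miRNA > rRNA > tRNA > snRNA > snoRNA >
   repeat > exon > intron > unannotated), plus known-miRNA quantification by
   exact mature-sequence identity.
4. **novel** — cluster unannotated mapped tags, fold precursor windows with
   a built-in deterministic nearest-neighbor RNA folder (pluggable backend),
   and screen candidates on mature length, read count, duplex geometry and
   folding energy; summary statistics (MFE mean ± sd, 5'U fraction).
5. **diffexpr** — reads-per-million normalisation with zero revision to
   0.01, a low-expression filter, log2 fold changes, and the two-library
   count statistic with both cumulative tails evaluated exactly in
   log-space; a 2^-ΔΔCt helper for qPCR comparisons.
6. **targets** — plant-style miRNA target scoring (mismatch 1, G:U 0.5,
   gap 2, doubled at positions 2–13, cutoff 4), transcriptome scanning with
   single-gap extension, and cleavage-site prediction between miRNA
   positions 10 and 11.

## Command line

```sh
srna-pipeline run --config cfg.yaml          # full pipeline (synthetic by default)
srna-pipeline synth --seed 1 --outdir data/  # synthetic dataset only
srna-pipeline clean --fastq SD8.fastq --adapter3 SEQ --adapter5 SEQ -o out/
srna-pipeline annotate --tags tags.fa --genome g.fa --mirbase mature.fa --gff ann.gff3 -o out/
srna-pipeline novel --tags tags.fa --genome g.fa --flank 150 -o out/
srna-pipeline diffexpr --counts c.tsv --totals SD8=1e6,C5=1e6,LD3=1e6 --control SD8 -o out.tsv
srna-pipeline targets --mirnas m.fa --transcripts t.fa -o hits.tsv
```

`run` writes per-stage TSV/GFF3 reports plus a `run_manifest.json` recording
the package version, seed and every threshold; reruns with the same config
and seed are byte-identical.

## Library use

```python
from srnapipe import synth, preprocess, annotation, hairpin, diffexpr, targets

cfg = synth.SynthConfig()
genome = synth.generate_toy_genome(cfg, seed=1)
manifest = synth.build_manifest(genome, cfg, seed=1)
sim = synth.simulate_libraries(genome, manifest, seed=1)
tags, report = preprocess.clean_reads(sim.reads["SD8"], cfg.adapter3, cfg.adapter5)
```

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: published-table
arithmetic round-trips, exactness and calibration of the count statistic,
end-to-end recovery of planted fold changes and hairpins, and dual-route
oracle checks (dynamic-programming folder vs exhaustive enumeration; target
scanner vs brute-force window rescoring).

## Notes on documented choices

The upstream accounting conventions leave several thresholds unspecified;
this package fixes and records them: low quality = mean Phred < 20 or > 10%
N; 3' adapter located by exact ≥ 6-base prefix match; polyA = a ≥ 6-base A
run making up ≥ 70% of the insert; hairpin acceptance needs ≥ 16 paired
mature bases, ≤ 4-nt asymmetric bulges, and MFE ≤ −18 kcal/mol; significance
defaults to smaller-tail p ≤ 0.01 with |log2FC| ≥ 1. All are configurable.
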