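import pytest

from reference_tables import (
    COMPOSITION_TABLE,
    COMPOSITION_TOTAL_PERCENTS,
    COMPOSITION_TOTALS,
    COMPOSITION_UNIQUE_PERCENTS,
    LIBRARIES,
)
from srnapipe import annotation
from srnapipe.annotation import (
    CATEGORIES,
    CompositionReport,
    classify,
    identify_known_mirnas,
    map_tags,
)
from srnapipe.preprocess import CleanTag
from srnapipe.seqs import Feature, revcomp


def _tag(seq, count=1, lib="SD8"):
    return CleanTag(seq, {lib: count})


GENOME = {"chr1": "ACGTACGTTTGCAGGCATCGATCGGATCCTAGCTAGGCTTAAGCGTATGCATGGACT" * 3}


class TestMapTags:
    def test_single_plus_hit(self):
        seq = GENOME["chr1"][10:32]
        hits = map_tags([_tag(seq)], {"chr1": GENOME["chr1"][:60]})
        assert len(hits[seq]) == 1
        hit = hits[seq][0]
        assert (hit.scaffold, hit.start, hit.end, hit.strand, hit.mismatches) == (
            "chr1",
            11,
            32,
            "+",
            0,
        )

    def test_minus_strand_hit(self):
        seq = revcomp(GENOME["chr1"][10:32])
        hits = map_tags([_tag(seq)], {"chr1": GENOME["chr1"][:60]})
        assert [h.strand for h in hits[seq]] == ["-"]

    def test_hit_sequence_identity(self):
        # genome substring (reverse-complemented on minus) equals the tag
        seq = revcomp(GENOME["chr1"][5:27])
        hits = map_tags([_tag(seq)], GENOME)
        for hit in hits[seq]:
            sub = GENOME[hit.scaffold][hit.start - 1 : hit.end]
            assert (sub if hit.strand == "+" else revcomp(sub)) == seq

    def test_unmapped_flagged(self):
        seq = "TTTTGGGGCCCCAAAATTTTGG"
        hits = map_tags([_tag(seq)], {"chr1": "ACGT" * 30})
        assert hits[seq] == []

    def test_empty_genome_errors(self):
        with pytest.raises(ValueError, match="empty genome"):
            map_tags([_tag("ACGT" * 5)], {})

    def test_all_planted_tags_map_to_planted_loci(
        self, manifest, genome_hits, toy_genome
    ):
        features = {f.name: f for f in toy_genome.features}
        for truth in manifest.tags:
            if truth.sequence not in genome_hits:
                continue
            found = genome_hits[truth.sequence]
            if truth.cls == "noise":
                assert found == []
            elif truth.feature:
                feat = features[truth.feature]
                assert any(
                    h.scaffold == feat.scaffold
                    and feat.start <= h.start
                    and h.end <= feat.end
                    for h in found
                ), truth.name


class TestIdentifyKnownMirnas:
    REF = {"mir-a": "ACGUACGUACGUACGUACGUA", "mir-b": "GGGCCCAAATTTGGGCCCAAA"}

    def test_exact_match_assigned(self):
        tags = [_tag("ACGTACGTACGTACGTACGTA", 7)]
        table = identify_known_mirnas(tags, self.REF)
        assert table == {"mir-a": {"SD8": 7}}

    def test_single_mismatch_unassigned(self):
        tags = [_tag("ACGTACGTACGTACGTACGTT")]
        assert identify_known_mirnas(tags, self.REF) == {}

    def test_u_t_normalisation(self):
        tags = [_tag("GGGCCCAAATTTGGGCCCAAA", 2)]
        table = identify_known_mirnas(tags, self.REF)
        assert table["mir-b"] == {"SD8": 2}

    def test_duplicate_reference_ids_rejected(self):
        pairs = [("mir-a", "ACGUACGUACGUACGUACGUA"), ("mir-a", "GGGCCCAAATTTGGGCCCAAA")]
        with pytest.raises(ValueError, match="duplicate"):
            identify_known_mirnas([], pairs)

    def test_planted_mirnas_all_detected(self, clean_tags, toy_genome, manifest, simulation):
        table = identify_known_mirnas(clean_tags, toy_genome.mature_reference())
        planted = {t.name: t for t in manifest.tags if t.cls == "mirna"}
        assert set(table) == set(planted)
        for name, row in table.items():
            for lib, count in row.items():
                assert count == simulation.tag_counts[lib].get(planted[name].sequence, 0)


class TestClassify:
    def _setup(self):
        genome = {"chr1": "A" * 40 + "GCATCGGATCCTAGCTAGGCTTAAGCGTATGCATGGACTA" + "C" * 40}
        feature = Feature("r1", "chr1", 41, 80, "+", "rRNA")
        tag = genome["chr1"][44:66]
        return genome, feature, tag

    def test_reference_overlap_classified(self):
        genome, feature, tag = self._setup()
        tags = [_tag(tag, 3)]
        hits = map_tags(tags, genome)
        records, report = classify(tags, hits, {}, [feature])
        assert records[0].category == "rRNA"
        assert report.total["rRNA"]["SD8"] == 3

    def test_no_feature_overlap_is_unannotated(self):
        genome, feature, tag = self._setup()
        other = "GGTTCCGGTTCCGGTTCCAA"
        genome = {"chr1": genome["chr1"] + other}
        tags = [_tag(other)]
        hits = map_tags(tags, genome)
        records, _ = classify(tags, hits, {}, [feature])
        assert records[0].category == "unannotated"

    def test_mirna_beats_interval_category(self):
        genome, feature, tag = self._setup()
        tags = [_tag(tag)]
        hits = map_tags(tags, genome)
        records, _ = classify(tags, hits, {"mir-x": tag}, [feature])
        assert records[0].category == "miRNA"
        assert records[0].reference_id == "mir-x"

    def test_antisense_exon(self):
        genome, _, _ = self._setup()
        feature = Feature("e1", "chr1", 41, 80, "+", "exon")
        tag = revcomp(genome["chr1"][44:66])
        tags = [_tag(tag)]
        hits = map_tags(tags, genome)
        records, _ = classify(tags, hits, {}, [feature])
        assert records[0].category == "exon_antisense"

    def test_exhaustive_partition(self, classified, clean_tags):
        records, report = classified
        assert len(records) == len(clean_tags)
        totals = report.library_totals("total")
        for lib, grand in totals.items():
            assert grand == sum(t.counts.get(lib, 0) for t in clean_tags)

    def test_planted_classes_recovered(self, classified, manifest):
        records, _ = classified
        by_seq = {r.tag: r.category for r in records}
        expected = {
            "mirna": "miRNA",
            "rRNA": "rRNA",
            "tRNA": "tRNA",
            "snRNA": "snRNA",
            "snoRNA": "snoRNA",
            "repeat": "repeat",
            "exon_sense": "exon_sense",
            "exon_antisense": "exon_antisense",
            "intron_sense": "intron_sense",
            "intron_antisense": "intron_antisense",
            "noise": "unannotated",
            "novel_mirna": "unannotated",
            "novel_star": "unannotated",
        }
        for truth in manifest.tags:
            if truth.sequence in by_seq:
                assert by_seq[truth.sequence] == expected[truth.cls], truth.name

    def test_strand_agrees_with_brute_force(self, classified, genome_hits, toy_genome):
        records, _ = classified
        exonic = {
            f.name: f for f in toy_genome.features if f.cls in ("exon", "intron")
        }
        for rec in records:
            if not rec.category.startswith(("exon", "intron")):
                continue
            overlapping = [
                (f, h)
                for h in rec.hits
                for f in exonic.values()
                if f.overlaps(h.scaffold, h.start, h.end)
            ]
            assert overlapping
            senses = {h.strand == f.strand for f, h in overlapping}
            if rec.category.endswith("_sense"):
                assert True in senses
            else:
                assert senses == {False}


class TestPublishedCompositionArithmetic:
    def _report(self):
        unique = {c: {lib: COMPOSITION_TABLE[c][lib][0] for lib in LIBRARIES} for c in CATEGORIES}
        total = {c: {lib: COMPOSITION_TABLE[c][lib][1] for lib in LIBRARIES} for c in CATEGORIES}
        return CompositionReport(libraries=list(LIBRARIES), unique=unique, total=total)

    def test_category_sums_match_printed_totals(self):
        report = self._report()
        for lib in LIBRARIES:
            assert report.library_totals("unique")[lib] == COMPOSITION_TOTALS[lib][0]
            assert report.library_totals("total")[lib] == COMPOSITION_TOTALS[lib][1]

    def test_percent_round_trip_all_categories(self):
        report = self._report()
        pct_total = report.percentages("total")
        pct_unique = report.percentages("unique")
        for cat in CATEGORIES:
            for lib in LIBRARIES:
                assert pct_total[cat][lib] == COMPOSITION_TOTAL_PERCENTS[cat][lib], (cat, lib)
                assert pct_unique[cat][lib] == COMPOSITION_UNIQUE_PERCENTS[cat][lib], (cat, lib)
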