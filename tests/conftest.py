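import pytest

from srnapipe import annotation, hairpin, preprocess, synth


@pytest.fixture(scope="session")
def synth_config():
    return synth.SynthConfig(depths={"SD8": 50_000, "C5": 50_000, "LD3": 50_000})


@pytest.fixture(scope="session")
def toy_genome(synth_config):
    return synth.generate_toy_genome(synth_config, seed=1)


@pytest.fixture(scope="session")
def manifest(toy_genome, synth_config):
    return synth.build_manifest(toy_genome, synth_config, seed=1)


@pytest.fixture(scope="session")
def simulation(toy_genome, manifest):
    return synth.simulate_libraries(toy_genome, manifest, seed=1)


@pytest.fixture(scope="session")
def cleaned(simulation, synth_config):
    """Per-library (tag counter, report) pairs from the simulated reads."""
    out = {}
    for lib in synth_config.libraries:
        out[lib] = preprocess.clean_reads(
            simulation.reads[lib], synth_config.adapter3, synth_config.adapter5
        )
    return out


@pytest.fixture(scope="session")
def clean_tags(cleaned):
    return preprocess.collapse_libraries({lib: tags for lib, (tags, _) in cleaned.items()})


@pytest.fixture(scope="session")
def genome_hits(clean_tags, toy_genome):
    return annotation.map_tags(clean_tags, toy_genome.scaffolds)


@pytest.fixture(scope="session")
def classified(clean_tags, genome_hits, toy_genome):
    return annotation.classify(
        clean_tags, genome_hits, toy_genome.mature_reference(), toy_genome.features
    )


@pytest.fixture(scope="session")
def accepted_novel(classified, toy_genome, clean_tags):
    records, _ = classified
    unann_hits = [h for r in records if r.category == "unannotated" for h in r.hits]
    windows = hairpin.extract_candidates(unann_hits, toy_genome.scaffolds)
    tag_counts = {t.sequence: t.counts for t in clean_tags}
    candidates = [
        hairpin.build_candidate(w, toy_genome.scaffolds, tag_counts) for w in windows
    ]
    return hairpin.screen_candidates(candidates), candidates
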