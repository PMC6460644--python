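"""Shared fixtures: a small trained embedding world, built once per session."""

from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import settings

from biosentsim import (
    CorpusLine,
    EmbeddingTrainConfig,
    GeneratorConfig,
    filter_long_lines,
    generate_benchmark,
    generate_corpus,
    split_hyphen_compounds,
    train_word_table,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gen_config() -> GeneratorConfig:
    """Small-but-realistic generator settings used across the suite."""
    return GeneratorConfig(seed=7, n_sentences=2000)


@pytest.fixture(scope="session")
def corpus_file(gen_config, tmp_path_factory) -> Path:
    return generate_corpus(gen_config, tmp_path_factory.mktemp("corpus") / "corpus.txt")


@pytest.fixture(scope="session")
def processed_corpus(corpus_file, tmp_path_factory) -> Path:
    """Corpus after post-processing: length filter + hyphen splitting."""
    lines = [CorpusLine(l) for l in corpus_file.read_text().splitlines()]
    kept = filter_long_lines(lines)
    out = tmp_path_factory.mktemp("proc") / "processed.txt"
    out.write_text("".join(split_hyphen_compounds(l).text + "\n" for l in kept))
    return out


@pytest.fixture(scope="session")
def trained_table(processed_corpus):
    return train_word_table(
        processed_corpus, EmbeddingTrainConfig(dimension=20, min_count=5, seed=7)
    )


@pytest.fixture(scope="session")
def benchmark_sigma0(gen_config):
    """Noise-free benchmark: gold is exactly 4x the constructed overlap."""
    cfg = GeneratorConfig(seed=gen_config.seed, n_sentences=gen_config.n_sentences,
                          overlap_noise=0.0)
    return generate_benchmark(cfg)


@pytest.fixture(scope="session")
def benchmark_noisy(gen_config):
    return generate_benchmark(gen_config)
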