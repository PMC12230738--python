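"""Shared fixtures: the deterministic toy genome and designed libraries."""

from __future__ import annotations

import pytest

from betiler import (
    BUILTIN_BASE_EDITORS,
    BUILTIN_CAS_VARIANTS,
    LibraryType,
    generate_fixture,
    load_annotation,
    load_genome,
)
from betiler.pipeline import design_library


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    return generate_fixture(out, seed=1, n_genes=3, chrom_length=9000)


@pytest.fixture(scope="session")
def genome(fixture_paths):
    return load_genome(fixture_paths.fasta)


@pytest.fixture(scope="session")
def transcripts(fixture_paths, genome):
    return load_annotation(fixture_paths.gff3, genome)


@pytest.fixture(scope="session")
def spcas9():
    return BUILTIN_CAS_VARIANTS["SpCas9"]


@pytest.fixture(scope="session")
def spg():
    return BUILTIN_CAS_VARIANTS["SpG"]


@pytest.fixture(scope="session")
def editors():
    return [BUILTIN_BASE_EDITORS["BE4"], BUILTIN_BASE_EDITORS["ABE8e"]]


@pytest.fixture(scope="session")
def designed_target(genome, transcripts, spcas9, editors):
    """Target library over the essential gene, fully annotated."""
    return design_library(
        genome, transcripts, ["ESS1"], spcas9, editors, flank_nt=10
    )


@pytest.fixture(scope="session")
def designed_positive(genome, transcripts, spcas9, editors):
    return design_library(
        genome,
        transcripts,
        ["GENE2"],
        spcas9,
        editors,
        flank_nt=10,
        library_type=LibraryType.POSITIVE,
    )


@pytest.fixture(scope="session")
def designed_negative(fixture_paths, genome, transcripts, spcas9, editors):
    return design_library(
        genome,
        transcripts,
        [fixture_paths.safe_harbor_region],
        spcas9,
        editors,
        library_type=LibraryType.NEGATIVE,
    )
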