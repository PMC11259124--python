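from __future__ import annotations

import numpy as np
import pytest

from ptvburden import TranscriptModel, simulate_transcript
from ptvburden.simulate import default_variant_pools


@pytest.fixture
def toy_single_exon() -> TranscriptModel:
    """Exon 101..109, all coding: ATG AAA TAG."""
    return TranscriptModel(
        id="TOY1", contig="chrT", strand="+", exons=((101, 109),),
        cds_start=101, cds_end=109, sequence="ATGAAATAG",
        contig_sequence="N" * 100 + "ATGAAATAG" + "N" * 20,
    )


@pytest.fixture
def toy_two_exon() -> TranscriptModel:
    """Exon1 101..109 (ATG AAA CCC), intron 110..209, exon2 210..215 (TAG AAA).

    CDS spans 101..212: ATG AAA CCC TAG.
    """
    contig = "N" * 100 + "ATGAAACCC" + "GT" + "N" * 96 + "AG" + "TAGAAA" + "N" * 20
    return TranscriptModel(
        id="TOY2", contig="chrT", strand="+", exons=((101, 109), (210, 215)),
        cds_start=101, cds_end=212, sequence="ATGAAACCCTAGAAA",
        contig_sequence=contig,
    )


@pytest.fixture
def toy_with_utr() -> TranscriptModel:
    """Single exon with UTRs: 5'UTR 6 bp, CDS ATG AAA GGG CCC TGA, 3'UTR 9 bp."""
    seq = "GGGGGG" + "ATGAAAGGGCCCTGA" + "TTAACCCGG"
    return TranscriptModel(
        id="TOY3", contig="chrT", strand="+", exons=((101, 100 + len(seq)),),
        cds_start=107, cds_end=121, sequence=seq,
        contig_sequence="N" * 100 + seq + "N" * 20,
    )


@pytest.fixture(scope="session")
def sim_transcript() -> TranscriptModel:
    return simulate_transcript(20240705, n_exons=5)


@pytest.fixture(scope="session")
def sim_pools(sim_transcript):
    return default_variant_pools(sim_transcript, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(987654321)
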