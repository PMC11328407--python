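"""Shared fixtures: a hand-designed pileup, toy transcript models, and a
small simulated dataset reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rnaedit.annotate import TranscriptIndex, TranscriptModel
from rnaedit.calling import AlleleCountRecord
from rnaedit.design import lps_design
from rnaedit.simulate import SimulationConfig, generate_dataset

# 12 hand-designed mpileup lines exercising reference matches, substitutions,
# case-insensitivity, read starts (^ + mapq), read ends ($), insertions,
# deletions, below-quality bases ('5' = Phred 20 < 25), '*' placeholders, 'N',
# a tied multi-allelic site, and a just-above-1% frequency site.
# Quality chars: 'I' = Phred 40, '5' = Phred 20.
PILEUP_LINES = [
    "chr1\t100\tA\t12\t....,,,,GGG.\tIIIIIIIIIIII",
    "chr1\t101\tA\t8\t....,,,G\tIIIIIIII",
    "chr1\t102\tT\t12\t..,,ccCC..,,\tIIIIIIIIIIII",
    "chr1\t103\tA\t7\t^].^].,,GG.$\tIIIIIII",
    "chr1\t105\tG\t7\t.+2AG.,,-1c..,\tIIIIIII",
    "chr1\t106\tA\t12\t..........GG\tIIIIIIIIII55",
    "chr1\t107\tA\t12\t..........GG\tIIIIIIIIIIII",
    "chr1\t108\tC\t12\t....TTGG..,,\tIIIIIIIIIIII",
    "chr1\t109\tA\t12\t*...,,....,,\tIIIIIIIIIIII",
    "chr1\t110\tA\t60\t" + "." * 59 + "G\t" + "I" * 60,
    "chr1\t111\tA\t100\t" + "." * 98 + "Gg\t" + "I" * 100,
    "chr1\t112\tA\t12\t..,,..N..,,.\tIIIIIIIIIIII",
]

# per-line manual oracle: pos -> (ref, alt, ref_count, alt_count, other,
# below_quality, depth_column)
PILEUP_EXPECTED = {
    100: ("A", "G", 9, 3, 0, 0, 12),
    101: ("A", "G", 7, 1, 0, 0, 8),
    102: ("T", "C", 8, 4, 0, 0, 12),
    103: ("A", "G", 5, 2, 0, 0, 7),
    105: ("G", None, 7, 0, 0, 0, 7),
    106: ("A", None, 10, 0, 0, 2, 12),
    107: ("A", "G", 10, 2, 0, 0, 12),
    108: ("C", "G", 8, 2, 2, 0, 12),
    109: ("A", None, 11, 0, 1, 0, 12),
    110: ("A", "G", 59, 1, 0, 0, 60),
    111: ("A", "G", 98, 2, 0, 0, 100),
    112: ("A", None, 11, 0, 1, 0, 12),
}

# sites passing depth>=10, alt>=2, freq>=1%
PILEUP_PASSING = {100, 102, 107, 108, 111}


@pytest.fixture
def pileup_text():
    return "\n".join(PILEUP_LINES) + "\n"


@pytest.fixture
def fixture_models():
    """Three genes giving the pileup sites their strands.

    Sites 100/101 sit in a plus-strand gene, 102-105 in a minus-strand gene
    (so the T>C at 102 is A-to-I) and 106-112 in a second plus-strand gene.
    """
    return [
        TranscriptModel("gA", "gA.t1", "chr1", "+", ((95, 101),), (), "lincRNA"),
        TranscriptModel("gB", "gB.t1", "chr1", "-", ((102, 105),), (), "lincRNA"),
        TranscriptModel("gC", "gC.t1", "chr1", "+", ((106, 115),), (), "lincRNA"),
    ]


@pytest.fixture
def fixture_index(fixture_models):
    return TranscriptIndex(fixture_models)


def second_sample_records():
    """Hand-built sample2 records for the retention scenario.

    Site 100 and 111 pass again (so they satisfy the >=2-sample rule);
    107 is covered but has no alternative reads.
    """
    return [
        AlleleCountRecord("chr1", 100, "A", "G", "s2", 20, 4),
        AlleleCountRecord("chr1", 111, "A", "G", "s2", 50, 2),
        AlleleCountRecord("chr1", 107, "A", None, "s2", 30, 0),
    ]


@pytest.fixture
def known_rescue_sites():
    """Known-site list containing site 102 (the rescue) only."""
    return pd.DataFrame(
        {"chrom": ["chr1"], "pos": [102], "ref": ["T"], "alt": ["C"], "strand": ["-"]}
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A 150-site simulated dataset shared by read-only tests."""
    config = SimulationConfig(n_sites=150, seed=11)
    dataset, truth = generate_dataset(config)
    return dataset, truth


@pytest.fixture
def design4x3():
    return lps_design((0, 15, 30, 240), 3, "vessels")
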