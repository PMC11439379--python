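"""Shared fixtures: the study's printed peptides and score-table fixtures."""

from __future__ import annotations

import pytest

from pepscan import ScoreRecord, build_score_table, parse_peptide

# Template peptides as printed: the 26-mer parent, the 24-mer scan parent
# (the ten screened variants are all Hamming-1 from it), and the two
# selected candidates.
ATMP1_26 = "THPPTTTTTTTTTTTTTTTAAPATTT"
PARENT_24 = "THPPTTTTTTTTTTTTTAAPATTT"
ATMP5_SEQ = "THPPTTTTTTTTTTTYTAAPATTT"
ATMP6_SEQ = "THPPTTTTTTTTTTTTTAAPARTT"

# The ten screened 24-mers with their published quarter-convention charges.
TOP10 = [
    ("seq_3541", "THPPTTTTTTTTYTTTTAAPATTT", 0.25),
    ("seq_3577", "THPPTTTTTTTTTYTTTAAPATTT", 0.25),
    ("seq_3628", "THPPTTTTTTTTTHTTTAAPATTT", 0.50),
    ("seq_3668", "THPPTTTTTTTTTTHTTAAPATTT", 0.50),
    ("seq_3690", "THPPTTTTTTTTKTTTTAAPATTT", 1.25),
    ("seq_3712", "THPPTTTTTTTTTKTTTAAPATTT", 1.25),
    ("seq_3738", "THPPTTTTTTTTTTTTTAAPATTK", 1.25),
    ("seq_3760", ATMP5_SEQ, 0.25),  # ATMP5
    ("seq_3785", "THPPTTTTTTTTTTTTTAAPAKTT", 1.25),
    ("seq_3833", ATMP6_SEQ, 1.25),  # ATMP6
]


@pytest.fixture
def top10_rows():
    return TOP10


@pytest.fixture
def atmp5():
    return parse_peptide("ATMP5", ATMP5_SEQ)


@pytest.fixture
def atmp6():
    return parse_peptide("ATMP6", ATMP6_SEQ)


@pytest.fixture
def parent24():
    return parse_peptide("AtMP1_24", PARENT_24)


@pytest.fixture
def top10_peptides():
    return [parse_peptide(pid, seq) for pid, seq, _ in TOP10]


@pytest.fixture
def top10_scores():
    """Published scores transcribed as a fixture: all ten are AMP-positive;
    anticancer scores exist only for the two selected candidates (0.57 and
    0.59); the other eight carry sub-threshold placeholders."""
    records = []
    for pid, _, _ in TOP10:
        if pid == "seq_3760":  # ATMP5
            rec = ScoreRecord(
                id=pid, amp_flag="AMP", amp_probability=0.519,
                anticancer_score=0.57, source="fixture",
            )
        elif pid == "seq_3833":  # ATMP6
            rec = ScoreRecord(
                id=pid, amp_flag="AMP", amp_probability=0.512,
                anticancer_score=0.59, source="fixture",
            )
        else:
            rec = ScoreRecord(
                id=pid, amp_flag="AMP", anticancer_score=0.30, source="fixture",
            )
        records.append(rec)
    return build_score_table(records, source="fixture")
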