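"""Shared fixtures: the two-transcript worked example and a synthetic dataset."""

import pytest

import genoviz as gv
from genoviz.simulate import FixtureSpec, generate_fixture

# Exons of two X-linked transcript isoforms (tx 35775 on +, tx 35778 on -),
# the standard worked example for gene-model plotting.
TX_EXONS = [
    ("chrX", 48242968, 48243005, "+", "35775"),
    ("chrX", 48243475, 48243563, "+", "35775"),
    ("chrX", 48244003, 48244117, "+", "35775"),
    ("chrX", 48244794, 48244889, "+", "35775"),
    ("chrX", 48246753, 48246802, "+", "35775"),
    ("chrX", 48270193, 48270307, "-", "35778"),
    ("chrX", 48269421, 48269516, "-", "35778"),
    ("chrX", 48267508, 48267557, "-", "35778"),
    ("chrX", 48262894, 48262998, "-", "35778"),
    ("chrX", 48261524, 48262111, "-", "35778"),
]


@pytest.fixture
def transcripts():
    return gv.make_range_table(
        [r[:4] for r in TX_EXONS],
        metadata={"tx_id": [r[4] for r in TX_EXONS]},
        group_key="tx_id",
    )


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """One deterministic synthetic dataset shared across the session."""
    out = tmp_path_factory.mktemp("fixture")
    return generate_fixture(FixtureSpec(seed=11), out)


def brute_force_coverage(intervals, lo, hi):
    """Per-base depth oracle over closed intervals within [lo, hi]."""
    depth = [0] * (hi - lo + 1)
    for s, e in intervals:
        for p in range(max(s, lo), min(e, hi) + 1):
            depth[p - lo] += 1
    return depth


def brute_force_union(intervals):
    """Set-of-bases union oracle for merge/gap computations."""
    bases = set()
    for s, e in intervals:
        bases.update(range(s, e + 1))
    return bases
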