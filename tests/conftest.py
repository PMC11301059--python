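import numpy as np
import pytest

from etrace import (
    Alignment,
    GroupedAlignment,
    MSASimConfig,
    PlantedSite,
    Sequence,
    simulate_grouped_msa,
)


def make_grouped(rows_a, rows_b, ref_a=None, ref_b=None):
    """Build a GroupedAlignment from raw residue strings."""
    seqs, group_of = [], {}
    for i, r in enumerate(rows_a):
        sid = f"a{i}"
        seqs.append(Sequence(id=sid, residues=r))
        group_of[sid] = "A"
    for i, r in enumerate(rows_b):
        sid = f"b{i}"
        seqs.append(Sequence(id=sid, residues=r))
        group_of[sid] = "B"
    return GroupedAlignment(
        alignment=Alignment(seqs), group_of=group_of, ref_a=ref_a, ref_b=ref_b
    )


@pytest.fixture(scope="session")
def planted_cfg():
    return MSASimConfig(
        planted_sites=[PlantedSite(column=42, modal_a="A", modal_b="H")], seed=7
    )


@pytest.fixture(scope="session")
def planted_ga(planted_cfg):
    """27 + 24 sequences, 300 columns, one A-vs-H site planted at column 42."""
    ga, truth = simulate_grouped_msa(planted_cfg)
    return ga, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240613)
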