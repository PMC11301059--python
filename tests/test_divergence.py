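"""Per-column compositions, symmetric KL, conservation, site ranking."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from etrace import (
    Sequence,
    Alignment,
    GroupedAlignment,
    conservation,
    conservation_pct,
    kl_symmetric,
    score_all_sites,
    site_composition,
    top_sites,
)
from etrace.errors import CompositionError, EtraceInputError
from conftest import make_grouped

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_kl(p, q):
    """Independent 20-term double sum, plain Python floats."""
    total = 0.0
    for i in range(20):
        total += p[i] * math.log(p[i] / q[i])
        total += q[i] * math.log(q[i] / p[i])
    return total


def random_composition(rng):
    return rng.dirichlet(np.full(20, 0.5))


class TestSiteComposition:
    def test_gap_excluded_counts(self):
        ga = make_grouped(["A", "A", "H", "-"], ["C", "C"])
        comp = site_composition(ga, 1, pseudocount=0.0)
        assert comp.p[AA.index("A")] == pytest.approx(2 / 3)
        assert comp.p[AA.index("H")] == pytest.approx(1 / 3)
        assert comp.count_a == 3
        assert comp.occupancy_a == pytest.approx(0.75)

    def test_pseudocount_formula(self):
        ga = make_grouped(["A"] * 10, ["A"] * 10)
        comp = site_composition(ga, 1, pseudocount=0.5)
        assert comp.p[AA.index("A")] == pytest.approx(10.5 / 20)
        others = np.delete(comp.p, AA.index("A"))
        assert np.allclose(others, 0.025)

    def test_random_column_against_tally_oracle(self, rng):
        letters_a = rng.choice(list(AA + "-X"), size=30)
        letters_b = rng.choice(list(AA + "-X"), size=25)
        ga = make_grouped(list(letters_a), list(letters_b))
        comp = site_composition(ga, 1, pseudocount=0.0)
        tally = Counter(x for x in letters_a if x not in "-X")
        n = sum(tally.values())
        assert comp.count_a == n
        for i, aa in enumerate(AA):
            assert comp.p[i] == pytest.approx(tally.get(aa, 0) / n)
        assert comp.p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_column_flagged(self):
        ga = make_grouped(["-", "-"], ["A", "A"])
        comp = site_composition(ga, 1, pseudocount=0.0)
        assert not comp.evaluable

    def test_column_out_of_range(self):
        ga = make_grouped(["AC", "AC"], ["AC", "AC"])
        with pytest.raises(IndexError):
            site_composition(ga, 3)


class TestKLSymmetric:
    def test_zero_when_equal(self, rng):
        p = random_composition(rng)
        assert kl_symmetric(p, p) == 0.0

    def test_two_conserved_groups(self):
        # 10x Ala vs 10x His with pseudocount 0.5: KL = 2 * 0.5 * ln 21
        ga = make_grouped(["A"] * 10, ["H"] * 10)
        comp = site_composition(ga, 1, pseudocount=0.5)
        assert kl_symmetric(comp.p, comp.q) == pytest.approx(math.log(21), rel=1e-12)

    def test_against_brute_force(self, rng):
        for _ in range(200):
            p, q = random_composition(rng), random_composition(rng)
            kl = kl_symmetric(p, q)
            assert kl == pytest.approx(brute_kl(p, q), abs=1e-12)
            assert kl == kl_symmetric(q, p)
            assert kl >= 0.0

    def test_rejects_zeros(self):
        p = np.zeros(20)
        p[0] = 1.0
        with pytest.raises(CompositionError, match="pseudocount"):
            kl_symmetric(p, p)

    def test_base_rescaling(self, rng):
        p, q = random_composition(rng), random_composition(rng)
        nats = kl_symmetric(p, q)
        bits = kl_symmetric(p, q, base=2)
        assert bits == pytest.approx(nats / math.log(2), rel=1e-12)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(1e-6, 1.0), min_size=20, max_size=20),
        st.lists(st.floats(1e-6, 1.0), min_size=20, max_size=20),
    )
    def test_nonnegative_zero_iff_equal(self, raw_p, raw_q):
        p = np.array(raw_p) / np.sum(raw_p)
        q = np.array(raw_q) / np.sum(raw_q)
        kl = kl_symmetric(p, q)
        assert kl >= 0.0
        gap = float(np.max(np.abs(p - q)))
        if gap < 1e-9:
            assert kl <= 1e-9
        elif gap > 1e-6:
            assert kl > 0.0


class TestConservation:
    def test_fraction_and_percent(self):
        ga = make_grouped(["A"] * 9 + ["S"] * 2, ["A"] * 3)
        modal, frac = conservation(ga, 1, "A")
        assert (modal, frac) == ("A", pytest.approx(9 / 11))
        assert conservation_pct(frac) == 82

    def test_all_identical(self):
        ga = make_grouped(["W"] * 5, ["W"] * 5)
        assert conservation(ga, 1, "A") == ("W", 1.0)
        assert conservation_pct(1.0) == 100

    def test_modal_tie_alphabetical(self):
        ga = make_grouped(["C", "C", "A", "A"], ["A", "A"])
        assert conservation(ga, 1, "A")[0] == "A"

    def test_empty_column_undefined(self):
        ga = make_grouped(["-", "-"], ["A", "A"])
        assert conservation(ga, 1, "A") == (None, None)

    def test_random_column_matches_counter(self, rng):
        letters = list(rng.choice(list(AA + "-X"), size=40))
        ga = make_grouped(letters, ["A", "A"])
        modal, frac = conservation(ga, 1, "A")
        tally = Counter(x for x in letters if x not in "-X")
        best = min(tally.items(), key=lambda kv: (-kv[1], kv[0]))
        assert modal == best[0]
        assert frac == pytest.approx(best[1] / sum(tally.values()))


class TestScoreAllSites:
    def test_identical_alignment_all_zero(self):
        rows = ["ACDEF"] * 4
        ga = make_grouped(rows[:2], rows[2:])
        report = score_all_sites(ga)
        assert all(s.kl == 0.0 for s in report.ranked)
        # ties broken by ascending column: rank order = column order
        assert [s.column for s in report.ranked] == [1, 2, 3, 4, 5]

    def test_planted_site_ranks_first(self, planted_ga):
        ga, truth = planted_ga
        report = score_all_sites(ga)
        assert report.ranked[0].column == truth[0][0] == 42
        assert top_sites(report, 1)[0].column == 42

    def test_reference_coordinates_attached(self, planted_ga):
        ga, _ = planted_ga
        report = score_all_sites(ga)
        top = report.ranked[0]
        ref_row = ga.alignment[ga.ref_a].residues
        expected_a = len(ref_row[:42].replace("-", ""))
        assert top.ref_a_pos == expected_a

    def test_gap_dominated_column_excluded(self):
        ga = make_grouped(
            ["AC", "AC", "AC", "AC"],
            ["A-", "A-", "A-", "AC"],  # column 2: 75% gaps in group B
        )
        report = score_all_sites(ga, min_occupancy=0.5)
        by_col = {s.column: s for s in report.all_sites}
        assert not by_col[2].evaluable
        assert all(s.column != 2 for s in report.ranked)

    def test_log_base_does_not_change_ranking(self, planted_ga):
        ga, _ = planted_ga
        nats = score_all_sites(ga)
        bits = score_all_sites(ga, log_base=2)
        assert [s.column for s in nats.ranked] == [s.column for s in bits.ranked]
        for a, b in zip(nats.ranked, bits.ranked):
            assert b.kl == pytest.approx(a.kl / math.log(2), rel=1e-9)

    def test_permutation_invariance(self, planted_ga, rng):
        ga, _ = planted_ga
        seqs = list(ga.alignment.sequences)
        rng.shuffle(seqs)
        shuffled = GroupedAlignment(
            alignment=Alignment(seqs),
            group_of=ga.group_of,
            ref_a=ga.ref_a,
            ref_b=ga.ref_b,
        )
        a = score_all_sites(ga)
        b = score_all_sites(shuffled)
        assert [(s.column, s.kl) for s in a.ranked] == [
            (s.column, s.kl) for s in b.ranked
        ]

    def test_stronger_difference_never_lowers_rank(self, planted_ga):
        # overwrite one fixed column with progressively larger A-vs-H
        # contrast, holding every other column fixed
        ga, _ = planted_ga
        base_rows = [s.residues for s in ga.alignment.sequences]
        ranks = []
        for freq in (0.3, 0.5, 0.7, 0.9):
            n_a = len(ga.members("A"))
            rows = []
            for i, r in enumerate(base_rows):
                group_n = n_a if i < n_a else len(base_rows) - n_a
                j = i if i < n_a else i - n_a
                modal = "A" if i < n_a else "H"
                letter = modal if j < round(freq * group_n) else "S"
                rows.append(r[:99] + letter + r[100:])
            ga2 = make_grouped(rows[:n_a], rows[n_a:])
            report = score_all_sites(ga2)
            ranks.append(
                next(k for k, s in enumerate(report.ranked) if s.column == 100)
            )
        assert ranks == sorted(ranks, reverse=True)

    def test_top_sites_bounds(self, planted_ga):
        ga, _ = planted_ga
        report = score_all_sites(ga)
        five = top_sites(report, 5)
        assert len(five) == 5
        assert all(five[i].kl >= five[i + 1].kl for i in range(4))
        assert len(top_sites(report, 10_000)) == len(report.ranked)
        with pytest.raises(EtraceInputError):
            top_sites(report, 0)

    def test_runtime_budget(self, planted_ga):
        import time

        ga, _ = planted_ga
        t0 = time.perf_counter()
        score_all_sites(ga)
        assert time.perf_counter() - t0 < 5.0
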