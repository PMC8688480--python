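"""Instrument selection: FDR, cis window, clumping, Steiger, specificity."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from targetmr.instruments import (bh_fdr, cis_window_filter, greedy_clump,
                                  read_snp_gene_map, specificity_filter,
                                  steiger_filter, variance_explained,
                                  write_snp_gene_map)
from targetmr.summary_data import GeneAnnotation

from .conftest import GENE, assoc, make_instruments


def bh_oracle(p):
    """Brute-force step-up definition: q_i = min_{k >= rank(i)} p_(k) * m / k."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    sorted_p = p[order]
    for i in range(m):
        q[order[i]] = min(sorted_p[k] * m / (k + 1) for k in range(i, m))
    return np.minimum(q, 1.0)


class TestBhFdr:
    def test_ties_collapse(self):
        assert np.allclose(bh_fdr([0.03] * 5), 0.03)

    def test_step_up_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.5]),
                           [0.04, 0.04, 0.04, 0.5])

    def test_single_p_identity(self):
        assert bh_fdr([0.2]) == pytest.approx(0.2)

    @pytest.mark.parametrize("bad", [[0.0], [1.1], [-0.5], [np.nan]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_fdr(bad)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 21))
            assert np.allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-9, 1.0, exclude_min=False), min_size=1,
                    max_size=20))
    def test_each_q_at_least_p_and_order_preserved(self, p):
        q = bh_fdr(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)


class TestCisWindow:
    gene = GeneAnnotation("G", "G", "1", 10_000, 20_000)

    @pytest.mark.parametrize("pos,kept", [
        (5_000, True), (4_999, False), (25_000, True), (25_001, False),
        (15_000, True),
    ])
    def test_inclusive_boundaries(self, pos, kept):
        out = cis_window_filter([assoc("rs1", pos=pos)], self.gene, window=5_000)
        assert (len(out) == 1) is kept

    def test_chromosome_mismatch_gives_empty(self):
        out = cis_window_filter([assoc("rs1", pos=15_000, chrom="2")], self.gene)
        assert out == []


class TestGreedyClump:
    def test_independent_set_all_retained(self):
        inst = make_instruments([0.2, 0.3, 0.1], [0.02] * 3, [0.1] * 3,
                                [0.05] * 3, rho=np.eye(3))
        assert len(greedy_clump(inst, 0.2)) == 3

    def test_perfect_proxy_keeps_smaller_p(self):
        rho = np.array([[1.0, 1.0], [1.0, 1.0]])
        inst = make_instruments([0.30, 0.25], [0.02, 0.02], [0.1, 0.1],
                                [0.05, 0.05], rho=rho)
        # rs1 has |z|=15 (p ~ 1e-8-ish smaller), rs2 |z|=12.5
        kept = greedy_clump(inst, 0.2)
        assert kept.variant_ids == ["rs1"]

    def test_three_snp_worked_example(self):
        # s1 (p=1e-8), s2 (p=1e-6, r2 with s1 = 0.5), s3 (p=1e-4, r2 0.05/0.1)
        rho = np.array([
            [1.0, np.sqrt(0.5), np.sqrt(0.05)],
            [np.sqrt(0.5), 1.0, np.sqrt(0.1)],
            [np.sqrt(0.05), np.sqrt(0.1), 1.0],
        ])
        inst = make_instruments([0.3, 0.25, 0.2], [0.02] * 3, [0.1] * 3,
                                [0.05] * 3, rho=rho)
        for v, p in zip(inst.exposure, (1e-8, 1e-6, 1e-4)):
            object.__setattr__(v, "pvalue", p)
        kept = greedy_clump(inst, 0.2)
        assert kept.variant_ids == ["rs1", "rs3"]

    def test_order_invariance_and_contains_min_p(self):
        rng = np.random.default_rng(7)
        J = 6
        from .conftest import ar1
        rho = ar1(J, 0.6)
        bx = rng.uniform(0.05, 0.4, J)
        inst = make_instruments(bx, [0.02] * J, rng.normal(0, 0.1, J),
                                [0.05] * J, rho=rho)
        baseline = greedy_clump(inst, 0.2).variant_ids
        best = min(inst.exposure, key=lambda v: v.pvalue).variant_id
        assert best in baseline
        for perm in itertools.permutations(range(J)):
            ids = [inst.variant_ids[i] for i in perm]
            assert sorted(greedy_clump(inst.subset(ids), 0.2).variant_ids) == \
                sorted(baseline)
            if perm[0] != 0:
                break  # a couple of permutations suffice

    def test_survivors_below_threshold(self):
        from .conftest import ar1
        inst = make_instruments([0.3] * 8, [0.02] * 8, [0.1] * 8, [0.05] * 8,
                                rho=ar1(8, 0.9))
        kept = greedy_clump(inst, 0.2)
        rho2 = kept.ld.rho ** 2
        off = rho2[~np.eye(len(kept), dtype=bool)]
        assert np.all(off < 0.2)


class TestVarianceExplained:
    def test_direct_evaluation(self):
        a = assoc("rs1", beta=0.5, se=0.1, n=1000.0)  # t = 5
        assert variance_explained(a) == pytest.approx(25.0 / 1023.0)

    def test_zero_beta(self):
        assert variance_explained(assoc("rs1", beta=0.0, se=0.1)) == 0.0

    def test_monotone_decreasing_in_n(self):
        r2 = [variance_explained(assoc("rs1", 0.5, 0.1, n=float(n)))
              for n in (100, 1_000, 10_000, 100_000)]
        assert all(a > b for a, b in zip(r2, r2[1:]))

    def test_binary_uses_effective_n(self):
        a = assoc("rs1", 0.5, 0.1, n=None, n_cases=100.0, n_controls=300.0,
                  trait_type="binary")
        n_eff = 4 / (1 / 100 + 1 / 300)
        assert variance_explained(a) == pytest.approx(25 / (25 + n_eff - 2))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            variance_explained(assoc("rs1", n=2.0))


class TestSteiger:
    def _inst(self, bx, by, n_exp=1000.0, n_out=1000.0):
        inst = make_instruments(bx, [0.05] * len(bx), by, [0.05] * len(by))
        for v in inst.exposure:
            object.__setattr__(v, "n", n_exp)
        for v in inst.outcome:
            object.__setattr__(v, "n", n_out)
        return inst

    def test_forward_kept(self):
        res = steiger_filter(self._inst([0.5], [0.05]))
        assert res.keep and res.r2_exposure > res.r2_outcome

    def test_reverse_dropped(self):
        assert not steiger_filter(self._inst([0.05], [0.5])).keep

    def test_tie_drops_gene(self):
        assert not steiger_filter(self._inst([0.3], [0.3])).keep


class TestSpecificity:
    def test_specific_kept_shared_removed(self):
        inst = make_instruments([0.2, 0.3], [0.02] * 2, [0.1] * 2, [0.05] * 2)
        mapping = {"rs1": {"GENE1"}, "rs2": {"GENE1", "GENE2"}}
        assert specificity_filter(inst, mapping).variant_ids == ["rs1"]

    def test_unmapped_removed_and_empty_ok(self):
        inst = make_instruments([0.2], [0.02], [0.1], [0.05])
        assert len(specificity_filter(inst, {})) == 0

    def test_map_round_trip(self, tmp_path):
        mapping = {"rs1": {"A", "B"}, "rs2": {"A"}}
        path = tmp_path / "map.tsv"
        write_snp_gene_map(mapping, path)
        assert read_snp_gene_map(path) == mapping
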