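"""Windows, nucleotide diversity, Weir-Cockerham Fst, and the sweep caller."""

import itertools

import numpy as np
import pandas as pd
import pytest

from teasig.popgen import (
    FST_WINDOWS,
    XPCLR_WINDOWS,
    WindowSpec,
    call_sweep_regions,
    make_windows,
    nearest_rank_quantile,
    site_pi,
    window_fst,
    window_pi,
)
from teasig.tables_io import GroupAssignment

from conftest import build_gm


def anova_fst_components(genotypes_a, genotypes_b):
    """Independent per-site Weir-Cockerham (a, b, c) via the hierarchical
    ANOVA on allele indicators (mean squares), not the frequency formulas."""
    pops = [
        [g for g in genotypes_a if g >= 0],
        [g for g in genotypes_b if g >= 0],
    ]
    n = [len(p) for p in pops]
    r = 2
    nbar = sum(n) / r
    nc = (sum(n) - sum(x * x for x in n) / sum(n)) / (r - 1)
    # individual allele means: 0, 0.5 or 1
    pij = [[g / 2 for g in pop] for pop in pops]
    pi = [sum(p) / len(p) for p in pij]
    pbar = sum(n[i] * pi[i] for i in range(r)) / sum(n)
    ssp = sum(2 * n[i] * (pi[i] - pbar) ** 2 for i in range(r))
    ssi = sum(2 * (pij[i][j] - pi[i]) ** 2 for i in range(r) for j in range(n[i]))
    # within-individual sum of squares: het individual contributes 2*(0.5)^2
    ssg = sum(
        (allele - pij[i][j]) ** 2
        for i in range(r)
        for j, g in enumerate(g for g in pops[i])
        for allele in ([0, 1] if g == 1 else [g / 2, g / 2])
    )
    msp = ssp / (r - 1)
    msi = ssi / (sum(n) - r)
    msg = ssg / sum(n)
    a = (msp - msi) / (2 * nc)
    b = (msi - msg) / 2
    c = msg
    return a, b, c


class TestMakeWindows:
    def test_sliding_windows_hand_enumerated(self):
        win = make_windows({"s": 100_000}, FST_WINDOWS)
        assert win.iloc[0].tolist() == ["s", 0, 100_000]
        assert win.iloc[1].tolist() == ["s", 10_000, 100_000]
        assert len(win) == 10
        assert win.iloc[-1].tolist() == ["s", 90_000, 100_000]

    def test_short_scaffold_truncated(self):
        win = make_windows({"s": 5_000}, XPCLR_WINDOWS)
        assert win.values.tolist() == [["s", 0, 5_000]]

    def test_empty_lengths(self):
        assert len(make_windows({}, WindowSpec(10, 10))) == 0

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            WindowSpec(5, 10)


class TestSitePi:
    def test_monomorphic_is_zero(self):
        assert site_pi(0, 10) == 0.0

    def test_matches_pair_enumeration_all_small_n(self):
        """site_pi equals the fraction of differing allele pairs for n <= 6."""
        for n in range(2, 7):
            for alt in range(n + 1):
                alleles = [1] * alt + [0] * (n - alt)
                pairs = list(itertools.combinations(alleles, 2))
                expected = sum(a != b for a, b in pairs) / len(pairs)
                assert site_pi(alt, n) == pytest.approx(expected), (n, alt)

    def test_single_called_genotype_is_missing(self):
        assert np.isnan(site_pi(1, 1))

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            site_pi(3, 2)


class TestWindowPi:
    def test_empty_window_is_zero_and_division_by_length(self, two_group_assignment):
        # one SNP with 2 alt of 4 alleles in the focal group -> site pi = 2/3
        calls = np.array([[1], [1], [0], [0]], dtype=np.int8)
        gm = build_gm(calls, positions=[5000])
        ga = two_group_assignment(2, 2, labels=("focal", "other"))
        windows = pd.DataFrame(
            {"scaffold": ["scf1", "scf1"], "start": [0, 10_000], "end": [10_000, 20_000]}
        )
        track = window_pi(gm, ga, "focal", windows)
        assert track["value"].iloc[0] == pytest.approx((2 / 3) / 10_000)
        assert track["value"].iloc[1] == 0.0

    def test_doubling_window_length_halves_pi(self, two_group_assignment):
        calls = np.array([[1], [1], [0], [0]], dtype=np.int8)
        gm = build_gm(calls, positions=[5000])
        ga = two_group_assignment(2, 2, labels=("focal", "other"))
        short = pd.DataFrame({"scaffold": ["scf1"], "start": [0], "end": [10_000]})
        long = pd.DataFrame({"scaffold": ["scf1"], "start": [0], "end": [20_000]})
        v_short = window_pi(gm, ga, "focal", short)["value"].iloc[0]
        v_long = window_pi(gm, ga, "focal", long)["value"].iloc[0]
        assert v_long == pytest.approx(v_short / 2)

    def test_bruteforce_recomputation_small_instance(self, two_group_assignment):
        rng = np.random.default_rng(2)
        n_sites = 40
        calls = rng.integers(0, 3, size=(8, n_sites)).astype(np.int8)
        positions = np.sort(rng.choice(np.arange(1, 50_000), n_sites, replace=False))
        gm = build_gm(
            np.vstack([calls, np.zeros((2, n_sites), dtype=np.int8)]),
            positions=positions,
        )
        ga = two_group_assignment(8, 2, labels=("f", "o"))
        windows = make_windows({"scf1": 50_000}, WindowSpec(10_000, 5_000))
        track = window_pi(gm, ga, "f", windows)
        for w, value in zip(windows.itertuples(index=False), track["value"]):
            total = 0.0
            for j in range(n_sites):
                if w.start <= positions[j] - 1 < w.end:
                    alt = int(calls[:, j].sum())
                    total += 2 * (alt / 16) * (1 - alt / 16) * 16 / 15
            assert value == pytest.approx(total / (w.end - w.start))


class TestWindowFst:
    def _window(self, n_sites):
        return pd.DataFrame({"scaffold": ["scf1"], "start": [0], "end": [100 * (n_sites + 1)]})

    def test_fixed_difference_gives_one(self, two_group_assignment):
        calls = np.vstack(
            [np.zeros((5, 3), dtype=np.int8), np.full((5, 3), 2, dtype=np.int8)]
        )
        gm = build_gm(calls)
        track = window_fst(gm, two_group_assignment(5, 5), "pop_a", "pop_b", self._window(3))
        assert track["value"].iloc[0] == pytest.approx(1.0)

    def test_identical_distributions_near_zero(self, two_group_assignment):
        rng = np.random.default_rng(0)
        half = rng.binomial(2, 0.4, size=(20, 50)).astype(np.int8)
        gm = build_gm(np.vstack([half, half]))
        track = window_fst(gm, two_group_assignment(20, 20), "pop_a", "pop_b", self._window(50))
        assert abs(track["value"].iloc[0]) <= 0.05

    def test_three_snp_toy_matches_anova_oracle(self, two_group_assignment):
        """Stated genotypes for 4+4 diploids match the mean-squares oracle."""
        a_geno = np.array([[0, 1, 2], [0, 1, 2], [1, 2, 2], [0, 0, 1]], dtype=np.int8)
        b_geno = np.array([[2, 1, 0], [2, 0, 0], [1, 0, 1], [2, 1, 0]], dtype=np.int8)
        gm = build_gm(np.vstack([a_geno, b_geno]))
        ga = two_group_assignment(4, 4)
        track = window_fst(gm, ga, "pop_a", "pop_b", self._window(3))
        comps = [
            anova_fst_components(a_geno[:, j], b_geno[:, j]) for j in range(3)
        ]
        expected = sum(c[0] for c in comps) / sum(sum(c) for c in comps)
        assert track["value"].iloc[0] == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_sites_match_anova_oracle_with_missing(self, seed, two_group_assignment):
        rng = np.random.default_rng(seed)
        calls = rng.integers(0, 3, size=(12, 8)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.1] = -1
        # keep only sites where both halves retain calls and are polymorphic
        gm = build_gm(calls)
        ga = two_group_assignment(6, 6)
        track = window_fst(gm, ga, "pop_a", "pop_b", self._window(8))
        num = den = 0.0
        for j in range(8):
            a_col, b_col = calls[:6, j], calls[6:, j]
            if (a_col >= 0).sum() == 0 or (b_col >= 0).sum() == 0:
                continue
            a, b, c = anova_fst_components(a_col, b_col)
            num += a
            den += a + b + c
        if den != 0:
            assert track["value"].iloc[0] == pytest.approx(num / den)

    def test_small_group_rejected(self, two_group_assignment):
        gm = build_gm(np.zeros((3, 2), dtype=np.int8))
        ga = two_group_assignment(1, 2)
        with pytest.raises(ValueError, match="2 samples"):
            window_fst(gm, ga, "pop_a", "pop_b", self._window(2))

    def test_hudson_agrees_on_fixed_difference(self, two_group_assignment):
        calls = np.vstack(
            [np.zeros((5, 2), dtype=np.int8), np.full((5, 2), 2, dtype=np.int8)]
        )
        gm = build_gm(calls)
        track = window_fst(
            gm, two_group_assignment(5, 5), "pop_a", "pop_b", self._window(2), estimator="hudson"
        )
        assert track["value"].iloc[0] == pytest.approx(1.0)


def _track(values, size=10_000, scaffold="s"):
    n = len(values)
    return pd.DataFrame(
        {
            "scaffold": [scaffold] * n,
            "start": np.arange(n) * size,
            "end": (np.arange(n) + 1) * size,
            "value": values,
        }
    )


class TestNearestRankQuantile:
    def test_definition(self):
        values = [10, 20, 30, 40, 50]
        assert nearest_rank_quantile(values, 0.5) == 30
        assert nearest_rank_quantile(values, 0.95) == 50
        assert nearest_rank_quantile(values, 0.0) == 10


class TestSweepCaller:
    def test_uniform_scores_merge_into_one_region_per_scaffold(self):
        """All-tied scores select everything (>= convention); the pi filter
        then keeps the top half of regions by ratio."""
        score = pd.concat(
            [_track([5.0] * 10, scaffold="s1"), _track([5.0] * 10, scaffold="s2")],
            ignore_index=True,
        )
        pi_f = pd.concat(
            [_track([0.001] * 10, scaffold="s1"), _track([0.004] * 10, scaffold="s2")],
            ignore_index=True,
        )
        pi_r = pd.concat(
            [_track([0.004] * 10, scaffold="s1"), _track([0.004] * 10, scaffold="s2")],
            ignore_index=True,
        )
        regions = call_sweep_regions(score, pi_f, pi_r)
        # s1 has ratio 4, s2 ratio 1; median interpolates to 2.5 -> keep s1
        assert len(regions) == 1
        assert regions[0].scaffold == "s1"
        assert (regions[0].start, regions[0].end) == (0, 100_000)
        assert regions[0].member_window_count == 10

    def test_planted_run_recovered_among_100_windows(self):
        rng = np.random.default_rng(4)
        scores = rng.gamma(4.0, 1.0, 100)
        scores[40:45] *= 10
        pi_f = 0.003 * np.exp(rng.normal(0, 0.2, 100))
        pi_f[40:45] *= 0.5
        pi_r = 0.003 * np.exp(rng.normal(0, 0.2, 100))
        regions = call_sweep_regions(_track(scores), _track(pi_f), _track(pi_r))
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (400_000, 450_000)
        assert regions[0].member_window_count == 5

    def test_run_without_pi_reduction_removed_at_ratio_step(self):
        """Of two high-score runs, only the one with reduced focal diversity
        survives the pi-ratio filter."""
        rng = np.random.default_rng(8)
        scores = rng.gamma(4.0, 1.0, 500)
        scores[100:105] *= 50
        scores[300:305] *= 50
        pi_f = 0.003 * np.exp(rng.normal(0, 0.2, 500))
        pi_f[100:105] *= 0.3  # genuine sweep signal
        pi_r = 0.003 * np.exp(rng.normal(0, 0.2, 500))
        regions = call_sweep_regions(_track(scores), _track(pi_f), _track(pi_r))
        starts = {r.start for r in regions}
        assert 1_000_000 in starts
        assert 3_000_000 not in starts

    def test_zero_focal_pi_kept_as_infinite_ratio(self):
        scores = np.ones(20)
        scores[5:7] = 100.0
        pi_f = np.full(20, 0.003)
        pi_f[5:7] = 0.0
        pi_r = np.full(20, 0.003)
        regions = call_sweep_regions(_track(scores), _track(pi_f), _track(pi_r))
        assert any(np.isinf(r.pi_ratio) for r in regions)

    @pytest.mark.parametrize("seed", range(5))
    def test_output_invariants(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.gamma(4.0, 1.0, 400)
        pi_f = 0.003 * np.exp(rng.normal(0, 0.2, 400))
        pi_r = 0.003 * np.exp(rng.normal(0, 0.2, 400))
        regions = call_sweep_regions(_track(scores), _track(pi_f), _track(pi_r))
        t5 = nearest_rank_quantile(scores, 0.95)
        t1 = nearest_rank_quantile(scores, 0.99)
        # sorted, non-overlapping
        for r1, r2 in zip(regions, regions[1:]):
            assert (r1.scaffold, r1.start) <= (r2.scaffold, r2.start)
            if r1.scaffold == r2.scaffold:
                assert r1.end <= r2.start
        for r in regions:
            member = scores[r.start // 10_000 : r.end // 10_000]
            assert (member >= t5).all()
            assert r.region_score >= t1
        # never more surviving regions than top-1% windows
        assert len(regions) <= int(np.ceil(0.01 * 400)) + 1

    def test_empty_track_is_an_error(self):
        empty = _track([])
        with pytest.raises(ValueError):
            call_sweep_regions(empty, empty, empty)
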