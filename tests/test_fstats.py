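"""f-statistics against brute-force oracles and identities."""

import numpy as np
import pytest

from bovid_admix import fstats
from bovid_admix.fstats import (BlockPartition, NoDataError, PopulationSpec,
                                allele_freq, block_jackknife, f2_from_freqs,
                                f3_from_freqs, f4_from_freqs,
                                f4_ratio_from_freqs, f4_ratio,
                                outgroup_f3_matrix, spearman_compare)

ONE_BLOCK = BlockPartition(np.zeros(3, dtype=int))


class TestAlleleFreq:
    def test_hand_computed_with_missingness(self, small_dataset, pops):
        matrix = small_dataset[0]
        members = matrix.members_of("yak")[:5]
        spec = PopulationSpec("sub", members)
        freq = allele_freq(spec, matrix)
        raw = matrix.rows(members).astype(float)
        for j in (0, 17, 123):
            col = raw[:, j]
            defined = col >= 0
            if defined.any():
                assert freq[j] == pytest.approx(col[defined].mean())
            else:
                assert freq.mask[j]

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            PopulationSpec("none", [])


class TestFStatOracles:
    def test_f4_hand_example(self):
        r = f4_from_freqs([0.5, 0.2, 0.9], [0.1, 0.4, 0.8],
                          [0.3, 0.6, 0.1], [0.9, 0.1, 0.3], ONE_BLOCK)
        assert r.estimate == pytest.approx(-0.12, abs=1e-12)

    def test_f3_hand_example(self):
        blocks = BlockPartition(np.zeros(2, dtype=int))
        r = f3_from_freqs([0.5, 0.2], [0.1, 0.4], [0.9, 0.1], blocks)
        assert r.estimate == pytest.approx(-0.09, abs=1e-12)

    def test_f2_brute_force(self):
        rng = np.random.default_rng(2)
        a, b = rng.random(20), rng.random(20)
        blocks = BlockPartition(np.arange(20) // 5)
        r = f2_from_freqs(a, b, blocks)
        assert r.estimate == pytest.approx(np.mean((a - b) ** 2), abs=1e-12)

    def test_f2_extremes(self):
        blocks = BlockPartition(np.zeros(2, dtype=int))
        assert f2_from_freqs([1, 0], [0, 1], blocks).estimate == 1.0
        assert f2_from_freqs([0.3, 0.7], [0.3, 0.7],
                             blocks).estimate == 0.0

    def test_f4_identical_pair_zero(self):
        rng = np.random.default_rng(3)
        a, b, c = (rng.random(30) for _ in range(3))
        blocks = BlockPartition(np.arange(30) // 10)
        assert f4_from_freqs(a, b, c, c, blocks).estimate == 0.0

    def test_f4_antisymmetry(self):
        rng = np.random.default_rng(4)
        a, b, c, d = (rng.random(40) for _ in range(4))
        blocks = BlockPartition(np.arange(40) // 8)
        base = f4_from_freqs(a, b, c, d, blocks).estimate
        assert f4_from_freqs(b, a, c, d, blocks).estimate == \
            pytest.approx(-base, abs=1e-15)
        assert f4_from_freqs(a, b, d, c, blocks).estimate == \
            pytest.approx(-base, abs=1e-15)

    def test_f4_additivity(self):
        rng = np.random.default_rng(5)
        a, b, c, d, e = (rng.random(40) for _ in range(5))
        blocks = BlockPartition(np.arange(40) // 8)
        whole = f4_from_freqs(a, b, c, d, blocks).estimate
        part = (f4_from_freqs(a, b, c, e, blocks).estimate
                + f4_from_freqs(a, b, e, d, blocks).estimate)
        assert whole == pytest.approx(part, abs=1e-12)

    def test_f3_symmetry_and_nonnegative_self(self):
        rng = np.random.default_rng(6)
        o, a, b = (rng.random(25) for _ in range(3))
        blocks = BlockPartition(np.arange(25) // 5)
        assert f3_from_freqs(o, a, b, blocks).estimate == \
            f3_from_freqs(o, b, a, blocks).estimate
        assert f3_from_freqs(o, a, a, blocks).estimate >= 0

    def test_zero_usable_sites_raises(self):
        masked = np.ma.masked_all(3)
        with pytest.raises(NoDataError):
            f4_from_freqs(masked, [0.1] * 3, [0.2] * 3, [0.3] * 3, ONE_BLOCK)


class TestBlockJackknife:
    def test_identical_blocks_zero_se(self):
        est, se = block_jackknife(np.full(6, 0.3), np.ones(6))
        assert est == pytest.approx(0.3)
        assert se == pytest.approx(0.0, abs=1e-15)

    def test_equal_weights_classical_closed_form(self):
        # for the mean, delete-one jackknife SE = SD(v, ddof=1)/sqrt(B)
        rng = np.random.default_rng(7)
        v = rng.random(12)
        est, se = block_jackknife(v, np.ones(12))
        assert est == pytest.approx(v.mean(), abs=1e-12)
        assert se == pytest.approx(v.std(ddof=1) / np.sqrt(12), abs=1e-12)

    def test_two_unequal_blocks_hand_computed(self):
        v = np.array([0.2, 0.5])
        w = np.array([10.0, 30.0])
        est, se = block_jackknife(v, w)
        assert est == pytest.approx(0.425)
        # hand weighted leave-one-out: theta_{-1}=0.5, theta_{-2}=0.2
        n, B = 40.0, 2
        loo = np.array([0.5, 0.2])
        h = n / w
        theta_j = B * est - np.sum((1 - w / n) * loo)
        tau = h * est - (h - 1) * loo
        var = np.sum((tau - theta_j) ** 2 / (h - 1)) / B
        assert se == pytest.approx(np.sqrt(var), abs=1e-12)

    def test_single_block_rejected(self):
        with pytest.raises(NoDataError):
            block_jackknife(np.array([0.1]), np.array([5.0]))


class TestF4Ratio:
    def _freq_level(self, alpha, n=4000, seed=0):
        from bovid_admix.simulate import DemographyConfig, AdmixtureEvent, \
            simulate_frequencies
        cfg = DemographyConfig()
        cfg.admixture_events = [AdmixtureEvent(
            "X", "european_aurochs", "anatolian_domestic", alpha)]
        freqs = simulate_frequencies(cfg, n, seed=seed)
        blocks = BlockPartition(np.arange(n) // 100)
        return freqs, blocks

    def test_alpha_zero_exact_for_domestic_target(self):
        freqs, blocks = self._freq_level(0.0)
        r = f4_ratio_from_freqs(freqs["anatolian_domestic"],
                                freqs["european_aurochs"],
                                freqs["anatolian_domestic"],
                                freqs["caucasus_aurochs"], freqs["yak"],
                                blocks)
        assert r.estimate == pytest.approx(0.0, abs=1e-12)

    def test_alpha_one_exact_for_wild_target(self):
        freqs, blocks = self._freq_level(1.0)
        r = f4_ratio_from_freqs(freqs["european_aurochs"],
                                freqs["european_aurochs"],
                                freqs["anatolian_domestic"],
                                freqs["caucasus_aurochs"], freqs["yak"],
                                blocks)
        assert r.estimate == pytest.approx(1.0, abs=1e-12)

    def test_frequency_level_recovery(self):
        freqs, blocks = self._freq_level(0.3, n=100_000, seed=9)
        r = f4_ratio_from_freqs(freqs["X"], freqs["european_aurochs"],
                                freqs["anatolian_domestic"],
                                freqs["caucasus_aurochs"], freqs["yak"],
                                blocks)
        assert r.estimate == pytest.approx(0.3, abs=1e-2)

    def test_degenerate_denominator_raises(self):
        blocks = BlockPartition(np.zeros(4, dtype=int))
        p = np.array([0.4, 0.5, 0.6, 0.7])
        with pytest.raises(ZeroDivisionError):
            f4_ratio_from_freqs(p, p + 0.1, p + 0.1, p, p, blocks)

    def test_population_interface_matches_freq_interface(self, small_dataset,
                                                         pops):
        matrix, blocks = small_dataset[0], small_dataset[1]
        r1 = f4_ratio(pops(matrix, "target"),
                      pops(matrix, "european_aurochs"),
                      pops(matrix, "anatolian_domestic"),
                      pops(matrix, "caucasus_aurochs"), pops(matrix, "yak"),
                      matrix, blocks)
        r2 = f4_ratio_from_freqs(
            allele_freq(pops(matrix, "target"), matrix),
            allele_freq(pops(matrix, "european_aurochs"), matrix),
            allele_freq(pops(matrix, "anatolian_domestic"), matrix),
            allele_freq(pops(matrix, "caucasus_aurochs"), matrix),
            allele_freq(pops(matrix, "yak"), matrix), blocks)
        assert r1.estimate == r2.estimate
        assert r1.se == r2.se


class TestOutgroupF3AndProfiles:
    def test_matrix_symmetric_and_consistent(self, small_dataset, pops):
        matrix, blocks = small_dataset[0], small_dataset[1]
        plist = [pops(matrix, g) for g in
                 ("european_aurochs", "anatolian_domestic",
                  "caucasus_aurochs")]
        labels, f3m = outgroup_f3_matrix(plist, pops(matrix, "yak"), matrix,
                                         blocks)
        assert np.array_equal(f3m, f3m.T)
        direct = fstats.f3(pops(matrix, "yak"), plist[0], plist[1], matrix,
                           blocks)
        assert f3m[0, 1] == direct.estimate

    def test_nearest_neighbours_match_tree_cherries(self, small_dataset,
                                                    pops):
        # caucasus and european aurochs are sisters: their pairwise f3
        # (shared drift) exceeds each one's f3 with the domestic lineage
        matrix, blocks = small_dataset[0], small_dataset[1]
        plist = [pops(matrix, g) for g in
                 ("caucasus_aurochs", "european_aurochs",
                  "anatolian_domestic", "indicine")]
        _, f3m = outgroup_f3_matrix(plist, pops(matrix, "yak"), matrix,
                                    blocks)
        assert f3m[0, 1] > f3m[0, 2] > f3m[0, 3]

    def test_f4_profile_tracks_alpha(self, pops):
        from bovid_admix.simulate import simulate_dataset
        targets = [(f"t{i}", a, None)
                   for i, a in enumerate(np.linspace(0, 1, 8))]
        matrix, blocks, truth, _ = simulate_dataset(targets, n_sites=8000,
                                                    seed=31)
        prof = [fstats.f4_profile(pops(matrix, t),
                                  pops(matrix, "european_aurochs"),
                                  pops(matrix, "anatolian_domestic"),
                                  pops(matrix, "yak"), matrix,
                                  blocks).estimate
                for t, _, _ in targets]
        rho, _ = spearman_compare(prof, [a for _, a, _ in targets])
        assert rho > 0.9

    def test_f4_profile_positive_for_wild_reference(self, small_dataset,
                                                    pops):
        matrix, blocks = small_dataset[0], small_dataset[1]
        res = fstats.f4_profile(pops(matrix, "european_aurochs"),
                                pops(matrix, "european_aurochs"),
                                pops(matrix, "anatolian_domestic"),
                                pops(matrix, "yak"), matrix, blocks)
        assert res.estimate > 0


class TestSpearman:
    def test_identical_and_reversed(self):
        x = [1.0, 2.0, 5.0, 3.0]
        assert spearman_compare(x, x)[0] == pytest.approx(1.0)
        assert spearman_compare(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson(self):
        rng = np.random.default_rng(12)
        a, b = rng.random(10), rng.random(10)
        rho, _ = spearman_compare(a, b)
        ra = np.argsort(np.argsort(a)).astype(float)
        rb = np.argsort(np.argsort(b)).astype(float)
        assert rho == pytest.approx(np.corrcoef(ra, rb)[0, 1], abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_compare([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
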