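"""The drift-tree generator against its closed-form moments."""

import numpy as np
import pytest
from scipy.integrate import quad

from bovid_admix.fstats import BlockPartition, f2_from_freqs, f4_from_freqs
from bovid_admix.simulate import (AdmixtureEvent, DemographyConfig,
                                  ReadSimConfig, calls_from_read_table,
                                  make_fixture, random_panel,
                                  simulate_dataset, simulate_frequencies,
                                  simulate_individuals, simulate_reads)


class TestFrequencies:
    def test_zero_drift_copies_ancestor(self):
        cfg = DemographyConfig(branches={"a": ("root", 0.0),
                                         "b": ("a", 0.0)})
        freqs = simulate_frequencies(cfg, 100, seed=1)
        assert np.array_equal(freqs["a"], freqs["b"])

    def test_alpha_one_copies_source(self):
        cfg = DemographyConfig()
        cfg.admixture_events = [AdmixtureEvent(
            "X", "european_aurochs", "anatolian_domestic", 1.0)]
        freqs = simulate_frequencies(cfg, 200, seed=2)
        assert np.array_equal(freqs["X"], freqs["european_aurochs"])

    def test_invalid_drift_rejected(self):
        with pytest.raises(ValueError):
            DemographyConfig(branches={"a": ("root", 1.0)})

    def test_sister_f2_matches_integrated_theory(self):
        # E[f2(A,B)] = (F1 + F2) * E[p(1-p)] under Balding-Nichols with
        # independent sister branches; E over the Uniform(0.05, 0.95)
        # ancestral distribution by numerical integration
        F1, F2 = 0.07, 0.12
        cfg = DemographyConfig(branches={"a": ("root", F1),
                                         "b": ("root", F2)})
        n = 50_000
        freqs = simulate_frequencies(cfg, n, seed=3)
        terms = (freqs["a"] - freqs["b"]) ** 2
        het, _ = quad(lambda p: p * (1 - p) / 0.9, 0.05, 0.95)
        theory = (F1 + F2) * het
        mc_se = terms.std() / np.sqrt(n)
        assert abs(terms.mean() - theory) < 3 * mc_se

    def test_x_chromosome_uses_alpha_x(self):
        cfg = DemographyConfig()
        cfg.admixture_events = [AdmixtureEvent(
            "X", "european_aurochs", "anatolian_domestic", 0.8, 0.2)]
        fa = simulate_frequencies(cfg, 50, seed=4)
        fx = simulate_frequencies(cfg, 50, seed=4, chromosome="X")
        expect_auto = (0.8 * fa["european_aurochs"]
                       + 0.2 * fa["anatolian_domestic"])
        expect_x = (0.2 * fx["european_aurochs"]
                    + 0.8 * fx["anatolian_domestic"])
        assert np.allclose(fa["X"], expect_auto)
        assert np.allclose(fx["X"], expect_x)


class TestIndividuals:
    def test_fixed_frequencies(self):
        zeros = simulate_individuals(np.zeros(50), 2, 4, seed=0)
        ones = simulate_individuals(np.ones(50), 2, 4, seed=0)
        assert (zeros == 0).all()
        assert (ones == 2).all()

    def test_heterozygosity_at_half(self):
        g = simulate_individuals(np.full(10_000, 0.5), 2, 1, seed=5)[0]
        het = float(np.mean(g == 1))
        bound = 2.576 * np.sqrt(0.5 * 0.5 / 10_000)
        assert abs(het - 0.5) < bound


class TestReads:
    def test_zero_depth_no_reads(self):
        panel = random_panel(100, seed=0)
        g = np.zeros(100, dtype=np.int8)
        reads = simulate_reads(g, panel, ReadSimConfig(mean_depth=0.0),
                               seed=1)
        assert reads.site_idx.size == 0

    def test_noise_free_reads_match_genotype(self):
        panel = random_panel(500, seed=1)
        g = simulate_individuals(np.full(500, 0.5), 2, 1, seed=2)[0]
        reads = simulate_reads(g, panel, ReadSimConfig(
            mean_depth=3.0, error_rate=0.0, damage_p0=0.0), seed=3)
        ref_i = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b]
                          for b in panel.ref])
        alt_i = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b]
                          for b in panel.alt])
        hom_ref = g[reads.site_idx] == 0
        hom_alt = g[reads.site_idx] == 2
        assert (reads.base[hom_ref] == ref_i[reads.site_idx][hom_ref]).all()
        assert (reads.base[hom_alt] == alt_i[reads.site_idx][hom_alt]).all()

    def test_damage_rate_at_5p_terminus(self):
        # C sites only; damage amplitude 0.3 at offset 0
        from bovid_admix.genotypes import SnpRecord, SnpPanel
        panel = SnpPanel([SnpRecord("1", 10 * (i + 1), "C", "A")
                          for i in range(30_000)])
        g = np.zeros(30_000, dtype=np.int8)  # all homozygous C
        cfg = ReadSimConfig(mean_depth=2.0, error_rate=0.0, damage_p0=0.3,
                            damage_decay=0.5)
        reads = simulate_reads(g, panel, cfg, seed=7)
        at0 = reads.off5 == 0
        # far from the 3' end so mirrored G->A cannot interfere (it cannot
        # anyway: these reads are all C or damaged T)
        rate = float(np.mean(reads.base[at0] == 3))
        n = int(at0.sum())
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(rate - 0.3) < 3 * se

    def test_rescaled_calls_drop_damaged_terminal_ts(self):
        from bovid_admix.genotypes import SnpRecord, SnpPanel
        panel = SnpPanel([SnpRecord("1", 10 * (i + 1), "C", "T")
                          for i in range(5000)])
        g = np.zeros(5000, dtype=np.int8)
        cfg = ReadSimConfig(mean_depth=1.5, error_rate=0.0, damage_p0=0.5,
                            damage_decay=0.3)
        reads = simulate_reads(g, panel, cfg, seed=8)
        rescaled = calls_from_read_table(reads, panel, seed=1,
                                         rescale_ends=5)
        raw = calls_from_read_table(reads, panel, seed=1, rescale_ends=0)
        # truth is all-ref; damage creates false alt calls, rescaling
        # removes the terminal ones
        false_rescaled = float(np.mean(rescaled == 1))
        false_raw = float(np.mean(raw == 1))
        assert false_rescaled < false_raw


class TestOutgroupF4Null:
    def test_f4_zero_when_pair_separated_by_root(self):
        # (A, B) below the root on one side, outgroups on the other: the
        # paths share no branch, so E[f4] = 0
        cfg = DemographyConfig()
        devs = []
        for rep in range(50):
            freqs = simulate_frequencies(cfg, 2000, seed=600 + rep)
            blocks = BlockPartition(np.arange(2000) // 100)
            r = f4_from_freqs(freqs["yak"], freqs["bison"],
                              freqs["european_aurochs"],
                              freqs["anatolian_domestic"], blocks)
            devs.append(r.estimate)
        devs = np.array(devs)
        assert abs(devs.mean()) < 3 * devs.std(ddof=1) / np.sqrt(50)


class TestFixtures:
    def test_unknown_scenario_lists_available(self, tmp_path):
        with pytest.raises(ValueError, match="iberia_timeline"):
            make_fixture("nope", str(tmp_path), seed=0)

    def test_fixture_deterministic(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        make_fixture("iberia_timeline", str(d1), seed=4, n_sites=400)
        make_fixture("iberia_timeline", str(d2), seed=4, n_sites=400)
        for name in ("iberia_timeline.geno", "iberia_timeline.snp",
                     "iberia_timeline.ind", "iberia_timeline_truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_timeline_truth_lists_eleven_targets(self, tmp_path):
        truth = make_fixture("iberia_timeline", str(tmp_path), seed=1,
                             n_sites=300)
        assert len(truth["targets"]) == 11
        alphas = sorted(v["alpha"] for v in truth["targets"].values())
        assert alphas == [round(i / 10, 1) for i in range(11)]

    def test_end_to_end_recovery(self, pops):
        from bovid_admix.fstats import f4_ratio
        targets = [(f"t{i}", a, None)
                   for i, a in enumerate((0.0, 0.3, 0.7, 1.0))]
        matrix, blocks, truth, _ = simulate_dataset(targets, n_sites=20_000,
                                                    seed=55)
        errs = []
        for name, alpha, _ in targets:
            r = f4_ratio(pops(matrix, name),
                         pops(matrix, "european_aurochs"),
                         pops(matrix, "anatolian_domestic"),
                         pops(matrix, "caucasus_aurochs"),
                         pops(matrix, "yak"), matrix, blocks)
            errs.append(abs(r.estimate - alpha))
        assert np.mean(errs) < 0.03
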