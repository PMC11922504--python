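"""Panel filtering, damage rescaling, pseudohaploid calling and I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bovid_admix import genotypes as gt
from bovid_admix.genotypes import (AlignedFragment, Observation, SitePile,
                                   SnpPanel, SnpRecord, build_genotype_matrix,
                                   filter_panel, pseudohaploid_call,
                                   read_eigenstrat, read_pileup,
                                   rescale_damage, transversions_only,
                                   write_eigenstrat)


class TestPanel:
    def test_maf_threshold_retains_and_drops(self):
        sites = [("1", 100, "A", "G", 75, 25),   # MAF 0.25 -> kept
                 ("1", 200, "A", "C", 100, 0),   # monomorphic -> dropped
                 ("1", 300, "C", "G", 95, 5)]    # MAF 0.05 -> dropped
        panel = filter_panel(sites, maf_min=0.10)
        assert [(r.chrom, r.pos) for r in panel] == [("1", 100)]
        assert panel[0].maf == 0.25

    def test_retained_count_matches_direct_scan(self):
        rng = np.random.default_rng(5)
        mafs = rng.uniform(0, 0.5, 100)
        sites = [("1", 10 * (i + 1), "A", "C", int(1000 * (1 - m)),
                  int(1000 * m)) for i, m in enumerate(mafs)]
        panel = filter_panel(sites, maf_min=0.10)
        expected = sum(min(int(1000 * (1 - m)), int(1000 * m))
                       / (int(1000 * (1 - m)) + int(1000 * m)) >= 0.10
                       for m in mafs)
        assert len(panel) == expected

    def test_unsorted_input_rejected(self):
        sites = [("1", 200, "A", "C", 50, 50), ("1", 100, "A", "C", 50, 50)]
        with pytest.raises(gt.PanelError, match="1:100"):
            filter_panel(sites)

    def test_duplicate_position_rejected(self):
        with pytest.raises(gt.PanelError):
            SnpPanel([SnpRecord("1", 5, "A", "C"), SnpRecord("1", 5, "A", "G")])

    def test_transversions_complement_transitions(self):
        rng = np.random.default_rng(9)
        pairs = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "C"), ("T", "A"),
                 ("G", "T")]
        records = [SnpRecord("1", 10 * (i + 1), *pairs[rng.integers(6)])
                   for i in range(50)]
        panel = SnpPanel(records)
        tv = transversions_only(panel)
        expected = [r for r in records
                    if frozenset((r.ref_allele, r.alt_allele))
                    not in (frozenset("CT"), frozenset("AG"))]
        assert [(r.chrom, r.pos) for r in tv] == \
            [(r.chrom, r.pos) for r in expected]
        assert len(tv) + int(panel.transition_mask.sum()) == len(panel)


class TestRescaleDamage:
    def test_terminal_t_floored(self):
        frag = AlignedFragment("G" * 2 + "T" + "G" * 37, tuple([37] * 40))
        out = rescale_damage(frag)
        assert out.quals[2] == 2
        assert all(q == 37 for i, q in enumerate(out.quals) if i != 2)

    def test_interior_t_untouched(self):
        frag = AlignedFragment("G" * 7 + "T" + "G" * 32, tuple([37] * 40))
        assert rescale_damage(frag).quals[7] == 37

    def test_terminal_a_floored_at_3p(self):
        frag = AlignedFragment("G" * 39 + "A", tuple([41] * 40))
        assert rescale_damage(frag).quals[39] == 2

    @given(st.text(alphabet="ACGT", min_size=1, max_size=60), st.data())
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, bases, data):
        quals = tuple(data.draw(st.integers(0, 45))
                      for _ in range(len(bases)))
        frag = AlignedFragment(bases, quals)
        once = rescale_damage(frag)
        assert rescale_damage(once) == once

    def test_short_fragment_both_windows(self):
        # a T inside both windows is floored regardless of 3' proximity
        frag = AlignedFragment("TTT", (30, 30, 30))
        assert rescale_damage(frag).quals == (2, 2, 2)


class TestPseudohaploidCall:
    SNP = SnpRecord("1", 100, "A", "G")

    def test_single_eligible_read_forces_draw(self):
        pile = SitePile("1", 100, [Observation("A", 37, 60),
                                   Observation("G", 12, 60)])
        rng = np.random.default_rng(0)
        assert pseudohaploid_call(pile, self.SNP, rng=rng) == 0

    def test_third_allele_removes_site(self):
        pile = SitePile("1", 100, [Observation("C", 40, 60)])
        assert pseudohaploid_call(pile, self.SNP,
                                  rng=np.random.default_rng(0)) == \
            gt.CALL_SITE_REMOVED

    def test_empty_pile_missing(self):
        assert pseudohaploid_call(SitePile("1", 100, []), self.SNP,
                                  rng=np.random.default_rng(0)) == \
            gt.CALL_MISSING

    def test_identical_bases_deterministic_across_seeds(self):
        pile = SitePile("1", 100, [Observation("G", 40, 60)] * 5)
        calls = {pseudohaploid_call(pile, self.SNP,
                                    rng=np.random.default_rng(s))
                 for s in range(20)}
        assert calls == {1}

    def test_draw_frequencies_uniform(self):
        # 2 ref reads + 1 alt read: P(alt) = 1/3; check against binomial
        # 99% bounds around the exact multinomial expectation
        pile = SitePile("1", 100, [Observation("A", 40, 60),
                                   Observation("A", 40, 60),
                                   Observation("G", 40, 60)])
        rng = np.random.default_rng(42)
        n = 3000
        alt = sum(pseudohaploid_call(pile, self.SNP, rng=rng) == 1
                  for _ in range(n))
        p = 1 / 3
        bound = 2.576 * np.sqrt(p * (1 - p) / n)
        assert abs(alt / n - p) < bound


class TestBuildMatrix:
    def _piles(self, bases_by_ind, panel):
        piles = {}
        for ind, per_site in bases_by_ind.items():
            piles[ind] = {
                (panel[j].chrom, panel[j].pos): SitePile(
                    panel[j].chrom, panel[j].pos,
                    [Observation(b, 40, 60) for b in bases])
                for j, bases in per_site.items()}
        return piles

    @pytest.fixture
    def panel(self):
        return SnpPanel([SnpRecord("1", 10 * (i + 1), "A", "G")
                         for i in range(5)])

    def test_seeded_determinism(self, panel):
        piles = self._piles({"s1": {0: "AG", 2: "GG"},
                             "s2": {1: "AA", 3: "AG"}}, panel)
        m1 = build_genotype_matrix(piles, panel, seed=7)
        m2 = build_genotype_matrix(piles, panel, seed=7)
        assert np.array_equal(m1.calls, m2.calls)

    def test_all_empty_piles_all_missing(self, panel):
        piles = {"s1": {}}
        m = build_genotype_matrix(piles, panel, seed=1)
        assert (m.row("s1") == gt.CALL_MISSING).all()

    def test_adding_individual_preserves_existing_calls(self, panel):
        base = self._piles({"s1": {0: "AG", 1: "AGAG", 2: "GG"}}, panel)
        extended = self._piles({"s1": {0: "AG", 1: "AGAG", 2: "GG"},
                                "zz": {0: "AA"}}, panel)
        m1 = build_genotype_matrix(base, panel, seed=3)
        m2 = build_genotype_matrix(extended, panel, seed=3)
        assert np.array_equal(m1.row("s1"), m2.row("s1"))

    def test_global_site_removal(self, panel):
        piles = self._piles({"s1": {0: "C"}, "s2": {0: "AA", 1: "GG"}}, panel)
        m = build_genotype_matrix(piles, panel, seed=0,
                                  drop_sites_globally=True)
        assert len(m.panel) == 4
        assert ("1", 10) not in m.panel

    def test_unknown_position_rejected(self, panel):
        piles = {"s1": {("1", 999): SitePile("1", 999, [])}}
        with pytest.raises(gt.PanelError, match="999"):
            build_genotype_matrix(piles, panel, seed=0)


class TestIO:
    def test_eigenstrat_round_trip(self, tmp_path, small_dataset):
        matrix = small_dataset[0]
        sub = matrix.subset_sites(np.arange(50))
        prefix = str(tmp_path / "rt")
        write_eigenstrat(sub, prefix)
        back = read_eigenstrat(prefix)
        assert back.individuals == sub.individuals
        assert np.array_equal(back.calls, sub.calls)
        assert [(r.chrom, r.pos) for r in back.panel] == \
            [(r.chrom, r.pos) for r in sub.panel]

    def test_geno_missing_convention(self, tmp_path):
        panel = SnpPanel([SnpRecord("1", 10 * (i + 1), "A", "G")
                          for i in range(4)])
        calls = np.array([[0, -1, 1, -1]], dtype=np.int8)
        m = gt.GenotypeMatrix(["s1"], ["g"], panel, calls)
        prefix = str(tmp_path / "conv")
        write_eigenstrat(m, prefix)
        rows = open(prefix + ".geno").read().split()
        assert rows == ["2", "9", "0", "9"]
        back = read_eigenstrat(prefix)
        assert list(back.calls[0]) == [0, -1, 1, -1]

    def test_pileup_phred_decoding(self, tmp_path):
        path = tmp_path / "x.pileup"
        path.write_text("1\t100\tA\t3\t.Gt\tII5\n")
        piles = read_pileup(str(path))
        obs = piles[("1", 100)].observations
        assert [o.base for o in obs] == ["A", "G", "T"]
        assert [o.base_quality for o in obs] == [40, 40, 20]

    def test_pileup_skips_read_markers(self, tmp_path):
        path = tmp_path / "x.pileup"
        path.write_text("1\t5\tC\t2\t^I.,$\tAB\n")
        obs = read_pileup(str(path))[("1", 5)].observations
        assert [o.base for o in obs] == ["C", "C"]

    def test_vcf_reader(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=1,length=1000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "1\t100\t.\tA\tG\t.\t.\t.\tGT\t0\t1\n"
            "1\t200\t.\tC\tT\t.\t.\t.\tGT\t1\t./.\n")
        m = gt.read_vcf(str(vcf))
        assert m.individuals == ["s1", "s2"]
        assert list(m.row("s1")) == [0, 1]
        assert list(m.row("s2")) == [1, -1]
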