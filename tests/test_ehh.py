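import numpy as np
import pytest
from scipy.stats import norm

from sweepkit.ehh import (AncestralAssignment, assign_ancestral_major,
                          assign_ancestral_random, consistency_check,
                          ehh_curve, ehhs_curve, ihs_scan, integrate_ihh,
                          p_transform, rsb_scan)
from sweepkit.types import HaplotypeSet

from conftest import random_haplotypes, uniform_map
from oracles import ehh_oracle, ehhs_oracle


class TestAncestralAssignment:
    def test_major_allele_selected(self):
        anc = assign_ancestral_major([0.7])
        assert anc.alleles[0] == 1

    def test_tie_breaks_to_zero(self):
        anc = assign_ancestral_major([0.5])
        assert anc.alleles[0] == 0

    def test_three_snp_rule(self):
        anc = assign_ancestral_major([0.2, 0.8, 0.5])
        assert list(anc.alleles) == [0, 1, 0]

    def test_random_reproducible(self):
        a = assign_ancestral_random(100, seed=7)
        b = assign_ancestral_random(100, seed=7)
        np.testing.assert_array_equal(a.alleles, b.alleles)
        assert a.provenance == "random" and a.seed == 7

    def test_two_seeds_differ_about_half(self):
        a = assign_ancestral_random(1000, seed=1)
        b = assign_ancestral_random(1000, seed=2)
        frac = (a.alleles != b.alleles).mean()
        assert 0.45 < frac < 0.55  # ~3 binomial sd around 0.5

    def test_empty(self):
        assert len(assign_ancestral_random(0, seed=0)) == 0


class TestEhhCurve:
    def test_identical_carriers_ehh_one_everywhere(self):
        H = HaplotypeSet(np.tile([1, 0, 1, 1, 0], (4, 1)).astype(np.int8))
        c = ehh_curve(H, core=2, allele=1, cutoff=0.0)
        assert (c.values() == 1.0).all()
        assert len(c.left_idx) == 3 and len(c.right_idx) == 3

    def test_two_two_split_gives_one_third(self):
        # 4 carriers of allele 1 at core 0; adjacent marker splits 2/2
        H = HaplotypeSet(np.array([[1, 0], [1, 0], [1, 1], [1, 1]],
                                  dtype=np.int8))
        c = ehh_curve(H, core=0, allele=1, cutoff=0.0)
        assert c.right_ehh[1] == pytest.approx(1 / 3)  # (C(2,2)*2)/C(4,2)

    def test_core_value_is_one(self):
        rng = np.random.default_rng(0)
        H = random_haplotypes(rng, 4, 6)
        c = ehh_curve(H, core=3, allele=int(H.values[0, 3]), cutoff=0.0)
        assert c.left_ehh[0] == 1.0 and c.right_ehh[0] == 1.0

    def test_fewer_than_two_carriers_undefined(self):
        H = HaplotypeSet(np.array([[1, 0], [0, 0], [0, 1], [0, 1]],
                                  dtype=np.int8))
        assert ehh_curve(H, core=0, allele=1) is None

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            H = random_haplotypes(rng, 4, 6)  # 8 copies x 6 SNPs
            for core in range(6):
                for allele in (0, 1):
                    c = ehh_curve(H, core, allele, cutoff=0.0)
                    if c is None:
                        assert (H.values[:, core] == allele).sum() < 2
                        continue
                    for idx, vals in ((c.left_idx, c.left_ehh),
                                      (c.right_idx, c.right_ehh)):
                        for t, v in zip(idx, vals):
                            assert v == ehh_oracle(H.values, core, allele, t)

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            H = random_haplotypes(rng, 6, 10)
            c = ehh_curve(H, core=5, allele=0, cutoff=0.0)
            if c is None:
                continue
            assert (np.diff(c.left_ehh) <= 1e-12).all()
            assert (np.diff(c.right_ehh) <= 1e-12).all()

    def test_stops_after_cutoff(self):
        rng = np.random.default_rng(13)
        H = random_haplotypes(rng, 10, 20)
        c = ehh_curve(H, core=10, allele=0, cutoff=0.3)
        assert (c.left_ehh >= 0.3).all() and (c.right_ehh >= 0.3).all()

    def test_bounds_respected(self):
        H = HaplotypeSet(np.ones((4, 10), dtype=np.int8))
        c = ehh_curve(H, core=5, allele=1, cutoff=0.0, bounds=(3, 7))
        assert c.left_idx.min() == 3 and c.right_idx.max() == 7
        assert c.truncated_left and c.truncated_right


class TestEhhsCurve:
    def test_monomorphic_window_is_one(self):
        H = HaplotypeSet(np.ones((6, 5), dtype=np.int8))
        c = ehhs_curve(H, core=2, cutoff=0.0)
        assert (c.values() == 1.0).all()

    def test_hand_partition_three_one(self):
        # core counts 3/1 (n=4): H(core) = 3/6; adjacent splits the
        # 3-class into 2/1: H(t) = 1/6 -> EHHS = 1/3
        H = HaplotypeSet(np.array([[1, 0], [1, 0], [1, 1], [0, 0]],
                                  dtype=np.int8))
        c = ehhs_curve(H, core=0, cutoff=0.0)
        assert c.right_ehh[1] == pytest.approx(1 / 3)

    def test_core_normalized_to_one(self):
        rng = np.random.default_rng(1)
        H = random_haplotypes(rng, 5, 8)
        c = ehhs_curve(H, core=4, cutoff=0.0)
        assert c.left_ehh[0] == 1.0 and c.right_ehh[0] == 1.0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(14)
        for _ in range(30):
            H = random_haplotypes(rng, 4, 6)
            for core in range(6):
                c = ehhs_curve(H, core, cutoff=0.0)
                if c is None:
                    continue
                for idx, vals in ((c.left_idx, c.left_ehh),
                                  (c.right_idx, c.right_ehh)):
                    for t, v in zip(idx, vals):
                        assert v == pytest.approx(
                            ehhs_oracle(H.values, core, t), abs=1e-12)


class TestIntegration:
    def test_rectangle(self):
        # EHH == 1 over 10,000 bp each side -> total 20,000
        H = HaplotypeSet(np.ones((4, 21), dtype=np.int8))
        mm = uniform_map(21, step=1000)
        c = ehh_curve(H, core=10, allele=1, cutoff=0.0)
        assert integrate_ihh(c, mm) == pytest.approx(20000.0)

    def test_two_point_trapezoid(self):
        from sweepkit.ehh import EhhCurve
        mm = uniform_map(2, step=1000, start=1000)
        c = EhhCurve(core=0, allele_class="1",
                     left_idx=np.array([0]), left_ehh=np.array([1.0]),
                     right_idx=np.array([0, 1]),
                     right_ehh=np.array([1.0, 0.5]))
        assert integrate_ihh(c, mm) == pytest.approx(750.0)

    def test_core_only_curve_integrates_to_zero(self):
        from sweepkit.ehh import EhhCurve
        mm = uniform_map(3)
        c = EhhCurve(core=1, allele_class="1",
                     left_idx=np.array([1]), left_ehh=np.array([1.0]),
                     right_idx=np.array([1]), right_ehh=np.array([1.0]))
        assert integrate_ihh(c, mm) == 0.0


class TestPTransform:
    def test_zero_maps_to_zero(self):
        assert p_transform(np.array([0.0]))[0] == 0.0

    def test_threshold_four_is_tail_1e4(self):
        # find v with transformed value 4.0; its two-sided tail must be 1e-4
        v = norm.isf(0.5e-4)
        assert p_transform(np.array([v]))[0] == pytest.approx(4.0, abs=1e-10)

    def test_symmetry(self):
        v = np.linspace(-5, 5, 41)
        np.testing.assert_allclose(p_transform(v), p_transform(-v), atol=1e-12)

    def test_monotone_in_absolute_value(self):
        v = np.linspace(0, 8, 100)
        out = p_transform(v)
        assert (np.diff(out) > 0).all()
        assert (out >= 0).all()

    def test_one_sided_literal_form(self):
        v = np.array([2.0])
        expected = -np.log10(2 * norm.sf(2.0))
        assert p_transform(v, side="one-sided")[0] == pytest.approx(expected)
        assert p_transform(np.array([-2.0]), side="one-sided")[0] < 0


@pytest.fixture(scope="module")
def sweep_dataset():
    from sweepkit.synthetic import default_scenario, simulate_dataset
    return simulate_dataset(default_scenario(seed=1, n_snps=800,
                                             n_per_pop=50))


class TestIhsScan:
    def test_symmetric_classes_give_raw_zero(self):
        vals = np.vstack([np.zeros((4, 9)), np.ones((4, 9))]).astype(np.int8)
        H = HaplotypeSet(vals)
        mm = uniform_map(9)
        anc = AncestralAssignment(np.zeros(9, dtype=np.int8), "major")
        track = ihs_scan(H, anc, mm, freq_bounds=(0.0, 1.0))
        np.testing.assert_allclose(track.raw, 0.0, atol=1e-12)

    def test_raw_negates_under_ancestral_flip(self, sweep_dataset):
        ds = sweep_dataset
        Hf = ds.H.take_samples(ds.st.indices_of_group("groupA"))
        anc = assign_ancestral_major(Hf.values.mean(axis=0))
        flipped = AncestralAssignment(1 - anc.alleles, "major")
        with np.errstate(invalid="ignore"):
            a = ihs_scan(Hf, anc, ds.mm).raw
            b = ihs_scan(Hf, flipped, ds.mm).raw
        both = ~np.isnan(a) & ~np.isnan(b)
        assert both.sum() > 100
        np.testing.assert_allclose(a[both], -b[both], atol=1e-10)

    def test_per_bin_mean_zero_sd_one(self, sweep_dataset):
        ds = sweep_dataset
        Hf = ds.H.take_samples(ds.st.indices_of_group("groupA"))
        anc = assign_ancestral_major(Hf.values.mean(axis=0))
        track = ihs_scan(Hf, anc, ds.mm, bin_width=0.05)
        der = np.array([(Hf.values[:, s] == 1 - anc.alleles[s]).mean()
                        for s in range(ds.mm.n_snps)])
        bins = np.floor(der / 0.05).astype(int)
        ok = ~np.isnan(track.standardized)
        for b in np.unique(bins[ok]):
            sel = ok & (bins == b)
            if sel.sum() >= 2:
                assert track.standardized[sel].mean() == pytest.approx(0, abs=1e-8)
                assert track.standardized[sel].std() == pytest.approx(1, abs=1e-8)

    def test_sweep_core_in_top_one_percent(self, sweep_dataset):
        ds = sweep_dataset
        core = ds.truths[0].core_idx
        Hf = ds.H.take_samples(ds.st.indices_of_group("groupA"))
        anc = assign_ancestral_major(Hf.values.mean(axis=0))
        track = ihs_scan(Hf, anc, ds.mm)
        a = np.abs(track.standardized)
        assert not np.isnan(a[core])
        assert a[core] >= np.nanquantile(a, 0.99)

    def test_flags_at_threshold(self):
        vals = np.array([3.9, 4.0, np.nan, 5.0])
        from sweepkit.ehh import EhhScanTrack
        with np.errstate(invalid="ignore"):
            flags = ~np.isnan(vals) & (vals >= 4.0)
        t = EhhScanTrack("ihs", vals, flags, raw=vals, standardized=vals)
        assert list(t.flags) == [False, True, False, True]


class TestRsbScan:
    def test_identical_groups_raw_zero(self):
        rng = np.random.default_rng(2)
        H = random_haplotypes(rng, 20, 60)
        mm = uniform_map(60)
        track = rsb_scan(H, H, mm)
        d = ~np.isnan(track.raw)
        assert d.sum() > 30
        np.testing.assert_allclose(track.raw[d], 0.0, atol=1e-12)

    def test_standardized_median_zero(self, sweep_dataset):
        ds = sweep_dataset
        Hf = ds.H.take_samples(ds.st.indices_of_group("groupA"))
        Ho = ds.H.take_samples(ds.st.indices_of_group("groupB"))
        track = rsb_scan(Hf, Ho, ds.mm)
        assert np.nanmedian(track.standardized) == pytest.approx(0, abs=1e-10)

    def test_sweep_core_positive_and_top_one_percent(self, sweep_dataset):
        ds = sweep_dataset
        core = ds.truths[0].core_idx
        Hf = ds.H.take_samples(ds.st.indices_of_group("groupA"))
        Ho = ds.H.take_samples(ds.st.indices_of_group("groupB"))
        track = rsb_scan(Hf, Ho, ds.mm)
        s = track.standardized
        assert s[core] > 0
        assert s[core] >= np.nanquantile(s, 0.99)


class TestConsistencyCheck:
    def test_major_assignment_gives_perfect_agreement(self):
        rng = np.random.default_rng(3)
        H = random_haplotypes(rng, 15, 40)
        mm = uniform_map(40)
        major = assign_ancestral_major(H.values.mean(axis=0))
        rep = consistency_check(H, mm, assignments=[major])
        assert rep["spearman_abs"][0] == pytest.approx(1.0)
        assert rep["jaccard_significant"][0] == 1.0

    def test_seeded_report_reproducible(self):
        rng = np.random.default_rng(4)
        H = random_haplotypes(rng, 10, 30)
        mm = uniform_map(30)
        a = consistency_check(H, mm, n_perm=3, seed=5)
        b = consistency_check(H, mm, n_perm=3, seed=5)
        assert a.equals(b)
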