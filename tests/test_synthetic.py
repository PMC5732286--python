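import numpy as np
import pytest
from scipy.stats import chi2

from sweepkit import io as gio
from sweepkit.differentiation import wc_fst_per_snp
from sweepkit.ehh import ehh_curve
from sweepkit.synthetic import (SimulationConfig, SweepSpec, bn_frequencies,
                                default_scenario, inject_sweep,
                                random_marker_map, sample_haplotypes,
                                simulate_dataset, write_dataset)


class TestBnFrequencies:
    def test_f_zero_equals_ancestral(self):
        df = bn_frequencies(100, ["a", "b"], F=0.0, seed=1)
        np.testing.assert_array_equal(df.loc["a"], df.attrs["ancestral"])
        np.testing.assert_array_equal(df.loc["b"], df.attrs["ancestral"])

    def test_beta_moment_recovery(self):
        F = 0.1
        df = bn_frequencies(10000, ["a"], F=F, seed=2)
        p = df.attrs["ancestral"]
        ratio = np.mean((df.loc["a"].to_numpy() - p) ** 2) / np.mean(
            F * p * (1 - p))
        assert 0.9 < ratio < 1.1

    def test_seed_reproducible(self):
        a = bn_frequencies(50, ["x", "y"], F=0.2, seed=3)
        b = bn_frequencies(50, ["x", "y"], F=0.2, seed=3)
        assert a.equals(b)


class TestMarkerMap:
    def test_sorted_and_spacing_in_bounds(self):
        mm = random_marker_map(500, 3, seed=4)
        assert mm.is_sorted()
        for _, idx in mm.chrom_slices():
            steps = np.diff(mm.pos[idx])
            assert (steps >= 500).all() and (steps <= 5000).all()


class TestSampleHaplotypes:
    def _freqs(self, values):
        import pandas as pd
        return pd.DataFrame([values], index=["g"])

    def test_fixed_frequency_all_ones(self):
        H, st = sample_haplotypes(self._freqs([1.0, 1.0]), {"p": 5},
                                  {"p": "g"}, seed=5)
        assert (H.values == 1).all()

    def test_half_frequency_within_binomial_band(self):
        H, _ = sample_haplotypes(self._freqs([0.5]), {"p": 100},
                                 {"p": "g"}, seed=6)
        f = H.values[:, 0].mean()  # 200 copies; 3 sd ~ 0.106
        assert abs(f - 0.5) < 0.106

    def test_hwe_by_construction(self):
        import pandas as pd
        rng = np.random.default_rng(7)
        freqs = pd.DataFrame([rng.uniform(0.1, 0.9, 500)], index=["g"])
        H, _ = sample_haplotypes(freqs, {"p": 200}, {"p": "g"}, seed=8)
        G = H.to_genotypes()
        rejected = 0
        tested = 0
        crit = chi2.isf(0.001, df=1)
        for s in range(500):
            n = G.values.shape[0]
            p = G.values[:, s].sum() / (2 * n)
            if p in (0, 1):
                continue
            exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
            obs = np.bincount(G.values[:, s], minlength=3)
            stat = ((obs - exp) ** 2 / exp).sum()
            tested += 1
            rejected += stat > crit
        assert rejected / tested < 0.01  # expect ~0.1% at alpha 0.001


class TestInjectSweep:
    def test_full_sweep_monomorphic_chromosome(self):
        cfg = SimulationConfig(
            n_snps=200, n_chroms=2,
            pop_sizes={"p1": 20, "p2": 20},
            pop_groups={"p1": "ga", "p2": "gb"},
            F=0.05, seed=9,
            sweeps=[SweepSpec("ga", 50, f=1.0, mean_half_len=1e6)])
        ds = simulate_dataset(cfg)
        rows = np.sort(np.concatenate([(2 * i, 2 * i + 1) for i in
                                       ds.st.indices_of_group("ga")]))
        chrom1 = ds.mm.chrom_slices()[0][1]
        sub = ds.H.values[np.ix_(rows, chrom1)]
        assert (sub == sub[0]).all()       # all copies share the template
        c = ehh_curve(ds.H.take_samples(ds.st.indices_of_group("ga")),
                      50, allele=1, cutoff=0.0,
                      bounds=(int(chrom1[0]), int(chrom1[-1])))
        assert (c.values() == 1.0).all()

    def test_default_scenario_core_frequency(self):
        ds = simulate_dataset(default_scenario(seed=1))
        truth = ds.truths[0]
        rows = np.sort(np.concatenate(
            [(2 * i, 2 * i + 1) for i in
             ds.st.indices_of_group(truth.group)]))
        f = (ds.H.values[rows, truth.core_idx] == 1).mean()
        assert f >= 0.8
        assert truth.n_carriers == 160  # 0.8 x 200 copies

    def test_other_groups_untouched(self):
        cfg = default_scenario(seed=3)
        rng_ds = simulate_dataset(cfg)
        neutral = SimulationConfig(
            n_snps=cfg.n_snps, n_chroms=cfg.n_chroms,
            pop_sizes=cfg.pop_sizes, pop_groups=cfg.pop_groups,
            F=cfg.F, sweeps=[], seed=cfg.seed)
        # same seeds feed frequency/map/haplotype stages, but the sweep
        # pins the core column frequency, so compare all other columns
        ds0 = simulate_dataset(neutral)
        rows_b = np.sort(np.concatenate(
            [(2 * i, 2 * i + 1) for i in rng_ds.st.indices_of_group("groupB")]))
        core = rng_ds.truths[0].core_idx
        mask = np.ones(cfg.n_snps, dtype=bool)
        mask[core] = False
        np.testing.assert_array_equal(rng_ds.H.values[np.ix_(rows_b, mask)],
                                      ds0.H.values[np.ix_(rows_b, mask)])

    def test_too_few_carriers_error(self):
        cfg = default_scenario(seed=2)
        ds = simulate_dataset(SimulationConfig(
            n_snps=cfg.n_snps, n_chroms=2, pop_sizes=cfg.pop_sizes,
            pop_groups=cfg.pop_groups, F=0.05, sweeps=[], seed=2))
        with pytest.raises(ValueError, match="<2 carrier"):
            inject_sweep(ds.H, ds.st, ds.mm,
                         SweepSpec("groupA", 100, f=0.001, mean_half_len=10),
                         seed=1)


class TestWriteDataset:
    def test_round_trips(self, tmp_path):
        ds = simulate_dataset(default_scenario(seed=4, n_snps=120,
                                               n_per_pop=10))
        paths = write_dataset(ds, tmp_path)
        H2, mm2, _ = gio.read_phased_vcf(paths["vcf"])
        np.testing.assert_array_equal(ds.H.values, H2.values)
        assert list(mm2.snp_id) == list(ds.mm.snp_id)

        G2, mmp, _ = gio.read_plink_textset(paths["ped"], paths["map"])
        # PED stores no orientation: reader recodes toward the file-wide
        # minor allele, flipping SNPs where the alt allele is major
        alt_count = ds.G.values.sum(axis=0)
        n2 = 2 * ds.G.n_samples
        flip = alt_count * 2 > n2  # alt major; ties keep "G" (lexically
        # larger) as the minor allele, matching the writer's orientation
        harmonized = np.where(flip, 2 - G2.values, G2.values)
        np.testing.assert_array_equal(ds.G.values, harmonized)

        st2 = gio.read_sample_table(paths["samples"])
        assert list(st2.sample_id) == list(ds.st.sample_id)

        import pandas as pd
        truth = pd.read_csv(paths["truth"], sep="\t")
        assert len(truth) == len(ds.config.sweeps)


class TestConfig:
    def test_from_file(self, tmp_path):
        p = tmp_path / "sim.cfg"
        p.write_text("n_snps=300\nn_chroms=3\nF=0.1\nseed=11\n"
                     "populations=p1:ga:10,p2:gb:12\n"
                     "sweeps=ga:40:0.8:15\n")
        cfg = SimulationConfig.from_file(p)
        assert cfg.n_snps == 300 and cfg.n_chroms == 3
        assert cfg.pop_sizes == {"p1": 10, "p2": 12}
        assert cfg.sweeps[0].group == "ga" and cfg.sweeps[0].core_idx == 40
        ds = simulate_dataset(cfg)
        assert ds.H.n_snps == 300

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="F must"):
            SimulationConfig(F=0.9)
        with pytest.raises(ValueError, match=">= 2 diploids"):
            SimulationConfig(pop_sizes={"p": 1}, pop_groups={"p": "g"})
        with pytest.raises(ValueError, match="outside marker range"):
            SimulationConfig(n_snps=10, pop_sizes={"p": 5},
                             pop_groups={"p": "g"},
                             sweeps=[SweepSpec("g", 50, 0.5, 10)])


class TestRealizedFst:
    def test_neutral_fst_matches_target(self):
        # F = 0.10, 100 diploids per group, 5000 SNPs
        cfg = SimulationConfig(
            n_snps=5000, n_chroms=2,
            pop_sizes={"p1": 100, "p2": 100},
            pop_groups={"p1": "ga", "p2": "gb"},
            F=0.10, sweeps=[], seed=1)
        ds = simulate_dataset(cfg)
        t = wc_fst_per_snp(ds.G, ds.st.group, "ga", "gb")
        mean_fst = np.nanmean(t.values)
        assert 0.08 <= mean_fst <= 0.12
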