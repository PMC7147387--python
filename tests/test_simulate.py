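import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sweepscan.errors import ConfigurationError
from sweepscan.simulate import (
    GroupSpec,
    PoolSpec,
    SimulationConfig,
    SweepSpec,
    apply_sweep,
    config_from_dict,
    make_pools,
    read_truth_bed,
    sample_individual_genotypes,
    sample_pool_reads,
    simulate_dataset,
    simulate_site_frequencies,
    write_simulated_vcf,
    write_truth_bed,
)
from sweepscan.stats import wc_fst_sites_array
from sweepscan.variant_io import GroupAssignment, group_count_arrays, read_sites


def two_group_config(**overrides):
    defaults = dict(
        chromosomes={"chr1": 1_000_000},
        groups=(
            GroupSpec("farmed", "pooled", 0.06, make_pools("farmed", 2, 22, 22.0)),
            GroupSpec("wild", "pooled", 0.06, make_pools("wild", 2, 20, 22.0)),
        ),
        seed=0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_invalid_density(self):
        with pytest.raises(ConfigurationError):
            two_group_config(snp_density=0)

    def test_invalid_divergence(self):
        with pytest.raises(ConfigurationError):
            GroupSpec("g", "pooled", 1.0, (PoolSpec("p"),))

    def test_invalid_error_rate(self):
        with pytest.raises(ConfigurationError):
            two_group_config(error_rate=0.5)

    def test_sweep_outside_chromosome(self):
        with pytest.raises(ConfigurationError):
            two_group_config(
                sweeps=(SweepSpec("chr1", 900_001, 1_100_000, "farmed", 1.0),)
            )

    def test_overlapping_sweeps_same_group_rejected(self):
        with pytest.raises(ConfigurationError, match="overlapping"):
            two_group_config(
                sweeps=(
                    SweepSpec("chr1", 100_001, 300_000, "farmed", 1.0),
                    SweepSpec("chr1", 250_001, 400_000, "farmed", 1.0),
                )
            )

    def test_overlapping_sweeps_different_groups_allowed(self):
        two_group_config(
            sweeps=(
                SweepSpec("chr1", 100_001, 300_000, "farmed", 1.0),
                SweepSpec("chr1", 250_001, 400_000, "wild", 1.0),
            )
        )

    def test_sweep_unknown_group(self):
        with pytest.raises(ConfigurationError):
            two_group_config(
                sweeps=(SweepSpec("chr1", 1, 1000, "nope", 1.0),)
            )


class TestSiteFrequencies:
    def test_f_zero_reproduces_ancestral(self):
        cfg = two_group_config(
            groups=(
                GroupSpec("a", "pooled", 0.0, make_pools("a", 1, 20, 20.0)),
                GroupSpec("b", "pooled", 0.0, make_pools("b", 1, 20, 20.0)),
            )
        )
        df = simulate_site_frequencies(cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(df["freq_a"], df["p0"])
        np.testing.assert_array_equal(df["freq_b"], df["p0"])

    def test_determinism(self):
        cfg = two_group_config()
        df1 = simulate_site_frequencies(cfg, np.random.default_rng(42))
        df2 = simulate_site_frequencies(cfg, np.random.default_rng(42))
        pd.testing.assert_frame_equal(df1, df2)

    def test_positions_sorted_unique_in_range(self):
        cfg = two_group_config(chromosomes={"c1": 500_000, "c2": 500_000})
        df = simulate_site_frequencies(cfg, np.random.default_rng(1))
        for chrom, sub in df.groupby("chrom"):
            pos = sub["pos"].to_numpy()
            assert (np.diff(pos) > 0).all()
            assert pos.min() >= 1 and pos.max() <= 500_000
        assert ((df["p0"] >= 0.05) & (df["p0"] <= 0.95)).all()
        for col in ("freq_farmed", "freq_wild"):
            assert ((df[col] >= 0) & (df[col] <= 1)).all()

    def test_poisson_site_count(self):
        cfg = two_group_config(chromosomes={"c": 5_000_000}, snp_density=1 / 500)
        df = simulate_site_frequencies(cfg, np.random.default_rng(2))
        assert 10_000 * 0.95 <= len(df) <= 10_000 * 1.05

    def test_mean_site_fst_larger_under_stronger_divergence(self):
        # Monte-Carlo oracle: F=0.10 must beat F=0.02 on mean per-site theta
        means = {}
        for F in (0.02, 0.10):
            rng = np.random.default_rng(7)
            cfg = two_group_config(
                chromosomes={"c": 5_000_000},
                groups=(
                    GroupSpec("a", "pooled", F, make_pools("a", 2, 22, 30.0)),
                    GroupSpec("b", "pooled", F, make_pools("b", 2, 22, 30.0)),
                ),
            )
            ds = simulate_dataset(cfg, rng)
            ref, alt = _group_sums(ds)
            num, den = wc_fst_sites_array(
                alt["a"], ref["a"] + alt["a"], alt["b"], ref["b"] + alt["b"]
            )
            means[F] = num.sum() / den.sum()
        assert means[0.10] > means[0.02]

    def test_fst_monotone_in_divergence(self):
        vals = []
        for F in (0.0, 0.02, 0.05, 0.10):
            rng = np.random.default_rng(11)
            cfg = two_group_config(
                chromosomes={"c": 5_000_000},
                groups=(
                    GroupSpec("a", "pooled", F, make_pools("a", 2, 22, 30.0)),
                    GroupSpec("b", "pooled", F, make_pools("b", 2, 22, 30.0)),
                ),
            )
            ds = simulate_dataset(cfg, rng)
            ref, alt = _group_sums(ds)
            num, den = wc_fst_sites_array(
                alt["a"], ref["a"] + alt["a"], alt["b"], ref["b"] + alt["b"]
            )
            vals.append(num.sum() / den.sum())
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_no_divergence_fst_near_zero(self):
        rng = np.random.default_rng(13)
        cfg = two_group_config(
            chromosomes={"c": 10_000_000},
            groups=(
                GroupSpec("a", "pooled", 0.0, make_pools("a", 3, 22, 30.0)),
                GroupSpec("b", "pooled", 0.0, make_pools("b", 3, 22, 30.0)),
            ),
        )
        ds = simulate_dataset(cfg, rng)
        assert len(ds.sites) >= 10_000
        ref, alt = _group_sums(ds)
        num, den = wc_fst_sites_array(
            alt["a"], ref["a"] + alt["a"], alt["b"], ref["b"] + alt["b"]
        )
        ok = den > 0
        mean_theta = float(np.mean(num[ok] / den[ok]))
        assert abs(mean_theta) < 0.01


def _group_sums(ds):
    ref = {}
    alt = {}
    groups = pd.Series(ds.sample_group)
    for g in groups.unique():
        cols = np.nonzero((groups == g).to_numpy())[0]
        ref[g] = ds.ref_depths[:, cols].sum(axis=1)
        alt[g] = ds.alt_depths[:, cols].sum(axis=1)
    return ref, alt


class TestApplySweep:
    @pytest.fixture
    def sites(self):
        cfg = two_group_config()
        return simulate_site_frequencies(cfg, np.random.default_rng(3))

    def test_f_zero_unchanged(self, sites):
        out = apply_sweep(
            sites, [SweepSpec("chr1", 1, 500_000, "farmed", 0.0)],
            np.random.default_rng(0),
        )
        pd.testing.assert_frame_equal(out, sites)

    def test_f_one_full_fixation(self, sites):
        sweep = SweepSpec("chr1", 200_001, 400_000, "farmed", 1.0)
        out = apply_sweep(sites, [sweep], np.random.default_rng(0))
        inside = (out["pos"] >= sweep.start) & (out["pos"] <= sweep.end)
        fr = out.loc[inside, "freq_farmed"]
        assert fr.isin([0.0, 1.0]).all()
        # pushed toward the ancestral major allele
        expect = np.where(out.loc[inside, "p0"] >= 0.5, 1.0, 0.0)
        np.testing.assert_array_equal(fr.to_numpy(), expect)
        # untouched elsewhere and in the other group
        pd.testing.assert_series_equal(out["freq_wild"], sites["freq_wild"])
        pd.testing.assert_series_equal(
            out.loc[~inside, "freq_farmed"], sites.loc[~inside, "freq_farmed"]
        )

    def test_partial_fixation_binomial_count(self):
        # ~200 in-sweep SNPs at f=0.5: fixed count within the central
        # binomial quantile band for every seed
        cfg = two_group_config(chromosomes={"chr1": 100_000}, snp_density=1 / 500)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            sites = simulate_site_frequencies(cfg, rng)
            n = len(sites)
            sweep = SweepSpec("chr1", 1, 100_000, "farmed", 0.5)
            out = apply_sweep(sites, [sweep], rng)
            fixed = (
                out["freq_farmed"].isin([0.0, 1.0])
                & ~sites["freq_farmed"].isin([0.0, 1.0])
            ).sum()
            lo, hi = sps.binom.ppf([0.0005, 0.9995], n, 0.5)
            assert lo <= fixed <= hi


class TestPoolReads:
    def make_sites(self, freq, n=20):
        return pd.DataFrame(
            {
                "chrom": ["c"] * n,
                "pos": np.arange(1, n + 1),
                "p0": [freq] * n,
                "freq_g": [freq] * n,
            }
        )

    def group(self, depth=1000.0, n_dip=20):
        return GroupSpec("g", "pooled", 0.0, (PoolSpec("g_p1", n_dip, depth),))

    def test_freq_one_all_alt(self):
        sites = self.make_sites(1.0)
        _, ref, alt = sample_pool_reads(sites, self.group(), np.random.default_rng(0))
        assert (ref == 0).all()
        assert (alt.sum(axis=1) > 0).any()

    def test_half_freq_concentration(self):
        # large pool so the binomial read-sampling term dominates:
        # sd ~ sqrt(0.25/1000) ~ 0.016, so +-0.05 covers ~3 sigma
        sites = self.make_sites(0.5)
        grp = self.group(depth=1000.0, n_dip=5000)
        _, ref, alt = sample_pool_reads(sites, grp, np.random.default_rng(1))
        tot = ref + alt
        frac = alt[tot > 0] / tot[tot > 0]
        assert (np.abs(frac - 0.5) <= 0.05).all()

    def test_poisson_depth_mean(self):
        sites = self.make_sites(0.5, n=10_000)
        grp = self.group(depth=22.0)
        _, ref, alt = sample_pool_reads(sites, grp, np.random.default_rng(2))
        mean_depth = (ref + alt).mean()
        assert abs(mean_depth - 22.0) / 22.0 < 0.05

    def test_error_rate_flips_reads(self):
        sites = self.make_sites(1.0, n=5_000)
        _, ref, alt = sample_pool_reads(
            sites, self.group(depth=30.0), np.random.default_rng(3), error_rate=0.01
        )
        frac_ref = ref.sum() / (ref.sum() + alt.sum())
        assert 0.005 < frac_ref < 0.02


class TestIndividualGenotypes:
    def make_sites(self, freq, n):
        return pd.DataFrame(
            {
                "chrom": ["c"] * n,
                "pos": np.arange(1, n + 1),
                "p0": [freq] * n,
                "freq_g": [freq] * n,
            }
        )

    def test_freq_zero_all_hom_ref(self):
        grp = GroupSpec("g", "individual", 0.0, n_individuals=5, mean_depth=8.0)
        sites = self.make_sites(0.0, 200)
        _, gt, ref, alt = sample_individual_genotypes(
            sites, grp, np.random.default_rng(0)
        )
        assert set(np.unique(gt)) <= {-1, 0}
        assert (alt == 0).all()

    def test_hwe_heterozygote_fraction(self):
        grp = GroupSpec("g", "individual", 0.0, n_individuals=1, mean_depth=50.0)
        sites = self.make_sites(0.5, 10_000)
        _, gt, _, _ = sample_individual_genotypes(
            sites, grp, np.random.default_rng(1)
        )
        called = gt[gt >= 0]
        het = (called == 1).mean()
        assert abs(het - 0.5) <= 0.02

    def test_missingness_matches_poisson_zero_mass(self):
        grp = GroupSpec("g", "individual", 0.0, n_individuals=1, mean_depth=6.0)
        sites = self.make_sites(0.5, 100_000)
        _, gt, ref, alt = sample_individual_genotypes(
            sites, grp, np.random.default_rng(2)
        )
        missing = (gt == -1).mean()
        assert missing == ((ref + alt) == 0).mean()
        assert abs(missing - np.exp(-6.0)) < 0.001


class TestVcfOutput:
    def test_empty_site_table_header_only(self, tmp_path):
        cfg = two_group_config(snp_density=1e-9)
        ds = simulate_dataset(cfg, np.random.default_rng(0))
        assert len(ds.sites) == 0
        out = tmp_path / "empty.vcf"
        write_simulated_vcf(ds, str(out))
        lines = out.read_text().splitlines()
        assert all(line.startswith("#") for line in lines)
        assert lines[-1].startswith("#CHROM")

    def test_byte_identical_under_fixed_seed(self, tmp_path):
        cfg = two_group_config(seed=99)
        texts = []
        for name in ("a.vcf", "b.vcf"):
            ds = simulate_dataset(cfg)
            p = tmp_path / name
            write_simulated_vcf(ds, str(p), str(tmp_path / (name + ".bed")))
            texts.append(p.read_bytes())
        assert texts[0] == texts[1]

    def test_round_trip_group_counts(self, tmp_path):
        cfg = two_group_config(
            chromosomes={"chr1": 200_000},
            error_rate=0.0,
            sweeps=(SweepSpec("chr1", 50_001, 100_000, "farmed", 1.0),),
        )
        ds = simulate_dataset(cfg, np.random.default_rng(5))
        vcf = tmp_path / "rt.vcf"
        write_simulated_vcf(ds, str(vcf))
        assignment = GroupAssignment(
            dict(zip(ds.sample_names, ds.sample_group)),
            {g.name: g.mode for g in cfg.groups},
        )
        sites = list(read_sites(str(vcf), assignment))
        assert len(sites) == len(ds.sites)
        ref, alt = group_count_arrays(sites, assignment)
        exp_ref, exp_alt = _group_sums(ds)
        for g in ("farmed", "wild"):
            np.testing.assert_array_equal(ref[g], exp_ref[g])
            np.testing.assert_array_equal(alt[g], exp_alt[g])

    def test_round_trip_individual_mode(self, tmp_path):
        cfg = SimulationConfig(
            chromosomes={"chr1": 100_000},
            groups=(
                GroupSpec("farmed", "individual", 0.05, n_individuals=4,
                          mean_depth=6.0),
                GroupSpec("wild", "individual", 0.05, n_individuals=4,
                          mean_depth=6.0),
            ),
            seed=8,
        )
        ds = simulate_dataset(cfg)
        vcf = tmp_path / "ind.vcf"
        write_simulated_vcf(ds, str(vcf))
        assignment = GroupAssignment(
            dict(zip(ds.sample_names, ds.sample_group)),
            {"farmed": "individual", "wild": "individual"},
        )
        sites = list(read_sites(str(vcf), assignment))
        ref, alt = group_count_arrays(sites, assignment)
        exp_ref, exp_alt = _group_sums(ds)
        for g in ("farmed", "wild"):
            np.testing.assert_array_equal(ref[g], exp_ref[g])
            np.testing.assert_array_equal(alt[g], exp_alt[g])

    def test_truth_bed_round_trip(self, tmp_path):
        sweeps = (
            SweepSpec("chr1", 100_001, 250_000, "farmed", 0.95),
            SweepSpec("chr1", 600_001, 800_000, "wild", 1.0),
        )
        cfg = two_group_config(sweeps=sweeps)
        bed = tmp_path / "truth.bed"
        write_truth_bed(cfg.truth_regions(), str(bed))
        lines = bed.read_text().splitlines()
        assert lines[0] == "chr1\t100000\t250000\tfarmed\t0.95"
        back = read_truth_bed(str(bed))
        assert [(t.chrom, t.start, t.end, t.group, t.f) for t in back] == [
            (s.chrom, s.start, s.end, s.group, s.f) for s in sweeps
        ]


class TestConfigFromDict:
    def test_pools_shorthand(self):
        cfg = config_from_dict(
            {
                "chromosomes": {"c": 100_000},
                "groups": [
                    {"name": "g", "mode": "pooled", "n_pools": 3, "diploids": 22,
                     "depth": 24},
                ],
            }
        )
        assert len(cfg.groups[0].pools) == 3
        assert cfg.groups[0].pools[0].n_diploids == 22

    def test_explicit_pools_and_individuals(self):
        cfg = config_from_dict(
            {
                "chromosomes": {"c": 100_000},
                "groups": [
                    {"name": "g", "pools": [{"diploids": 20, "depth": 22}]},
                    {"name": "h", "mode": "individual", "individuals": 13,
                     "depth": 6},
                ],
                "sweeps": [
                    {"chrom": "c", "start": 1, "end": 50_000, "group": "g",
                     "f": 0.9}
                ],
            }
        )
        assert cfg.groups[1].n_individuals == 13
        assert cfg.sweeps[0].f == 0.9
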