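import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ewaskit as ek
from ewaskit.dmr import (
    DMRParams,
    gaussian_smooth,
    group_regions,
    moderated_site_stats,
    site_significance,
    squeeze_variances,
)
from ewaskit.models import fit_glm_site


class TestVarianceShrinkage:
    def test_identical_variances_are_fixed_point(self):
        s2 = np.full(50, 0.04)
        post, d0, s02 = squeeze_variances(s2, df=20)
        assert np.allclose(post, 0.04, atol=1e-6)

    def test_outlier_variance_shrunk_towards_prior(self, rng):
        s2 = np.concatenate([0.01 * stats.chi2.rvs(20, size=200, random_state=1) / 20, [0.5]])
        post, d0, s02 = squeeze_variances(s2, df=20)
        assert post[-1] < 0.5  # inflated outlier pulled down
        assert post[-1] > s02  # but not past the prior

    def test_no_shrinkage_matches_per_site_glm(self, small_glm_data):
        m, sh, _, _ = small_glm_data
        stats_df = moderated_site_stats(m, sh, "exposure", shrink=False)
        X = np.column_stack([np.ones(len(sh)), sh.column("exposure").to_numpy()])
        for i, probe in enumerate(m.probe_ids[:10]):
            fit = fit_glm_site(m.values.loc[probe].to_numpy(), X, 1)
            t_ref = fit.estimate / fit.se
            assert stats_df["t"].iloc[i] == pytest.approx(t_ref, abs=1e-8)

    def test_shrinkage_direction_for_variance_outliers(self, rng):
        """Moderation pulls outlying variances toward the prior: a probe with
        deflated residual variance loses |t|, an inflated one gains |t|."""
        m, sh, _, _ = ek.simulate_ewas_dataset(n_samples=60, n_probes=100, n_causal=0, seed=31)
        vals = m.values.copy()
        center = vals.mean(axis=1)
        vals.iloc[0] = center.iloc[0] + (vals.iloc[0] - center.iloc[0]) * 0.1  # deflated
        vals.iloc[1] = center.iloc[1] + (vals.iloc[1] - center.iloc[1]) * 10.0  # inflated
        m2 = ek.MethylationMatrix(vals, value_type="m")
        mod = moderated_site_stats(m2, sh, "exposure", shrink=True)
        raw = moderated_site_stats(m2, sh, "exposure", shrink=False)
        assert abs(mod["t"].iloc[0]) <= abs(raw["t"].iloc[0]) + 1e-12
        assert abs(mod["t"].iloc[1]) >= abs(raw["t"].iloc[1]) - 1e-12


class TestSmoothing:
    def test_single_site_identity(self):
        out, w2 = gaussian_smooth(np.array([100.0]), np.array([3.7]), DMRParams())
        assert out[0] == pytest.approx(3.7)
        assert w2[0] == pytest.approx(1.0)

    def test_constant_stats_invariant(self, rng):
        pos = np.sort(rng.choice(100_000, 50, replace=False)).astype(float)
        out, _ = gaussian_smooth(pos, np.full(50, 2.5), DMRParams())
        assert np.allclose(out, 2.5)

    def test_distant_sites_unaffected(self):
        params = DMRParams(bandwidth_lambda=1000)
        pos = np.array([0.0, 10_000.0])  # 10 lambda apart
        vals = np.array([1.0, 9.0])
        out, _ = gaussian_smooth(pos, vals, params)
        assert np.allclose(out, vals, atol=1e-6)

    def test_smoothed_bounded_by_raw_range(self, rng):
        pos = np.sort(rng.choice(50_000, 80, replace=False)).astype(float)
        vals = rng.chisquare(1, 80)
        out, w2 = gaussian_smooth(pos, vals, DMRParams())
        assert np.all(out >= vals.min() - 1e-12) and np.all(out <= vals.max() + 1e-12)
        assert np.all(w2 <= 1.0 + 1e-12)

    def test_unsorted_positions_error(self):
        with pytest.raises(ValueError, match="increasing"):
            gaussian_smooth(np.array([5.0, 1.0]), np.array([1.0, 2.0]), DMRParams())


class TestSiteSignificance:
    def test_single_site_collapses_to_chi2_1_tail(self):
        t2 = np.array([4.0])
        p, _ = site_significance(t2, np.array([1.0]))
        assert p[0] == pytest.approx(stats.chi2.sf(4.0, 1), abs=1e-6)

    def test_null_calibration(self, rng):
        """Pure-null smoothed stats: FDR<0.05 calls should be rare."""
        n_sites = 5000
        pos = np.cumsum(rng.integers(50, 2000, n_sites)).astype(float)
        t2 = rng.chisquare(1, n_sites)
        smoothed, w2 = gaussian_smooth(pos, t2, DMRParams())
        _, fdr = site_significance(smoothed, w2)
        assert (fdr < 0.05).mean() <= 0.05


class TestGrouping:
    def _sites(self, chrom, pos, p, fdr, effect=None):
        return pd.DataFrame(
            {"chrom": chrom, "pos": pos, "p": p, "fdr": fdr,
             "effect": effect if effect is not None else np.ones(len(pos))}
        )

    def test_gap_rule_example(self):
        sites = self._sites(["1"] * 3, [100, 900, 2500], [1e-4] * 3, [0.01] * 3)
        regions = group_regions(sites, DMRParams(bandwidth_lambda=1000))
        assert len(regions) == 1
        assert regions.iloc[0]["start"] == 100 and regions.iloc[0]["end"] == 900
        assert regions.iloc[0]["n_cpgs"] == 2

    def test_no_significant_sites_empty(self):
        sites = self._sites(["1"] * 3, [100, 200, 300], [0.5] * 3, [0.9] * 3)
        assert group_regions(sites, DMRParams()).empty

    def test_stouffer_decreases_with_region_size(self):
        params = DMRParams()
        prev = 1.0
        for k in (2, 4, 8):
            sites = self._sites(["1"] * k, list(range(100, 100 + 100 * k, 100)),
                                [0.01] * k, [0.01] * k)
            region = group_regions(sites, params).iloc[0]
            assert region["stouffer_p"] < 0.01
            assert region["stouffer_p"] < prev
            prev = region["stouffer_p"]

    def test_chromosomes_never_merge(self):
        sites = self._sites(["1", "2"], [100, 150], [1e-4] * 2, [0.01] * 2)
        assert group_regions(sites, DMRParams()).empty  # singletons per chrom


class TestRunDmr:
    def test_planted_regions_recovered(self):
        m, sh, ann, truth = ek.simulate_dmr_dataset(
            n_samples=80, n_null_probes=2000, n_regions=5, effect_size=0.1, seed=41
        )
        called = ek.run_dmr(m, sh, "exposure", ann)
        recovered = 0
        for r in truth.regions:
            hit = (
                (called["chrom"] == r["chrom"])
                & (called["end"] >= r["start"])
                & (called["start"] <= r["end"])
            ).any()
            recovered += hit
        assert recovered >= 4
        assert set(called.columns) == set(ek.dmr.DMR_COLUMNS)
        assert (called["start"] <= called["end"]).all()
        assert (called["n_cpgs"] >= 2).all()

    def test_null_input_yields_no_regions(self):
        m, sh, ann, _ = ek.simulate_dmr_dataset(
            n_samples=60, n_null_probes=2000, n_regions=0, seed=42
        )
        called = ek.run_dmr(m, sh, "exposure", ann)
        assert len(called) == 0

    def test_threshold_monotonicity(self):
        m, sh, ann, _ = ek.simulate_dmr_dataset(
            n_samples=80, n_null_probes=1000, n_regions=4, effect_size=0.08, seed=43
        )
        n_loose = len(ek.run_dmr(m, sh, "exposure", ann, params=DMRParams(site_fdr_threshold=0.10)))
        n_tight = len(ek.run_dmr(m, sh, "exposure", ann, params=DMRParams(site_fdr_threshold=0.01)))
        assert n_loose >= n_tight

    def test_bed_export_converts_to_zero_based_half_open(self, tmp_path):
        from ewaskit.core import dmrs_to_bed

        regions = pd.DataFrame(
            {"chrom": ["1", "2"], "start": [100, 5000], "end": [900, 5400]}
        )
        path = tmp_path / "dmr.bed"
        dmrs_to_bed(regions, path)
        bed = pd.read_csv(path, sep="\t", header=None)
        assert bed[1].tolist() == [99, 4999]  # 1-based inclusive -> 0-based
        assert bed[2].tolist() == [900, 5400]

    def test_no_annotation_overlap_errors(self):
        m, sh, ann, _ = ek.simulate_dmr_dataset(n_samples=40, n_null_probes=200,
                                                n_regions=0, seed=44)
        foreign = ann.copy()
        foreign.index = [f"x{i}" for i in range(len(foreign))]
        with pytest.raises(ValueError, match="annotation"):
            ek.run_dmr(m, sh, "exposure", foreign)
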