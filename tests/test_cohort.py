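"""Cohort-level TI computation, weighting, summaries and IRR regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tindex import (
    BNNConfig,
    SyntheticCohortSpec,
    balanced_weights,
    compute_ti_cohort,
    irr_ti_regression,
    simulate_cohort,
    summarize_cohort,
)
from tindex.bnn import NeighborSequence, bnn_posterior, order_neighbors
from tindex.cohort import CohortSummary, TIResult, results_frame


def _two_cluster_cohort(n_per=20, sep=100.0, seed=0):
    """Well-separated all-male and all-female clusters in 5-D expression space."""
    rng = np.random.default_rng(seed)
    male = rng.normal(0.0, 1.0, size=(n_per, 5))
    female = rng.normal(sep, 1.0, size=(n_per, 5))
    profiles = np.vstack([male, female])
    samples = [f"M{i:02d}" for i in range(n_per)] + [f"F{i:02d}" for i in range(n_per)]
    expr = pd.DataFrame(profiles.T, index=[f"g{j}" for j in range(5)], columns=samples)
    ann = pd.DataFrame(
        {"sex": ["male"] * n_per + ["female"] * n_per, "cancer_type": "T"},
        index=pd.Index(samples, name="sample"),
    )
    return expr, ann


class TestComputeTICohort:
    def test_two_separated_clusters_rank_and_oracle(self, default_config):
        expr, ann = _two_cluster_cohort()
        results = compute_ti_cohort(expr, ann, default_config)
        df = results_frame(results)
        male_ti = df.loc[df.sex == "male", "ti"]
        female_ti = df.loc[df.sex == "female", "ti"]
        assert male_ti.min() > female_ti.max()

        # every TI must equal bnn_posterior on the hand-constructed ordering
        samples = sorted(ann.index)
        for rec in results:
            training = [
                (s, expr[s].to_numpy(), int(ann.loc[s, "sex"] == "male"), 1.0)
                for s in samples
                if s != rec.sample
            ]
            seq = order_neighbors(expr[rec.sample].to_numpy(), training)
            expected, _ = bnn_posterior(seq, default_config)
            assert rec.ti == pytest.approx(expected, abs=1e-12)

    def test_singleton_cancer_type_gets_prior_mean(self, default_config):
        expr = pd.DataFrame([[1.0], [2.0]], index=["g1", "g2"], columns=["S1"])
        ann = pd.DataFrame({"sex": ["male"], "cancer_type": ["LONE"]}, index=["S1"])
        with pytest.warns(UserWarning, match="LONE"):
            results = compute_ti_cohort(expr, ann, default_config)
        assert results[0].ti == 0.5 and results[0].support == 0.0

    def test_sex_relabeling_flips_ti(self, default_config):
        expr, ann = _two_cluster_cohort(n_per=8)
        flipped = ann.copy()
        flipped["sex"] = ann["sex"].map({"male": "female", "female": "male"})
        t1 = {r.sample: r.ti for r in compute_ti_cohort(expr, ann, default_config)}
        t2 = {r.sample: r.ti for r in compute_ti_cohort(expr, flipped, default_config)}
        for s in t1:
            assert t1[s] + t2[s] == pytest.approx(1.0, abs=1e-12)

    def test_sample_order_invariance(self, default_config):
        expr, ann = _two_cluster_cohort(n_per=6, sep=3.0)
        perm = list(expr.columns)[::-1]
        t1 = {r.sample: r.ti for r in compute_ti_cohort(expr, ann, default_config)}
        t2 = {
            r.sample: r.ti
            for r in compute_ti_cohort(expr[perm], ann.loc[perm], default_config)
        }
        assert t1 == t2

    def test_missing_annotation_is_an_error(self, default_config):
        expr, ann = _two_cluster_cohort(n_per=3)
        with pytest.raises(ValueError, match="M00"):
            compute_ti_cohort(expr, ann.drop(index="M00"), default_config)

    def test_balanced_null_cohort_centers_near_half(self):
        spec = SyntheticCohortSpec(
            n_samples=200, n_genes=300, male_module_size=0, female_module_size=0,
            effect=0.0, seed=3,
        )
        expr, ann, _ = simulate_cohort(spec)
        results = compute_ti_cohort(expr, ann, BNNConfig(weighting="balanced"))
        mean_ti = float(np.mean([r.ti for r in results]))
        assert abs(mean_ti - 0.5) < 0.05

    def test_support_increases_with_cluster_tightness(self):
        supports = []
        for noise in (2.0, 1.0, 0.5):
            spec = SyntheticCohortSpec(
                n_samples=80, n_genes=300, male_module_size=60,
                female_module_size=60, noise_sd=noise, seed=7,
            )
            expr, ann, _ = simulate_cohort(spec)
            results = compute_ti_cohort(expr, ann, BNNConfig())
            supports.append(float(np.mean([r.support for r in results])))
        assert supports[0] < supports[1] < supports[2]

    def test_ti_tracks_latent_continuum(self, small_cohort):
        _, expr, ann, truth = small_cohort
        results = compute_ti_cohort(expr, ann, BNNConfig(weighting="balanced"))
        df = results_frame(results).set_index("sample")
        rho = stats.spearmanr(df["ti"], truth.z.loc[df.index]).statistic
        assert rho >= 0.7


class TestBalancedWeights:
    def test_even_composition_all_ones(self):
        ann = pd.DataFrame(
            {"sex": ["male"] * 5 + ["female"] * 5, "cancer_type": "A"},
            index=[f"S{i}" for i in range(10)],
        )
        assert (balanced_weights(ann) == 1.0).all()

    def test_stated_formula(self):
        ann = pd.DataFrame(
            {"sex": ["male"] * 30 + ["female"] * 10, "cancer_type": "A"},
            index=[f"S{i}" for i in range(40)],
        )
        w = balanced_weights(ann)
        assert w.iloc[0] == pytest.approx(2 / 3)
        assert w.iloc[-1] == pytest.approx(2.0)
        male_total = w[ann.sex == "male"].sum()
        female_total = w[ann.sex == "female"].sum()
        assert male_total == pytest.approx(20.0) and female_total == pytest.approx(20.0)

    def test_sex_totals_equal_for_random_compositions(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n_m = int(rng.integers(1, 50))
            n_f = int(rng.integers(1, 50))
            ann = pd.DataFrame(
                {"sex": ["male"] * n_m + ["female"] * n_f, "cancer_type": "A"},
                index=[f"S{i}" for i in range(n_m + n_f)],
            )
            w = balanced_weights(ann)
            assert (w > 0).all()
            assert abs(w[ann.sex == "male"].sum() - w[ann.sex == "female"].sum()) < 1e-12

    def test_single_sex_type_is_an_error(self):
        ann = pd.DataFrame({"sex": ["male"] * 3, "cancer_type": "A"}, index=list("abc"))
        with pytest.raises(ValueError, match="female"):
            balanced_weights(ann)


def _summary_from(ti_values, sexes, ctype="X"):
    results = [
        TIResult(f"S{i}", ctype, sex, ti, 0.0)
        for i, (ti, sex) in enumerate(zip(ti_values, sexes))
    ]
    return summarize_cohort(results)[0]


class TestSummaries:
    def test_median_of_three(self):
        s = _summary_from([0.2, 0.4, 0.6], ["male", "female", "male"])
        assert s.median_ti == pytest.approx(0.4)
        assert s.q05 <= s.q25 <= s.q75 <= s.q95

    def test_pancan_caption_irr(self):
        # cohort composition matching the adult pan-cancer counts
        results = [TIResult(f"M{i}", "PANCAN", "male", 0.6, 0.0) for i in range(4668)]
        results += [TIResult(f"F{i}", "PANCAN", "female", 0.4, 0.0) for i in range(3213)]
        s = summarize_cohort(results)[0]
        assert round(s.irr, 2) == 1.45

    def test_pediatric_caption_irr(self):
        results = [TIResult(f"M{i}", "PED", "male", 0.6, 0.0) for i in range(259)]
        results += [TIResult(f"F{i}", "PED", "female", 0.4, 0.0) for i in range(230)]
        s = summarize_cohort(results)[0]
        assert round(s.irr, 2) == 1.13


class TestIRRRegression:
    @staticmethod
    def _mk(ctype, irr, median):
        return CohortSummary(ctype, 10, 10, irr, median, 0, 0, 1, 1)

    def test_collinear_points(self):
        summaries = [self._mk("A", 1.0, 0.4), self._mk("B", 2.0, 0.5), self._mk("C", 3.0, 0.6)]
        slope, intercept, r, p = irr_ti_regression(summaries)
        assert abs(r - 1.0) < 1e-12
        assert slope == pytest.approx(0.1, abs=1e-12)

    def test_constant_response(self):
        summaries = [self._mk("A", 1.0, 0.5), self._mk("B", 2.0, 0.5), self._mk("C", 3.0, 0.5)]
        slope, _, r, _ = irr_ti_regression(summaries)
        assert slope == 0.0 and r == 0.0

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(4)
        irr = rng.uniform(0.3, 4.0, 12)
        med = 0.45 + 0.03 * irr + rng.normal(0, 0.02, 12)
        summaries = [self._mk(f"C{i}", irr[i], med[i]) for i in range(12)]
        slope, intercept, r, _ = irr_ti_regression(summaries)
        # textbook OLS from sums
        sxx = np.sum((irr - irr.mean()) ** 2)
        sxy = np.sum((irr - irr.mean()) * (med - med.mean()))
        syy = np.sum((med - med.mean()) ** 2)
        assert slope == pytest.approx(sxy / sxx, abs=1e-12)
        assert intercept == pytest.approx(med.mean() - slope * irr.mean(), abs=1e-12)
        assert r == pytest.approx(sxy / np.sqrt(sxx * syy), abs=1e-12)

    def test_log2_scale_and_external_irr(self):
        summaries = [self._mk("A", 1.0, 0.4), self._mk("B", 2.0, 0.5), self._mk("C", 4.0, 0.6)]
        slope, _, r, _ = irr_ti_regression(summaries, scale="log2")
        assert abs(r - 1.0) < 1e-12  # log2 IRRs are 0,1,2: collinear with medians
        # externally supplied IRRs reversing the order flip the correlation sign
        ext = {"A": 4.0, "B": 2.0, "C": 1.0}
        _, _, r2, _ = irr_ti_regression(summaries, external_irr=ext)
        assert r2 < 0

    def test_too_few_cohorts(self):
        with pytest.raises(ValueError, match="3"):
            irr_ti_regression([self._mk("A", 1.0, 0.5), self._mk("B", 2.0, 0.6)])
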