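"""Generator statistics and the closed-form expectations of the channel."""

import numpy as np
import pandas as pd
import pytest

from imputeval.evaluation import (
    concordance,
    contingency,
    estimated_rsq,
    iqs,
    most_likely_genotype,
    true_rsq,
)
from imputeval.synthetic import (
    ChannelParams,
    MafLaw,
    PlantedClass,
    SimConfig,
    default_scenario_config,
    imputation_channel,
    scenario_three_panels,
    simulate_genotypes,
    simulate_population_freqs,
)


def small_cfg(**kw):
    base = dict(
        n_snps=200,
        n_samples=100,
        populations=(("YRI", 88), ("CEU", 85)),
        study_ancestry=("YRI", "CEU"),
        seed=11,
    )
    base.update(kw)
    return SimConfig(**base)


def hwe_freqs(p):
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])


class TestPopulationFreqs:
    def test_low_fst_stays_near_ancestral(self):
        cfg = small_cfg(n_snps=2000, fst=1e-6,
                        maf_law=MafLaw("uniform", 0.05, 0.5))
        freqs = simulate_population_freqs(cfg)
        # Beta variance p(1-p)F: with F = 1e-6 nearly all draws are within
        # 0.01 of the ancestral value, so the two populations nearly coincide
        close = np.abs(freqs["YRI"] - freqs["CEU"]) < 0.02
        assert close.mean() >= 0.99

    def test_planted_counts_exact(self):
        cfg = small_cfg(
            n_snps=1000,
            planted=(PlantedClass(fraction=0.3, zero_pops=("YRI",)),),
        )
        freqs = simulate_population_freqs(cfg)
        planted = freqs.attrs["planted"][0]
        assert len(planted) == 300
        assert (freqs.loc[sorted(planted), "YRI"] == 0.0).all()
        assert (freqs.loc[sorted(planted), "CEU"] > 0.0).all()

    def test_bit_reproducible(self):
        cfg = small_cfg()
        a = simulate_population_freqs(cfg)
        b = simulate_population_freqs(cfg)
        pd.testing.assert_frame_equal(a, b)


class TestGenotypes:
    def test_hwe_proportions_at_half(self):
        cfg = small_cfg(n_snps=1, n_samples=10_000,
                        admixture_law=("fixed", 1.0))
        freqs = pd.DataFrame({"YRI": [0.5], "CEU": [0.5]}, index=["snp000000"])
        g, _ = simulate_genotypes(freqs, cfg)
        obs = np.bincount(g.calls[0], minlength=3) / 10_000
        se = 3 * np.sqrt(np.array([0.25, 0.5, 0.25]) * 0.75 / 10_000)
        assert (np.abs(obs - [0.25, 0.5, 0.25]) < np.maximum(se, 0.02)).all()

    def test_fixed_ancestry_reduces_to_single_population(self):
        cfg = small_cfg(n_snps=50, n_samples=500, admixture_law=("fixed", 1.0))
        freqs = pd.DataFrame(
            {"YRI": np.full(50, 0.4), "CEU": np.zeros(50)},
            index=[f"snp{i:06d}" for i in range(50)],
        )
        g, info = simulate_genotypes(freqs, cfg)
        # CEU frequency is 0: any ALT allele proves the draw came from YRI
        assert g.calls.sum() > 0
        assert (info["african_fraction"] == 1.0).all()

    def test_zero_frequency_gives_all_reference(self):
        cfg = small_cfg(n_snps=10, n_samples=200, admixture_law=("beta", 8, 2))
        freqs = pd.DataFrame(
            {"YRI": np.zeros(10), "CEU": np.zeros(10)},
            index=[f"snp{i:06d}" for i in range(10)],
        )
        g, _ = simulate_genotypes(freqs, cfg)
        assert (g.calls == 0).all()

    def test_missingness_injected(self):
        cfg = small_cfg(missing_rate=0.1, n_snps=500, n_samples=50)
        freqs = simulate_population_freqs(cfg)
        g, _ = simulate_genotypes(freqs, cfg)
        rate = (g.calls == -1).mean()
        assert rate == pytest.approx(0.1, abs=0.01)


def run_channel(p, n, e, q, seed=5, n_snps=1):
    """Channel over n_snps iid SNPs at frequency p; returns (truth, posterior)."""
    cfg = small_cfg(
        n_snps=n_snps, n_samples=n, admixture_law=("fixed", 1.0), seed=seed,
        channel=ChannelParams(base_error=e, calibration=q,
                              panel_penalty=0.0, maf_penalty=0.0),
    )
    vids = [f"snp{i:06d}" for i in range(n_snps)]
    freqs = pd.DataFrame({"YRI": np.full(n_snps, p), "CEU": np.full(n_snps, p)},
                         index=vids)
    truth, _ = simulate_genotypes(freqs, cfg)
    post = imputation_channel(truth, np.full(n_snps, p), cfg, seed=seed + 1)
    return truth, post


class TestChannel:
    def test_perfect_channel_identity(self):
        truth, post = run_channel(p=0.3, n=400, e=0.0, q=1.0, n_snps=20)
        d = post.dosages()
        for i in range(truth.n_variants):
            if len(np.unique(truth.calls[i])) < 2:
                continue
            ml = most_likely_genotype(post.probs[i])
            table = contingency(truth.calls[i], ml)
            assert concordance(table) == 1.0
            assert iqs(table) == 1.0
            assert true_rsq(d[i], truth.calls[i]) == pytest.approx(1.0)

    def test_random_caller_null_iqs(self):
        truth, post = run_channel(p=0.25, n=2000, e=1.0, q=1.0, n_snps=200)
        vals = []
        for i in range(200):
            v = iqs(contingency(truth.calls[i], most_likely_genotype(post.probs[i])))
            if not np.isnan(v):
                vals.append(v)
        assert abs(np.mean(vals)) < 0.02

    def test_error_rate_concordance_closed_form(self):
        e, p, n = 0.3, 0.2, 10_000
        truth, post = run_channel(p=p, n=n, e=e, q=1.0)
        table = contingency(truth.calls[0], most_likely_genotype(post.probs[0]))
        f = hwe_freqs(p)
        expect = 1 - e + e * (f**2).sum()
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(concordance(table) - expect) < 3 * se

    def test_error_rate_recovered_from_concordance(self):
        e, p, n = 0.3, 0.2, 10_000
        truth, post = run_channel(p=p, n=n, e=e, q=1.0)
        table = contingency(truth.calls[0], most_likely_genotype(post.probs[0]))
        f = hwe_freqs(p)
        c = concordance(table)
        e_hat = (1 - c) / (1 - (f**2).sum())
        se_c = np.sqrt(c * (1 - c) / n)
        assert abs(e_hat - e) < 3 * se_c / (1 - (f**2).sum())

    @pytest.mark.parametrize("maf", [0.05, 0.2, 0.45])
    def test_calibration_recovered_by_estimated_rsq(self, maf):
        q = 0.8
        reps = []
        for k in range(10):
            truth, post = run_channel(p=maf, n=10_000, e=0.0, q=q, seed=100 + k)
            reps.append(estimated_rsq(post.dosages()[0]))
        se = np.std(reps, ddof=1) / np.sqrt(len(reps))
        assert abs(np.mean(reps) - q**2) < 3 * max(se, 1e-4)

    def test_missing_truth_imputed_from_prior(self):
        cfg = small_cfg(n_snps=1, n_samples=100, admixture_law=("fixed", 1.0),
                        missing_rate=1.0,
                        channel=ChannelParams(base_error=0.0, calibration=1.0))
        freqs = pd.DataFrame({"YRI": [0.5], "CEU": [0.5]}, index=["snp000000"])
        truth, _ = simulate_genotypes(freqs, cfg)
        post = imputation_channel(truth, np.array([0.5]), cfg)
        # all truth missing, e = 0: reported must still be HWE draws
        assert len(np.unique(most_likely_genotype(post.probs[0]))) > 1

    def test_channel_deterministic(self):
        a = run_channel(p=0.3, n=100, e=0.2, q=0.9)[1]
        b = run_channel(p=0.3, n=100, e=0.2, q=0.9)[1]
        np.testing.assert_array_equal(a.probs, b.probs)


@pytest.fixture(scope="module")
def scen():
    return scenario_three_panels(default_scenario_config(seed=3))


class TestScenario:

    def test_nested_panels_and_totals(self, scen):
        assert [p.n_total for p in scen.panels.values()] == [234, 625, 1092]
        close, mid, all_ = (set(scen.posteriors[k].vids) for k in ("close", "mid", "all"))
        assert close <= mid <= all_

    def test_planted_snps_absent_from_close_panel(self, scen):
        close_vids = set(scen.posteriors["close"].vids)
        planted = set().union(*scen.planted.values())
        assert not (planted & close_vids)

    def test_self_filter_identity_on_close_panel(self, scen):
        from imputeval.panels import monomorphic_set

        mono_close = monomorphic_set(scen.panels["close"])
        assert not (set(scen.posteriors["close"].vids) & mono_close)

    def test_low_maf_fraction_rises_with_panel_diversity(self, scen):
        from imputeval.pipeline import imputed_snp_metrics

        fracs = []
        for name in ("close", "mid", "all"):
            ms = imputed_snp_metrics(scen.posteriors[name])
            poly = [m for m in ms if m.maf > 0]
            fracs.append(
                sum(1 for m in poly if m.maf <= 0.02 + 1e-12) / len(poly)
            )
        assert fracs[0] < fracs[1] < fracs[2]

    def test_rsq_gradient_directions(self, scen):
        from imputeval.evaluation import summarize
        from imputeval.pipeline import imputed_snp_metrics

        overall, common = [], []
        for name in ("close", "mid", "all"):
            ms = imputed_snp_metrics(scen.posteriors[name])
            s = summarize(ms)
            overall.append(s.rsq_mean)
            gt2 = [m.rsq_est for m in ms if m.maf > 0.02 + 1e-12]
            common.append(np.mean(gt2))
        assert overall[0] > overall[1] > overall[2]
        assert common[0] <= common[1] <= common[2] + 1e-9

    def test_scenario_bit_reproducible(self):
        cfg = default_scenario_config(seed=9, n_snps=300, n_samples=60)
        a = scenario_three_panels(cfg)
        b = scenario_three_panels(cfg)
        np.testing.assert_array_equal(a.truth.calls, b.truth.calls)
        for name in a.posteriors:
            np.testing.assert_array_equal(
                a.posteriors[name].probs, b.posteriors[name].probs
            )
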