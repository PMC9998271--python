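import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plastevol.de import (
    ModelError,
    NormalizationError,
    _design_matrix,
    _irls_nb,
    bh_adjust,
    fit_dispersion,
    fit_model,
    run_contrast,
    size_factors,
    vst,
)
from plastevol.io import CountMatrix, SampleDesign
from plastevol.simulate import SimParams, simulate_experiment


def _matrix(arr, genes=None, samples=None):
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=genes, columns=samples))


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        m = _matrix([[10, 10], [20, 20], [5, 5]])
        np.testing.assert_allclose(size_factors(m).to_numpy(), [1.0, 1.0])

    def test_exact_doubling_splits_symmetrically(self):
        m = _matrix([[10, 20], [30, 60], [7, 14]])
        np.testing.assert_allclose(
            size_factors(m).to_numpy(), [1 / np.sqrt(2), np.sqrt(2)]
        )

    def test_matches_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(0)
        arr = rng.poisson(50, size=(50, 4)) + 1
        m = _matrix(arr)
        # independent oracle: literal median over genes of count/geomean
        geomean = np.prod(arr.astype(float), axis=1) ** (1 / arr.shape[1])
        expected = np.median(arr / geomean[:, None], axis=0)
        np.testing.assert_allclose(size_factors(m).to_numpy(), expected, rtol=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        arr = rng.poisson(40, size=(30, 3)) + 1
        base = size_factors(_matrix(arr)).to_numpy()
        scaled = arr.copy()
        scaled[:, 1] *= 5
        got = size_factors(_matrix(scaled)).to_numpy()
        # multiplying one sample by c multiplies its factor by c relative to
        # the others (the geometric-mean recentering spreads a c^(-1/n) term
        # over all samples)
        np.testing.assert_allclose(got[1] / got[0], 5 * base[1] / base[0], rtol=1e-12)
        np.testing.assert_allclose(got[2] / got[0], base[2] / base[0], rtol=1e-12)

    def test_no_common_gene_raises(self):
        m = _matrix([[0, 5], [5, 0]])
        with pytest.raises(NormalizationError):
            size_factors(m)


class TestDispersion:
    def _sim(self, **kw):
        p = SimParams(n_genes=2000, lfc_scale=0.0, rng_seed=13, **kw)
        cm, design, _ = simulate_experiment(p)
        return cm, design

    def test_poisson_data_yields_near_zero_dispersion(self):
        cm, design = self._sim(dispersion_mean=1e-6)
        d = fit_dispersion(cm, size_factors(cm), design)
        assert float(np.median(d.alpha_final)) <= 0.05

    def test_constant_dispersion_recovered(self):
        cm, design = self._sim(dispersion_mean=0.2, dispersion_shape=1e6)
        d = fit_dispersion(cm, size_factors(cm), design)
        assert 0.1 <= float(np.median(d.alpha_final)) <= 0.4

    def test_zero_variance_gene_floors_at_zero(self, toy_design):
        arr = np.full((3, 24), 50)
        m = _matrix(arr, samples=toy_design.sample_ids)
        d = fit_dispersion(m, size_factors(m), toy_design)
        assert (d.alpha_raw == 0).all()

    def test_singleton_groups_rejected_at_design_level(self):
        # one sample per population x treatment cell: replication invariant fails
        rows = []
        for pop in ("S1", "T1", "S2", "T2"):
            for trt in ("C", "Z"):
                rows.append(
                    dict(sample=f"{pop}_{trt}", population=pop, treatment=trt,
                         individual=f"{pop}_a")
                )
        from plastevol.io import ValidationError

        with pytest.raises(ValidationError, match="<2 samples"):
            SampleDesign(pd.DataFrame(rows))


class TestVST:
    def test_zero_count_pseudocount_one_maps_to_zero(self):
        m = _matrix([[0, 1], [10, 10]])
        sf = pd.Series([1.0, 1.0], index=m.sample_ids)
        nm = vst(m, sf, pseudocount=1.0)
        assert nm.vst_values.iloc[0, 0] == 0.0

    def test_monotone_in_counts(self):
        m = _matrix([[0, 1], [5, 10], [200, 400], [1000, 2000]])
        sf = pd.Series([1.0, 1.0], index=m.sample_ids)
        nm = vst(m, sf, pseudocount=4.0)
        assert (nm.vst_values["s0"] < nm.vst_values["s1"]).all()

    def test_variance_flat_across_means(self):
        """SD-vs-mean slope of VST values ~ 0 for the upper half of means."""
        rng = np.random.default_rng(5)
        mus = np.geomspace(10, 10_000, 600)
        alpha = 0.05
        draws = rng.negative_binomial(
            1 / alpha, (1 / alpha) / (1 / alpha + mus[:, None]), size=(600, 50)
        )
        m = _matrix(draws)
        sf = pd.Series(np.ones(50), index=m.sample_ids)
        nm = vst(m, sf, pseudocount=1 / (4 * alpha))
        sd = nm.vst_values.std(axis=1).to_numpy()
        upper = mus >= np.median(mus)
        slope = np.polyfit(np.log10(mus[upper]), sd[upper], 1)[0]
        assert abs(slope) < 0.1


class TestContrasts:
    def test_power_simulation_signs_correct(self):
        cm, design, truth = simulate_experiment(
            SimParams(n_genes=800, frac_stress=0.5, frac_cec=0.0, frac_dp=0.0,
                      lfc_scale=3.0, dispersion_mean=0.01, rng_seed=21)
        )
        sf = size_factors(cm)
        disp = fit_dispersion(cm, sf, design)
        de = run_contrast(cm, sf, disp, design, "S_CvZ")
        affected = truth["category"] == "stress_reverted"
        expected = np.where(truth.loc[affected, "direction"] == "up", 1.0, -1.0)
        got = de.direction.loc[affected.index[affected]].to_numpy()
        assert np.mean(got == expected) >= 0.99

    def test_shrunken_fc_never_exceeds_raw(self, default_sim_fit):
        _, res = default_sim_fit
        for de in res.de.values():
            t = de.table.dropna(subset=["lfc_raw"])
            assert (t["lfc_shrunk"].abs() <= t["lfc_raw"].abs() + t["se"]).all()

    def test_gene_order_invariance(self):
        cm, design, _ = simulate_experiment(SimParams(n_genes=100, rng_seed=2))
        sf = size_factors(cm)
        disp = fit_dispersion(cm, sf, design)
        de = run_contrast(cm, sf, disp, design, "T1vS1_C")
        perm = np.random.default_rng(0).permutation(cm.shape[0])
        cm2 = CountMatrix(cm.data.iloc[perm])
        disp2 = fit_dispersion(cm2, sf, design)
        de2 = run_contrast(cm2, sf, disp2, design, "T1vS1_C")
        pd.testing.assert_series_equal(
            de.table["pvalue"].sort_index(), de2.table["pvalue"].sort_index()
        )

    def test_paired_model_absorbs_genotype_offsets(self):
        """Adding a constant offset to one clone pair leaves the zinc effect alone."""
        rows = []
        for k in "ab":
            for trt in ("C", "Z"):
                rows.append(dict(sample=f"S1_{trt}_{k}", population="S1",
                                 treatment=trt, individual=f"S1_{k}"))
        design = SampleDesign(pd.DataFrame(rows))
        X, names = _design_matrix(design, "paired_population")
        offset = np.zeros(4)
        mu = 100 * np.exp(np.array([0.0, 0.8, 0.0, 0.8]))  # zinc effect 0.8
        Y = mu[None, :].copy()
        beta1, _, _ = _irls_nb(Y, X, offset, np.array([0.01]))
        Y2 = Y.copy()
        shifted = [i for i, r in design.table.iterrows() if r["individual"] == "S1_a"]
        Y2[:, shifted] *= 2.5  # constant multiplicative genotype offset
        beta2, _, _ = _irls_nb(Y2, X, offset, np.array([0.01]))
        j = names.index("S1:Z")
        assert beta1[0, j] == pytest.approx(0.8, abs=1e-6)
        assert beta2[0, j] == pytest.approx(beta1[0, j], abs=1e-6)

    def test_empty_cell_contrast_rejected(self, toy_counts, toy_design):
        sub = toy_design.restrict(
            [s for s in toy_design.sample_ids if not s.startswith("T1")]
        )
        m = CountMatrix(toy_counts.data[sub.sample_ids])
        sf = size_factors(m)
        disp = fit_dispersion(m, sf, sub)
        fit = fit_model(m, sf, disp, sub, "group")
        with pytest.raises(ModelError, match="not estimable"):
            fit.contrast("T1vS1_C")

    def test_contrast_model_mismatch_rejected(self, toy_counts, toy_design):
        sf = size_factors(toy_counts)
        disp = fit_dispersion(toy_counts, sf, toy_design)
        fit = fit_model(toy_counts, sf, disp, toy_design, "group")
        with pytest.raises(ModelError, match="needs model"):
            fit.contrast("CvZ_S1")


def _bh_oracle(p):
    """Literal step-up definition: adj_(i) = min_{j>=i} p_(j) * n / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestBHAdjust:
    def test_step_up_example(self):
        got = bh_adjust(pd.Series([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(got.to_numpy(), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust(pd.Series([0.37]))[0] == pytest.approx(0.37)

    def test_all_ones_stay_ones(self):
        assert (bh_adjust(pd.Series([1.0] * 5)) == 1.0).all()

    def test_matches_oracle_on_grid(self):
        grid = [0.001, 0.01, 0.04, 0.2, 0.5, 1.0]
        for n in range(1, 7):
            for combo in itertools.combinations_with_replacement(grid, n):
                got = bh_adjust(pd.Series(combo)).to_numpy()
                np.testing.assert_allclose(got, _bh_oracle(combo), atol=1e-12)

    def test_nan_excluded_and_propagated(self):
        got = bh_adjust(pd.Series([0.01, np.nan, 0.04]))
        assert np.isnan(got[1])
        np.testing.assert_allclose(got[[0, 2]], _bh_oracle([0.01, 0.04]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(pd.Series([0.5, 1.2]))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_oracle_equivalence_property(self, p):
        np.testing.assert_allclose(
            bh_adjust(pd.Series(p)).to_numpy(), _bh_oracle(p), atol=1e-12
        )
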