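import dataclasses

import numpy as np
import pytest

from proxyshift.chronology import sample_age_models
from proxyshift.ensemble import (
    EnsembleSummary,
    default_time_grid,
    envelope_coverage,
    fractional_mean_uncertainty,
    pca_median,
    propagate_pc_envelope,
    simulate_ensemble,
)
from proxyshift.proxies import MeasurementUncertainty, ProxySeries
from proxyshift.synthetic import generate_record, marine_preset

from conftest import exact_truth_spec


def _summary(name, values, grid=None, n_draws=120):
    """A degenerate summary whose every draw equals `values` (zero spread)."""
    values = np.asarray(values, dtype=float)
    grid = np.arange(values.size, dtype=float) if grid is None else grid
    return EnsembleSummary(name=name, time_grid=grid, draws=np.tile(values, (n_draws, 1)))


def _series(name, depth, value, unc):
    return ProxySeries(name=name, depth=depth, value=value, units="", meas_unc=unc)


class TestSimulateEnsemble:
    def test_zero_uncertainty_median_is_raw_interpolation(self, marine_record):
        _, _, spec = marine_record
        horizons, series, _ = generate_record(exact_truth_spec(spec))
        ages = sample_age_models(horizons, 100, series[0].depth, seed=0)
        grid = default_time_grid(series, ages)
        s = series[0]
        summary = simulate_ensemble(s, ages, 100, grid, seed=1)
        true_ages = ages.median_ages  # zero dating error: exact truth
        expected = np.interp(summary.time_grid, true_ages, s.value)
        assert np.allclose(summary.median, expected, atol=1e-9)
        assert np.allclose(summary.p95 - summary.p5, 0.0, atol=1e-12)

    def test_constant_series_median_concentrates_on_truth(self, marine_record):
        horizons, series, _ = marine_record
        ages = sample_age_models(horizons, 10_000, series[0].depth, seed=3)
        v = 50.0
        s = _series(
            "const",
            series[0].depth,
            np.full(series[0].depth.size, v),
            MeasurementUncertainty("relative", 0.075),
        )
        grid = default_time_grid([s], ages)
        summary = simulate_ensemble(s, ages, 10_000, grid, seed=4)
        # the median of n draws has standard error ~ 1.2533 sigma/sqrt(n)
        se = 1.2533 * 0.075 * v / np.sqrt(10_000)
        assert np.all(np.abs(summary.median - v) < 6 * se)

    def test_density_columns_conserve_draws(self, marine_summaries):
        _, summaries, _ = marine_summaries
        for s in summaries:
            assert np.all(s.density.sum(axis=0) == s.n_draws)

    def test_envelope_ordered_and_90pct_coverage(self, marine_summaries):
        _, summaries, _ = marine_summaries
        for s in summaries:
            assert np.all(s.p5 <= s.median) and np.all(s.median <= s.p95)
            assert envelope_coverage(s) == pytest.approx(0.90, abs=0.01)

    def test_seeded_determinism_is_bitwise(self, marine_record):
        horizons, series, _ = marine_record
        ages = sample_age_models(horizons, 200, series[0].depth, seed=5)
        grid = default_time_grid(series, ages)
        a = simulate_ensemble(series[0], ages, 200, grid, seed=6)
        b = simulate_ensemble(series[0], ages, 200, grid, seed=6)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.density, b.density)

    def test_rejects_small_or_oversized_draw_counts(self, marine_record):
        horizons, series, _ = marine_record
        ages = sample_age_models(horizons, 150, series[0].depth, seed=7)
        grid = default_time_grid(series, ages)
        with pytest.raises(ValueError):
            simulate_ensemble(series[0], ages, 50, grid, seed=0)
        with pytest.raises(ValueError):
            simulate_ensemble(series[0], ages, 500, grid, seed=0)

    def test_uncovered_grid_times_are_rejected(self, marine_record, caplog):
        horizons, series, _ = marine_record
        ages = sample_age_models(horizons, 150, series[0].depth, seed=8)
        grid = np.arange(-2000.0, 8000.0, 50.0)  # extends far past the record
        summary = simulate_ensemble(series[0], ages, 150, grid, seed=9)
        assert summary.time_grid.size < grid.size
        assert np.all(np.isfinite(summary.draws))


class TestPcaMedian:
    def test_three_perfectly_correlated_series(self):
        t = np.linspace(0, 1, 40)
        base = np.sin(2 * np.pi * t)
        summaries = [_summary(f"s{i}", (i + 1) * base, grid=t) for i in range(3)]
        syn = pca_median(summaries, orient_proxy="s0")
        assert syn.var_explained[0] == pytest.approx(1.0)
        assert np.abs(syn.loadings[:, 0]) == pytest.approx(np.full(3, 1 / np.sqrt(3)))

    def test_two_exactly_uncorrelated_series_split_variance(self):
        t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        a, b = np.sin(t), np.cos(t)  # orthogonal over a full period
        syn = pca_median([_summary("a", a, t), _summary("b", b, t)])
        assert syn.var_explained == pytest.approx([0.5, 0.5], abs=1e-9)

    def test_orientation_proxy_fixes_pc1_sign(self, marine_summaries):
        _, summaries, _ = marine_summaries
        syn = pca_median(summaries, orient_proxy="hbi3_flux")
        assert syn.loadings[summaries.index(summaries[-1]), 0] > 0

    def test_loadings_orthonormal(self, marine_summaries):
        _, summaries, _ = marine_summaries
        syn = pca_median(summaries)
        gram = syn.loadings.T @ syn.loadings
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-9)
        assert syn.var_explained.sum() == pytest.approx(1.0)

    def test_scale_invariance_of_loadings(self):
        rng = np.random.default_rng(12)
        t = np.arange(50.0)
        vals = rng.standard_normal((3, 50)) + np.sin(t / 5)
        s1 = [_summary(f"s{i}", v, t) for i, v in enumerate(vals)]
        vals2 = vals.copy()
        vals2[1] *= 10.0  # rescaling one raw series
        s2 = [_summary(f"s{i}", v, t) for i, v in enumerate(vals2)]
        a, b = pca_median(s1), pca_median(s2)
        assert np.allclose(a.loadings, b.loadings, atol=1e-9)

    def test_zero_variance_series_rejected_by_name(self):
        s = [_summary("flat", np.ones(20)), _summary("ok", np.arange(20.0))]
        with pytest.raises(ValueError, match="flat"):
            pca_median(s)

    def test_matches_sklearn_pca(self, marine_summaries):
        sklearn = pytest.importorskip("sklearn.decomposition")
        _, summaries, _ = marine_summaries
        syn = pca_median(summaries)
        m = np.column_stack([s.median for s in summaries])
        z = (m - m.mean(0)) / m.std(0, ddof=1)
        ref = sklearn.PCA(n_components=3).fit(z)
        for j in range(3):
            ours, theirs = syn.loadings[:, j], ref.components_[j]
            align = np.sign(ours @ theirs)
            assert np.allclose(ours, align * theirs, atol=1e-8)
        assert np.allclose(syn.var_explained, ref.explained_variance_ratio_, atol=1e-8)


class TestEnvelopePropagation:
    def test_zero_fractions_collapse_envelope(self):
        t = np.arange(30.0)
        vals = [np.sin(t / 3) + 2, np.cos(t / 3) + 2]
        summaries = [_summary(f"s{i}", v, t) for i, v in enumerate(vals)]
        syn = propagate_pc_envelope(pca_median(summaries), summaries)
        assert np.allclose(syn.pc1_lo, syn.pc1_series)
        assert np.allclose(syn.pc1_hi, syn.pc1_series)

    def test_uniform_fraction_gives_proportional_halfwidth(self):
        # two perfectly correlated series (equal |loadings|) built from a
        # symmetric three-point draw cloud, so every fractional width is equal
        t = np.arange(40.0)
        base = np.sin(t / 4) + 3.0
        offsets = np.array([-0.1645, 0.0, 0.1645])
        summaries = []
        for i in range(2):
            draws = base * (i + 1) * (1.0 + offsets[:, None])
            summaries.append(
                EnsembleSummary(name=f"s{i}", time_grid=t, draws=np.repeat(draws, 40, axis=0))
            )
        syn = pca_median(summaries, orient_proxy="s0")
        out = propagate_pc_envelope(syn, summaries)
        f = [fractional_mean_uncertainty(s) for s in summaries]
        assert f[0] == pytest.approx(f[1], rel=1e-9)  # same fractional width
        half = (out.pc1_hi - out.pc1_lo) / 2.0
        assert np.allclose(half, np.abs(syn.pc1_series) * f[0], atol=1e-9)

    def test_envelope_widens_when_one_fraction_doubles(self):
        t = np.arange(50.0)
        base = [np.sin(t / 5) + 2.5, np.cos(t / 5) + 2.5, np.sin(t / 7) + 2.5]

        def make(frac0):
            out = []
            for i, b in enumerate(base):
                frac = frac0 if i == 0 else 0.05
                offsets = np.array([-1.0, 0.0, 1.0]) * frac * 1.645
                draws = b * (1.0 + offsets[:, None])
                out.append(
                    EnsembleSummary(name=f"s{i}", time_grid=t, draws=np.repeat(draws, 40, 0))
                )
            return out

        widths = []
        for frac0 in (0.05, 0.10, 0.20):
            summaries = make(frac0)
            syn = propagate_pc_envelope(pca_median(summaries), summaries)
            widths.append(float(np.mean(syn.pc1_hi - syn.pc1_lo)))
        assert widths[0] < widths[1] < widths[2]

    def test_x_envelope_from_age_ensemble(self, marine_summaries):
        ages, summaries, _ = marine_summaries
        syn = propagate_pc_envelope(pca_median(summaries), summaries, ages=ages)
        assert syn.x_halfwidth is not None
        assert syn.x_halfwidth.shape == syn.time_grid.shape
        assert np.all(syn.x_halfwidth >= 0)

    def test_mismatched_summaries_rejected(self, marine_summaries):
        _, summaries, _ = marine_summaries
        syn = pca_median(summaries)
        with pytest.raises(ValueError):
            propagate_pc_envelope(syn, summaries[::-1])


def test_marine_pc1_sign_structure_recovered_across_replicates():
    """Production proxies load together and opposite to the ice-margin biomarker.

    The marine preset injects anticorrelated production/HBI III histories; the
    PC1 sign pattern (+, +, -) should be recovered in nearly every replicate.
    """
    hits = 0
    n_rep = 100
    for rep in range(n_rep):
        horizons, series, _ = generate_record(marine_preset(seed=1000 + rep))
        ages = sample_age_models(horizons, 100, series[0].depth, seed=rep)
        grid = default_time_grid(series, ages)
        summaries = [
            simulate_ensemble(s, ages, 100, grid, seed=3 * rep + i)
            for i, s in enumerate(series)
        ]
        syn = pca_median(summaries, orient_proxy="diatom_flux")
        l = syn.loadings[:, 0]
        hits += l[0] > 0 and l[1] > 0 and l[2] < 0
    assert hits >= 0.95 * n_rep
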