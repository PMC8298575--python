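import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proxyshift.proxies import (
    AssemblageTable,
    MeasurementUncertainty,
    ProxySeries,
    assemblage_pc_scores,
    cd_ti_ratio,
    compute_flux,
    diatom_index,
    fractional_sterol,
    load_proxies_csv,
    relative_abundance,
    sterol_index,
    toc_normalise,
    write_derived_csv,
)


def _series(name, values, depth=None, unc=None, units=""):
    values = np.asarray(values, dtype=float)
    depth = np.arange(len(values), dtype=float) if depth is None else np.asarray(depth)
    return ProxySeries(
        name=name,
        depth=depth,
        value=values,
        units=units,
        meas_unc=unc or MeasurementUncertainty("absolute", 0.0),
    )


class TestFlux:
    def test_examples(self):
        conc = _series("diatom", [0.0, 200.0, 150.0], units="ind g-1")
        mar = _series("mar", [0.4, 0.5, 1.0], units="g cm-2 yr-1")
        flux = compute_flux(conc, mar)
        assert flux.value == pytest.approx([0.0, 100.0, 150.0])
        assert flux.units == "ind cm-2 yr-1"

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        c, m = rng.uniform(1, 100, 30), rng.uniform(0.1, 2, 30)
        flux = compute_flux(_series("c", c), _series("m", m))
        expected = [ci * mi for ci, mi in zip(c, m)]  # brute-force recompute
        assert flux.value == pytest.approx(expected)

    def test_rejects_depth_mismatch_and_nonpositive_mar(self):
        with pytest.raises(ValueError):
            compute_flux(_series("c", [1, 2]), _series("m", [1, 2], depth=[0, 5]))
        with pytest.raises(ValueError):
            compute_flux(_series("c", [1, 2]), _series("m", [1, 0]))


class TestTocNormalise:
    def test_identity_at_100pct_and_arithmetic(self):
        bio = _series("ip25", [10.0, 10.0], units="ng")
        assert toc_normalise(bio, _series("toc", [100.0, 100.0])).value == pytest.approx(
            [10.0, 10.0]
        )
        assert toc_normalise(bio, _series("toc", [2.0, 2.0])).value == pytest.approx(
            [500.0, 500.0]
        )

    def test_drops_nonpositive_toc_samples(self, caplog):
        bio = _series("ip25", [10.0, 20.0, 30.0])
        with caplog.at_level("WARNING"):
            out = toc_normalise(bio, _series("toc", [1.0, 0.0, 2.0]))
        assert len(out) == 2
        assert out.value == pytest.approx([1000.0, 1500.0])
        assert "dropping" in caplog.text

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        b, t = rng.uniform(1, 50, 20), rng.uniform(0.5, 5, 20)
        out = toc_normalise(_series("b", b), _series("t", t))
        assert out.value == pytest.approx([bi / (ti / 100) for bi, ti in zip(b, t)])


class TestSterolIndex:
    def test_excrement_reference_values(self):
        """Little auk excrement gives ~0.99, goose excrement ~0.09."""
        assert round(sterol_index(1497.0, 15.0), 2) == 0.99
        assert round(sterol_index(16.0, 159.0), 2) == 0.09

    def test_pure_cholesterol_and_undefined_cases(self):
        assert sterol_index(5.0, 0.0) == 1.0
        with pytest.raises(ValueError):
            sterol_index(0.0, 0.0)
        with pytest.raises(ValueError):
            sterol_index(-1.0, 2.0)

    @given(
        c=st.floats(0.001, 1e6),
        b=st.floats(0.001, 1e6),
        k=st.floats(0.001, 1e6),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, c, b, k):
        assert sterol_index(k * c, k * b) == pytest.approx(sterol_index(c, b), rel=1e-9)


class TestFractionalSterol:
    def test_index_one_is_identity_and_product(self):
        assert fractional_sterol(0.002, 1.0) == pytest.approx(0.002)
        assert fractional_sterol(0.002, 0.5) == pytest.approx(0.001)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        f, r = rng.uniform(0, 0.01, 25), rng.uniform(0, 1, 25)
        assert fractional_sterol(f, r) == pytest.approx([a * b for a, b in zip(f, r)])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fractional_sterol(-0.1, 0.5)
        with pytest.raises(ValueError):
            fractional_sterol(0.1, 1.5)


class TestCdTi:
    def test_equal_counts_give_unit_ratio(self):
        depth = np.arange(0, 1.0, 0.01)  # 0.1 mm steps
        cd = _series("cd", np.full(depth.size, 3.0), depth=depth)
        ti = _series("ti", np.full(depth.size, 3.0), depth=depth)
        out = cd_ti_ratio(cd, ti, bin_mm=1.0)
        assert np.allclose(out.value, 1.0)

    def test_bins_sum_before_dividing(self):
        depth = np.arange(10) * 0.01  # all rows inside one 1-mm bin
        cd = _series("cd", np.ones(10), depth=depth)
        ti = _series("ti", np.full(10, 2.0), depth=depth)
        out = cd_ti_ratio(cd, ti, bin_mm=1.0)
        assert out.value == pytest.approx([0.5])

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(4)
        depth = np.arange(0, 2.0, 0.01)
        cd_v = rng.integers(0, 50, depth.size).astype(float)
        ti_v = rng.integers(1, 80, depth.size).astype(float)
        out = cd_ti_ratio(
            _series("cd", cd_v, depth=depth), _series("ti", ti_v, depth=depth), bin_mm=2.0
        )
        # brute-force binning at 2 mm = 0.2 cm
        edges = np.arange(depth[0], depth[-1] + 0.2, 0.2)
        expected = []
        for a, b in zip(edges[:-1], edges[1:]):
            sel = (depth >= a) & (depth < b)
            if sel.any() and ti_v[sel].sum() > 0:
                expected.append(cd_v[sel].sum() / ti_v[sel].sum())
        assert out.value == pytest.approx(expected)

    def test_drops_zero_ti_bins(self, caplog):
        depth = np.arange(20) * 0.01
        ti_v = np.r_[np.zeros(10), np.ones(10)]
        with caplog.at_level("WARNING"):
            out = cd_ti_ratio(
                _series("cd", np.ones(20), depth=depth),
                _series("ti", ti_v, depth=depth),
                bin_mm=1.0,
            )
        assert len(out) == 1
        assert "zero Ti" in caplog.text


def _table(counts, depth=None):
    counts = pd.DataFrame(counts)
    depth = np.arange(len(counts), dtype=float) if depth is None else depth
    return AssemblageTable(depth=depth, counts=counts)


class TestAssemblage:
    def test_single_taxon_and_ratio(self):
        pct = relative_abundance(_table({"a": [500], "b": [0]}))
        assert pct["a"].iloc[0] == pytest.approx(100.0)
        pct = relative_abundance(_table({"a": [300], "b": [100]}))
        assert pct[["a", "b"]].iloc[0].to_list() == pytest.approx([75.0, 25.0])

    def test_rows_sum_to_100_on_random_tables(self):
        rng = np.random.default_rng(5)
        counts = {f"t{i}": rng.integers(0, 300, 12) for i in range(6)}
        counts["t0"] += 400  # keep totals above the quantitative minimum
        pct = relative_abundance(_table(counts))
        sums = pct.drop(columns="depth_cm").sum(axis=1)
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_warns_below_400_valves_and_rejects_zero_totals(self, caplog):
        with caplog.at_level("WARNING"):
            relative_abundance(_table({"a": [100], "b": [50]}))
        assert "below the 400-valve minimum" in caplog.text
        with pytest.raises(ValueError):
            relative_abundance(_table({"a": [0], "b": [0]}))

    def test_pc_scores_shapes_and_variance_fractions(self):
        rng = np.random.default_rng(6)
        n = 30
        grad = np.linspace(0, 1, n)
        counts = {
            "acid1": np.round(400 * grad + rng.integers(0, 30, n)).astype(int),
            "acid2": np.round(300 * grad + rng.integers(0, 30, n)).astype(int),
            "alk1": np.round(400 * (1 - grad) + rng.integers(0, 30, n)).astype(int),
            "alk2": np.round(200 + rng.integers(0, 40, n)).astype(int),
        }
        scores, var = assemblage_pc_scores(_table(counts), n_components=2)
        assert scores.shape == (n, 2)
        assert var.sum() == pytest.approx(1.0)
        assert var[0] >= var[1] >= 0
        # opposing gradient taxa -> PC1 tracks the gradient strongly
        assert abs(np.corrcoef(scores[:, 0], grad)[0, 1]) > 0.9


class TestDiatomIndex:
    def test_equal_weights_give_plain_mean(self):
        scores = np.array([[1.0, 3.0], [2.0, 0.0]])
        out = diatom_index(scores, (0.5, 0.5))
        assert out == pytest.approx([2.0, 1.0])

    def test_study_weights_hand_value(self):
        # v = (0.34, 0.27), PC1 = 1, PC2 = 0 -> 0.34/0.61
        out = diatom_index(np.array([[1.0, 0.0]]), (0.34, 0.27))
        assert out[0] == pytest.approx(0.34 / 0.61)

    def test_zero_second_weight_reduces_to_pc1(self):
        scores = np.array([[1.0, 9.0], [-2.0, 4.0]])
        assert diatom_index(scores, (0.4, 0.0)) == pytest.approx([1.0, -2.0])

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            diatom_index(np.array([[1.0]]), (0.3, 0.3))
        with pytest.raises(ValueError):
            diatom_index(np.array([[1.0, 2.0]]), (0.0, 0.0))


def test_proxies_csv_roundtrip_preserves_units(tmp_path):
    path = tmp_path / "proxies.csv"
    s1 = _series("d15n", [3.0, 4.0, 5.0], units="per mil")
    s2 = _series("cd_ti", [0.1, 0.2, 0.3], units="ratio")
    write_derived_csv([s1, s2], path)
    loaded = load_proxies_csv(
        path, {"d15n": MeasurementUncertainty("absolute", 0.5)}
    )
    by_name = {s.name: s for s in loaded}
    assert by_name["d15n"].units == "per mil"
    assert by_name["d15n"].meas_unc.magnitude == 0.5
    assert by_name["cd_ti"].value == pytest.approx([0.1, 0.2, 0.3])
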