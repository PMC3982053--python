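"""Signal conditioning and connectivity construction."""

import numpy as np
import pytest

from signet import (
    ConnectivityMatrix,
    ROITimeSeries,
    bandpass_filter,
    connectivity_matrix,
    discard_initial_volumes,
    regress_nuisance,
    subnetwork,
)
from signet.atlas import aal90_labels, cognitive_circuit_labels


def make_ts(values, tr=2.4):
    values = np.asarray(values, dtype=float)
    labels = tuple(f"R{i}" for i in range(values.shape[1]))
    return ROITimeSeries(values, tr, labels)


class TestDiscardInitialVolumes:
    def test_two_of_212_leaves_210(self, rng):
        ts = make_ts(rng.standard_normal((212, 4)))
        out = discard_initial_volumes(ts, 2)
        assert out.n_volumes == 210
        np.testing.assert_array_equal(out.values, ts.values[2:])
        assert out.tr_seconds == ts.tr_seconds
        assert out.roi_labels == ts.roi_labels

    def test_zero_discard_is_identity(self, rng):
        ts = make_ts(rng.standard_normal((10, 3)))
        np.testing.assert_array_equal(discard_initial_volumes(ts, 0).values, ts.values)

    def test_discarding_all_volumes_rejected(self, rng):
        ts = make_ts(rng.standard_normal((5, 3)))
        with pytest.raises(ValueError, match="discard"):
            discard_initial_volumes(ts, 5)


class TestRegressNuisance:
    def test_roi_equal_to_nuisance_becomes_zero(self, rng):
        vals = rng.standard_normal((50, 3))
        out = regress_nuisance(make_ts(vals), vals[:, [0]])
        assert np.abs(out.values[:, 0]).max() < 1e-10

    def test_orthogonal_nuisance_only_demeans(self, rng):
        vals = rng.standard_normal((100, 4))
        vals -= vals.mean(axis=0)
        nuis = rng.standard_normal((100, 2))
        nuis -= nuis.mean(axis=0)
        # orthogonalize nuisance against the ROI columns
        nuis -= vals @ np.linalg.lstsq(vals, nuis, rcond=None)[0]
        out = regress_nuisance(make_ts(vals), nuis)
        np.testing.assert_allclose(out.values, vals, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        vals = rng.standard_normal((100, 5))
        nuis = rng.standard_normal((100, 3))
        out = regress_nuisance(make_ts(vals), nuis)
        design = np.column_stack([np.ones(100), nuis])
        beta = np.linalg.solve(design.T @ design, design.T @ vals)
        np.testing.assert_allclose(out.values, vals - design @ beta, atol=1e-10)

    def test_residuals_orthogonal_to_nuisance(self, rng):
        vals = rng.standard_normal((80, 6))
        nuis = rng.standard_normal((80, 2))
        out = regress_nuisance(make_ts(vals), nuis)
        inner = np.abs(nuis.T @ out.values)
        bound = 1e-8 * np.outer(
            np.linalg.norm(nuis, axis=0), np.linalg.norm(vals, axis=0)
        )
        assert (inner < bound + 1e-12).all()

    def test_rank_deficient_design_warns(self, rng):
        vals = rng.standard_normal((30, 2))
        col = rng.standard_normal((30, 1))
        with pytest.warns(RuntimeWarning, match="rank deficient"):
            regress_nuisance(make_ts(vals), np.hstack([col, col]))


class TestBandpassFilter:
    def make_sine(self, freq_hz, tr=2.4, n=210):
        t = np.arange(n) * tr
        return make_ts(np.sin(2 * np.pi * freq_hz * t)[:, None], tr)

    def test_stopband_sine_attenuated(self):
        ts = self.make_sine(0.15)
        out = bandpass_filter(ts, 0.01, 0.08)
        assert out.values.var() < 0.1 * ts.values.var()

    def test_passband_sine_retained(self):
        ts = self.make_sine(0.04)
        out = bandpass_filter(ts, 0.01, 0.08)
        assert out.values.var() > 0.7 * ts.values.var()

    def test_constant_series_zeroed(self):
        ts = make_ts(np.full((50, 2), 3.7))
        out = bandpass_filter(ts, 0.01, 0.08)
        assert np.abs(out.values).max() < 1e-10

    def test_output_mean_free(self, rng):
        ts = make_ts(rng.standard_normal((100, 3)) + 5.0)
        out = bandpass_filter(ts, 0.01, 0.08)
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-10)

    def test_band_above_nyquist_rejected(self, rng):
        ts = make_ts(rng.standard_normal((50, 2)), tr=2.4)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(ts, 0.01, 0.3)


class TestConnectivityMatrix:
    def test_duplicated_column_gives_unit_weight(self, rng):
        col = rng.standard_normal(100)
        cm = connectivity_matrix(make_ts(np.column_stack([col, col])))
        assert cm.weights[0, 1] == pytest.approx(1.0)
        assert cm.weights[0, 0] == 0.0

    def test_negated_column_gives_minus_one(self, rng):
        col = rng.standard_normal(100)
        cm = connectivity_matrix(make_ts(np.column_stack([col, -col])))
        assert cm.weights[0, 1] == pytest.approx(-1.0)

    def test_matches_pearson_formula_oracle(self, rng):
        vals = rng.standard_normal((210, 4))
        cm = connectivity_matrix(make_ts(vals))
        for i in range(4):
            for j in range(i + 1, 4):
                x, y = vals[:, i] - vals[:, i].mean(), vals[:, j] - vals[:, j].mean()
                r = (x @ y) / np.sqrt((x @ x) * (y @ y))
                assert cm.weights[i, j] == pytest.approx(r, abs=1e-12)

    def test_affine_rescaling_invariance(self, rng):
        vals = rng.standard_normal((120, 5))
        cm1 = connectivity_matrix(make_ts(vals))
        scaled = vals * np.array([2.0, -3.0, 0.5, 10.0, 1.0]) + np.arange(5)
        cm2 = connectivity_matrix(make_ts(scaled))
        # negating a column flips its correlations' signs only
        signs = np.sign([2.0, -3.0, 0.5, 10.0, 1.0])
        np.testing.assert_allclose(
            cm2.weights, cm1.weights * np.outer(signs, signs), atol=1e-12
        )

    def test_zero_variance_column_named(self, rng):
        vals = rng.standard_normal((50, 3))
        vals[:, 1] = 4.2
        with pytest.raises(ValueError, match="R1"):
            connectivity_matrix(make_ts(vals))


class TestSubnetwork:
    def make_cm(self, n, rng):
        w = rng.uniform(-1, 1, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        return ConnectivityMatrix(w, tuple(f"R{i}" for i in range(n)))

    def test_full_subset_is_identity(self, rng):
        cm = self.make_cm(5, rng)
        out = subnetwork(cm, list(cm.roi_labels))
        np.testing.assert_array_equal(out.weights, cm.weights)

    def test_packaged_circuit_on_90_roi_matrix(self, rng):
        w = rng.uniform(-0.9, 0.9, (90, 90))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        cm = ConnectivityMatrix(w, tuple(aal90_labels()))
        out = subnetwork(cm, cognitive_circuit_labels())
        assert out.n_nodes == 60

    def test_pair_subset_keeps_original_weight(self, rng):
        cm = self.make_cm(6, rng)
        out = subnetwork(cm, ["R1", "R4"])
        assert out.weights[0, 1] == cm.weights[1, 4]

    def test_composition(self, rng):
        cm = self.make_cm(8, rng)
        a = ["R0", "R2", "R3", "R5", "R7"]
        b = ["R2", "R5", "R7"]
        direct = subnetwork(cm, b)
        nested = subnetwork(subnetwork(cm, a), b)
        np.testing.assert_array_equal(direct.weights, nested.weights)
        assert direct.roi_labels == nested.roi_labels

    def test_unknown_label_listed(self, rng):
        cm = self.make_cm(4, rng)
        with pytest.raises(ValueError, match="Rx"):
            subnetwork(cm, ["R0", "Rx"])
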