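"""HRF, condition weights, weighted correlation, Fisher z, RRC matrices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nbsfc
from nbsfc import (
    DegenerateConditionError,
    InvalidArgumentError,
    OutOfDomainError,
    ZeroVarianceError,
    build_rrc,
    canonical_hrf,
    condition_weights,
    fisher_z,
    weighted_pearson,
)
from nbsfc.connectivity import _boxcar
from nbsfc.design import TaskDesign, TrialEvent
from nbsfc.preprocess import CensorMask, CleanSeries


class TestCanonicalHRF:
    def test_double_gamma_shape(self):
        h = canonical_hrf(tr=2.0)
        signs = np.sign(h[np.abs(h) > 1e-6])
        flips = np.flatnonzero(np.diff(signs))
        assert len(flips) == 1  # single + to - crossing
        assert signs[0] > 0 and signs[-1] < 0
        assert h.sum() > 0

    def test_impulse_convolution_identity(self):
        h = canonical_hrf(tr=1.0)
        impulse = np.zeros(len(h))
        impulse[0] = 1.0
        assert np.allclose(np.convolve(impulse, h)[: len(h)], h)

    def test_invalid_tr(self):
        with pytest.raises(InvalidArgumentError):
            canonical_hrf(tr=0.0)


class TestConditionWeights:
    def _single_event_design(self):
        return TaskDesign(
            events=[TrialEvent("self", 10.0, 0.1)], tr=2.0, n_frames=30
        )

    def test_matches_direct_convolution_oracle(self):
        """Single event: weights equal the rectified discrete convolution."""
        d = self._single_event_design()
        hrf = canonical_hrf(d.tr)
        w = condition_weights(d, "self", hrf=hrf).w
        box = _boxcar(d, "self")
        oracle = np.maximum(np.convolve(box, hrf)[:30], 0.0)
        assert np.allclose(w, oracle, atol=1e-12)
        assert (w >= 0).all() and w.sum() > 0

    def test_absent_condition_rejected(self):
        with pytest.raises(InvalidArgumentError, match="does not occur"):
            condition_weights(self._single_event_design(), "stranger")

    def test_fully_censored_run_is_degenerate(self):
        d = self._single_event_design()
        mask = CensorMask(keep=np.zeros(30, dtype=bool))
        with pytest.raises(DegenerateConditionError, match="no usable frames"):
            condition_weights(d, "self", mask=mask)

    def test_censored_frames_zero_weight(self):
        d = self._single_event_design()
        keep = np.ones(30, dtype=bool)
        keep[6] = False
        w = condition_weights(d, "self", mask=CensorMask(keep=keep)).w
        assert w[6] == 0.0


class TestWeightedPearson:
    def test_uniform_weights_reduce_to_pearson(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(2, 200))
        r_w = weighted_pearson(x, y, np.full(200, 2.7))
        r_plain = np.corrcoef(x, y)[0, 1]
        assert abs(r_w - r_plain) < 1e-12

    def test_affine_invariance_gives_unity(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=100)
        w = rng.uniform(0.1, 2.0, size=100)
        assert weighted_pearson(x, 2 * x + 3, w) == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_definitional_sum_oracle(self, seed):
        """Matches the explicit weighted-sum formula to 1e-12."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        x, y = rng.normal(size=(2, n))
        w = rng.uniform(0.0, 3.0, size=n)
        w[0] = 1.0  # guarantee positive total weight
        sw = w.sum()
        mx, my = (w * x).sum() / sw, (w * y).sum() / sw
        num = (w * (x - mx) * (y - my)).sum()
        den = np.sqrt((w * (x - mx) ** 2).sum() * (w * (y - my) ** 2).sum())
        assert abs(weighted_pearson(x, y, w) - num / den) < 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroVarianceError):
            weighted_pearson(np.ones(10), np.arange(10.0), np.ones(10))

    def test_negative_weights_rejected(self):
        with pytest.raises(InvalidArgumentError, match="nonnegative"):
            weighted_pearson(np.arange(5.0), np.arange(5.0), np.array([1, 1, -1, 1, 1.0]))


class TestFisherZ:
    def test_known_values_and_oddness(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493061443340549, abs=1e-12)
        grid = np.linspace(-0.95, 0.95, 21)
        assert np.allclose(fisher_z(-grid), -fisher_z(grid))
        assert np.all(np.diff(fisher_z(grid)) > 0)

    @pytest.mark.parametrize("bad", [1.0, -1.0, 1.5])
    def test_out_of_domain(self, bad):
        with pytest.raises(OutOfDomainError):
            fisher_z(bad)


class TestBuildRRC:
    def _design_and_series(self, n_nodes=6, seed=0):
        d = nbsfc.generate_design(8, ["self", "stranger"], seed=seed)
        rng = np.random.default_rng(seed + 1)
        series = rng.normal(size=(d.total_frames, n_nodes))
        return d, series

    def test_edge_count_30_nodes(self):
        assert nbsfc.n_edges(30) == 435
        d, _ = self._design_and_series()
        rng = np.random.default_rng(9)
        series = rng.normal(size=(d.total_frames, 30))
        rrc = build_rrc(series, d, ["self"])["self"]
        assert rrc.edge_vector().shape == (435,)
        assert np.isfinite(rrc.edge_vector()).all()

    def test_symmetry_and_nan_diagonal(self):
        d, series = self._design_and_series()
        z = build_rrc(series, d, ["self", "stranger"])["stranger"].z
        assert np.allclose(z, z.T, equal_nan=True)
        assert np.isnan(np.diag(z)).all()

    def test_identical_nodes_raise(self):
        d, series = self._design_and_series()
        series[:, 1] = series[:, 0]
        with pytest.raises(OutOfDomainError, match="cannot Fisher-transform"):
            build_rrc(series, d, ["self"])

    def test_node_permutation_equivariance(self):
        d, series = self._design_and_series()
        perm = np.array([3, 1, 5, 0, 2, 4])
        z = build_rrc(series, d, ["self"])["self"].z
        z_perm = build_rrc(series[:, perm], d, ["self"])["self"].z
        assert np.allclose(z_perm, z[np.ix_(perm, perm)], equal_nan=True)

    def test_positive_scaling_invariance(self):
        d, series = self._design_and_series()
        scaled = series.copy()
        scaled[:, 2] *= 17.0
        z1 = build_rrc(series, d, ["self"])["self"].z
        z2 = build_rrc(scaled, d, ["self"])["self"].z
        assert np.allclose(z1, z2, equal_nan=True)

    def test_whole_run_condition_uniform_weights_equal_plain_corr(self):
        """A single condition spanning the run with uniform weights reduces
        to the ordinary correlation matrix of the series."""
        n, nn = 120, 5
        d = TaskDesign(
            events=[TrialEvent("all", 0.0, n * 2.0 - 1e-6)], tr=2.0, n_frames=n
        )
        rng = np.random.default_rng(11)
        series = rng.normal(size=(n, nn))
        hrf = np.array([1.0])  # identity kernel: weights = boxcar = 1
        z = build_rrc(series, d, ["all"], hrf=hrf)["all"].z
        iu, ju = np.triu_indices(nn, 1)
        expected = np.arctanh(np.corrcoef(series.T)[iu, ju])
        assert np.allclose(z[iu, ju], expected, atol=1e-10)

    def test_mask_zero_weights_respected(self):
        d, series = self._design_and_series()
        keep = np.ones(d.total_frames, dtype=bool)
        keep[::7] = False
        clean = CleanSeries(
            timeseries=series, mask=CensorMask(keep=keep), node_labels=[]
        )
        z_masked = build_rrc(clean, d, ["self"])["self"].z
        z_plain = build_rrc(series, d, ["self"])["self"].z
        assert not np.allclose(z_masked, z_plain, equal_nan=True)
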