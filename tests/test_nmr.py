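"""Karplus couplings, centroid distances, and iRED order parameters."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from glycoconf.nmr import (
    KarplusParameters,
    compare_j_tables,
    ensemble_j,
    ired_order_parameters,
    karplus_3jhh,
    load_karplus_parameters,
    ring_centroid_distance,
)

from _oracles import karplus_oracle

BARE = KarplusParameters(P1=13.22, P2=-0.99, P3=0.0)
SUBSTITUTED = KarplusParameters(
    P1=13.22, P2=-0.99, P3=0.0, P4=0.87, P5=-2.46, P6=19.9,
    substituents=((1.27, +1), (1.26, -1), (0.40, +1)),
)


def cone_vectors(rng, alpha_deg, n_vec, n_frames):
    """Independent uniform-cap wobble about isotropic fixed axes."""
    alpha = math.radians(alpha_deg)
    axes = rng.standard_normal((n_vec, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    cos_t = rng.uniform(math.cos(alpha), 1.0, (n_frames, n_vec))
    phi = rng.uniform(0.0, 2.0 * math.pi, (n_frames, n_vec))
    sin_t = np.sqrt(1.0 - cos_t**2)
    local = np.stack(
        [sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=-1
    )
    frames = []
    for a in axes:
        x = np.cross(a, [0.0, 0.0, 1.0])
        if np.linalg.norm(x) < 1e-8:
            x = np.cross(a, [0.0, 1.0, 0.0])
        x /= np.linalg.norm(x)
        y = np.cross(a, x)
        frames.append(np.stack([x, y, a], axis=1))
    return np.einsum("vij,tvj->tvi", np.stack(frames), local)


class TestKarplus:
    def test_unsubstituted_limits(self):
        assert karplus_3jhh(90.0, BARE) == pytest.approx(BARE.P3, abs=1e-12)
        assert karplus_3jhh(0.0, BARE) == pytest.approx(
            BARE.P1 + BARE.P2 + BARE.P3, abs=1e-12
        )

    def test_reduces_to_classic_three_term_curve(self):
        thetas = np.linspace(-180, 180, 37)
        t = np.radians(thetas)
        classic = BARE.P1 * np.cos(t) ** 2 + BARE.P2 * np.cos(t) + BARE.P3
        assert np.allclose(karplus_3jhh(thetas, BARE), classic, atol=1e-12)

    @pytest.mark.parametrize("theta", [-150.0, -60.0, 0.0, 60.0, 90.0, 178.0])
    def test_substituted_matches_term_oracle(self, theta):
        expected = karplus_oracle(
            theta, SUBSTITUTED.P1, SUBSTITUTED.P2, SUBSTITUTED.P3,
            SUBSTITUTED.P4, SUBSTITUTED.P5, SUBSTITUTED.P6,
            SUBSTITUTED.substituents,
        )
        assert karplus_3jhh(theta, SUBSTITUTED) == pytest.approx(
            expected, abs=1e-12
        )

    def test_shipped_parameter_file(self):
        params = load_karplus_parameters([("OR", 1), ("OH", -1), ("C", 1)])
        assert len(params.substituents) == 3
        assert params.P1 == pytest.approx(13.22)
        with pytest.raises(ValueError):
            load_karplus_parameters([("XX", 1), ("C", -1)])
        with pytest.raises(ValueError):
            load_karplus_parameters([("C", 1)])  # no 1-substituent set

    def test_orientation_factor_validated(self):
        with pytest.raises(ValueError):
            KarplusParameters(P1=1, P2=1, P3=0, substituents=((1.0, 2),))


class TestEnsembleJ:
    def test_constant_series(self):
        res = ensemble_j(np.full(50, 55.0), SUBSTITUTED)
        assert res.mean_hz == pytest.approx(
            karplus_3jhh(55.0, SUBSTITUTED), abs=1e-12
        )

    def test_mixture_averages_j_not_theta(self):
        series = np.concatenate([np.full(500, 60.0), np.full(500, 180.0)])
        res = ensemble_j(series, BARE)
        j_mixture = 0.5 * (
            karplus_3jhh(60.0, BARE) + karplus_3jhh(180.0, BARE)
        )
        assert res.mean_hz == pytest.approx(j_mixture, abs=1e-12)
        assert res.mean_hz != pytest.approx(
            karplus_3jhh(120.0, BARE), abs=0.5
        )

    def test_two_state_population_weighting(self):
        from glycoconf.synthetic import MarkovState, SyntheticTrajectorySpec
        from glycoconf.synthetic import simulate_markov_series

        spec = SyntheticTrajectorySpec(
            states=(
                MarkovState.make("g", (60.0,), (2.0,)),
                MarkovState.make("t", (180.0,), (2.0,)),
            ),
            populations=(0.7, 0.3),
            pair_rates={frozenset({"g", "t"}): 5000.0},
            n_frames=200_000,
            seed=12,
        )
        sim = simulate_markov_series(spec)
        res = ensemble_j(sim.angles[:, 0], BARE)
        # population-weighted closed form with the Gaussian width correction
        # folded in numerically
        rng = np.random.default_rng(1)
        noise = 2.0 * rng.standard_normal(100_000)
        closed = 0.7 * np.mean(karplus_3jhh(60.0 + noise, BARE)) + \
            0.3 * np.mean(karplus_3jhh(180.0 + noise, BARE))
        assert res.mean_hz == pytest.approx(closed, abs=0.1)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            ensemble_j([], BARE)


class TestCompareTables:
    def test_identical_tables(self):
        table = {"H1H2": 3.2, "H2H3": 9.8}
        cmp = compare_j_tables(table, dict(table))
        assert cmp.n_within == cmp.n_total == 2

    def test_outlier_excluded_and_reported(self):
        cmp = compare_j_tables(
            {"a": 5.0, "b": 4.0}, {"a": 5.0, "b": 1.6}, tolerance_hz=2.0
        )
        assert cmp.n_within == 1 and cmp.n_total == 2
        assert cmp.deviations_hz["b"] == pytest.approx(2.4)

    def test_empty_experimental(self):
        cmp = compare_j_tables({"a": 5.0}, {})
        assert (cmp.n_within, cmp.n_total) == (0, 0)
        assert cmp.unmatched_calculated == ("a",)

    def test_unmatched_listed_both_ways(self):
        cmp = compare_j_tables({"a": 1.0}, {"b": 1.0})
        assert cmp.unmatched_calculated == ("a",)
        assert cmp.unmatched_experimental == ("b",)


class TestCentroidDistance:
    def test_rigid_translation(self):
        rng = np.random.default_rng(3)
        ring = rng.standard_normal((6, 3))
        a = np.tile(ring, (20, 1, 1))
        b = a + np.array([5.0, 0.0, 0.0])
        mean, sd, _ = ring_centroid_distance(a, b)
        assert mean == pytest.approx(5.0, abs=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_single_frame_sd_zero(self):
        ring = np.eye(6, 3)
        _, sd, series = ring_centroid_distance(ring[None], ring[None] + 1.0)
        assert sd == 0.0 and series.shape == (1,)

    def test_breathing_sinusoid(self):
        t = np.linspace(0, 200 * np.pi, 100_000, endpoint=False)
        d = 4.6 + 0.2 * np.sin(t)
        a = np.zeros((t.size, 6, 3))
        b = np.zeros((t.size, 6, 3))
        b[:, :, 0] = d[:, None]
        mean, sd, _ = ring_centroid_distance(a, b)
        assert mean == pytest.approx(4.6, rel=0.02)
        assert sd == pytest.approx(0.2 / math.sqrt(2), rel=0.02)


class TestIRED:
    def test_rigid_corotation_fully_ordered(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((20, 3))
        base /= np.linalg.norm(base, axis=1, keepdims=True)
        rots = Rotation.random(300, rng=rng).as_matrix()
        vecs = np.einsum("tij,vj->tvi", rots, base)
        res = ired_order_parameters(vecs, fit_correlations=False)
        assert min(r.S2 for r in res) > 0.99

    def test_disordered_limit(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((2000, 150, 3))
        v /= np.linalg.norm(v, axis=2, keepdims=True)
        res = ired_order_parameters(v, fit_correlations=False)
        assert np.mean([r.S2 for r in res]) < 0.05

    def test_cone_closed_form(self):
        rng = np.random.default_rng(0)
        vecs = cone_vectors(rng, 30.0, 200, 2000)
        res = ired_order_parameters(vecs, fit_correlations=False)
        alpha = math.radians(30.0)
        s2_true = (math.cos(alpha) * (1 + math.cos(alpha)) / 2) ** 2
        assert np.mean([r.S2 for r in res]) == pytest.approx(s2_true,
                                                             abs=0.02)

    def test_global_rotation_invariance(self):
        rng = np.random.default_rng(5)
        vecs = cone_vectors(rng, 25.0, 30, 400)
        rot = Rotation.random(rng=rng).as_matrix()
        a = ired_order_parameters(vecs, fit_correlations=False)
        b = ired_order_parameters(
            np.einsum("ij,tvj->tvi", rot, vecs), fit_correlations=False
        )
        assert np.allclose([r.S2 for r in a], [r.S2 for r in b], atol=1e-9)

    def test_correlation_fit_on_exchange_series(self):
        rng = np.random.default_rng(7)
        vecs = cone_vectors(rng, 30.0, 4, 600)
        res = ired_order_parameters(vecs, frame_interval_ps=10.0)
        assert all(r.fit_converged for r in res)
        assert all(np.isfinite(r.tau_fast_ps) for r in res)
        assert all(0.0 <= r.amplitude_fast <= 1.0 for r in res)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="unit"):
            ired_order_parameters(np.ones((200, 3, 3)))
        v = np.zeros((50, 3, 3))
        v[..., 0] = 1.0
        with pytest.raises(ValueError, match="100 frames"):
            ired_order_parameters(v)
        v = np.zeros((200, 1, 3))
        v[..., 0] = 1.0
        with pytest.raises(ValueError, match="2 vectors"):
            ired_order_parameters(v)
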