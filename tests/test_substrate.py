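"""Substrate: gradients, placement, genotype assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist

from ephmap.substrate import (
    Circle,
    GradientParams,
    PackingError,
    RETINAL_EPHA,
    RETINAL_EPHB,
    SC_EPHRINA,
    SC_EPHRINB,
    SCOutline,
    WT_PEAKS,
    build_substrate,
    eval_gradient,
    genotype,
    place_neurons,
    summed_gradient,
)


class TestEvalGradient:
    @pytest.mark.parametrize(
        "params, x, expected",
        [
            # flat EphA4 profile: constant 1.05 everywhere
            (GradientParams(1.05, 0.0, 0.0, 1.0), 0.3, 1.05),
            (GradientParams(1.05, 0.0, 0.0, 1.0), 1.0, 1.05),
            # EphA5 at its peak position x = G3
            (GradientParams(0.0, 0.85, 1.8, 1.0), 1.0, 0.85),
            # ephrin-A2 at the anterior pole: G0 + G1 exp(-G2*0.8)
            (
                GradientParams(-0.06, 0.35, 2.0, 0.8),
                0.0,
                max(0.0, -0.06 + 0.35 * np.exp(-1.6)),
            ),
            # clamping at zero: ephrin-A5 is negative anteriorly
            (GradientParams(-0.1, 0.9, 3.0, 1.0), 0.0, 0.0),
        ],
    )
    def test_profile_values(self, params, x, expected):
        assert eval_gradient(params, x) == pytest.approx(expected, abs=1e-12)

    @given(
        g0=st.floats(-1, 2),
        g1=st.floats(0, 2),
        g2=st.floats(0, 5),
        g3=st.floats(0, 1),
        x=st.floats(0, 1),
    )
    @settings(deadline=None, max_examples=100)
    def test_nonnegative_everywhere(self, g0, g1, g2, g3, x):
        assert eval_gradient(GradientParams(g0, g1, g2, g3), x) >= 0.0

    def test_negative_decay_rejected(self):
        with pytest.raises(ValueError):
            eval_gradient(GradientParams(0, 1, -1, 0), 0.5)


class TestWTNormalization:
    @pytest.mark.parametrize(
        "table, peak_key",
        [
            (RETINAL_EPHA, "EphA"),
            (RETINAL_EPHB, "EphB"),
            (SC_EPHRINA, "ephrin-A"),
            (SC_EPHRINB, "ephrin-B"),
        ],
    )
    def test_scaled_wt_peak_is_one(self, table, peak_key):
        grid = np.linspace(0, 1, 4001)
        scaled = summed_gradient(table, grid) / WT_PEAKS[peak_key]
        assert np.max(scaled) == pytest.approx(1.0, abs=1e-9)

    def test_wt_epha_monotone_nasal_to_temporal(self):
        grid = np.linspace(0, 1, 1001)
        vals = summed_gradient(RETINAL_EPHA, grid)
        assert np.all(np.diff(vals) >= -1e-12)

    def test_wt_ephrina_monotone_anterior_to_posterior(self):
        grid = np.linspace(0, 1, 1001)
        vals = summed_gradient(SC_EPHRINA, grid)
        assert np.all(np.diff(vals) >= -1e-12)


class TestPlacement:
    def test_single_point_inside(self, rng):
        pts = place_neurons(1, Circle(), 0.3, rng)
        assert pts.shape == (1, 2)
        assert Circle().contains(pts).all()

    def test_exclusion_respected_at_reference_density(self, rng):
        pts = place_neurons(2000, Circle(), 0.0139, rng)
        assert pts.shape == (2000, 2)
        assert pdist(pts).min() >= 0.0139
        assert Circle().contains(pts).all()

    def test_packing_infeasible_raises(self, rng):
        with pytest.raises(PackingError):
            place_neurons(50, Circle(), 0.5, rng)

    def test_sc_outline_placement(self, rng):
        out = SCOutline()
        pts = place_neurons(400, out, 0.0238, rng)
        assert out.contains(pts).all()
        assert pdist(pts).min() >= 0.0238


class TestGenotypes:
    def test_unknown_genotype_rejected(self):
        with pytest.raises(ValueError):
            genotype("nonexistent")

    def test_wt_peak_scaled_samples(self, wt_medium):
        # max over sampled RGCs of the scaled summed EphA approaches 1
        assert 0.97 < wt_medium.R_A.max() <= 1.0 + 1e-9

    def test_tko_zeroes_ephrin_a(self):
        sub = build_substrate(genotype("tko", K=0.0), 200, 200, seed=0)
        assert np.all(sub.L_A == 0.0)

    def test_tko_weak_gradient_scaled_below_wt(self):
        sub = build_substrate(genotype("tko", K=0.1), 200, 200, seed=0)
        wt = build_substrate(genotype("wild_type"), 200, 200, seed=0)
        assert np.allclose(sub.L_A, 0.1 * wt.L_A)
        assert sub.L_A.max() < 1.0

    def test_knockin_isl2_fraction_and_peak(self):
        sub = build_substrate(genotype("isl2_epha3_ki_ki"), 2000, 200, seed=5)
        frac = sub.isl2.mean()
        assert abs(frac - 0.4) < 3 * np.sqrt(0.4 * 0.6 / 2000)
        assert sub.R_A.max() > 1.0
        # knocked-in cells exceed their unlabelled neighbours everywhere
        assert sub.R_A[sub.isl2].min() > 0.4

    def test_het_adds_half_the_epha3(self):
        ki = genotype("isl2_epha3_ki_ki")
        het = genotype("isl2_epha3_ki_het")
        assert het.epha3_g0 == pytest.approx(ki.epha3_g0 / 2.0, rel=0.01)

    def test_math5_population_fraction(self):
        sub = build_substrate(genotype("math5"), 1000, 300, seed=2)
        assert sub.n_rgc == 100
        assert sub.n_sc == 300


class TestSerialization:
    def test_substrate_roundtrip(self, tmp_path, wt_small):
        path = tmp_path / "sub.h5"
        wt_small.save(path)
        from ephmap.substrate import Substrate

        back = Substrate.load(path)
        assert np.array_equal(back.retina, wt_small.retina)
        assert np.array_equal(back.L_A, wt_small.L_A)
        assert back.genotype == wt_small.genotype
        assert back.seed == wt_small.seed

    def test_determinism(self):
        a = build_substrate(genotype("wild_type"), 150, 150, seed=9)
        b = build_substrate(genotype("wild_type"), 150, 150, seed=9)
        assert np.array_equal(a.retina, b.retina)
        assert np.array_equal(a.sc, b.sc)
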