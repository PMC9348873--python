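import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from polysas.exceptions import (
    ConfigurationError,
    DomainError,
    InvalidGridError,
    MemoryBudgetError,
    ShapeError,
)
from polysas.greens import (
    GreenTensor,
    ParameterGrid,
    QGrid,
    SmearingMatrix,
    apply_smearing,
    apply_structure_factor,
    cylinder_form_green_2d,
    estimate_tensor_bytes,
    hard_sphere_structure,
    load_green_hdf5,
    save_green_hdf5,
    smearing_matrix,
    sphere_form_green,
    volume_weight,
)


def sphere_amplitude_quadrature(q, r):
    """Independent oracle: |4π ∫_0^r sin(qs)/(qs) s² ds|² for unit contrast."""
    val, _ = quad(lambda s: np.sin(q * s) / (q * s) * s**2, 0.0, r, limit=400)
    return (4.0 * np.pi * val) ** 2


class TestGrids:
    def test_parameter_grid_invariants(self):
        g = ParameterGrid("radius", [1.0, 2.0, 3.0])
        assert g.n == 3
        with pytest.raises(InvalidGridError):
            ParameterGrid("r", [3.0, 2.0, 1.0])
        with pytest.raises(InvalidGridError):
            ParameterGrid("r", [1.0])
        with pytest.raises(InvalidGridError):
            ParameterGrid("r", [1.0, 1.0, 2.0])

    def test_from_spec_log(self):
        g = ParameterGrid.from_spec("radius", 1.0, 100.0, 5, "logarithmic")
        assert np.allclose(g.values, np.logspace(0, 2, 5))

    def test_qgrid(self):
        q = QGrid((np.array([0.1, 0.2]), np.array([0.3, 0.4, 0.5])))
        assert q.m == 2 and q.shape == (2, 3)
        with pytest.raises(InvalidGridError):
            QGrid((np.array([0.1]), np.array([0.2]), np.array([0.3])))

    def test_qgrid_magnitude(self):
        q = QGrid((np.array([-0.3, 0.4]),))
        assert np.allclose(q.magnitude(), [0.3, 0.4])


class TestSphereGreen:
    def test_small_q_limit(self):
        # G -> v² Δρ² as q -> 0; with r = 1 Å this is (4π/3)² ≈ 17.546
        q = QGrid((np.array([1e-8, 1e-7]),))
        r = ParameterGrid("radius", np.array([1.0, 2.0]))
        g = sphere_form_green(q, r, contrast=1.0)
        assert g.data[0, 0] == pytest.approx((4.0 * np.pi / 3.0) ** 2, rel=1e-10)

    def test_zero_contrast(self):
        q = QGrid((np.logspace(-2, 0, 5),))
        r = ParameterGrid("radius", np.array([10.0, 20.0]))
        g = sphere_form_green(q, r, contrast=0.0)
        assert np.all(g.data == 0.0)

    def test_quadrature_oracle_single_point(self):
        q = QGrid((np.array([0.01]),))
        r = ParameterGrid("radius", np.array([499.0, 500.0]))
        g = sphere_form_green(q, r, contrast=1.0)
        expected = sphere_amplitude_quadrature(0.01, 500.0)
        assert g.data[0, 1] == pytest.approx(expected, rel=1e-8)

    @pytest.mark.parametrize("qr", [1e-3, 0.1, 1.0, 10.0, 100.0, 1e3])
    def test_quadrature_oracle_sweep(self, qr):
        r_val = 100.0
        q_val = qr / r_val
        q = QGrid((np.array([q_val]),))
        r = ParameterGrid("radius", np.array([r_val / 2, r_val]))
        g = sphere_form_green(q, r)
        expected = sphere_amplitude_quadrature(q_val, r_val)
        # relative to the tensor scale: the kernel oscillates through zeros
        scale = (4.0 / 3.0 * np.pi * r_val**3) ** 2
        assert abs(g.data[0, 1] - expected) <= 1e-10 * scale + 1e-8 * abs(expected)

    def test_invalid_grids(self):
        q = QGrid((np.array([0.0, 0.1]),))
        r = ParameterGrid("radius", np.array([1.0, 2.0]))
        with pytest.raises(InvalidGridError):
            sphere_form_green(q, r)
        q_ok = QGrid((np.array([0.1, 0.2]),))
        r_bad = ParameterGrid("radius", np.array([-2.0, 1.0]))
        with pytest.raises(InvalidGridError):
            sphere_form_green(q_ok, r_bad)

    @settings(max_examples=25, deadline=None)
    @given(qlo=st.floats(1e-4, 1e-1), span=st.floats(1.5, 50.0),
           rlo=st.floats(1.0, 500.0), rspan=st.floats(1.5, 4.0))
    def test_nonnegative_finite_property(self, qlo, span, rlo, rspan):
        q = QGrid((np.geomspace(qlo, qlo * span, 17),))
        r = ParameterGrid("radius", np.geomspace(rlo, rlo * rspan, 9))
        g = sphere_form_green(q, r)
        assert np.all(np.isfinite(g.data))
        assert np.all(g.data >= 0.0)


class TestCylinderGreen:
    def _grids(self, n=3):
        l = ParameterGrid("length", np.linspace(100.0, 200.0, n))
        r = ParameterGrid("radius", np.linspace(20.0, 40.0, n))
        th = ParameterGrid("theta", np.linspace(0.3, 1.2, n))
        ph = ParameterGrid("phi", np.linspace(0.2, 2.8, n))
        return l, r, th, ph

    def test_shape_and_positivity(self):
        qx = np.linspace(-0.2, 0.2, 6)
        qy = np.linspace(-0.2, 0.2, 5)
        g = cylinder_form_green_2d(qx, qy, *self._grids())
        assert g.data.shape == (6, 5, 3, 3, 3, 3)
        assert np.all(np.isfinite(g.data)) and np.all(g.data >= 0.0)

    def test_forward_scattering_limit(self):
        qx = np.array([0.0])
        qy = np.array([0.0])
        l, r, th, ph = self._grids()
        g = cylinder_form_green_2d(qx, qy, l, r, th, ph)
        vols = np.pi * r.values**2 * l.values[:, None]
        assert np.allclose(g.data[0, 0], (vols**2)[:, :, None, None], rtol=1e-12)

    def test_axis_along_beam(self):
        # θ -> 0: cos α -> 0, the length factor drops out; G depends on r
        # only through the Bessel factor at sin α = 1
        qx = np.array([0.05])
        qy = np.array([0.07])
        l = ParameterGrid("length", np.array([100.0, 300.0]))
        r = ParameterGrid("radius", np.array([30.0, 31.0]))
        th = ParameterGrid("theta", np.array([1e-9, 1e-8]))
        ph = ParameterGrid("phi", np.array([0.4, 1.2]))
        g = cylinder_form_green_2d(qx, qy, l, r, th, ph)
        block = g.data[0, 0]  # (l, r, θ, ϕ)
        vols2 = (np.pi * r.values**2 * l.values[:, None]) ** 2
        norm = block / vols2[:, :, None, None]
        assert np.allclose(norm, norm[0, :, :1, :1], rtol=1e-8)

    def test_scalar_oracle(self):
        from scipy.special import j1
        qx, qy = np.array([0.03]), np.array([-0.08])
        lv, rv, tv, pv = 150.0, 25.0, 0.7, 1.1
        g = cylinder_form_green_2d(
            qx, qy,
            ParameterGrid("length", [lv, lv + 1]),
            ParameterGrid("radius", [rv, rv + 1]),
            ParameterGrid("theta", [tv, tv + 0.1]),
            ParameterGrid("phi", [pv, pv + 0.1]))
        # independent one-line evaluation of the kernel
        qmag = np.hypot(qx[0], qy[0])
        cos_a = (qx[0] * np.sin(tv) * np.cos(pv)
                 + qy[0] * np.sin(tv) * np.sin(pv)) / qmag
        sin_a = np.sqrt(1 - cos_a**2)
        v = np.pi * rv**2 * lv
        amp = (v * np.sin(qmag * lv * cos_a / 2) / (qmag * lv * cos_a / 2)
               * 2 * j1(qmag * rv * sin_a) / (qmag * rv * sin_a))
        assert g.data[0, 0, 0, 0, 0, 0] == pytest.approx(amp**2, rel=1e-12)

    def test_memory_budget_refusal(self):
        qx = np.linspace(-0.2, 0.2, 8)
        with pytest.raises(MemoryBudgetError) as exc:
            cylinder_form_green_2d(qx, qx, *self._grids(4), memory_budget=1000)
        assert exc.value.estimated_bytes == estimate_tensor_bytes((8, 8, 4, 4, 4, 4))

    def test_chunked_build_matches_dense(self, tmp_path):
        qx = np.linspace(-0.2, 0.2, 8)
        l, r, th, ph = self._grids()
        dense = cylinder_form_green_2d(qx, qx, l, r, th, ph)
        out = str(tmp_path / "g.h5")
        chunked = cylinder_form_green_2d(qx, qx, l, r, th, ph,
                                         memory_budget=10_000, out=out)
        assert np.allclose(chunked.data, dense.data, rtol=1e-14)


class TestHardSphereStructure:
    def test_dilute_limit(self):
        q = QGrid((np.logspace(-3, 0, 50),))
        assert np.all(hard_sphere_structure(q, 100.0, 0.0) == 1.0)

    def test_compressibility_limit(self):
        # S(0) = (1 − V_f)^4 / (1 + 2 V_f)^2 ≈ 0.2090 at V_f = 0.2,
        # checked against the numerical q -> 0 evaluation
        v_f = 0.2
        s0_closed = (1 - v_f) ** 4 / (1 + 2 * v_f) ** 2
        assert s0_closed == pytest.approx(0.20898, abs=5e-5)
        s = hard_sphere_structure(np.array([1e-9, 1e-6]), 100.0, v_f)
        assert s[0] == pytest.approx(s0_closed, rel=1e-10)

    def test_large_q_limit(self):
        s = hard_sphere_structure(np.array([50.0, 100.0]), 100.0, 0.3)
        assert np.allclose(s, 1.0, atol=1e-3)

    def test_series_matches_direct_at_crossover(self):
        # the small-argument series and the closed form must agree where
        # they hand over (A = 2 q r_eff = 0.5)
        r_eff, v_f = 100.0, 0.25
        q = np.array([0.5 / (2 * r_eff) * (1 - 1e-9), 0.5 / (2 * r_eff) * (1 + 1e-9)])
        s = hard_sphere_structure(q, r_eff, v_f)
        assert s[0] == pytest.approx(s[1], rel=1e-9)

    def test_monotone_to_one_beyond_peak(self):
        q = np.geomspace(1e-4, 1.0, 400)
        s = hard_sphere_structure(q, 100.0, 0.3)
        peak = int(np.argmax(s))
        tail = s[peak:]
        assert np.all(np.isfinite(tail)) and np.all(tail > 0)
        # |S - 1| decays beyond the principal peak
        dev = np.abs(tail - 1.0)
        coarse = dev[:: max(1, dev.size // 8)]
        assert coarse[-1] <= coarse[0]

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            hard_sphere_structure(np.array([0.1]), 100.0, 0.8)
        with pytest.raises(DomainError):
            hard_sphere_structure(np.array([0.1]), -1.0, 0.2)

    def test_apply_structure_factor(self, rng):
        q = QGrid((np.logspace(-3, -1, 20),))
        r = ParameterGrid("radius", np.linspace(50, 100, 5))
        g = sphere_form_green(q, r)
        s = hard_sphere_structure(q, 80.0, 0.25)
        gs = apply_structure_factor(g, s)
        assert np.allclose(gs.data, g.data * s[:, None])


class TestSmearing:
    def test_zero_dq_is_identity(self):
        q = QGrid((np.linspace(0.01, 0.1, 12),))
        w = smearing_matrix(q, np.zeros(12))
        assert np.allclose(w.weights, np.eye(12))
        r = ParameterGrid("radius", np.linspace(10, 50, 4))
        g = sphere_form_green(q, r)
        assert np.allclose(apply_smearing(g, w).data, g.data)

    def test_constant_signal_preserved(self):
        q = QGrid((np.linspace(0.01, 0.1, 15),))
        w = smearing_matrix(q, np.full(15, 0.005))
        const = np.ones((15, 3))
        g = GreenTensor(const, q, [ParameterGrid("radius", [1.0, 2.0, 3.0])])
        sm = apply_smearing(g, w)
        assert np.allclose(sm.data, 1.0, atol=1e-12)

    def test_gaussian_row_brute_force(self):
        qv = np.linspace(0.01, 0.1, 21)
        q = QGrid((qv,))
        dq = np.zeros(21)
        i = 10
        dq[i] = 0.008
        w = smearing_matrix(q, dq)
        raw = np.zeros(21)
        for k in range(21):  # brute-force loop oracle
            d = qv[k] - qv[i]
            if abs(d) <= 3 * dq[i]:
                raw[k] = np.exp(-0.5 * (d / dq[i]) ** 2)
        raw /= raw.sum()
        assert np.allclose(w.weights[i], raw, rtol=1e-14)

    def test_row_stochastic_invariant(self):
        q = QGrid((np.linspace(0.01, 0.2, 30),))
        w = smearing_matrix(q, np.full(30, 0.01))
        assert np.allclose(w.weights.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(w.weights >= 0)

    def test_length_mismatch(self):
        q = QGrid((np.linspace(0.01, 0.1, 10),))
        with pytest.raises(ShapeError):
            smearing_matrix(q, np.zeros(9))

    def test_smearing_commutes_with_contraction(self, rng):
        from polysas import forward
        from polysas.forward import DistributionSet
        q = QGrid((np.linspace(0.01, 0.1, 12),))
        r = ParameterGrid("radius", np.linspace(10, 50, 6))
        g = sphere_form_green(q, r)
        w = smearing_matrix(q, np.full(12, 0.004))
        wt = rng.uniform(0.1, 1, 6)
        wt /= wt.sum()
        d = DistributionSet([wt], xi=2.0)
        i_then_smear = w.weights @ forward.intensity(g, d)
        smear_then_i = forward.intensity(apply_smearing(g, w), d)
        assert np.allclose(i_then_smear, smear_then_i, rtol=1e-12)

    def test_bad_matrix_rejected(self):
        with pytest.raises(ShapeError):
            SmearingMatrix(np.array([[0.5, 0.4], [0.5, 0.5]]))
        with pytest.raises(ShapeError):
            SmearingMatrix(np.array([[1.5, -0.5], [0.0, 1.0]]))


class TestVolumeWeight:
    def test_unit_volumes_unchanged(self):
        q = QGrid((np.array([0.1, 0.2]),))
        pg = ParameterGrid("radius", [1.0, 2.0, 3.0])
        g = GreenTensor(np.ones((2, 3)), q, [pg], volumes=np.ones(3))
        assert np.allclose(volume_weight(g).data, g.data)

    def test_column_scaling_oracle(self, rng):
        q = QGrid((np.array([0.1, 0.2, 0.3]),))
        pg = ParameterGrid("radius", [1.0, 2.0, 3.0])
        raw = rng.uniform(1, 2, (3, 3))
        g = GreenTensor(raw, q, [pg], volumes=np.array([1.0, 2.0, 4.0]))
        wtd = volume_weight(g)
        for j, scale in enumerate([1.0, 0.5, 0.25]):
            assert np.allclose(wtd.data[:, j], raw[:, j] * scale)

    def test_sphere_small_q_weighted_limit(self):
        q = QGrid((np.array([1e-8]),))
        r = ParameterGrid("radius", np.array([10.0, 20.0]))
        g = volume_weight(sphere_form_green(q, r))
        vols = 4 / 3 * np.pi * r.values**3
        assert np.allclose(g.data[0], vols, rtol=1e-8)

    def test_missing_volumes(self):
        q = QGrid((np.array([0.1]),))
        pg = ParameterGrid("radius", [1.0, 2.0])
        g = GreenTensor(np.ones((1, 2)), q, [pg], volumes=None)
        with pytest.raises(ConfigurationError):
            volume_weight(g)


class TestPersistence:
    def test_hdf5_round_trip(self, tmp_path):
        q = QGrid((np.logspace(-2, 0, 10),))
        r = ParameterGrid("radius", np.linspace(10, 100, 7))
        g = sphere_form_green(q, r, contrast=2.0)
        path = str(tmp_path / "green.h5")
        save_green_hdf5(g, path)
        g2 = load_green_hdf5(path)
        assert np.array_equal(g.data, g2.data)
        assert g2.contrast == 2.0
        assert g2.param_grids[0].name == "radius"
        assert np.array_equal(g2.volumes, g.volumes)
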