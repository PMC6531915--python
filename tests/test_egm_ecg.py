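"""Electrogram annotation/filtering and the forward-ECG solvers."""

import numpy as np
import pytest

from ivtlab.ecg import (
    EGMTrace,
    MappingPoint,
    annotate_lat,
    annotate_point,
    assemble_tet_stiffness,
    box_torso,
    compare_ecg,
    extracellular_from_vm,
    filter_points,
    forward_ecg,
    shell_wedge,
    solve_torso,
)
from ivtlab.solver import CHI_CM_DEFAULT, ConductivityAssignment, assemble_diffusion
from ivtlab.substrate import TissueGrid


def synthetic_egm(lat=100.0, delay=2.0, amp=4.0, dt=1.0, duration=400.0,
                  extra_deflection=None):
    """Unipolar pair with the steepest negative slope exactly at ``lat``."""
    t = np.arange(0.0, duration, dt)
    u1 = amp * (1.0 - 2.0 / (1.0 + np.exp(-(t - lat) / 3.0)))
    u2 = amp * (1.0 - 2.0 / (1.0 + np.exp(-(t - lat - delay) / 3.0)))
    if extra_deflection is not None:
        u2 = u2 + 0.8 * amp * np.exp(-((t - extra_deflection) ** 2) / 18.0)
    return EGMTrace(t=t, unipolar1=u1, unipolar2=u2)


class TestAnnotation:
    def test_nearest_deflection_rule(self):
        trace = synthetic_egm(lat=100.0, extra_deflection=140.0)
        lat = annotate_lat(trace)
        # brute-force oracle: all |bipolar| local maxima above the floor,
        # keep the one closest to the steepest unipolar downslope
        b = np.abs(trace.bipolar)
        du = np.gradient(trace.unipolar1, trace.t)
        t_star = trace.t[np.argmin(du)]
        floor = 0.05 * np.ptp(trace.bipolar)
        cands = [trace.t[i] for i in range(1, b.size - 1)
                 if b[i] >= b[i - 1] and b[i] >= b[i + 1] and b[i] > floor]
        expect = min(cands, key=lambda tc: abs(tc - t_star))
        assert lat == expect
        assert abs(lat - 100.0) < 5.0  # near the true activation, not 140

    def test_flat_trace_invalid(self):
        t = np.arange(0.0, 100.0, 1.0)
        trace = EGMTrace(t=t, unipolar1=np.zeros_like(t), unipolar2=np.zeros_like(t))
        assert annotate_lat(trace) is None
        p = annotate_point(MappingPoint(position=(0, 0, 0), trace=trace))
        assert not p.valid

    def test_time_shift_equivariance(self):
        tr1 = synthetic_egm(lat=100.0)
        tr2 = synthetic_egm(lat=137.0)
        assert annotate_lat(tr2) - annotate_lat(tr1) == pytest.approx(37.0, abs=1e-9)


class TestFiltering:
    @staticmethod
    def _grid_points(n=5, lat_fn=lambda x, y: 2.0 * x + y, amp=3.0):
        pts = []
        for i in range(n):
            for j in range(n):
                lat = lat_fn(float(i), float(j))
                tr = synthetic_egm(lat=50.0 + lat, amp=amp)
                pts.append(MappingPoint(position=(5.0 * i, 5.0 * j, 0.0), trace=tr))
        return pts

    def test_low_voltage_dropped_first(self):
        pts = self._grid_points()
        weak = MappingPoint(position=(2.0, 2.0, 0.0),
                            trace=synthetic_egm(amp=0.05))  # p2p < 0.5 mV
        pts.append(weak)
        kept = filter_points(pts, neighbor_radius=12.0)
        assert weak not in kept
        assert weak.reason == "low_voltage"

    def test_identical_lats_none_dropped(self):
        pts = self._grid_points(lat_fn=lambda x, y: 0.0)
        kept = filter_points(pts, neighbor_radius=12.0)
        assert len(kept) == 25

    def test_single_outlier_dropped(self):
        pts = self._grid_points(lat_fn=lambda x, y: 10.0)
        outlier = MappingPoint(position=(11.0, 11.0, 0.0),
                               trace=synthetic_egm(lat=350.0))
        pts.append(outlier)
        kept = filter_points(pts, neighbor_radius=12.0)
        assert outlier not in kept
        assert outlier.reason == "incoherent_lat"
        assert len(kept) == 25

    def test_filtering_idempotent(self):
        pts = self._grid_points(lat_fn=lambda x, y: 10.0)
        pts.append(MappingPoint(position=(11.0, 11.0, 0.0),
                                trace=synthetic_egm(lat=350.0)))
        once = filter_points(pts, neighbor_radius=12.0)
        twice = filter_points(list(once), neighbor_radius=12.0)
        assert [id(p) for p in twice] == [id(p) for p in once]


@pytest.fixture(scope="module")
def heart_op():
    g = TissueGrid(shape=(5, 5, 5), dx=0.4)
    ConductivityAssignment().apply(g)
    return assemble_diffusion(g, CHI_CM_DEFAULT)


class TestExtracellular:
    def test_uniform_vm_gives_zero(self, heart_op):
        phi = extracellular_from_vm(heart_op, np.full(heart_op.n_active, -85.0))
        assert np.abs(phi).max() < 1e-8

    def test_linearity(self, heart_op, rng):
        vm = rng.normal(size=heart_op.n_active)
        assert np.allclose(extracellular_from_vm(heart_op, 3.0 * vm),
                           3.0 * extracellular_from_vm(heart_op, vm), atol=1e-7)

    def test_matches_dense_direct_solve(self, heart_op, rng):
        vm = rng.normal(size=heart_op.n_active)
        phi = extracellular_from_vm(heart_op, vm)
        K = heart_op.K.toarray()
        rhs = -(K @ vm) / 2.0  # lambda = 1
        sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
        sol -= sol.mean()
        assert np.abs(phi - sol).max() < 1e-6

    def test_gauge_zero_mean(self, heart_op, rng):
        phi = extracellular_from_vm(heart_op, rng.normal(size=heart_op.n_active))
        assert abs(phi.mean()) < 1e-12


class TestTorsoSolve:
    def test_uniform_dirichlet_gives_constant(self):
        torso = box_torso(size=(60.0, 40.0, 60.0), spacing=10.0)
        phi = solve_torso(torso, torso.heart_nodes,
                          np.full(torso.heart_nodes.size, 3.5))
        assert np.abs(phi - 3.5).max() < 1e-7

    def test_concentric_shell_analytic_within_2pct(self):
        mesh, dirichlet, exact = shell_wedge(n_r=12, n_theta=12, n_phi=20)
        phi = solve_torso(mesh, dirichlet, exact[dirichlet])
        rel = np.abs(phi - exact).max() / np.abs(exact).max()
        assert rel <= 0.02

    def test_conductivity_scale_invariance(self):
        mesh, dirichlet, exact = shell_wedge(n_r=8, n_theta=8, n_phi=12)
        phi1 = solve_torso(mesh, dirichlet, exact[dirichlet])
        mesh.sigma = 2.0 * mesh.sigma
        phi2 = solve_torso(mesh, dirichlet, exact[dirichlet])
        assert np.abs(phi1 - phi2).max() < 1e-6

    def test_gauge_shift_propagates(self):
        torso = box_torso(size=(60.0, 40.0, 60.0), spacing=10.0)
        vals = np.linspace(-1.0, 1.0, torso.heart_nodes.size)
        phi1 = solve_torso(torso, torso.heart_nodes, vals)
        phi2 = solve_torso(torso, torso.heart_nodes, vals + 5.0)
        assert np.allclose(phi2 - phi1, 5.0, atol=1e-6)

    def test_dipole_reversal_flips_leads(self):
        torso = box_torso(size=(60.0, 40.0, 60.0), spacing=10.0,
                          heart_center=(30.0, 20.0, 30.0), heart_radius=12.0)
        z = torso.nodes[torso.heart_nodes][:, 0] - 30.0
        ecg = forward_ecg(torso, z)
        flipped = forward_ecg(torso, -z)
        for lead in ecg["leads"]:
            assert flipped["leads"][lead][0] == pytest.approx(
                -ecg["leads"][lead][0], abs=1e-6)


class TestCompareEcg:
    @staticmethod
    def _set(leads, t=None):
        return {"time": np.arange(10.0) if t is None else t, "leads": leads}

    def test_identical_signals(self, rng):
        s = rng.normal(size=10)
        out = compare_ecg(self._set({"V1": s}), self._set({"V1": s.copy()}),
                          resample=False)
        assert out["V1"] == pytest.approx(1.0)

    def test_sign_flip(self, rng):
        s = rng.normal(size=10)
        out = compare_ecg(self._set({"V1": s}), self._set({"V1": -s}),
                          resample=False)
        assert out["V1"] == pytest.approx(-1.0)

    def test_matches_bruteforce_covariance(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        out = compare_ecg(self._set({"V2": a}), self._set({"V2": b}),
                          resample=False)
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        expect = cov / (a.std() * b.std())
        assert out["V2"] == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_lead_is_nan(self):
        out = compare_ecg(self._set({"V1": np.zeros(10)}),
                          self._set({"V1": np.arange(10.0)}), resample=False)
        assert np.isnan(out["V1"])

    def test_resampling_aligns_different_rates(self):
        t1 = np.linspace(0.0, 1.0, 50)
        t2 = np.linspace(0.0, 2.0, 80)
        sig = lambda t: np.sin(2 * np.pi * t / t[-1])
        out = compare_ecg({"time": t1, "leads": {"V1": sig(t1)}},
                          {"time": t2, "leads": {"V1": sig(t2)}})
        assert out["V1"] > 0.999

    def test_no_common_leads_rejected(self):
        with pytest.raises(ValueError, match="common"):
            compare_ecg(self._set({"V1": np.ones(3)}), self._set({"V9": np.ones(3)}))
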