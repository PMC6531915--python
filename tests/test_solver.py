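"""Monodomain solver: operator assembly, propagation, maps, stabilization."""

import numpy as np
import pytest

from ivtlab.membrane import derive_phenotype, pace_single_cell
from ivtlab.solver import (
    BZ_SETS,
    CHI_CM_DEFAULT,
    ConductionBlockError,
    ConductivityAssignment,
    ModelVersion,
    SolverConfig,
    StimulusDef,
    TissueModel,
    assemble_diffusion,
    compute_lat_apd_maps,
    measure_cv,
    run_simulation,
    site_lat,
    stabilize_fibrosis,
)
from ivtlab.substrate import (
    LABEL_BZ,
    LABEL_FIBROSIS,
    LABEL_SCAR,
    TissueGrid,
    strand,
)


def make_model(grid, version=ModelVersion(), conductivities=None, **cfg_kw):
    cfg = SolverConfig(chi_cm=CHI_CM_DEFAULT, linear_solver="lu", **cfg_kw)
    return TissueModel(grid, version, config=cfg, conductivities=conductivities)


@pytest.fixture(scope="module")
def small_grid():
    g = TissueGrid(shape=(3, 3, 3), dx=0.4)
    ConductivityAssignment().apply(g)
    return g


class TestConductivities:
    def test_label_assignment(self):
        g = TissueGrid(shape=(2, 2, 1), dx=0.4)
        g.label[0, 0, 0] = LABEL_SCAR
        g.label[1, 0, 0] = LABEL_BZ
        g.label[0, 1, 0] = LABEL_FIBROSIS
        ConductivityAssignment().apply(g)
        assert g.sigma_l[0, 0, 0] == 0.0  # scar excluded
        assert (g.sigma_l[1, 0, 0], g.sigma_t[1, 0, 0]) == (0.05, 0.01)
        assert g.sigma_l[0, 1, 0] == g.sigma_t[0, 1, 0] == 0.1  # isotropic
        assert (g.sigma_l[1, 1, 0], g.sigma_t[1, 1, 0]) == (0.24, 0.0456)

    def test_bz_sets(self):
        assert BZ_SETS["cv50"] == (0.12, 0.03)
        assert BZ_SETS["cv25"] == (0.22, 0.0485)
        assert ConductivityAssignment.with_bz_set("cv50").bz == (0.12, 0.03)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            ConductivityAssignment(healthy=(0.01, 0.04))
        with pytest.raises(ValueError):
            ConductivityAssignment(fibrosis=-1.0)


class TestDiffusionOperator:
    def test_constants_in_null_space(self, small_grid):
        op = assemble_diffusion(small_grid, CHI_CM_DEFAULT)
        ones = np.ones(op.n_active)
        assert np.abs(op.K @ ones).max() < 1e-10

    def test_symmetry(self, small_grid):
        op = assemble_diffusion(small_grid, CHI_CM_DEFAULT)
        assert np.abs(op.K - op.K.T).max() < 1e-12

    def test_scar_isolated_element_has_no_coupling(self):
        g = TissueGrid(shape=(3, 3, 3), dx=0.4)
        g.label[:] = LABEL_SCAR
        g.label[1, 1, 1] = 0
        ConductivityAssignment().apply(g)
        op = assemble_diffusion(g, CHI_CM_DEFAULT)
        # only the 8 nodes of the single conducting element are active
        assert op.n_active == 8
        # its stiffness couples those nodes to nothing else and K 1 = 0
        assert np.abs(op.K @ np.ones(8)).max() < 1e-12

    def test_matches_bruteforce_fem_assembly(self, small_grid):
        op = assemble_diffusion(small_grid, CHI_CM_DEFAULT)
        K = op.K.toarray()
        # independent element-by-element assembly from first principles
        dx = small_grid.dx
        gp = 1.0 / np.sqrt(3.0)
        corners = [(i, j, k) for k in (0, 1) for j in (0, 1) for i in (0, 1)]
        # order must match the solver's corner convention
        corners = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
                   (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1)]
        n_nodes = 4 ** 3
        Kref = np.zeros((n_nodes, n_nodes))
        f = np.array([1.0, 0.0, 0.0])
        D = 0.24 * np.outer(f, f) + 0.0456 * (np.eye(3) - np.outer(f, f))
        for ei in range(3):
            for ej in range(3):
                for ek in range(3):
                    ids = [((ei + ci) * 4 + (ej + cj)) * 4 + (ek + ck)
                           for ci, cj, ck in corners]
                    for qx in (-gp, gp):
                        for qy in (-gp, gp):
                            for qz in (-gp, gp):
                                B = np.zeros((8, 3))
                                for a, (sx, sy, sz) in enumerate(
                                        [(2 * c[0] - 1, 2 * c[1] - 1, 2 * c[2] - 1)
                                         for c in corners]):
                                    B[a, 0] = 0.125 * sx * (1 + sy * qy) * (1 + sz * qz)
                                    B[a, 1] = 0.125 * sy * (1 + sx * qx) * (1 + sz * qz)
                                    B[a, 2] = 0.125 * sz * (1 + sx * qx) * (1 + sy * qy)
                                B *= 2.0 / dx
                                ke = B @ D @ B.T * (dx / 2.0) ** 3
                                for a in range(8):
                                    for b in range(8):
                                        Kref[ids[a], ids[b]] += ke[a, b]
        assert np.abs(K - Kref).max() < 1e-12


class TestPropagation:
    @staticmethod
    def _run_strand(sigma, dx=0.2, length=20.0, duration=200.0):
        g = strand(length=length, cross=2 * dx, dx=dx)
        cond = ConductivityAssignment(healthy=sigma)
        model = make_model(g, conductivities=cond)
        stim = StimulusDef(nodes=model.op.active_nodes[model.coords[:, 0] <= 3 * dx],
                           onset=0.0, duration=2.0, amplitude=-80.0)
        a = (length / 3, dx, dx)
        b = (2 * length / 3, dx, dx)
        stop = np.concatenate([model.nodes_near(a, 0.01), model.nodes_near(b, 0.01)])
        res = run_simulation(model, [stim], duration, stop_after_captured=stop)
        return measure_cv(res, model, a, b), res, model

    def test_cv_scales_as_sqrt_sigma(self):
        """Quadrupling sigma_L doubles longitudinal CV (continuum property)."""
        cv1, _, _ = self._run_strand((0.06, 0.01))
        cv4, _, _ = self._run_strand((0.24, 0.01))
        assert cv4 / cv1 == pytest.approx(2.0, rel=0.10)

    def test_planarity_doubling_distance(self):
        _, res, model = self._run_strand((0.24, 0.0456), duration=60.0)
        a, m, b = (7.0, 0.2, 0.2), (10.0, 0.2, 0.2), (13.0, 0.2, 0.2)
        cv_short = measure_cv(res, model, a, m)
        cv_long = measure_cv(res, model, a, b)
        assert cv_long == pytest.approx(cv_short, rel=0.01)

    def test_block_raises(self):
        g = strand(length=10.0, cross=0.8, dx=0.4)
        model = make_model(g)
        res = run_simulation(model, [], 5.0)
        with pytest.raises(ConductionBlockError, match="block"):
            site_lat(res, model, (5.0, 0.4, 0.4))

    def test_determinism_bit_identical(self):
        _, r1, _ = self._run_strand((0.24, 0.0456), duration=60.0)
        _, r2, _ = self._run_strand((0.24, 0.0456), duration=60.0)
        assert np.array_equal(r1.first_activation, r2.first_activation,
                              equal_nan=True)

    def test_quiescence_without_stimulus(self):
        g = strand(length=10.0, cross=0.8, dx=0.4)
        model = make_model(g)
        res = run_simulation(model, [], 1000.0)
        from ivtlab.membrane import tp06

        assert np.abs(res.final_state.V - tp06.V_INIT).max() < 1.0

    def test_lat_converges_under_dt_halving(self):
        cvs = []
        for dt in (0.02, 0.01):
            g = strand(length=20.0, cross=0.8, dx=0.4)
            model = make_model(g, dt=dt)
            stim = StimulusDef(nodes=model.op.active_nodes[model.coords[:, 0] <= 1.2],
                               onset=0.0, duration=2.0, amplitude=-80.0)
            b = (15.0, 0.4, 0.4)
            res = run_simulation(model, [stim], 60.0,
                                 stop_after_captured=model.nodes_near(b, 0.01))
            cvs.append(site_lat(res, model, b))
        assert abs(cvs[1] - cvs[0]) / cvs[0] < 0.02

    def test_decoupled_node_matches_single_cell(self):
        g = strand(length=2.0, cross=0.8, dx=0.4)
        cond = ConductivityAssignment(healthy=(1e-9, 1e-10))
        model = make_model(g, conductivities=cond)
        node = model.nodes_near((1.0, 0.4, 0.4), 0.0)
        # stimulate at t = 0 so both paths start from the same initial state
        stim = StimulusDef(nodes=node, onset=0.0, duration=1.0, amplitude=-52.0)
        res = run_simulation(model, [stim], 400.0, probes={"n": int(node[0])})
        cell = pace_single_cell(derive_phenotype("epi"), 400.0, 1,
                                stim_amp=-52.0, stim_dur=1.0)
        v_cell = np.interp(res.probe_times, cell.t, cell.v)
        assert np.abs(res.probe_traces["n"] - v_cell).max() < 1.0


class TestMembraneAssignment:
    def test_majority_rule_with_fibroblast_tie_break(self):
        g = TissueGrid(shape=(2, 1, 1), dx=0.4)
        g.label[0, 0, 0] = LABEL_FIBROSIS
        ConductivityAssignment().apply(g)
        model = make_model(g, ModelVersion(er=True))
        # shared nodes between one fibrotic and one healthy element tie ->
        # myocyte; outer nodes of the fibrotic element are fibroblast
        from ivtlab.solver.monodomain import CTYPE_FIBROBLAST

        x = model.coords[:, 0]
        assert np.all(model.ctype[x < 0.3] == CTYPE_FIBROBLAST)
        assert np.all(model.ctype[x > 0.3] != CTYPE_FIBROBLAST)

    def test_er_applies_only_to_bz(self):
        g = TissueGrid(shape=(4, 1, 1), dx=0.4)
        g.label[:2] = LABEL_BZ
        ConductivityAssignment().apply(g)
        model = make_model(g, ModelVersion(er=True))
        x = model.coords[:, 0]
        assert np.all(model.sna[x < 0.7] == 0.38)
        assert np.all(model.sna[x > 0.9] == 1.0)


class TestStabilization:
    @staticmethod
    def _fibrosis_sheet():
        g = TissueGrid(shape=(20, 20, 1), dx=0.4)
        g.label[8:12, 8:12, 0] = LABEL_FIBROSIS
        ConductivityAssignment().apply(g)
        return g

    def test_no_fibrosis_stays_at_rest(self):
        g = TissueGrid(shape=(10, 10, 1), dx=0.4)
        ConductivityAssignment().apply(g)
        model = make_model(g)
        state = stabilize_fibrosis(model, duration=200.0)
        from ivtlab.membrane import tp06

        assert np.abs(state.V - tp06.V_INIT).max() < 1.0

    def test_fixed_point_and_rmp_elevation(self):
        model = make_model(self._fibrosis_sheet())
        state = stabilize_fibrosis(model, duration=1000.0)
        res2 = run_simulation(model, [], 1000.0, initial=state.copy())
        assert np.abs(res2.final_state.V - state.V).max() < 0.5
        # myocyte nodes bordering the fibrotic cluster: elevated RMP
        from ivtlab.solver.monodomain import CTYPE_FIBROBLAST

        myo = model.ctype != CTYPE_FIBROBLAST
        d = np.linalg.norm(model.coords - np.array([4.0, 4.0, 0.0]), axis=1)
        near = myo & (d < 1.5)
        far = myo & (d > 4.0)
        assert state.V[near].mean() > res2.final_state.V[far].mean() + 0.5


@pytest.fixture(scope="module")
def paced_sheet():
    g = TissueGrid(shape=(20, 20, 1), dx=0.4)
    g.label[8:12, 8:12, 0] = LABEL_FIBROSIS
    ConductivityAssignment().apply(g)
    model = make_model(g)
    initial = stabilize_fibrosis(model, duration=600.0)
    stim = StimulusDef(nodes=model.op.active_nodes[model.coords[:, 0] <= 0.8],
                       onset=600.0, duration=2.0, amplitude=-80.0)
    res = run_simulation(model, [stim], 420.0, initial=initial,
                         snapshot_stride=25)  # 0.5 ms snapshots
    return model, res


class TestMaps:

    def test_lat_monotone_along_propagation(self, paced_sheet):
        model, res = paced_sheet
        lat, _ = compute_lat_apd_maps(res, (600.0, 1020.0))
        y_mid = np.abs(model.coords[:, 1] - 4.0) < 0.3
        xs = model.coords[y_mid, 0]
        order = np.argsort(xs)
        lat_line = lat[y_mid][order]
        ok = ~np.isnan(lat_line)
        assert np.all(np.diff(lat_line[ok]) > -1e-9)

    def test_maps_match_independent_rescan(self, paced_sheet):
        model, res = paced_sheet
        lat, apd = compute_lat_apd_maps(res, (600.0, 1020.0))
        sel = (res.times >= 600.0) & (res.times <= 1020.0)
        t = res.times[sel]
        v = res.snapshots[sel]
        for j in (10, 50, 150):  # spot-check nodes against a naive rescan
            dv = np.diff(v[:, j]) / np.diff(t)
            i_up = int(np.argmax(dv))
            if dv[i_up] < 5.0:
                assert np.isnan(lat[j])
                continue
            assert lat[j] == pytest.approx(t[i_up], abs=1e-9)
            seg = v[i_up:, j]
            k = int(np.argmax(seg))
            v90 = seg[k] - 0.9 * (seg[k] - v[0, j])
            below = np.nonzero(seg[k:] <= v90)[0]
            if below.size:
                assert apd[j] == pytest.approx(t[i_up + k + below[0]] - t[i_up], abs=1e-9)

    def test_apd_shortens_next_to_fibrosis(self, paced_sheet):
        model, res = paced_sheet
        _, apd = compute_lat_apd_maps(res, (600.0, 1020.0))
        from ivtlab.solver.monodomain import CTYPE_FIBROBLAST

        myo = model.ctype != CTYPE_FIBROBLAST
        d = np.linalg.norm(model.coords - np.array([4.0, 4.0, 0.0]), axis=1)
        near = myo & (d < 1.2) & ~np.isnan(apd)
        far = myo & (d > 4.0) & ~np.isnan(apd)
        assert np.nanmean(apd[near]) < np.nanmean(apd[far]) - 2.0
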