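"""Stability analysis: onset/bifurcation detectors, buckling ordering."""

import numpy as np
import pytest

from spinefe.assembly import ConstraintSet, DofMap, FEModel, LoadSchedule, \
    assemble_tangent
from spinefe.geometry import build_vertebra
from spinefe.grading import apply_grade
from spinefe.materials import default_material_library
from spinefe.solver import SolutionHistory, SolutionState, solve_quasi_static
from spinefe.stability import (classify_failure, detect_bifurcation,
                               detect_plastic_onset, linearized_buckling)

from tests.conftest import box_mesh


def synthetic_history(t, ux, F, alpha=None, vm=None):
    alpha = np.zeros_like(t) if alpha is None else np.asarray(alpha, float)
    vm = np.zeros_like(t) if vm is None else np.asarray(vm, float)
    states = []
    for i in range(len(t)):
        u = np.zeros((1, 3))
        u[0, 0] = ux[i]
        states.append(SolutionState(t_bar=float(t[i]), u_node=u,
                                    reaction=float(F[i]),
                                    max_vm_cortical=float(vm[i]),
                                    max_eq_plastic=float(alpha[i]),
                                    n_iter=1))
    return SolutionHistory(states=states)


class TestPlasticOnsetDetector:
    def test_elastic_history_has_no_onset(self):
        t = np.linspace(0, 1, 11)
        h = synthetic_history(t, 0.01 * t, 2 * t)
        assert detect_plastic_onset(h) is None

    def test_onset_at_first_plastic_increment(self):
        t = np.linspace(0, 1, 11)
        alpha = np.where(t >= 0.6, 1e-4, 0.0)
        vm = 64 * t / 0.6
        h = synthetic_history(t, 0.01 * t, 2 * t, alpha=alpha, vm=vm)
        onset = detect_plastic_onset(h)
        assert onset.t_bar_pl == pytest.approx(0.6)
        assert onset.F_pl == pytest.approx(1.2)
        assert onset.sigma_pl == pytest.approx(64.0)

    def test_too_short_history_rejected(self):
        h = synthetic_history(np.array([0.0]), [0.0], [0.0])
        with pytest.raises(ValueError):
            detect_plastic_onset(h)


class TestBifurcationDetector:
    def test_proportional_response_has_no_bifurcation(self):
        t = np.linspace(0, 1, 21)
        h = synthetic_history(t, 0.05 * t, 2 * t)
        assert detect_bifurcation(h, probe=0) is None

    def test_rate_jump_detected(self):
        t = np.linspace(0, 1, 21)
        ux = 0.01 * t + np.where(t > 0.6, 0.5 * (t - 0.6), 0.0)
        h = synthetic_history(t, ux, 2 * t)
        bif = detect_bifurcation(h, probe=0)
        assert bif is not None
        assert bif.t_bar_cr == pytest.approx(0.6, abs=0.06)

    def test_unstable_postbuckling_classified(self):
        t = np.linspace(0, 1, 21)
        # lateral excursion jumps at t=0.5 and then decays while the axial
        # force plateaus: the signature of unstable post-buckling motion
        ux = np.where(t < 0.5, 0.01 * t,
                      0.1 * np.exp(-5.0 * (t - 0.5)))
        F = np.minimum(2 * t, 1.0)
        h = synthetic_history(t, ux, F)
        bif = detect_bifurcation(h, probe=0)
        assert bif is not None
        assert bif.post_buckling == "unstable"


class TestEulerColumnBifurcation:
    @pytest.fixture(scope="class")
    def column(self):
        d, L = 4.0, 60.0
        n_side, n_len = 4, 30
        mesh = box_mesh(n_side, n_side, n_len, d, d, L)
        mesh.element_sets = {"posterior_T": np.arange(len(mesh.hexes))}
        # seeded lateral bow imperfection, zero at both ends
        z = mesh.nodes[:, 2]
        mesh.nodes[:, 0] += 0.02 * np.sin(np.pi * z / L)
        nid = mesh.meta["nid"]
        dm = DofMap(mesh.node_ndof)
        mid = n_side // 2
        fixed = np.concatenate([
            dm.trans[[nid[mid, mid, 0]]].ravel(),
            dm.trans[[nid[mid, mid, -1]]][:, :2].ravel(),
            dm.trans[[nid[0, 0, 0]]][:, 1]])
        cons = ConstraintSet(
            fixed_dofs=fixed,
            driven_dofs=dm.trans[[nid[mid, mid, -1]]][:, 2])
        model = FEModel(mesh, default_material_library(1), cons)
        probe = int(nid[0, mid, n_len // 2])
        return model, probe

    def test_detected_critical_shortening_near_analytic(self, column):
        """Driving an imperfect pinned column past its Euler load: the
        detected critical end-shortening lies within 10% of
        P_euler / k_axial."""
        model, probe = column
        lib = model.library
        d, L = 4.0, 60.0
        P_euler = np.pi ** 2 * lib.posterior.E * d ** 4 / 12.0 / L ** 2
        probe_hist = solve_quasi_static(
            model, LoadSchedule(u_z_max=0.02, n_increments=1))
        k_axial = probe_hist.reactions[-1] * 1000.0 / 0.02
        u_cr = P_euler / k_axial
        hist = solve_quasi_static(
            model, LoadSchedule(u_z_max=2.0 * u_cr, n_increments=25))
        # a rate-jump factor J fires at P/P_cr ~ 1 - 1/sqrt(J) on the
        # pre-critical amplification hyperbola; J=100 places the trigger
        # within a few percent of the critical point itself
        bif = detect_bifurcation(hist, probe, jump_factor=100.0)
        assert bif is not None
        detected = bif.t_bar_cr * 2.0 * u_cr
        assert detected == pytest.approx(u_cr, rel=0.10)

    def test_critical_load_stable_under_increment_doubling(self, column):
        model, probe = column
        lib = model.library
        d, L = 4.0, 60.0
        P_euler = np.pi ** 2 * lib.posterior.E * d ** 4 / 12.0 / L ** 2
        h1 = solve_quasi_static(model, LoadSchedule(u_z_max=0.8,
                                                    n_increments=20))
        h2 = solve_quasi_static(model, LoadSchedule(u_z_max=0.8,
                                                    n_increments=40))
        b1 = detect_bifurcation(h1, probe, jump_factor=100.0)
        b2 = detect_bifurcation(h2, probe, jump_factor=100.0)
        assert b1 is not None and b2 is not None
        assert b2.F_cr == pytest.approx(b1.F_cr, rel=0.05)


class TestVertebralBuckling:
    def test_lambda_decreases_with_trabecular_density(self):
        """Linearized buckling load of a single vertebra drops when the
        trabecular core softens (all else fixed)."""
        vert = build_vertebra(element_size=3.0, label="L3")
        loads = {}
        for g in (1, 2):                     # density 300 vs 100 kg/m^3
            gm, lib = apply_grade(vert, g)
            model = FEModel(gm, lib)
            hist = solve_quasi_static(model, LoadSchedule(u_z_max=0.05,
                                                          n_increments=1))
            tan = assemble_tangent(model, hist.u_owner_final)
            lam = linearized_buckling(tan.K_e, tan.K_sigma, k=1)[0].lam
            loads[g] = lam * hist.reactions[-1]
        assert loads[2] < loads[1]


class TestClassification:
    def test_labels(self):
        t = np.linspace(0, 1, 11)
        rising = synthetic_history(t, 0.01 * t, 2 * t)
        flat = synthetic_history(t, 0.01 * t, np.minimum(2 * t, 1.0))
        onset = detect_plastic_onset(synthetic_history(
            t, 0.01 * t, 2 * t, alpha=np.where(t >= 0.5, 1e-4, 0)))
        bif = detect_bifurcation(synthetic_history(
            t, 0.01 * t + np.where(t > 0.7, 0.5 * (t - 0.7), 0.0), 2 * t),
            probe=0)
        assert classify_failure(rising, None, None) == "elastic-stable"
        assert classify_failure(rising, None, bif) == "buckling-limited"
        assert classify_failure(flat, onset, None) == "plasticity-limited"
        # hardening continues past onset with a later bifurcation: mixed
        assert classify_failure(rising, onset, bif) == "mixed"
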