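"""Assembly + quasi-static solver: ties, closed forms, equilibrium,
geometric softening, Euler buckling."""

import numpy as np
import pytest
import scipy.sparse.linalg as spla

from spinefe.assembly import (ConstraintSet, DofMap, FEModel, LoadSchedule,
                              assemble_tangent)
from spinefe.geometry import SegmentMesh
from spinefe.materials import (IsotropicElastic, default_material_library,
                               neo_hookean_from_linear)
from spinefe.solver import solve_quasi_static
from spinefe.stability import linearized_buckling

from tests.conftest import box_mesh, uniaxial_constraints


def _library(**overrides):
    lib = default_material_library(1)
    for k, v in overrides.items():
        setattr(lib, k, v)
    return lib


class TestClosedFormColumn:
    def _run(self, u_max, n_inc=4):
        mesh = box_mesh(2, 2, 6, 10, 10, 30)
        dm = DofMap(mesh.node_ndof)
        model = FEModel(mesh, _library(), uniaxial_constraints(mesh, dm))
        hist = solve_quasi_static(model, LoadSchedule(u_z_max=u_max,
                                                      n_increments=n_inc))
        assert not hist.failed
        return hist, model

    def test_small_strain_matches_linear_form(self):
        """At 0.33% strain the reaction matches E A strain / h within 1%
        (the finite-strain measure deviates ~1.2% already at 0.8%)."""
        hist, model = self._run(0.1)
        E = model.library.trabecular.E_zz
        expect = E * 100.0 * 0.1 / 30.0 / 1000.0
        assert hist.reactions[-1] == pytest.approx(expect, rel=0.01)

    def test_finite_strain_matches_total_lagrangian_form(self):
        """At 8.3% strain the exact TL uniaxial form F = A lam E (lam^2-1)/2
        applies (the engineering form overestimates by ~12% there)."""
        hist, model = self._run(2.5, n_inc=8)
        E = model.library.trabecular.E_zz
        lam = 1.0 - 2.5 / 30.0
        expect = abs(100.0 * lam * E * (lam ** 2 - 1.0) / 2.0) / 1000.0
        assert hist.reactions[-1] == pytest.approx(expect, rel=0.01)

    def test_zero_displacement_zero_state(self):
        mesh = box_mesh(2, 2, 3, 10, 10, 30)
        dm = DofMap(mesh.node_ndof)
        model = FEModel(mesh, _library(), uniaxial_constraints(mesh, dm))
        hist = solve_quasi_static(model, LoadSchedule(u_z_max=0.0,
                                                      n_increments=2))
        assert hist.reactions.max() == 0.0
        assert np.abs(hist.final_state().u_node).max() == 0.0


class TestTieEquivalence:
    def test_tied_stack_matches_conforming_mesh(self):
        """Two stacked blocks joined node-to-node by tie constraints give
        the same solution as one conforming mesh, to 1e-8."""
        lib = _library()
        # conforming reference
        ref = box_mesh(2, 2, 4, 10, 10, 20)
        dm_ref = DofMap(ref.node_ndof)
        mr = FEModel(ref, lib, uniaxial_constraints(ref, dm_ref))
        hr = solve_quasi_static(mr, LoadSchedule(u_z_max=0.3,
                                                 n_increments=2))
        # split version: duplicate interface nodes, tie them
        lo = box_mesh(2, 2, 2, 10, 10, 10)
        hi = box_mesh(2, 2, 2, 10, 10, 10, origin=(0, 0, 10.0))
        n_lo = lo.n_nodes
        nodes = np.vstack([lo.nodes, hi.nodes])
        hexes = np.vstack([lo.hexes, hi.hexes + n_lo])
        mesh = SegmentMesh(
            nodes=nodes, node_ndof=np.full(len(nodes), 3), hexes=hexes,
            element_sets={"trabecular_T": np.arange(len(hexes))},
            node_sets={"bottom": lo.node_sets["bottom"],
                       "top": hi.node_sets["top"] + n_lo})
        top_lo = lo.node_sets["top"]
        bot_hi = hi.node_sets["bottom"] + n_lo
        order_lo = np.lexsort(lo.nodes[top_lo][:, :2].T)
        order_hi = np.lexsort(hi.nodes[bot_hi - n_lo][:, :2].T)
        pairs = np.column_stack([bot_hi[order_hi], top_lo[order_lo]])
        mesh.interface_pairs["T"] = pairs
        mesh.interface_edge["T"] = np.zeros(len(pairs), bool)
        mesh.active_ties["T"] = np.ones(len(pairs), bool)
        mesh.meta["nid"] = lo.meta["nid"]       # for the base constraints
        dm = DofMap(mesh.node_ndof)
        nid_lo = lo.meta["nid"]
        fixed = np.concatenate([
            dm.trans[lo.node_sets["bottom"]][:, 2],
            dm.trans[[nid_lo[0, 0, 0]]][:, :2].ravel(),
            dm.trans[[nid_lo[0, -1, 0]]][:, 0]])
        cons = ConstraintSet(fixed_dofs=fixed,
                             driven_dofs=dm.trans[mesh.node_sets["top"]][:, 2])
        mt = FEModel(mesh, lib, cons)
        ht = solve_quasi_static(mt, LoadSchedule(u_z_max=0.3,
                                                 n_increments=2))
        assert ht.reactions[-1] == pytest.approx(hr.reactions[-1], rel=1e-8)
        # compare displacement fields node-by-node (orders differ)
        mask_r = ref.nodes[:, 2] <= 10.0 + 1e-9
        ur = hr.final_state().u_node[mask_r]
        ut = ht.final_state().u_node[:n_lo]
        key_r = np.lexsort(np.round(ref.nodes[mask_r], 9).T)
        key_t = np.lexsort(np.round(lo.nodes, 9).T)
        assert np.abs(ut[key_t] - ur[key_r]).max() < 1e-8


class TestEquilibrium:
    def test_reactions_balance_at_every_increment(self):
        mesh = box_mesh(2, 2, 4, 10, 10, 30)
        dm = DofMap(mesh.node_ndof)
        model = FEModel(mesh, _library(), uniaxial_constraints(mesh, dm))
        hist = solve_quasi_static(model, LoadSchedule(u_z_max=1.0,
                                                      n_increments=4))
        u = hist.u_owner_final
        f, _, _, _ = model.assemble(u, need_tangent=False)
        # total axial force over all constrained dofs balances to zero
        z_dofs = dm.trans[:, 2]
        assert abs(f[z_dofs].sum()) < 1e-6 * np.abs(f[z_dofs]).max()


class TestEnergyGradientOracle:
    def test_internal_force_matches_fd_energy_gradient(self):
        """On a small mixed-material mesh (elastic cards) the assembled
        internal force equals the central-FD gradient of the total strain
        energy to 1e-4 relative."""
        mesh = box_mesh(3, 3, 6, 9, 9, 18)          # 54 elements
        ne = len(mesh.hexes)
        mesh.element_sets = {
            "trabecular_T": np.arange(0, ne // 3),
            "nucleus_T": np.arange(ne // 3, 2 * ne // 3),
            "annulus_T": np.arange(2 * ne // 3, ne)}
        dm = DofMap(mesh.node_ndof)
        model = FEModel(mesh, _library(),
                        ConstraintSet(fixed_dofs=np.zeros(0, int),
                                      driven_dofs=np.zeros(0, int)))
        rng = np.random.default_rng(11)
        u = 0.02 * rng.standard_normal(model.dofmap.ndof)
        f, _, _, _ = model.assemble(u, need_tangent=False)
        check = rng.choice(model.dofmap.ndof, size=60, replace=False)
        eps = 1e-5
        for d in check:
            up, um = u.copy(), u.copy()
            up[d] += eps
            um[d] -= eps
            fd = (model.energy(up) - model.energy(um)) / (2 * eps)
            assert f[d] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestGeometricStiffness:
    def test_compression_softens_a_slender_column(self):
        """The smallest eigenvalue of K_e + K_sigma decreases as the axial
        pre-compression grows."""
        mesh = box_mesh(2, 2, 16, 2, 2, 32)
        dm = DofMap(mesh.node_ndof)
        lib = _library(trabecular=None)
        lib.trabecular = None
        model_lib = default_material_library(1)
        mesh.element_sets = {"posterior_T": np.arange(len(mesh.hexes))}
        model = FEModel(mesh, model_lib, uniaxial_constraints(mesh, dm))
        eigs = []
        for u_z in (0.01, 0.05):
            hist = solve_quasi_static(model, LoadSchedule(u_z_max=u_z,
                                                          n_increments=2))
            tan = assemble_tangent(model, hist.u_owner_final)
            val = spla.eigsh(tan.K_total, k=1, which="SA",
                             return_eigenvectors=False)[0]
            eigs.append(val)
        assert eigs[1] < eigs[0]


class TestEulerBuckling:
    def test_linearized_buckling_matches_euler_load(self):
        """Pinned-pinned elastic column: lambda * F_ref within 5% of
        pi^2 E I / L^2 at a refined mesh."""
        d, L = 4.0, 60.0
        n_side, n_len = 4, 60
        mesh = box_mesh(n_side, n_side, n_len, d, d, L)
        mesh.element_sets = {"posterior_T": np.arange(len(mesh.hexes))}
        nid = mesh.meta["nid"]
        dm = DofMap(mesh.node_ndof)
        mid = n_side // 2
        # pinned-pinned: support and drive only the end centre nodes, so
        # the end sections are free to rotate
        fixed = np.concatenate([
            dm.trans[[nid[mid, mid, 0]]].ravel(),           # base pin
            dm.trans[[nid[mid, mid, -1]]][:, :2].ravel(),   # top lateral pin
            dm.trans[[nid[0, 0, 0]]][:, 1],                 # twist restraint
        ])
        cons = ConstraintSet(
            fixed_dofs=fixed,
            driven_dofs=dm.trans[[nid[mid, mid, -1]]][:, 2])
        lib = default_material_library(1)
        model = FEModel(mesh, lib, cons)
        u_ref = 0.01
        hist = solve_quasi_static(model, LoadSchedule(u_z_max=u_ref,
                                                      n_increments=1))
        F_ref = hist.reactions[-1] * 1000.0              # N
        tan = assemble_tangent(model, hist.u_owner_final)
        modes = linearized_buckling(tan.K_e, tan.K_sigma, k=2)
        P_cr = modes[0].lam * F_ref
        E = lib.posterior.E
        I = d ** 4 / 12.0
        euler = np.pi ** 2 * E * I / L ** 2
        assert P_cr == pytest.approx(euler, rel=0.05)

    def test_lambda_scales_with_elastic_moduli(self):
        """Doubling all elastic moduli doubles lambda at a fixed reference
        stress state."""
        import scipy.sparse as sp
        rng = np.random.default_rng(2)
        n = 40
        B = sp.random(n, n, density=0.2, random_state=3)
        K_e = (B @ B.T + 10 * sp.eye(n)).tocsr()
        Ks = sp.diags(-rng.random(n))
        lam1 = linearized_buckling(K_e, Ks, k=1)[0].lam
        lam2 = linearized_buckling((2 * K_e).tocsr(), Ks, k=1)[0].lam
        assert lam2 == pytest.approx(2 * lam1, rel=1e-9)
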