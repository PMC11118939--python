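"""Compact verification oracles shared by the acceptance checks."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from spinefe.assembly import ConstraintSet, DofMap, FEModel, LoadSchedule, \
    assemble_tangent
from spinefe.fe.hex import HexBlock
from spinefe.geometry import SegmentMesh
from spinefe.materials import IsotropicElastic, default_material_library
from spinefe.solver import solve_quasi_static
from spinefe.stability import linearized_buckling

from tests.conftest import box_mesh, uniaxial_constraints


def patch_test_stress_spread() -> float:
    """Relative stress spread of a distorted patch under a linear field."""
    rng = np.random.default_rng(3)
    mesh = box_mesh(2, 2, 2, 1, 1, 1)
    corners = ((mesh.nodes[:, 0] % 1 == 0) & (mesh.nodes[:, 1] % 1 == 0)
               & (mesh.nodes[:, 2] % 1 == 0))
    mesh.nodes[~corners] += 0.08 * rng.standard_normal(mesh.nodes.shape)[~corners]
    blk = HexBlock(mesh.nodes, mesh.hexes, IsotropicElastic(E=7.0, nu=0.3))
    A = 1e-3 * np.array([[1.0, 0.3, 0.1], [0.0, -0.5, 0.2], [0.4, 0.0, 0.8]])
    S = blk.stress_voigt(mesh.nodes @ A.T)
    return float(np.abs(S - S.reshape(-1, 6).mean(axis=0)).max()
                 / np.abs(S).max())


def tie_equivalence_mismatch() -> float:
    """Max relative difference between a tied stack and a conforming mesh."""
    lib = default_material_library(1)
    ref = box_mesh(2, 2, 4, 10, 10, 20)
    mr = FEModel(ref, lib, uniaxial_constraints(ref, DofMap(ref.node_ndof)))
    hr = solve_quasi_static(mr, LoadSchedule(u_z_max=0.3, n_increments=2))

    lo = box_mesh(2, 2, 2, 10, 10, 10)
    hi = box_mesh(2, 2, 2, 10, 10, 10, origin=(0, 0, 10.0))
    n_lo = lo.n_nodes
    mesh = SegmentMesh(
        nodes=np.vstack([lo.nodes, hi.nodes]),
        node_ndof=np.full(lo.n_nodes + hi.n_nodes, 3),
        hexes=np.vstack([lo.hexes, hi.hexes + n_lo]),
        element_sets={"trabecular_T":
                      np.arange(len(lo.hexes) + len(hi.hexes))},
        node_sets={})
    top_lo = lo.node_sets["top"]
    bot_hi = hi.node_sets["bottom"] + n_lo
    o1 = np.lexsort(lo.nodes[top_lo][:, :2].T)
    o2 = np.lexsort(hi.nodes[bot_hi - n_lo][:, :2].T)
    mesh.interface_pairs["T"] = np.column_stack([bot_hi[o2], top_lo[o1]])
    mesh.interface_edge["T"] = np.zeros(len(top_lo), bool)
    mesh.active_ties["T"] = np.ones(len(top_lo), bool)
    dm = DofMap(mesh.node_ndof)
    nid = lo.meta["nid"]
    fixed = np.concatenate([
        dm.trans[lo.node_sets["bottom"]][:, 2],
        dm.trans[[nid[0, 0, 0]]][:, :2].ravel(),
        dm.trans[[nid[0, -1, 0]]][:, 0]])
    cons = ConstraintSet(
        fixed_dofs=fixed,
        driven_dofs=dm.trans[hi.node_sets["top"] + n_lo][:, 2])
    mt = FEModel(mesh, lib, cons)
    ht = solve_quasi_static(mt, LoadSchedule(u_z_max=0.3, n_increments=2))
    return abs(ht.reactions[-1] - hr.reactions[-1]) / hr.reactions[-1]


def euler_buckling_ratio() -> float:
    """(lambda * F_ref) / (pi^2 E I / L^2) for a pinned hex column."""
    d, L = 4.0, 60.0
    n_side, n_len = 4, 60
    mesh = box_mesh(n_side, n_side, n_len, d, d, L)
    mesh.element_sets = {"posterior_T": np.arange(len(mesh.hexes))}
    nid = mesh.meta["nid"]
    dm = DofMap(mesh.node_ndof)
    mid = n_side // 2
    fixed = np.concatenate([
        dm.trans[[nid[mid, mid, 0]]].ravel(),
        dm.trans[[nid[mid, mid, -1]]][:, :2].ravel(),
        dm.trans[[nid[0, 0, 0]]][:, 1]])
    cons = ConstraintSet(fixed_dofs=fixed,
                         driven_dofs=dm.trans[[nid[mid, mid, -1]]][:, 2])
    lib = default_material_library(1)
    model = FEModel(mesh, lib, cons)
    hist = solve_quasi_static(model, LoadSchedule(u_z_max=0.01,
                                                  n_increments=1))
    tan = assemble_tangent(model, hist.u_owner_final)
    lam = linearized_buckling(tan.K_e, tan.K_sigma, k=2)[0].lam
    euler = np.pi ** 2 * lib.posterior.E * d ** 4 / 12.0 / L ** 2
    return lam * hist.reactions[-1] * 1000.0 / euler


def energy_gradient_max_error(n_check: int = 40) -> float:
    """Max relative error of f_int vs the FD energy gradient (elastic)."""
    mesh = box_mesh(3, 3, 6, 9, 9, 18)
    ne = len(mesh.hexes)
    mesh.element_sets = {
        "trabecular_T": np.arange(0, ne // 3),
        "nucleus_T": np.arange(ne // 3, 2 * ne // 3),
        "annulus_T": np.arange(2 * ne // 3, ne)}
    model = FEModel(mesh, default_material_library(1),
                    ConstraintSet(fixed_dofs=np.zeros(0, int),
                                  driven_dofs=np.zeros(0, int)))
    rng = np.random.default_rng(11)
    u = 0.02 * rng.standard_normal(model.dofmap.ndof)
    f, _, _, _ = model.assemble(u, need_tangent=False)
    worst = 0.0
    eps = 1e-5
    scale = np.abs(f).max()
    for d in rng.choice(model.dofmap.ndof, size=n_check, replace=False):
        up, um = u.copy(), u.copy()
        up[d] += eps
        um[d] -= eps
        fd = (model.energy(up) - model.energy(um)) / (2 * eps)
        worst = max(worst, abs(f[d] - fd) / max(abs(fd), 1e-3 * scale))
    return worst
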