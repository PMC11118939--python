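"""Shared fixtures: small synthetic meshes and solved model runs."""

from __future__ import annotations

import numpy as np
import pytest

from spinefe.assembly import ConstraintSet, DofMap, FEModel, LoadSchedule
from spinefe.geometry import SegmentMesh


def box_mesh(nx, ny, nz, lx, ly, lz, set_name="trabecular_T",
             origin=(0.0, 0.0, 0.0)):
    """Structured hex box as a SegmentMesh (single element set)."""
    xs = np.linspace(0, lx, nx + 1) + origin[0]
    ys = np.linspace(0, ly, ny + 1) + origin[1]
    zs = np.linspace(0, lz, nz + 1) + origin[2]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    nid = np.arange(len(nodes)).reshape(nx + 1, ny + 1, nz + 1)
    conn = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                conn.append([nid[i, j, k], nid[i + 1, j, k],
                             nid[i + 1, j + 1, k], nid[i, j + 1, k],
                             nid[i, j, k + 1], nid[i + 1, j, k + 1],
                             nid[i + 1, j + 1, k + 1], nid[i, j + 1, k + 1]])
    conn = np.array(conn, int)
    mesh = SegmentMesh(nodes=nodes, node_ndof=np.full(len(nodes), 3),
                       hexes=conn,
                       element_sets={set_name: np.arange(len(conn))},
                       node_sets={"bottom": nid[:, :, 0].ravel(),
                                  "top": nid[:, :, -1].ravel()})
    mesh.meta["nid"] = nid
    return mesh


def uniaxial_constraints(mesh: SegmentMesh, dofmap: DofMap) -> ConstraintSet:
    """Frictionless uniaxial compression: base z fixed (+ rigid-mode pins),
    top z driven."""
    nid = mesh.meta["nid"]
    bot = mesh.node_sets["bottom"]
    fixed = [dofmap.trans[bot][:, 2],
             dofmap.trans[[nid[0, 0, 0]]][:, :2].ravel(),
             dofmap.trans[[nid[0, -1, 0]]][:, 0]]
    driven = dofmap.trans[mesh.node_sets["top"]][:, 2]
    return ConstraintSet(fixed_dofs=np.concatenate(fixed),
                         driven_dofs=driven)


@pytest.fixture(scope="session")
def grade_sweep():
    """Scaled-down five-grade sweep shared by the acceptance checks.

    Session-scoped: the sweep is the most expensive computation in the
    suite and every grade-comparison assertion reads from it.
    """
    from spinefe.pipeline import RunConfig, run_grade_sweep
    cfg = RunConfig(grade=1, element_size=3.0, n_increments=50, seed=1)
    return run_grade_sweep(cfg)
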