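"""Global assembly: dof numbering, tie elimination, sparse tangents.

Shell-wall nodes are tied to their coincident solid-surface nodes by a
dof-representative map (slave translation dofs are renumbered onto the
master's), which realizes the bonded shell-solid constraint exactly and
makes debonding a pure bookkeeping change.  The assembled operators are
restricted to the free (owner, unconstrained) dofs; the elastic/material
part ``K_e`` and the geometric (initial-stress) part ``K_sigma`` are kept
separate so linearized buckling can form K_e + lambda K_sigma.

Assembly is pattern-cached: the CSR structure is computed once per model
and each call only scatters new data, which keeps the per-iteration cost
far below the factorization cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from .fe.hex import HexBlock
from .fe.link import LinkBlock
from .fe.shell import ShellBlock, cortical_plane_stress, fibre_plane_stress
from .geometry import SegmentMesh
from .materials import MaterialLibrary

__all__ = ["DofMap", "FEModel", "TangentStiffness", "ConstraintSet",
           "LoadSchedule", "segment_constraints", "assemble_tangent"]


@dataclass(frozen=True)
class LoadSchedule:
    """Displacement-controlled axial compression schedule.

    The driven dofs move by ``-u_z_max * t_bar`` (downward compression);
    ``t_bar`` is the pseudo-time in [0, 1].
    """

    u_z_max: float = 2.5
    n_increments: int = 50
    t_bar: Optional[np.ndarray] = None

    def times(self) -> np.ndarray:
        if self.t_bar is not None:
            t = np.asarray(self.t_bar, float)
            if t[0] != 0.0 or t[-1] != 1.0 or np.any(np.diff(t) <= 0):
                raise ValueError("t_bar must increase strictly from 0 to 1")
            return t
        if self.n_increments < 1:
            raise ValueError("need at least one increment")
        return np.linspace(0.0, 1.0, self.n_increments + 1)


@dataclass
class ConstraintSet:
    """Fixed and driven dof index arrays (in full dof space)."""

    fixed_dofs: np.ndarray
    driven_dofs: np.ndarray

    def __post_init__(self):
        if np.intersect1d(self.fixed_dofs, self.driven_dofs).size:
            raise ValueError("a dof cannot be both fixed and driven")


@dataclass
class TangentStiffness:
    """Separated tangent operators on the free-dof space."""

    K_e: sp.csr_matrix
    K_sigma: sp.csr_matrix

    @property
    def K_total(self) -> sp.csr_matrix:
        return (self.K_e + self.K_sigma).tocsr()


class DofMap:
    """Node-wise dof numbering: 3 dofs for solids, 6 for shell nodes."""

    def __init__(self, node_ndof: np.ndarray):
        self.node_ndof = np.asarray(node_ndof, int)
        offsets = np.concatenate([[0], np.cumsum(self.node_ndof)])
        self.offsets = offsets
        self.ndof = int(offsets[-1])
        n = len(self.node_ndof)
        self.trans = offsets[:-1, None] + np.arange(3)
        self.rot = np.where((self.node_ndof == 6)[:, None],
                            offsets[:-1, None] + np.arange(3, 6), -1)

    def translations(self, u_full: np.ndarray) -> np.ndarray:
        return u_full[self.trans]

    def rotations(self, u_full: np.ndarray) -> np.ndarray:
        out = np.zeros((len(self.node_ndof), 3))
        has = self.node_ndof == 6
        out[has] = u_full[self.rot[has]]
        return out


class _Pattern:
    """CSR pattern + scatter map for a fixed (rows, cols) multiset."""

    def __init__(self, rows: np.ndarray, cols: np.ndarray, n: int):
        order = np.lexsort((cols, rows))
        r, c = rows[order], cols[order]
        # unique (r,c) entries
        key_new = np.ones(len(r), bool)
        if len(r):
            key_new[1:] = (r[1:] != r[:-1]) | (c[1:] != c[:-1])
        upos = np.cumsum(key_new) - 1
        self.scatter = np.empty(len(r), int)
        self.scatter[order] = upos
        ur, uc = r[key_new], c[key_new]
        self.indices = uc.astype(np.int32)
        self.indptr = np.zeros(n + 1, np.int64)
        np.add.at(self.indptr, ur + 1, 1)
        np.cumsum(self.indptr, out=self.indptr)
        self.n = n
        self.nnz = len(ur)

    def build(self, data: np.ndarray) -> sp.csr_matrix:
        vals = np.zeros(self.nnz)
        np.add.at(vals, self.scatter, data)
        return sp.csr_matrix((vals, self.indices, self.indptr),
                             shape=(self.n, self.n))


class FEModel:
    """Assembled FE model of a (graded) segment mesh + material library."""

    def __init__(self, mesh: SegmentMesh, library: MaterialLibrary,
                 constraints: Optional[ConstraintSet] = None):
        self.mesh = mesh
        self.library = library
        self.dofmap = DofMap(mesh.node_ndof)
        nd = self.dofmap.ndof

        # --- tie representative map -----------------------------------
        rep = np.arange(nd)
        for pairs in ([mesh.tie_pairs_active()] if mesh.interface_pairs else []):
            if len(pairs):
                sh = self.dofmap.trans[pairs[:, 0]]
                so = self.dofmap.trans[pairs[:, 1]]
                rep[sh.ravel()] = so.ravel()
        self.rep = rep
        self.is_owner = rep == np.arange(nd)

        # --- constraints -----------------------------------------------
        if constraints is None:
            constraints = segment_constraints(mesh, self.dofmap)
        self.constraints = constraints
        status = np.zeros(nd, np.int8)          # 0 free, 1 fixed, 2 driven
        status[rep[constraints.fixed_dofs]] = 1
        status[rep[constraints.driven_dofs]] = 2
        self.free_ids = np.nonzero(self.is_owner & (status == 0))[0]
        self.driven_owner = np.unique(rep[constraints.driven_dofs])
        self.fixed_owner = np.unique(rep[constraints.fixed_dofs])
        self.pos = np.full(nd, -1)
        self.pos[self.free_ids] = np.arange(len(self.free_ids))
        self.n_free = len(self.free_ids)

        # --- element blocks ---------------------------------------------
        self.hex_blocks: List[Tuple[HexBlock, np.ndarray]] = []
        self.shell_blocks: List[Tuple[ShellBlock, np.ndarray]] = []
        self.link_blocks: List[Tuple[LinkBlock, np.ndarray]] = []
        self._build_blocks()

        # committed plastic state per plastic shell block index
        self.state: Dict[int, tuple] = {
            i: blk.fresh_state() for i, (blk, _) in
            enumerate(self.shell_blocks) if blk.plastic is not None}
        self._trial: Dict[int, tuple] = dict(self.state)

        # --- assembly pattern -------------------------------------------
        rows, cols = [], []
        for blk, dofs in (self.hex_blocks + self.shell_blocks
                          + self.link_blocks):
            r, c, keep = self._free_entries(dofs)
            rows.append(r)
            cols.append(c)
        self._entry_keep = [self._free_entries(d)[2] for _, d in
                            (self.hex_blocks + self.shell_blocks
                             + self.link_blocks)]
        self.pattern = _Pattern(np.concatenate(rows) if rows else
                                np.zeros(0, int),
                                np.concatenate(cols) if cols else
                                np.zeros(0, int), self.n_free)

    # -- construction helpers ---------------------------------------------
    def _free_entries(self, dofs: np.ndarray):
        nd = dofs.shape[1]
        p = self.pos[self.rep[dofs]]
        rr = np.repeat(p, nd, axis=1).ravel()
        cc = np.tile(p, (1, nd)).ravel()
        keep = (rr >= 0) & (cc >= 0)
        return rr[keep], cc[keep], keep

    def _build_blocks(self):
        mesh, lib = self.mesh, self.library
        for name, idx in mesh.element_sets.items():
            card = lib.card_for(name)
            blk = HexBlock(mesh.nodes, mesh.hexes[idx], card, name=name)
            dofs = self.dofmap.trans[blk.conn].reshape(len(idx), 24)
            self.hex_blocks.append((blk, dofs))
        C_cort, Gt = cortical_plane_stress(lib.cortical)
        for name, idx in mesh.shell_sets.items():
            conn = mesh.shells[idx]
            t = mesh.shell_thickness[idx]
            if name.startswith("cortical"):
                blk = ShellBlock(mesh.nodes, conn, t, C_cort, mode="shell",
                                 transverse_G=Gt,
                                 plasticity=lib.cortical_plasticity, name=name)
                dofs = np.concatenate(
                    [self.dofmap.trans[conn], self.dofmap.rot[conn]],
                    axis=2).reshape(len(idx), 24)
            elif name.startswith("fibre"):
                E_layer = (lib.fibres.E_external if "external" in name
                           else lib.fibres.E_internal)
                angles = mesh.fibre_angle_pairs.get(name,
                                                    lib.fibres.angles_deg)
                blk = ShellBlock(mesh.nodes, conn, t,
                                 fibre_plane_stress(E_layer, angles),
                                 mode="membrane", name=name)
                dofs = self.dofmap.trans[conn].reshape(len(idx), 12)
            else:
                raise KeyError(f"unrecognized shell set {name!r}")
            self.shell_blocks.append((blk, dofs))
        if len(mesh.links):
            E = np.array([lib.ligaments[g].E for g in mesh.link_group])
            blk = LinkBlock(mesh.nodes, mesh.links, mesh.link_area, E)
            dofs = self.dofmap.trans[mesh.links].reshape(len(mesh.links), 6)
            self.link_blocks.append((blk, dofs))

    # -- state handling ----------------------------------------------------
    def expand(self, u_owner: np.ndarray) -> np.ndarray:
        """Owner-space vector -> full dof vector (slaves follow masters)."""
        return u_owner[self.rep]

    def commit_state(self):
        self.state = {k: (v[0].copy(), v[1].copy())
                      for k, v in self._trial.items()}

    def committed_alpha_max(self) -> float:
        return max((float(v[1].max()) for v in self.state.values()),
                   default=0.0)

    # -- assembly ----------------------------------------------------------
    def assemble(self, u_owner: np.ndarray, need_tangent: bool = True):
        """Internal force + tangents at the given owner-space displacement.

        Returns (f_full, K_e, K_sigma, diag); K_* are None without tangent.
        ``f_full`` lives in owner dof space (tie-condensed).
        """
        u_full = self.expand(u_owner)
        ut = self.dofmap.translations(u_full)
        ur = self.dofmap.rotations(u_full)
        nd = self.dofmap.ndof
        f = np.zeros(nd)
        dat_e, dat_g = [], []
        diag = {"max_vm_cortical": 0.0, "max_eq_plastic": 0.0,
                "vm_by_set": {}}
        kidx = 0
        for blk, dofs in self.hex_blocks:
            fe, Km, Kg = blk.force_and_tangent(ut, need_tangent)
            np.add.at(f, self.rep[dofs], fe)
            if need_tangent:
                keep = self._entry_keep[kidx]
                dat_e.append(Km.ravel()[keep])
                dat_g.append(Kg.ravel()[keep])
            kidx += 1
        for i, (blk, dofs) in enumerate(self.shell_blocks):
            st = self.state.get(i)
            fe, Km, Kg, new_state, vm = blk.force_and_tangent(
                ut, ur if blk.mode == "shell" else None, st, need_tangent)
            if new_state is not None:
                self._trial[i] = new_state
                diag["max_eq_plastic"] = max(diag["max_eq_plastic"],
                                             float(new_state[1].max()))
            vmax = float(vm.max()) if vm.size else 0.0
            diag["vm_by_set"][blk.name] = vmax
            if blk.name.startswith("cortical"):
                diag["max_vm_cortical"] = max(diag["max_vm_cortical"], vmax)
            np.add.at(f, self.rep[dofs], fe)
            if need_tangent:
                keep = self._entry_keep[kidx]
                dat_e.append(Km.ravel()[keep])
                dat_g.append(Kg.ravel()[keep])
            kidx += 1
        for blk, dofs in self.link_blocks:
            fe, K = blk.force_and_tangent(self.mesh.nodes, ut, need_tangent)
            np.add.at(f, self.rep[dofs], fe)
            if need_tangent:
                keep = self._entry_keep[kidx]
                dat_e.append(K.ravel()[keep])
                dat_g.append(np.zeros(int(keep.sum())))
            kidx += 1
        K_e = K_g = None
        if need_tangent:
            K_e = self.pattern.build(np.concatenate(dat_e)
                                     if dat_e else np.zeros(0))
            K_g = self.pattern.build(np.concatenate(dat_g)
                                     if dat_g else np.zeros(0))
        return f, K_e, K_g, diag

    def internal_force(self, u_owner: np.ndarray):
        return self.assemble(u_owner, need_tangent=False)

    def energy(self, u_owner: np.ndarray) -> float:
        """Total strain energy (elastic constitutive state)."""
        u_full = self.expand(u_owner)
        ut = self.dofmap.translations(u_full)
        ur = self.dofmap.rotations(u_full)
        total = 0.0
        for blk, _ in self.hex_blocks:
            total += blk.energy(ut)
        for i, (blk, _) in enumerate(self.shell_blocks):
            total += blk.energy(None, ut, ur if blk.mode == "shell" else None,
                                self.state.get(i))
        for blk, _ in self.link_blocks:
            total += blk.energy(self.mesh.nodes, ut)
        return total

    def reaction_force(self, f_full: np.ndarray) -> float:
        """Total axial reaction [kN] transmitted through the driven dofs."""
        return float(np.abs(f_full[self.driven_owner].sum())) / 1000.0


def segment_constraints(mesh: SegmentMesh,
                        dofmap: Optional[DofMap] = None) -> ConstraintSet:
    """Fixed L4 base (all dofs), driven axial dofs on the L2 top endplate."""
    dofmap = dofmap or DofMap(mesh.node_ndof)
    if "base_L4" in mesh.node_sets:
        base = mesh.node_sets["base_L4"]
        top = mesh.node_sets["top_endplate_L2"]
    else:   # single-body meshes keep base_<label>/top_endplate_<label>
        base_keys = [k for k in mesh.node_sets if k.startswith("base_")]
        top_keys = [k for k in mesh.node_sets if k.startswith("top_endplate_")]
        if not base_keys or not top_keys:
            raise ValueError("mesh defines no base/top node sets")
        base = mesh.node_sets[base_keys[0]]
        top = mesh.node_sets[top_keys[0]]
    fixed = dofmap.trans[base].ravel()
    driven = dofmap.trans[top][:, 2].ravel()
    return ConstraintSet(fixed_dofs=fixed, driven_dofs=driven)


def assemble_tangent(model: FEModel, u_owner: np.ndarray) -> TangentStiffness:
    """Tangent operators (free-dof space) at a given state."""
    _, K_e, K_g, _ = model.assemble(u_owner, need_tangent=True)
    return TangentStiffness(K_e=K_e, K_sigma=K_g)
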