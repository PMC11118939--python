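"""Flat-facet 4-node shells and membranes, vectorized per element block.

Two modes:

* ``shell`` (cortical wall): total-Lagrangian membrane (full quadratic
  Green strain in all three local displacement components, so membrane
  forces couple to out-of-plane deflection and the wall can buckle)
  + Mindlin bending with one-point (selectively reduced) transverse shear
  and a small hourglass stabilization + a small drilling penalty.
  Six dofs per node.  Membrane plasticity via a plane-stress von Mises
  return; bending stays elastic.
* ``membrane`` (annulus fibre layers): small-strain membrane on 3-dof
  nodes with no bending resistance and no out-of-plane coupling at all.
  A true TL membrane would wrinkle under the axial compression the disc
  wall sees (zero bending stiffness makes that instability immediate at
  the element scale); the linear-kinematics membrane is the standard
  desk-scale regularization and keeps the fibre layers acting purely as
  in-plane reinforcement.

Element material axes: local e2 is the projection of the global z axis
(axial direction) onto the element plane, e1 the circumferential
direction; the plane-stress operator is expressed in that frame.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from ..materials import OrthotropicElastic, PlasticityCard, FibreLayerCard
from .plasticity import PlaneStressReturn

__all__ = ["ShellBlock", "shell_stiffness_and_force",
           "cortical_plane_stress", "fibre_plane_stress"]

_QP = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], float) / np.sqrt(3.0)
_QC = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], float)
_CENTER = np.zeros((1, 2))
_SHEAR_CORR = 5.0 / 6.0


def _dN2(xi: np.ndarray) -> np.ndarray:
    xi = np.atleast_2d(xi)
    out = np.empty((xi.shape[0], 4, 2))
    for a in range(4):
        cx, cy = _QC[a]
        out[:, a, 0] = cx * (1 + cy * xi[:, 1]) / 4
        out[:, a, 1] = cy * (1 + cx * xi[:, 0]) / 4
    return out


def _N2(xi: np.ndarray) -> np.ndarray:
    xi = np.atleast_2d(xi)
    out = np.empty((xi.shape[0], 4))
    for a in range(4):
        cx, cy = _QC[a]
        out[:, a] = (1 + cx * xi[:, 0]) * (1 + cy * xi[:, 1]) / 4
    return out


_DN_GP = _dN2(_QP)      # (4 gp, 4, 2)
_DN_C = _dN2(_CENTER)   # (1, 4, 2)
_N_GP = _N2(_QP)
_N_C = _N2(_CENTER)


def cortical_plane_stress(card: OrthotropicElastic) -> Tuple[np.ndarray, float]:
    """(3x3 plane-stress operator in (circ, axial, shear), transverse G).

    Local 1 = circumferential -> x-row of the card, local 2 = axial -> z.
    """
    S = np.array([[1.0 / card.E_xx, -card.nu_xz / max(card.E_xx, card.E_zz)],
                  [-card.nu_xz / max(card.E_xx, card.E_zz), 1.0 / card.E_zz]])
    C2 = np.linalg.inv(S)
    C = np.zeros((3, 3))
    C[:2, :2] = C2
    C[2, 2] = card.G_xz
    return C, card.G_xy


def fibre_plane_stress(E_layer: float, angles_deg) -> np.ndarray:
    """Smeared cross-ply membrane operator of one fibre layer.

    Each +-theta family contributes E * m m^T with m = (a1^2, a2^2, a1 a2),
    a the fibre direction in the (circ, axial) plane; families are averaged.
    """
    C = np.zeros((3, 3))
    for th in angles_deg:
        t = np.deg2rad(th)
        a1, a2 = np.cos(t), np.sin(t)
        m = np.array([a1 ** 2, a2 ** 2, a1 * a2])
        C += 0.5 * E_layer * np.outer(m, m)
    return C


class ShellBlock:
    """A batch of flat 4-node shell (or membrane) elements."""

    def __init__(self, nodes: np.ndarray, conn: np.ndarray,
                 thickness: np.ndarray, C_ps: np.ndarray,
                 mode: str = "shell",
                 transverse_G: float = 0.0,
                 plasticity: Optional[PlasticityCard] = None,
                 drilling: float = 1e-3,
                 shear_stab: float = 0.002,
                 name: str = "shell"):
        if mode not in ("shell", "membrane"):
            raise ValueError(f"unknown shell mode {mode!r}")
        self.conn = np.asarray(conn, int)
        self.t = np.broadcast_to(np.asarray(thickness, float),
                                 (self.conn.shape[0],)).copy()
        self.C = np.asarray(C_ps, float)
        self.mode = mode
        self.name = name
        S = self.conn.shape[0]

        X = nodes[self.conn]                          # (S,4,3)
        d1 = X[:, 2] - X[:, 0]
        d2 = X[:, 3] - X[:, 1]
        e3 = np.cross(d1, d2)
        a = np.linalg.norm(e3, axis=1)
        if a.min(initial=np.inf) <= 1e-12 and S:
            raise ValueError(f"zero-area shell element in {name!r}")
        e3 /= a[:, None]
        z = np.array([0.0, 0.0, 1.0])
        e2 = z - e3 * e3[:, 2:3]
        n2 = np.linalg.norm(e2, axis=1)
        degen = n2 < 1e-6
        if degen.any():                   # element lies in the x-y plane
            alt = d1 - e3 * np.einsum("si,si->s", d1, e3)[:, None]
            e2[degen] = alt[degen]
            n2 = np.linalg.norm(e2, axis=1)
        e2 /= n2[:, None]
        e1 = np.cross(e2, e3)
        self.R = np.stack([e1, e2, e3], axis=1)       # rows: local axes (S,3,3)

        centroid = X.mean(axis=1)
        rel = X - centroid[:, None, :]
        xl = np.einsum("sij,saj->sai", self.R, rel)[..., :2]   # (S,4,2)
        self.xl = xl

        J = np.einsum("gai,saj->sgij", _DN_GP, xl)    # (S,4gp,2,2)
        self.detJ = np.linalg.det(J)
        if S and self.detJ.min() <= 0:
            raise ValueError(f"inverted shell element in {name!r}")
        Jinv = np.linalg.inv(J)
        self.dNdx = np.einsum("sgji,gai->sgaj", Jinv, _DN_GP)  # (S,4gp,4,2)
        Jc = np.einsum("gai,saj->sgij", _DN_C, xl)
        self.detJc = np.linalg.det(Jc)[:, 0]
        self.dNdx_c = np.einsum("sgji,gai->sgaj", np.linalg.inv(Jc), _DN_C)[:, 0]
        self.area = self.detJ.sum(axis=1)

        self.plastic = PlaneStressReturn(self.C, plasticity) \
            if plasticity is not None else None
        self.n_eldof = 24 if mode == "shell" else 12
        self.linear_kinematics = (mode == "membrane")

        if mode == "shell":
            self.Gt = transverse_G
            self.K_plate = self._plate_stiffness(drilling, shear_stab)
        else:
            self.K_plate = None

    # -- elastic plate (bending + shear + drilling), local, constant ------
    def _plate_stiffness(self, drilling: float, shear_stab: float) -> np.ndarray:
        S = self.conn.shape[0]
        K = np.zeros((S, 24, 24))
        # dof layout per node: (u1,u2,w,r1,r2,r3) local
        ir1 = np.arange(4) * 6 + 3
        ir2 = np.arange(4) * 6 + 4
        iw = np.arange(4) * 6 + 2
        Db = (self.t ** 3 / 12.0)[:, None, None] * self.C
        for g in range(4):
            B = np.zeros((S, 3, 24))
            B[:, 0, ir2] = self.dNdx[:, g, :, 0]
            B[:, 1, ir1] = -self.dNdx[:, g, :, 1]
            B[:, 2, ir2] = self.dNdx[:, g, :, 1]
            B[:, 2, ir1] = -self.dNdx[:, g, :, 0]
            K += np.einsum("sri,srq,sqj,s->sij", B, Db, B, self.detJ[:, g])
        kG = _SHEAR_CORR * self.Gt * self.t
        # one-point shear + small full-integration stabilization
        for pts, dN, N, w, fac in (
                ((0,), self.dNdx_c[:, None], _N_C, self.detJc[:, None], 1.0),
                (range(4), self.dNdx, _N_GP, self.detJ, shear_stab)):
            for g in pts:
                Bs = np.zeros((S, 2, 24))
                Bs[:, 0, iw] = dN[:, g, :, 0]
                Bs[:, 0, ir2] = N[g]
                Bs[:, 1, iw] = dN[:, g, :, 1]
                Bs[:, 1, ir1] = -N[g]
                K += fac * np.einsum("sri,srj,s,s->sij", Bs, Bs, kG, w[:, g])
        # drilling penalty
        kd = drilling * self.Gt * self.t * self.area / 4.0
        ir3 = np.arange(4) * 6 + 5
        K[:, ir3, ir3] += kd[:, None]
        return K

    # -- kinematics --------------------------------------------------------
    def _local_disp(self, u: np.ndarray, r: Optional[np.ndarray]):
        ul = np.einsum("sij,saj->sai", self.R, u[self.conn])
        rl = None
        if self.mode == "shell":
            rl = np.einsum("sij,saj->sai", self.R, r[self.conn])
        return ul, rl

    def _membrane_strain(self, ul: np.ndarray):
        grad = np.einsum("sai,sgaj->sgij", ul, self.dNdx)      # (S,g,3,2)
        if self.linear_kinematics:
            Fh = np.zeros_like(grad)
            Fh[..., 0, 0] = 1.0
            Fh[..., 1, 1] = 1.0
            e = np.stack([grad[..., 0, 0], grad[..., 1, 1],
                          grad[..., 0, 1] + grad[..., 1, 0]], axis=-1)
            return Fh, e
        Fh = grad.copy()
        Fh[..., 0, 0] += 1.0
        Fh[..., 1, 1] += 1.0
        E = 0.5 * (np.einsum("sgki,sgkj->sgij", Fh, Fh)
                   - np.eye(2))
        e = np.stack([E[..., 0, 0], E[..., 1, 1], 2.0 * E[..., 0, 1]], axis=-1)
        return Fh, e

    def _Bm(self, Fh: np.ndarray) -> np.ndarray:
        """(S, g, 3, 4, 3) local-translation membrane B matrix."""
        S, g = Fh.shape[:2]
        B = np.empty((S, g, 3, 4, 3))
        B[:, :, 0] = self.dNdx[..., 0:1] * Fh[:, :, None, :, 0]
        B[:, :, 1] = self.dNdx[..., 1:2] * Fh[:, :, None, :, 1]
        B[:, :, 2] = (self.dNdx[..., 1:2] * Fh[:, :, None, :, 0]
                      + self.dNdx[..., 0:1] * Fh[:, :, None, :, 1])
        return B

    # -- public ------------------------------------------------------------
    def energy(self, nodes_unused, u: np.ndarray,
               r: Optional[np.ndarray] = None,
               state: Optional[tuple] = None) -> float:
        """Elastic strain energy (valid while no plasticity has occurred)."""
        ul, rl = self._local_disp(u, r)
        _, e = self._membrane_strain(ul)
        if state is not None:
            e = e - state[0]
        w = 0.5 * np.einsum("sgI,IJ,sgJ->sg", e, self.C, e)
        total = (w * self.detJ * self.t[:, None]).sum()
        if self.mode == "shell":
            q = np.concatenate([ul, rl], axis=2)  # (S,4,6) -> local dof order
            q = q.reshape(-1, 24)
            total += 0.5 * np.einsum("si,sij,sj->", q, self.K_plate, q)
        return float(total)

    def force_and_tangent(self, u: np.ndarray, r: Optional[np.ndarray],
                          state: Optional[tuple] = None,
                          need_tangent: bool = True):
        """Returns (f, Km, Kg, new_state, von_mises) in GLOBAL components.

        ``state`` is (plastic strain (S,g,3), alpha (S,g)) or None;
        element dof order: node-major, (ux,uy,uz[,rx,ry,rz]) per node.
        """
        S = self.conn.shape[0]
        nd = self.n_eldof
        ul, rl = self._local_disp(u, r)
        Fh, e = self._membrane_strain(ul)
        Bm = self._Bm(Fh)                                     # (S,g,3,4,3)

        if self.plastic is not None and state is not None:
            ep, al = state
            flat_e = e.reshape(-1, 3)
            sig, ep_new, al_new, Dalg = self.plastic.map(
                flat_e, ep.reshape(-1, 3), al.reshape(-1),
                need_tangent=need_tangent)
            sig = sig.reshape(S, -1, 3)
            new_state = (ep_new.reshape(ep.shape), al_new.reshape(al.shape))
            D = Dalg.reshape(S, -1, 3, 3) if need_tangent else None
            vm = self.plastic.von_mises(sig.reshape(-1, 3)).reshape(S, -1)
        else:
            sig = np.einsum("IJ,sgJ->sgI", self.C, e)
            new_state = state
            D = None
            vm = np.sqrt(np.maximum(
                sig[..., 0] ** 2 - sig[..., 0] * sig[..., 1]
                + sig[..., 1] ** 2 + 3 * sig[..., 2] ** 2, 0.0))

        wt = self.detJ * self.t[:, None]                      # (S,g)
        f_m = np.einsum("sgIai,sgI,sg->sai", Bm, sig, wt)     # (S,4,3) local
        if need_tangent:
            if D is None:
                Km_m = np.einsum("sgIai,IJ,sgJbj,sg->saibj", Bm, self.C, Bm, wt, optimize=True)
            else:
                Km_m = np.einsum("sgIai,sgIJ,sgJbj,sg->saibj", Bm, D, Bm, wt, optimize=True)
            Sm = np.empty(sig.shape[:-1] + (2, 2))
            Sm[..., 0, 0] = sig[..., 0]
            Sm[..., 1, 1] = sig[..., 1]
            Sm[..., 0, 1] = Sm[..., 1, 0] = sig[..., 2]
            if self.linear_kinematics:
                H = np.zeros((S, 4, 4))
            else:
                H = np.einsum("sgac,sgcd,sgbd,sg->sab", self.dNdx, Sm,
                              self.dNdx, wt)
        # scatter membrane (local translations) into element dof order, then
        # add plate part, then rotate to global
        npn = nd // 4
        f_loc = np.zeros((S, 4, npn))
        f_loc[:, :, :3] = f_m
        if self.mode == "shell":
            q = np.concatenate([ul, rl], axis=2).reshape(S, 24)
            f_loc = f_loc.reshape(S, 24) + np.einsum(
                "sij,sj->si", self.K_plate, q)
        else:
            f_loc = f_loc.reshape(S, nd)

        Km = Kg = None
        if need_tangent:
            Km = np.zeros((S, nd, nd))
            tr = (np.arange(4)[:, None] * npn + np.arange(3)).ravel()
            Km[np.ix_(np.arange(S), tr, tr)] = \
                Km_m.reshape(S, 12, 12)
            if self.mode == "shell":
                Km += self.K_plate
            Kg = np.zeros((S, nd, nd))
            for i in range(3):
                idx = np.arange(4) * npn + i
                Kg[np.ix_(np.arange(S), idx, idx)] = H

        # rotate to global: block diag of R per 3-vector
        T = np.zeros((S, nd, nd))
        for blk in range(nd // 3):
            T[:, blk * 3:blk * 3 + 3, blk * 3:blk * 3 + 3] = self.R
        f_g = np.einsum("sji,sj->si", T, f_loc)
        if need_tangent:
            Km = np.einsum("sji,sjk,skl->sil", T, Km, T, optimize=True)
            Kg = np.einsum("sji,sjk,skl->sil", T, Kg, T, optimize=True)
        return f_g, Km, Kg, new_state, vm

    def fresh_state(self):
        if self.plastic is None:
            return None
        S = self.conn.shape[0]
        return (np.zeros((S, 4, 3)), np.zeros((S, 4)))

    def fibre_angle_check(self) -> np.ndarray:
        """Angle [deg] between local e1 (circumferential) and the horizontal
        plane, per element: ~0 means the frame is aligned with the disc
        mid-plane circumference as intended."""
        return np.rad2deg(np.arcsin(np.abs(self.R[:, 0, 2])))


def shell_stiffness_and_force(element_nodes: np.ndarray, thickness: float,
                              C_ps: np.ndarray, displacements: np.ndarray,
                              rotations: Optional[np.ndarray] = None,
                              mode: str = "shell",
                              transverse_G: float = 1000.0):
    """Single-element convenience wrapper; returns (K, f) in global dofs."""
    X = np.asarray(element_nodes, float).reshape(4, 3)
    blk = ShellBlock(X, np.arange(4)[None, :], thickness, C_ps, mode=mode,
                     transverse_G=transverse_G)
    u = np.asarray(displacements, float).reshape(4, 3)
    r = np.zeros((4, 3)) if rotations is None else \
        np.asarray(rotations, float).reshape(4, 3)
    f, Km, Kg, _, _ = blk.force_and_tangent(u, r if mode == "shell" else None)
    return (Km + Kg)[0], f[0]
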