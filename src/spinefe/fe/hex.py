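"""8-node hexahedra, total-Lagrangian, vectorized over an element block.

Kinematics: Green-Lagrange strain E = (F^T F - I)/2; 2nd Piola-Kirchhoff
stress; 2x2x2 Gauss quadrature.  Three material routes:

* ``svk``: St. Venant-Kirchhoff with an arbitrary 6x6 stiffness (orthotropic
  bone, moderately compressible isotropic tissues).
* ``neo_hookean``: W = C10 (I1_bar - 3) + (1/D)(J - 1)^2 (annulus ground
  substance).
* ``nh_bbar``: near-incompressible isotropic cards (nu >= 0.45, the nucleus)
  as a compressible Neo-Hookean with the card's small-strain moduli and the
  volumetric energy at the element-mean dilatation (mean-dilatation B-bar):
  robust at finite strain and free of the volumetric locking a trilinear
  hex otherwise shows at nu -> 0.5.

Every force routine is the exact gradient of the element strain energy
(checked against central finite differences in the test-suite), and the
geometric (initial-stress) tangent is kept separate from the material one
so linearized buckling can combine them.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from ..materials import IsotropicElastic, NeoHookean, OrthotropicElastic

__all__ = ["HexBlock", "hex_stiffness_and_force"]

_G = 1.0 / np.sqrt(3.0)
_CORNERS = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                     [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], float)
_GP = np.array([[sx * _G, sy * _G, sz * _G]
                for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)])
_VOIGT = [(0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (0, 2)]
_M_VOL = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])

# nu above which the volumetric term of an isotropic SVK card is integrated
# with the element mean (B-bar); harmless but unnecessary below it
_SRI_NU_THRESHOLD = 0.45


def _dN(xi: np.ndarray) -> np.ndarray:
    xi = np.atleast_2d(xi)
    out = np.empty((xi.shape[0], 8, 3))
    for a in range(8):
        cx, cy, cz = _CORNERS[a]
        out[:, a, 0] = cx * (1 + cy * xi[:, 1]) * (1 + cz * xi[:, 2]) / 8
        out[:, a, 1] = cy * (1 + cx * xi[:, 0]) * (1 + cz * xi[:, 2]) / 8
        out[:, a, 2] = cz * (1 + cx * xi[:, 0]) * (1 + cy * xi[:, 1]) / 8
    return out


_DN = _dN(_GP)  # (8 gp, 8 node, 3)


def _tensor_to_voigt66(Ct: np.ndarray) -> np.ndarray:
    """(..., 3,3,3,3) minor-symmetric tensor -> (...,6,6) Voigt (eng. shear)."""
    out = np.empty(Ct.shape[:-4] + (6, 6))
    for I, (i, j) in enumerate(_VOIGT):
        for J, (k, l) in enumerate(_VOIGT):
            out[..., I, J] = Ct[..., i, j, k, l]
    return out


class HexBlock:
    """A batch of hexahedra sharing one constitutive card."""

    def __init__(self, nodes: np.ndarray, conn: np.ndarray, card,
                 name: str = "solid"):
        self.conn = np.asarray(conn, int)
        self.name = name
        self.card = card
        X = nodes[self.conn]                                   # (E,8,3)
        J = np.einsum("eai,gaj->egji", X, _DN)                 # (E,g,3,3)
        self.detJ = np.linalg.det(J)
        if self.detJ.min() <= 0:
            raise ValueError(f"non-positive jacobian in block {name!r}")
        Jinv = np.linalg.inv(J)
        # dN_a/dX_j = dN_a/dxi_k * dxi_k/dX_j, with dxi_k/dX_j = Jinv[j, k]
        self.G = np.einsum("gak,egjk->egaj", _DN, Jinv)        # dN/dX (E,g,8,3)
        self.vol = self.detJ.sum(axis=1)                        # (E,)

        if isinstance(card, NeoHookean):
            self.kind = "neo_hookean"
        elif isinstance(card, IsotropicElastic):
            if card.nu >= _SRI_NU_THRESHOLD:
                # near-incompressible tissue: St. Venant-Kirchhoff is not
                # robust at the finite strains the discs reach, so the card
                # is realized as a compressible Neo-Hookean with the same
                # small-strain moduli, volumetric term at the element-mean
                # dilatation (B-bar) to avoid locking
                self.kind = "nh_bbar"
                self.mu_iso = card.shear_modulus
                self.K_bulk = card.bulk_modulus
            else:
                self.kind = "svk"
                self.C_dev = card.stiffness()
                self.K_bulk = 0.0
        elif isinstance(card, OrthotropicElastic):
            self.kind = "svk"
            self.C_dev = card.stiffness()
            self.K_bulk = 0.0
        else:
            raise TypeError(f"unsupported solid card {type(card).__name__}")

    # -- kinematics --------------------------------------------------------
    def _deformation(self, u: np.ndarray):
        ue = u[self.conn]                                      # (E,8,3)
        grad = np.einsum("eai,egaj->egij", ue, self.G)
        F = grad + np.eye(3)
        E = 0.5 * (np.einsum("egki,egkj->egij", F, F) - np.eye(3))
        return F, E

    @staticmethod
    def _voigt_strain(E: np.ndarray) -> np.ndarray:
        e = np.empty(E.shape[:-2] + (6,))
        for I, (i, j) in enumerate(_VOIGT):
            e[..., I] = E[..., i, j] * (1.0 if i == j else 2.0)
        return e

    def _B(self, F: np.ndarray) -> np.ndarray:
        """delta(E_voigt) = B delta(u): (E,g,6,24)."""
        Ne, ng = F.shape[:2]
        B = np.empty((Ne, ng, 6, 8, 3))
        for I, (j, k) in enumerate(_VOIGT):
            if j == k:
                B[:, :, I] = self.G[..., j:j + 1] * F[:, :, None, :, j]
            else:
                B[:, :, I] = (self.G[..., k:k + 1] * F[:, :, None, :, j]
                              + self.G[..., j:j + 1] * F[:, :, None, :, k])
        return B.reshape(Ne, ng, 6, 24)

    # -- constitutive ------------------------------------------------------
    def _svk_stress(self, e: np.ndarray):
        """Voigt PK2 stress; with B-bar the bulk part uses the mean trace."""
        S = np.einsum("IJ,egJ->egI", self.C_dev, e)
        trEbar = None
        if self.K_bulk:
            trE = e[..., :3].sum(axis=-1)
            trEbar = (trE * self.detJ).sum(axis=1) / self.vol   # (E,)
            S += self.K_bulk * trEbar[:, None, None] * _M_VOL
        return S, trEbar

    def _nh_stress_tangent(self, F: np.ndarray, need_tangent: bool):
        card: NeoHookean = self.card
        mu, k = card.mu0, 2.0 / card.D
        C = np.einsum("egki,egkj->egij", F, F)
        invC = np.linalg.inv(C)
        J2 = np.linalg.det(C)
        J = np.sqrt(J2)
        I1 = np.trace(C, axis1=-2, axis2=-1)
        Jm23 = J ** (-2.0 / 3.0)
        S = (mu * Jm23[..., None, None]
             * (np.eye(3) - (I1 / 3.0)[..., None, None] * invC)
             + (k * (J - 1.0) * J)[..., None, None] * invC)
        D = None
        if need_tangent:
            II = np.einsum("egij,egkl->egijkl", invC, invC)
            IC = np.einsum("ij,egkl->egijkl", np.eye(3), invC)
            CI = np.einsum("egij,kl->egijkl", invC, np.eye(3))
            sym = 0.5 * (np.einsum("egik,egjl->egijkl", invC, invC)
                         + np.einsum("egil,egjk->egijkl", invC, invC))
            a = (2.0 * mu * Jm23)
            Ct = (a[..., None, None, None, None]
                  * ((I1 / 9.0)[..., None, None, None, None] * II
                     - (IC + CI) / 3.0
                     + (I1 / 3.0)[..., None, None, None, None] * sym)
                  + k * ((2 * J - 1) * J)[..., None, None, None, None] * II
                  - k * (2 * (J2 - J))[..., None, None, None, None] * sym)
            D = _tensor_to_voigt66(Ct)
        return S, D

    def _nh_bbar_terms(self, F: np.ndarray, need_tangent: bool):
        """Stress/tangent of the near-incompressible Neo-Hookean route.

        Deviatoric part per gauss point; volumetric pressure from the
        element-mean dilatation Jbar (mean-dilatation B-bar).  Returns
        (S_voigt, D_voigt or None, bJ_voigt, p) where bJ = J C^-1 is the
        volumetric strain row (dJ = bJ : dE in engineering Voigt).
        """
        mu, K = self.mu_iso, self.K_bulk
        C = np.einsum("egki,egkj->egij", F, F)
        invC = np.linalg.inv(C)
        J = np.sqrt(np.linalg.det(C))
        I1 = np.trace(C, axis1=-2, axis2=-1)
        Jm23 = J ** (-2.0 / 3.0)
        Jbar = (J * self.detJ).sum(axis=1) / self.vol          # (E,)
        p = K * (Jbar - 1.0)                                   # (E,)
        S_t = (mu * Jm23[..., None, None]
               * (np.eye(3) - (I1 / 3.0)[..., None, None] * invC)
               + (p[:, None] * J)[..., None, None] * invC)
        S = np.empty(S_t.shape[:-2] + (6,))
        bJ = np.empty_like(S)
        for I, (i, j) in enumerate(_VOIGT):
            S[..., I] = S_t[..., i, j]
            bJ[..., I] = J * invC[..., i, j]
        D = None
        if need_tangent:
            II = np.einsum("egij,egkl->egijkl", invC, invC)
            IC = np.einsum("ij,egkl->egijkl", np.eye(3), invC)
            CI = np.einsum("egij,kl->egijkl", invC, np.eye(3))
            sym = 0.5 * (np.einsum("egik,egjl->egijkl", invC, invC)
                         + np.einsum("egil,egjk->egijkl", invC, invC))
            a = 2.0 * mu * Jm23
            Ct = (a[..., None, None, None, None]
                  * ((I1 / 9.0)[..., None, None, None, None] * II
                     - (IC + CI) / 3.0
                     + (I1 / 3.0)[..., None, None, None, None] * sym)
                  + (p[:, None] * J)[..., None, None, None, None]
                  * (II - 2.0 * sym))
            D = _tensor_to_voigt66(Ct)
        return S, D, bJ, p

    # -- public API --------------------------------------------------------
    def energy(self, u: np.ndarray) -> float:
        F, E = self._deformation(u)
        if self.kind == "nh_bbar":
            C = np.einsum("egki,egkj->egij", F, F)
            J = np.sqrt(np.linalg.det(C))
            I1 = np.trace(C, axis1=-2, axis2=-1)
            Wdev = 0.5 * self.mu_iso * (J ** (-2.0 / 3.0) * I1 - 3.0)
            Jbar = (J * self.detJ).sum(axis=1) / self.vol
            return float((Wdev * self.detJ).sum()
                         + (0.5 * self.K_bulk * (Jbar - 1.0) ** 2
                            * self.vol).sum())
        if self.kind == "svk":
            e = self._voigt_strain(E)
            w = 0.5 * np.einsum("egI,IJ,egJ->eg", e, self.C_dev, e)
            total = (w * self.detJ).sum()
            if self.K_bulk:
                trE = e[..., :3].sum(axis=-1)
                trEbar = (trE * self.detJ).sum(axis=1) / self.vol
                total += (0.5 * self.K_bulk * trEbar ** 2 * self.vol).sum()
            return float(total)
        card: NeoHookean = self.card
        C = np.einsum("egki,egkj->egij", F, F)
        J = np.sqrt(np.linalg.det(C))
        I1 = np.trace(C, axis1=-2, axis2=-1)
        W = card.C10 * (J ** (-2.0 / 3.0) * I1 - 3.0) \
            + (1.0 / card.D) * (J - 1.0) ** 2
        return float((W * self.detJ).sum())

    def force_and_tangent(self, u: np.ndarray, need_tangent: bool = True
                          ) -> Tuple[np.ndarray, Optional[np.ndarray],
                                     Optional[np.ndarray]]:
        """Internal force (E,24) and material/geometric tangents (E,24,24)."""
        F, E = self._deformation(u)
        B = self._B(F)
        bJ = None
        if self.kind == "svk":
            e = self._voigt_strain(E)
            S, _ = self._svk_stress(e)
            D = None
        elif self.kind == "nh_bbar":
            S, D, bJ, _ = self._nh_bbar_terms(F, need_tangent)
        else:
            S_t, D = self._nh_stress_tangent(F, need_tangent)
            S = np.empty(S_t.shape[:-2] + (6,))
            for I, (i, j) in enumerate(_VOIGT):
                S[..., I] = S_t[..., i, j]

        wd = self.detJ
        f = np.einsum("egIa,egI,eg->ea", B, S, wd, optimize=True)
        if not need_tangent:
            return f, None, None

        if self.kind == "svk":
            Km = np.einsum("egIa,IJ,egJb,eg->eab", B, self.C_dev, B, wd,
                           optimize=True)
        else:
            Km = np.einsum("egIa,egIJ,egJb,eg->eab", B, D, B, wd,
                           optimize=True)
            if self.kind == "nh_bbar":
                ghat = np.einsum("egIa,egI,eg->ea", B, bJ, wd,
                                 optimize=True)
                Km += (self.K_bulk / self.vol)[:, None, None] \
                    * np.einsum("ea,eb->eab", ghat, ghat)

        # geometric (initial-stress) part: S contracted with shape gradients
        S_t = np.empty(S.shape[:-1] + (3, 3))
        for I, (i, j) in enumerate(_VOIGT):
            S_t[..., i, j] = S[..., I]
            S_t[..., j, i] = S[..., I]
        H = np.einsum("egaj,egjk,egbk,eg->eab", self.G, S_t, self.G, wd,
                      optimize=True)
        Kg = np.zeros_like(Km)
        for i in range(3):
            Kg[:, i::3, i::3] = H
        return f, Km, Kg

    def stress_voigt(self, u: np.ndarray) -> np.ndarray:
        """PK2 stress per element/gauss point, Voigt (E,g,6)."""
        F, E = self._deformation(u)
        if self.kind == "svk":
            S, _ = self._svk_stress(self._voigt_strain(E))
            return S
        if self.kind == "nh_bbar":
            S, _, _, _ = self._nh_bbar_terms(F, False)
            return S
        S_t, _ = self._nh_stress_tangent(F, False)
        S = np.empty(S_t.shape[:-2] + (6,))
        for I, (i, j) in enumerate(_VOIGT):
            S[..., I] = S_t[..., i, j]
        return S

    def von_mises(self, u: np.ndarray) -> np.ndarray:
        """von Mises equivalent of the (PK2) stress, (E, g)."""
        S = self.stress_voigt(u)
        s11, s22, s33, s12, s23, s13 = (S[..., i] for i in range(6))
        return np.sqrt(0.5 * ((s11 - s22) ** 2 + (s22 - s33) ** 2
                              + (s33 - s11) ** 2)
                       + 3.0 * (s12 ** 2 + s23 ** 2 + s13 ** 2))


def hex_stiffness_and_force(element_nodes: np.ndarray, card,
                            displacements: np.ndarray
                            ) -> Tuple[np.ndarray, np.ndarray]:
    """Single-element convenience kernel.

    Returns the 24x24 consistent tangent (material + geometric) and the
    24-vector internal force for one hex at the given nodal displacements.
    """
    X = np.asarray(element_nodes, float).reshape(8, 3)
    u = np.asarray(displacements, float).reshape(8, 3)
    blk = HexBlock(X, np.arange(8)[None, :], card)
    f, Km, Kg = blk.force_and_tangent(u)
    return (Km + Kg)[0], f[0]
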