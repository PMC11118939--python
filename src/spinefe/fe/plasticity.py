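"""von Mises return mapping: 3-D radial return and plane-stress (shell) form.

The cortical shell yields at 64 MPa with linear isotropic hardening.  The
membrane stress state of a shell is plane stress, so the shell kernel uses
the plane-stress projected return (Simo-style: solve a scalar consistency
equation for the plastic multiplier with the full anisotropic elastic
operator); the classical 3-D radial return is exposed for general use.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from ..materials import PlasticityCard

__all__ = ["return_map_von_mises", "PlaneStressReturn", "von_mises_voigt"]

#: plane-stress von Mises flow matrix (s^T P s = (2/3) vm^2)
_P = np.array([[2.0, -1.0, 0.0], [-1.0, 2.0, 0.0], [0.0, 0.0, 6.0]]) / 3.0


def von_mises_voigt(stress: np.ndarray) -> np.ndarray:
    """von Mises equivalent of a Voigt-6 stress (11,22,33,12,23,13)."""
    s = np.asarray(stress, float)
    s11, s22, s33, s12, s23, s13 = (s[..., i] for i in range(6))
    return np.sqrt(0.5 * ((s11 - s22) ** 2 + (s22 - s33) ** 2
                          + (s33 - s11) ** 2)
                   + 3.0 * (s12 ** 2 + s23 ** 2 + s13 ** 2))


def return_map_von_mises(trial_stress: np.ndarray, card: PlasticityCard,
                         eq_plastic: float, shear_modulus: float = 3000.0
                         ) -> Tuple[np.ndarray, float]:
    """Radial return of a 3-D Voigt trial stress onto the hardened surface.

    Returns the mapped stress and the updated equivalent plastic strain.
    The elastic trial state is accepted unchanged when its von Mises
    equivalent does not exceed the current yield stress.
    """
    s = np.asarray(trial_stress, float)
    if s.shape[-1] != 6:
        raise ValueError("trial stress must be Voigt-6")
    q = float(von_mises_voigt(s))
    y = card.yield_stress + card.hardening_modulus * eq_plastic
    if q <= y + 1e-12 * max(y, 1.0):
        return s.copy(), float(eq_plastic)
    G, H = shear_modulus, card.hardening_modulus
    dgamma = (q - y) / (3.0 * G + H)
    p = s[..., :3].mean()
    dev = s.copy()
    dev[..., :3] -= p
    scale = 1.0 - 3.0 * G * dgamma / q
    out = dev * scale
    out[..., :3] += p
    return out, float(eq_plastic + dgamma)


class PlaneStressReturn:
    """Vectorized plane-stress von Mises return with general elastic C.

    Works in the engineering Voigt triplet (e11, e22, gamma12) /
    (s11, s22, s12).  Consistency g(dl) = q(sigma(dl))^2/2 - y^2/3 = 0 is
    solved by bracketed bisection on each active point (robust for the
    anisotropic elastic operator of the cortical shell, where the classic
    isotropic closed form does not apply).
    """

    def __init__(self, C: np.ndarray, card: PlasticityCard):
        self.C = np.asarray(C, float)
        self.card = card

    def _solve(self, e_el_tr: np.ndarray, alpha: np.ndarray):
        """Map elastic trial strains -> (stress, dlambda, new alpha)."""
        C, y0, H = self.C, self.card.yield_stress, self.card.hardening_modulus
        s_tr = e_el_tr @ C.T
        n = s_tr.shape[0]
        dl = np.zeros(n)
        q2_tr = 1.5 * np.einsum("ni,ij,nj->n", s_tr, _P, s_tr)  # vm^2
        y_cur = y0 + H * alpha
        active = q2_tr > y_cur ** 2 * (1.0 + 1e-12)
        s_out = s_tr.copy()
        alpha_out = alpha.astype(float).copy()
        if not active.any():
            return s_out, dl, alpha_out
        st = s_tr[active]
        al = alpha[active]

        CP = C @ _P

        def g(d):
            M = np.eye(3) + d[:, None, None] * CP
            sig = np.linalg.solve(M, st[..., None])[..., 0]
            pPp = np.einsum("ni,ij,nj->n", sig, _P, sig)   # = (2/3) vm^2
            dalpha = d * np.sqrt(2.0 * np.maximum(pPp, 0.0) / 3.0)
            y = y0 + H * (al + dalpha)
            return 0.5 * pPp - y ** 2 / 3.0, sig, dalpha

        lo = np.zeros(st.shape[0])
        hi = np.full(st.shape[0], 1e-8)
        for _ in range(80):
            val, _, _ = g(hi)
            grow = val > 0
            if not grow.any():
                break
            hi[grow] *= 4.0
        for _ in range(70):
            mid = 0.5 * (lo + hi)
            val, _, _ = g(mid)
            pos = val > 0
            lo[pos] = mid[pos]
            hi[~pos] = mid[~pos]
        d = 0.5 * (lo + hi)
        _, sig, dalpha = g(d)
        s_out[active] = sig
        alpha_out[active] = al + dalpha
        dl[active] = d
        return s_out, dl, alpha_out

    def map(self, e_total: np.ndarray, e_plastic: np.ndarray,
            alpha: np.ndarray, need_tangent: bool = True):
        """Return (stress, new plastic strain, new alpha, algorithmic D)."""
        e_total = np.atleast_2d(e_total)
        e_plastic = np.atleast_2d(e_plastic)
        alpha = np.atleast_1d(alpha)
        e_tr = e_total - e_plastic
        s, dl, al = self._solve(e_tr, alpha)
        ep_new = e_plastic + dl[:, None] * (s @ _P.T)
        D = None
        if need_tangent:
            D = np.broadcast_to(self.C, (e_total.shape[0], 3, 3)).copy()
            act = dl > 0
            if act.any():
                Da = np.empty((int(act.sum()), 3, 3))
                e_act, a_act = e_tr[act], alpha[act]
                eps = 1e-7
                for j in range(3):
                    de = np.zeros(3)
                    de[j] = eps
                    sp, _, _ = self._solve(e_act + de, a_act)
                    sm, _, _ = self._solve(e_act - de, a_act)
                    Da[:, :, j] = (sp - sm) / (2 * eps)
                D[act] = 0.5 * (Da + np.transpose(Da, (0, 2, 1)))
        return s, ep_new, al, D

    def von_mises(self, stress: np.ndarray) -> np.ndarray:
        s = np.atleast_2d(stress)
        return np.sqrt(np.maximum(
            1.5 * np.einsum("ni,ij,nj->n", s, _P, s), 0.0))
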