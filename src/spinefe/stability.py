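"""Stability analysis: plastic onset, bifurcation at a probe point,
linearized buckling, and failure-mode classification.

The bifurcation detector is numeric: the lateral displacement u_x at a
probe node on the L3 cortical wall grows essentially proportionally with
pseudo-time while the response is stable; the first increment at which
the incremental rate du_x/dt changes sign or jumps by a configurable
factor (default 10x) relative to the initial secant marks the critical
state.  Post-buckling is classified unstable when the lateral excursion
subsequently shrinks while the axial force plateaus or drops.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .solver import SolutionHistory

__all__ = ["PlasticOnset", "BifurcationResult", "BucklingMode",
           "detect_plastic_onset", "detect_bifurcation",
           "linearized_buckling", "classify_failure"]


@dataclass(frozen=True)
class PlasticOnset:
    """First appearance of plastic strain in the cortical shell."""

    t_bar_pl: float
    F_pl: float                  # [kN]
    sigma_pl: float              # max cortical von Mises at onset [MPa]


@dataclass(frozen=True)
class BifurcationResult:
    """First departure of the probe response from proportional growth."""

    t_bar_cr: float
    F_cr: float                  # [kN]
    u_x_cr: float                # lateral probe displacement [mm]
    post_buckling: str           # "stable" | "unstable"


@dataclass(frozen=True)
class BucklingMode:
    """One linearized buckling mode: load multiplier + normalized shape."""

    lam: float
    mode_shape: np.ndarray


def detect_plastic_onset(history: SolutionHistory,
                         threshold: float = 1e-8) -> Optional[PlasticOnset]:
    """First increment with equivalent plastic strain above threshold.

    Returns None for a purely elastic history.
    """
    if len(history.states) < 2:
        raise ValueError("history needs at least two increments")
    for s in history.states[1:]:
        if s.max_eq_plastic > threshold:
            return PlasticOnset(t_bar_pl=s.t_bar, F_pl=s.reaction,
                                sigma_pl=s.max_vm_cortical)
    return None


def detect_bifurcation(history: SolutionHistory, probe: int,
                       jump_factor: float = 10.0,
                       force_slope_tol: float = 0.02,
                       min_amplitude: float = 0.02
                       ) -> Optional[BifurcationResult]:
    """Detect loss of proportionality of the lateral probe response.

    ``probe`` is a node id; its x-displacement is examined.  Returns None
    when u_x grows proportionally throughout (no bifurcation).
    ``min_amplitude`` [mm] guards against firing on sub-resolution probe
    noise: the lateral excursion at the candidate critical state must be
    mechanically visible (published critical displacements are ~0.05 mm).
    """
    t = history.t_bar
    if len(t) < 3:
        return None
    ux = history.probe_displacement(probe)[:, 0]
    F = history.reactions
    dt = np.diff(t)
    rate = np.diff(ux) / dt
    # initial secant rate over the first fifth of the loading
    n0 = max(1, len(rate) // 5)
    r0 = rate[:n0].mean()
    scale = max(abs(r0), np.abs(ux).max() / max(t[-1], 1e-9) * 1e-2, 1e-12)
    crit = None
    for i in range(n0, len(rate)):
        jump = abs(rate[i]) / scale
        sign_change = rate[i] * r0 < 0 and abs(rate[i]) > 0.5 * scale
        visible = abs(ux[i + 1] - ux[0]) >= min_amplitude
        if (jump >= jump_factor or sign_change) and visible:
            crit = i + 1                       # state index of the increment
            break
    if crit is None:
        return None
    # interpolate the threshold crossing between interval midpoints so the
    # detected critical state is insensitive to the increment count
    t_mid = 0.5 * (t[:-1] + t[1:])
    if crit - 1 > n0 and abs(rate[crit - 1]) > abs(rate[crit - 2]):
        y0, y1 = abs(rate[crit - 2]), abs(rate[crit - 1])
        target = jump_factor * scale
        w = np.clip((target - y0) / max(y1 - y0, 1e-30), 0.0, 1.0)
        t_star = t_mid[crit - 2] + w * (t_mid[crit - 1] - t_mid[crit - 2])
    else:
        t_star = t_mid[crit - 1]
    t_star = min(max(t_star, t[1]), t[-1])
    F_star = float(np.interp(t_star, t, F))
    ux_star = float(np.interp(t_star, t, ux))
    post = "stable"
    tail_ux = np.abs(ux[crit:])
    tail_F = F[crit:]
    if len(tail_ux) >= 2:
        shrinking = tail_ux[-1] < tail_ux[0] * (1 - 1e-9)
        dF = np.diff(tail_F)
        flat_or_drop = (dF <= force_slope_tol * max(F.max(), 1e-9)).all()
        if shrinking and flat_or_drop:
            post = "unstable"
    return BifurcationResult(t_bar_cr=float(t_star), F_cr=F_star,
                             u_x_cr=ux_star, post_buckling=post)


def linearized_buckling(K_e_ref: sp.spmatrix, K_sigma_ref: sp.spmatrix,
                        k: int = 4) -> List[BucklingMode]:
    """Smallest positive load multipliers of K_e + lambda K_sigma.

    ``K_e_ref`` must be positive definite (stable reference state); the
    critical load estimate is lambda times the reference load.
    """
    n = K_e_ref.shape[0]
    # no row pivoting (stable for SPD K_e): the U diagonal then carries the
    # true pivot signs, giving a cheap definiteness probe
    lu = spla.splu(K_e_ref.tocsc(), permc_spec="COLAMD",
                   diag_pivot_thresh=0.0,
                   options={"SymmetricMode": True})
    dU = lu.U.diagonal()
    if np.any(dU <= 0):
        raise ValueError("reference elastic stiffness is not positive "
                         "definite (rigid mode or post-critical state)")

    def mv(x):
        return lu.solve(-(K_sigma_ref @ x))

    op = spla.LinearOperator((n, n), matvec=mv)
    kk = min(k + 2, n - 2)
    vals, vecs = spla.eigs(op, k=kk, which="LM")
    vals = np.real(vals)
    vecs = np.real(vecs)
    modes = []
    for i in np.argsort(-vals):
        if vals[i] <= 1e-12:
            continue
        lam = 1.0 / vals[i]
        shape = vecs[:, i]
        shape = shape / np.abs(shape).max()
        modes.append(BucklingMode(lam=float(lam), mode_shape=shape))
        if len(modes) >= k:
            break
    return modes


def classify_failure(history: SolutionHistory,
                     onset: Optional[PlasticOnset],
                     bifurcation: Optional[BifurcationResult]) -> str:
    """One of 'plasticity-limited', 'buckling-limited', 'mixed',
    'elastic-stable'."""
    if onset is None and bifurcation is None:
        return "elastic-stable"
    if onset is None:
        return "buckling-limited"
    if bifurcation is None:
        return "plasticity-limited"
    F = history.reactions
    t = history.t_bar
    t_first = min(onset.t_bar_pl, bifurcation.t_bar_cr)
    after = F[t >= t_first]
    rising = len(after) >= 2 and after[-1] > after[0] * (1 + 1e-9)
    if onset.t_bar_pl < bifurcation.t_bar_cr and rising:
        return "mixed"
    if bifurcation.t_bar_cr <= onset.t_bar_pl:
        return "buckling-limited"
    return "mixed" if rising else "plasticity-limited"
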