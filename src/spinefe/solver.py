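"""Quasi-static geometrically nonlinear solution under displacement control.

Newton-Raphson per pseudo-time increment with adaptive factorization reuse
(the sparse LU from a previous iteration/increment is retained while
convergence is healthy) and increment bisection (up to 4 cuts) on failure.
A run that loses convergence after the cuts returns the partial history
with a failure flag - under displacement control that is itself a result:
the model can no longer statically carry the imposed shortening.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import scipy.sparse.linalg as spla

from .assembly import ConstraintSet, FEModel, LoadSchedule

__all__ = ["SolutionState", "SolutionHistory", "solve_quasi_static"]

log = logging.getLogger(__name__)

_PERMC = "COLAMD"


@dataclass
class SolutionState:
    """One converged increment."""

    t_bar: float
    u_node: np.ndarray               # nodal translations (N, 3) [mm]
    reaction: float                  # total axial reaction [kN]
    max_vm_cortical: float           # max cortical membrane von Mises [MPa]
    max_eq_plastic: float            # max equivalent plastic strain
    n_iter: int
    vm_by_set: Dict[str, float] = field(default_factory=dict)


@dataclass
class SolutionHistory:
    """Ordered converged states plus convergence diagnostics."""

    states: List[SolutionState] = field(default_factory=list)
    failed: bool = False
    t_bar_fail: Optional[float] = None
    u_owner_final: Optional[np.ndarray] = None
    wall_time: float = 0.0

    @property
    def t_bar(self) -> np.ndarray:
        return np.array([s.t_bar for s in self.states])

    @property
    def reactions(self) -> np.ndarray:
        return np.array([s.reaction for s in self.states])

    def probe_displacement(self, node: int) -> np.ndarray:
        return np.array([s.u_node[node] for s in self.states])

    def final_state(self) -> SolutionState:
        return self.states[-1]


class _Solver:
    def __init__(self, model: FEModel, tol_rel: float, tol_abs: float):
        self.model = model
        self.tol_rel = tol_rel
        self.tol_abs = tol_abs
        self.lu = None
        self.lu_good = None          # tangent at the last committed state
        self.n_factor = 0

    def factorize(self, K):
        self.lu = spla.splu(K.tocsc(), permc_spec=_PERMC)
        self.n_factor += 1

    def _lin_solve(self, K, b: np.ndarray) -> np.ndarray:
        """Solve K du = b with the retained LU as preconditioner.

        With ``K=None`` the (possibly stale) LU is applied directly.  When
        the preconditioned GMRES needs many iterations the LU is refreshed
        from K, so the expensive factorization happens only when the
        tangent has drifted far from the factored one.
        """
        if K is None:
            return self.lu.solve(b)
        count = [0]

        def cb(_):
            count[0] += 1

        M = spla.LinearOperator(K.shape, matvec=self.lu.solve)
        x, info = spla.gmres(K, b, M=M, rtol=1e-3, atol=0.0,
                             restart=50, maxiter=50, callback=cb,
                             callback_type="pr_norm")
        if info != 0 or not np.all(np.isfinite(x)):
            self.factorize(K)
            return self.lu.solve(b)
        if count[0] > 20:
            self.factorize(K)
        return x

    def newton(self, u_owner: np.ndarray, max_iter: int = 45):
        """Iterate on the free dofs; returns (u, ok, n_iter, diag, f).

        Inexact Newton: the consistent tangent is reassembled when progress
        is slow (cheap), linear solves are LU-preconditioned GMRES, and the
        LU is refactorized only when the Krylov solver reports the tangent
        has drifted.  The consistent tangent is skipped entirely while the
        trial plastic state is far from the committed one - the tangent at
        a wildly-plastic transient iterate destabilizes the iteration - and
        a backtracking line search rejects diverging steps.
        """
        m = self.model
        alpha_committed = m.committed_alpha_max()
        K_cur = None
        K_at = -10
        last_norm = np.inf
        f, _, _, diag = m.assemble(u_owner, need_tangent=False)
        for it in range(1, max_iter + 1):
            r = f[m.free_ids]
            rnorm = np.linalg.norm(r)
            scale = max(np.abs(f[m.driven_owner]).sum(),
                        np.abs(f[m.fixed_owner]).sum(), 1.0)
            if rnorm <= max(self.tol_abs, self.tol_rel * scale):
                return u_owner, True, it - 1, diag, f
            trustworthy = diag["max_eq_plastic"] <= alpha_committed + 0.02
            if trustworthy and (K_cur is None
                                or (rnorm > 0.25 * last_norm
                                    and it - K_at >= 2)):
                _, K_e, K_g, _ = m.assemble(u_owner, need_tangent=True)
                K_cur = (K_e + K_g).tocsr()
                K_at = it
            last_norm = rnorm
            du = self._lin_solve(K_cur, -r)
            if not np.all(np.isfinite(du)):
                return u_owner, False, it, diag, f
            # backtracking line search on the residual norm; reject steps
            # that blow the residual up (or produce non-finite states)
            best = None
            u_try = u_owner.copy()
            for ls in range(5):
                step = 0.5 ** ls
                u_try[m.free_ids] = u_owner[m.free_ids] + step * du
                f_t, _, _, d_t = m.assemble(u_try, need_tangent=False)
                rt = np.linalg.norm(f_t[m.free_ids])
                if not np.isfinite(rt):
                    continue
                if best is None or rt < best[0]:
                    best = (rt, u_try.copy(), f_t, d_t)
                if rt <= 1.2 * rnorm:
                    break
            if best is None or best[0] > 3.0 * rnorm:
                return u_owner, False, it, diag, f
            _, u_owner, f, diag = best
        return u_owner, False, max_iter, diag, f


def solve_quasi_static(model: FEModel,
                       schedule: LoadSchedule = LoadSchedule(),
                       constraints: Optional[ConstraintSet] = None,
                       tol_rel: float = 1e-6, tol_abs: float = 1e-8,
                       max_cuts: int = 4,
                       store_every: int = 1) -> SolutionHistory:
    """Drive the model through the displacement schedule.

    ``constraints`` defaults to the ones the model was built with.  Each
    scheduled increment may be bisected up to ``max_cuts`` times; a failed
    increment terminates the run with ``history.failed`` set and the last
    converged pseudo-time recorded.
    """
    if constraints is not None and constraints is not model.constraints:
        raise ValueError("model was assembled with different constraints")
    t0 = time.time()
    times = schedule.times()
    sol = _Solver(model, tol_rel, tol_abs)
    hist = SolutionHistory()
    nd = model.dofmap.ndof
    u = np.zeros(nd)

    def set_driven(uvec, tb):
        uvec[model.driven_owner] = -schedule.u_z_max * tb
        return uvec

    # record the reference state and factor the clean elastic tangent once
    f0, K_e0, K_g0, d0 = model.assemble(u, need_tangent=True)
    sol.factorize(K_e0 + K_g0)
    sol.lu_good = sol.lu
    hist.states.append(SolutionState(
        0.0, model.dofmap.translations(model.expand(u)), 0.0,
        d0["max_vm_cortical"], d0["max_eq_plastic"], 0, d0["vm_by_set"]))

    t_cur = 0.0
    u_prev, t_prev = None, None
    for k in range(1, len(times)):
        t_target = times[k]
        cuts = 0
        f = None
        while t_cur < t_target - 1e-12:
            dt = (t_target - t_cur) / (2 ** cuts)
            t_try = min(t_target, t_cur + dt)
            if u_prev is not None and t_cur > t_prev:
                # linear extrapolation of the last two converged states
                w = (t_try - t_cur) / (t_cur - t_prev)
                du_pred = u + w * (u - u_prev)
            elif t_cur > 0:
                # proportional predictor: scale the converged field so the
                # increment perturbation is small everywhere (not just a
                # jump at the driven surface)
                du_pred = u * (t_try / t_cur)
            else:
                # tangent predictor for the cold start: probe the elastic
                # response at a tiny driven displacement and scale it up,
                # so the first iterate is already near the linear solution
                eps = 1e-3 * t_try
                u_eps = u.copy()
                set_driven(u_eps, eps)
                f_eps, _, _, _ = model.assemble(u_eps, need_tangent=False)
                du_pred = u.copy()
                du_pred[model.free_ids] += sol.lu.solve(
                    -f_eps[model.free_ids]) * (t_try / eps)
            set_driven(du_pred, t_try)
            u_new, ok, n_iter, diag, f = sol.newton(du_pred)
            if ok:
                u_prev, t_prev = u, t_cur
                t_cur = t_try
                u = u_new
                model.commit_state()
                sol.lu_good = sol.lu
            else:
                cuts += 1
                model._trial = dict(model.state)
                sol.lu = sol.lu_good     # fall back to a trusted tangent
                if cuts > max_cuts:
                    hist.failed = True
                    hist.t_bar_fail = t_target
                    log.warning("increment to t=%.3f failed after %d cuts",
                                t_target, max_cuts)
                    hist.u_owner_final = u
                    hist.wall_time = time.time() - t0
                    return hist
        reaction = model.reaction_force(f)
        if k % store_every == 0 or k == len(times) - 1:
            hist.states.append(SolutionState(
                t_cur, model.dofmap.translations(model.expand(u)), reaction,
                diag["max_vm_cortical"], diag["max_eq_plastic"], n_iter,
                diag["vm_by_set"]))
        log.info("t=%.3f F=%.3f kN vm=%.1f MPa iters=%d factors=%d",
                 t_cur, reaction, diag["max_vm_cortical"], n_iter,
                 sol.n_factor)
    hist.u_owner_final = u
    hist.wall_time = time.time() - t0
    return hist
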