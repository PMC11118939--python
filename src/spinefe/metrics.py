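"""Outcome metrics of a compression run and the mesh-convergence harness.

Definitions (all magnitudes in mm, forces in kN):

* bulging ``du``: maximum outward radial displacement of a lateral
  boundary region, measured relative to the body's mean lateral
  translation (rigid-body invariant);
* shearing ``db``: magnitude of the difference between the mean
  horizontal displacements of a disc's cranial and caudal interfaces;
* shortening ``dh``: decrease of the mean axial distance between a
  body's cranial and caudal surfaces;
* ``F_max``: maximum axial reaction over the history.

Mesh convergence follows the successive-refinement rule: a mesh is
convergent when the tracked summaries of two successive resolutions
differ by no more than 5%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import SegmentMesh
from .solver import SolutionHistory, SolutionState

__all__ = ["SegmentMetrics", "ConvergenceReport", "bulge_metric",
           "shear_metric", "shortening_metric", "percent_more",
           "segment_metrics", "convergence_study", "export_results"]

CONVERGENCE_LIMIT_PCT = 5.0


@dataclass
class SegmentMetrics:
    """Per-run outcome metrics."""

    grade: int
    F_max: float                                  # [kN]
    disc_bulge: Dict[str, float] = field(default_factory=dict)
    wall_bulge: Dict[str, float] = field(default_factory=dict)
    disc_shear: Dict[str, float] = field(default_factory=dict)
    disc_shortening: Dict[str, float] = field(default_factory=dict)
    vertebra_shortening: Dict[str, float] = field(default_factory=dict)
    max_vm_cortical: float = 0.0                  # [MPa]

    def to_json(self, **kw) -> str:
        return json.dumps(asdict(self), **kw)


@dataclass
class ConvergenceReport:
    """Successive-mesh percent differences of tracked quantities."""

    sizes: List[float]
    quantities: Dict[str, List[float]]
    percent_diffs: Dict[str, List[float]] = field(default_factory=dict)
    converged: bool = False
    complete: bool = True

    def evaluate(self):
        self.percent_diffs = {}
        ok = True
        for name, vals in self.quantities.items():
            diffs = []
            for a, b in zip(vals[:-1], vals[1:]):
                if b == 0:
                    diffs.append(0.0 if a == 0 else float("inf"))
                else:
                    diffs.append(100.0 * abs(a - b) / abs(b))
            self.percent_diffs[name] = diffs
            # "no more than 5%": the boundary itself passes
            if any(d > CONVERGENCE_LIMIT_PCT * (1 + 1e-12) + 1e-9
                   for d in diffs):
                ok = False
        self.converged = ok and self.complete
        return self


def _region_displacement(state: SolutionState, nodes: np.ndarray,
                         region: np.ndarray):
    if region.size == 0:
        raise ValueError("empty node region")
    return state.u_node[region], nodes[region]


def bulge_metric(state: SolutionState, mesh: SegmentMesh,
                 region: np.ndarray) -> float:
    """Max outward radial displacement over a lateral region [mm]."""
    u, x = _region_displacement(state, mesh.nodes, region)
    u_lat = u[:, :2] - u[:, :2].mean(axis=0)     # remove rigid lateral drift
    r = x[:, :2] - x[:, :2].mean(axis=0)
    rn = np.linalg.norm(r, axis=1)
    rn = np.where(rn > 1e-12, rn, 1.0)
    radial = (u_lat * r).sum(axis=1) / rn
    return float(np.max(radial, initial=0.0))


def shear_metric(state: SolutionState, mesh: SegmentMesh,
                 disc_label: str) -> float:
    """|mean horizontal (cranial) - mean horizontal (caudal)| [mm]."""
    try:
        top = mesh.node_sets[f"disc_{disc_label}_cranial"]
        bot = mesh.node_sets[f"disc_{disc_label}_caudal"]
    except KeyError as exc:
        raise ValueError(f"disc {disc_label} has no interface sets") from exc
    d = state.u_node[top][:, :2].mean(axis=0) \
        - state.u_node[bot][:, :2].mean(axis=0)
    return float(np.linalg.norm(d))


def shortening_metric(state: SolutionState, mesh: SegmentMesh,
                      cranial: np.ndarray, caudal: np.ndarray) -> float:
    """Decrease of the mean axial gap between two surfaces [mm]."""
    if cranial.size == 0 or caudal.size == 0:
        raise ValueError("empty surface set")
    dz = state.u_node[cranial][:, 2].mean() - state.u_node[caudal][:, 2].mean()
    return float(-dz)


def percent_more(value: float, baseline: float) -> float:
    """100 * (value / baseline - 1).

    The published "X% more" figures are percent_more(degenerated, healthy);
    the "X% smaller" force statements match percent_more(F_healthy,
    F_degenerated) - both conventions route through this one function.
    """
    if baseline == 0:
        raise ValueError("zero baseline")
    return 100.0 * (value / baseline - 1.0)


def segment_metrics(history: SolutionHistory, mesh: SegmentMesh,
                    grade: int = 0,
                    at_t_bar: Optional[float] = None) -> SegmentMetrics:
    """All outcome metrics of a segment run (at final time by default)."""
    if at_t_bar is None:
        state = history.final_state()
    else:
        idx = int(np.argmin(np.abs(history.t_bar - at_t_bar)))
        state = history.states[idx]
    m = SegmentMetrics(grade=grade,
                       F_max=float(history.reactions.max()),
                       max_vm_cortical=state.max_vm_cortical)
    for lab in ("L2L3", "L3L4"):
        if f"disc_{lab}_lateral" not in mesh.node_sets:
            continue
        m.disc_bulge[lab] = bulge_metric(state, mesh,
                                         mesh.node_sets[f"disc_{lab}_lateral"])
        m.disc_shear[lab] = shear_metric(state, mesh, lab)
        m.disc_shortening[lab] = shortening_metric(
            state, mesh, mesh.node_sets[f"disc_{lab}_cranial"],
            mesh.node_sets[f"disc_{lab}_caudal"])
    for lab in ("L2", "L3", "L4"):
        if f"wall_{lab}" not in mesh.node_sets:
            continue
        m.wall_bulge[lab] = bulge_metric(state, mesh,
                                         mesh.node_sets[f"wall_{lab}"])
        m.vertebra_shortening[lab] = shortening_metric(
            state, mesh, mesh.node_sets[f"vert_{lab}_cranial"],
            mesh.node_sets[f"vert_{lab}_caudal"])
    return m


def convergence_study(run_fn, sizes: Sequence[float] = (3.0, 2.0, 1.0)
                      ) -> ConvergenceReport:
    """Run ``run_fn(element_size) -> dict of summaries`` per mesh size.

    Sizes must be strictly decreasing (coarse to fine).  A failing run
    flags the report as partial instead of raising.
    """
    sizes = list(sizes)
    if len(sizes) < 2 or any(b >= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("need >= 2 strictly decreasing mesh sizes")
    quantities: Dict[str, List[float]] = {}
    report = ConvergenceReport(sizes=sizes, quantities=quantities)
    for h in sizes:
        try:
            summ = run_fn(h)
        except Exception:           # noqa: BLE001 - report, don't raise
            report.complete = False
            break
        for k, v in summ.items():
            quantities.setdefault(k, []).append(float(v))
    return report.evaluate()


def history_frame(history: SolutionHistory, mesh: SegmentMesh
                  ) -> pd.DataFrame:
    """Per-increment time series as a DataFrame."""
    probe = None
    if "probe_point_A" in mesh.node_sets:
        probe = int(mesh.node_sets["probe_point_A"][0])
    top_keys = [k for k in mesh.node_sets if k.startswith("top_endplate")]
    if top_keys:
        top_ids = mesh.node_sets[top_keys[0]]
    else:
        zmax = mesh.nodes[:, 2].max()
        top_ids = np.nonzero(mesh.nodes[:, 2] >= zmax - 1e-9)[0]
    rows = []
    for s in history.states:
        rows.append({
            "t_bar": s.t_bar,
            "u_z_mm": -s.u_node[top_ids][:, 2].mean(),
            "F_kN": s.reaction,
            "sigma_vm_max_MPa": s.max_vm_cortical,
            "u_x_A_mm": s.u_node[probe, 0] if probe is not None else np.nan,
            "max_eq_plastic": s.max_eq_plastic,
        })
    return pd.DataFrame(rows)


def export_results(history: SolutionHistory, metrics: SegmentMetrics,
                   mesh: SegmentMesh, outdir: str | Path,
                   stability: Optional[dict] = None,
                   write_vtu: bool = True) -> Dict[str, Path]:
    """Write CSV time series, JSON metrics, and a final-state VTU snapshot.

    Deterministic: identical runs produce byte-identical CSV/JSON.
    """
    if not history.states:
        raise ValueError("empty history")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    df = history_frame(history, mesh)
    paths["csv"] = outdir / "history.csv"
    df.to_csv(paths["csv"], index=False, float_format="%.10g")

    payload = {"schema": "spinefe/metrics-v1", "metrics": asdict(metrics)}
    if stability is not None:
        payload["stability"] = stability
    paths["json"] = outdir / "metrics.json"
    paths["json"].write_text(json.dumps(payload, indent=2, sort_keys=True))

    if write_vtu:
        from .vtkio import write_vtu
        paths["vtu"] = outdir / "final_state.vtu"
        write_vtu(paths["vtu"], mesh, history.final_state())
    return paths
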