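"""Parametric L2-L4 lumbar segment meshes.

This module is the synthetic-geometry stand-in for a patient CT pipeline:
it builds quasi-cylindrical vertebral bodies (elliptic cross-section,
mildly waisted), 10 mm intervertebral discs with a nucleus core and a
fibre-reinforced annulus, simplified posterior blocks, and six ligament
groups, and stacks them into an L2-L4 segment.

Mesh technology
---------------
* cross-sections are "butterfly" meshes: a structured square core blended
  into concentric quad rings out to the ellipse boundary, extruded along z
  into 8-node hexahedra;
* the cortical shell is a separate sheet of 4-node shell elements on the
  lateral wall, node-to-node tied to the underlying solid surface (the tie
  map is what degeneration grading removes to model debonding);
* annulus fibre layers are membrane quads living directly on solid-node
  faces (outer disc surface and nucleus/annulus interface ring);
* ligaments are 2-node tension-only links between anatomical landmark
  nodes of the simplified geometry.

Coordinates: x lateral, y antero-posterior (anterior = +y), z cranio-caudal.
Units mm.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "VertebraConfig", "DiscConfig", "Imperfection", "SegmentMesh",
    "CrossSection", "build_cross_section", "build_vertebra", "build_disc",
    "assemble_segment", "apply_imperfection", "hex_volumes", "hex_jacobians",
    "measured_nucleus_fraction",
]

# Gauss points / trilinear shape-function derivatives for jacobian checks
_G = 1.0 / np.sqrt(3.0)
_HEX_XI = np.array([[sx * _G, sy * _G, sz * _G]
                    for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)])
_CORNERS = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                     [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], float)


def _hex_dN(xi: np.ndarray) -> np.ndarray:
    """dN/dxi for the 8-node trilinear hex, shape (npts, 8, 3)."""
    xi = np.atleast_2d(xi)
    out = np.empty((xi.shape[0], 8, 3))
    for a in range(8):
        cx, cy, cz = _CORNERS[a]
        out[:, a, 0] = cx * (1 + cy * xi[:, 1]) * (1 + cz * xi[:, 2]) / 8
        out[:, a, 1] = cy * (1 + cx * xi[:, 0]) * (1 + cz * xi[:, 2]) / 8
        out[:, a, 2] = cz * (1 + cx * xi[:, 0]) * (1 + cy * xi[:, 1]) / 8
    return out


_DN_GP = _hex_dN(_HEX_XI)  # (8, 8, 3)


def hex_jacobians(nodes: np.ndarray, hexes: np.ndarray) -> np.ndarray:
    """det J at the 8 Gauss points of every hex, shape (n_elem, 8)."""
    X = nodes[hexes]                            # (E, 8, 3)
    J = np.einsum("eai,gaj->egji", X, _DN_GP)   # (E, 8, 3, 3)
    return np.linalg.det(J)


def hex_volumes(nodes: np.ndarray, hexes: np.ndarray) -> np.ndarray:
    """Element volumes by Gauss integration of det J."""
    return hex_jacobians(nodes, hexes).sum(axis=1)


@dataclass(frozen=True)
class VertebraConfig:
    """Quasi-cylindrical vertebral body dimensions [mm]."""

    width: float = 40.0
    depth: float = 33.0
    height: float = 30.0
    cortical_thickness: float = 0.5
    endplate_thickness: float = 0.5
    waist: float = 0.10               # mid-height lateral recession fraction
    posterior_simplified: bool = True
    posterior_depth: float = 8.0
    posterior_arc_deg: float = 50.0

    def __post_init__(self):
        for name in ("width", "depth", "height",
                     "cortical_thickness", "endplate_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cortical_thickness >= 0.05 * self.width:
            raise ValueError("cortical shell must be thin (< 5% of width)")
        if not (0 <= self.waist < 0.5):
            raise ValueError("waist fraction outside [0, 0.5)")


@dataclass(frozen=True)
class DiscConfig:
    """Intervertebral disc dimensions and fibre layup."""

    height: float = 10.0
    nucleus_area_fraction: float = 0.40
    fibre_angles: Tuple[float, float] = (30.0, -30.0)
    fibre_shell_thickness: float = 1.5

    def __post_init__(self):
        if not (8.0 <= self.height <= 12.0):
            raise ValueError("disc height outside the anatomical 8-12 mm range")
        if not (0.30 <= self.nucleus_area_fraction <= 0.50):
            raise ValueError("nucleus area fraction outside [0.30, 0.50]")
        if self.fibre_shell_thickness <= 0:
            raise ValueError("fibre shell thickness must be positive")


@dataclass(frozen=True)
class Imperfection:
    """Seeded geometric imperfection of the lateral cortical walls."""

    amplitude: float = 0.04           # 0.1% of the 40 mm vertebral width
    mode: str = "random"              # "random" | "first-buckling-mode"
    seed: int = 0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.mode not in ("random", "first-buckling-mode"):
            raise ValueError(f"unknown imperfection mode {self.mode!r}")


@dataclass
class CrossSection:
    """Butterfly quad mesh of the (normalized, unit-circle) cross-section.

    ``pts`` live on the unit disc; scaling x by the semi-width and y by the
    semi-depth maps them onto the physical ellipse.
    """

    pts: np.ndarray                   # (n, 2) normalized coordinates
    quads: np.ndarray                 # (q, 4) CCW connectivity
    nucleus_mask: np.ndarray          # (q,) bool, inside nucleus interface
    rings: List[np.ndarray]           # closed node loops, core -> boundary
    nucleus_ring: int                 # index into rings of the nucleus interface
    fraction: float                   # achieved nucleus area fraction

    @property
    def boundary(self) -> np.ndarray:
        return self.rings[-1]

    def quad_areas(self, scale=(1.0, 1.0)) -> np.ndarray:
        p = self.pts * np.asarray(scale)
        q = p[self.quads]
        d1 = q[:, 2] - q[:, 0]
        d2 = q[:, 3] - q[:, 1]
        return 0.5 * np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])


def _core_perimeter(m: int) -> np.ndarray:
    """CCW perimeter (i, j) index pairs of an (m+1)x(m+1) grid."""
    idx = []
    idx += [(i, 0) for i in range(m)]
    idx += [(m, j) for j in range(m)]
    idx += [(i, m) for i in range(m, 0, -1)]
    idx += [(0, j) for j in range(m, 0, -1)]
    return np.array(idx)


def build_cross_section(width: float, depth: float, element_size: float,
                        nucleus_fraction: float = 0.40,
                        core_fraction: float = 0.45) -> CrossSection:
    """Butterfly mesh of an ellipse (width x depth) at a target element size.

    One ring interface is placed (by 1-D root solving on the polygon area)
    so that the enclosed area is ``nucleus_fraction`` of the total; discs
    use it as the nucleus/annulus boundary.
    """
    if not (0.5 <= element_size <= 5.0):
        raise ValueError("element_size outside [0.5, 5] mm")
    a, b = width / 2.0, depth / 2.0
    s = core_fraction
    m = max(2, int(round(s * (a + b) / element_size)) + 1)
    m += m % 2                               # even: a node lands on each axis
    n_rad = max(2, int(round((1 - s) * (a + b) / 2.0 / element_size)))

    # square core grid
    u = np.linspace(-s, s, m + 1)
    uu, vv = np.meshgrid(u, u, indexing="ij")
    core_pts = np.column_stack([uu.ravel(), vv.ravel()])
    core_id = np.arange((m + 1) ** 2).reshape(m + 1, m + 1)
    perim_ij = _core_perimeter(m)
    perim = core_id[perim_ij[:, 0], perim_ij[:, 1]]
    p0 = core_pts[perim]
    theta = np.arctan2(p0[:, 1], p0[:, 0])
    circ = np.column_stack([np.cos(theta), np.sin(theta)])

    def ring_at(w: float) -> np.ndarray:
        return p0 + w * (circ - p0)

    def area_at(w: float) -> float:
        r = ring_at(w)
        x, y = r[:, 0], r[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    total = area_at(1.0)
    if area_at(0.0) / total >= nucleus_fraction:
        raise ValueError("core too large for the requested nucleus fraction")
    w_nuc = brentq(lambda w: area_at(w) / total - nucleus_fraction, 0.0, 1.0,
                   xtol=1e-12)

    # radial ladder of blend weights, containing the nucleus interface
    n_in = max(1, int(round(n_rad * w_nuc)))
    n_out = max(1, n_rad - n_in)
    ws = np.concatenate([np.linspace(0.0, w_nuc, n_in + 1)[1:],
                         np.linspace(w_nuc, 1.0, n_out + 1)[1:]])

    pts = [core_pts]
    rings = [perim]
    offset = core_pts.shape[0]
    for w in ws:
        pts.append(ring_at(w))
        rings.append(np.arange(offset, offset + perim.size))
        offset += perim.size
    pts = np.vstack(pts)

    quads = []
    for i in range(m):
        for j in range(m):
            quads.append([core_id[i, j], core_id[i + 1, j],
                          core_id[i + 1, j + 1], core_id[i, j + 1]])
    n_core = len(quads)
    for r in range(len(rings) - 1):
        inner, outer = rings[r], rings[r + 1]
        k1 = np.roll(np.arange(perim.size), -1)
        for k in range(perim.size):
            quads.append([inner[k], outer[k], outer[k1[k]], inner[k1[k]]])
    quads = np.array(quads)

    nucleus_mask = np.zeros(len(quads), bool)
    nucleus_mask[:n_core + n_in * perim.size] = True
    return CrossSection(pts=pts, quads=quads, nucleus_mask=nucleus_mask,
                        rings=rings, nucleus_ring=n_in, fraction=nucleus_fraction)


@dataclass
class SegmentMesh:
    """Nodes + solid/shell/link elements with named sets and the tie map.

    ``interface_pairs`` maps each vertebra label to an (P, 2) array of
    [shell node, solid node] coincident pairs on the lateral wall;
    ``interface_edge`` flags the rows belonging to the endplate layers
    (their ties survive debonding so the load path through the endplates
    is preserved); ``active_ties`` is the per-pair on/off state set by the
    degeneration grade.

    Cortical shell nodes intentionally coincide with their solid partner;
    solid nodes themselves are unique.
    """

    nodes: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    node_ndof: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    hexes: np.ndarray = field(default_factory=lambda: np.zeros((0, 8), int))
    shells: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), int))
    shell_thickness: np.ndarray = field(default_factory=lambda: np.zeros(0))
    links: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), int))
    link_area: np.ndarray = field(default_factory=lambda: np.zeros(0))
    link_group: List[str] = field(default_factory=list)
    element_sets: Dict[str, np.ndarray] = field(default_factory=dict)
    shell_sets: Dict[str, np.ndarray] = field(default_factory=dict)
    node_sets: Dict[str, np.ndarray] = field(default_factory=dict)
    interface_pairs: Dict[str, np.ndarray] = field(default_factory=dict)
    interface_edge: Dict[str, np.ndarray] = field(default_factory=dict)
    active_ties: Dict[str, np.ndarray] = field(default_factory=dict)
    fibre_angle_pairs: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    meta: Dict[str, object] = field(default_factory=dict)

    # -- bookkeeping -------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def copy(self) -> "SegmentMesh":
        return copy.deepcopy(self)

    def solid_node_ids(self) -> np.ndarray:
        return np.nonzero(self.node_ndof == 3)[0]

    def volume(self) -> float:
        return float(hex_volumes(self.nodes, self.hexes).sum())

    def tie_pairs_active(self) -> np.ndarray:
        """All active [shell, solid] tie rows across vertebrae."""
        rows = [self.interface_pairs[lab][self.active_ties[lab]]
                for lab in self.interface_pairs]
        if not rows:
            return np.zeros((0, 2), int)
        return np.vstack(rows)

    def validate(self, check_jacobians: bool = True) -> None:
        """Raise on any violated mesh invariant."""
        n = self.n_nodes
        for name, conn in (("hex", self.hexes), ("shell", self.shells),
                           ("link", self.links)):
            if conn.size and (conn.min() < 0 or conn.max() >= n):
                raise ValueError(f"{name} element references a missing node")
        solid = self.solid_node_ids()
        if solid.size:
            coords = np.round(self.nodes[solid] / 1e-9).astype(np.int64)
            uniq = np.unique(coords, axis=0)
            if uniq.shape[0] != solid.size:
                raise ValueError("duplicate solid nodes within 1e-9 mm")
        for lab, pairs in self.interface_pairs.items():
            if np.unique(pairs[:, 0]).size != pairs.shape[0] or \
               np.unique(pairs[:, 1]).size != pairs.shape[0]:
                raise ValueError(f"interface map for {lab} is not a bijection")
            gap = np.linalg.norm(self.nodes[pairs[:, 0]]
                                 - self.nodes[pairs[:, 1]], axis=1)
            if gap.max(initial=0.0) > 1e-9:
                raise ValueError(f"tie pair nodes of {lab} are not coincident")
        if check_jacobians and self.hexes.size:
            if hex_jacobians(self.nodes, self.hexes).min() <= 0:
                raise ValueError("non-positive hex jacobian")


class _Builder:
    """Accumulates nodes/elements while stacking bodies along z."""

    def __init__(self):
        self.nodes: List[np.ndarray] = []
        self.ndof: List[int] = []
        self.mesh = SegmentMesh()
        self.hexes: List[List[int]] = []
        self.hex_set_members: Dict[str, List[int]] = {}
        self.shells: List[List[int]] = []
        self.shell_t: List[float] = []
        self.shell_set_members: Dict[str, List[int]] = {}
        self.links: List[List[int]] = []
        self.link_area: List[float] = []
        self.link_group: List[str] = []

    def add_nodes(self, pts: np.ndarray, ndof: int = 3) -> np.ndarray:
        start = sum(len(p) for p in self.nodes)
        self.nodes.append(np.atleast_2d(pts))
        self.ndof.extend([ndof] * len(pts))
        return np.arange(start, start + len(pts))

    def add_hexes(self, conn: np.ndarray, set_name: str) -> None:
        start = len(self.hexes)
        self.hexes.extend(np.asarray(conn, int).tolist())
        self.hex_set_members.setdefault(set_name, []).extend(
            range(start, len(self.hexes)))

    def add_shells(self, conn: np.ndarray, thickness: float,
                   set_name: str) -> None:
        start = len(self.shells)
        self.shells.extend(np.asarray(conn, int).tolist())
        self.shell_t.extend([thickness] * len(conn))
        self.shell_set_members.setdefault(set_name, []).extend(
            range(start, len(self.shells)))

    def add_link(self, n1: int, n2: int, area: float, group: str) -> None:
        self.links.append([n1, n2])
        self.link_area.append(area)
        self.link_group.append(group)

    def finish(self) -> SegmentMesh:
        m = self.mesh
        m.nodes = np.vstack(self.nodes) if self.nodes else np.zeros((0, 3))
        m.node_ndof = np.array(self.ndof, int)
        m.hexes = np.array(self.hexes, int).reshape(-1, 8)
        m.shells = (np.array(self.shells, int).reshape(-1, 4)
                    if self.shells else np.zeros((0, 4), int))
        m.shell_thickness = np.array(self.shell_t)
        m.links = (np.array(self.links, int).reshape(-1, 2)
                   if self.links else np.zeros((0, 2), int))
        m.link_area = np.array(self.link_area)
        m.link_group = list(self.link_group)
        m.element_sets = {k: np.array(v, int)
                          for k, v in self.hex_set_members.items()}
        m.shell_sets = {k: np.array(v, int)
                        for k, v in self.shell_set_members.items()}
        for lab in m.interface_pairs:
            m.active_ties.setdefault(
                lab, np.ones(len(m.interface_pairs[lab]), bool))
        return m


def _extrude_quads(quads: np.ndarray, bot: np.ndarray,
                   top: np.ndarray) -> np.ndarray:
    q = np.asarray(quads, int)
    return np.concatenate([bot[q], top[q]], axis=1)


def _loop_wall(bot_loop: np.ndarray, top_loop: np.ndarray) -> np.ndarray:
    """Quads covering the wall strip between two closed node loops."""
    nxt = np.roll(np.arange(bot_loop.size), -1)
    return np.column_stack([bot_loop, bot_loop[nxt],
                            top_loop[nxt], top_loop])


def _add_vertebra(b: _Builder, cross: CrossSection, cfg: VertebraConfig,
                  element_size: float, z0: float, label: str,
                  bottom_ids: Optional[np.ndarray]) -> np.ndarray:
    """Stack one vertebra; returns the node ids of its top cross-section."""
    a, bb = cfg.width / 2.0, cfg.depth / 2.0
    ep, H = cfg.endplate_thickness, cfg.height
    n_core = max(2, int(round((H - 2 * ep) / element_size)))
    if H - 2 * ep <= 0:
        raise ValueError("endplates thicker than the vertebra")
    z_loc = np.concatenate([[0.0, ep],
                            ep + (H - 2 * ep) * np.arange(1, n_core + 1) / n_core,
                            [H]])
    z_loc = np.unique(z_loc)
    if len(z_loc) < 4:
        raise ValueError("degenerate mesh: too few layers through the vertebra")

    def scale(z):
        return 1.0 - cfg.waist * np.sin(np.pi * z / H)

    level_ids = []
    for k, z in enumerate(z_loc):
        if k == 0 and bottom_ids is not None:
            level_ids.append(bottom_ids)
            continue
        sc = scale(z)
        pts = np.column_stack([cross.pts[:, 0] * a * sc,
                               cross.pts[:, 1] * bb * sc,
                               np.full(cross.pts.shape[0], z0 + z)])
        level_ids.append(b.add_nodes(pts, 3))

    n_layers = len(z_loc) - 1
    for k in range(n_layers):
        conn = _extrude_quads(cross.quads, level_ids[k], level_ids[k + 1])
        is_endplate = (k == 0) or (k == n_layers - 1)
        b.add_hexes(conn, f"endplate_{label}" if is_endplate
                    else f"trabecular_{label}")

    # cortical shell: duplicated boundary nodes tied to the solid wall.
    # The sheet spans the wall BETWEEN the endplate interfaces (levels
    # 1 .. n-1); its edge rows sit exactly on the endplate boundaries and
    # stay tied under debonding, preserving the endplate load path.
    shell_levels = list(range(1, len(z_loc) - 1))
    shell_level_ids = {}
    for k in shell_levels:
        solid_ring = level_ids[k][cross.boundary]
        ring_pts = np.concatenate(b.nodes)[solid_ring]
        shell_level_ids[k] = b.add_nodes(ring_pts, 6)
    nb = cross.boundary.size
    shell_conn = []
    for k in shell_levels[:-1]:
        bot = shell_level_ids[k]
        top = shell_level_ids[k + 1]
        loc = np.arange(nb)
        nxt = np.roll(loc, -1)
        shell_conn.append(np.column_stack([bot[loc], bot[nxt],
                                           top[nxt], top[loc]]))
    b.add_shells(np.vstack(shell_conn), cfg.cortical_thickness,
                 f"cortical_{label}")

    pairs, edge = [], []
    for k in shell_levels:
        solid_ring = level_ids[k][cross.boundary]
        for sh, so in zip(shell_level_ids[k], solid_ring):
            pairs.append([sh, so])
            edge.append(k == shell_levels[0] or k == shell_levels[-1])
    b.mesh.interface_pairs[label] = np.array(pairs, int)
    b.mesh.interface_edge[label] = np.array(edge, bool)

    # simplified posterior block: extrude posterior-most wall edges in -y
    if cfg.posterior_simplified:
        theta = np.arctan2(cross.pts[cross.boundary][:, 1],
                           cross.pts[cross.boundary][:, 0])
        half_arc = np.deg2rad(cfg.posterior_arc_deg) / 2.0
        sel = np.abs(theta + np.pi / 2.0) <= half_arc      # around -y
        sel_idx = np.nonzero(sel)[0]
        if sel_idx.size >= 2:
            n_lay = 2
            post_ids = {}                                   # (level, layer) -> ids
            all_nodes = np.concatenate(b.nodes)
            for k in range(len(z_loc)):
                base = level_ids[k][cross.boundary[sel_idx]]
                base_pts = all_nodes[base] if k == 0 and bottom_ids is not None \
                    else np.concatenate(b.nodes)[base]
                for lay in range(1, n_lay + 1):
                    pts = base_pts + np.array([0.0,
                                               -cfg.posterior_depth * lay / n_lay,
                                               0.0])
                    post_ids[(k, lay)] = b.add_nodes(pts, 3)
                post_ids[(k, 0)] = base
            conn = []
            for k in range(n_layers):
                for lay in range(n_lay):
                    for i in range(sel_idx.size - 1):
                        conn.append([post_ids[(k, lay)][i + 1],
                                     post_ids[(k, lay)][i],
                                     post_ids[(k, lay + 1)][i],
                                     post_ids[(k, lay + 1)][i + 1],
                                     post_ids[(k + 1, lay)][i + 1],
                                     post_ids[(k + 1, lay)][i],
                                     post_ids[(k + 1, lay + 1)][i],
                                     post_ids[(k + 1, lay + 1)][i + 1]])
            b.add_hexes(np.array(conn), f"posterior_{label}")
            mid = len(z_loc) // 2
            b.mesh.node_sets[f"posterior_outer_{label}"] = np.concatenate(
                [post_ids[(0, n_lay)], post_ids[(mid, n_lay)],
                 post_ids[(len(z_loc) - 1, n_lay)]])

    # bookkeeping node sets used by metrics and BCs
    b.mesh.node_sets[f"vert_{label}_caudal"] = level_ids[0]
    b.mesh.node_sets[f"vert_{label}_cranial"] = level_ids[-1]
    mid = len(z_loc) // 2
    interior = shell_levels[1:-1] if len(shell_levels) > 2 else shell_levels
    b.mesh.node_sets[f"wall_{label}"] = np.concatenate(
        [shell_level_ids[k] for k in interior])
    mid_level = shell_levels[len(shell_levels) // 2]
    b.mesh.node_sets[f"wall_{label}_mid_ring"] = shell_level_ids[mid_level]
    b.mesh.meta.setdefault("vertebra_levels", {})[label] = \
        [ids for ids in level_ids]
    return level_ids[-1]


def _add_disc(b: _Builder, cross: CrossSection, cfg: DiscConfig,
              element_size: float, z0: float, label: str, scale_xy: Tuple[float, float],
              bottom_ids: Optional[np.ndarray]) -> np.ndarray:
    a, bb = scale_xy
    nz = max(2, int(round(cfg.height / element_size)))
    z_loc = cfg.height * np.arange(nz + 1) / nz
    level_ids = []
    for k, z in enumerate(z_loc):
        if k == 0 and bottom_ids is not None:
            level_ids.append(bottom_ids)
            continue
        pts = np.column_stack([cross.pts[:, 0] * a, cross.pts[:, 1] * bb,
                               np.full(cross.pts.shape[0], z0 + z)])
        level_ids.append(b.add_nodes(pts, 3))

    nuc = np.nonzero(cross.nucleus_mask)[0]
    ann = np.nonzero(~cross.nucleus_mask)[0]
    for k in range(nz):
        b.add_hexes(_extrude_quads(cross.quads[nuc], level_ids[k],
                                   level_ids[k + 1]), f"nucleus_{label}")
        b.add_hexes(_extrude_quads(cross.quads[ann], level_ids[k],
                                   level_ids[k + 1]), f"annulus_{label}")

    # fibre membranes on solid faces: external on the outer wall, internal
    # on the nucleus/annulus interface ring
    t_half = cfg.fibre_shell_thickness / 2.0
    for k in range(nz):
        b.add_shells(_loop_wall(level_ids[k][cross.boundary],
                                level_ids[k + 1][cross.boundary]),
                     t_half, f"fibre_layer_external_{label}")
        ring = cross.rings[cross.nucleus_ring]
        b.add_shells(_loop_wall(level_ids[k][ring], level_ids[k + 1][ring]),
                     t_half, f"fibre_layer_internal_{label}")
    b.mesh.fibre_angle_pairs[f"fibre_layer_external_{label}"] = cfg.fibre_angles
    b.mesh.fibre_angle_pairs[f"fibre_layer_internal_{label}"] = cfg.fibre_angles

    b.mesh.node_sets[f"disc_{label}_caudal"] = level_ids[0]
    b.mesh.node_sets[f"disc_{label}_cranial"] = level_ids[-1]
    b.mesh.node_sets[f"disc_{label}_lateral"] = np.concatenate(
        [level_ids[k][cross.boundary] for k in range(len(z_loc))])
    b.mesh.meta.setdefault("disc_fraction", {})[label] = cross.fraction
    return level_ids[-1]


def build_vertebra(config: VertebraConfig = VertebraConfig(),
                   element_size: float = 3.0, label: str = "L3") -> SegmentMesh:
    """Mesh of a single vertebra (solid core + cortical shell + posterior)."""
    cross = build_cross_section(config.width, config.depth, element_size)
    b = _Builder()
    _add_vertebra(b, cross, config, element_size, 0.0, label, None)
    mesh = b.finish()
    mesh.node_sets[f"base_{label}"] = mesh.node_sets[f"vert_{label}_caudal"]
    mesh.node_sets[f"top_endplate_{label}"] = mesh.node_sets[f"vert_{label}_cranial"]
    mesh.meta["cross_section"] = cross
    mesh.meta["configs"] = {label: config}
    mesh.meta["element_size"] = element_size
    mesh.validate()
    return mesh


def build_disc(config: DiscConfig = DiscConfig(),
               footprint: Optional[CrossSection] = None,
               element_size: float = 3.0, label: str = "L3L4",
               width: float = 40.0, depth: float = 33.0) -> SegmentMesh:
    """Mesh of a single disc (nucleus + annulus + two fibre membranes)."""
    cross = footprint or build_cross_section(
        width, depth, element_size, nucleus_fraction=config.nucleus_area_fraction)
    b = _Builder()
    _add_disc(b, cross, config, element_size, 0.0, label,
              (width / 2.0, depth / 2.0), None)
    mesh = b.finish()
    mesh.meta["cross_section"] = cross
    mesh.meta["configs"] = {label: config}
    mesh.meta["element_size"] = element_size
    mesh.validate()
    return mesh


def measured_nucleus_fraction(mesh: SegmentMesh, label: str) -> float:
    """Nucleus / total cross-sectional area from mid-plane element volumes."""
    nuc = hex_volumes(mesh.nodes, mesh.hexes[mesh.element_sets[f"nucleus_{label}"]]).sum()
    ann = hex_volumes(mesh.nodes, mesh.hexes[mesh.element_sets[f"annulus_{label}"]]).sum()
    return float(nuc / (nuc + ann))


_LIG_SPANS = (("L4", "L3"), ("L3", "L2"))


def _nearest_node(nodes: np.ndarray, ids: np.ndarray, target: np.ndarray) -> int:
    d = np.linalg.norm(nodes[ids] - target, axis=1)
    return int(ids[np.argmin(d)])


def assemble_segment(vertebrae: Sequence[VertebraConfig] = None,
                     discs: Sequence[DiscConfig] = None,
                     element_size: float = 3.0,
                     ligament_areas: Optional[Dict[str, float]] = None) -> SegmentMesh:
    """Assembled L2-L4 segment: 3 vertebrae, 2 discs, 6 ligament groups.

    Bodies are stacked caudal to cranial (L4 at z=0), with disc/vertebra
    interfaces sharing nodes.  ``probe_point_A`` is the lateral-most node
    of the L3 cortical wall at mid-height.
    """
    from .materials import LIGAMENT_AREAS
    vertebrae = list(vertebrae) if vertebrae is not None else [VertebraConfig()] * 3
    discs = list(discs) if discs is not None else [DiscConfig()] * 2
    if len(vertebrae) != 3 or len(discs) != 2:
        raise ValueError("segment needs 3 vertebra configs and 2 disc configs")
    v0 = vertebrae[0]
    for v in vertebrae[1:]:
        if (v.width, v.depth) != (v0.width, v0.depth):
            raise ValueError("non-conforming interface meshes: "
                             "all vertebrae must share one footprint")
    areas = dict(LIGAMENT_AREAS)
    if ligament_areas:
        areas.update(ligament_areas)

    cross = build_cross_section(v0.width, v0.depth, element_size,
                                nucleus_fraction=discs[0].nucleus_area_fraction)
    b = _Builder()
    z = 0.0
    order = [("vert", "L4", vertebrae[2]), ("disc", "L3L4", discs[1]),
             ("vert", "L3", vertebrae[1]), ("disc", "L2L3", discs[0]),
             ("vert", "L2", vertebrae[0])]
    top = None
    for kind, label, cfg in order:
        if kind == "vert":
            top = _add_vertebra(b, cross, cfg, element_size, z, label, top)
            z += cfg.height
        else:
            if cfg.nucleus_area_fraction != discs[0].nucleus_area_fraction:
                cross_d = build_cross_section(
                    v0.width, v0.depth, element_size,
                    nucleus_fraction=cfg.nucleus_area_fraction)
            else:
                cross_d = cross
            top = _add_disc(b, cross_d, cfg, element_size, z, label,
                            (v0.width / 2.0, v0.depth / 2.0), top)
            z += cfg.height

    mesh = b.finish()
    mesh.node_sets["base_L4"] = mesh.node_sets["vert_L4_caudal"]
    mesh.node_sets["top_endplate_L2"] = mesh.node_sets["vert_L2_cranial"]

    # probe point A: lateral-most L3 cortical wall node at mid-height
    ring = mesh.node_sets["wall_L3_mid_ring"]
    mesh.node_sets["probe_point_A"] = np.array(
        [ring[np.argmax(mesh.nodes[ring][:, 0])]])

    # ligaments ------------------------------------------------------------
    nodes = mesh.nodes
    deep = vertebrae[0].posterior_depth
    for lower, upper in _LIG_SPANS:
        lo_ids = mesh.node_sets[f"vert_{lower}_cranial"]
        up_ids = mesh.node_sets[f"vert_{upper}_caudal"]
        z_lo = nodes[lo_ids][:, 2].mean()
        z_up = nodes[up_ids][:, 2].mean()
        a, bb = v0.width / 2.0, v0.depth / 2.0

        def pick(ids, x, y, zz):
            return _nearest_node(nodes, ids, np.array([x, y, zz]))

        def span(group, x, y):
            n1 = pick(lo_ids, x, y, z_lo)
            n2 = pick(up_ids, x, y, z_up)
            if n1 != n2:
                b2_area = areas[group]
                mesh.links = np.vstack([mesh.links, [n1, n2]])
                mesh.link_area = np.append(mesh.link_area, b2_area)
                mesh.link_group.append(group)

        # anterior / posterior body wall
        for dx in (-0.3 * a, 0.0, 0.3 * a):
            span("ALL", dx, bb)
            span("PLL", dx, -bb)
        # posterior element groups, anchored on the posterior blocks
        po_lo = mesh.node_sets[f"posterior_outer_{lower}"]
        po_up = mesh.node_sets[f"posterior_outer_{upper}"]

        def pspan(group, x, y_off):
            n1 = _nearest_node(nodes, po_lo, np.array([x, -bb - y_off, z_lo]))
            n2 = _nearest_node(nodes, po_up, np.array([x, -bb - y_off, z_up]))
            if n1 != n2:
                mesh.links = np.vstack([mesh.links, [n1, n2]])
                mesh.link_area = np.append(mesh.link_area, areas[group])
                mesh.link_group.append(group)

        for dx in (-0.25 * a, 0.25 * a):
            pspan("CL", dx, 0.3 * deep)
            pspan("LF", dx, 0.6 * deep)
        pspan("ISS", 0.0, 0.8 * deep)
        pspan("SSL", 0.0, deep)

    mesh.meta["cross_section"] = cross
    mesh.meta["configs"] = {"L2": vertebrae[0], "L3": vertebrae[1],
                            "L4": vertebrae[2], "L2L3": discs[0],
                            "L3L4": discs[1]}
    mesh.meta["element_size"] = element_size
    mesh.meta["total_height"] = z
    mesh.validate()
    return mesh


def apply_imperfection(mesh: SegmentMesh, imp: Imperfection,
                       mode_shape: Optional[np.ndarray] = None) -> SegmentMesh:
    """Perturb the lateral cortical walls radially by <= ``imp.amplitude``.

    The random field is a smooth low-order Fourier series in the wall's
    circumferential angle, modulated by sin(pi * zeta) through each body's
    height so the vertebra/disc interface planes stay put.  Deterministic
    for a fixed seed.  With ``mode="first-buckling-mode"`` a precomputed
    nodal shape (from linearized buckling) must be supplied.
    """
    if imp.amplitude == 0.0:
        return mesh
    out = mesh.copy()
    if imp.mode == "first-buckling-mode":
        if mode_shape is None:
            raise ValueError("first-buckling-mode imperfection needs mode_shape")
        disp = mode_shape[:, :3] if mode_shape.ndim == 2 else \
            mode_shape.reshape(-1, 3)
        scale = imp.amplitude / max(np.abs(disp).max(), 1e-30)
        out.nodes = out.nodes + scale * disp
        return out

    rng = np.random.default_rng(imp.seed)
    delta = np.zeros(out.n_nodes)
    touched = np.zeros(out.n_nodes, bool)
    for lab, pairs in out.interface_pairs.items():
        shell_nodes = pairs[:, 0]
        solid_nodes = pairs[:, 1]
        pos = out.nodes[shell_nodes]
        zmin, zmax = pos[:, 2].min(), pos[:, 2].max()
        zeta = (pos[:, 2] - zmin) / max(zmax - zmin, 1e-12)
        theta = np.arctan2(pos[:, 1], pos[:, 0])
        f = np.zeros(len(pairs))
        for k in range(1, 4):
            ak, bk = rng.standard_normal(2)
            f += ak * np.cos(k * theta) + bk * np.sin(k * theta)
        f *= np.sin(np.pi * zeta)
        if np.abs(f).max() > 0:
            f *= imp.amplitude / np.abs(f).max()
        for ids in (shell_nodes, solid_nodes):
            delta[ids] = f
            touched[ids] = True
    r = np.linalg.norm(out.nodes[:, :2], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nhat = np.where(r[:, None] > 1e-12,
                        out.nodes[:, :2] / np.maximum(r, 1e-12)[:, None], 0.0)
    out.nodes[:, :2] += (delta * touched)[:, None] * nhat
    return out
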