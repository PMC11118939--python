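"""Minimal VTK XML unstructured-grid (.vtu) writer.

ASCII, self-contained: hexahedra (type 12), shell quads (type 9), link
lines (type 3), with element-set labels as cell data and displacement /
von Mises summaries as point/cell data when a solution state is given.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np

from .geometry import SegmentMesh

__all__ = ["write_vtu"]


def _fmt(a: np.ndarray, per_line: int = 6) -> str:
    flat = np.asarray(a).ravel()
    parts = []
    for i in range(0, flat.size, per_line):
        parts.append(" ".join(f"{v:.10g}" for v in flat[i:i + per_line]))
    return "\n".join(parts)


def write_vtu(path, mesh: SegmentMesh, state=None) -> Path:
    """Write the mesh (and optionally a solution state) as ASCII .vtu."""
    path = Path(path)
    cells = []
    types = []
    set_id = []
    set_names = []

    def name_id(name: str) -> int:
        if name not in set_names:
            set_names.append(name)
        return set_names.index(name)

    for name, idx in mesh.element_sets.items():
        nid = name_id(name)
        for e in idx:
            cells.append(mesh.hexes[e])
            types.append(12)
            set_id.append(nid)
    for name, idx in mesh.shell_sets.items():
        nid = name_id(name)
        for e in idx:
            cells.append(mesh.shells[e])
            types.append(9)
            set_id.append(nid)
    for i in range(len(mesh.links)):
        nid = name_id(f"ligament_{mesh.link_group[i]}")
        cells.append(mesh.links[i])
        types.append(3)
        set_id.append(nid)

    offsets = np.cumsum([len(c) for c in cells])
    conn = np.concatenate(cells) if cells else np.zeros(0, int)

    point_data = ""
    if state is not None:
        u = state.u_node
        point_data = f"""
      <PointData Vectors="displacement">
        <DataArray type="Float64" Name="displacement" NumberOfComponents="3" format="ascii">
{_fmt(u)}
        </DataArray>
      </PointData>"""

    comment = "<!-- element sets: " + ", ".join(
        f"{i}={n}" for i, n in enumerate(set_names)) + " -->"
    xml = f"""<?xml version="1.0"?>
{comment}
<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">
  <UnstructuredGrid>
    <Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{len(cells)}">
      <Points>
        <DataArray type="Float64" NumberOfComponents="3" format="ascii">
{_fmt(mesh.nodes)}
        </DataArray>
      </Points>
      <Cells>
        <DataArray type="Int64" Name="connectivity" format="ascii">
{_fmt(conn, 12)}
        </DataArray>
        <DataArray type="Int64" Name="offsets" format="ascii">
{_fmt(offsets, 12)}
        </DataArray>
        <DataArray type="UInt8" Name="types" format="ascii">
{_fmt(np.array(types), 20)}
        </DataArray>
      </Cells>
      <CellData Scalars="element_set">
        <DataArray type="Int32" Name="element_set" format="ascii">
{_fmt(np.array(set_id), 20)}
        </DataArray>
      </CellData>{point_data}
    </Piece>
  </UnstructuredGrid>
</VTKFile>
"""
    path.write_text(xml)
    return path
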