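"""Five age-degeneration scenarios and their application to a mesh.

The scenarios combine three mechanisms: trabecular density loss
(300 -> 100 kg/m^3), loss of the cortical-trabecular bond (gaps between
the shell and the core), and disc degeneration (stiffer, more
compressible nucleus; stiffer annulus):

========  ========  =========  ==================  =====================
grade     density    bond       nucleus (E, nu)     annulus (C10, D1/nu)
========  ========  =========  ==================  =====================
1 healthy   300      bonded     (1, 0.4999)         0.25, 0.86 / 0.40
2           100      bonded     (1, 0.4999)         0.25, 0.86 / 0.40
3           100      unbonded   (1, 0.4999)         0.25, 0.86 / 0.40
4           100      bonded     (1.66, 0.4)         1.13, 0.19 / 0.40
5           100      unbonded   (1.66, 0.4)         1.13, 0.19 / 0.40
========  ========  =========  ==================  =====================

Debonding is modelled as removal of the lateral-wall tie constraints
(free separation, no contact closure); the shell stays connected to the
core through the endplate layers so the load path is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

from .geometry import SegmentMesh

__all__ = ["GradeSpec", "grade_spec", "apply_grade", "DEBOND_DEFAULT_SCOPE"]

#: Linear moduli behind the two annulus Neo-Hookean cards (the unique values
#: consistent with the printed C10 entries at nu = 0.40).
_ANNULUS_HEALTHY = (1.4, 0.40)
_ANNULUS_DEGENERATED = (6.3, 0.40)

#: Vertebrae whose wall is debonded in unbonded grades (the published failure
#: analysis is L3-centric); pass ``debond_scope=("L2","L3","L4")`` to widen.
DEBOND_DEFAULT_SCOPE: Tuple[str, ...] = ("L3",)


@dataclass(frozen=True)
class GradeSpec:
    """One column of the five-grade degeneration table."""

    grade: int
    trabecular_density: float          # [kg/m^3]
    bond_state: str                    # "bonded" | "unbonded"
    nucleus: Tuple[float, float]       # (E [MPa], nu)
    annulus_linear: Tuple[float, float]  # (E [MPa], nu) behind the NH card

    def __post_init__(self):
        if self.grade not in range(1, 6):
            raise ValueError(f"grade {self.grade} outside 1..5")
        if self.bond_state not in ("bonded", "unbonded"):
            raise ValueError(f"unknown bond state {self.bond_state!r}")


_TABLE = {
    1: GradeSpec(1, 300.0, "bonded", (1.0, 0.4999), _ANNULUS_HEALTHY),
    2: GradeSpec(2, 100.0, "bonded", (1.0, 0.4999), _ANNULUS_HEALTHY),
    3: GradeSpec(3, 100.0, "unbonded", (1.0, 0.4999), _ANNULUS_HEALTHY),
    4: GradeSpec(4, 100.0, "bonded", (1.66, 0.4), _ANNULUS_DEGENERATED),
    5: GradeSpec(5, 100.0, "unbonded", (1.66, 0.4), _ANNULUS_DEGENERATED),
}


def grade_spec(g: int) -> GradeSpec:
    """The degeneration scenario for grade ``g`` in 1..5."""
    try:
        return _TABLE[int(g)]
    except (KeyError, ValueError) as exc:
        raise ValueError(f"grade must be an integer in 1..5, got {g!r}") from exc


def apply_grade(mesh: SegmentMesh, spec: GradeSpec | int,
                debond_scope: Sequence[str] = DEBOND_DEFAULT_SCOPE):
    """Return (graded mesh, material library) for one scenario.

    For unbonded grades the lateral-wall ties of every vertebra in
    ``debond_scope`` are deactivated; tie rows on the endplate layers stay
    active.  Idempotent: applying the same grade twice is a no-op.
    """
    from .materials import default_material_library

    if not isinstance(spec, GradeSpec):
        spec = grade_spec(spec)
    if not mesh.interface_pairs:
        raise ValueError("mesh has no cortical-trabecular interface map")
    out = mesh.copy()
    for lab, pairs in out.interface_pairs.items():
        active = out.active_ties[lab]
        active[:] = True
        if spec.bond_state == "unbonded" and lab in debond_scope:
            active[:] = out.interface_edge[lab]
    out.meta["grade"] = spec.grade
    out.meta["debond_scope"] = tuple(debond_scope)
    return out, default_material_library(spec)
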