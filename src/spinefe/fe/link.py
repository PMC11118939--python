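"""Tension-only 2-node link elements (ligaments).

Force follows the current chord direction (large-rotation capable); a link
carries no force and no stiffness when shorter than its rest length.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from ..materials import LigamentCard

__all__ = ["LinkBlock", "link_force_tension_only"]


def link_force_tension_only(elongation: float, card: LigamentCard,
                            rest_length: float = 10.0) -> float:
    """Axial force F = E A elongation / L0 in tension, zero otherwise."""
    if rest_length <= 0:
        raise ValueError("rest length must be positive")
    if elongation <= 0 and card.tension_only:
        return 0.0
    return card.E * card.area * elongation / rest_length


class LinkBlock:
    """A batch of tension-only truss elements."""

    def __init__(self, nodes: np.ndarray, links: np.ndarray,
                 area: np.ndarray, modulus: np.ndarray,
                 tension_only: bool = True, name: str = "links"):
        self.links = np.asarray(links, int)
        self.area = np.asarray(area, float)
        self.E = np.broadcast_to(np.asarray(modulus, float),
                                 (self.links.shape[0],)).copy()
        self.tension_only = tension_only
        self.name = name
        d0 = nodes[self.links[:, 1]] - nodes[self.links[:, 0]]
        self.L0 = np.linalg.norm(d0, axis=1)
        if self.L0.min(initial=np.inf) <= 1e-12 and len(self.L0):
            raise ValueError("zero-length link element")

    def _state(self, nodes: np.ndarray, u: np.ndarray):
        x = nodes[self.links] + u[self.links]
        d = x[:, 1] - x[:, 0]
        length = np.linalg.norm(d, axis=1)
        n = d / length[:, None]
        strain = (length - self.L0) / self.L0
        return length, n, strain

    def energy(self, nodes: np.ndarray, u: np.ndarray) -> float:
        if not len(self.L0):
            return 0.0
        _, _, e = self._state(nodes, u)
        if self.tension_only:
            e = np.maximum(e, 0.0)
        return float((0.5 * self.E * self.area * self.L0 * e ** 2).sum())

    def force_and_tangent(self, nodes: np.ndarray, u: np.ndarray,
                          need_tangent: bool = True
                          ) -> Tuple[np.ndarray, np.ndarray]:
        """Internal force (L, 6) and tangent (L, 6, 6) in [node0, node1] order."""
        L = self.links.shape[0]
        f = np.zeros((L, 6))
        K = np.zeros((L, 6, 6)) if need_tangent else None
        if L == 0:
            return f, K
        length, n, e = self._state(nodes, u)
        act = (e > 0) | (not self.tension_only)
        N = self.E * self.area * e * act
        fn = N[:, None] * n
        f[:, :3] = -fn
        f[:, 3:] = fn
        if need_tangent:
            nn = np.einsum("li,lj->lij", n, n)
            I = np.eye(3)
            k = (self.E * self.area / self.L0 * act)[:, None, None] * nn \
                + (N / length)[:, None, None] * (I - nn)
            K[:, :3, :3] = k
            K[:, 3:, 3:] = k
            K[:, :3, 3:] = -k
            K[:, 3:, :3] = -k
        return f, K
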