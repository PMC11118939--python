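"""Element kernels: hexahedra, shells/membranes, links, return mappings.

The backbone checks are consistency oracles: internal forces must be the
exact gradients of the strain energies (central finite differences), the
tangents the exact jacobians of the forces, and simple closed-form states
must be reproduced.
"""

import numpy as np
import pytest

from spinefe.fe.hex import HexBlock, hex_stiffness_and_force
from spinefe.fe.link import LinkBlock, link_force_tension_only
from spinefe.fe.plasticity import (PlaneStressReturn, return_map_von_mises,
                                   von_mises_voigt)
from spinefe.fe.shell import (ShellBlock, cortical_plane_stress,
                              fibre_plane_stress, shell_stiffness_and_force)
from spinefe.materials import (CORTICAL, IsotropicElastic, LigamentCard,
                               PlasticityCard, neo_hookean_from_linear)

UNIT_CUBE = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                      [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], float)


def fd_gradient(energy, q0, eps=1e-6):
    g = np.zeros_like(q0)
    for d in range(q0.size):
        qp, qm = q0.copy(), q0.copy()
        qp[d] += eps
        qm[d] -= eps
        g[d] = (energy(qp) - energy(qm)) / (2 * eps)
    return g


class TestHexKernel:
    @pytest.mark.parametrize("card", [
        IsotropicElastic(E=10.0, nu=0.3),
        IsotropicElastic(E=1.0, nu=0.4999),          # B-bar route
        neo_hookean_from_linear(1.4, 0.40),
    ], ids=["isotropic", "near-incompressible", "neo-hookean"])
    def test_force_is_energy_gradient_and_tangent_consistent(self, card):
        rng = np.random.default_rng(0)
        X = UNIT_CUBE + 0.15 * rng.standard_normal((8, 3))
        blk = HexBlock(X, np.arange(8)[None, :], card)
        u = 0.05 * rng.standard_normal((8, 3))
        f, Km, Kg, = blk.force_and_tangent(u)
        fd = fd_gradient(lambda q: blk.energy(q.reshape(8, 3)),
                         u.ravel())
        assert np.abs(f[0] - fd).max() / np.abs(fd).max() < 1e-7
        K = (Km + Kg)[0]
        Kfd = np.zeros((24, 24))
        for d in range(24):
            qp, qm = u.ravel().copy(), u.ravel().copy()
            qp[d] += 1e-6
            qm[d] -= 1e-6
            fp = blk.force_and_tangent(qp.reshape(8, 3), False)[0][0]
            fm = blk.force_and_tangent(qm.reshape(8, 3), False)[0][0]
            Kfd[:, d] = (fp - fm) / 2e-6
        assert np.abs(K - Kfd).max() / np.abs(Kfd).max() < 1e-6
        assert np.abs(K - K.T).max() < 1e-9 * np.abs(K).max()

    def test_uniaxial_nu_zero(self):
        blk = HexBlock(UNIT_CUBE, np.arange(8)[None, :],
                       IsotropicElastic(E=1.0, nu=0.0))
        u = np.zeros((8, 3))
        u[UNIT_CUBE[:, 2] == 1, 2] = 0.001
        S = blk.stress_voigt(u)
        assert S[0, :, 2].mean() == pytest.approx(0.001, rel=1e-3)
        assert np.abs(S[0, :, [0, 1, 3, 4, 5]]).max() < 1e-12

    def test_neo_hookean_tangent_at_identity_matches_linear_moduli(self):
        nh = neo_hookean_from_linear(1.4, 0.40)
        blk = HexBlock(UNIT_CUBE, np.arange(8)[None, :], nh)
        F = np.broadcast_to(np.eye(3), (1, 8, 3, 3)).copy()
        S, D = blk._nh_stress_tangent(F, True)
        assert np.abs(S).max() < 1e-14
        Clin = IsotropicElastic(E=1.4, nu=0.4).stiffness()
        assert np.abs(D[0, 0] - Clin).max() < 1e-6

    def test_patch_constant_stress(self):
        """Distorted multi-element patch under a linear displacement field
        reproduces the constant stress state to machine precision."""
        from tests.conftest import box_mesh
        import scipy.sparse.linalg as spla
        import scipy.sparse as sp
        rng = np.random.default_rng(3)
        mesh = box_mesh(2, 2, 2, 1, 1, 1)
        nid = mesh.meta["nid"]
        interior = nid[1, 1, 1]
        # distort every non-corner node a little (faces + center)
        pert = 0.08 * rng.standard_normal(mesh.nodes.shape)
        corners = ((mesh.nodes[:, 0] % 1 == 0) & (mesh.nodes[:, 1] % 1 == 0)
                   & (mesh.nodes[:, 2] % 1 == 0))
        mesh.nodes[~corners] += pert[~corners]
        mesh.nodes[interior] = [0.45, 0.55, 0.5]
        card = IsotropicElastic(E=7.0, nu=0.3)
        blk = HexBlock(mesh.nodes, mesh.hexes, card)
        A = 1e-3 * np.array([[1.0, 0.3, 0.1], [0.0, -0.5, 0.2],
                             [0.4, 0.0, 0.8]])
        u = mesh.nodes @ A.T
        free = np.arange(3 * interior, 3 * interior + 3)
        for _ in range(4):                       # full Newton on the patch
            f, Km, Kg = blk.force_and_tangent(u)
            dofs = (blk.conn[:, :, None] * 3 + np.arange(3)).reshape(-1, 24)
            rows = np.repeat(dofs, 24, axis=1).ravel()
            cols = np.tile(dofs, (1, 24)).ravel()
            K = sp.coo_matrix(((Km + Kg).ravel(), (rows, cols))).tocsc()
            r = np.zeros(mesh.n_nodes * 3)
            np.add.at(r, dofs, f)
            if np.abs(r[free]).max() < 1e-13:
                break
            u = u.reshape(-1)
            u[free] -= spla.spsolve(K[np.ix_(free, free)], r[free])
            u = u.reshape(-1, 3)
        S = blk.stress_voigt(u)
        spread = np.abs(S - S.reshape(-1, 6).mean(axis=0)).max()
        assert spread < 1e-10 * np.abs(S).max()
        assert np.abs(u[interior] - A @ mesh.nodes[interior]).max() < 1e-12


class TestShellKernel:
    def test_force_is_energy_gradient(self):
        rng = np.random.default_rng(1)
        X = np.array([[0, 0, 0], [2, 0, 0.1], [2.2, 1.9, 0],
                      [0.1, 2, 0.05]], float)
        C, Gt = cortical_plane_stress(CORTICAL)
        blk = ShellBlock(X, np.arange(4)[None, :], 0.5, C, mode="shell",
                         transverse_G=Gt)
        u = 0.01 * rng.standard_normal((4, 3))
        r = 0.01 * rng.standard_normal((4, 3))
        f, Km, Kg, _, _ = blk.force_and_tangent(u, r)

        def en(q):
            q = q.reshape(4, 6)
            return blk.energy(None, q[:, :3], q[:, 3:])

        fd = fd_gradient(en, np.concatenate([u, r], axis=1).ravel(), 1e-7)
        assert np.abs(f[0] - fd).max() / np.abs(fd).max() < 1e-6
        K = (Km + Kg)[0]
        assert np.abs(K - K.T).max() < 1e-9 * np.abs(K).max()

    def test_cantilever_plate_matches_beam_theory(self):
        """Clamped plate strip with a tip load: deflection within 2% of
        the thin-plate (cylindrical bending) closed form at a fine mesh."""
        import scipy.sparse as sp
        import scipy.sparse.linalg as spla
        # nu = 0: narrow-strip (beam) and plate closed forms coincide,
        # so the check isolates the bending formulation itself
        E, nu, t = 1000.0, 0.0, 0.1
        L, b = 10.0, 1.0
        nx, ny = 40, 4
        xs = np.linspace(0, L, nx + 1)
        ys = np.linspace(0, b, ny + 1)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        nodes = np.column_stack([X.ravel(), Y.ravel(),
                                 np.zeros(X.size)])
        nid = np.arange(len(nodes)).reshape(nx + 1, ny + 1)
        conn = [[nid[i, j], nid[i + 1, j], nid[i + 1, j + 1], nid[i, j + 1]]
                for i in range(nx) for j in range(ny)]
        Ciso = IsotropicElastic(E=E, nu=nu)
        C = np.zeros((3, 3))
        C[:2, :2] = np.linalg.inv(np.array([[1 / E, -nu / E],
                                            [-nu / E, 1 / E]]))
        C[2, 2] = Ciso.shear_modulus
        blk = ShellBlock(nodes, np.array(conn), t, C, mode="shell",
                         transverse_G=Ciso.shear_modulus)
        _, Km, Kg, _, _ = blk.force_and_tangent(np.zeros((len(nodes), 3)),
                                                np.zeros((len(nodes), 3)))
        dofs = (blk.conn[:, :, None] * 6 + np.arange(6)).reshape(-1, 24)
        rows = np.repeat(dofs, 24, axis=1).ravel()
        cols = np.tile(dofs, (1, 24)).ravel()
        K = sp.coo_matrix((Km.ravel(), (rows, cols)),
                          shape=(6 * len(nodes),) * 2).tocsc()
        fixed = np.concatenate([nid[0] * 6 + c for c in range(6)])
        free = np.setdiff1d(np.arange(6 * len(nodes)), fixed)
        P = 1.0
        fext = np.zeros(6 * len(nodes))
        fext[nid[-1] * 6 + 2] = P / (ny + 1)
        w = np.zeros(6 * len(nodes))
        w[free] = spla.spsolve(K[np.ix_(free, free)], fext[free])
        tip = w[nid[-1] * 6 + 2].mean()
        D = E * t ** 3 / (12 * (1 - nu ** 2))
        expect = P * L ** 3 / (3 * D * b)    # = P L^3 / 3EI at nu = 0
        assert tip == pytest.approx(expect, rel=0.02)

    def test_in_plane_uniaxial_plane_stress(self):
        """Single shell element: imposed plane-stress uniaxial strain state
        gives s11 = E e11 after accounting for the local element frame."""
        Xs = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        E, nu = 100.0, 0.3
        C = np.zeros((3, 3))
        C[:2, :2] = np.linalg.inv(np.array([[1 / E, -nu / E],
                                            [-nu / E, 1 / E]]))
        C[2, 2] = E / (2 * (1 + nu))
        blk = ShellBlock(Xs, np.arange(4)[None, :], 0.1, C, mode="membrane")
        eps = 1e-5
        u = np.zeros((4, 3))
        u[:, 0] = eps * Xs[:, 0]
        u[:, 1] = -nu * eps * Xs[:, 1]
        ul = np.einsum("sij,saj->sai", blk.R, u[blk.conn])
        _, e = blk._membrane_strain(ul)
        sig_local = np.einsum("IJ,sgJ->sgI", blk.C, e)
        # rotate the membrane stress back to the global x-y frame
        th = np.arctan2(blk.R[0, 0, 1], blk.R[0, 0, 0])
        c, s = np.cos(th), np.sin(th)
        s11l, s22l, s12l = sig_local[0].mean(axis=0)
        s11 = c * c * s11l + s * s * s22l - 2 * c * s * s12l
        assert s11 == pytest.approx(E * eps, rel=1e-3)

    def test_fibre_membrane_has_no_bending_resistance(self):
        """Out-of-plane deformation of a fibre membrane produces no force
        at all (membrane-only reinforcement)."""
        Xs = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        blk = ShellBlock(Xs, np.arange(4)[None, :], 0.75,
                         fibre_plane_stress(500.0, (30, -30)),
                         mode="membrane")
        u = np.zeros((4, 3))
        u[:, 2] = 1e-2 * np.array([1, -1, 1, -1])
        f, _, _, _, _ = blk.force_and_tangent(u, None)
        assert np.abs(f).max() == 0.0

    def test_single_element_wrapper(self):
        K, f = shell_stiffness_and_force(
            np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float),
            0.5, cortical_plane_stress(CORTICAL)[0], np.zeros((4, 3)))
        assert K.shape == (24, 24) and np.abs(f).max() == 0.0


class TestLinks:
    def test_tension_only_closed_form(self):
        card = LigamentCard(group="ALL", E=20.0, area=10.0)
        assert link_force_tension_only(-0.5, card, 10.0) == 0.0
        assert link_force_tension_only(0.0, card, 10.0) == 0.0
        assert link_force_tension_only(0.1, card, 10.0) == pytest.approx(2.0)

    def test_block_slack_in_compression(self):
        nodes = np.array([[0, 0, 0], [0, 0, 10.0]])
        blk = LinkBlock(nodes, np.array([[0, 1]]), np.array([10.0]),
                        np.array([20.0]))
        u = np.zeros((2, 3))
        u[1, 2] = -0.5                        # shorten: slack
        f, K = blk.force_and_tangent(nodes, u)
        assert np.abs(f).max() == 0.0 and np.abs(K).max() == 0.0
        u[1, 2] = 0.1                         # stretch: F = EA dL / L
        f, K = blk.force_and_tangent(nodes, u)
        assert f[0, 5] == pytest.approx(20 * 10 * 0.1 / 10, rel=1e-3)

    def test_force_follows_rotated_chord(self):
        nodes = np.array([[0, 0, 0], [0, 0, 10.0]])
        blk = LinkBlock(nodes, np.array([[0, 1]]), np.array([1.0]),
                        np.array([10.0]))
        u = np.zeros((2, 3))
        u[1] = [3.0, 0.0, 1.0]                # stretched and tilted
        f, _ = blk.force_and_tangent(nodes, u)
        d = (nodes[1] + u[1]) - nodes[0]
        assert np.cross(f[0, 3:], d) == pytest.approx(np.zeros(3), abs=1e-12)


class TestReturnMapping:
    def test_elastic_below_yield(self):
        card = PlasticityCard()
        s = np.array([30.0, -10.0, 0.0, 5.0, 0.0, 0.0])
        assert von_mises_voigt(s) < 64.0
        out, a = return_map_von_mises(s, card, 0.0)
        assert np.array_equal(out, s) and a == 0.0

    def test_on_surface_no_increment(self):
        card = PlasticityCard()
        s = np.array([64.0, 0, 0, 0, 0, 0.0])
        out, a = return_map_von_mises(s, card, 0.0)
        assert a == 0.0 and np.array_equal(out, s)

    def test_perfect_plasticity_returns_to_surface(self):
        card = PlasticityCard(yield_stress=64.0, hardening_modulus=0.0)
        s = np.array([100.0, 0, 0, 0, 0, 0.0])
        out, a = return_map_von_mises(s, card, 0.0)
        assert von_mises_voigt(out) == pytest.approx(64.0, rel=1e-9)
        assert a > 0

    def test_hardening_consistency(self):
        card = PlasticityCard(yield_stress=64.0, hardening_modulus=400.0)
        s = np.array([150.0, 20.0, 0, 10.0, 0, 0.0])
        out, a = return_map_von_mises(s, card, 0.0)
        assert von_mises_voigt(out) == pytest.approx(64.0 + 400.0 * a,
                                                     rel=1e-6)

    def test_plane_stress_return_lands_on_hardened_surface(self):
        C, _ = cortical_plane_stress(CORTICAL)
        ret = PlaneStressReturn(C, PlasticityCard())
        e = np.array([[0.02, -0.005, 0.01], [1e-5, 5e-6, 2e-6]])
        s, ep, al, D = ret.map(e, np.zeros((2, 3)), np.zeros(2))
        assert ret.von_mises(s)[0] == pytest.approx(64.0 + 400.0 * al[0],
                                                    rel=1e-6)
        assert al[1] == 0.0                      # elastic point untouched
        assert np.abs(D[1] - C).max() < 1e-8

    def test_plane_stress_algorithmic_tangent_consistent(self):
        C, _ = cortical_plane_stress(CORTICAL)
        ret = PlaneStressReturn(C, PlasticityCard())
        e = np.array([[0.02, -0.005, 0.01]])
        _, _, _, D = ret.map(e, np.zeros((1, 3)), np.zeros(1))
        eps = 1e-8
        for j in range(3):
            de = np.zeros(3)
            de[j] = eps
            sp_, _, _, _ = ret.map(e + de, np.zeros((1, 3)), np.zeros(1),
                                   need_tangent=False)
            sm_, _, _, _ = ret.map(e - de, np.zeros((1, 3)), np.zeros(1),
                                   need_tangent=False)
            fd = (sp_ - sm_)[0] / (2 * eps)
            assert np.abs(D[0][:, j] - fd).max() / np.abs(fd).max() < 1e-4


def test_single_element_hex_wrapper_matches_block():
    card = IsotropicElastic(E=5.0, nu=0.25)
    u = 0.01 * np.random.default_rng(5).standard_normal((8, 3))
    K, f = hex_stiffness_and_force(UNIT_CUBE, card, u)
    blk = HexBlock(UNIT_CUBE, np.arange(8)[None, :], card)
    f2, Km, Kg = blk.force_and_tangent(u)
    assert np.allclose(f, f2[0]) and np.allclose(K, (Km + Kg)[0])
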