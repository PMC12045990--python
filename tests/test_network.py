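"""Fiber-network construction, energetics and stiffness extraction.

The energy oracle here is an intentionally naive pure-Python term-by-term
summation, written independently of the vectorized production code: it
measures the interior angle at each hinge directly and penalizes its
deviation from pi.
"""

import math
from dataclasses import replace

import numpy as np
import pytest

from organoid_mech.errors import GeometryError, InvalidInputError
from organoid_mech.network import (
    CompressionProtocol,
    DilutionSpec,
    build_lattice,
    compute_stiffness,
    dilute,
    energy_gradient,
    minimize_energy,
    patterned_vs_random_comparison,
    place_cells,
    stiffness_vs_p_sweep,
    total_energy,
)


def brute_force_energy(net, pos):
    """Independent term-by-term evaluation of the network energy."""
    Lx = net.box_width
    E = 0.0
    for e in range(net.edges.shape[0]):
        i, j = net.edges[e]
        si, sj = net.edge_shifts[e]
        dx = (pos[j, 0] + sj * Lx) - (pos[i, 0] + si * Lx)
        dy = pos[j, 1] - pos[i, 1]
        E += 0.5 * net.ks * net.edge_occ[e] * (math.hypot(dx, dy) - net.l0) ** 2
    for t in range(net.triples.shape[0]):
        i, j, k = net.triples[t]
        si, sj, sk = net.triple_shifts[t]
        # interior angle at j between the rays j->i and j->k
        ux = (pos[i, 0] + si * Lx) - (pos[j, 0] + sj * Lx)
        uy = pos[i, 1] - pos[j, 1]
        vx = (pos[k, 0] + sk * Lx) - (pos[j, 0] + sj * Lx)
        vy = pos[k, 1] - pos[j, 1]
        theta = math.atan2(abs(ux * vy - uy * vx), ux * vx + uy * vy)
        occ = net.edge_occ[net.triple_edges[t, 0]] * net.edge_occ[net.triple_edges[t, 1]]
        E += 0.5 * net.kb * occ * (theta - math.pi) ** 2
    A0 = net.rest_area
    for c in range(net.triangles.shape[0]):
        if net.cell_occ[c] == 0:
            continue
        xs, ys = [], []
        for m in range(3):
            v = net.triangles[c, m]
            xs.append(pos[v, 0] + net.tri_shifts[c, m] * Lx)
            ys.append(pos[v, 1])
        area = 0.5 * abs((xs[1] - xs[0]) * (ys[2] - ys[0])
                         - (xs[2] - xs[0]) * (ys[1] - ys[0]))
        E += net.lam * (area - A0) ** 2
    return E


class TestLatticeConstruction:
    def test_default_lattice_dimensions(self, full_lattice_64):
        net = full_lattice_64
        assert net.n_nodes == 64
        assert (net.n_rows, net.n_cols) == (8, 8)
        assert total_energy(net) == pytest.approx(0.0, abs=1e-20)

    def test_edge_count_matches_brute_force(self):
        """Edges = all rest-distance-l0 node pairs under the periodic
        horizontal / open vertical boundary."""
        for n in (25, 64):
            net = build_lattice(n)
            Lx = net.box_width
            count = 0
            for i in range(net.n_nodes):
                for j in range(i + 1, net.n_nodes):
                    dx = net.positions[j, 0] - net.positions[i, 0]
                    dx -= Lx * round(dx / Lx)
                    dy = net.positions[j, 1] - net.positions[i, 1]
                    if abs(math.hypot(dx, dy) - net.l0) < 1e-9:
                        count += 1
            assert net.edges.shape[0] == count
            assert count == net.n_cols * net.n_rows + 2 * net.n_cols * (net.n_rows - 1)

    def test_interior_nodes_center_three_triples(self, full_lattice_64):
        net = full_lattice_64
        middle_counts = np.bincount(net.triples[:, 1], minlength=net.n_nodes)
        interior = np.zeros(net.n_nodes, dtype=bool)
        interior[net.n_cols:-net.n_cols] = True
        assert np.all(middle_counts[interior] == 3)
        # boundary rows only carry the horizontal fiber triple
        assert np.all(middle_counts[~interior] == 1)

    def test_triples_match_geometric_enumeration(self):
        """Every triple is two consecutive collinear edges of one fiber:
        the rest vectors j->i and j->k are antiparallel unit steps."""
        net = build_lattice(64)
        Lx = net.box_width
        for t in range(net.triples.shape[0]):
            i, j, k = net.triples[t]
            si, sj, sk = net.triple_shifts[t]
            u = net.positions[i] - net.positions[j] + [(si - sj) * Lx, 0]
            v = net.positions[k] - net.positions[j] + [(sk - sj) * Lx, 0]
            assert np.allclose(u, -v, atol=1e-9)
            assert math.hypot(*u) == pytest.approx(net.l0, abs=1e-9)
        # and the enumeration is exhaustive: 3 per interior node + 1 per boundary node
        n_expected = 3 * net.n_cols * (net.n_rows - 2) + 2 * net.n_cols
        assert net.triples.shape[0] == n_expected

    def test_rest_state_invariants(self, full_lattice_64):
        net = full_lattice_64
        v = net.positions[net.edges[:, 1]] - net.positions[net.edges[:, 0]]
        v[:, 0] += (net.edge_shifts[:, 1] - net.edge_shifts[:, 0]) * net.box_width
        assert np.allclose(np.hypot(v[:, 0], v[:, 1]), net.l0)
        assert net.triangles.shape[0] == 2 * net.n_cols * (net.n_rows - 1)

    def test_too_small_lattice_raises(self):
        with pytest.raises(InvalidInputError):
            build_lattice(9)


class TestDilution:
    def test_p_one_is_identity(self, full_lattice_64):
        net = dilute(full_lattice_64, DilutionSpec(mode="random", p=1.0, seed=0))
        assert net.edge_occ.all()

    def test_p_zero_removes_everything(self, full_lattice_64):
        net = dilute(full_lattice_64, DilutionSpec(mode="random", p=0.0, seed=0))
        assert not net.edge_occ.any()

    def test_random_realized_fraction_binomial(self, full_lattice_64):
        """Mean realized fraction over many seeds sits within 3 SE of p."""
        p = 0.9
        n_edges = full_lattice_64.edges.shape[0]
        fracs = [dilute(full_lattice_64,
                        DilutionSpec(mode="random", p=p, seed=s)).occupied_fraction
                 for s in range(1000)]
        se = math.sqrt(p * (1 - p) / n_edges / len(fracs))
        assert abs(np.mean(fracs) - p) < 3 * se

    def test_patterned_hits_target_within_one_edge(self, full_lattice_64):
        net = dilute(full_lattice_64, DilutionSpec(mode="patterned", p=0.85, seed=1))
        n_edges = net.edge_occ.size
        assert abs(net.occupied_fraction - 0.85) <= 1.0 / n_edges

    def test_patterned_removes_a_central_disk(self, full_lattice_64):
        """Removed edges are exactly those nearest the system center."""
        net0 = full_lattice_64
        net = dilute(net0, DilutionSpec(mode="patterned", p=0.85, seed=1))
        center = np.array([net0.box_width / 2, net0.height / 2])
        mids = []
        Lx = net0.box_width
        for e in range(net0.edges.shape[0]):
            i, j = net0.edges[e]
            si, sj = net0.edge_shifts[e]
            mx = 0.5 * (net0.positions[i, 0] + si * Lx + net0.positions[j, 0] + sj * Lx)
            my = 0.5 * (net0.positions[i, 1] + net0.positions[j, 1])
            dx = mx - center[0]
            dx -= Lx * round(dx / Lx)
            mids.append(math.hypot(dx, my - center[1]))
        mids = np.array(mids)
        removed = net.edge_occ == 0
        assert mids[removed].max() <= mids[~removed].min() + 1e-9

    def test_patterned_infeasible_raises(self, full_lattice_64):
        with pytest.raises(GeometryError):
            dilute(full_lattice_64, DilutionSpec(mode="patterned", p=0.05, seed=0))

    def test_seeded_determinism(self, full_lattice_64):
        a = dilute(full_lattice_64, DilutionSpec(mode="random", p=0.7, seed=9))
        b = dilute(full_lattice_64, DilutionSpec(mode="random", p=0.7, seed=9))
        assert np.array_equal(a.edge_occ, b.edge_occ)


class TestCellPlacement:
    def test_exact_count_no_duplicates(self, full_lattice_64):
        net = place_cells(full_lattice_64, 32, seed=4)
        assert net.cell_occ.sum() == 32
        assert set(np.unique(net.cell_occ)) <= {0.0, 1.0}

    def test_zero_cells_zero_cell_energy(self, full_lattice_64):
        net = place_cells(full_lattice_64, 0, seed=4)
        rng = np.random.default_rng(0)
        pos = net.positions + 0.05 * rng.standard_normal(net.positions.shape)
        no_fibers = replace(net, edge_occ=np.zeros_like(net.edge_occ))
        assert total_energy(no_fibers, pos) == 0.0

    def test_reproducible(self, full_lattice_64):
        a = place_cells(full_lattice_64, 32, seed=5)
        b = place_cells(full_lattice_64, 32, seed=5)
        assert np.array_equal(a.cell_occ, b.cell_occ)

    def test_too_many_cells_raises(self, full_lattice_64):
        with pytest.raises(InvalidInputError):
            place_cells(full_lattice_64, 10_000)


class TestEnergy:
    def test_rest_configuration_zero(self, default_network):
        assert total_energy(default_network) == pytest.approx(0.0, abs=1e-18)

    def test_single_stretched_edge_hand_value(self):
        """One occupied edge at l = 1.1 l0 and ks = 1 stores 0.5 * 0.01."""
        net = build_lattice(16, ks=1.0)
        occ = np.zeros_like(net.edge_occ)
        # pick a horizontal edge away from the seam
        e = int(np.nonzero((net.edge_class == 0)
                           & (net.edge_shifts.sum(axis=1) == 0))[0][0])
        occ[e] = 1.0
        net = replace(net, edge_occ=occ)
        pos = net.positions.copy()
        pos[net.edges[e, 1], 0] += 0.1
        assert total_energy(net, pos) == pytest.approx(0.5 * 0.1 ** 2, rel=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        """Vectorized energy equals the naive term-by-term sum to 1e-12 on
        randomly diluted, cell-laden, randomly displaced 5x5 lattices."""
        rng = np.random.default_rng(seed)
        net = build_lattice(25)
        net = dilute(net, DilutionSpec(mode="random", p=0.7, seed=seed))
        net = place_cells(net, 10, seed=seed + 1)
        for _ in range(10):
            pos = net.positions + 0.08 * rng.standard_normal(net.positions.shape)
            e_fast = total_energy(net, pos)
            e_slow = brute_force_energy(net, pos)
            assert e_fast == pytest.approx(e_slow, abs=1e-12 * max(1.0, e_slow))

    def test_energy_nonnegative_random_configs(self, default_network, rng):
        for _ in range(20):
            pos = default_network.positions + 0.1 * rng.standard_normal(
                default_network.positions.shape)
            assert total_energy(default_network, pos) >= 0.0

    def test_horizontal_translation_invariance(self, default_network, rng):
        pos = default_network.positions + 0.05 * rng.standard_normal(
            default_network.positions.shape)
        e0 = total_energy(default_network, pos)
        for shift in (0.3, default_network.box_width, -2.7):
            moved = pos.copy()
            moved[:, 0] += shift
            assert total_energy(default_network, moved) == pytest.approx(e0, rel=1e-12)

    def test_gradient_matches_finite_differences(self, default_network, rng):
        net = default_network
        pos = net.positions + 0.03 * rng.standard_normal(net.positions.shape)
        g = energy_gradient(net, pos)
        eps = 1e-6
        idx = rng.integers(0, net.n_nodes, size=8)
        for i in idx:
            for j in (0, 1):
                p1, p2 = pos.copy(), pos.copy()
                p1[i, j] += eps
                p2[i, j] -= eps
                fd = (total_energy(net, p1) - total_energy(net, p2)) / (2 * eps)
                assert g[i, j] == pytest.approx(fd, abs=1e-7)


class TestMinimization:
    def test_zero_strain_is_rest(self, full_lattice_64):
        pos, e = minimize_energy(full_lattice_64, 0.0)
        assert e == pytest.approx(0.0, abs=1e-16)
        assert np.allclose(pos, full_lattice_64.positions, atol=1e-6)

    def test_linear_response_quadratic_in_strain(self, full_lattice_64):
        _, e1 = minimize_energy(full_lattice_64, 1e-4)
        _, e2 = minimize_energy(full_lattice_64, 2e-4)
        assert e1 > 0
        assert e2 / e1 == pytest.approx(4.0, rel=0.01)

    def test_floating_cells_carry_no_load(self, full_lattice_64):
        """With no fibers and cells only in the interior, compression of
        the clamped boundary rows costs no energy."""
        net = replace(full_lattice_64, edge_occ=np.zeros_like(full_lattice_64.edge_occ))
        rows = full_lattice_64.positions[net.triangles, 1]
        interior = (rows.min(axis=1) > 1.0) & (rows.max(axis=1) < net.height - 1.0)
        q = np.zeros(net.triangles.shape[0])
        q[np.nonzero(interior)[0][:8]] = 1.0
        net = replace(net, cell_occ=q)
        _, e = minimize_energy(net, 0.05)
        assert e == pytest.approx(0.0, abs=1e-12)


class TestStiffness:
    def test_empty_system_zero_stiffness(self):
        net = build_lattice(64)
        net = replace(net, edge_occ=np.zeros_like(net.edge_occ))
        res = compute_stiffness(net)
        assert res.K == pytest.approx(0.0, abs=1e-10)

    def test_invariant_to_halving_fd_step(self, default_network):
        k1 = compute_stiffness(default_network,
                               CompressionProtocol(finite_difference_step=1e-3)).K
        k2 = compute_stiffness(default_network,
                               CompressionProtocol(finite_difference_step=5e-4)).K
        assert k2 == pytest.approx(k1, rel=0.01)

    def test_matches_hessian_quadratic_form(self):
        """Finite-difference K equals the Schur-complement quadratic form
        of the energy Hessian at rest on a small full lattice."""
        net = build_lattice(16)
        n_dof = 2 * net.n_nodes
        h = 1e-5

        def grad_flat(x):
            return energy_gradient(net, x.reshape(-1, 2)).ravel()

        x0 = net.positions.ravel().copy()
        H = np.empty((n_dof, n_dof))
        for k in range(n_dof):
            xp, xm = x0.copy(), x0.copy()
            xp[k] += h
            xm[k] -= h
            H[:, k] = (grad_flat(xp) - grad_flat(xm)) / (2 * h)
        H = 0.5 * (H + H.T)

        prescribed = np.zeros(n_dof, dtype=bool)
        prescribed[2 * net.bottom_nodes + 1] = True
        prescribed[2 * net.top_nodes + 1] = True
        mode = np.zeros(n_dof)
        mode[2 * net.top_nodes + 1] = -net.height   # d(y_top)/d(gamma)
        d = mode[prescribed]
        Hpp = H[np.ix_(prescribed, prescribed)]
        Hpf = H[np.ix_(prescribed, ~prescribed)]
        Hff = H[np.ix_(~prescribed, ~prescribed)]
        u = np.linalg.lstsq(Hff, Hpf.T @ d, rcond=None)[0]
        k_hess = (d @ Hpp @ d - d @ Hpf @ u) / net.system_area

        k_fd = compute_stiffness(net, CompressionProtocol(
            eval_strain=1e-3, finite_difference_step=5e-4)).K
        assert k_fd == pytest.approx(k_hess, rel=0.01)

    def test_sweep_is_deterministic(self):
        kwargs = dict(p_values=[0.9], modes=("random",), seeds=[3, 4],
                      protocol=CompressionProtocol())
        a = stiffness_vs_p_sweep(**kwargs)
        b = stiffness_vs_p_sweep(**kwargs)
        assert a.equals(b)

    def test_comparison_reports_positive_increase(self):
        r = patterned_vs_random_comparison(0.85, 0.95, seeds=3)
        assert r["K_random_mean"] > r["K_patterned_mean"] > 0
        assert r["relative_increase"] > 0
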