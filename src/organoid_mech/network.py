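"""Diluted fiber-network microstructure model of organoid tissue stiffness.

The extracellular matrix is modeled as a triangular lattice of semiflexible
fibers: a straight line of edges along one of the three principal lattice
directions is a collagen fiber, with harmonic stretching of each occupied
edge and harmonic bending at each pair of consecutive collinear occupied
edges.  Cells are individual lattice triangles with an area-elastic
penalty.  The total energy is

    E = ks/2 sum_<ij> p_ij (l_ij - l0)^2
      + kb/2 sum_<ijk> p_ij p_jk (theta_ijk - pi)^2
      + sum_n lambda q_n (A_n - A0)^2,

with p_ij in {0,1} the edge occupancy, theta_ijk the interior angle at the
middle node of a collinear triple, q_n in {0,1} the cell indicator and A0
the rest triangle area.  The dimensionless ratio R = ks/(kb l0^2) compares
fiber stretching to bending stiffness (l0 = 1 here, so ks = R kb).

ECM amount is the occupied-edge fraction p; ECM *organization* enters
through the dilution mode: random (every edge kept independently with
probability p — the disorganized, mutant-like matrix) versus patterned
(edges removed only inside a central circular region — the ring-like,
control-like matrix).  Tissue stiffness K is the second strain derivative
of the minimized energy under uniaxial vertical compression (periodic
horizontally, open vertically), normalized by the undeformed system area.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize as _scipy_minimize

from .errors import GeometryError, InvalidInputError, InvalidParameterError, MinimizationError

__all__ = [
    "LatticeNetwork",
    "DilutionSpec",
    "CompressionProtocol",
    "StiffnessResult",
    "build_lattice",
    "dilute",
    "place_cells",
    "total_energy",
    "energy_gradient",
    "minimize_energy",
    "compute_stiffness",
    "stiffness_vs_p_sweep",
    "patterned_vs_random_comparison",
]

ROW_HEIGHT = math.sqrt(3.0) / 2.0


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class LatticeNetwork:
    """Triangular lattice with per-edge occupancy, bend triples and cells.

    Horizontal direction is periodic with box width ``n_cols * l0``; the
    vertical direction is open.  Image shifts are pre-resolved per element
    so geometry is continuous across the periodic seam.
    """

    n_rows: int
    n_cols: int
    l0: float
    positions: np.ndarray          # (N, 2) rest coordinates
    edges: np.ndarray              # (E, 2) node indices
    edge_shifts: np.ndarray        # (E, 2) x-image shift (units of box width) per endpoint
    edge_class: np.ndarray         # (E,) direction class 0/1/2
    edge_occ: np.ndarray           # (E,) occupancy in {0., 1.}
    triples: np.ndarray            # (T, 3) node indices (i, j, k), j the hinge
    triple_shifts: np.ndarray      # (T, 3) x-image shift per vertex
    triple_edges: np.ndarray       # (T, 2) edge indices (ij, jk) for occupancy
    triangles: np.ndarray          # (C, 3) node indices of all lattice triangles
    tri_shifts: np.ndarray         # (C, 3)
    cell_occ: np.ndarray           # (C,) q_n in {0., 1.}
    ks: float = 10.0
    kb: float = 1.0
    lam: float = 1.0

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    @property
    def box_width(self) -> float:
        return self.n_cols * self.l0

    @property
    def height(self) -> float:
        return (self.n_rows - 1) * ROW_HEIGHT * self.l0

    @property
    def system_area(self) -> float:
        return self.box_width * self.height

    @property
    def rest_area(self) -> float:
        """Rest area A0 of one lattice triangle."""
        return math.sqrt(3.0) / 4.0 * self.l0 ** 2

    @property
    def occupied_fraction(self) -> float:
        return float(self.edge_occ.mean())

    @property
    def bottom_nodes(self) -> np.ndarray:
        return np.arange(self.n_cols)

    @property
    def top_nodes(self) -> np.ndarray:
        return np.arange((self.n_rows - 1) * self.n_cols, self.n_rows * self.n_cols)

    @property
    def stretch_bend_ratio(self) -> float:
        """R = ks / (kb l0^2)."""
        return self.ks / (self.kb * self.l0 ** 2)


@dataclass(frozen=True)
class DilutionSpec:
    """How to remove ECM edges: independently at random, or from a central
    circular region (patterned)."""

    mode: Literal["random", "patterned"]
    p: float
    circle_center: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("random", "patterned"):
            raise InvalidParameterError(f"unknown dilution mode {self.mode!r}")
        if not (0.0 <= self.p <= 1.0):
            raise InvalidParameterError(f"p must be in [0, 1], got {self.p}")


@dataclass(frozen=True)
class CompressionProtocol:
    """Uniaxial-compression schedule and stiffness-extraction settings."""

    eval_strain: float = 0.01
    finite_difference_step: float = 1e-3
    strain_values: tuple[float, ...] = ()
    minimizer_tolerance: float = 1e-8
    max_iterations: int = 20000

    def __post_init__(self):
        if self.eval_strain < 0:
            raise InvalidParameterError("eval_strain must be >= 0")
        if not (0 < self.finite_difference_step <= self.eval_strain or self.eval_strain == 0):
            if self.finite_difference_step <= 0:
                raise InvalidParameterError("finite_difference_step must be > 0")
        sv = tuple(self.strain_values)
        if any(s < 0 for s in sv) or any(b <= a for a, b in zip(sv, sv[1:])):
            raise InvalidParameterError("strain_values must be non-negative and increasing")


@dataclass(frozen=True)
class StiffnessResult:
    """Stiffness of one (mode, p) condition, with per-seed replicates."""

    mode: str
    p_target: float
    p_realized: float
    K: float
    E_curve: tuple[tuple[float, float], ...] = ()   # (gamma, E_min) pairs
    replicate_K: tuple[float, ...] = ()
    replicate_p: tuple[float, ...] = ()
    seeds: tuple[int, ...] = ()
    unstable: bool = False

    @property
    def K_mean(self) -> float:
        return float(np.mean(self.replicate_K)) if self.replicate_K else self.K

    @property
    def K_sd(self) -> float:
        return float(np.std(self.replicate_K, ddof=1)) if len(self.replicate_K) > 1 else 0.0


# ---------------------------------------------------------------------------
# lattice construction


def _node_index(r: int, c: int, n_cols: int) -> tuple[int, int]:
    """Map an unwrapped (row, col) to (node index, x-image shift)."""
    shift, cw = divmod(c, n_cols)
    return r * n_cols + cw, shift


def build_lattice(n_nodes: int = 64, l0: float = 1.0, *, ks: float = 10.0,
                  kb: float = 1.0, lam: float = 1.0) -> LatticeNetwork:
    """Build a fully occupied near-square triangular lattice of ``n_nodes``.

    Nodes are arranged on ``n_rows`` rows of ``n_cols`` columns with
    ``n_cols = round(sqrt(n_nodes))``; the lattice is periodic horizontally
    and open vertically.  All edges are occupied and no cells are placed.
    Collinear bend triples are enumerated for all three fiber directions,
    including across the periodic seam.
    """
    if n_nodes < 12:
        raise InvalidInputError(
            f"lattice needs >= 12 nodes for an interior bend triple, got {n_nodes}")
    n_cols = int(round(math.sqrt(n_nodes)))
    if n_cols < 3:
        raise InvalidInputError("lattice needs >= 3 columns")
    n_rows, rem = divmod(n_nodes, n_cols)
    if rem != 0 or n_rows < 3:
        raise InvalidInputError(
            f"{n_nodes} nodes cannot be arranged on a near-square {n_cols}-column lattice")

    pos = np.empty((n_nodes, 2), dtype=float)
    for r in range(n_rows):
        for c in range(n_cols):
            pos[r * n_cols + c] = ((c + 0.5 * (r % 2)) * l0, r * ROW_HEIGHT * l0)

    edges, e_shifts, e_class = [], [], []
    edge_lookup: dict[tuple[int, int, int], int] = {}

    def add_edge(r1, c1, r2, c2, cls):
        i, si = _node_index(r1, c1, n_cols)
        j, sj = _node_index(r2, c2, n_cols)
        idx = len(edges)
        edges.append((i, j))
        e_shifts.append((si, sj))
        e_class.append(cls)
        # canonical key on wrapped endpoints + relative shift
        edge_lookup[(i, j, sj - si)] = idx
        edge_lookup[(j, i, si - sj)] = idx
        return idx

    for r in range(n_rows):
        rho = r % 2
        for c in range(n_cols):
            add_edge(r, c, r, c + 1, 0)                      # horizontal
            if r + 1 < n_rows:
                add_edge(r, c, r + 1, c + rho, 1)            # up-right diagonal
                add_edge(r, c, r + 1, c - 1 + rho, 2)        # up-left diagonal

    def find_edge(r1, c1, r2, c2):
        i, si = _node_index(r1, c1, n_cols)
        j, sj = _node_index(r2, c2, n_cols)
        return edge_lookup[(i, j, sj - si)]

    triples, t_shifts, t_edges = [], [], []

    def add_triple(rc_i, rc_j, rc_k):
        (ri, ci), (rj, cj), (rk, ck) = rc_i, rc_j, rc_k
        i, si = _node_index(ri, ci, n_cols)
        j, sj = _node_index(rj, cj, n_cols)
        k, sk = _node_index(rk, ck, n_cols)
        triples.append((i, j, k))
        t_shifts.append((si, sj, sk))
        t_edges.append((find_edge(ri, ci, rj, cj), find_edge(rj, cj, rk, ck)))

    for r in range(n_rows):
        rho = r % 2
        for c in range(n_cols):
            add_triple((r, c - 1), (r, c), (r, c + 1))       # along a horizontal fiber
            if 0 < r < n_rows - 1:
                # up-right fiber: ... (r-1, c-1+rho) -> (r, c) -> (r+1, c+rho) ...
                add_triple((r - 1, c - 1 + rho), (r, c), (r + 1, c + rho))
                # up-left fiber:  ... (r-1, c+rho) -> (r, c) -> (r+1, c-1+rho) ...
                add_triple((r - 1, c + rho), (r, c), (r + 1, c - 1 + rho))

    tris, tri_shift_list = [], []

    def add_triangle(*rcs):
        idx, shifts = [], []
        for (r, c) in rcs:
            i, s = _node_index(r, c, n_cols)
            idx.append(i)
            shifts.append(s)
        tris.append(tuple(idx))
        tri_shift_list.append(tuple(shifts))

    for r in range(n_rows - 1):
        rho = r % 2
        for c in range(n_cols):
            if rho == 0:
                add_triangle((r, c), (r, c + 1), (r + 1, c))             # upward
                add_triangle((r, c + 1), (r + 1, c + 1), (r + 1, c))     # downward
            else:
                add_triangle((r, c), (r, c + 1), (r + 1, c + 1))
                add_triangle((r, c), (r + 1, c + 1), (r + 1, c))

    return LatticeNetwork(
        n_rows=n_rows, n_cols=n_cols, l0=l0, positions=pos,
        edges=np.array(edges, dtype=np.intp),
        edge_shifts=np.array(e_shifts, dtype=np.intp),
        edge_class=np.array(e_class, dtype=np.intp),
        edge_occ=np.ones(len(edges), dtype=float),
        triples=np.array(triples, dtype=np.intp),
        triple_shifts=np.array(t_shifts, dtype=np.intp),
        triple_edges=np.array(t_edges, dtype=np.intp),
        triangles=np.array(tris, dtype=np.intp),
        tri_shifts=np.array(tri_shift_list, dtype=np.intp),
        cell_occ=np.zeros(len(tris), dtype=float),
        ks=ks, kb=kb, lam=lam)


# ---------------------------------------------------------------------------
# dilution and cell placement


def _edge_midpoints(net: LatticeNetwork) -> np.ndarray:
    Lx = net.box_width
    pi = net.positions[net.edges[:, 0]].copy()
    pj = net.positions[net.edges[:, 1]].copy()
    pi[:, 0] += net.edge_shifts[:, 0] * Lx
    pj[:, 0] += net.edge_shifts[:, 1] * Lx
    return 0.5 * (pi + pj)


def dilute(net: LatticeNetwork, spec: DilutionSpec) -> LatticeNetwork:
    """Remove edges according to the dilution spec; returns a new network.

    Random mode keeps every edge independently with probability ``p``.
    Patterned mode deletes the edges whose midpoints are nearest the circle
    center, growing the removal radius until the realized occupied fraction
    matches the target within one edge; distance ties are broken by a
    seeded shuffle.  Bend triples containing an unoccupied edge are
    deactivated automatically through the occupancy product.
    """
    rng = np.random.default_rng(spec.seed)
    n_edges = net.edges.shape[0]
    occ = np.ones(n_edges, dtype=float)
    if spec.mode == "random":
        occ = (rng.random(n_edges) < spec.p).astype(float)
    else:
        n_remove = int(round((1.0 - spec.p) * n_edges))
        if n_remove > 0:
            center = np.array(spec.circle_center if spec.circle_center is not None
                              else (net.box_width / 2.0, net.height / 2.0))
            mid = _edge_midpoints(net)
            d = mid - center
            Lx = net.box_width
            d[:, 0] -= Lx * np.round(d[:, 0] / Lx)   # minimum image horizontally
            dist = np.hypot(d[:, 0], d[:, 1])
            # seeded shuffle before a stable sort breaks distance ties randomly
            perm = rng.permutation(n_edges)
            order = perm[np.argsort(dist[perm], kind="stable")]
            removal_radius = dist[order[n_remove - 1]]
            if removal_radius > min(net.box_width, net.height) / 2.0:
                raise GeometryError(
                    f"patterned dilution to p={spec.p} needs a removal circle of radius "
                    f"{removal_radius:.2f}, exceeding the system half-size")
            occ[order[:n_remove]] = 0.0
    return replace(net, edge_occ=occ)


def place_cells(net: LatticeNetwork, n_cells: int, lam: float | None = None,
                seed: int = 0) -> LatticeNetwork:
    """Tag ``n_cells`` distinct lattice triangles, chosen uniformly at
    random (seeded), as area-elastic cells."""
    n_tri = net.triangles.shape[0]
    if n_cells < 0 or n_cells > n_tri:
        raise InvalidInputError(
            f"n_cells={n_cells} must be between 0 and the {n_tri} available triangles")
    rng = np.random.default_rng(seed)
    q = np.zeros(n_tri, dtype=float)
    if n_cells:
        q[rng.choice(n_tri, size=n_cells, replace=False)] = 1.0
    out = replace(net, cell_occ=q)
    if lam is not None:
        out = replace(out, lam=float(lam))
    return out


# ---------------------------------------------------------------------------
# energy, gradient, minimization


def _edge_vectors(net: LatticeNetwork, pos: np.ndarray) -> np.ndarray:
    Lx = net.box_width
    v = pos[net.edges[:, 1]] - pos[net.edges[:, 0]]
    v[:, 0] += (net.edge_shifts[:, 1] - net.edge_shifts[:, 0]) * Lx
    return v


def _triple_vectors(net: LatticeNetwork, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Lx = net.box_width
    i, j, k = net.triples[:, 0], net.triples[:, 1], net.triples[:, 2]
    si, sj, sk = (net.triple_shifts[:, m] for m in range(3))
    a = pos[j] - pos[i]
    a[:, 0] += (sj - si) * Lx
    b = pos[k] - pos[j]
    b[:, 0] += (sk - sj) * Lx
    return a, b


def _triangle_area_terms(net: LatticeNetwork, pos: np.ndarray):
    Lx = net.box_width
    p = [pos[net.triangles[:, m]].copy() for m in range(3)]
    for m in range(3):
        p[m][:, 0] += net.tri_shifts[:, m] * Lx
    e1 = p[1] - p[0]
    e2 = p[2] - p[0]
    signed = 0.5 * (e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    return p, signed


def total_energy(net: LatticeNetwork, positions: np.ndarray | None = None) -> float:
    """Total elastic energy of the network at the given node positions."""
    pos = net.positions if positions is None else np.asarray(positions, dtype=float)
    if pos.shape != net.positions.shape:
        raise InvalidInputError("positions shape mismatch")

    v = _edge_vectors(net, pos)
    lengths = np.hypot(v[:, 0], v[:, 1])
    occ = net.edge_occ
    if np.any(lengths[occ > 0] < 1e-12 * net.l0):
        raise GeometryError("degenerate zero-length occupied edge")
    e_stretch = 0.5 * net.ks * float(occ @ (lengths - net.l0) ** 2)

    a, b = _triple_vectors(net, pos)
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1]
    # delta = pi - theta_ijk: the turning angle between consecutive fiber
    # segments, zero (and smooth) at the straight rest state
    delta = np.arctan2(cross, dot)
    t_occ = net.edge_occ[net.triple_edges[:, 0]] * net.edge_occ[net.triple_edges[:, 1]]
    e_bend = 0.5 * net.kb * float(t_occ @ delta ** 2)

    _, signed = _triangle_area_terms(net, pos)
    areas = np.abs(signed)
    e_cell = net.lam * float(net.cell_occ @ (areas - net.rest_area) ** 2)

    return e_stretch + e_bend + e_cell


def energy_gradient(net: LatticeNetwork, positions: np.ndarray) -> np.ndarray:
    """Analytic gradient of :func:`total_energy` with respect to positions."""
    pos = np.asarray(positions, dtype=float)
    grad = np.zeros_like(pos)

    # stretching
    v = _edge_vectors(net, pos)
    lengths = np.hypot(v[:, 0], v[:, 1])
    safe = np.where(lengths > 0, lengths, 1.0)
    f = (net.ks * net.edge_occ * (lengths - net.l0) / safe)[:, None] * v
    np.add.at(grad, net.edges[:, 1], f)
    np.add.at(grad, net.edges[:, 0], -f)

    # bending: delta = atan2(a x b, a . b)
    a, b = _triple_vectors(net, pos)
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1]
    delta = np.arctan2(cross, dot)
    t_occ = net.edge_occ[net.triple_edges[:, 0]] * net.edge_occ[net.triple_edges[:, 1]]
    denom = cross ** 2 + dot ** 2
    denom = np.where(denom > 0, denom, 1.0)
    w = net.kb * t_occ * delta / denom
    # d delta / d a = (dot * (by, -bx) - cross * (bx, by)) / denom, similarly for b
    dd_a = np.stack([dot * b[:, 1] - cross * b[:, 0],
                     -dot * b[:, 0] - cross * b[:, 1]], axis=1)
    dd_b = np.stack([-dot * a[:, 1] - cross * a[:, 0],
                     dot * a[:, 0] - cross * a[:, 1]], axis=1)
    ga = w[:, None] * dd_a
    gb = w[:, None] * dd_b
    i, j, k = net.triples[:, 0], net.triples[:, 1], net.triples[:, 2]
    np.add.at(grad, i, -ga)
    np.add.at(grad, j, ga - gb)
    np.add.at(grad, k, gb)

    # cell areas
    p, signed = _triangle_area_terms(net, pos)
    areas = np.abs(signed)
    sgn = np.where(signed >= 0, 1.0, -1.0)
    coef = 2.0 * net.lam * net.cell_occ * (areas - net.rest_area) * sgn * 0.5
    p1, p2, p3 = p
    dA1 = np.stack([p2[:, 1] - p3[:, 1], p3[:, 0] - p2[:, 0]], axis=1)
    dA2 = np.stack([p3[:, 1] - p1[:, 1], p1[:, 0] - p3[:, 0]], axis=1)
    dA3 = np.stack([p1[:, 1] - p2[:, 1], p2[:, 0] - p1[:, 0]], axis=1)
    np.add.at(grad, net.triangles[:, 0], coef[:, None] * dA1)
    np.add.at(grad, net.triangles[:, 1], coef[:, None] * dA2)
    np.add.at(grad, net.triangles[:, 2], coef[:, None] * dA3)

    return grad


def minimize_energy(net: LatticeNetwork, gamma: float,
                    start_positions: np.ndarray | None = None,
                    tol: float = 1e-8, max_iterations: int = 20000,
                    ) -> tuple[np.ndarray, float]:
    """Relax the network at uniaxial compressive strain ``gamma``.

    Top- and bottom-row nodes are displacement-controlled vertically (the
    height change is ``gamma * H0``) but free to slide horizontally; all
    other degrees of freedom are relaxed by L-BFGS with the analytic
    gradient.  ``start_positions`` supports strain continuation: the
    initial guess is that state rescaled affinely to the new height.
    """
    if gamma < 0:
        raise InvalidParameterError("strain must be >= 0")
    rest = net.positions
    H0 = net.height
    y0_bottom = 0.0

    base = rest if start_positions is None else np.asarray(start_positions, dtype=float)
    pos0 = base.copy()
    # affine vertical rescale onto the new prescribed height
    pos0[:, 1] = y0_bottom + (base[:, 1] - y0_bottom) * (1.0 - gamma) / (
        1.0 - _implied_strain(net, base))

    fixed_y = np.zeros(net.n_nodes, dtype=bool)
    fixed_y[net.bottom_nodes] = True
    fixed_y[net.top_nodes] = True
    pos0[net.bottom_nodes, 1] = 0.0
    pos0[net.top_nodes, 1] = H0 * (1.0 - gamma)

    free_mask = np.ones((net.n_nodes, 2), dtype=bool)
    free_mask[:, 1] = ~fixed_y
    flat_free = free_mask.ravel()

    work = pos0.copy()

    def fun(x):
        work.ravel()[flat_free] = x
        e = total_energy(net, work)
        g = energy_gradient(net, work)
        return e, g.ravel()[flat_free]

    x0 = pos0.ravel()[flat_free]
    res = _scipy_minimize(fun, x0, jac=True, method="L-BFGS-B",
                          options={"maxiter": max_iterations, "ftol": 1e-16,
                                   "gtol": tol, "maxcor": 30})
    work.ravel()[flat_free] = res.x
    e_min = total_energy(net, work)
    g_norm = float(np.abs(energy_gradient(net, work).ravel()[flat_free]).max()) \
        if res.x.size else 0.0
    if g_norm > max(100.0 * tol, 1e-6):
        raise MinimizationError(
            f"relaxation at strain {gamma} stalled (grad inf-norm {g_norm:.2e})",
            diagnostics={"grad_norm": g_norm, "energy": e_min, "nit": res.nit})
    return work, float(e_min)


def _implied_strain(net: LatticeNetwork, pos: np.ndarray) -> float:
    """Compressive strain implied by the current top-row height."""
    H0 = net.height
    y_top = pos[net.top_nodes, 1].mean()
    return float(1.0 - y_top / H0)


def compute_stiffness(net: LatticeNetwork,
                      protocol: CompressionProtocol = CompressionProtocol(),
                      ) -> StiffnessResult:
    """Stiffness K = (1/A_sys) d^2 E_min / d gamma^2 by central differences.

    The three strains ``eval_strain -/0/+ finite_difference_step`` are
    relaxed with continuation from zero strain; extra ``strain_values`` are
    appended to the reported energy curve.  ``A_sys`` is the undeformed
    system area, making K intensive (simulation units: kb / l0^2 per unit
    area with l0 = 1).
    """
    ge, dg = protocol.eval_strain, protocol.finite_difference_step
    if 0.0 < ge < dg:
        dg = ge   # keep the central stencil symmetric and non-negative
    fd_strains = [max(ge - dg, 0.0), ge, ge + dg]
    all_strains = sorted(set(fd_strains) | set(protocol.strain_values))

    energies: dict[float, float] = {}
    pos = None
    # strain continuation in small steps up to the largest requested strain
    schedule: list[float] = []
    prev = 0.0
    for g in all_strains:
        while g - prev > 5e-3 + 1e-12:
            prev = prev + 5e-3
            schedule.append(prev)
        schedule.append(g)
        prev = g
    for g in schedule:
        pos, e = minimize_energy(net, g, start_positions=pos,
                                 tol=protocol.minimizer_tolerance,
                                 max_iterations=protocol.max_iterations)
        energies[g] = e

    e_m, e_0, e_p = (energies[g] for g in fd_strains)
    if fd_strains[0] == fd_strains[1]:   # eval at gamma = 0: forward-style second difference
        k_raw = 2.0 * (e_p - e_0) / dg ** 2
    else:
        k_raw = (e_p - 2.0 * e_0 + e_m) / dg ** 2
    K = k_raw / net.system_area
    unstable = K < -1e-8
    if unstable:
        warnings.warn(f"negative stiffness K={K:.3e}: numerical instability",
                      RuntimeWarning, stacklevel=2)
    curve = tuple(sorted((g, energies[g]) for g in all_strains))
    return StiffnessResult(mode="", p_target=net.occupied_fraction,
                           p_realized=net.occupied_fraction, K=float(K),
                           E_curve=curve, unstable=bool(unstable))


# ---------------------------------------------------------------------------
# sweeps and comparisons


def _single_replicate(n_nodes: int, n_cells: int, ks: float, kb: float,
                      lam: float, mode: str, p: float, seed: int,
                      protocol: CompressionProtocol) -> tuple[float, float]:
    net = build_lattice(n_nodes, ks=ks, kb=kb, lam=lam)
    rng = np.random.default_rng(seed)
    dilution_seed = int(rng.integers(2 ** 31))
    cell_seed = int(rng.integers(2 ** 31))
    net = dilute(net, DilutionSpec(mode=mode, p=p, seed=dilution_seed))
    net = place_cells(net, n_cells, seed=cell_seed)
    res = compute_stiffness(net, protocol)
    return res.K, net.occupied_fraction


def stiffness_vs_p_sweep(p_values: Sequence[float], *, modes=("random", "patterned"),
                         n_nodes: int = 64, n_cells: int = 32, R: float = 10.0,
                         kb: float = 1.0, lam: float = 1.0,
                         seeds: Sequence[int] | int = 20,
                         protocol: CompressionProtocol = CompressionProtocol(),
                         ) -> pd.DataFrame:
    """Replicate-averaged stiffness K(p) for each dilution mode.

    Defaults follow the study configuration: a 64-node lattice with 32
    cells and stretch/bend ratio R = 10 (kb = 1, so ks = R).  Returns a
    tidy frame with one row per (mode, p, seed).
    """
    if isinstance(seeds, int):
        seeds = list(range(seeds))
    ks = R * kb  # l0 = 1
    rows = []
    for mode in modes:
        for p in p_values:
            for seed in seeds:
                K, p_real = _single_replicate(n_nodes, n_cells, ks, kb, lam,
                                              mode, p, int(seed), protocol)
                rows.append({"mode": mode, "p_target": p, "p_realized": p_real,
                             "seed": int(seed), "K": K})
    return pd.DataFrame(rows)


def summarize_sweep(sweep: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD stiffness per (mode, p) from a sweep frame."""
    g = sweep.groupby(["mode", "p_target"])["K"]
    out = g.agg(K_mean="mean", K_sd="std", n_seeds="count").reset_index()
    out["K_sd"] = out["K_sd"].fillna(0.0)
    return out


def patterned_vs_random_comparison(p_patterned: float = 0.85,
                                   p_random: float = 0.95, *,
                                   n_nodes: int = 64, n_cells: int = 32,
                                   R: float = 10.0, kb: float = 1.0,
                                   lam: float = 1.0,
                                   seeds: Sequence[int] | int = 20,
                                   protocol: CompressionProtocol = CompressionProtocol(),
                                   ) -> dict:
    """Relative stiffness change from patterned dilution at ``p_patterned``
    to random dilution at ``p_random``.

    Returns mean K per condition and the relative increase
    ``(K_random - K_patterned) / K_patterned`` as a fraction.
    """
    if isinstance(seeds, int):
        seeds = list(range(seeds))
    ks = R * kb
    K_pat, K_rand = [], []
    for seed in seeds:
        kp, _ = _single_replicate(n_nodes, n_cells, ks, kb, lam,
                                  "patterned", p_patterned, int(seed), protocol)
        kr, _ = _single_replicate(n_nodes, n_cells, ks, kb, lam,
                                  "random", p_random, int(seed), protocol)
        K_pat.append(kp)
        K_rand.append(kr)
    K_pat, K_rand = np.array(K_pat), np.array(K_rand)
    rel = (K_rand.mean() - K_pat.mean()) / K_pat.mean()
    return {"p_patterned": p_patterned, "p_random": p_random,
            "K_patterned_mean": float(K_pat.mean()), "K_patterned_sd": float(K_pat.std(ddof=1)),
            "K_random_mean": float(K_rand.mean()), "K_random_sd": float(K_rand.std(ddof=1)),
            "relative_increase": float(rel), "n_seeds": len(K_pat)}
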