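"""Self-stress form finding and geometrically nonlinear statics of the
tensegrity cytoskeleton.

A tensegrity is a mechanism without prestress: the 6-strut/24-cable graph has
a one-dimensional self-stress space (found here as the null space of the nodal
equilibrium matrix in the force-density variable) which must be activated for
the structure to carry load.  :func:`apply_prestress` scales that self-stress
to a chosen cable prestrain and stores the corresponding member rest lengths;
:func:`solve_static` then solves the geometrically nonlinear equilibrium under
prescribed displacements and point loads with an incremental Newton-Raphson
scheme.  Cables are bilinear (linear in tension, zero force and stiffness when
slack); struts stay linear in both tension and compression -- Euler buckling
is not modelled, only flagged through :class:`StrutBucklingWarning`.

Units: um, MPa, uN (1 MPa*um^2 = 1 uN).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .geometry import TensegrityGraph, validate_topology
from .materials import ParameterError

__all__ = [
    "SingularSystemError",
    "NoSelfStressError",
    "StrutBucklingWarning",
    "EmptyLoadWarning",
    "SolverSettings",
    "SelfStressState",
    "BoundaryConditions",
    "EquilibriumSolution",
    "find_selfstress",
    "apply_prestress",
    "solve_static",
    "indentation_sweep",
    "aspiration_load",
    "strain_energy",
    "tangent_stiffness",
    "internal_forces",
]


class SingularSystemError(RuntimeError):
    """Tangent system is singular (mechanism motion without prestress or
    regularization)."""


class NoSelfStressError(RuntimeError):
    """The equilibrium matrix has no null space: the topology cannot carry a
    self-stress (corrupted graph)."""


class StrutBucklingWarning(UserWarning):
    """A strut compression exceeds its Euler-type force floor; buckling is not
    modelled, forces are reported as if the strut stayed straight."""


class EmptyLoadWarning(UserWarning):
    """An aspiration load found no junction node inside the pipette radius."""


@dataclass
class SolverSettings:
    """Newton-Raphson settings.  ``newton_tol`` is the infinity norm of the
    nodal residual in uN; ``regularization`` adds a small stiffness floor
    (uN/um) on the free DOFs for fully slack configurations."""

    n_increments: int = 50
    newton_tol: float = 1e-10
    max_newton_iter: int = 60
    cable_model: str = "slack_bilinear"
    regularization: float = 0.0

    def __post_init__(self) -> None:
        if not self.newton_tol > 0:
            raise ParameterError("newton_tol must be positive")
        if self.cable_model != "slack_bilinear":
            raise ParameterError(f"unknown cable model {self.cable_model!r}")


@dataclass
class SelfStressState:
    """A self-equilibrated member force pattern.

    ``force_density`` (uN/um, signed: + tension, - compression) is normalized
    so the cable entries average +1; ``member_force`` = density * length.
    """

    force_density: np.ndarray
    member_force: np.ndarray
    prestrain_scale: float = 1.0


@dataclass
class BoundaryConditions:
    """Per-node constraints and loads.

    ``fixed_nodes`` maps node index -> (lock_x, lock_y, lock_z) at zero
    displacement; ``prescribed_displacements`` maps node -> per-axis
    displacement in um with ``None`` for free axes; ``point_loads`` maps
    node -> force vector in uN.  A node axis may not be both load-driven and
    displacement-driven.
    """

    fixed_nodes: Dict[int, Tuple[bool, bool, bool]] = field(default_factory=dict)
    prescribed_displacements: Dict[int, tuple] = field(default_factory=dict)
    point_loads: Dict[int, np.ndarray] = field(default_factory=dict)

    def dof_arrays(self, n_nodes: int):
        """Flatten to (mask, displacement, load) arrays of length 3*n_nodes."""
        mask = np.zeros(3 * n_nodes, dtype=bool)
        disp = np.zeros(3 * n_nodes)
        load = np.zeros(3 * n_nodes)
        for n, locks in self.fixed_nodes.items():
            for a, locked in enumerate(locks):
                if locked:
                    mask[3 * n + a] = True
        for n, d in self.prescribed_displacements.items():
            for a, val in enumerate(d):
                if val is not None:
                    mask[3 * n + a] = True
                    disp[3 * n + a] = float(val)
        for n, f in self.point_loads.items():
            f = np.asarray(f, dtype=float)
            for a in range(3):
                if f[a] != 0.0 and mask[3 * n + a]:
                    raise ParameterError(
                        f"node {n} axis {a} is both load-driven and displacement-driven"
                    )
            load[3 * n: 3 * n + 3] += f
        return mask, disp, load


@dataclass
class EquilibriumSolution:
    """Converged (or flagged) static state: node positions (um), member forces
    (uN, + tension), support reactions (uN) at constrained nodes."""

    positions: np.ndarray
    member_forces: np.ndarray
    reactions: Dict[int, np.ndarray]
    converged: bool
    iterations: int
    residual_norm: float

    def displacements(self, graph: TensegrityGraph) -> np.ndarray:
        return self.positions - graph.nodes


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def _member_data(g: TensegrityGraph):
    conn = np.array(g.members, dtype=int)
    EA = g.member_EA()
    cable = g.is_cable()
    L0 = g.rest_lengths if g.rest_lengths is not None else g.lengths()
    return conn, EA, cable, np.asarray(L0, dtype=float)


def _axial_forces(x, conn, EA, cable, L0):
    d = x[conn[:, 1]] - x[conn[:, 0]]
    L = np.linalg.norm(d, axis=1)
    n = d / L[:, None]
    N = EA * (L - L0) / L0
    slack = cable & (N < 0.0)
    N = np.where(slack, 0.0, N)
    return N, L, n, slack


def _assemble(x, conn, EA, cable, L0, with_K=True):
    """Internal nodal forces (member pull on each node) and tangent stiffness."""
    N, L, n, slack = _axial_forces(x, conn, EA, cable, L0)
    nn = x.size
    fint = np.zeros(nn)
    for m, (i, j) in enumerate(conn):
        f = N[m] * n[m]
        fint[3 * i: 3 * i + 3] += f
        fint[3 * j: 3 * j + 3] -= f
    K = None
    if with_K:
        K = np.zeros((nn, nn))
        I3 = np.eye(3)
        for m, (i, j) in enumerate(conn):
            proj = np.outer(n[m], n[m])
            k_mat = 0.0 if slack[m] else EA[m] / L0[m]
            B = k_mat * proj + (N[m] / L[m]) * (I3 - proj)
            si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
            K[si, si] += B
            K[sj, sj] += B
            K[si, sj] -= B
            K[sj, si] -= B
    return fint, K, N


def internal_forces(g: TensegrityGraph, positions: Optional[np.ndarray] = None) -> np.ndarray:
    """Member axial forces (uN) at the given (default: built) positions."""
    conn, EA, cable, L0 = _member_data(g)
    x = g.nodes if positions is None else positions
    N, _, _, _ = _axial_forces(np.asarray(x, dtype=float), conn, EA, cable, L0)
    return N


def strain_energy(g: TensegrityGraph, positions: Optional[np.ndarray] = None) -> float:
    """Total strain energy (uN*um) with slack cables storing none."""
    conn, EA, cable, L0 = _member_data(g)
    x = g.nodes if positions is None else positions
    d = x[conn[:, 1]] - x[conn[:, 0]]
    L = np.linalg.norm(d, axis=1)
    e = L - L0
    e = np.where(cable & (e < 0.0), 0.0, e)
    return float(0.5 * np.sum(EA / L0 * e**2))


def tangent_stiffness(g: TensegrityGraph, positions: Optional[np.ndarray] = None) -> np.ndarray:
    """Assembled material + geometric tangent stiffness (3n x 3n, uN/um)."""
    conn, EA, cable, L0 = _member_data(g)
    x = g.nodes if positions is None else positions
    _, K, _ = _assemble(np.asarray(x, dtype=float), conn, EA, cable, L0)
    return K


# ---------------------------------------------------------------------------
# form finding and prestress
# ---------------------------------------------------------------------------


def find_selfstress(g: TensegrityGraph, tol: float = 1e-10) -> SelfStressState:
    """Self-stress of the graph as the null space of the equilibrium matrix.

    The nodal equilibrium in the force-density variable q reads
    ``sum_m q_m (x_j - x_i) = 0`` at every node i; its matrix null space gives
    the self-stress modes.  For the expanded-octahedron topology this space is
    one-dimensional with force-density ratio strut:cable = -3/2 and member
    force ratio ``|F_strut| / |F_cable| = sqrt(6)``.
    """
    report = validate_topology(g)
    if not report.ok:
        raise NoSelfStressError(f"invalid topology: {report.violations}")
    conn = np.array(g.members, dtype=int)
    x = g.nodes
    A = np.zeros((3 * g.n_nodes, g.n_members))
    for m, (i, j) in enumerate(conn):
        d = x[j] - x[i]
        A[3 * i: 3 * i + 3, m] = d
        A[3 * j: 3 * j + 3, m] = -d
    _, s, Vt = np.linalg.svd(A)
    null_mask = s < tol * s[0]
    n_null = int(null_mask.sum()) + (A.shape[1] - len(s))
    if n_null == 0:
        raise NoSelfStressError("equilibrium matrix has trivial null space")
    q = Vt[len(s) - int(null_mask.sum()):][0] if null_mask.any() else Vt[-1]
    cable = g.is_cable()
    scale = q[cable].mean()
    if scale == 0.0:
        raise NoSelfStressError("null-space vector carries no cable force density")
    q = q / scale
    L = g.lengths()
    return SelfStressState(force_density=q, member_force=q * L)


def apply_prestress(
    g: TensegrityGraph,
    s: Optional[SelfStressState] = None,
    cable_prestrain: float = 0.01,
) -> TensegrityGraph:
    """Return a copy of ``g`` whose rest lengths carry the self-stress scaled
    to the given cable prestrain.

    Member rest lengths are ``L0 = L / (1 + F / (E A))`` with F the scaled
    self-stress forces, so re-solving with no external load reproduces the
    built geometry exactly.  The default prestrain 0.01 reflects that some
    prestress is mandatory (the unstressed graph is a mechanism); its
    magnitude is a modelling choice reported in all outputs.
    """
    if cable_prestrain < 0:
        raise ParameterError("cable_prestrain must be non-negative")
    if s is None:
        s = find_selfstress(g)
    out = g.copy()
    L = g.lengths()
    EA = g.member_EA()
    if cable_prestrain == 0.0:
        out.rest_lengths = L.copy()
        out.prestress_forces = np.zeros_like(L)
        return out
    cable = g.is_cable()
    target_cable_force = g.E_cable * g.area_cable * cable_prestrain
    scale = target_cable_force / s.member_force[cable].mean()
    N = s.member_force * scale
    out.rest_lengths = L / (1.0 + N / EA)
    out.prestress_forces = N

    # Euler-type floor for a solid circular strut: P_cr = pi^2 E I / L^2,
    # I = A^2 / (4 pi).  Real microtubules buckle far below the axial strength.
    I_strut = g.area_strut**2 / (4.0 * math.pi)
    P_cr = math.pi**2 * g.E_strut * I_strut / L[~cable].max() ** 2
    if np.any(-N[~cable] > P_cr):
        warnings.warn(
            f"strut prestress compression exceeds the Euler force floor "
            f"({P_cr:.3g} uN); buckling is not modelled",
            StrutBucklingWarning,
            stacklevel=2,
        )
    return out


# ---------------------------------------------------------------------------
# nonlinear statics
# ---------------------------------------------------------------------------


def _lin_solve(Kff, rhs, allow_reg: bool):
    """Newton direction; near critical points of a prestressed path (slack-
    cable mechanisms, strut-compression buckling of the symmetric branch) the
    tangent can be momentarily singular, in which case a small Tikhonov shift
    is added.  Without prestress the singularity is a true mechanism and is
    raised."""
    singular = False
    try:
        du = np.linalg.solve(Kff, rhs)
        if not np.all(np.isfinite(du)):
            singular = True
    except np.linalg.LinAlgError:
        singular = True
    if not allow_reg:
        # an unprestressed tensegrity is a mechanism: its tangent is singular
        # (or numerically indistinguishable from singular)
        if singular or np.linalg.cond(Kff) > 1e12:
            raise SingularSystemError(
                "singular tangent system: mechanism motion without prestress "
                "or regularization"
            )
        return du
    if not singular:
        return du
    reg = 1e-8 * max(abs(np.trace(Kff)) / Kff.shape[0], 1e-12)
    for _ in range(8):
        try:
            du = np.linalg.solve(Kff + reg * np.eye(Kff.shape[0]), rhs)
            if np.all(np.isfinite(du)):
                return du
        except np.linalg.LinAlgError:
            pass
        reg *= 100.0
    raise SingularSystemError("tangent system unsolvable even with regularization")


def _newton(x_init, conn, EA, cable, L0, mask, target_x, f_ext, settings, allow_reg=True):
    """Solve nodal equilibrium at fixed constraints; returns (x, N, fint,
    converged, iterations, residual)."""
    x = x_init.copy().reshape(-1)
    x[mask] = target_x[mask]
    free = ~mask
    iters = 0
    fint, K, N = _assemble(x.reshape(-1, 3), conn, EA, cable, L0)
    r = f_ext + fint
    rn = np.abs(r[free]).max() if free.any() else 0.0
    while rn > settings.newton_tol and iters < settings.max_newton_iter:
        Kff = K[np.ix_(free, free)]
        if settings.regularization > 0.0:
            Kff = Kff + settings.regularization * np.eye(Kff.shape[0])
        du = _lin_solve(Kff, r[free], allow_reg or settings.regularization > 0.0)
        # line search with step halving
        alpha, best = 1.0, None
        for _ in range(10):
            x_try = x.copy()
            x_try[free] += alpha * du
            fint_t, K_t, N_t = _assemble(x_try.reshape(-1, 3), conn, EA, cable, L0)
            r_t = f_ext + fint_t
            rn_t = np.abs(r_t[free]).max()
            if best is None or rn_t < best[0]:
                best = (rn_t, x_try, fint_t, K_t, N_t, r_t)
            if rn_t < rn:
                break
            alpha *= 0.5
        rn, x, fint, K, N, r = best
        iters += 1
    return x.reshape(-1, 3), N, fint, rn <= settings.newton_tol, iters, r


def solve_static(
    g: TensegrityGraph,
    bc: BoundaryConditions,
    settings: Optional[SolverSettings] = None,
) -> EquilibriumSolution:
    """Incremental Newton-Raphson static solve under the given boundary
    conditions.  Loads and prescribed displacements are ramped over
    ``settings.n_increments`` equal increments; each increment is iterated to
    ``newton_tol``.  Cable forces are clipped at zero (slack)."""
    settings = settings or SolverSettings()
    conn, EA, cable, L0 = _member_data(g)
    allow_reg = g.rest_lengths is not None
    mask, disp, load = bc.dof_arrays(g.n_nodes)
    x0 = g.nodes.reshape(-1)
    x = g.nodes.copy()
    total_iters = 0
    converged = True
    N = internal_forces(g)
    r = np.zeros_like(x0)
    fint = None
    for inc in range(1, settings.n_increments + 1):
        lam = inc / settings.n_increments
        target = x0 + lam * disp
        x, N, fint, ok, iters, r = _newton(
            x, conn, EA, cable, L0, mask, target, lam * load, settings, allow_reg
        )
        total_iters += iters
        if not ok:
            converged = False
            break
    if fint is None:  # settings.n_increments == 0 degenerate guard
        fint, _, N = _assemble(x, conn, EA, cable, L0, with_K=False)
        r = load + fint
    reactions: Dict[int, np.ndarray] = {}
    for node in range(g.n_nodes):
        sl = slice(3 * node, 3 * node + 3)
        if mask[sl].any():
            rx = np.where(mask[sl], -r[sl], 0.0)
            reactions[node] = rx
    free = ~mask
    residual = float(np.abs(r[free]).max()) if free.any() else 0.0
    return EquilibriumSolution(
        positions=x,
        member_forces=N,
        reactions=reactions,
        converged=converged,
        iterations=total_iters,
        residual_norm=residual,
    )


# ---------------------------------------------------------------------------
# virtual-experiment boundary conditions
# ---------------------------------------------------------------------------


def _lowest_nodes(g: TensegrityGraph, k: int = 4, axis: int = 2):
    order = np.argsort(g.nodes[:, axis], kind="stable")
    return [int(n) for n in order[:k]]


def default_support(g: TensegrityGraph, n_support: int = 4) -> Dict[int, tuple]:
    """Fully fix the ``n_support`` lowest junctions, mimicking focal adhesion
    sites of a substrate-adherent cell."""
    return {n: (True, True, True) for n in _lowest_nodes(g, n_support)}


def indentation_sweep(
    g: TensegrityGraph,
    delta_max: float,
    n_steps: int = 50,
    bc_base: Optional[BoundaryConditions] = None,
    settings: Optional[SolverSettings] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Quasi-static indentation of the cytoskeleton by a rigid plane.

    The contact plane starts at the highest junction and descends by ``delta``;
    every junction crossed by the plane has its axial coordinate prescribed to
    the plane (transverse motion stays free).  Returns ``(delta_um, force_uN)``
    including the trivial (0, 0) sample; the force is the total axial reaction
    the displaced junctions exert on the plane.
    """
    if not delta_max > 0:
        raise ParameterError("delta_max must be positive")
    settings = settings or SolverSettings()
    if g.rest_lengths is None and settings.regularization == 0.0:
        raise ParameterError(
            "indentation requires a prestressed graph (apply_prestress) or a "
            "regularization floor"
        )
    conn, EA, cable, L0 = _member_data(g)
    fixed = (bc_base.fixed_nodes if bc_base is not None else None) or default_support(g)
    base_mask, base_disp, base_load = BoundaryConditions(fixed_nodes=fixed).dof_arrays(g.n_nodes)
    if bc_base is not None and bc_base.point_loads:
        _, _, base_load = bc_base.dof_arrays(g.n_nodes)

    z0 = g.nodes[:, 2]
    z_top = z0.max()
    x0 = g.nodes.reshape(-1)
    deltas = np.linspace(0.0, delta_max, n_steps + 1)
    forces = np.zeros_like(deltas)
    x = g.nodes.copy()
    for k, d in enumerate(deltas[1:], start=1):
        plane = z_top - d
        engaged = np.where(z0 > plane + 1e-12)[0]
        mask = base_mask.copy()
        target = x0.copy()
        for n in engaged:
            # engaged junctions ride with the indenter: displaced straight
            # down to the plane, no transverse slip
            mask[3 * n: 3 * n + 3] = True
            target[3 * n + 2] = plane
        x, N, fint, ok, iters, r = _newton(
            x, conn, EA, cable, L0, mask, target, base_load, settings,
            g.rest_lengths is not None,
        )
        if not ok:
            raise SingularSystemError(f"indentation increment {k} did not converge")
        # indenter force = sum of axial member pull at the engaged junctions
        forces[k] = float(sum(fint[3 * n + 2] for n in engaged))
    return deltas, forces


def aspiration_load(
    g: TensegrityGraph,
    R_p: float,
    dP: float,
    axis: int = 2,
) -> BoundaryConditions:
    """Boundary conditions for micropipette aspiration along ``axis``.

    Junctions whose radial distance from the pipette axis is below ``R_p`` on
    the aspirated (+axis) side share the total suction force
    ``dP * pi * R_p**2`` equally as axial point loads; the four lowest
    junctions on the opposite side are fully fixed (the pole resting against
    the support).
    """
    if not R_p > 0:
        raise ParameterError("R_p must be positive")
    other = [a for a in range(3) if a != axis]
    r = np.linalg.norm(g.nodes[:, other], axis=1)
    inside = np.where((r < R_p) & (g.nodes[:, axis] > 0))[0]
    loads: Dict[int, np.ndarray] = {}
    if len(inside) == 0:
        warnings.warn(
            f"no junction inside the pipette radius {R_p} um; cytoskeleton "
            "carries no aspiration load",
            EmptyLoadWarning,
            stacklevel=2,
        )
    elif dP != 0.0:
        total = dP * math.pi * R_p**2
        per_node = total / len(inside)
        for n in inside:
            f = np.zeros(3)
            f[axis] = per_node
            loads[int(n)] = f
    fixed = {n: (True, True, True) for n in _lowest_nodes(g, 4, axis=axis)}
    return BoundaryConditions(fixed_nodes=fixed, point_loads=loads)
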