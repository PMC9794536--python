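"""Cell geometry and the 6-strut / 24-cable tensegrity cytoskeleton graph.

The cytoskeleton is the classic expanded-octahedron ("Jessen icosahedron")
tensegrity: 12 nodes at the cyclic sign permutations of ``(0, +-1, +-2)``
scaled by ``u = R_cell / sqrt(5)`` so every node lies on the cell sphere.
Six struts (microtubules, compression) connect the node pairs that differ only
in the sign of their "+-2" coordinate; the 24 edges of length ``sqrt(6) u``
are the cables (actin microfilaments, tension).  All struts have length
``4 u``, all cables ``sqrt(6) u``, giving the cable/strut length ratio
``sqrt(6)/4``.  Each node joins exactly one strut and four cables; these 12
junctions represent the receptor sites where filaments cluster at adhesion
complexes.

Two reference orientations are provided: ``config1`` has one strut pair
parallel to the loading (z) axis with its nodes nearest the poles; ``config2``
is ``config1`` rotated 45 degrees about a transverse (x) axis, which changes
which junctions face the indenter or pipette.  (A rotation about the loading
axis itself would leave both axisymmetric virtual experiments exactly
invariant, so it cannot distinguish orientations.)  An arbitrary extra
``rotation`` can be supplied to explore other dispositions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .materials import CellMaterialSet, ParameterError

__all__ = [
    "CellGeometry",
    "TensegrityGraph",
    "TopologyReport",
    "build_tensegrity",
    "validate_topology",
    "spherical_cap_contact",
    "write_obj",
    "write_vtk",
    "write_edge_tsv",
    "save_graph_json",
    "load_graph_json",
]

# unscaled Jessen-icosahedron vertices: cyclic sign permutations of (0, 1, 2)
_RAW_NODES = np.array(
    [
        (0, 1, 2), (0, 1, -2), (0, -1, 2), (0, -1, -2),
        (2, 0, 1), (-2, 0, 1), (2, 0, -1), (-2, 0, -1),
        (1, 2, 0), (1, -2, 0), (-1, 2, 0), (-1, -2, 0),
    ],
    dtype=float,
)

# struts join the pairs differing only in the sign of the "+-2" coordinate
_STRUTS = ((0, 1), (2, 3), (4, 5), (6, 7), (8, 9), (10, 11))


def _find_cables() -> tuple:
    d2 = ((_RAW_NODES[:, None, :] - _RAW_NODES[None, :, :]) ** 2).sum(axis=-1)
    cables = [(i, j) for i in range(12) for j in range(i + 1, 12) if abs(d2[i, j] - 6.0) < 1e-12]
    assert len(cables) == 24
    return tuple(cables)


_CABLES = _find_cables()

#: default cross sections, um^2 (190 nm^2 microtubule strut, 18 nm^2 actin cable)
AREA_STRUT_UM2 = 190e-6
AREA_CABLE_UM2 = 18e-6


def spherical_cap_contact(R_cell: float, height: float) -> float:
    """Contact radius of a sphere of radius ``R_cell`` truncated to ``height``.

    For an adherent cell of height ``h`` the substrate plane cuts the sphere at
    distance ``|h - R|`` from the centre, so the contact radius is
    ``sqrt(R^2 - (h - R)^2)``.  Valid for ``0 < height <= 2 R_cell``.
    """
    if not R_cell > 0:
        raise ParameterError(f"R_cell must be positive, got {R_cell}")
    if not 0.0 < height <= 2.0 * R_cell:
        raise ParameterError(f"height must lie in (0, 2*R_cell], got {height}")
    return math.sqrt(R_cell**2 - (height - R_cell) ** 2)


@dataclass(frozen=True)
class CellGeometry:
    """Overall cell geometry: 16 um diameter sphere, adherent height ~14 um,
    nucleus ellipsoid with 8 um major / 5 um minor axis, 6 nm membrane."""

    R_cell: float = 8.0
    height: float = 14.0
    contact_radius: Optional[float] = None
    nucleus_semiaxes: tuple = (4.0, 4.0, 2.5)
    membrane_thickness: float = 0.006

    def __post_init__(self) -> None:
        if not self.R_cell > 0:
            raise ParameterError("R_cell must be positive")
        if not 0.0 < self.height <= 2.0 * self.R_cell:
            raise ParameterError("height must lie in (0, 2*R_cell]")
        if self.contact_radius is None:
            object.__setattr__(
                self, "contact_radius", spherical_cap_contact(self.R_cell, self.height)
            )
        elif not self.contact_radius < self.R_cell:
            raise ParameterError("contact_radius must be smaller than R_cell")
        if not self.membrane_thickness < 0.1 * self.R_cell:
            raise ParameterError("membrane thickness must be far smaller than the cell radius")


@dataclass
class TensegrityGraph:
    """The cytoskeleton truss: node positions (um), strut/cable connectivity,
    cross sections (um^2), member moduli (MPa) and optional rest lengths (um).

    ``rest_lengths`` is ``None`` for an as-built (stress-free) graph; the
    solver module sets it when prestress is applied.  Member ordering is
    struts first (6) then cables (24).
    """

    nodes: np.ndarray
    struts: tuple = _STRUTS
    cables: tuple = _CABLES
    area_strut: float = AREA_STRUT_UM2
    area_cable: float = AREA_CABLE_UM2
    E_strut: float = 1.53e4
    E_cable: float = 3.32e4
    rest_lengths: Optional[np.ndarray] = None
    prestress_forces: Optional[np.ndarray] = None
    orientation: str = "config1"

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def members(self) -> tuple:
        return tuple(self.struts) + tuple(self.cables)

    @property
    def n_members(self) -> int:
        return len(self.struts) + len(self.cables)

    def is_cable(self) -> np.ndarray:
        """Boolean mask over members, True for cables."""
        return np.array([False] * len(self.struts) + [True] * len(self.cables))

    def member_EA(self) -> np.ndarray:
        """Axial stiffness E*A per member (uN)."""
        ea_s = self.E_strut * self.area_strut
        ea_c = self.E_cable * self.area_cable
        return np.array([ea_s] * len(self.struts) + [ea_c] * len(self.cables))

    def lengths(self, positions: Optional[np.ndarray] = None) -> np.ndarray:
        x = self.nodes if positions is None else positions
        conn = np.array(self.members)
        d = x[conn[:, 1]] - x[conn[:, 0]]
        return np.linalg.norm(d, axis=1)

    def copy(self) -> "TensegrityGraph":
        return replace(
            self,
            nodes=self.nodes.copy(),
            rest_lengths=None if self.rest_lengths is None else self.rest_lengths.copy(),
            prestress_forces=None
            if self.prestress_forces is None
            else self.prestress_forces.copy(),
        )

    def rotated(self, R: np.ndarray) -> "TensegrityGraph":
        """Graph with all node positions rotated by the 3x3 matrix ``R``."""
        g = self.copy()
        g.nodes = self.nodes @ np.asarray(R, dtype=float).T
        return g


def _rotation_x(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def build_tensegrity(
    R_cell: float,
    orientation: str = "config1",
    *,
    materials: Optional[CellMaterialSet] = None,
    E_strut: float = 1.53e4,
    E_cable: float = 3.32e4,
    area_strut: float = AREA_STRUT_UM2,
    area_cable: float = AREA_CABLE_UM2,
    rotation: Optional[np.ndarray] = None,
) -> TensegrityGraph:
    """Build the 12-node expanded-octahedron tensegrity inscribed in the cell
    sphere of radius ``R_cell`` (um).

    ``materials`` (a :class:`~cytomech.materials.CellMaterialSet`) supplies the
    microtubule/microfilament moduli when given, overriding ``E_strut`` /
    ``E_cable``.  ``rotation`` is an optional extra 3x3 matrix applied after
    the orientation is selected.
    """
    if not R_cell > 0:
        raise ParameterError(f"R_cell must be positive, got {R_cell}")
    if orientation not in ("config1", "config2"):
        raise ParameterError(f"orientation must be 'config1' or 'config2', got {orientation!r}")
    if materials is not None:
        E_strut = materials["microtubule"].elastic.E
        E_cable = materials["microfilament"].elastic.E

    u = R_cell / math.sqrt(5.0)
    nodes = _RAW_NODES * u
    if orientation == "config2":
        nodes = nodes @ _rotation_x(45.0).T
    if rotation is not None:
        nodes = nodes @ np.asarray(rotation, dtype=float).T
    return TensegrityGraph(
        nodes=nodes,
        area_strut=area_strut,
        area_cable=area_cable,
        E_strut=E_strut,
        E_cable=E_cable,
        orientation=orientation,
    )


# ---------------------------------------------------------------------------
# topology validation
# ---------------------------------------------------------------------------


@dataclass
class TopologyReport:
    violations: list

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_topology(g: TensegrityGraph, rel_tol: float = 1e-9) -> TopologyReport:
    """Check counts (12/6/24), per-node degree (1 strut + 4 cables), member
    length uniformity and the sqrt(6)/4 cable/strut length ratio."""
    v: list = []
    if g.n_nodes != 12:
        v.append(f"expected 12 nodes, found {g.n_nodes}")
    if len(g.struts) != 6:
        v.append(f"expected 6 struts, found {len(g.struts)}")
    if len(g.cables) != 24:
        v.append(f"expected 24 cables, found {len(g.cables)}")

    deg_s = np.zeros(g.n_nodes, dtype=int)
    deg_c = np.zeros(g.n_nodes, dtype=int)
    for i, j in g.struts:
        deg_s[i] += 1
        deg_s[j] += 1
    for i, j in g.cables:
        deg_c[i] += 1
        deg_c[j] += 1
    for n in range(g.n_nodes):
        if deg_s[n] != 1:
            v.append(f"node {n}: strut degree {deg_s[n]} != 1")
        if deg_c[n] != 4:
            v.append(f"node {n}: cable degree {deg_c[n]} != 4")

    L = g.lengths()
    Ls = L[: len(g.struts)]
    Lc = L[len(g.struts):]
    if len(Ls) and (Ls.max() - Ls.min()) > rel_tol * Ls.mean():
        v.append(f"strut lengths not uniform: spread {(Ls.max() - Ls.min()):.3e} um")
    if len(Lc) and (Lc.max() - Lc.min()) > rel_tol * Lc.mean():
        v.append(f"cable lengths not uniform: spread {(Lc.max() - Lc.min()):.3e} um")
    if len(Ls) and len(Lc):
        ratio = Lc.mean() / Ls.mean()
        want = math.sqrt(6.0) / 4.0
        if abs(ratio - want) > rel_tol * want:
            v.append(f"cable/strut length ratio {ratio:.12f} != sqrt(6)/4")
    return TopologyReport(violations=v)


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------


def write_obj(g: TensegrityGraph, path) -> None:
    """Wavefront OBJ: nodes as vertices, members as line elements."""
    lines = [f"# cytomech tensegrity ({g.orientation}): 12 nodes, 6 struts, 24 cables"]
    for p in g.nodes:
        lines.append(f"v {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    for i, j in g.members:
        lines.append(f"l {i + 1} {j + 1}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_vtk(g: TensegrityGraph, path) -> None:
    """Legacy-VTK polydata with a member-kind cell scalar (0=strut, 1=cable)."""
    n, m = g.n_nodes, g.n_members
    out = [
        "# vtk DataFile Version 3.0",
        f"cytomech tensegrity {g.orientation}",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} double",
    ]
    out += [f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}" for p in g.nodes]
    out.append(f"LINES {m} {3 * m}")
    out += [f"2 {i} {j}" for i, j in g.members]
    out += [f"CELL_DATA {m}", "SCALARS kind int 1", "LOOKUP_TABLE default"]
    out += ["0"] * len(g.struts) + ["1"] * len(g.cables)
    Path(path).write_text("\n".join(out) + "\n")


def write_edge_tsv(g: TensegrityGraph, path) -> None:
    """Plain TSV edge list: node_i, node_j, kind, length_um."""
    L = g.lengths()
    kinds = ["strut"] * len(g.struts) + ["cable"] * len(g.cables)
    lines = ["node_i\tnode_j\tkind\tlength_um"]
    for (i, j), kind, length in zip(g.members, kinds, L):
        lines.append(f"{i}\t{j}\t{kind}\t{length:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")


def save_graph_json(g: TensegrityGraph, path) -> None:
    """Lossless JSON round-trip format for a graph (used by the CLI)."""
    d = {
        "nodes": g.nodes.tolist(),
        "struts": [list(s) for s in g.struts],
        "cables": [list(c) for c in g.cables],
        "area_strut_um2": g.area_strut,
        "area_cable_um2": g.area_cable,
        "E_strut_MPa": g.E_strut,
        "E_cable_MPa": g.E_cable,
        "rest_lengths_um": None if g.rest_lengths is None else g.rest_lengths.tolist(),
        "orientation": g.orientation,
    }
    Path(path).write_text(json.dumps(d, indent=1))


def load_graph_json(path) -> TensegrityGraph:
    d = json.loads(Path(path).read_text())
    rl = d.get("rest_lengths_um")
    return TensegrityGraph(
        nodes=np.asarray(d["nodes"], dtype=float),
        struts=tuple(tuple(s) for s in d["struts"]),
        cables=tuple(tuple(c) for c in d["cables"]),
        area_strut=float(d["area_strut_um2"]),
        area_cable=float(d["area_cable_um2"]),
        E_strut=float(d["E_strut_MPa"]),
        E_cable=float(d["E_cable_MPa"]),
        rest_lengths=None if rl is None else np.asarray(rl, dtype=float),
        orientation=d.get("orientation", "config1"),
    )
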