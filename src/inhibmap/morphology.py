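"""Passive neuron morphologies: SWC trees, elliptical-to-circular equivalence,
distal-length regressions and explicit spine geometry.

A morphology is a rooted tree of cylindrical sections. Dendritic cross
sections measured by serial EM are typically elliptical; a simulator that
only knows circular cross sections preserves the EM cross-sectional area and
compensates the lost membrane perimeter by scaling the leak-conductance and
capacitance densities of each section (``density_scale``). Dendritic
geometry not measured directly can be predicted from the summed length of
distal dendrites ``R`` through two linear relations fitted to the EM data:

    S(R) = 0.00033258 * R + 0.048097   (cross-sectional area, µm²)
    L(R) = 0.0012661  * R + 1.3206     (circumference, µm)

Spines are modelled explicitly as a thin neck cylinder plus a head cylinder;
with the default geometry (0.5 µm x 0.07 µm neck at 385 Ω·cm) the neck
resistance is 500 MΩ, enough to electrically isolate the head.

Units: µm for lengths and diameters, µm² for areas, Ω·cm for axial
resistivity, MΩ for resistances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "Section",
    "Morphology",
    "MorphometricRelations",
    "SpineGeometry",
    "SWC_TYPE_CODES",
    "read_swc",
    "write_swc",
    "elliptical_equivalent",
    "ellipse_geometry",
    "section_geometry_from_distal_length",
    "attach_spine",
    "neck_resistance",
]

SECTION_KINDS = ("soma", "basal", "apical", "axon", "spine_neck", "spine_head")

#: SWC type codes. 1-4 are the standard dialect; 5/6 are this package's
#: extension for explicitly modelled spine necks and heads.
SWC_TYPE_CODES = {
    "soma": 1,
    "axon": 2,
    "basal": 3,
    "apical": 4,
    "spine_neck": 5,
    "spine_head": 6,
}
_KIND_FROM_CODE = {v: k for k, v in SWC_TYPE_CODES.items()}


class MorphologyError(ValueError):
    """Structural problem in a morphology or SWC file."""


@dataclass
class Section:
    """One cylindrical section of a morphology.

    ``density_scale`` multiplies the membrane leak-conductance and
    capacitance densities so that a circular cylinder carries the same total
    membrane conductance/capacitance per unit length as the elliptical
    original; it is ≥ 1 because the circle minimises perimeter at fixed area.
    ``points`` optionally stores the (x, y, z, radius) polyline the section
    was built from (used for exact SWC round trips and Sholl analysis).
    ``parent_position`` is the attachment point on the parent (0-1).
    """

    id: int
    parent_id: int | None
    kind: str
    length: float
    diameter: float
    density_scale: float = 1.0
    axial_resistivity: float = 100.0
    parent_position: float = 1.0
    points: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in SECTION_KINDS:
            raise MorphologyError(f"unknown section kind {self.kind!r}")
        if not self.length > 0:
            raise MorphologyError(f"section {self.id}: length must be > 0")
        if not self.diameter > 0:
            raise MorphologyError(f"section {self.id}: diameter must be > 0")
        if self.density_scale < 1.0 - 1e-12:
            raise MorphologyError(
                f"section {self.id}: density_scale {self.density_scale} < 1"
            )
        if self.points is not None:
            self.points = np.asarray(self.points, dtype=float)

    @property
    def membrane_area(self) -> float:
        """Effective lateral membrane area, µm² (density scale included)."""
        return math.pi * self.diameter * self.length * self.density_scale


class Morphology:
    """A connected rooted tree of :class:`Section` objects.

    Sections are kept in topological order (parent before child); exactly one
    section is the root (``parent_id is None``). Path distances are measured
    along the tree from the soma centre; by convention the soma section
    itself contributes no length, so everything attached to the soma starts
    at distance 0.
    """

    def __init__(self, sections: Iterable[Section] = (), name: str = "") -> None:
        self.name = name
        self._sections: dict[int, Section] = {}
        self._children: dict[int, list[int]] = {}
        self._root_id: int | None = None
        for sec in sections:
            self.add(sec)

    # -- construction ----------------------------------------------------

    def add(self, section: Section) -> Section:
        if section.id in self._sections:
            raise MorphologyError(f"duplicate section id {section.id}")
        if section.parent_id is None:
            if self._root_id is not None:
                raise MorphologyError("morphology already has a root")
            self._root_id = section.id
        else:
            if section.parent_id not in self._sections:
                raise MorphologyError(
                    f"section {section.id}: parent {section.parent_id} "
                    "not defined yet (parent must precede child)"
                )
            if not 0.0 <= section.parent_position <= 1.0:
                raise MorphologyError(
                    f"section {section.id}: parent_position outside [0, 1]"
                )
        self._sections[section.id] = section
        self._children.setdefault(section.parent_id, []).append(section.id)
        return section

    def next_id(self) -> int:
        return max(self._sections, default=0) + 1

    # -- access ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self._sections)

    def __iter__(self) -> Iterator[Section]:
        return iter(self._sections.values())

    def __getitem__(self, section_id: int) -> Section:
        return self._sections[section_id]

    def __contains__(self, section_id: int) -> bool:
        return section_id in self._sections

    @property
    def root(self) -> Section:
        if self._root_id is None:
            raise MorphologyError("empty morphology has no root")
        return self._sections[self._root_id]

    def children(self, section_id: int | None) -> list[Section]:
        return [self._sections[i] for i in self._children.get(section_id, [])]

    def sections(self, kind: str | None = None) -> list[Section]:
        if kind is None:
            return list(self._sections.values())
        return [s for s in self._sections.values() if s.kind == kind]

    # -- geometry --------------------------------------------------------

    def path_distance(self, section_id: int, position: float = 1.0) -> float:
        """Path distance (µm) from the soma centre to ``position`` along a
        section. Soma sections contribute zero length."""
        sec = self._sections[section_id]
        if sec.kind == "soma":
            return 0.0
        dist = position * sec.length
        while sec.parent_id is not None:
            pos = sec.parent_position
            sec = self._sections[sec.parent_id]
            if sec.kind == "soma":
                break
            dist += pos * sec.length
        return dist

    def total_length(self, kinds: tuple[str, ...] = ("basal", "apical")) -> float:
        return sum(s.length for s in self if s.kind in kinds)

    def validate(self) -> None:
        """Check tree invariants (one root, connectivity, positive geometry)."""
        if self._root_id is None:
            raise MorphologyError("morphology has no root section")
        # connectivity: every section reachable from the root
        seen: set[int] = set()
        stack = [self._root_id]
        while stack:
            sid = stack.pop()
            seen.add(sid)
            stack.extend(self._children.get(sid, []))
        if seen != set(self._sections):
            missing = sorted(set(self._sections) - seen)
            raise MorphologyError(f"sections not connected to root: {missing}")

    def copy(self) -> "Morphology":
        out = Morphology(name=self.name)
        for sec in self:
            pts = None if sec.points is None else sec.points.copy()
            out.add(replace(sec, points=pts))
        return out


# ---------------------------------------------------------------------------
# Elliptical-to-circular equivalence
# ---------------------------------------------------------------------------

def elliptical_equivalent(
    section_area: float, section_circumference: float, rtol: float = 1e-9
) -> tuple[float, float]:
    """Circular-equivalent diameter and membrane density scale.

    Given an elliptical cross section of area ``A`` and circumference ``L``,
    returns the diameter of the circle with the same cross-sectional area,
    ``d = 2·sqrt(A/π)`` (preserving axial resistance), and the factor
    ``L / (π·d)`` by which the circular model's leak-conductance and
    capacitance densities must be multiplied so that the total membrane
    conductance and capacitance per unit length match the ellipse's.
    """
    if not section_area > 0:
        raise ValueError("section_area must be > 0")
    diameter = 2.0 * math.sqrt(section_area / math.pi)
    minimum = math.pi * diameter  # circumference of the equal-area circle
    if section_circumference < minimum * (1.0 - rtol):
        raise ValueError(
            f"circumference {section_circumference:.6g} below the equal-area "
            f"circle's {minimum:.6g}: not a valid ellipse"
        )
    density_scale = max(section_circumference / minimum, 1.0)
    return diameter, density_scale


def ellipse_geometry(semi_major: float, semi_minor: float) -> tuple[float, float]:
    """Area and (Ramanujan-approximate) perimeter of an ellipse, for building
    test geometries: area = π·a·b; perimeter by Ramanujan's second formula."""
    a, b = float(semi_major), float(semi_minor)
    if not (a > 0 and b > 0):
        raise ValueError("semi-axes must be > 0")
    h = (a - b) ** 2 / (a + b) ** 2
    perimeter = math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))
    return math.pi * a * b, perimeter


@dataclass(frozen=True)
class MorphometricRelations:
    """Linear relations predicting dendritic cross-sectional area ``S`` (µm²)
    and circumference ``L`` (µm) from the summed length ``R`` (µm) of the
    dendrites distal to a section, fitted to serial-EM measurements of the
    reconstructed pyramidal cell."""

    s_slope: float = 0.00033258   # µm²/µm
    s_intercept: float = 0.048097  # µm²
    l_slope: float = 0.0012661    # µm/µm
    l_intercept: float = 1.3206   # µm

    def area(self, R: float) -> float:
        return self.s_slope * R + self.s_intercept

    def circumference(self, R: float) -> float:
        return self.l_slope * R + self.l_intercept


def section_geometry_from_distal_length(
    R: float, relations: MorphometricRelations | None = None
) -> tuple[float, float]:
    """Predicted (cross-sectional area µm², circumference µm) of a dendritic
    section carrying ``R`` µm of distal dendrite."""
    if R < 0:
        raise ValueError("summed distal dendritic length R must be >= 0")
    rel = relations or MorphometricRelations()
    return rel.area(R), rel.circumference(R)


# ---------------------------------------------------------------------------
# Spines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpineGeometry:
    """Explicit spine model: neck cylinder (0.5 µm x 0.07 µm, 385 Ω·cm, i.e.
    500 MΩ) and a head cylinder of 0.043 µm³ with length = diameter."""

    neck_length: float = 0.5        # µm
    neck_diameter: float = 0.07     # µm
    head_volume: float = 0.043      # µm³
    spine_axial_resistivity: float = 385.0  # Ω·cm

    @property
    def head_diameter(self) -> float:
        """Diameter of the equal-length/diameter cylinder holding the stated
        head volume: V = π d³ / 4  →  d = (4V/π)^(1/3)."""
        return (4.0 * self.head_volume / math.pi) ** (1.0 / 3.0)

    @property
    def neck_resistance_megaohm(self) -> float:
        return neck_resistance(
            self.neck_length, self.neck_diameter, self.spine_axial_resistivity
        )


def neck_resistance(length: float, diameter: float, resistivity: float) -> float:
    """Axial resistance of a cylinder, MΩ; lengths in µm, resistivity Ω·cm.

    R = 4·Ra·L / (π·d²), the series resistance governing how well a spine
    head is electrically isolated from its parent shaft.
    """
    if not (length > 0 and diameter > 0 and resistivity > 0):
        raise ValueError("length, diameter and resistivity must be > 0")
    r_ohm = 4.0 * resistivity * 1e4 * length / (math.pi * diameter**2)
    return r_ohm / 1e6


def attach_spine(
    m: Morphology,
    parent_section: int,
    position: float,
    geom: SpineGeometry | None = None,
) -> tuple[int, int]:
    """Attach an explicit spine (neck + head) to a dendritic section.

    Modifies ``m`` in place and returns ``(neck_id, head_id)``.
    """
    geom = geom or SpineGeometry()
    if parent_section not in m:
        raise MorphologyError(f"no section {parent_section}")
    parent = m[parent_section]
    if parent.kind not in ("basal", "apical"):
        raise MorphologyError(
            f"spines attach to dendrites, not {parent.kind!r} sections"
        )
    if not 0.0 <= position <= 1.0:
        raise ValueError("position must be within [0, 1]")
    neck_id = m.next_id()
    m.add(
        Section(
            id=neck_id,
            parent_id=parent_section,
            kind="spine_neck",
            length=geom.neck_length,
            diameter=geom.neck_diameter,
            axial_resistivity=geom.spine_axial_resistivity,
            parent_position=position,
        )
    )
    head_id = m.next_id()
    d = geom.head_diameter
    m.add(
        Section(
            id=head_id,
            parent_id=neck_id,
            kind="spine_head",
            length=d,
            diameter=d,
            axial_resistivity=geom.spine_axial_resistivity,
        )
    )
    return neck_id, head_id


# ---------------------------------------------------------------------------
# SWC input/output
# ---------------------------------------------------------------------------

def read_swc(path) -> Morphology:
    """Read a standard 7-column SWC file into a :class:`Morphology`.

    Per-point cylinders are merged into sections at branch points: every
    maximal unbranched run of same-type points becomes one section whose
    polyline is retained in ``Section.points``. The single root point (type
    soma, parent −1) becomes a soma cylinder of equal surface area to the
    SWC sphere (length = diameter = 2·radius). Unknown type codes map to
    ``basal`` with a warning; a child listed before its parent, a missing
    root or a cyclic parent link is a structural error.
    """
    ids: list[int] = []
    rows: dict[int, tuple[int, float, float, float, float, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise MorphologyError(f"{path}:{lineno}: expected 7 columns")
            pid = int(parts[0])
            rows[pid] = (
                int(parts[1]),
                float(parts[2]),
                float(parts[3]),
                float(parts[4]),
                float(parts[5]),
                int(parts[6]),
            )
            ids.append(pid)
    if not rows:
        raise MorphologyError(f"{path}: empty SWC file")

    seen: set[int] = set()
    roots = []
    for pid in ids:
        parent = rows[pid][5]
        if parent == -1:
            roots.append(pid)
        elif parent not in seen:
            raise MorphologyError(
                f"point {pid}: parent {parent} not defined before child "
                "(forward reference or cycle)"
            )
        seen.add(pid)
    if len(roots) != 1:
        raise MorphologyError(f"expected exactly one root point, found {len(roots)}")
    root_pid = roots[0]
    if rows[root_pid][0] != SWC_TYPE_CODES["soma"]:
        raise MorphologyError("root point must be of soma type (code 1)")

    def kind_of(code: int, pid: int) -> str:
        if code not in _KIND_FROM_CODE:
            warnings.warn(
                f"SWC point {pid}: unknown type code {code}, mapping to basal",
                stacklevel=2,
            )
            return "basal"
        return _KIND_FROM_CODE[code]

    children: dict[int, list[int]] = {}
    for pid in ids:
        children.setdefault(rows[pid][5], []).append(pid)

    m = Morphology(name=str(path))
    # soma: merge the root with any contiguous chain of soma points
    soma_pts = [root_pid]
    cursor = root_pid
    while True:
        kids = children.get(cursor, [])
        soma_kids = [k for k in kids if rows[k][0] == SWC_TYPE_CODES["soma"]]
        if len(soma_kids) == 1 and len(kids) == 1:
            cursor = soma_kids[0]
            soma_pts.append(cursor)
        else:
            break
    if len(soma_pts) == 1:
        r = rows[root_pid][4]
        length = diameter = 2.0 * r
        pts = np.array([[*rows[root_pid][1:4], r]])
    else:
        coords = np.array([rows[p][1:5] for p in soma_pts])
        seglen = np.linalg.norm(np.diff(coords[:, :3], axis=0), axis=1)
        length = float(seglen.sum())
        diameter = float(np.average(coords[1:, 3] * 2.0, weights=seglen))
        pts = coords
    soma_sec_id = 1
    m.add(
        Section(
            id=soma_sec_id,
            parent_id=None,
            kind="soma",
            length=length,
            diameter=diameter,
            points=pts,
        )
    )

    # non-soma: walk unbranched chains
    section_of_point: dict[int, int] = {p: soma_sec_id for p in soma_pts}
    stack: list[int] = []
    for p in soma_pts:
        for k in children.get(p, []):
            if k not in soma_pts:
                stack.append(k)
    while stack:
        start = stack.pop(0)  # FIFO keeps section order stable across reads
        chain = [start]
        cursor = start
        while True:
            kids = children.get(cursor, [])
            if len(kids) == 1 and rows[kids[0]][0] == rows[start][0]:
                cursor = kids[0]
                chain.append(cursor)
            else:
                break
        parent_point = rows[start][5]
        parent_sec = section_of_point[parent_point]
        parent_is_soma = parent_point in soma_pts
        if parent_is_soma and len(chain) >= 2:
            # dendrites start at their first point: the virtual segment from
            # the soma centre to the first dendritic point carries no cable
            coords = np.array([list(rows[p][1:5]) for p in chain])
        else:
            anchor = rows[parent_point]
            coords = np.array(
                [[anchor[1], anchor[2], anchor[3], anchor[4]]]
                + [list(rows[p][1:5]) for p in chain]
            )
        seglen = np.linalg.norm(np.diff(coords[:, :3], axis=0), axis=1)
        if not seglen.sum() > 0:
            raise MorphologyError(f"zero-length chain starting at point {start}")
        diameter = float(np.average(coords[1:, 3] * 2.0, weights=np.maximum(seglen, 1e-300)))
        sec_id = m.next_id()
        kind = kind_of(rows[start][0], start)
        resistivity = 385.0 if kind.startswith("spine") else 100.0
        m.add(
            Section(
                id=sec_id,
                parent_id=parent_sec,
                kind=kind,
                length=float(seglen.sum()),
                diameter=diameter,
                axial_resistivity=resistivity,
                points=coords,
            )
        )
        for p in chain:
            section_of_point[p] = sec_id
        for k in children.get(chain[-1], []):
            stack.append(k)

    m.validate()
    return m


def write_swc(m: Morphology, path) -> None:
    """Write a morphology as standard 7-column SWC (spine extension codes
    5/6). Sections carrying a stored polyline are written verbatim; sections
    without one are written as a single straight segment continuing away
    from the parent endpoint."""
    m.validate()
    lines = ["# SWC export; type codes: 1 soma, 2 axon, 3 basal, 4 apical, "
             "5 spine_neck (ext), 6 spine_head (ext)"]
    next_point = 1
    last_point: dict[int, int] = {}
    end_xyz: dict[int, np.ndarray] = {}

    root = m.root
    code = SWC_TYPE_CODES[root.kind]
    if root.points is not None and len(root.points) == 1:
        x, y, z, r = root.points[0]
    else:
        x = y = z = 0.0
        r = root.diameter / 2.0
    lines.append(f"{next_point} {code} {x:.6f} {y:.6f} {z:.6f} {r:.6f} -1")
    last_point[root.id] = next_point
    end_xyz[root.id] = np.array([x, y, z])
    next_point += 1

    for sec in m:
        if sec.id == root.id:
            continue
        code = SWC_TYPE_CODES[sec.kind]
        parent_pt = last_point[sec.parent_id]
        if sec.points is not None and len(sec.points) >= 2:
            # sections attached to the soma keep their first point (their
            # polyline does not start at the soma centre)
            rows_out = sec.points if m[sec.parent_id].kind == "soma" else sec.points[1:]
            for row in rows_out:
                px, py, pz, pr = row
                lines.append(
                    f"{next_point} {code} {px:.6f} {py:.6f} {pz:.6f} "
                    f"{pr:.6f} {parent_pt}"
                )
                parent_pt = next_point
                next_point += 1
            end_xyz[sec.id] = sec.points[-1, :3].copy()
        else:
            origin = end_xyz[sec.parent_id]
            direction = np.array([1.0, 0.0, 0.0])
            tip = origin + direction * sec.length
            lines.append(
                f"{next_point} {code} {tip[0]:.6f} {tip[1]:.6f} {tip[2]:.6f} "
                f"{sec.diameter / 2.0:.6f} {parent_pt}"
            )
            parent_pt = next_point
            next_point += 1
            end_xyz[sec.id] = tip
        last_point[sec.id] = parent_pt

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
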