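"""Idealized coronary-arterial-fistula geometries on labelled Cartesian grids.

Patient anatomies in this problem are a parent vessel (ascending aorta), a
dilated fistulous coronary artery branching off it, a saccular aneurysm at the
fistula terminus, and small coronary side branches that must keep perfusing the
myocardium after the fistula is occluded.  This module builds an idealized 2D
planar stand-in: a straight horizontal parent vessel, a perpendicular fistula
channel of width ``D_E`` and centerline length ``L_F`` whose last ``L_A`` is
dilated to width ``D_MA``, and optional coronary side branches.  All "volumes"
are planar areas times a unit (1 mm) out-of-plane depth.

Three occlusion variants are generated from one spec:

``untreated``
    the distal fistula outlet is open (blood "stealing" through the fistula).
``aneurysm_reserved``
    distal occlusion: the fistula outlet faces become wall, the aneurysm stays.
``aneurysm_removed``
    proximal occlusion: the aneurysm (and any branch attached to it) is
    excised — its cells become solid — and no fistula outlet exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from enum import Enum, IntEnum

import numpy as np
from scipy import ndimage

__all__ = [
    "OcclusionMode",
    "Region",
    "BoundaryKind",
    "BranchSpec",
    "GeometrySpec",
    "Port",
    "DomainGrid",
    "build_fistula_geometry",
    "build_channel",
    "region_measure",
]


class OcclusionMode(str, Enum):
    UNTREATED = "untreated"
    ANEURYSM_RESERVED = "aneurysm_reserved"
    ANEURYSM_REMOVED = "aneurysm_removed"


class Region(IntEnum):
    """Per-fluid-cell region tag; SOLID marks non-fluid cells."""

    SOLID = 0
    AORTA = 1
    FISTULA = 2
    ANEURYSM = 3


class BoundaryKind(str, Enum):
    WALL = "wall"
    INLET = "inlet"
    AORTIC_OUTLET = "aortic_outlet"
    CORONARY_OUTLET = "coronary_outlet"
    FISTULA_OUTLET = "fistula_outlet"


@dataclass(frozen=True)
class BranchSpec:
    """A small coronary side branch, rectangular, branching at a right angle.

    ``attach`` is either ``"fistula"`` (branch leaves the proximal fistula
    channel sideways) or ``"aneurysm"`` (branch leaves the aneurysm sac; such a
    branch is excised together with the sac in the aneurysm-removed variant).
    ``along`` in [0, 1] positions the branch along the attached segment,
    measured from its proximal end.  ``side`` is "left" (-x) or "right" (+x).
    """

    name: str
    attach: str = "fistula"
    along: float = 0.25
    side: str = "left"
    width: float = 8.0   # mm
    length: float = 24.0  # mm

    def __post_init__(self) -> None:
        if self.attach not in ("fistula", "aneurysm"):
            raise ValueError(f"unknown branch attachment {self.attach!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"unknown branch side {self.side!r}")
        if not (0.0 <= self.along <= 1.0):
            raise ValueError("branch position 'along' must lie in [0, 1]")
        if self.width <= 0 or self.length <= 0:
            raise ValueError("branch width and length must be positive")


def _default_branches() -> tuple[BranchSpec, ...]:
    return (
        BranchSpec(name="coronary_proximal", attach="fistula", along=0.25,
                   side="left", width=8.0, length=24.0),
        BranchSpec(name="coronary_distal", attach="aneurysm", along=0.5,
                   side="right", width=8.0, length=24.0),
    )


@dataclass(frozen=True)
class GeometrySpec:
    """Morphology parameters of an idealized fistula-with-aneurysm model.

    Lengths are millimetres.  ``L_F`` is the total fistula centerline length
    *including* the terminal aneurysm of length ``L_A`` (the published
    convention: the fistula volume contains the aneurysm volume).
    """

    D_E: float                      # fistula entrance diameter
    L_F: float                      # fistula centerline length
    D_MA: float                     # aneurysm max diameter
    L_A: float                      # aneurysm length
    occlusion_mode: OcclusionMode = OcclusionMode.UNTREATED
    D_aorta: float = 24.0           # parent-vessel diameter (not published; adult aortic scale)
    L_aorta: float = 160.0          # parent-vessel length
    cell_size: float = 2.0          # grid spacing
    fistula_position: float = 0.4   # fistula centerline at this fraction of L_aorta
    aneurysm_offset: float = 0.0    # sac eccentricity: 0 centered on the
    # channel axis, +/-1 flush with one channel wall (saccular bulges are
    # typically eccentric, which makes the entering jet sweep the sac wall)
    branches: tuple[BranchSpec, ...] = field(default_factory=_default_branches)

    def __post_init__(self) -> None:
        if isinstance(self.occlusion_mode, str) and not isinstance(
            self.occlusion_mode, OcclusionMode
        ):
            object.__setattr__(self, "occlusion_mode", OcclusionMode(self.occlusion_mode))
        if isinstance(self.branches, list):
            object.__setattr__(self, "branches", tuple(self.branches))
        if self.D_E <= 0 or self.cell_size <= 0 or self.D_aorta <= 0 or self.L_aorta <= 0:
            raise ValueError("all diameters, lengths and cell_size must be positive")
        if self.L_A < 0 or self.L_F <= self.L_A:
            raise ValueError("need L_F > L_A >= 0")
        if not (-1.0 <= self.aneurysm_offset <= 1.0):
            raise ValueError("aneurysm_offset must lie in [-1, 1]")
        if self.D_MA < self.D_E:
            raise ValueError(
                f"aneurysm max diameter D_MA={self.D_MA} must be >= entrance "
                f"diameter D_E={self.D_E} (the aneurysm is a dilation)"
            )
        n_across = self.D_E / self.cell_size
        if n_across < 8 - 1e-9:
            raise ValueError(
                f"resolution floor violated: D_E={self.D_E} mm spans only "
                f"{n_across:.1f} cells at cell_size={self.cell_size} mm "
                "(need >= 8); the limiting dimension is D_E"
            )
        for b in self.branches:
            if b.width / self.cell_size < 3 - 1e-9:
                raise ValueError(
                    f"resolution floor violated: branch {b.name!r} width "
                    f"{b.width} mm spans < 3 cells at cell_size={self.cell_size}"
                )

    def with_mode(self, mode: OcclusionMode | str) -> "GeometrySpec":
        d = asdict(self)
        d["occlusion_mode"] = OcclusionMode(mode)
        d["branches"] = self.branches
        return GeometrySpec(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["occlusion_mode"] = self.occlusion_mode.value
        d["branches"] = [asdict(b) for b in self.branches]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeometrySpec":
        d = dict(d)
        if "branches" in d:
            d["branches"] = tuple(BranchSpec(**b) for b in d["branches"])
        return cls(**d)


@dataclass(frozen=True)
class Port:
    """A named opening in the domain boundary (inlet or an outlet)."""

    name: str
    kind: BoundaryKind


class DomainGrid:
    """Uniform cell-centered Cartesian grid with region tags and port labels.

    Arrays are indexed ``[i, j]`` with ``i`` along x (parent vessel axis) and
    ``j`` along y.  ``region[i, j]`` is a :class:`Region` value (SOLID for
    non-fluid cells).  Boundary faces are carried on staggered arrays:
    ``port_u[i, j]`` labels the x-normal face between cells ``(i-1, j)`` and
    ``(i, j)`` and ``port_v[i, j]`` the y-normal face below/above analogously;
    a value of 0 means "not a port face" (interior or wall), ``k >= 1`` refers
    to ``ports[k - 1]``.
    """

    def __init__(self, nx: int, ny: int, spacing: float,
                 region: np.ndarray, ports: list[Port],
                 port_u: np.ndarray, port_v: np.ndarray,
                 spec: GeometrySpec | None = None) -> None:
        self.nx = int(nx)
        self.ny = int(ny)
        self.spacing = float(spacing)
        self.region = np.asarray(region, dtype=np.int8)
        self.ports = list(ports)
        self.port_u = np.asarray(port_u, dtype=np.int16)
        self.port_v = np.asarray(port_v, dtype=np.int16)
        self.spec = spec
        if self.region.shape != (self.nx, self.ny):
            raise ValueError("region array shape mismatch")
        if self.port_u.shape != (self.nx + 1, self.ny):
            raise ValueError("port_u array shape mismatch")
        if self.port_v.shape != (self.nx, self.ny + 1):
            raise ValueError("port_v array shape mismatch")
        self._validate()

    # -- derived masks ----------------------------------------------------
    @property
    def fluid(self) -> np.ndarray:
        return self.region != Region.SOLID

    @property
    def n_fluid(self) -> int:
        return int(np.count_nonzero(self.fluid))

    @property
    def cell_measure(self) -> float:
        """Measure of one cell in mm^3 (planar area times 1 mm depth)."""
        return self.spacing ** 2

    def port_id(self, name: str) -> int:
        for k, p in enumerate(self.ports):
            if p.name == name:
                return k + 1
        raise KeyError(f"no port named {name!r}")

    def ports_of_kind(self, kind: BoundaryKind) -> list[str]:
        return [p.name for p in self.ports if p.kind == kind]

    def wall_faces(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean masks of x-normal and y-normal wall faces.

        A wall face separates a fluid cell from a solid cell or from the
        domain exterior and carries no port label.
        """
        f = self.fluid
        fx = np.zeros((self.nx + 1, self.ny), dtype=bool)
        fx[1:-1] = f[:-1] != f[1:]
        fx[0] = f[0]
        fx[-1] = f[-1]
        fy = np.zeros((self.nx, self.ny + 1), dtype=bool)
        fy[:, 1:-1] = f[:, :-1] != f[:, 1:]
        fy[:, 0] = f[:, 0]
        fy[:, -1] = f[:, -1]
        return fx & (self.port_u == 0), fy & (self.port_v == 0)

    # -- invariant checks -------------------------------------------------
    def _validate(self) -> None:
        f = self.fluid
        if not f.any():
            raise ValueError("grid has no fluid cells")
        _, n_comp = ndimage.label(f, structure=np.array([[0, 1, 0],
                                                         [1, 1, 1],
                                                         [0, 1, 0]]))
        if n_comp != 1:
            raise ValueError(f"fluid region is not 4-connected ({n_comp} components)")
        # port faces must be adjacent to exactly one fluid cell on the inside
        for arr, axis in ((self.port_u, 0), (self.port_v, 1)):
            ids = arr[arr > 0]
            if ids.size and (ids.max() > len(self.ports)):
                raise ValueError("port label out of range")
        if not any(p.kind == BoundaryKind.INLET for p in self.ports):
            raise ValueError("grid has no inlet port")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DomainGrid):
            return NotImplemented
        return (
            self.nx == other.nx and self.ny == other.ny
            and self.spacing == other.spacing
            and np.array_equal(self.region, other.region)
            and self.ports == other.ports
            and np.array_equal(self.port_u, other.port_u)
            and np.array_equal(self.port_v, other.port_v)
        )


# ---------------------------------------------------------------------------


def _snap(x: float, h: float) -> int:
    return int(round(x / h))


def build_channel(length: float, width: float, cell_size: float,
                  inlet_name: str = "inlet",
                  outlet_name: str = "outlet") -> DomainGrid:
    """A straight horizontal channel: inlet at x=0, aortic outlet at x=length.

    Used for verification fixtures (plane Poiseuille, plug-flow washout); the
    single fluid region is tagged AORTA.
    """
    h = cell_size
    nx, ny = _snap(length, h), _snap(width, h)
    if nx < 2 or ny < 2:
        raise ValueError("channel must span at least 2 cells each way")
    region = np.full((nx, ny), int(Region.AORTA), dtype=np.int8)
    port_u = np.zeros((nx + 1, ny), dtype=np.int16)
    port_v = np.zeros((nx, ny + 1), dtype=np.int16)
    ports = [Port(inlet_name, BoundaryKind.INLET),
             Port(outlet_name, BoundaryKind.AORTIC_OUTLET)]
    port_u[0, :] = 1
    port_u[-1, :] = 2
    return DomainGrid(nx, ny, h, region, ports, port_u, port_v)


def build_fistula_geometry(spec: GeometrySpec) -> DomainGrid:
    """Rasterize an idealized fistula-with-terminal-aneurysm model.

    Layout (mm, y up): the parent vessel occupies the top horizontal band of
    the domain; the fistula descends perpendicularly from it; the terminal
    aneurysm is a wider rectangle at the fistula's lower end.  Boundary faces
    are labelled per the occlusion mode: the untreated variant has an open
    ``fistula_outlet`` strip (width D_E) at the bottom of the terminal
    segment; both occluded variants turn it to wall; the aneurysm-removed
    variant additionally converts the aneurysm cells (and any branch attached
    to the aneurysm) to solid.
    """
    h = spec.cell_size
    mode = spec.occlusion_mode

    # snap every physical dimension to a whole cell count once, then
    # compose bands, so refinement changes each measure by at most half a
    # cell layer per dimension
    nx = _snap(spec.L_aorta, h)
    j_a0 = _snap(spec.L_F, h)       # aorta occupies j in [j_a0, ny)
    ny = j_a0 + _snap(spec.D_aorta, h)
    x_c = spec.fistula_position * spec.L_aorta
    n_de = _snap(spec.D_E, h)
    i_f0 = _snap(x_c - spec.D_E / 2, h)
    i_f1 = i_f0 + n_de
    j_an1 = _snap(spec.L_A, h)      # aneurysm occupies j in [0, j_an1)
    n_ma = _snap(spec.D_MA, h)
    x_an = x_c + spec.aneurysm_offset * (spec.D_MA - spec.D_E) / 2.0
    i_an0 = _snap(x_an - spec.D_MA / 2, h)
    i_an1 = i_an0 + n_ma
    if i_an0 < 0 or i_an1 > nx:
        raise ValueError("aneurysm extends outside the domain; widen L_aorta "
                         "or move fistula_position")

    region = np.zeros((nx, ny), dtype=np.int8)
    region[:, j_a0:ny] = Region.AORTA
    region[i_f0:i_f1, j_an1:j_a0] = Region.FISTULA
    has_aneurysm = j_an1 > 0 and mode != OcclusionMode.ANEURYSM_REMOVED
    if j_an1 > 0 and mode != OcclusionMode.ANEURYSM_REMOVED:
        region[i_an0:i_an1, 0:j_an1] = Region.ANEURYSM

    # coronary branches (tagged as AORTA: they are "the rest of the domain")
    branch_rects: dict[str, tuple[int, int, int, int]] = {}
    for b in spec.branches:
        if b.attach == "aneurysm" and not has_aneurysm:
            continue  # excised with the sac (or no sac exists)
        nb = _snap(b.width, h)
        nl = _snap(b.length, h)
        if b.attach == "fistula":
            seg_lo, seg_hi = j_an1, j_a0
            wall_left, wall_right = i_f0, i_f1
        else:
            seg_lo, seg_hi = 0, j_an1
            wall_left, wall_right = i_an0, i_an1
        # position measured from the proximal (aortic) end of the segment
        j_center = seg_hi - b.along * (seg_hi - seg_lo)
        j0 = int(round(j_center - nb / 2))
        j0 = max(seg_lo, min(j0, seg_hi - nb))
        j1 = j0 + nb
        if b.side == "left":
            i0, i1 = wall_left - nl, wall_left
            i_out = i0
        else:
            i0, i1 = wall_right, wall_right + nl
            i_out = i1
        if i0 < 0 or i1 > nx:
            raise ValueError(f"branch {b.name!r} extends outside the domain")
        region[i0:i1, j0:j1] = np.where(
            region[i0:i1, j0:j1] == Region.SOLID, Region.AORTA,
            region[i0:i1, j0:j1])
        branch_rects[b.name] = (i_out, j0, j1, -1 if b.side == "left" else +1)

    # ports
    ports: list[Port] = [Port("inlet", BoundaryKind.INLET),
                         Port("aortic", BoundaryKind.AORTIC_OUTLET)]
    port_u = np.zeros((nx + 1, ny), dtype=np.int16)
    port_v = np.zeros((nx, ny + 1), dtype=np.int16)
    port_u[0, j_a0:ny] = 1          # inlet: left end of the parent vessel
    port_u[nx, j_a0:ny] = 2         # aortic outlet: right end

    for b in spec.branches:
        if b.name not in branch_rects:
            continue
        ports.append(Port(b.name, BoundaryKind.CORONARY_OUTLET))
        pid = len(ports)
        i_out, j0, j1, side = branch_rects[b.name]
        port_u[i_out, j0:j1] = pid

    if mode == OcclusionMode.UNTREATED:
        ports.append(Port("fistula", BoundaryKind.FISTULA_OUTLET))
        pid = len(ports)
        port_v[i_f0:i_f1, 0] = pid  # open distal strip, width D_E
    return DomainGrid(nx, ny, h, region, ports, port_u, port_v, spec=spec)


def region_measure(grid: DomainGrid, region: Region | str) -> float:
    """Measure (mm^3; planar area times unit depth) of a tagged region.

    The fistula measure *includes* the aneurysm cells when present, matching
    the convention that the fistula volume contains the aneurysm volume.
    ``region='all'`` returns the total fluid measure.
    """
    if isinstance(region, str):
        key = region.lower()
        if key == "all":
            return grid.n_fluid * grid.cell_measure
        try:
            region = Region[key.upper()]
        except KeyError:
            raise ValueError(f"unknown region tag {region!r}") from None
    if region == Region.SOLID:
        raise ValueError("SOLID is not a fluid region")
    mask = grid.region == int(region)
    if region == Region.FISTULA:
        mask = mask | (grid.region == int(Region.ANEURYSM))
    return int(np.count_nonzero(mask)) * grid.cell_measure
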