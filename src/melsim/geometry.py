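"""Spatial and structural domains, their grids, and the cell-state geography.

The simulator lives on two rectangular planes: a physical tissue section
(the *spatial* plane, coordinates ``x = (x1, x2)``) and an abstract
gene-expression map (the *structural* plane, coordinates ``y = (y1, y2)``)
in which a cell's internal state moves continuously.  Six named melanoma
cell states — proliferative, invasive, pigmented, NCSC (neural-crest stem
cells), SMC (starved-like melanoma cells) and URC (uncharacterized
resistant cells) — are represented as closed discs around fixed anchor
points of the structural plane.  A cell belongs to a subpopulation while
its state lies inside the corresponding disc; states between discs are
"unassigned", reflecting the continuum of expression profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DomainError

SUBPOPULATIONS = ("proliferative", "invasive", "pigmented", "NCSC", "SMC", "URC")

#: Reference cardinal geography on the unit square.  URC is placed in the
#: south-east: horizontal structural diffusion links it to the proliferative
#: state in the south, and the HCT drug spans east/south regions, which is
#: only geometrically consistent with a SE placement.
DEFAULT_ANCHORS = {
    "proliferative": ((0.20, 0.20), "SW"),
    "invasive": ((0.85, 0.50), "E"),
    "pigmented": ((0.20, 0.85), "NW"),
    "NCSC": ((0.85, 0.85), "NE"),
    "SMC": ((0.50, 0.90), "N"),
    "URC": ((0.80, 0.15), "SE"),
}

DEFAULT_RADIUS = 0.15


@dataclass(frozen=True)
class GridSpec:
    """Cell-centered uniform finite-volume grids for both planes.

    Coordinates are cell centers ``(i + 1/2) * h``; indexing is 0-based.
    The full 4D density array is laid out ``c[ix1, ix2, iy1, iy2]``.
    """

    n_spatial: int
    n_structural: int
    spatial_extent: float = 1.0
    structural_extent: float = 1.0

    def __post_init__(self):
        for key in ("n_spatial", "n_structural"):
            n = getattr(self, key)
            if not isinstance(n, (int, np.integer)) or isinstance(n, bool):
                raise ConfigurationError(f"grid.{key} must be an integer, got {n!r}")
            if n < 4:
                raise ConfigurationError(f"grid.{key} must be >= 4, got {n}")
        for key in ("spatial_extent", "structural_extent"):
            ext = getattr(self, key)
            if not ext > 0:
                raise ConfigurationError(f"grid.{key} must be positive, got {ext}")

    # -- spacings -----------------------------------------------------
    @property
    def dx(self) -> float:
        return self.spatial_extent / self.n_spatial

    @property
    def dy(self) -> float:
        return self.structural_extent / self.n_structural

    @property
    def spatial_cell_area(self) -> float:
        return self.dx * self.dx

    @property
    def structural_cell_area(self) -> float:
        return self.dy * self.dy

    @property
    def cell_volume_4d(self) -> float:
        return self.spatial_cell_area * self.structural_cell_area

    @property
    def n_cells_4d(self) -> int:
        return self.n_spatial**2 * self.n_structural**2

    # -- coordinates --------------------------------------------------
    @property
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.n_spatial) + 0.5) * self.dx

    @property
    def y_centers(self) -> np.ndarray:
        return (np.arange(self.n_structural) + 0.5) * self.dy

    @property
    def x_faces(self) -> np.ndarray:
        """Interior face coordinates of the spatial axes (n_spatial - 1)."""
        return np.arange(1, self.n_spatial) * self.dx

    @property
    def y_faces(self) -> np.ndarray:
        return np.arange(1, self.n_structural) * self.dy

    def spatial_mesh(self):
        x = self.x_centers
        return np.meshgrid(x, x, indexing="ij")

    def structural_mesh(self):
        y = self.y_centers
        return np.meshgrid(y, y, indexing="ij")


def build_grids(config: dict | None = None, **kwargs) -> GridSpec:
    """Build the grid specification from a ``grid`` config section."""
    cfg = dict(config or {})
    cfg.update(kwargs)
    known = {"n_spatial", "n_structural", "spatial_extent", "structural_extent"}
    unknown = set(cfg) - known
    if unknown:
        raise ConfigurationError(f"unknown grid keys: {sorted(unknown)}")
    return GridSpec(**cfg)


@dataclass(frozen=True)
class StructuralAnchor:
    """A named cell state anchored at a fixed point of the structural plane."""

    name: str
    position: tuple[float, float]
    cardinal: str = ""

    def __post_init__(self):
        if self.name not in SUBPOPULATIONS:
            raise ConfigurationError(
                f"unknown subpopulation name {self.name!r}; expected one of {SUBPOPULATIONS}"
            )


@dataclass(frozen=True)
class SubpopulationAtlas:
    """The six cell-state anchors and the common subdomain radius.

    Subdomains are closed discs of the given radius; where discs overlap a
    point is assigned to the nearest anchor.
    """

    anchors: tuple[StructuralAnchor, ...]
    radius: float = DEFAULT_RADIUS
    extent: float = 1.0

    def __post_init__(self):
        names = [a.name for a in self.anchors]
        if sorted(names) != sorted(SUBPOPULATIONS):
            raise ConfigurationError(
                f"atlas must contain exactly the six subpopulations, got {names}"
            )
        if not (0 < self.radius < 0.5 * self.extent):
            raise ConfigurationError(
                f"atlas radius must lie in (0, {0.5 * self.extent}), got {self.radius}"
            )
        for a in self.anchors:
            if not all(0 <= p <= self.extent for p in a.position):
                raise ConfigurationError(
                    f"anchor {a.name} position {a.position} outside the structural extent"
                )

    def anchor(self, name: str) -> StructuralAnchor:
        for a in self.anchors:
            if a.name == name:
                return a
        raise ConfigurationError(f"no anchor named {name!r}")

    def position(self, name: str) -> np.ndarray:
        return np.asarray(self.anchor(name).position, dtype=float)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.anchors)

    @property
    def positions(self) -> np.ndarray:
        """(6, 2) array of anchor positions, in ``self.names`` order."""
        return np.asarray([a.position for a in self.anchors], dtype=float)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "radius": float(self.radius),
            "anchors": {
                a.name: {"position": [float(p) for p in a.position], "cardinal": a.cardinal}
                for a in self.anchors
            },
        }

    @classmethod
    def from_dict(cls, d: dict, extent: float = 1.0) -> "SubpopulationAtlas":
        anchors = tuple(
            StructuralAnchor(name, tuple(spec["position"]), spec.get("cardinal", ""))
            for name, spec in d["anchors"].items()
        )
        return cls(anchors=anchors, radius=float(d.get("radius", DEFAULT_RADIUS)), extent=extent)


def default_atlas(extent: float = 1.0) -> SubpopulationAtlas:
    """The reference six-state geography on the unit structural square."""
    anchors = tuple(
        StructuralAnchor(name, pos, card) for name, (pos, card) in DEFAULT_ANCHORS.items()
    )
    return SubpopulationAtlas(anchors=anchors, radius=DEFAULT_RADIUS, extent=extent)


def _check_inside(y, extent: float):
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != 2:
        raise DomainError(f"structural point must be 2D, got shape {y.shape}")
    if np.any(y < 0) or np.any(y > extent):
        raise DomainError(f"structural point {y} outside extent [0, {extent}]^2")
    return y


def classify_state(y, atlas: SubpopulationAtlas) -> str:
    """Assign a structural point to a subpopulation, or ``"unassigned"``.

    The point gets the name of the closed disc that contains it; nearest
    anchor breaks ties when discs overlap.
    """
    y = _check_inside(y, atlas.extent)
    d = np.linalg.norm(atlas.positions - y, axis=1)
    i = int(np.argmin(d))
    if d[i] <= atlas.radius:
        return atlas.names[i]
    return "unassigned"


def classify_grid(grid: GridSpec, atlas: SubpopulationAtlas) -> np.ndarray:
    """Label every structural cell center; -1 marks unassigned cells.

    Returns an (n_structural, n_structural) integer array indexing into
    ``atlas.names``.
    """
    y1, y2 = grid.structural_mesh()
    pts = np.stack([y1, y2], axis=-1)  # (ny, ny, 2)
    d = np.linalg.norm(pts[..., None, :] - atlas.positions, axis=-1)  # (ny, ny, 6)
    nearest = np.argmin(d, axis=-1)
    inside = np.take_along_axis(d, nearest[..., None], axis=-1)[..., 0] <= atlas.radius
    return np.where(inside, nearest, -1)
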