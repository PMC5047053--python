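"""2D numerical model of a fractured rat tibia under layered soft tissue.

The model is a horizontal stack of nine tissue layers (skin, fat, muscle,
cortical bone, bone marrow, cortical bone, muscle, fat, skin from the top
surface downward, 5.90 mm in total) rasterized onto a uniform grid.  The
two thin cortical plates are interrupted over a central lateral span — the
fracture gap, 4 mm wide by default — and a 10-mm line source sits on the
top surface.  Fifteen receivers R1–R15 lie on the vertical propagation
axis through the gap center: R1 on the top surface, the even-numbered
receivers at the mid-depth of each of the seven layers the axis crosses
(skin, fat, muscle, gap, muscle, fat, skin), and the odd-numbered
receivers one grid cell above each internal interface and above the
bottom surface.

Depth is measured downward from the top surface; a cell covers the
half-open square [i*dx, (i+1)*dx) in each coordinate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .tissue_materials import TissueProperties, material_map

__all__ = [
    "LayerStack",
    "Receiver",
    "ModelGrid",
    "default_layer_stack",
    "rasterize",
    "place_receivers",
]

# (tissue, thickness mm) from the top surface downward
_DEFAULT_LAYERS = [
    ("skin", 0.55),
    ("fat", 0.58),
    ("muscle", 1.73),
    ("cortical bone", 0.04),
    ("bone marrow", 0.10),
    ("cortical bone", 0.04),
    ("muscle", 1.73),
    ("fat", 0.58),
    ("skin", 0.55),
]


@dataclass(frozen=True)
class LayerStack:
    """Ordered (tissue name, thickness mm) list from the top surface down."""

    layers: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        for name, th in self.layers:
            if th <= 0:
                raise ValueError(f"layer {name!r} has non-positive thickness {th}")

    @property
    def total_thickness(self) -> float:
        return sum(th for _, th in self.layers)

    def boundaries(self) -> list[float]:
        """Cumulative layer-boundary depths in mm, starting at 0."""
        out = [0.0]
        for _, th in self.layers:
            out.append(out[-1] + th)
        return out

    def axis_layers(self, gap_name: str = "gap") -> tuple[tuple[str, float], ...]:
        """Layers crossed by the axis through the fracture gap.

        The contiguous bone band (first through last cortical layer) is
        merged into a single pseudo-layer named ``gap_name``, since the
        cortical plates are interrupted on the axis.
        """
        names = [n for n, _ in self.layers]
        if "cortical bone" not in names:
            return self.layers
        i0 = names.index("cortical bone")
        i1 = len(names) - 1 - names[::-1].index("cortical bone")
        band = sum(th for _, th in self.layers[i0 : i1 + 1])
        return (
            *self.layers[:i0],
            (gap_name, band),
            *self.layers[i1 + 1 :],
        )

    def snapped(self, dx: float) -> "LayerStack":
        """Layer thicknesses snapped to integer multiples of ``dx``.

        Boundaries are snapped cumulatively (round-half-up) and every
        layer keeps at least one cell; a warning is issued when any
        boundary moves.
        """
        rows = _snap_boundaries(self.boundaries(), dx)
        new = []
        moved = False
        for k, (name, th) in enumerate(self.layers):
            th_new = (rows[k + 1] - rows[k]) * dx
            if not math.isclose(th_new, th, rel_tol=0, abs_tol=1e-12):
                moved = True
            new.append((name, th_new))
        if moved:
            warnings.warn(
                f"layer boundaries snapped to the {dx}-mm grid "
                f"(total {self.total_thickness} -> {rows[-1] * dx} mm)",
                stacklevel=2,
            )
        return LayerStack(tuple(new))


def _snap_boundaries(bounds_mm: list[float], dx: float) -> list[int]:
    """Cumulative boundary depths -> grid rows (round half up, layers >= 1 cell)."""
    rows = [0]
    for b in bounds_mm[1:]:
        # epsilon guards against 27.499999... float noise at exact halves
        r = math.floor(b / dx + 0.5 + 1e-9)
        rows.append(max(r, rows[-1] + 1))
    return rows


def default_layer_stack() -> LayerStack:
    """The nine-layer rat-tibia stack (total thickness 5.90 mm)."""
    return LayerStack(tuple(_DEFAULT_LAYERS))


@dataclass(frozen=True)
class Receiver:
    label: str
    depth_mm: float  # analytic (unsnapped) depth
    lateral_mm: float  # offset from the model mid-line
    role: str  # surface | mid-layer | interface


def place_receivers(stack: LayerStack, dx: float = 0.01) -> list[Receiver]:
    """The fifteen receivers R1–R15 on the axis through the gap center.

    R1 is on the top surface.  Even labels sit at the mid-depth of each of
    the seven layers the axis crosses; odd labels sit one cell (``dx``)
    above each internal interface, with R15 one cell above the bottom
    surface.  Labels ascend strictly with depth.
    """
    axis = stack.axis_layers()
    if len(axis) != 7:
        raise ValueError(f"expected 7 axis layers, got {len(axis)}")
    bounds = [0.0]
    for _, th in axis:
        bounds.append(bounds[-1] + th)
    receivers = [Receiver("R1", 0.0, 0.0, "surface")]
    k = 2
    for i in range(7):
        mid = 0.5 * (bounds[i] + bounds[i + 1])
        receivers.append(Receiver(f"R{k}", mid, 0.0, "mid-layer"))
        receivers.append(Receiver(f"R{k + 1}", bounds[i + 1] - dx, 0.0, "interface"))
        k += 2
    return receivers


@dataclass
class ModelGrid:
    """Material-index map plus source and receiver placement.

    ``index[j, i]`` gives the material of the cell at depth row ``j`` and
    lateral column ``i``; ``materials`` maps indices to tissue properties.
    """

    dx: float  # grid step, mm
    width: float  # lateral extent, mm
    height: float  # depth extent, mm
    index: np.ndarray  # (ny, nx) uint8 material indices
    materials: list[TissueProperties]
    stack: LayerStack  # snapped stack actually rasterized
    gap_width: float  # mm
    gap_fill: str
    source_aperture: float  # mm, centered on the top surface
    receivers: list[Receiver] = field(default_factory=list)

    @property
    def ny(self) -> int:
        return self.index.shape[0]

    @property
    def nx(self) -> int:
        return self.index.shape[1]

    def material_names(self) -> list[str]:
        return [m.name for m in self.materials]

    def receiver_cells(self) -> list[tuple[str, int, int]]:
        """(label, row, col) of each receiver, snapped to the grid."""
        mid = self.width / 2.0
        out = []
        for r in self.receivers:
            row = min(math.floor(r.depth_mm / self.dx + 0.5 + 1e-9), self.ny - 1)
            col = min(math.floor((mid + r.lateral_mm) / self.dx), self.nx - 1)
            out.append((r.label, row, col))
        return out

    def source_cells(self) -> tuple[int, np.ndarray]:
        """(row, columns) of the source aperture on the top surface."""
        half = min(self.source_aperture, self.width) / 2.0
        mid = self.width / 2.0
        centers = (np.arange(self.nx) + 0.5) * self.dx - mid
        cols = np.nonzero(np.abs(centers) < half)[0]
        return 0, cols

    def to_text(self) -> str:
        """Material map as a delimited-text integer matrix."""
        buf = np.asarray(self.index, dtype=int)
        header = "# materials: " + ", ".join(
            f"{i}={m.name}" for i, m in enumerate(self.materials)
        )
        body = "\n".join(" ".join(str(v) for v in row) for row in buf)
        return header + "\n" + body + "\n"


def rasterize(
    stack: LayerStack | None = None,
    dx: float = 0.01,
    width: float = 16.0,
    gap_width: float = 4.0,
    gap_fill: str = "bone marrow",
    source_aperture: float = 10.0,
    materials: dict[str, TissueProperties] | None = None,
    table_variant: str = "reconciled",
) -> ModelGrid:
    """Rasterize the layered model onto a ``dx``-mm grid.

    Cortical-band cells whose lateral offset from the mid-line satisfies
    ``|offset| < gap_width/2`` (half-open test on cell centers) are
    replaced by ``gap_fill``; cells outside the cortical depth band are
    unaffected by ``gap_width``.  A zero gap width gives the intact-bone
    control model.  If the source aperture exceeds the model width it is
    clipped with a warning.
    """
    if stack is None:
        stack = default_layer_stack()
    if gap_width < 0:
        raise ValueError("gap_width must be non-negative")
    if materials is None:
        materials = material_map(table_variant)
    snapped = stack.snapped(dx)

    names = list(dict.fromkeys([n for n, _ in snapped.layers] + [gap_fill]))
    missing = [n for n in names if n not in materials]
    if missing:
        raise KeyError(f"materials missing from table: {missing}")
    mat_list = [materials[n] for n in names]
    mat_idx = {n: i for i, n in enumerate(names)}

    rows = _snap_boundaries(snapped.boundaries(), dx)
    ny = rows[-1]
    nx = max(int(round(width / dx)), 1)
    width = nx * dx
    index = np.zeros((ny, nx), dtype=np.uint8)
    for k, (name, _) in enumerate(snapped.layers):
        index[rows[k] : rows[k + 1], :] = mat_idx[name]

    # interrupt the cortical plates over the gap's lateral extent
    centers = (np.arange(nx) + 0.5) * dx - width / 2.0
    gap_cols = np.abs(centers) < gap_width / 2.0
    for k, (name, _) in enumerate(snapped.layers):
        if name == "cortical bone":
            index[rows[k] : rows[k + 1], gap_cols] = mat_idx[gap_fill]

    if source_aperture > width:
        warnings.warn(
            f"source aperture {source_aperture} mm clipped to model width {width} mm",
            stacklevel=2,
        )
        source_aperture = width

    grid = ModelGrid(
        dx=dx,
        width=width,
        height=ny * dx,
        index=index,
        materials=mat_list,
        stack=snapped,
        gap_width=gap_width,
        gap_fill=gap_fill,
        source_aperture=source_aperture,
    )
    if len(snapped.axis_layers()) == 7:
        grid.receivers = place_receivers(snapped, dx)
    return grid
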