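"""Intra-retinal layer volumetrics inside the 2.5 mm foveal disc.

Layer-boundary depth surfaces come from OCT segmentation of a 6 x 6 mm
raster scan (128 B-scans x 512 A-scans). Six layers are delimited by
seven ordered boundary surfaces: RNFL, GCIPL, INL, OPL, ONL, PR. The
inner retina — the tissue containing the retinal vascular plexuses — is
the RNFL+GCIPL+INL+OPL composite; its volume inside the disc is the
denominator of the tissue-perfusion metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InvalidGeometryError,
    InvalidInputError,
    InvalidSegmentationError,
)

LAYER_NAMES = ("RNFL", "GCIPL", "INL", "OPL", "ONL", "PR")
INNER_LAYERS = ("RNFL", "GCIPL", "INL", "OPL")

#: default raster: 128 B-scans (rows) x 512 A-scans (cols) over 6 x 6 mm
DEFAULT_GRID_SHAPE = (128, 512)
DEFAULT_EXTENT_MM = (6.0, 6.0)


@dataclass
class LayerSurfaces:
    """Seven boundary depth maps (mm) delimiting six intra-retinal layers.

    ``boundaries`` has shape (7, rows, cols); depth increases with
    boundary index. Cell centers are at ``(i + 0.5) * extent / n`` so the
    raster covers the extent exactly; the fovea defaults to the grid
    center.
    """

    boundaries: np.ndarray
    extent_mm: tuple[float, float] = DEFAULT_EXTENT_MM
    fovea_mm: tuple[float, float] | None = None
    layer_names: tuple[str, ...] = LAYER_NAMES

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.boundaries.ndim != 3 or self.boundaries.shape[0] != \
                len(self.layer_names) + 1:
            raise InvalidInputError(
                "boundaries must have shape (n_layers + 1, rows, cols)"
            )
        if self.fovea_mm is None:
            self.fovea_mm = (self.extent_mm[0] / 2.0, self.extent_mm[1] / 2.0)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.boundaries.shape[1:]

    def thicknesses(self) -> np.ndarray:
        """Per-layer thickness maps, shape (n_layers, rows, cols)."""
        return np.diff(self.boundaries, axis=0)


@dataclass
class LayerVolumes:
    """Per-layer and composite volumes (mm³) within the foveal disc."""

    per_layer_mm3: dict[str, float]
    inner_retina_mm3: float
    total_retina_mm3: float
    disc_diameter_mm: float = 2.5
    masked_area_mm2: float = field(default=float("nan"))

    def to_dict(self) -> dict:
        out = dict(self.per_layer_mm3)
        out["inner_retina_mm3"] = self.inner_retina_mm3
        out["total_retina_mm3"] = self.total_retina_mm3
        out["disc_diameter_mm"] = self.disc_diameter_mm
        out["masked_area_mm2"] = self.masked_area_mm2
        return out


def disc_mask(
    grid_shape: tuple[int, int] = DEFAULT_GRID_SHAPE,
    extent_mm: tuple[float, float] = DEFAULT_EXTENT_MM,
    fovea_mm: tuple[float, float] | None = None,
    disc_diameter_mm: float = 2.5,
    supersample: int = 4,
) -> np.ndarray:
    """Fractional per-cell weights of the foveal disc on the raster.

    Each cell is subdivided ``supersample x supersample``; the weight is
    the fraction of subcell centers inside the circle, so boundary cells
    get fractional weights and the masked area converges to
    ``pi * (d/2)**2`` with resolution. Cell area is anisotropic:
    ``(extent_y / rows) * (extent_x / cols)``.
    """
    if disc_diameter_mm < 0:
        raise InvalidGeometryError("disc_diameter_mm must be non-negative")
    if supersample < 1:
        raise InvalidGeometryError("supersample must be >= 1")
    rows, cols = grid_shape
    ey, ex = extent_mm
    if fovea_mm is None:
        fovea_mm = (ey / 2.0, ex / 2.0)
    fy, fx = fovea_mm
    r = disc_diameter_mm / 2.0
    if fy - r < 0 or fy + r > ey or fx - r < 0 or fx + r > ex:
        raise InvalidGeometryError(
            f"disc of diameter {disc_diameter_mm} mm at ({fy}, {fx}) "
            f"exceeds the {ey} x {ex} mm grid extent"
        )
    if r == 0:
        return np.zeros(grid_shape)
    s = supersample
    ys = (np.arange(rows * s) + 0.5) * (ey / (rows * s))
    xs = (np.arange(cols * s) + 0.5) * (ex / (cols * s))
    inside = ((ys[:, None] - fy) ** 2 + (xs[None, :] - fx) ** 2) <= r * r
    return inside.reshape(rows, s, cols, s).mean(axis=(1, 3))


def layer_volume(
    surfaces: LayerSurfaces,
    mask: np.ndarray | None = None,
    disc_diameter_mm: float = 2.5,
    supersample: int = 4,
) -> LayerVolumes:
    """Integrate per-layer thickness over the disc.

    ``volume = sum(weight * cell_area * thickness)`` per layer; the inner
    retina is the RNFL+GCIPL+INL+OPL sum and the total is the sum over
    all six layers (same mask, same summation order, so additivity is
    exact).
    """
    thick = surfaces.thicknesses()
    bad = thick < -1e-12
    if bad.any():
        n_bad = int(bad.sum())
        layers = [surfaces.layer_names[i]
                  for i in sorted(set(np.nonzero(bad)[0].tolist()))]
        raise InvalidSegmentationError(
            f"boundary order violated at {n_bad} grid nodes "
            f"(layers: {', '.join(layers)})"
        )
    rows, cols = surfaces.grid_shape
    if mask is None:
        mask = disc_mask(
            (rows, cols), surfaces.extent_mm, surfaces.fovea_mm,
            disc_diameter_mm, supersample,
        )
    if mask.shape != (rows, cols):
        raise InvalidInputError("mask shape does not match the surfaces grid")
    cell_area = (surfaces.extent_mm[0] / rows) * (surfaces.extent_mm[1] / cols)
    weighted = mask * cell_area
    per_layer = {
        name: float(np.sum(weighted * thick[i]))
        for i, name in enumerate(surfaces.layer_names)
    }
    inner = sum(per_layer[n] for n in INNER_LAYERS)
    total = sum(per_layer.values())
    return LayerVolumes(
        per_layer_mm3=per_layer,
        inner_retina_mm3=inner,
        total_retina_mm3=total,
        disc_diameter_mm=disc_diameter_mm,
        masked_area_mm2=float(np.sum(weighted)),
    )
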