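"""Scene and table serialization.

A scene directory bundles one synthetic (or user-supplied) eye::

    scene/
      image.tiff     16-bit grayscale fundus raster
      meta.json      fov_setting, mm_per_px, fovea_px, intensity scale,
                     injected ground-truth targets if synthetic
      vessels.csv    vessel_id, kind, velocity_mm_s [, true_diameter_um,
                     contrast], x0, y0, x1, y1, ... (NaN-padded polyline)
      surfaces.bin   raw float64 boundary depths, C order
      surfaces.json  shape, dtype, layer names, extent, fovea
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import InvalidInputError
from .flow import FundusImage, VesselSegment
from .synth import Scene, VesselGroundTruth
from .volume import LayerSurfaces


def save_scene(scene: Scene, directory: str | Path) -> Path:
    """Write a scene bundle; returns the directory path."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    img = scene.image
    vmax = float(max(img.pixels.max(), 1e-9))
    raster = np.clip(img.pixels / vmax, 0.0, 1.0)
    tifffile.imwrite(
        d / "image.tiff", np.round(raster * 65535).astype(np.uint16)
    )
    meta = {
        "fov_setting": img.fov_setting,
        "mm_per_px": img.mm_per_px,
        "fovea_px": list(img.fovea_px),
        "intensity_max": vmax,
        "truth": scene.truth,
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=2))

    rows = []
    max_pts = max(len(v.centerline) for v in scene.vessels) \
        if scene.vessels else 0
    for v in scene.vessels:
        row: dict = {
            "vessel_id": v.vessel_id,
            "kind": v.kind,
            "velocity_mm_s": v.velocity_mm_s,
        }
        if isinstance(v, VesselGroundTruth):
            row["true_diameter_um"] = v.true_diameter_um
            row["contrast"] = v.contrast
        for i in range(max_pts):
            if i < len(v.centerline):
                row[f"x{i}"], row[f"y{i}"] = v.centerline[i]
            else:
                row[f"x{i}"] = row[f"y{i}"] = np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(d / "vessels.csv", index=False)

    surf = scene.surfaces
    surf.boundaries.astype("<f8").tofile(d / "surfaces.bin")
    (d / "surfaces.json").write_text(json.dumps({
        "shape": list(surf.boundaries.shape),
        "dtype": "<f8",
        "layer_names": list(surf.layer_names),
        "extent_mm": list(surf.extent_mm),
        "fovea_mm": list(surf.fovea_mm),
    }, indent=2))
    return d


def load_image(directory: str | Path) -> tuple[FundusImage, dict]:
    """Read image.tiff + meta.json; returns the image and the metadata."""
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    raster = tifffile.imread(d / "image.tiff").astype(float)
    pixels = raster / 65535.0 * meta["intensity_max"]
    image = FundusImage(
        pixels=pixels,
        mm_per_px=meta["mm_per_px"],
        fovea_px=tuple(meta["fovea_px"]),
        fov_setting=meta["fov_setting"],
    )
    return image, meta


def load_vessels(path: str | Path) -> list[VesselSegment]:
    """Read a vessel table CSV (wide NaN-padded polyline columns)."""
    df = pd.read_csv(path)
    required = {"vessel_id", "kind", "velocity_mm_s"}
    if not required.issubset(df.columns):
        raise InvalidInputError(
            f"vessel table must have columns {sorted(required)}"
        )
    n_pts = 0
    while f"x{n_pts}" in df.columns:
        n_pts += 1
    vessels: list[VesselSegment] = []
    for _, row in df.iterrows():
        pts = []
        for i in range(n_pts):
            x, y = row[f"x{i}"], row[f"y{i}"]
            if pd.isna(x) or pd.isna(y):
                break
            pts.append((float(x), float(y)))
        common = dict(
            vessel_id=str(row["vessel_id"]),
            kind=str(row["kind"]),
            centerline=np.asarray(pts),
            velocity_mm_s=float(row["velocity_mm_s"]),
        )
        if "true_diameter_um" in df.columns \
                and not pd.isna(row.get("true_diameter_um")):
            vessels.append(VesselGroundTruth(
                **common,
                true_diameter_um=float(row["true_diameter_um"]),
                contrast=float(row.get("contrast", 0.5)),
            ))
        else:
            vessels.append(VesselSegment(**common))
    return vessels


def load_surfaces(directory: str | Path) -> LayerSurfaces:
    """Read surfaces.bin + surfaces.json into a LayerSurfaces."""
    d = Path(directory)
    desc = json.loads((d / "surfaces.json").read_text())
    data = np.fromfile(d / "surfaces.bin", dtype=desc["dtype"])
    boundaries = data.reshape(desc["shape"])
    return LayerSurfaces(
        boundaries=boundaries,
        extent_mm=tuple(desc["extent_mm"]),
        fovea_mm=tuple(desc["fovea_mm"]),
        layer_names=tuple(desc["layer_names"]),
    )


def load_scene(directory: str | Path) -> Scene:
    """Read a full scene bundle back into memory."""
    d = Path(directory)
    image, meta = load_image(d)
    vessels = load_vessels(d / "vessels.csv")
    surfaces = load_surfaces(d)
    return Scene(
        image=image, vessels=vessels, surfaces=surfaces,
        truth=meta.get("truth", {}),
    )
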