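"""File formats: 8-bit PNG frames, multi-page TIFF cubes with JSON
sidecars, CSV manifests and spectra tables, JSON reports, YAML configs.

Every writer has a matching reader so outputs round-trip through the
package's own code.  Coordinates are 0-based, row-major, origin top-left.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .raw import ImageCube, RawFrame, N_BANDS
from .spectral import Spectrum


def write_frame(path, frame: RawFrame) -> None:
    path = Path(path)
    iio.imwrite(path, frame.pixels.astype(np.uint8))


def read_frame(path, role: str = "sample", meta: dict | None = None) -> RawFrame:
    pixels = np.asarray(iio.imread(Path(path)))
    if pixels.ndim == 3:  # grayscale PNG saved with redundant channels
        pixels = pixels[..., 0]
    return RawFrame(pixels=pixels.astype(np.uint8), role=role, meta=dict(meta or {}))


def write_cube(path, cube: ImageCube) -> None:
    """Write a cube as a multi-page TIFF (nine float band pages followed by
    one uint8 mask page) plus a JSON sidecar with labels and stage ledger."""
    path = Path(path)
    with tifffile.TiffWriter(path) as tw:
        for b in range(N_BANDS):
            tw.write(cube.values[:, :, b].astype(np.float32))
        tw.write(cube.mask.astype(np.uint8))
    sidecar = {"labels": _jsonable(cube.labels), "stages": list(cube.stages)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_cube(path) -> ImageCube:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        pages = [p.asarray() for p in tf.pages]
    values = np.stack(pages[:N_BANDS], axis=2).astype(float)
    mask = pages[N_BANDS].astype(np.uint8)
    sidecar_path = path.with_suffix(".json")
    labels, stages = {}, []
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        labels = sidecar.get("labels", {})
        stages = sidecar.get("stages", [])
    return ImageCube(values, mask, labels=labels, stages=stages)


def write_manifest(path, rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)


def spectra_to_frame(spectra: list[Spectrum]) -> pd.DataFrame:
    """Spectra table: patient, region, class, level, band_1..band_9, n_pixels."""
    rows = []
    for s in spectra:
        row = {
            "patient": s.labels.get("patient"),
            "region": s.labels.get("region"),
            "class": s.labels.get("class"),
            "cube_id": s.labels.get("cube_id", -1),
            "level": s.level,
            "n_pixels": s.n_pixels,
        }
        for b in range(N_BANDS):
            row[f"band_{b + 1}"] = s.y[b]
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_spectra(df: pd.DataFrame) -> list[Spectrum]:
    bands = [f"band_{b + 1}" for b in range(N_BANDS)]
    out = []
    for _, row in df.iterrows():
        out.append(
            Spectrum(
                y=row[bands].to_numpy(dtype=float),
                level=row["level"],
                labels={
                    "patient": row["patient"],
                    "region": row["region"],
                    "class": row["class"],
                    "cube_id": int(row.get("cube_id", -1)),
                },
                normalized=True,
                n_pixels=int(row["n_pixels"]),
            )
        )
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=1, sort_keys=True))


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


def load_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def save_config(path, config: dict) -> None:
    Path(path).write_text(yaml.safe_dump(_jsonable(config), sort_keys=True))


def write_rgb_png(path, rgb: np.ndarray) -> None:
    """Write a float (h, w, 3) image in [0, 1] as an 8-bit PNG."""
    iio.imwrite(Path(path), np.clip(np.round(rgb * 255), 0, 255).astype(np.uint8))


#: display palette for classification maps: squamous green, NDBE blue,
#: neoplasia red; masked pixels white
MAP_PALETTE = np.array(
    [[0.20, 0.65, 0.25], [0.20, 0.35, 0.85], [0.85, 0.20, 0.20]]
)


def map_to_rgb(labels: np.ndarray, n_classes: int = 3) -> np.ndarray:
    """Render a label grid (-1 = masked) to an RGB float image."""
    h, w = labels.shape
    out = np.ones((h, w, 3))
    if n_classes <= len(MAP_PALETTE):
        palette = MAP_PALETTE[:n_classes]
    else:  # chart mode: 24 distinct hues
        t = np.linspace(0.0, 1.0, n_classes, endpoint=False)
        palette = np.stack(
            [
                0.5 + 0.5 * np.cos(2 * np.pi * t),
                0.5 + 0.5 * np.cos(2 * np.pi * (t + 1 / 3)),
                0.5 + 0.5 * np.cos(2 * np.pi * (t + 2 / 3)),
            ],
            axis=1,
        )
    for c in range(n_classes):
        out[labels == c] = palette[c]
    return out
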