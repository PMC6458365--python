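"""Reading and writing image stacks and tables.

Stacks travel as multi-page grayscale TIFF (16-bit) or numbered PNG
sequences; internally frames are float arrays in [0, 1].
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile


def write_stack(frames: np.ndarray, path: str | Path) -> None:
    """Write a float [0, 1] stack as 16-bit TIFF or a PNG directory."""
    frames = np.asarray(frames)
    path = Path(path)
    data = np.clip(frames, 0.0, 1.0)
    u16 = (data * 65535.0 + 0.5).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, u16, photometric="minisblack")
    elif path.suffix == "" or path.is_dir():
        path.mkdir(parents=True, exist_ok=True)
        for k, frame in enumerate(u16):
            iio.imwrite(path / f"frame_{k:05d}.png", frame)
    else:
        raise ValueError(f"unsupported stack format {path.suffix!r}")


def read_stack(path: str | Path) -> np.ndarray:
    """Read a TIFF stack or numbered PNG directory back to float [0, 1]."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("frame_*.png"))
        if not files:
            raise ValueError(f"no frame_*.png files in {path}")
        arr = np.stack([iio.imread(f) for f in files])
    elif path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
    else:
        raise ValueError(f"unsupported stack format {path.suffix!r}")
    arr = arr.astype(float)
    scale = 65535.0 if arr.max() > 255 else (255.0 if arr.max() > 1 else 1.0)
    return arr / scale


def write_population_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Per-cell table: cell_id, viscosity_Pa_s, radius_um."""
    out = df.rename(
        columns={"true_viscosity": "viscosity_Pa_s", "mu_Pa_s": "viscosity_Pa_s",
                 "cell_radius": "radius_um", "Rc_um": "radius_um"}
    )
    cols = [c for c in ("cell_id", "viscosity_Pa_s", "radius_um") if c in out]
    out[cols].to_csv(path, index=False, float_format="%.6g")


def read_viscosity_csv(path: str | Path) -> pd.DataFrame:
    """Read a per-cell viscosity table; accepts either naming convention."""
    df = pd.read_csv(path)
    if "viscosity_Pa_s" not in df:
        if "mu_Pa_s" in df:
            df = df.rename(columns={"mu_Pa_s": "viscosity_Pa_s"})
        else:
            raise ValueError(f"{path}: no viscosity column found")
    return df
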