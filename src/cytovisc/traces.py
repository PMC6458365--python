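"""Shared containers for aspiration experiments.

An *aspiration trace* is the primary observable of a continuous
micropipette-aspiration assay: the length ``Lp(t)`` of the cell tongue that
has advanced past the pipette mouth, sampled once per video frame, together
with the radius ``Rc`` of the undeformed cell.  The acquisition settings
(suction pressure, pipette radius, optics calibration) are the fixed
experimental context of one video and are carried separately so that many
traces can share them.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

# Per-frame quality flags (bit mask).
FLAG_LOW_CONTRAST = 1
FLAG_FIT_FAILED = 2
FLAG_INTERPOLATED = 4
FLAG_TRUNCATED = 8


@dataclass(frozen=True)
class AcquisitionSettings:
    """Fixed experimental context of one aspiration video.

    Parameters
    ----------
    suction_pressure : float
        Magnitude of the applied negative pressure, in Pa.  A nominal
        "-10 kPa" aspiration is stored as ``10_000.0``.
    pipette_radius : float
        Inner pipette radius ``Rp`` in µm.
    pixel_size : float
        Image calibration in µm per pixel.
    frame_rate : float
        Acquisition speed in frames per second.
    pipette_axis : int or None
        Image row of the pipette centreline (0-based).  ``None`` until the
        geometry of a concrete video is known.
    mouth_position : int or None
        Image column of the pipette mouth (0-based); columns increase into
        the pipette.
    """

    suction_pressure: float
    pipette_radius: float
    pixel_size: float
    frame_rate: float
    pipette_axis: int | None = None
    mouth_position: int | None = None

    def __post_init__(self) -> None:
        for name in ("suction_pressure", "pipette_radius", "pixel_size", "frame_rate"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")

    def require_geometry(self) -> tuple[int, int]:
        if self.pipette_axis is None or self.mouth_position is None:
            raise ValueError(
                "acquisition settings carry no pipette geometry "
                "(pipette_axis / mouth_position are unset)"
            )
        return int(self.pipette_axis), int(self.mouth_position)

    def with_geometry(self, axis: int, mouth: int) -> "AcquisitionSettings":
        return replace(self, pipette_axis=int(axis), mouth_position=int(mouth))

    # -- config file round-trip ------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "AcquisitionSettings":
        """Load from a YAML config.

        Recognised keys: ``pressure_kPa`` (or ``pressure_Pa``),
        ``pipette_radius_um``, ``pixel_size_um``, ``frame_rate_fps``,
        ``pipette_axis_row``, ``mouth_col``.
        """
        data = yaml.safe_load(Path(path).read_text())
        if "pressure_Pa" in data:
            dp = float(data["pressure_Pa"])
        else:
            dp = float(data["pressure_kPa"]) * 1e3
        return cls(
            suction_pressure=dp,
            pipette_radius=float(data["pipette_radius_um"]),
            pixel_size=float(data["pixel_size_um"]),
            frame_rate=float(data["frame_rate_fps"]),
            pipette_axis=data.get("pipette_axis_row"),
            mouth_position=data.get("mouth_col"),
        )

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "pressure_kPa": self.suction_pressure / 1e3,
            "pipette_radius_um": self.pipette_radius,
            "pixel_size_um": self.pixel_size,
            "frame_rate_fps": self.frame_rate,
        }
        if self.pipette_axis is not None:
            data["pipette_axis_row"] = int(self.pipette_axis)
        if self.mouth_position is not None:
            data["mouth_col"] = int(self.mouth_position)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class AspirationTrace:
    """Aspiration length versus time for one cell.

    ``times`` are in seconds (strictly increasing, nominally spaced at the
    frame period) and ``lengths`` in µm.  ``flags`` is a per-frame bit mask
    built from the ``FLAG_*`` constants.  ``meta`` holds provenance such as
    simulator ground truth; it is never consulted by the analysis.
    """

    cell_id: str
    cell_radius: float  # µm
    times: np.ndarray
    lengths: np.ndarray
    flags: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.lengths.shape:
            raise ValueError("times and lengths must be 1-D arrays of equal length")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(~np.isfinite(self.lengths)) or np.any(self.lengths < -1e-9):
            raise ValueError("aspiration lengths must be finite and non-negative")
        if not (np.isfinite(self.cell_radius) and self.cell_radius > 0):
            raise ValueError(f"cell_radius must be positive, got {self.cell_radius!r}")
        if self.flags is None:
            self.flags = np.zeros(self.times.size, dtype=np.uint8)
        else:
            self.flags = np.asarray(self.flags, dtype=np.uint8)
            if self.flags.shape != self.times.shape:
                raise ValueError("flags must match times in length")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def frame_rate(self) -> float:
        """Nominal frame rate inferred from the median time step."""
        if len(self) < 2:
            raise ValueError("frame rate undefined for a single-frame trace")
        return 1.0 / float(np.median(np.diff(self.times)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.cell_id, "t_s": self.times, "Lp_um": self.lengths,
             "flag": self.flags}
        )

    # -- CSV round-trip ---------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write ``# key=value`` metadata lines followed by a CSV body."""
        buf = io.StringIO()
        buf.write(f"# cell_id={self.cell_id}\n")
        buf.write(f"# cell_radius_um={self.cell_radius:.6f}\n")
        df = pd.DataFrame({"t_s": self.times, "Lp_um": self.lengths, "flag": self.flags})
        df.to_csv(buf, index=False, float_format="%.6f")
        Path(path).write_text(buf.getvalue())

    @classmethod
    def from_csv(cls, path: str | Path) -> "AspirationTrace":
        text = Path(path).read_text()
        meta: dict[str, str] = {}
        body_lines = []
        for line in text.splitlines():
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = value.strip()
            else:
                body_lines.append(line)
        df = pd.read_csv(io.StringIO("\n".join(body_lines)))
        return cls(
            cell_id=meta.get("cell_id", Path(path).stem),
            cell_radius=float(meta["cell_radius_um"]),
            times=df["t_s"].to_numpy(),
            lengths=df["Lp_um"].to_numpy(),
            flags=df["flag"].to_numpy() if "flag" in df else None,
        )
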