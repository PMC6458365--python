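"""Forward simulation of continuous micropipette aspiration.

Everything the analysis consumes can be generated here with known ground
truth: log-normal single-cell viscosity populations, aspiration traces
obeying the Newtonian liquid-drop entry law, and microscope-like grayscale
frame sequences of a cell entering a pipette.

Physical picture
----------------
A cell of radius ``Rc`` (µm) is held at the mouth of a pipette of inner
radius ``Rp < Rc`` and aspirated by a suction of magnitude ``dP`` (Pa).
After a brief elastic response, the tongue length grows linearly at

    v = Rp * (dP - Pcr) / (6 * (1 - Rp/Rc) * mu_c)

where ``mu_c`` is the cytoplasmic viscosity (Pa·s) and ``Pcr`` the
cortical-tension critical pressure.  Entry completes when the aspirated
tongue holds the whole cell volume, ``L_full = (4/3) Rc^3 / Rp^2``
(cylindrical tongue, end caps ignored).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import full_entry_length
from .liquiddrop import critical_pressure
from .traces import FLAG_TRUNCATED, AcquisitionSettings, AspirationTrace

# Upper-quartile deviate of the standard normal; fixed constant so that the
# quartile->log-normal map is exact and dependency-free.
Z_UPPER_QUARTILE = 0.6744897501960817

#: Frame rates the trace simulator accepts (frames/s).  High-speed cameras
#: used for this assay run at several hundred fps; we support a generous
#: envelope around that regime.
SUPPORTED_FRAME_RATE = (50.0, 5000.0)

#: Default cell-radius range in µm for sampled populations.
DEFAULT_RADIUS_RANGE = (6.0, 12.5)


@dataclass(frozen=True)
class PopulationSpec:
    """A log-normal single-cell viscosity population.

    ``log_median`` / ``log_sigma`` parameterize ln(viscosity) ~
    Normal(log_median, log_sigma); radii are uniform on ``radius_range``.
    """

    label: str
    n_cells: int
    log_median: float  # ln(Pa·s)
    log_sigma: float   # ln-scale spread, >= 0
    radius_range: tuple[float, float] = DEFAULT_RADIUS_RANGE

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if not np.isfinite(self.log_sigma) or self.log_sigma < 0:
            raise ValueError(f"log_sigma must be >= 0, got {self.log_sigma}")
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise ValueError(f"radius_range must satisfy 0 < min <= max, got {self.radius_range}")

    @property
    def median(self) -> float:
        return math.exp(self.log_median)

    def quartiles(self) -> tuple[float, float, float]:
        """Population quartiles of the implied log-normal."""
        half = Z_UPPER_QUARTILE * self.log_sigma
        m = self.median
        return m * math.exp(-half), m, m * math.exp(half)


@dataclass(frozen=True)
class TraceSpec:
    """Ground-truth parameters of one simulated entry."""

    true_viscosity: float   # Pa·s
    cell_radius: float      # µm
    elastic_jump: float = 2.0        # µm, section-I amplitude
    elastic_duration: float = 0.002  # s, section-I duration (rapid vs viscous flow)
    noise_sd: float = 0.3   # µm, additive Gaussian noise on Lp
    frame_rate: float = 800.0  # frames/s

    def __post_init__(self) -> None:
        if self.true_viscosity <= 0:
            raise ValueError(f"true_viscosity must be positive, got {self.true_viscosity}")
        if self.cell_radius <= 0:
            raise ValueError(f"cell_radius must be positive, got {self.cell_radius}")
        if self.elastic_jump < 0:
            raise ValueError(f"elastic_jump must be >= 0, got {self.elastic_jump}")
        if self.elastic_duration <= 0:
            raise ValueError(f"elastic_duration must be positive, got {self.elastic_duration}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        lo, hi = SUPPORTED_FRAME_RATE
        if not (lo <= self.frame_rate <= hi):
            raise ValueError(
                f"frame_rate {self.frame_rate} outside supported range {SUPPORTED_FRAME_RATE}"
            )


@dataclass(frozen=True)
class RenderSpec:
    """Appearance of synthetic microscope frames (grayscale in [0, 1])."""

    image_size: tuple[int, int] = (72, 288)  # (rows, cols)
    pixel_size: float = 0.5                  # µm / pixel
    pipette_wall_thickness: float = 2.0      # µm
    background_level: float = 0.08
    cell_level: float = 0.85
    wall_level: float = 0.30
    photon_noise_sd: float = 0.008

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        for name in ("background_level", "cell_level", "wall_level"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.photon_noise_sd < 0:
            raise ValueError("photon_noise_sd must be >= 0")
        contrast = min(
            abs(self.cell_level - self.background_level),
            abs(self.wall_level - self.background_level),
        )
        if self.photon_noise_sd > 0 and contrast <= 3 * self.photon_noise_sd:
            raise ValueError(
                "cell/wall levels must differ from background by more than "
                f"3x photon_noise_sd (contrast {contrast:.3f} vs noise {self.photon_noise_sd:.3f})"
            )


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------

#: Reported cohort quartiles (Pa·s), sample sizes and suction (kPa) used
#: throughout the validation suite.  These are reported experiment-level
#: summaries, used here as generator inputs.
REPORTED_COHORTS: dict[str, dict] = {
    "H1299_10kPa": {"quartiles": (16.7, 42.1, 110.3), "n_cells": 652, "pressure_kPa": 10.0},
    "A549_10kPa": {"quartiles": (144.8, 489.8, 1390.7), "n_cells": 785, "pressure_kPa": 10.0},
    "H1299_CD_10kPa": {"quartiles": (7.1, 13.7, 31.5), "n_cells": 651, "pressure_kPa": 10.0},
    "H1299_5kPa": {"quartiles": (16.9, 48.2, 150.2), "n_cells": 600, "pressure_kPa": 5.0},
}


def fit_lognormal_from_quartiles(
    q1: float,
    median: float,
    q3: float,
    *,
    label: str = "population",
    n_cells: int = 1,
    radius_range: tuple[float, float] = DEFAULT_RADIUS_RANGE,
) -> PopulationSpec:
    """Parameterize a log-normal population from its quartiles.

    The fit is symmetric in log space: ``log_median = ln(median)`` and
    ``log_sigma = ln(q3/q1) / (2 * z0.75)``.  The implied population then
    reproduces the quartile *ratio* exactly and satisfies
    ``q1' * q3' = median**2``; any asymmetry of the supplied quartiles about
    the median in log space is averaged away.
    """
    for name, v in (("q1", q1), ("median", median), ("q3", q3)):
        if not (np.isfinite(v) and v > 0):
            raise ValueError(f"quartile {name}={v!r} must be a positive finite number")
    if not (q1 <= median <= q3):
        raise ValueError(
            f"quartiles must be ordered q1 <= median <= q3, got ({q1}, {median}, {q3})"
        )
    return PopulationSpec(
        label=label,
        n_cells=n_cells,
        log_median=math.log(median),
        log_sigma=math.log(q3 / q1) / (2.0 * Z_UPPER_QUARTILE),
        radius_range=radius_range,
    )


def cohort_spec(name: str, n_cells: int | None = None) -> PopulationSpec:
    """Population spec for one of the reported cohorts (see REPORTED_COHORTS)."""
    info = REPORTED_COHORTS[name]
    q1, med, q3 = info["quartiles"]
    return fit_lognormal_from_quartiles(
        q1, med, q3, label=name, n_cells=n_cells or info["n_cells"]
    )


def sample_population(spec: PopulationSpec, seed: int) -> pd.DataFrame:
    """Draw a single-cell table (cell_id, true_viscosity, cell_radius).

    Viscosities are log-normal per ``spec``; radii uniform on
    ``spec.radius_range``.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    visc = np.exp(rng.normal(spec.log_median, spec.log_sigma, spec.n_cells))
    lo, hi = spec.radius_range
    radii = rng.uniform(lo, hi, spec.n_cells)
    ids = [f"{spec.label}_{i:04d}" for i in range(spec.n_cells)]
    return pd.DataFrame(
        {"cell_id": ids, "true_viscosity": visc, "cell_radius": radii}
    )


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------

def entry_rate(
    viscosity: float,
    cell_radius: float,
    acq: AcquisitionSettings,
    T0: float = 1e-5,
) -> float:
    """Section-II aspiration rate ``dLp/dt`` in µm/s from the liquid-drop law."""
    Rp = acq.pipette_radius
    Rc = cell_radius
    if Rc <= Rp:
        raise ValueError(f"cell radius {Rc} µm must exceed pipette radius {Rp} µm")
    pcr = critical_pressure(T0, Rp, Rc)
    dp = acq.suction_pressure
    if dp <= pcr:
        raise ValueError(
            f"suction {dp} Pa does not exceed the critical pressure {pcr:.3g} Pa"
        )
    v_m_per_s = (Rp * 1e-6) * (dp - pcr) / (6.0 * (1.0 - Rp / Rc) * viscosity)
    return v_m_per_s * 1e6


def simulate_trace(
    spec: TraceSpec,
    acq: AcquisitionSettings,
    *,
    seed: int | None = None,
    T0: float = 1e-5,
    max_duration: float = 5.0,
    cell_id: str = "sim",
) -> AspirationTrace:
    """Simulate one entry trace.

    ``Lp(t)`` ramps linearly to ``elastic_jump`` over ``elastic_duration``
    (the phenomenological section I), then grows at the liquid-drop rate
    until the full-entry length is reached.  i.i.d. Gaussian noise of sd
    ``noise_sd`` is added to every sample.  Traces that would run longer
    than ``max_duration`` are truncated and flagged.
    """
    v = entry_rate(spec.true_viscosity, spec.cell_radius, acq, T0)
    l_full = full_entry_length(spec.cell_radius, acq.pipette_radius)
    fr = spec.frame_rate
    jump, ed = spec.elastic_jump, spec.elastic_duration

    if jump >= l_full:
        raise ValueError(
            f"elastic_jump {jump} µm reaches the full-entry length {l_full:.3g} µm"
        )
    if jump == 0:
        ed = 0.0  # no elastic phase at all: purely viscous from t = 0
    t_full = ed + (l_full - jump) / v
    truncated = t_full > max_duration
    t_end = min(t_full, max_duration)
    n_frames = int(math.ceil(t_end * fr)) + 1

    t = np.arange(n_frames) / fr
    if ed > 0:
        lp = np.where(t < ed, jump * t / ed, jump + v * (t - ed))
    else:
        lp = v * t
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        lp = lp + rng.normal(0.0, spec.noise_sd, n_frames)
    lp = np.clip(lp, 0.0, None)

    flags = np.zeros(n_frames, dtype=np.uint8)
    if truncated:
        flags[-1] |= FLAG_TRUNCATED
    return AspirationTrace(
        cell_id=cell_id,
        cell_radius=spec.cell_radius,
        times=t,
        lengths=lp,
        flags=flags,
        meta={
            "true_viscosity": spec.true_viscosity,
            "true_rate_um_s": v,
            "L_full_um": l_full,
            "truncated": truncated,
        },
    )


def simulate_population_traces(
    spec: PopulationSpec,
    acq: AcquisitionSettings,
    seed: int,
    *,
    trace_kwargs: dict | None = None,
    max_duration: float = 5.0,
) -> tuple[pd.DataFrame, list[AspirationTrace]]:
    """Sample a population and simulate one trace per cell.

    Returns the ground-truth table and the traces; per-cell noise seeds are
    spawned deterministically from ``seed``.
    """
    table = sample_population(spec, seed)
    kwargs = dict(trace_kwargs or {})
    seeds = np.random.SeedSequence(seed).spawn(len(table))
    traces = []
    for (row, ss) in zip(table.itertuples(index=False), seeds):
        tspec = TraceSpec(
            true_viscosity=row.true_viscosity, cell_radius=row.cell_radius, **kwargs
        )
        traces.append(
            simulate_trace(
                tspec, acq,
                seed=int(ss.generate_state(1)[0] % (2**31)),
                max_duration=max_duration,
                cell_id=row.cell_id,
            )
        )
    return table, traces


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def body_radius(cell_radius: float, pipette_radius: float, lp: float) -> float:
    """Radius (µm) of the cell body remaining outside the pipette.

    Volume conservation: the sphere sheds the volume of the cylindrical
    tongue of length ``lp``; ``r^3 = Rc^3 - (3/4) Rp^2 lp``, floored at 0.
    """
    r3 = cell_radius**3 - 0.75 * pipette_radius**2 * lp
    return max(r3, 0.0) ** (1.0 / 3.0)


def plan_geometry(
    cell_radius: float,
    acq: AcquisitionSettings,
    render: RenderSpec,
) -> AcquisitionSettings:
    """Place the pipette in the image and validate the canvas size.

    The axis sits at the middle row; the mouth column leaves room for the
    undeformed cell body on the left.  Raises with the minimum canvas size
    when the geometry does not fit.
    """
    rows, cols = render.image_size
    px = render.pixel_size
    rc_px = cell_radius / px
    rp_px = acq.pipette_radius / px
    wall_px = render.pipette_wall_thickness / px
    l_full_px = full_entry_length(cell_radius, acq.pipette_radius) / px

    axis = rows // 2
    mouth = int(math.ceil(2 * rc_px)) + 4
    need_rows = int(math.ceil(2 * max(rc_px, rp_px + wall_px))) + 6
    need_cols = mouth + int(math.ceil(l_full_px)) + 4
    if rows < need_rows or cols < need_cols:
        raise ValueError(
            f"image_size {render.image_size} too small for this geometry; "
            f"need at least ({need_rows}, {need_cols}) pixels"
        )
    return acq.with_geometry(axis, mouth)


def _coverage(dist_px: np.ndarray, radius_px: float) -> np.ndarray:
    """Approximate pixel coverage of a disk edge (linear 1-px feather)."""
    return np.clip(radius_px - dist_px + 0.5, 0.0, 1.0)


def render_frame(
    lp_um: float,
    cell_radius: float,
    acq: AcquisitionSettings,
    render: RenderSpec,
    *,
    return_mask: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Render one noiseless frame; optionally return the true cell mask."""
    axis, mouth = acq.require_geometry()
    rows, cols = render.image_size
    px = render.pixel_size
    rp_px = acq.pipette_radius / px
    wall_px = render.pipette_wall_thickness / px
    lp_px = lp_um / px

    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    cov = np.zeros((rows, cols))

    # cell body outside the pipette, tangent to the mouth plane
    r_out = body_radius(cell_radius, acq.pipette_radius, lp_um) / px
    if r_out > 0:
        d_body = np.hypot(rr - axis, cc - (mouth - r_out))
        cov_body = _coverage(d_body, r_out)
        cov_body[:, mouth:] = 0.0  # the body never crosses the mouth plane
        cov = np.maximum(cov, cov_body)

    # aspirated tongue: channel-filling slug with a rounded leading cap
    if lp_px > 0:
        tip_c = mouth + lp_px - rp_px  # centre column of the hemispherical cap
        dc = np.maximum(cc - tip_c, 0.0)
        d_tip = np.hypot(rr - axis, dc)
        cov_tongue = _coverage(d_tip, rp_px)
        cov_tongue[:, :mouth] = 0.0
        cov = np.maximum(cov, cov_tongue)

    img = render.background_level + (render.cell_level - render.background_level) * cov

    # pipette walls: two opaque bars bounding the channel, columns >= mouth
    dist_axis = np.abs(rr - axis)
    wall = (dist_axis >= rp_px) & (dist_axis < rp_px + wall_px) & (cc >= mouth)
    img[wall] = render.wall_level

    if return_mask:
        mask = (cov > 0.5) & ~wall
        return img, mask
    return img


def render_sequence(
    trace: AspirationTrace,
    acq: AcquisitionSettings,
    render: RenderSpec,
    seed: int | None = None,
    *,
    return_masks: bool = False,
):
    """Render a full image stack (frames, rows, cols) for one trace.

    Frame 0 shows the undeformed cell touching the mouth when the trace
    starts at ``Lp = 0``.  Additive Gaussian noise of sd
    ``render.photon_noise_sd`` is applied per pixel; deterministic under a
    fixed seed.
    """
    if acq.pipette_axis is None or acq.mouth_position is None:
        acq = plan_geometry(trace.cell_radius, acq, render)
    else:
        plan_geometry(trace.cell_radius, acq, render)  # validate canvas

    frames = np.empty((len(trace), *render.image_size), dtype=np.float32)
    masks = np.empty((len(trace), *render.image_size), dtype=bool)
    for k, lp in enumerate(trace.lengths):
        img, mask = render_frame(
            float(lp), trace.cell_radius, acq, render, return_mask=True
        )
        frames[k] = img
        masks[k] = mask
    if render.photon_noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(
            0.0, render.photon_noise_sd, frames.shape
        ).astype(np.float32)
    frames = np.clip(frames, 0.0, 1.0)
    if return_masks:
        return frames, masks
    return frames
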