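"""Two-section kinetics of cell entry.

An entry trace shows a fast initial rise of ``Lp(t)`` (section I, the
elastic response of the cell) followed by a linear increase (section II,
viscous flow of the cytoplasm into the pipette).  This module locates the
I/II boundary by exhaustive two-segment continuous piecewise-linear least
squares, fits the section-II aspiration rate by OLS, and measures the
aspiration time ``Tc`` from first contact to complete entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .traces import AcquisitionSettings, AspirationTrace

#: Fallback contact-detection floor (µm) when no pixel calibration is known;
#: one pixel at a typical 0.5 µm/px calibration.
DEFAULT_DETECTION_FLOOR_UM = 0.5


def full_entry_length(cell_radius: float, pipette_radius: float) -> float:
    """Tongue length at complete entry, ``(4/3) Rc^3 / Rp^2`` in µm."""
    return (4.0 / 3.0) * cell_radius**3 / pipette_radius**2


#: Fraction of L_full above which terminal frames are excluded from the
#: section-II fit (edge effects as the cell rear passes the mouth).
RATE_FIT_CEILING = 0.95

#: Tolerance band for declaring full entry when a trace terminates
#: marginally short of L_full.
FULL_ENTRY_BAND = 0.95

#: F-test p-value below which the two-segment fit is accepted over a single
#: line (i.e. an elastic section is declared present).
SEGMENT_P_THRESHOLD = 1e-3


@dataclass
class KineticsResult:
    """Fitted entry kinetics for one cell."""

    cell_id: str
    boundary_index: int          # first frame of section II
    rate: float                  # dLp/dt, µm/s
    rate_stderr: float           # µm/s
    fit_r2: float
    Tc: float | None             # s; None when full entry was not reached
    full_entry_index: int | None
    n_section2: int = 0
    flags: list[str] = field(default_factory=list)

    def summary(self) -> str:
        tc = f"{self.Tc:.4g} s" if self.Tc is not None else "not reached"
        lines = [
            f"Entry kinetics: {self.cell_id}",
            f"  section I/II boundary   frame {self.boundary_index}",
            f"  aspiration rate dLp/dt  {self.rate:.4g} +/- {self.rate_stderr:.2g} µm/s",
            f"  section II R^2          {self.fit_r2:.4f}  (n={self.n_section2})",
            f"  aspiration time Tc      {tc}",
        ]
        if self.flags:
            lines.append(f"  flags: {', '.join(self.flags)}")
        return "\n".join(lines)


def _first_above(values: np.ndarray, floor: float) -> int | None:
    idx = np.nonzero(values > floor)[0]
    return int(idx[0]) if idx.size else None


def _two_segment_sse(t: np.ndarray, y: np.ndarray, b: int) -> float:
    """SSE of the continuous two-segment linear fit with breakpoint at t[b]."""
    X = np.column_stack([np.ones_like(t), t, np.maximum(t - t[b], 0.0)])
    _, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3 or res.size == 0:
        pred = X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return float(np.sum((y - pred) ** 2))
    return float(res[0])


def segment_sections(
    trace: AspirationTrace,
    acq: AcquisitionSettings | None = None,
    *,
    detection_floor_um: float | None = None,
) -> tuple[int, list[str]]:
    """Locate the boundary frame between elastic section I and viscous section II.

    Fits every candidate breakpoint of a continuous two-segment piecewise
    linear model over the window from first contact to full entry and keeps
    the one minimizing total squared error (ties toward the earliest frame).
    When the two-segment fit is not significantly better than a single line
    (F-style test), the boundary is 0 with a ``no_elastic_section`` flag.

    Returns ``(boundary_index, flags)`` with the index in original trace
    coordinates.
    """
    floor = _default_floor(acq, detection_floor_um)
    y_all = trace.lengths
    t_all = trace.times

    start = _first_above(y_all, floor)
    if start is None:
        raise ValueError(f"trace {trace.cell_id}: no sample above the detection floor")
    start = max(start - 1, 0)  # include the last pre-contact frame as the anchor

    end = _full_entry_index(trace, acq)
    stop = (end + 1) if end is not None else len(trace)
    t = t_all[start:stop]
    y = y_all[start:stop]
    n = t.size
    if n < 8:
        raise ValueError(
            f"trace {trace.cell_id}: need >= 8 frames before full entry, got {n}"
        )

    # single-line reference
    X1 = np.column_stack([np.ones_like(t), t])
    beta1, _, _, _ = np.linalg.lstsq(X1, y, rcond=None)
    sse1 = float(np.sum((y - X1 @ beta1) ** 2))

    lo, hi = 1, n - 4  # candidate breakpoints t[lo:hi]
    # coarse-to-fine scan: exhaustive for short traces, strided + local
    # refinement for long ones (the fit is O(n) per candidate)
    stride = max(1, (hi - lo) // 200)
    best_b, best_sse = 0, np.inf
    for b in range(lo, hi, stride):
        sse = _two_segment_sse(t, y, b)
        if sse < best_sse - 1e-15:  # strict improvement -> earliest tie wins
            best_b, best_sse = b, sse
    if stride > 1 and best_b:
        for b in range(max(lo, best_b - stride), min(hi, best_b + stride + 1)):
            sse = _two_segment_sse(t, y, b)
            if sse < best_sse - 1e-15:
                best_b, best_sse = b, sse

    scale = max(float(np.max(np.abs(y))), 1.0)
    flags: list[str] = []
    degenerate = sse1 <= n * (1e-9 * scale) ** 2
    if degenerate or best_b == 0:
        return start, ["no_elastic_section"] if degenerate else flags
    f_stat = ((sse1 - best_sse) / 2.0) / (best_sse / max(n - 4, 1)) if best_sse > 0 else np.inf
    p = stats.f.sf(f_stat, 2, max(n - 4, 1)) if np.isfinite(f_stat) else 0.0
    if p >= SEGMENT_P_THRESHOLD:
        return start, ["no_elastic_section"]
    return start + best_b, flags


def fit_rate(
    trace: AspirationTrace,
    boundary_index: int,
    acq: AcquisitionSettings | None = None,
) -> tuple[float, float, float, int, list[str]]:
    """OLS slope of section II: ``(rate, stderr, r2, n_used, flags)``.

    Fits frames from ``boundary_index`` up to ``RATE_FIT_CEILING`` of the
    full-entry length (terminal frames excluded); requires >= 4 frames.
    """
    y_all = trace.lengths
    stop = len(trace)
    if acq is not None:
        l_full = full_entry_length(trace.cell_radius, acq.pipette_radius)
        over = np.nonzero(y_all > RATE_FIT_CEILING * l_full)[0]
        if over.size:
            stop = min(stop, int(over[0]) + 1)
    flags: list[str] = []
    if stop - boundary_index < 4 <= len(trace) - boundary_index:
        # keep a fittable section on very short traces rather than dropping
        # the cell; terminal frames then enter the fit (flagged)
        stop = len(trace)
        flags.append("includes_terminal_frames")
    t = trace.times[boundary_index:stop]
    y = y_all[boundary_index:stop]
    if t.size < 4:
        raise ValueError(
            f"trace {trace.cell_id}: section II has {t.size} frames, need >= 4"
        )
    res = stats.linregress(t, y)
    r2 = float(res.rvalue**2)
    if r2 < 0.9:
        flags.append("poor_linear_fit")
    return float(res.slope), float(res.stderr), r2, int(t.size), flags


def _full_entry_index(
    trace: AspirationTrace, acq: AcquisitionSettings | None
) -> int | None:
    if acq is None:
        return None
    l_full = full_entry_length(trace.cell_radius, acq.pipette_radius)
    idx = np.nonzero(trace.lengths >= l_full)[0]
    if idx.size:
        return int(idx[0])
    return None


def _default_floor(
    acq: AcquisitionSettings | None, detection_floor_um: float | None
) -> float:
    """1-pixel-equivalent contact detection floor."""
    if detection_floor_um is not None:
        return detection_floor_um
    if acq is not None:
        return acq.pixel_size
    return DEFAULT_DETECTION_FLOOR_UM


def compute_Tc(
    trace: AspirationTrace,
    acq: AcquisitionSettings,
    *,
    detection_floor_um: float | None = None,
) -> tuple[float | None, int | None, list[str]]:
    """Aspiration time: first contact to complete entry.

    ``Tc = t(first frame with Lp >= L_full) - t(first frame with Lp above the
    detection floor)``.  If the trace never reaches ``L_full`` but terminates
    within the tolerance band (>= 95% of it), the band crossing is used and
    flagged; otherwise ``(None, None, [...])`` is returned ("not reached").
    """
    floor = _default_floor(acq, detection_floor_um)
    l_full = full_entry_length(trace.cell_radius, acq.pipette_radius)
    contact = _first_above(trace.lengths, floor)
    if contact is None:
        return None, None, ["no_contact_detected"]
    full_idx = _full_entry_index(trace, acq)
    flags: list[str] = []
    if full_idx is None:
        band = np.nonzero(trace.lengths >= FULL_ENTRY_BAND * l_full)[0]
        if band.size == 0:
            return None, None, ["full_entry_not_reached"]
        full_idx = int(band[0])
        flags.append("full_entry_within_band")
    return float(trace.times[full_idx] - trace.times[contact]), full_idx, flags


def fit_trace_kinetics(
    trace: AspirationTrace,
    acq: AcquisitionSettings,
    *,
    detection_floor_um: float | None = None,
) -> KineticsResult:
    """Segment, fit the rate and measure Tc for one trace.

    Very fast entries (fewer than 8 frames before full entry, where the
    two-segment search cannot run) fall back to fitting from one frame
    after first contact: the elastic phase lasts under two frame periods at
    the supported camera speeds, so the remaining samples are viscous.  The
    fallback is flagged ``short_trace_no_segmentation``.
    """
    try:
        boundary, seg_flags = segment_sections(
            trace, acq, detection_floor_um=detection_floor_um
        )
    except ValueError as exc:
        if "8 frames" not in str(exc):
            raise
        floor = _default_floor(acq, detection_floor_um)
        contact = _first_above(trace.lengths, floor)
        if contact is None:
            raise
        boundary = min(contact + 1, len(trace) - 4)
        if boundary < 0 or len(trace) - boundary < 4:
            raise
        seg_flags = ["short_trace_no_segmentation"]
    rate, stderr, r2, n2, rate_flags = fit_rate(trace, boundary, acq)
    if rate <= 0:
        raise ValueError(
            f"trace {trace.cell_id}: non-positive fitted aspiration rate {rate:.3g} µm/s"
        )
    tc, full_idx, tc_flags = compute_Tc(
        trace, acq, detection_floor_um=detection_floor_um
    )
    return KineticsResult(
        cell_id=trace.cell_id,
        boundary_index=boundary,
        rate=rate,
        rate_stderr=stderr,
        fit_r2=r2,
        Tc=tc,
        full_entry_index=full_idx,
        n_section2=n2,
        flags=[*seg_flags, *rate_flags, *tc_flags],
    )
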