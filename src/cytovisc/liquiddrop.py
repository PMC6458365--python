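"""Newtonian liquid-drop viscosity inversion.

The cell is idealized as a homogeneous viscous droplet bounded by a cortical
membrane under tension ``T0``.  During continuous aspiration at suction
``dP`` through a pipette of radius ``Rp``, the tongue advances at a constant
rate ``dLp/dt`` related to the cytoplasmic viscosity ``mu_c`` by

    Rp * (dP - Pcr) / (mu_c * dLp/dt) = 6 * (1 - Rp/Rc)

with the critical (threshold) pressure set by cortical tension,

    Pcr = 2 * T0 * (1/Rp - 1/Rc).

For kPa-scale suction Pcr is of order 10 Pa — three orders of magnitude
smaller — so by default it is neglected whenever ``dP/Pcr > 100``.
All interfaces accept radii in µm, pressures in Pa and rates in µm/s;
computation is in SI and viscosities are returned in Pa·s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traces import AcquisitionSettings, AspirationTrace

#: Default cortical tension of tumour cells, N/m (literature order of magnitude).
DEFAULT_T0 = 1e-5

#: dP/Pcr ratio above which Pcr is neglected under the "auto" policy.
PCR_NEGLECT_RATIO = 100.0

#: Rc/Rp below which the thin-annulus geometry is flagged as marginal.
MARGINAL_GEOMETRY_RATIO = 1.1


@dataclass
class CellViscosityRecord:
    """One cell's inversion result (µm / Pa / µm·s⁻¹ / Pa·s units)."""

    cell_id: str
    Rc: float
    Rp: float
    dP: float
    T0: float
    Pcr: float
    dLp_dt: float
    mu_c: float
    pcr_neglected: bool
    flags: tuple[str, ...] = ()


def critical_pressure(T0: float, Rp: float, Rc: float) -> float:
    """Critical suction ``2 T0 (1/Rp - 1/Rc)`` in Pa (radii in µm, T0 in N/m)."""
    if T0 < 0:
        raise ValueError(f"cortical tension T0 must be >= 0, got {T0}")
    if not (0 < Rp <= Rc):
        raise ValueError(
            f"model requires Rc >= Rp > 0, got Rp={Rp} µm, Rc={Rc} µm"
        )
    return 2.0 * T0 * (1.0 / (Rp * 1e-6) - 1.0 / (Rc * 1e-6))


def estimate_viscosity(
    Rp: float,
    Rc: float,
    dP: float,
    dLp_dt: float,
    *,
    T0: float = DEFAULT_T0,
    policy: str = "auto",
) -> tuple[float, float, bool]:
    """Invert the liquid-drop law for the cytoplasmic viscosity.

    Parameters
    ----------
    Rp, Rc : float
        Pipette and cell radii in µm; requires ``Rc > Rp``.
    dP : float
        Suction magnitude in Pa.
    dLp_dt : float
        Fitted section-II aspiration rate in µm/s.
    T0 : float
        Cortical tension in N/m (used only when Pcr is applied).
    policy : {"auto", "include", "neglect"}
        "auto" neglects Pcr when ``dP/Pcr > 100`` (the high-pressure regime),
        otherwise includes it; the other values force one behaviour.

    Returns
    -------
    (mu_c, Pcr, pcr_neglected) : viscosity in Pa·s, the Eq.-level critical
    pressure in Pa, and whether it was dropped from the numerator.
    """
    if Rc <= Rp:
        raise ValueError(
            f"liquid-drop model invalid for Rc <= Rp (Rc={Rc} µm, Rp={Rp} µm)"
        )
    if dLp_dt <= 0:
        raise ValueError(f"aspiration rate must be positive, got {dLp_dt}")
    if policy not in ("auto", "include", "neglect"):
        raise ValueError(f"unknown Pcr policy {policy!r}")

    pcr = critical_pressure(T0, Rp, Rc)
    if policy == "neglect":
        neglect = True
    elif policy == "include":
        neglect = False
    else:
        neglect = (pcr == 0.0) or (dP / pcr > PCR_NEGLECT_RATIO)
    pcr_eff = 0.0 if neglect else pcr
    if dP <= pcr_eff:
        raise ValueError(
            f"suction {dP} Pa does not exceed the applied critical pressure {pcr_eff:.3g} Pa"
        )
    mu = (Rp * 1e-6) * (dP - pcr_eff) / (6.0 * (1.0 - Rp / Rc) * (dLp_dt * 1e-6))
    return mu, pcr, neglect


def invert_pipeline(
    traces: list[AspirationTrace],
    acq: AcquisitionSettings,
    *,
    T0: float = DEFAULT_T0,
    policy: str = "auto",
    detection_floor_um: float | None = None,
    kinetics_results: list | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run kinetics fitting + viscosity inversion over a trace collection.

    Returns ``(records, rejected)`` DataFrames.  Cells violating the model
    geometry or failing the kinetics fit are listed in ``rejected`` with a
    reason, never silently dropped.  Pre-computed ``kinetics_results``
    (aligned with ``traces``) can be supplied to skip refitting.
    """
    from .kinetics import fit_trace_kinetics  # local import: avoid cycle

    if not traces:
        import warnings

        warnings.warn("invert_pipeline received no traces", stacklevel=2)

    rows, rejects = [], []
    for i, trace in enumerate(traces):
        if trace.cell_radius <= acq.pipette_radius:
            rejects.append(
                {"cell_id": trace.cell_id,
                 "reason": f"cell radius {trace.cell_radius:.2f} µm <= pipette radius "
                           f"{acq.pipette_radius:.2f} µm (outside model scope)"}
            )
            continue
        try:
            if kinetics_results is not None:
                kin = kinetics_results[i]
            else:
                kin = fit_trace_kinetics(
                    trace, acq, detection_floor_um=detection_floor_um
                )
            mu, pcr, neglected = estimate_viscosity(
                acq.pipette_radius, trace.cell_radius, acq.suction_pressure,
                kin.rate, T0=T0, policy=policy,
            )
        except ValueError as exc:
            rejects.append({"cell_id": trace.cell_id, "reason": str(exc)})
            continue
        flags = list(kin.flags)
        if trace.cell_radius / acq.pipette_radius < MARGINAL_GEOMETRY_RATIO:
            flags.append("marginal_geometry")
        rows.append(
            {
                "cell_id": trace.cell_id,
                "Rc_um": trace.cell_radius,
                "Rp_um": acq.pipette_radius,
                "dP_Pa": acq.suction_pressure,
                "Pcr_Pa": pcr,
                "pcr_neglected": neglected,
                "boundary_index": kin.boundary_index,
                "rate_um_s": kin.rate,
                "rate_stderr_um_s": kin.rate_stderr,
                "fit_r2": kin.fit_r2,
                "Tc_s": kin.Tc if kin.Tc is not None else np.nan,
                "mu_Pa_s": mu,
                "flags": ";".join(flags),
            }
        )
    records = pd.DataFrame(
        rows,
        columns=[
            "cell_id", "Rc_um", "Rp_um", "dP_Pa", "Pcr_Pa", "pcr_neglected",
            "boundary_index", "rate_um_s", "rate_stderr_um_s", "fit_r2",
            "Tc_s", "mu_Pa_s", "flags",
        ],
    )
    rejected = pd.DataFrame(rejects, columns=["cell_id", "reason"])
    return records, rejected
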