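"""Liquid-drop model fitting, statsmodels-style.

``LiquidDropModel`` bundles a collection of aspiration traces with their
acquisition settings; ``fit()`` runs section segmentation, section-II rate
fitting and viscosity inversion for every cell and returns a
``LiquidDropResults`` carrying the per-cell estimates, rejections,
diagnostics and population summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .liquiddrop import DEFAULT_T0, invert_pipeline
from .popstats import PopulationStats, describe_population
from .traces import AcquisitionSettings, AspirationTrace


class LiquidDropModel:
    """Newtonian liquid-drop model over a set of entry traces.

    Parameters
    ----------
    traces : list of AspirationTrace
        Per-cell aspiration traces (simulated, extracted from images, or
        loaded from CSV).
    acq : AcquisitionSettings
        Shared experimental context (suction, pipette radius, optics).
    T0 : float
        Cortical tension in N/m used for the critical pressure.
    pcr_policy : {"auto", "include", "neglect"}
        Whether the critical pressure enters the inversion (see
        :mod:`cytovisc.liquiddrop`).
    """

    def __init__(
        self,
        traces: list[AspirationTrace],
        acq: AcquisitionSettings,
        *,
        T0: float = DEFAULT_T0,
        pcr_policy: str = "auto",
        detection_floor_um: float | None = None,
    ):
        self.traces = list(traces)
        self.acq = acq
        self.T0 = T0
        self.pcr_policy = pcr_policy
        self.detection_floor_um = detection_floor_um

    @classmethod
    def from_csv(
        cls, paths: list[str | Path] | str | Path, acq: AcquisitionSettings, **kwargs
    ) -> "LiquidDropModel":
        """Build from per-cell trace CSV files (or a directory of them)."""
        if isinstance(paths, (str, Path)) and Path(paths).is_dir():
            paths = sorted(Path(paths).glob("*.csv"))
        elif isinstance(paths, (str, Path)):
            paths = [paths]
        traces = [AspirationTrace.from_csv(p) for p in paths]
        return cls(traces, acq, **kwargs)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        acq: AcquisitionSettings,
        radii: dict[str, float] | pd.Series | None = None,
        **kwargs,
    ) -> "LiquidDropModel":
        """Build from a long table with columns cell_id, t_s, Lp_um.

        Cell radii come either from a ``radius_um`` column or from the
        ``radii`` mapping.
        """
        traces = []
        for cell_id, grp in df.groupby("cell_id", sort=True):
            if radii is not None:
                rc = float(radii[cell_id])
            elif "radius_um" in grp:
                rc = float(grp["radius_um"].iloc[0])
            else:
                raise ValueError(f"no radius available for cell {cell_id!r}")
            traces.append(
                AspirationTrace(
                    cell_id=str(cell_id),
                    cell_radius=rc,
                    times=grp["t_s"].to_numpy(),
                    lengths=grp["Lp_um"].to_numpy(),
                    flags=grp["flag"].to_numpy() if "flag" in grp else None,
                )
            )
        return cls(traces, acq, **kwargs)

    def fit(self) -> "LiquidDropResults":
        records, rejected = invert_pipeline(
            self.traces,
            self.acq,
            T0=self.T0,
            policy=self.pcr_policy,
            detection_floor_um=self.detection_floor_um,
        )
        return LiquidDropResults(model=self, records=records, rejected=rejected)


@dataclass
class LiquidDropResults:
    """Per-cell viscosity estimates and diagnostics."""

    model: LiquidDropModel
    records: pd.DataFrame
    rejected: pd.DataFrame
    extras: dict = field(default_factory=dict)

    @property
    def viscosities(self) -> np.ndarray:
        return self.records["mu_Pa_s"].to_numpy()

    @property
    def n_accepted(self) -> int:
        return len(self.records)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def population_stats(self, label: str = "population", edges=None) -> PopulationStats:
        return describe_population(self.viscosities, label=label, edges=edges)

    def summary(self) -> str:
        acq = self.model.acq
        head = [
            "Newtonian liquid-drop viscosity fit",
            "===================================",
            f"  cells accepted / rejected : {self.n_accepted} / {self.n_rejected}",
            f"  suction dP                : {acq.suction_pressure / 1e3:.3g} kPa",
            f"  pipette radius Rp         : {acq.pipette_radius:.3g} µm",
            f"  cortical tension T0       : {self.model.T0:.3g} N/m",
            f"  Pcr policy                : {self.model.pcr_policy}",
            f"  software                  : cytovisc {__version__}",
        ]
        if self.n_accepted:
            mu = self.viscosities
            q1, med, q3 = np.quantile(mu, [0.25, 0.5, 0.75])
            rate = self.records["rate_um_s"]
            head += [
                "",
                f"  viscosity quartiles [Pa·s]: {q1:.1f} / {med:.1f} / {q3:.1f}",
                f"  QCD                       : {(q3 - q1) / (q3 + q1) * 100:.0f}%",
                f"  aspiration rate [µm/s]    : median {rate.median():.3g} "
                f"(range {rate.min():.3g}–{rate.max():.3g})",
                f"  median section-II R²      : {self.records['fit_r2'].median():.4f}",
            ]
        if self.n_rejected:
            head += ["", "  rejection reasons:"]
            for reason, cnt in self.rejected["reason"].value_counts().items():
                head.append(f"    [{cnt}] {reason}")
        return "\n".join(head)

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False, float_format="%.6g")

    def plot_trace(self, cell_id: str, ax=None):
        """Plot one trace with its fitted section boundary and rate line."""
        import matplotlib.pyplot as plt

        trace = next(t for t in self.model.traces if t.cell_id == cell_id)
        rec = self.records.set_index("cell_id").loc[cell_id]
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(trace.times * 1e3, trace.lengths, ".", ms=3, label="Lp(t)")
        b = int(rec["boundary_index"])
        tb = trace.times[b]
        ax.axvline(tb * 1e3, color="grey", ls="--", lw=1, label="section I/II")
        tt = trace.times[b:]
        ax.plot(
            tt * 1e3,
            trace.lengths[b] + rec["rate_um_s"] * (tt - tb),
            "r-",
            lw=1,
            label=f"fit: {rec['rate_um_s']:.0f} µm/s",
        )
        ax.set_xlabel("time [ms]")
        ax.set_ylabel("aspiration length Lp [µm]")
        ax.set_title(f"{cell_id}: µc = {rec['mu_Pa_s']:.1f} Pa·s")
        ax.legend()
        return ax
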