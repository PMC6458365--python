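"""Population summaries of single-cell viscosity.

Single-cell viscosity distributions are heavily right-skewed, so the
summary statistics are order-based: the three quartiles, the quartile
coefficient of dispersion QCD = (Q3 - Q1)/(Q3 + Q1) (scale-free, robust),
and a histogram over 1-2-5 decade bins (1-10, 10-20, 20-50, 50-100, ... Pa·s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def quartiles(values) -> tuple[float, float, float]:
    """(Q1, median, Q3) with linear interpolation between order statistics.

    Uses the common "type 7" quantile convention (the numpy default).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot compute quartiles of an empty collection")
    if np.any(~np.isfinite(values)) or np.any(values <= 0):
        raise ValueError("viscosity values must be finite and positive")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    return float(q1), float(med), float(q3)


def qcd(q1: float, q3: float) -> float:
    """Quartile coefficient of dispersion, ``(Q3 - Q1)/(Q3 + Q1)``."""
    if q1 <= 0:
        raise ValueError(f"Q1 must be positive, got {q1}")
    if q3 < q1:
        raise ValueError(f"requires Q3 >= Q1, got Q1={q1}, Q3={q3}")
    return (q3 - q1) / (q3 + q1)


def qcd_percent(q1: float, q3: float) -> int:
    """QCD rounded to the nearest integer percent (the reporting convention)."""
    return int(round(qcd(q1, q3) * 100))


def decade_edges(lo: float, hi: float) -> np.ndarray:
    """1-2-5 bin edges covering [lo, hi]: ..., 1, 10, 20, 50, 100, 200, ...

    Below 10 each decade is a single bin (e.g. 1-10); from 10 upward decades
    split at 2x and 5x, expressing the conventional reporting bins.
    """
    if not (0 < lo <= hi):
        raise ValueError("need 0 < lo <= hi")
    import math

    d0 = math.floor(math.log10(lo))
    d1 = math.ceil(math.log10(hi))
    edges = []
    for d in range(d0, d1 + 1):
        base = 10.0**d
        edges.append(base)
        if d >= 1:
            edges.extend([2 * base, 5 * base])
    edges = np.array(sorted(set(edges)))
    return edges[(edges >= 10.0**d0) & (edges <= 10.0**d1)]


@dataclass
class PopulationStats:
    """Quartiles, dispersion and binned distribution of one population."""

    label: str
    n_cells: int
    q1: float
    median: float
    q3: float
    qcd: float                 # fraction in [0, 1)
    histogram: pd.DataFrame    # columns: lo, hi, count, percent
    peak_bin: tuple[float, float]

    @property
    def qcd_percent(self) -> int:
        return int(round(self.qcd * 100))

    def summary(self) -> str:
        lines = [
            f"Population: {self.label}  (n = {self.n_cells})",
            f"  quartiles [Pa·s]   Q1 = {self.q1:.1f}   median = {self.median:.1f}   "
            f"Q3 = {self.q3:.1f}",
            f"  quartile coeff. of dispersion   {self.qcd_percent}%",
            f"  modal bin   {self.peak_bin[0]:g}-{self.peak_bin[1]:g} Pa·s",
            "  distribution:",
        ]
        for row in self.histogram.itertuples(index=False):
            lo = f"{row.lo:g}" if np.isfinite(row.lo) else "<"
            hi = f"{row.hi:g}" if np.isfinite(row.hi) else ">"
            lines.append(f"    {lo:>7} - {hi:<7}  {row.percent:5.1f}%")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_cells": self.n_cells,
            "q1_Pa_s": self.q1,
            "median_Pa_s": self.median,
            "q3_Pa_s": self.q3,
            "qcd": self.qcd,
            "qcd_percent": self.qcd_percent,
            "peak_bin_Pa_s": list(self.peak_bin),
            "histogram": self.histogram.to_dict(orient="records"),
        }


def decade_histogram(
    values, edges: np.ndarray | None = None
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Percentage histogram over 1-2-5 decade bins, plus the modal bin.

    With explicit ``edges``, values outside the range are counted into open
    end-bins (-inf / +inf bounds).  Percentages sum to 100; the modal bin is
    the one with the largest percentage (ties resolved toward the lower bin).
    """
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0) or np.any(~np.isfinite(values)):
        raise ValueError("viscosity values must be finite and positive")
    if edges is None:
        edges = decade_edges(values.min(), values.max())
    else:
        edges = np.asarray(edges, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be strictly increasing")
    full = np.concatenate([[-np.inf], edges, [np.inf]])
    counts, _ = np.histogram(values, bins=full)
    df = pd.DataFrame({"lo": full[:-1], "hi": full[1:], "count": counts})
    # keep open end-bins only when occupied
    keep = np.isfinite(df["lo"]) & np.isfinite(df["hi"]) | (df["count"] > 0)
    df = df[keep].reset_index(drop=True)
    df["percent"] = df["count"] / values.size * 100.0
    peak = df.loc[df["percent"].idxmax()]  # idxmax: first (lowest) bin on ties
    return df, (float(peak.lo), float(peak.hi))


def describe_population(
    values, label: str = "population", edges: np.ndarray | None = None
) -> PopulationStats:
    """Full summary of one per-cell viscosity collection."""
    values = np.asarray(values, dtype=float)
    q1, med, q3 = quartiles(values)
    hist, peak = decade_histogram(values, edges)
    return PopulationStats(
        label=label,
        n_cells=int(values.size),
        q1=q1,
        median=med,
        q3=q3,
        qcd=qcd(q1, q3),
        histogram=hist,
        peak_bin=peak,
    )
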