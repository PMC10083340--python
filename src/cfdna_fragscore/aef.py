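"""Automated-electrophoresis (AEF) trace analysis.

Capillary electrophoresis instruments report a mass-concentration density
over fragment size.  Because molarity of a DNA species is its mass divided
by (length x mass-per-bp), converting the trace to a molar density and
integrating above two size cutoffs gives the ratio of molar concentrations
of fragments longer than each cutoff — an orthogonal, PCR-free readout of
the same "short vs long" contrast the amplicon assays measure.  High
molecular weight contamination pushes the above-612-bp integral up and the
ratio down toward 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema, savgol_filter

from .constants import BP_MASS_G_PER_MOL

__all__ = [
    "Electropherogram",
    "molar_density",
    "molarity_ratio",
    "find_nucleosomal_peaks",
    "NO_HMW_SENTINEL",
    "read_trace_tsv",
    "write_trace_tsv",
]

#: Returned by :func:`molarity_ratio` when no mass lies above the long
#: cutoff (denominator integral is zero): "no HMW material detected".
NO_HMW_SENTINEL: float = math.inf


@dataclass
class Electropherogram:
    """A size-vs-mass-concentration trace.

    ``size_bp`` is a strictly increasing grid (bp); ``mass_density`` is the
    non-negative mass concentration per bp on that grid (arbitrary linear
    units — ng/ul per bp on real instruments, total-bp units for synthetic
    traces).
    """

    size_bp: np.ndarray
    mass_density: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.size_bp = np.asarray(self.size_bp, dtype=float)
        self.mass_density = np.asarray(self.mass_density, dtype=float)
        if self.size_bp.ndim != 1 or self.size_bp.size < 2:
            raise ValueError("size grid needs at least 2 points")
        if self.size_bp.shape != self.mass_density.shape:
            raise ValueError("size grid and density must have equal length")
        if np.any(np.diff(self.size_bp) <= 0):
            raise ValueError("size grid must be strictly increasing")
        if np.any(self.mass_density < 0):
            raise ValueError("mass density must be non-negative")
        if np.any(self.size_bp <= 0):
            raise ValueError("sizes must be positive")

    @property
    def total_mass(self) -> float:
        """Trapezoidal integral of the mass density over the grid."""
        return float(np.trapezoid(self.mass_density, self.size_bp))


def molar_density(eg: Electropherogram, mass_per_bp: float = BP_MASS_G_PER_MOL) -> np.ndarray:
    """Molar density over the size grid: ``mass_density(L) / (L * mass_per_bp)``.

    Linear in the input mass.  With ``mass_per_bp = 1`` and a trace in
    total-bp units the integral equals the fragment count, which is how the
    synthetic-generator round-trip is checked.
    """
    return eg.mass_density / (eg.size_bp * mass_per_bp)


def _integral_above(x: np.ndarray, y: np.ndarray, cut: float) -> float:
    """Trapezoidal integral of y over [cut, x_max], interpolating at cut."""
    if cut >= x[-1]:
        return 0.0
    if cut <= x[0]:
        return float(np.trapezoid(y, x))
    y_cut = float(np.interp(cut, x, y))
    mask = x > cut
    xs = np.concatenate(([cut], x[mask]))
    ys = np.concatenate(([y_cut], y[mask]))
    return float(np.trapezoid(ys, xs))


def molarity_ratio(
    eg: Electropherogram,
    short_cut: float = 106.0,
    long_cut: float = 612.0,
    mass_per_bp: float = BP_MASS_G_PER_MOL,
) -> float:
    """Ratio of molarities of fragments longer than ``short_cut`` vs ``long_cut``.

    Both integrals are taken over the molar density above the respective
    cutoff.  Scale-invariant: multiplying the whole trace by a constant
    leaves the ratio unchanged.  Returns :data:`NO_HMW_SENTINEL` (inf) when
    the denominator integral is zero — i.e. no material above the long
    cutoff — rather than raising.
    """
    if not short_cut < long_cut:
        raise ValueError("short_cut must be < long_cut")
    if short_cut < eg.size_bp[0] or long_cut > eg.size_bp[-1]:
        raise ValueError("cutoffs must lie inside the size grid")
    md = molar_density(eg, mass_per_bp)
    num = _integral_above(eg.size_bp, md, short_cut)
    den = _integral_above(eg.size_bp, md, long_cut)
    if den <= 0.0:
        return NO_HMW_SENTINEL
    return num / den


def find_nucleosomal_peaks(
    eg: Electropherogram,
    windows: list[tuple[float, float]] = ((360.0, 400.0), (540.0, 600.0)),
    smooth_window_bp: float = 15.0,
    use_molar: bool = False,
) -> dict[tuple[float, float], list[float]]:
    """Locate local density maxima inside given size windows.

    Di- and tri-nucleosome degradation products appear as peaks near
    360-400 bp and 540-600 bp; their presence in a trace indicates white
    blood cell DNA released during storage.  The density is
    Savitzky-Golay smoothed (window ``smooth_window_bp``) before the maxima
    search.  Returns a mapping from window to the list of peak sizes found
    there (empty list when none).  Peak positions are invariant to scaling
    the trace by a constant.
    """
    y = molar_density(eg) if use_molar else eg.mass_density
    step = float(np.median(np.diff(eg.size_bp)))
    wl = max(5, int(round(smooth_window_bp / step)) | 1)  # odd, >= 5 points
    if wl < y.size:
        y = savgol_filter(y, window_length=wl, polyorder=2)
    idx = argrelextrema(y, np.greater_equal, order=2)[0]
    # Drop flat-zero "maxima" and plateau duplicates.
    idx = idx[y[idx] > 1e-12 * max(y.max(), 1e-300)]
    out: dict[tuple[float, float], list[float]] = {}
    for lo, hi in windows:
        sizes = eg.size_bp[idx]
        out[(lo, hi)] = [float(s) for s in sizes if lo <= s <= hi]
    return out


def read_trace_tsv(path, sample_id: str | None = None) -> Electropherogram:
    """Read a two-column TSV trace (size_bp, concentration)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (size_bp, concentration)")
    return Electropherogram(
        size_bp=df.iloc[:, 0].to_numpy(float),
        mass_density=df.iloc[:, 1].to_numpy(float),
        sample_id=sample_id or str(path),
    )


def write_trace_tsv(eg: Electropherogram, path) -> None:
    pd.DataFrame({"size_bp": eg.size_bp, "concentration": eg.mass_density}).to_csv(
        path, sep="\t", index=False
    )
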