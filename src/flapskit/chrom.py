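"""Molecular-weight distributions and extracellular hydrolysis rates from
gel permeation chromatography (GPC) of fluorescently labeled polysaccharides.

A FLA-PS incubation is sampled over time; each sample is run over a GPC
column with fluorescence detection, yielding an elution profile in which
elution position maps to molecular weight through a calibration of
standards. Extracellular (endo-acting and exo-acting) enzymes cleave the
labeled parent chain, so label mass migrates from the high-MW parent peak
toward low-MW classes. The hydrolysis rate is derived from that migration:
moving one monomer-equivalent of label from the parent chain (degree of
polymerization ``P``) into fragments of representative DP ``d`` requires
``1/d - 1/P`` glycosidic cleavages per monomer-equivalent, so

    rate = C * sum_i max(0, f_i(t) - f_i(0)) * (1/d_i - 1/P) / (t - t0)

where ``C`` is the added concentration in nmol monomer L^-1 and ``f_i`` the
label mass fraction in MW class ``i``. The parent class carries weight 0,
and only increases in non-parent classes count, so sequential cleavage of
fragments is not double-counted. The rate unit is nmol monomer L^-1 h^-1.

Because the rate divides a bounded distribution change by elapsed time, a
substrate that is fully hydrolyzed early in an incubation yields estimates
that decay as 1/t at later sampling times; sparse late timepoints therefore
underestimate the true activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

if TYPE_CHECKING:  # pragma: no cover
    from .synth import SubstrateSpec

#: Mass of an anhydro-hexose residue (Da); chain MW = residues * mass + water.
MONOMER_MASS_DA = 162.14
WATER_MASS_DA = 18.02


def mw_of_dp(dp):
    """Molecular weight (Da) of a glucan chain of degree of polymerization dp."""
    return MONOMER_MASS_DA * np.asarray(dp, dtype=float) + WATER_MASS_DA


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone linear map between log10(MW / Da) and elution position.

    ``elution = intercept + slope * log10(MW)``; on a size-exclusion column
    larger molecules elute earlier, so ``slope`` is normally negative.
    """

    slope: float
    intercept: float
    mw_min: float
    mw_max: float
    residual_rms: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.slope) or self.slope == 0.0:
            raise ValueError("calibration slope must be finite and nonzero")
        if not (0 < self.mw_min < self.mw_max):
            raise ValueError("calibration MW range must satisfy 0 < mw_min < mw_max")

    def elution_of_mw(self, mw):
        return self.intercept + self.slope * np.log10(np.asarray(mw, dtype=float))

    def mw_of_elution(self, elution):
        return 10.0 ** ((np.asarray(elution, dtype=float) - self.intercept) / self.slope)

    @property
    def elution_range(self) -> tuple[float, float]:
        lo, hi = self.elution_of_mw(self.mw_max), self.elution_of_mw(self.mw_min)
        return (min(lo, hi), max(lo, hi))


def fit_calibration(standards) -> CalibrationCurve:
    """Fit a calibration curve from (MW_Da, elution_position) standard pairs.

    Requires at least 3 standards with distinct molecular weights whose
    elution positions are strictly monotone in MW; fits elution linearly in
    log10(MW) by least squares.
    """
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("standards must be an (n, 2) array of (MW_Da, elution)")
    if arr.shape[0] < 3:
        raise ValueError("at least 3 calibration standards are required")
    mw, elu = arr[:, 0], arr[:, 1]
    if np.any(mw <= 0):
        raise ValueError("standard molecular weights must be positive")
    order = np.argsort(mw)
    mw, elu = mw[order], elu[order]
    if np.any(np.diff(mw) == 0):
        raise ValueError("standard molecular weights must be distinct")
    d = np.diff(elu)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("standards are not monotone: elution must be strictly "
                         "monotone in molecular weight")
    slope, intercept = np.polyfit(np.log10(mw), elu, 1)
    resid = elu - (intercept + slope * np.log10(mw))
    return CalibrationCurve(slope=float(slope), intercept=float(intercept),
                            mw_min=float(mw[0]), mw_max=float(mw[-1]),
                            residual_rms=float(np.sqrt(np.mean(resid ** 2))))


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MWBinning:
    """Ordered molecular-weight classes expressed in degree of polymerization.

    ``edges`` are strictly decreasing DP bin boundaries (len = n_bins + 1),
    from above the parent chain down to below the monomer; bin ``i`` spans
    ``(edges[i+1], edges[i]]``. ``reps`` are the representative DP values
    ``d_i`` used as cleavage cut-weights; when omitted they default to the
    geometric mean of the bin edges.
    """

    edges: tuple[float, ...]
    reps: tuple[float, ...] = field(default=())

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=float)
        if e.ndim != 1 or len(e) < 2:
            raise ValueError("edges must be a 1-D sequence of length >= 2")
        if np.any(np.diff(e) >= 0):
            raise ValueError("bin edges must be strictly decreasing in DP")
        if e[-1] > 1.0:
            raise ValueError("lowest bin must include DP 1")
        if len(self.reps) == 0:
            object.__setattr__(self, "reps", tuple(np.sqrt(e[:-1] * e[1:])))
        elif len(self.reps) != len(e) - 1:
            raise ValueError("reps must have one entry per bin")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def bin_of_dp(self, dp: float) -> int:
        e = np.asarray(self.edges)
        for i in range(self.n_bins):
            if e[i + 1] < dp <= e[i]:
                return i
        raise ValueError(f"DP {dp} outside binning range ({e[-1]}, {e[0]}]")

    @classmethod
    def default(cls, parent_dp: int) -> "MWBinning":
        """Six classes: parent, 0.5*parent, 0.1*parent, DP 10, DP 2-3, monomer.

        Representative DPs sit on the class centers (monomer exactly 1);
        edges are the geometric midpoints of adjacent representatives.
        Classes that collide for small parents are merged.
        """
        p = float(parent_dp)
        reps = [p, 0.5 * p, 0.1 * p, 10.0, 2.5, 1.0]
        # drop non-decreasing duplicates (e.g. 0.1*P == 10 for P == 100)
        uniq = [reps[0]]
        for r in reps[1:]:
            if r < uniq[-1] * 0.999:
                uniq.append(r)
        inner = [float(np.sqrt(a * b)) for a, b in zip(uniq[:-1], uniq[1:])]
        edges = [2.0 * p] + inner + [0.5]
        return cls(edges=tuple(edges), reps=tuple(uniq))

    @classmethod
    def log_spaced(cls, parent_dp: int, n_bins: int = 16) -> "MWBinning":
        """Fine log-spaced classes from the parent chain down to the monomer."""
        p = float(parent_dp)
        reps = np.geomspace(p, 1.0, n_bins)
        inner = np.sqrt(reps[:-1] * reps[1:])
        edges = np.concatenate([[2.0 * p], inner, [reps[-1] ** 2 / inner[-1]]])
        return cls(edges=tuple(edges), reps=tuple(reps))


# ---------------------------------------------------------------------------
# Distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MWDistribution:
    """Label mass fractions across MW classes at one incubation timepoint."""

    timepoint_h: float
    fractions: tuple[float, ...]
    total_signal: float

    def __post_init__(self):
        f = np.asarray(self.fractions)
        if np.any(f < 0):
            raise ValueError("mass fractions must be non-negative")
        if abs(f.sum() - 1.0) > 1e-6:
            raise ValueError("mass fractions must sum to 1 within 1e-6")


def bin_distribution(elution, signal, calib: CalibrationCurve, bins: MWBinning,
                     blank=None, timepoint_h: float = 0.0) -> MWDistribution:
    """Integrate a blank-subtracted elution profile into MW-class fractions.

    The signal is integrated (trapezoid rule) between the elution positions
    of each bin's DP edges; negative bin integrals are floored at zero and
    the result normalized to fractions. ``total_signal`` is the integral
    over the full binned range before normalization.
    """
    x = np.asarray(elution, dtype=float)
    y = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.shape != y.shape or len(x) < 3:
        raise ValueError("elution and signal must be matching 1-D arrays (n >= 3)")
    if np.any(np.diff(x) <= 0):
        raise ValueError("elution positions must be strictly increasing")
    if blank is not None:
        y = y - np.asarray(blank, dtype=float)

    lo, hi = calib.elution_range
    if x[0] > lo + 1e-9 or x[-1] < hi - 1e-9:
        raise ValueError("chromatogram does not cover the calibrated elution range")

    # cumulative integral, interpolated at arbitrary elution positions
    cum = np.concatenate([[0.0], cumulative_trapezoid(y, x)])

    def integral(a: float, b: float) -> float:
        a, b = sorted((a, b))
        a, b = np.clip([a, b], x[0], x[-1])
        return float(np.interp(b, x, cum) - np.interp(a, x, cum))

    e = np.asarray(bins.edges)
    positions = calib.elution_of_mw(mw_of_dp(e))
    raw = np.array([integral(positions[i], positions[i + 1])
                    for i in range(bins.n_bins)])
    total = float(raw.sum())
    if total <= 0:
        raise ValueError("total signal <= 0 after blank subtraction; sample rejected")
    clipped = np.clip(raw, 0.0, None)
    fractions = clipped / clipped.sum()
    return MWDistribution(timepoint_h=float(timepoint_h),
                          fractions=tuple(fractions), total_signal=total)


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HydrolysisRateEstimate:
    """Hydrolysis rate in nmol monomer L^-1 h^-1 with sample provenance."""

    rate: float
    substrate: str
    elapsed_h: float
    station: str = ""
    depth_m: float = float("nan")
    replicate: int = 0
    killed_corrected: bool = False

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("hydrolysis rate must be non-negative")
        if self.elapsed_h <= 0:
            raise ValueError("elapsed time must be positive")


def cut_weights(bins: MWBinning, parent_dp: int) -> np.ndarray:
    """Cleavages per monomer-equivalent to reach each class from the parent.

    ``w_i = 1/d_i - 1/P``: a chain of DP P needs P-1 cuts to become P
    monomers, i.e. ``1 - 1/P`` cuts per monomer-equivalent; reaching
    fragments of DP d needs ``1/d - 1/P``. The class containing the parent
    carries weight 0.
    """
    d = np.asarray(bins.reps, dtype=float)
    w = np.clip(1.0 / d - 1.0 / parent_dp, 0.0, None)
    w[bins.bin_of_dp(float(parent_dp))] = 0.0
    return w


def compute_rate(dist0: MWDistribution, dist_t: MWDistribution,
                 substrate: "SubstrateSpec", bins: MWBinning,
                 **provenance) -> HydrolysisRateEstimate:
    """Hydrolysis rate from the change in MW distribution between t0 and t.

    Only increases of non-parent class fractions contribute, weighted by the
    per-class cleavage count; see the module docstring for the formula.
    """
    elapsed = dist_t.timepoint_h - dist0.timepoint_h
    if elapsed <= 0:
        raise ValueError("dist_t must be later than dist0 (zero elapsed time)")
    w = cut_weights(bins, substrate.parent_dp)
    df = np.asarray(dist_t.fractions) - np.asarray(dist0.fractions)
    cuts_per_monomer = float(np.sum(np.clip(df, 0.0, None) * w))
    rate = substrate.monomer_conc * cuts_per_monomer / elapsed
    return HydrolysisRateEstimate(rate=rate, substrate=substrate.name,
                                  elapsed_h=float(elapsed), **provenance)


def correct_with_killed(live: HydrolysisRateEstimate,
                        killed: HydrolysisRateEstimate) -> HydrolysisRateEstimate:
    """Subtract the killed-control (autoclaved seawater) rate, flooring at 0."""
    if live.substrate != killed.substrate:
        raise ValueError("killed control substrate does not match live incubation")
    if abs(live.elapsed_h - killed.elapsed_h) > 1e-9:
        raise ValueError("killed control elapsed time does not match live incubation")
    return HydrolysisRateEstimate(rate=max(0.0, live.rate - killed.rate),
                                  substrate=live.substrate, elapsed_h=live.elapsed_h,
                                  station=live.station, depth_m=live.depth_m,
                                  replicate=live.replicate, killed_corrected=True)


def rate_timecourse(series_list, substrate: "SubstrateSpec",
                    calib: CalibrationCurve, bins: MWBinning,
                    blank=None) -> pd.DataFrame:
    """Per-timepoint rates (always against t0) for replicate chromatogram series.

    Parameters
    ----------
    series_list : sequence of ChromatogramSeries
        Replicate incubations; each needs >= 2 timepoints including t0.

    Returns
    -------
    DataFrame with one row per (replicate, timepoint > 0):
    substrate, replicate, timepoint_h, rate_nmol_monomer_L_h.
    """
    rows = []
    for rep, series in enumerate(series_list):
        t = np.asarray(series.timepoints_h, dtype=float)
        if len(t) < 2:
            raise ValueError("a rate timecourse needs at least 2 timepoints")
        if t[0] != 0.0:
            raise ValueError("missing t0 chromatogram; rates are computed against t0")
        dists = [bin_distribution(series.elution, series.signals[i], calib, bins,
                                  blank=blank, timepoint_h=t[i])
                 for i in range(len(t))]
        for i in range(1, len(t)):
            est = compute_rate(dists[0], dists[i], substrate, bins, replicate=rep)
            rows.append({"substrate": substrate.name, "replicate": rep,
                         "timepoint_h": t[i],
                         "rate_nmol_monomer_L_h": est.rate})
    return pd.DataFrame(rows)


def summarize_replicates(rates: pd.DataFrame) -> pd.DataFrame:
    """Replicate mean and standard deviation per substrate and timepoint."""
    g = rates.groupby(["substrate", "timepoint_h"])["rate_nmol_monomer_L_h"]
    out = g.agg(rate_mean="mean", rate_sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0)
    return out.reset_index()
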