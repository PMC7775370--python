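"""In situ corrections for potential hydrolysis rates.

Incubations of deep water run at ~20 degC measure *potential* rates; two
corrections translate them to approximate in situ rates:

* temperature — laminarin hydrolysis correlates linearly with temperature;
  evaluating the regression ``y = 0.5644 x + 0.5098`` (rate in nmol monomer
  L^-1 h^-1, x in degC, r^2 = 0.7695) at the in situ temperature gives the
  temperature-corrected rate (e.g. 2.3 at 3.19 degC).
* community growth — warm incubation lets an opportunist bloom; scaling by
  the ratio of initial to day-3 cell counts (e.g. 5% at 2,800 m) converts
  to the rate the in situ standing stock could have sustained, reported in
  pmol monomer L^-1 h^-1.

Both corrections are scalar multiplications/evaluations; composing them is
order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class TemperatureModel:
    """Linear temperature -> laminarin hydrolysis rate regression.

    Units: slope in nmol monomer L^-1 h^-1 per degC, intercept in nmol
    monomer L^-1 h^-1. ``r_squared`` is diagnostic only. Predictions are
    clamped at 0 below the x-intercept.
    """

    slope: float = 0.5644
    intercept: float = 0.5098
    r_squared: float = 0.7695

    def __post_init__(self):
        import math
        if not (math.isfinite(self.slope) and math.isfinite(self.intercept)):
            raise ValueError("slope and intercept must be finite")


@dataclass(frozen=True)
class GrowthCorrection:
    """Initial vs reference (day-3) cell counts for growth normalization."""

    n_initial: float
    n_reference: float

    def __post_init__(self):
        if self.n_initial <= 0 or self.n_reference <= 0:
            raise ValueError("cell counts must be positive")

    @property
    def ratio(self) -> float:
        return self.n_initial / self.n_reference


def temperature_adjust(model: TemperatureModel, in_situ_temp: float) -> float:
    """Rate (nmol monomer L^-1 h^-1) predicted at the in situ temperature.

    Direct evaluation ``max(0, slope * T + intercept)``.
    """
    import math
    if not math.isfinite(in_situ_temp):
        raise ValueError("temperature must be finite")
    return max(0.0, model.slope * in_situ_temp + model.intercept)


def temperature_rescale(model: TemperatureModel, measured_rate: float,
                        incubation_temp: float, in_situ_temp: float) -> float:
    """Ratio variant: rescale a measured rate by y(T_insitu)/y(T_incubation).

    Provided for sensitivity analysis; the default correction is direct
    evaluation (`temperature_adjust`).
    """
    y_inc = temperature_adjust(model, incubation_temp)
    if y_inc <= 0:
        raise ValueError("regression predicts no activity at incubation temperature")
    return measured_rate * temperature_adjust(model, in_situ_temp) / y_inc


def growth_adjust(rate_nmol: float, corr: GrowthCorrection) -> float:
    """Growth-normalized rate in pmol monomer L^-1 h^-1.

    Multiplies the rate by the initial/reference cell ratio and converts
    nmol -> pmol (factor exactly 1000).
    """
    if corr.ratio <= 0:
        raise ValueError("growth correction ratio must be positive")
    return rate_nmol * corr.ratio * 1000.0


def fraction_of_reference(n_initial: float, n_reference: float) -> float:
    """Initial cell count as a percentage of the reference count."""
    if n_reference <= 0:
        raise ValueError("reference cell count must be positive")
    return 100.0 * n_initial / n_reference
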