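"""Michaelis–Menten fitting and substrate-discrimination arithmetic.

The model is the steady-state Michaelis–Menten rate law

    v([S]) = kcat * [S] / (Km + [S])

with ``v`` in s^-1 per enzyme and ``[S]`` in the concentration unit carried
by the data (mM or uM — the unit travels with every quantity, so catalytic
efficiencies kcat/Km come out in unit^-1 s^-1 and never silently mix
scales).  Fitting is nonlinear least squares (scipy's trust-region
reflective, equivalent to Levenberg–Marquardt away from the bounds) with a
double-reciprocal (Lineweaver–Burk) linear pre-fit supplying the starting
point; parameter standard errors come from the fit covariance.

Derived quantities:

* efficiency — kcat/Km, the second-order rate constant of the free
  enzyme + free substrate reaction;
* discrimination factor — (kcat/Km)_cognate / (kcat/Km)_noncognate, the
  fold preference of the enzyme for its proper substrate, conventionally
  printed as a nearest integer;
* fold change — a plain ratio for "kcat decreased N-fold" statements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "RateSeries",
    "MMParams",
    "FitError",
    "UnitError",
    "fit_mm",
    "efficiency",
    "discrimination_factor",
    "fold_change",
    "simulate_mm_data",
    "mm_rate",
]


class FitError(RuntimeError):
    """The nonlinear fit failed to converge or produced an invalid estimate."""


class UnitError(ValueError):
    """Quantities with different concentration units were combined."""


def mm_rate(s, kcat: float, km: float):
    """The Michaelis–Menten rate law v = kcat*S/(Km+S)."""
    s = np.asarray(s, dtype=float)
    return kcat * s / (km + s)


@dataclass(frozen=True)
class RateSeries:
    """One substrate-saturation data set: concentrations vs initial velocities."""

    substrate: str
    stereo: str  # 'l', 'd' or 'achiral'
    concentrations: np.ndarray
    velocities: np.ndarray
    conc_unit: str = "mM"
    replicate: str = ""

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        vel = np.asarray(self.velocities, dtype=float)
        if conc.ndim != 1 or conc.shape != vel.shape:
            raise ValueError("concentrations and velocities must be equal-length 1-d arrays")
        if conc.size < 4:
            raise ValueError("need at least 4 concentration points to fit two parameters")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.allclose(conc, conc[0]):
            raise ValueError("concentrations must not all be equal")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "velocities", vel)


@dataclass(frozen=True)
class MMParams:
    """Fitted turnover number and Michaelis constant with standard errors."""

    kcat: float
    km: float
    kcat_se: float
    km_se: float
    conc_unit: str = "mM"
    substrate: str = ""

    def __post_init__(self) -> None:
        if self.kcat <= 0 or self.km <= 0:
            raise FitError(
                f"invalid Michaelis-Menten estimate: kcat={self.kcat}, Km={self.km} "
                "(both must be positive)"
            )

    @property
    def efficiency(self) -> float:
        """Catalytic efficiency kcat/Km in conc_unit^-1 s^-1."""
        return self.kcat / self.km


def _reciprocal_init(conc: np.ndarray, vel: np.ndarray) -> tuple[float, float]:
    """Lineweaver–Burk starting point: 1/v = (Km/kcat)(1/S) + 1/kcat."""
    mask = vel > 0
    if mask.sum() >= 2:
        slope, intercept = np.polyfit(1.0 / conc[mask], 1.0 / vel[mask], 1)
        if intercept > 0 and slope > 0:
            return 1.0 / intercept, slope / intercept
    # fallback when the linearization is unusable (noise, nonpositive v)
    vmax = max(float(np.max(vel)), 1e-12)
    return 1.05 * vmax, float(np.median(conc))


def fit_mm(series: RateSeries) -> MMParams:
    """Nonlinear least-squares Michaelis–Menten fit of one rate series."""
    conc = series.concentrations
    vel = series.velocities
    p0 = _reciprocal_init(conc, vel)
    try:
        popt, pcov = curve_fit(
            mm_rate,
            conc,
            vel,
            p0=p0,
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(
            f"Michaelis-Menten fit did not converge for {series.substrate!r} "
            f"(start kcat={p0[0]:.3g}, Km={p0[1]:.3g}): {exc}"
        ) from exc
    kcat, km = popt
    se = np.sqrt(np.diag(pcov))
    return MMParams(
        kcat=float(kcat),
        km=float(km),
        kcat_se=float(se[0]),
        km_se=float(se[1]),
        conc_unit=series.conc_unit,
        substrate=series.substrate,
    )


def efficiency(params: MMParams) -> float:
    """kcat/Km in the unit convention of the fitted series (conc_unit^-1 s^-1)."""
    return params.efficiency


def _as_efficiency(value: "float | MMParams") -> tuple[float, str | None]:
    if isinstance(value, MMParams):
        return value.efficiency, value.conc_unit
    return float(value), None


def discrimination_factor(
    cognate: "float | MMParams",
    noncognate: "float | MMParams",
    rounded: bool = True,
) -> float:
    """(kcat/Km)_cognate / (kcat/Km)_noncognate.

    Accepts raw efficiencies or fitted :class:`MMParams` (units are checked
    when both carry one).  By convention the factor is printed as a nearest
    integer; pass ``rounded=False`` for the raw ratio.
    """
    eff_c, unit_c = _as_efficiency(cognate)
    eff_n, unit_n = _as_efficiency(noncognate)
    if unit_c is not None and unit_n is not None and unit_c != unit_n:
        raise UnitError(f"efficiency units differ: {unit_c} vs {unit_n}")
    if eff_c <= 0 or eff_n <= 0:
        raise ValueError("efficiencies must be positive")
    ratio = eff_c / eff_n
    return float(round(ratio)) if rounded else ratio


def fold_change(a: float, b: float) -> float:
    """Plain ratio a/b for N-fold increase/decrease statements (display
    rounding is the caller's concern)."""
    if b == 0:
        raise ZeroDivisionError("fold change denominator is zero")
    return a / b


def simulate_mm_data(
    kcat: float,
    km: float,
    concentrations: Sequence[float],
    noise_sigma: float = 0.0,
    seed: int | None = None,
    conc_unit: str = "mM",
    substrate: str = "synthetic",
    stereo: str = "l",
) -> RateSeries:
    """Synthetic saturation data from a known parameter pair.

    ``noise_sigma`` is the Gaussian noise s.d. expressed as a fraction of
    Vmax (= kcat), i.e. 0.02 adds 2%-of-Vmax noise; 0 gives the exact curve.
    Deterministic for a fixed seed.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    v = mm_rate(conc, kcat, km)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sigma * kcat, size=conc.shape)
    return RateSeries(
        substrate=substrate,
        stereo=stereo,
        concentrations=conc,
        velocities=v,
        conc_unit=conc_unit,
    )
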