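"""Equilibrium DNA-binding and ATP-hydrolysis fits.

DNA affinity is measured by fluorescence polarization (FP) of a short
labeled duplex titrated with condensin.  Because the probe
concentration is comparable to the dissociation constant, the fit uses
the quadratic ligand-depletion binding isotherm rather than the simple
hyperbola:

    FP(C) = FP_max / (2 [DNA]) * ( (C + [DNA] + Kd)
                                   - sqrt((C + [DNA] + Kd)^2 - 4 C [DNA]) )

with C the condensin concentration, [DNA] the probe concentration (both
μM), Kd the dissociation constant (μM) and FP_max the polarization
change at saturation (mP).  All replicate points are fit globally with
shared Kd and FP_max.

ATPase activity is the slope of a linear fit of the hydrolyzed
ADP/(ADP+ATP) fraction over the linear range of the reaction, rescaled
to ATP per second per holocomplex by [ATP]_total / [enzyme].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

ArrayLike = Union[float, np.ndarray]


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class FPModel:
    kd_um: float
    fp_max_mp: float
    dna_conc_um: float

    def __post_init__(self) -> None:
        if self.kd_um <= 0 or self.fp_max_mp <= 0 or self.dna_conc_um <= 0:
            raise ValueError("kd, fp_max and dna_conc must all be > 0")


@dataclass
class FPFitResult:
    model: FPModel
    kd_se: float
    fp_max_se: float
    rss: float
    n_points: int

    def normalized_curve(self, conc_um: np.ndarray) -> np.ndarray:
        """Fit curve divided by FP_max (bound fraction of the probe)."""
        return fp_predict(conc_um, self.model) / self.model.fp_max_mp


@dataclass
class ATPaseTimeCourse:
    t_s: np.ndarray
    adp_fraction: np.ndarray
    enzyme_um: float = 0.2
    atp_total_um: float = 2000.0

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.adp_fraction = np.asarray(self.adp_fraction, dtype=float)
        if self.t_s.shape != self.adp_fraction.shape:
            raise ValueError("t and adp_fraction must be aligned")
        if np.any((self.adp_fraction < 0) | (self.adp_fraction > 1)):
            raise ValueError("adp_fraction must lie in [0, 1]")
        if self.enzyme_um <= 0 or self.atp_total_um <= 0:
            raise ValueError("enzyme and ATP concentrations must be > 0")


@dataclass
class ATPaseFitResult:
    rate_per_s: float
    rate_se: float
    slope_per_s: float
    n_linear: int


def fp_predict(conc_um: ArrayLike, model: FPModel) -> ArrayLike:
    """Quadratic ligand-depletion binding isotherm; 0 <= FP <= FP_max."""
    c = np.asarray(conc_um, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    d, kd = model.dna_conc_um, model.kd_um
    s = c + d + kd
    disc = s * s - 4.0 * c * d
    if np.any(disc < 0):
        raise FitError("negative discriminant: invalid binding parameters")
    fp = model.fp_max_mp / (2.0 * d) * (s - np.sqrt(disc))
    return float(fp) if np.isscalar(conc_um) else fp


def fit_fp(titration: pd.DataFrame, dna_conc_um: float,
           p0: Optional[tuple[float, float]] = None) -> FPFitResult:
    """Global least-squares fit of Kd and FP_max over all replicates.

    ``titration`` needs columns ``conc_uM`` and ``fp_mP`` (a ``rep``
    column may be present but is not used: all points enter the global
    fit with equal weight).
    """
    c = titration["conc_uM"].to_numpy(dtype=float)
    y = titration["fp_mP"].to_numpy(dtype=float)
    if np.unique(c).size < 5:
        raise ValueError("at least 5 distinct concentrations are required")
    if np.ptp(y) <= 1e-12 * max(abs(y).max(), 1.0):
        raise FitError("constant FP series: binding signal absent")
    if p0 is None:
        fp0 = float(np.max(y))
        half = 0.5 * fp0
        kd0 = float(c[np.argmin(np.abs(y - half))]) or 1.0
        p0 = (max(kd0, 1e-3), max(fp0, 1e-3))

    def f(cc, kd, fpmax):
        return fp_predict(cc, FPModel(kd_um=kd, fp_max_mp=fpmax,
                                      dna_conc_um=dna_conc_um))

    try:
        popt, pcov = optimize.curve_fit(f, c, y, p0=p0,
                                        bounds=([1e-9, 1e-9], [np.inf, np.inf]),
                                        maxfev=20_000)
    except (RuntimeError, ValueError) as err:
        raise FitError(f"FP fit did not converge: {err}") from err
    if not np.all(np.isfinite(pcov)):
        raise FitError("FP fit degenerate: non-finite parameter covariance")
    resid = y - f(c, *popt)
    se = np.sqrt(np.diag(pcov))
    return FPFitResult(
        model=FPModel(kd_um=float(popt[0]), fp_max_mp=float(popt[1]),
                      dna_conc_um=dna_conc_um),
        kd_se=float(se[0]), fp_max_se=float(se[1]),
        rss=float(np.sum(resid ** 2)), n_points=int(c.size))


def fit_atpase(tc: ATPaseTimeCourse, linear_range_max: float = 0.3,
               fit_intercept: bool = True) -> ATPaseFitResult:
    """ATP-hydrolysis rate from the linear range of the time course.

    The linear range is the maximal prefix with hydrolyzed fraction
    below ``linear_range_max``; the slope of the least-squares line
    over it is rescaled by [ATP]_total / [enzyme] to ATP per second per
    holocomplex.  Replicate measurements at the same timepoint all
    enter the fit.  ``fit_intercept=False`` constrains the line through
    the origin, appropriate when the zero-time hydrolyzed fraction is
    known to be zero (as for the synthetic time courses); the default
    keeps a free intercept to absorb background ADP in real assays.
    """
    if np.unique(tc.t_s).size < 4:
        raise ValueError("at least 4 time points are required")
    order = np.argsort(tc.t_s, kind="stable")
    t, y = tc.t_s[order], tc.adp_fraction[order]
    in_range = y < linear_range_max
    n_lin = int(np.argmin(in_range)) if not in_range.all() else t.size
    if n_lin < 3:
        raise FitError(f"fewer than 3 points in the linear range "
                       f"(fraction < {linear_range_max})")
    t, y = t[:n_lin], y[:n_lin]
    if fit_intercept:
        res = stats.linregress(t, y)
        slope, se = float(res.slope), float(res.stderr)
    else:
        stt = float(np.sum(t * t))
        slope = float(np.sum(t * y) / stt)
        resid = y - slope * t
        dof = max(t.size - 1, 1)
        se = float(np.sqrt(np.sum(resid ** 2) / dof / stt))
    scale = tc.atp_total_um / tc.enzyme_um
    return ATPaseFitResult(rate_per_s=slope * scale, rate_se=se * scale,
                           slope_per_s=slope, n_linear=n_lin)


def fold_stimulation(basal_rate: float, stimulated_rate: float) -> float:
    """DNA stimulation of ATPase activity: stimulated / basal."""
    if basal_rate <= 0:
        raise ValueError("basal rate must be > 0")
    return stimulated_rate / basal_rate
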