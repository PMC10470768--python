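"""Formula-level assay computations: competitive index, one-site binding, melt Tm.

These are the small quantitative reductions used around interbacterial
competition and biophysics experiments: the competitive index from CFU
counts of co-cultured donor and recipient strains, the equilibrium
dissociation constant from a one-site binding isotherm (biolayer
interferometry style, with optional nonspecific-control subtraction), and
the melting temperature from the inflection point of a thermal-shift
fluorescence curve.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence, Tuple

import numpy as np
import scipy.optimize
import scipy.signal

__all__ = [
    "CompetitionCounts",
    "CompetitiveIndex",
    "BindingCurve",
    "BindingFit",
    "MeltCurve",
    "competitive_index",
    "fit_one_site",
    "melt_tm",
    "NoTransitionError",
    "FitError",
]


class FitError(RuntimeError):
    """Raised when a curve fit fails to converge."""


class NoTransitionError(ValueError):
    """Raised when a melt curve shows no unfolding transition."""


# ---------------------------------------------------------------------------
# Competitive index
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CompetitionCounts:
    pre_recipient: float
    pre_donor: float
    post_recipient: float
    post_donor: float

    def __post_init__(self) -> None:
        for name in ("pre_recipient", "pre_donor", "post_recipient", "post_donor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.pre_recipient <= 0 or self.pre_donor <= 0:
            raise ValueError("pre-competition counts must be positive")


@dataclasses.dataclass
class CompetitiveIndex:
    value: float
    at_detection_limit: bool = False


def competitive_index(
    counts: CompetitionCounts, pseudocount: Optional[float] = None
) -> CompetitiveIndex:
    """Competitive index from CFU counts.

    ``CI = (post_recipient / pre_recipient) / (post_donor / pre_donor)``.
    A zero post-competition recipient count returns 0 flagged as at the
    limit of detection (or uses ``pseudocount`` in place of zero if given).
    """
    if counts.post_donor <= 0:
        raise ValueError("post-competition donor count is zero: CI undefined")
    post_r = counts.post_recipient
    at_lod = post_r == 0
    if at_lod and pseudocount is not None:
        post_r = pseudocount
        at_lod = False
    value = (post_r / counts.pre_recipient) / (counts.post_donor / counts.pre_donor)
    return CompetitiveIndex(value=value, at_detection_limit=at_lod)


# ---------------------------------------------------------------------------
# One-site equilibrium binding
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BindingCurve:
    concentrations: np.ndarray      # molar, > 0
    responses: np.ndarray           # instrument units
    nonspecific: Optional[np.ndarray] = None  # matched control responses

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.nonspecific is not None:
            self.nonspecific = np.asarray(self.nonspecific, dtype=float)
            if self.nonspecific.shape != self.responses.shape:
                raise ValueError("nonspecific control must match responses in length")
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must have equal length")
        if len(self.concentrations) < 4:
            raise ValueError("need at least 4 doses for a one-site fit")
        if (self.concentrations <= 0).any():
            raise ValueError("concentrations must be positive")


@dataclasses.dataclass
class BindingFit:
    kd: float                       # molar
    rmax: float
    rss: float
    residuals: np.ndarray
    converged: bool
    n_starts: int


def fit_one_site(curve: BindingCurve) -> BindingFit:
    """Least-squares fit of ``R(C) = Rmax * C / (Kd + C)``.

    The nonspecific control, if present, is subtracted point-wise first.
    The fit runs in log-Kd parameterisation (Kd > 0 by construction) with
    multiple starts taken from the dose-range quartiles to avoid local
    minima.
    """
    conc = curve.concentrations
    resp = curve.responses.copy()
    if curve.nonspecific is not None:
        resp = resp - curve.nonspecific

    def residual(theta: np.ndarray) -> np.ndarray:
        log_kd, rmax = theta
        kd = np.exp(log_kd)
        return rmax * conc / (kd + conc) - resp

    starts = np.quantile(np.log(conc), [0.25, 0.5, 0.75])
    rmax0 = float(resp.max()) if resp.max() > 0 else 1.0
    best = None
    n_ok = 0
    for lk in starts:
        sol = scipy.optimize.least_squares(residual, x0=[lk, rmax0], method="lm", max_nfev=5000)
        if not sol.success:
            continue
        n_ok += 1
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        raise FitError("one-site binding fit failed to converge from all starts")
    rss, sol = best
    kd = float(np.exp(sol.x[0]))
    return BindingFit(
        kd=kd,
        rmax=float(sol.x[1]),
        rss=rss,
        residuals=-sol.fun,  # observed minus fitted
        converged=True,
        n_starts=n_ok,
    )


# ---------------------------------------------------------------------------
# Thermal melt
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MeltCurve:
    temperatures: np.ndarray        # deg C, strictly ascending
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.shape != self.fluorescence.shape:
            raise ValueError("temperatures and fluorescence must have equal length")
        if len(self.temperatures) < 10:
            raise ValueError("need at least 10 points for Tm assignment")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("temperatures must be strictly increasing")


def melt_tm(curve: MeltCurve, smooth_window: int = 5) -> float:
    """Melting temperature at the fluorescence-curve inflection point.

    The curve is smoothed with a centred moving quadratic (Savitzky-Golay)
    of odd window ``smooth_window`` and the first derivative is taken from
    the same filter; Tm is the temperature of the maximum absolute
    derivative, refined by parabolic interpolation between neighbouring
    grid points.  Curves without a transition (derivative signal
    indistinguishable from baseline) raise :class:`NoTransitionError`.
    """
    if smooth_window % 2 == 0 or smooth_window < 3:
        raise ValueError("smooth_window must be odd and >= 3")
    t = curve.temperatures
    f = curve.fluorescence
    step = float(np.median(np.diff(t)))
    deriv = scipy.signal.savgol_filter(f, smooth_window, polyorder=2, deriv=1, delta=step)
    mag = np.abs(deriv)
    i = int(np.argmax(mag))

    # a transition shows as a derivative peak well above the typical
    # (baseline) derivative level; flat or purely linear curves do not
    frange = float(f.max() - f.min())
    if frange <= 0 or mag[i] <= 3.0 * float(np.median(mag)) + 1e-12:
        raise NoTransitionError("no unfolding transition detected in melt curve")

    # parabolic refinement around the discrete peak
    if 0 < i < len(t) - 1:
        y0, y1, y2 = mag[i - 1], mag[i], mag[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            offset = 0.5 * (y0 - y2) / denom
            offset = float(np.clip(offset, -0.5, 0.5))
            return float(t[i] + offset * step)
    return float(t[i])
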