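"""Elastic-scan (fixed-window) analysis of hydrated-powder temperature series.

Workflow: a temperature series of elastic intensity curves S(Q) is normalized
to the lowest-temperature curve, then each curve is fitted two ways:

* Gaussian approximation S(Q) = S(0) exp(-Q^2 <u2>/3), restricted to the
  self-consistently chosen low-Q window Q^2 <u2> < 2.4 (the Gaussian
  approximation is only valid at small Q^2 <u2>), yielding the mean square
  displacement (MSD);
* heterogeneity model S(Q) = S(0) (1 + Q^2 <r2>/beta)^(-beta) over *all* Q
  points, yielding the mean-square position fluctuation (MSPF) <r2> and the
  motional-heterogeneity parameter beta.

Both fits are weighted nonlinear least squares (weights 1/sigma^2); the MSD
fit is not log-linearized, because log-linearization distorts the weights
where the intensity is small.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import models
from .exceptions import FitError, FitWindowError, NormalizationError, ParameterError

__all__ = [
    "EinsCurve",
    "EinsSeries",
    "MsdResult",
    "MspfResult",
    "normalize_series",
    "MsdModel",
    "MspfModel",
    "fit_msd",
    "fit_mspf",
    "fit_series",
]

#: beta values at or above this are reported as indistinguishable from the
#: Gaussian model over the accessible Q range (deviation < noise).
BETA_UPPER_BOUND = 1.0e6
BETA_GAUSSIAN_FLAG = 1.0e5


@dataclass(frozen=True, eq=False)
class EinsCurve:
    """Elastic intensity vs Q at one temperature, with 1-sigma errors."""

    q: np.ndarray
    intensity: np.ndarray
    error: np.ndarray
    temperature: float

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        e = np.asarray(self.error, dtype=float)
        if not (q.shape == i.shape == e.shape) or q.ndim != 1:
            raise ParameterError("q, intensity and error must be equal-length 1-d arrays")
        if np.any(np.diff(q) <= 0):
            raise ParameterError("q must be strictly increasing")
        if np.any(e <= 0):
            raise ParameterError("errors must be > 0")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        object.__setattr__(self, "error", e)

    def __len__(self) -> int:
        return self.q.size


@dataclass(frozen=True, eq=False)
class EinsSeries:
    """Temperature-ordered elastic curves on one Q grid."""

    curves: tuple[EinsCurve, ...]
    resolution_ueV: float = 8.0
    normalized: bool = False

    def __post_init__(self):
        curves = tuple(self.curves)
        if not curves:
            raise ParameterError("series must contain at least one curve")
        temps = [c.temperature for c in curves]
        if any(t2 <= t1 for t1, t2 in zip(temps, temps[1:])):
            raise ParameterError("curve temperatures must be strictly increasing")
        q0 = curves[0].q
        for c in curves[1:]:
            if c.q.shape != q0.shape or not np.allclose(c.q, q0, rtol=1e-9, atol=0):
                raise ParameterError("all curves must share one Q grid")
        object.__setattr__(self, "curves", curves)

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([c.temperature for c in self.curves])

    @property
    def reference(self) -> EinsCurve:
        """The lowest-temperature curve (the normalization reference)."""
        return self.curves[0]


def normalize_series(series: EinsSeries) -> EinsSeries:
    """Divide every curve pointwise by the lowest-temperature curve.

    Errors propagate by the quotient rule,
    sigma(A/B) = |A/B| sqrt((sA/A)^2 + (sB/B)^2); the reference curve becomes
    identically 1 with its propagated error.  The extracted MSD/MSPF are then
    relative to the reference temperature.
    """
    if series.normalized:
        raise NormalizationError("series is already normalized")
    ref = series.reference
    bad = np.flatnonzero(ref.intensity <= 0)
    if bad.size:
        raise NormalizationError(
            f"reference curve has nonpositive intensity at Q = {ref.q[bad[0]]:g} 1/A")
    out = []
    for c in series.curves:
        ratio = c.intensity / ref.intensity
        rel = np.sqrt((c.error / c.intensity) ** 2 + (ref.error / ref.intensity) ** 2)
        err = np.abs(ratio) * rel
        out.append(EinsCurve(c.q, ratio, err, c.temperature))
    return replace(series, curves=tuple(out), normalized=True)


# --------------------------------------------------------------------------
# results
# --------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class MsdResult:
    """Gaussian-approximation fit of one elastic curve."""

    temperature: float
    u2: float
    s0: float
    u2_err: float
    s0_err: float
    q_max_used: float
    n_points_used: int
    covariance: np.ndarray
    validity_limit: float

    def summary(self) -> str:
        return (f"MSD fit at T = {self.temperature:.1f} K: "
                f"<u2> = {self.u2:.4f} +/- {self.u2_err:.4f} A^2, "
                f"S(0) = {self.s0:.4f} +/- {self.s0_err:.4f}, "
                f"window Q <= {self.q_max_used:.3f} 1/A "
                f"({self.n_points_used} points, Q^2<u2> < {self.validity_limit:g})")

    def plot(self, curve: EinsCurve | None = None, ax=None):
        """Plot the fitted Gaussian decay (and the data if given)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if curve is not None:
            ax.errorbar(curve.q ** 2, curve.intensity, curve.error, fmt="o", ms=3,
                        label="data")
            qline = np.linspace(curve.q[0], curve.q[-1], 200)
        else:
            qline = np.linspace(0, self.q_max_used, 200)
        par = models.GaussianEinsParams(self.s0, max(self.u2, 0.0))
        ax.plot(qline ** 2, models.eins_gaussian_intensity(qline, par),
                label="Gaussian fit")
        ax.axvline(self.q_max_used ** 2, ls=":", color="grey")
        ax.set_xlabel(r"$Q^2$ [$\mathrm{\AA^{-2}}$]")
        ax.set_ylabel("S(Q)/S(Q, T$_{ref}$)")
        ax.set_yscale("log")
        ax.legend()
        return ax


@dataclass(frozen=True, eq=False)
class MspfResult:
    """Heterogeneity-model fit of one elastic curve (all Q points)."""

    temperature: float
    r2: float
    beta: float
    s0: float
    r2_err: float
    beta_err: float
    s0_err: float
    covariance: np.ndarray
    gaussian_indistinguishable: bool

    def summary(self) -> str:
        note = " [Gaussian-indistinguishable]" if self.gaussian_indistinguishable else ""
        return (f"MSPF fit at T = {self.temperature:.1f} K: "
                f"<r2> = {self.r2:.4f} +/- {self.r2_err:.4f} A^2, "
                f"beta = {self.beta:.4g} +/- {self.beta_err:.3g}, "
                f"S(0) = {self.s0:.4f} +/- {self.s0_err:.4f}{note}")


# --------------------------------------------------------------------------
# model objects
# --------------------------------------------------------------------------

class MsdModel:
    """Gaussian-approximation MSD extraction with a self-consistent Q window.

    The validity criterion Q^2 <u2> < `validity_limit` depends on the fitted
    <u2> itself, so the window is found iteratively: fit on the lowest six
    points, compute q_max from q_max^2 u2 = limit, refit on all points with
    q <= q_max, and repeat until the window is stable (at most 10 rounds).
    """

    def __init__(self, curve: EinsCurve, validity_limit: float = 2.4):
        if len(curve) < 4:
            raise FitWindowError("need at least 4 points for the MSD fit")
        if validity_limit <= 0:
            raise ParameterError("validity_limit must be > 0")
        self.curve = curve
        self.validity_limit = float(validity_limit)

    @staticmethod
    def _model(q, s0, u2):
        return s0 * np.exp(-q * q * u2 / 3.0)

    def _fit_window(self, mask: np.ndarray):
        c = self.curve
        q, i, e = c.q[mask], c.intensity[mask], c.error[mask]
        u2_guess = 0.0
        if i[0] > 0 and i[-1] > 0 and i[-1] < i[0]:
            u2_guess = 3.0 * np.log(i[0] / i[-1]) / (q[-1] ** 2 - q[0] ** 2)
        try:
            popt, pcov = curve_fit(
                self._model, q, i, p0=[max(i[0], 1e-6), max(u2_guess, 1e-6)],
                sigma=e, absolute_sigma=True,
                bounds=([1e-12, 0.0], [np.inf, np.inf]), maxfev=10000)
        except RuntimeError as exc:  # pragma: no cover - pathological input
            raise FitError(f"MSD fit failed to converge: {exc}") from exc
        return popt, pcov

    def fit(self) -> MsdResult:
        c = self.curve
        mask = np.zeros(len(c), dtype=bool)
        mask[: min(6, len(c))] = True
        popt = pcov = None
        for _ in range(10):
            popt, pcov = self._fit_window(mask)
            u2 = popt[1]
            if u2 <= 0:
                new_mask = np.ones(len(c), dtype=bool)
            else:
                new_mask = c.q <= np.sqrt(self.validity_limit / u2)
            if new_mask.sum() < 4:
                raise FitWindowError(
                    f"fewer than 4 points satisfy Q^2<u2> < {self.validity_limit:g} "
                    f"at T = {c.temperature:g} K (u2 ~ {u2:.3g} A^2)")
            if np.array_equal(new_mask, mask):
                break
            mask = new_mask
        s0, u2 = popt
        errs = np.sqrt(np.diag(pcov))
        return MsdResult(
            temperature=c.temperature, u2=float(u2), s0=float(s0),
            u2_err=float(errs[1]), s0_err=float(errs[0]),
            q_max_used=float(c.q[mask].max()), n_points_used=int(mask.sum()),
            covariance=pcov, validity_limit=self.validity_limit)


class MspfModel:
    """Heterogeneity-model fit over the full Q range of one curve."""

    def __init__(self, curve: EinsCurve, beta_max: float = BETA_UPPER_BOUND):
        if len(curve) < 4:
            raise FitWindowError("need at least 4 points for the MSPF fit")
        self.curve = curve
        self.beta_max = float(beta_max)

    @staticmethod
    def _model(q, s0, r2, beta):
        return s0 * np.exp(-beta * np.log1p(q * q * r2 / beta))

    def fit(self) -> MspfResult:
        c = self.curve
        q, i, e = c.q, c.intensity, c.error
        r2_guess = 1e-3
        if i[0] > 0 and i[-1] > 0 and i[-1] < i[0]:
            r2_guess = np.log(i[0] / i[-1]) / (q[-1] ** 2 - q[0] ** 2)
        try:
            popt, pcov = curve_fit(
                self._model, q, i, p0=[max(i[0], 1e-6), max(r2_guess, 1e-6), 5.0],
                sigma=e, absolute_sigma=True,
                bounds=([1e-12, 0.0, 1e-3], [np.inf, np.inf, self.beta_max]),
                maxfev=20000)
        except RuntimeError as exc:
            raise FitError(f"MSPF fit failed to converge: {exc}") from exc
        s0, r2, beta = popt
        errs = np.sqrt(np.diag(pcov))
        return MspfResult(
            temperature=c.temperature, r2=float(r2), beta=float(beta),
            s0=float(s0), r2_err=float(errs[1]), beta_err=float(errs[2]),
            s0_err=float(errs[0]), covariance=pcov,
            gaussian_indistinguishable=bool(beta >= BETA_GAUSSIAN_FLAG))


def fit_msd(curve: EinsCurve, validity_limit: float = 2.4) -> MsdResult:
    """MSD from one normalized elastic curve (see :class:`MsdModel`)."""
    return MsdModel(curve, validity_limit=validity_limit).fit()


def fit_mspf(curve: EinsCurve) -> MspfResult:
    """MSPF and heterogeneity beta from one normalized curve (:class:`MspfModel`)."""
    return MspfModel(curve).fit()


def fit_series(series: EinsSeries, validity_limit: float = 2.4) -> pd.DataFrame:
    """Fit every curve of a normalized series both ways; tidy per-temperature table.

    Columns: temperature, u2, u2_err, q_max_used, r2, r2_err, beta, beta_err,
    s0_mspf, gaussian_indistinguishable.
    """
    if not series.normalized:
        series = normalize_series(series)
    rows = []
    for curve in series.curves:
        msd = fit_msd(curve, validity_limit=validity_limit)
        mspf = fit_mspf(curve)
        rows.append({
            "temperature": curve.temperature,
            "u2": msd.u2, "u2_err": msd.u2_err, "q_max_used": msd.q_max_used,
            "r2": mspf.r2, "r2_err": mspf.r2_err,
            "beta": mspf.beta, "beta_err": mspf.beta_err,
            "s0_mspf": mspf.s0,
            "gaussian_indistinguishable": mspf.gaussian_indistinguishable,
        })
    return pd.DataFrame(rows)
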