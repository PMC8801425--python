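"""Quasi-elastic spectrum analysis: resolution fits and the global model fit.

Two model objects:

* :class:`ResolutionModel` fits the asymmetric elastic-peak profile to each
  vanadium spectrum independently (five parameters per Q: amplitude, peak
  position, Gaussian sigma, asymmetry xi, constant background);
* :class:`QensGlobalModel` fits all sample spectra at once with shared
  physical parameters — immobile fraction p0, sphere radius a, residence
  time tau, jump diffusion coefficient D (or a single correlation time for
  the Q-independent width law), background slope/offset (s, t) — plus one
  free scale factor C(Q) per spectrum.  The quasi-elastic Lorentzian is
  convolved with the fitted analytic resolution shape.

The quoted chi^2 follows the convention

    chi^2 = 1/(N-1) * sum_Q sum_omega ((S_exp - S_sim)/sigma)^2,

where N is the number of Q values (not the number of degrees of freedom), so
for well-specified noise it scales like M*N/(N-1) with M points per spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from . import models
from .exceptions import FitError, GridError, ParameterError
from .models import (ConvolvedQensModel, D_UNIT_A2_PS, HBAR_UEV_PS,
                     QensModelParams, ResolutionParams, resolution_profile)

__all__ = [
    "QensSpectrum",
    "QensDataset",
    "ResolutionModel",
    "ResolutionFitResult",
    "QensGlobalModel",
    "QensGlobalFit",
    "WidthLawComparison",
    "fit_resolution",
    "global_fit",
    "chi_squared",
    "compare_width_models",
]

#: default fit bounds of the global QENS model (D in 1e-8 cm^2/s)
GLOBAL_BOUNDS = {
    "p0": (0.0, 1.0),
    "a": (0.1, 5.0),
    "tau": (0.1, 500.0),
    "d8": (0.1, 50.0),
    "s": (-10.0, 10.0),
    "t": (-10.0, 10.0),
}


@dataclass(frozen=True, eq=False)
class QensSpectrum:
    """Intensity vs energy transfer at one Q, with 1-sigma errors."""

    q: float
    omega: np.ndarray
    intensity: np.ndarray
    error: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.omega, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        e = np.asarray(self.error, dtype=float)
        if not (w.shape == i.shape == e.shape) or w.ndim != 1:
            raise ParameterError("omega, intensity and error must be equal-length 1-d arrays")
        d = np.diff(w)
        if w.size < 3 or d[0] <= 0 or np.max(np.abs(d - d[0])) > 1e-6 * abs(d[0]):
            raise GridError("omega grid must be uniform and increasing")
        if np.any(e <= 0):
            raise ParameterError("errors must be > 0")
        object.__setattr__(self, "omega", w)
        object.__setattr__(self, "intensity", i)
        object.__setattr__(self, "error", e)

    def __len__(self) -> int:
        return self.omega.size


@dataclass(frozen=True, eq=False)
class QensDataset:
    """Spectra at distinct Q plus per-Q resolution parameters."""

    spectra: tuple[QensSpectrum, ...]
    temperature: float = 300.0
    resolution: Mapping[float, ResolutionParams] | None = None

    def __post_init__(self):
        spectra = tuple(sorted(self.spectra, key=lambda s: s.q))
        qs = [s.q for s in spectra]
        if len(set(qs)) != len(qs):
            raise ParameterError("spectra must have distinct Q values")
        object.__setattr__(self, "spectra", spectra)
        if self.resolution is not None:
            missing = [q for q in qs if not self._lookup(self.resolution, q)]
            if missing:
                raise ParameterError(f"no resolution entry for Q = {missing}")

    @staticmethod
    def _lookup(mapping, q):
        for key in mapping:
            if np.isclose(key, q, rtol=1e-9, atol=1e-12):
                return [mapping[key]]
        return []

    @property
    def q_values(self) -> np.ndarray:
        return np.array([s.q for s in self.spectra])

    def resolution_at(self, q: float) -> ResolutionParams:
        if self.resolution is None:
            raise ParameterError("dataset carries no resolution parameters")
        found = self._lookup(self.resolution, q)
        if not found:
            raise ParameterError(f"no resolution entry for Q = {q}")
        return found[0]

    def with_resolution(self, resolution: Mapping[float, ResolutionParams]
                        ) -> "QensDataset":
        return replace(self, resolution=dict(resolution))


# --------------------------------------------------------------------------
# resolution (vanadium) fits
# --------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class ResolutionFitResult:
    """Per-Q asymmetric-peak fit with uncertainties and residual diagnostics."""

    q: float
    params: ResolutionParams
    errors: dict
    redchi: float
    residuals: np.ndarray
    symmetric: bool  # xi pinned at its zero bound

    def summary(self) -> str:
        p, e = self.params, self.errors
        note = " [symmetric]" if self.symmetric else ""
        return (f"resolution at Q = {self.q:.2f} 1/A: A = {p.amp:.4g} +/- "
                f"{e.get('amp', float('nan')):.2g}, w0 = {p.omega0:.3f} ueV, "
                f"sigma = {p.sigma:.3f} +/- {e.get('sigma', float('nan')):.2g} ueV, "
                f"xi = {p.xi:.3f} +/- {e.get('xi', float('nan')):.2g}, "
                f"B = {p.bg:.4g}{note}")


def _resolution_func(omega, amp, omega0, sigma, xi, bg):
    delta = omega - omega0
    sig2 = 2.0 * sigma ** 2
    left = np.exp(-delta * delta / (sig2 + xi * np.abs(delta)))
    right = np.exp(-delta * delta / sig2)
    return amp * np.where(delta < 0.0, left, right) + bg


class ResolutionModel:
    """Independent weighted fit of the elastic-peak profile at each Q."""

    def __init__(self, vanadium: QensDataset):
        for s in vanadium.spectra:
            if len(s) < 15:
                raise ParameterError(
                    f"need >= 15 omega points per spectrum (Q = {s.q:g})")
        self.data = vanadium

    def _fit_one(self, spec: QensSpectrum) -> ResolutionFitResult:
        w, i, e = spec.omega, spec.intensity, spec.error
        bg0 = max(float(np.median(np.concatenate([i[:3], i[-3:]]))), 0.0)
        amp0 = max(float(i.max() - bg0), 1e-9)
        w0 = float(w[np.argmax(i)])
        above = i - bg0 > amp0 / 2.0
        fwhm0 = (w[above][-1] - w[above][0]) if above.sum() >= 2 else 5.0
        sigma0 = max(fwhm0 / models.GAUSSIAN_FWHM, 0.3)

        model = lmfit.Model(_resolution_func)
        p = model.make_params(amp=amp0, omega0=w0, sigma=sigma0, xi=1.0, bg=bg0)
        p["amp"].min = 1e-12
        p["sigma"].min = 1e-3
        p["xi"].min = 0.0
        res = model.fit(i, p, omega=w, weights=1.0 / e)
        if not res.success:
            raise FitError(f"resolution fit did not converge at Q = {spec.q:g}")
        v = res.best_values
        errors = {k: (res.params[k].stderr if res.params[k].stderr is not None
                      else float("nan")) for k in v}
        return ResolutionFitResult(
            q=spec.q,
            params=ResolutionParams(amp=v["amp"], omega0=v["omega0"],
                                    sigma=v["sigma"], xi=v["xi"], bg=v["bg"]),
            errors=errors, redchi=float(res.redchi),
            residuals=np.asarray(res.residual), symmetric=bool(v["xi"] < 1e-6))

    def fit(self) -> dict[float, ResolutionFitResult]:
        out = {}
        for spec in self.data.spectra:
            try:
                out[spec.q] = self._fit_one(spec)
            except FitError:
                raise
            except Exception as exc:
                raise FitError(f"resolution fit failed at Q = {spec.q:g}: {exc}") from exc
        return out


def fit_resolution(vanadium: QensDataset) -> dict[float, ResolutionParams]:
    """Per-Q resolution parameters from vanadium spectra (see ResolutionModel)."""
    return {q: r.params for q, r in ResolutionModel(vanadium).fit().items()}


# --------------------------------------------------------------------------
# chi-squared
# --------------------------------------------------------------------------

def chi_squared(data: QensDataset, model_eval: Sequence[np.ndarray]) -> float:
    """Quoted goodness-of-fit: sum of squared standardized residuals over all
    Q and omega, divided by (N - 1) with N the number of Q values."""
    n = len(data.spectra)
    if n < 2:
        raise ParameterError("chi_squared requires >= 2 Q values (N-1 normalization)")
    if len(model_eval) != n:
        raise ParameterError("one model vector per spectrum required")
    total = 0.0
    for spec, m in zip(data.spectra, model_eval):
        m = np.asarray(m, dtype=float)
        if m.shape != spec.intensity.shape:
            raise ParameterError(f"shape mismatch at Q = {spec.q:g}")
        if np.any(spec.error == 0):
            raise ParameterError("zero experimental error encountered")
        total += float(np.sum(((spec.intensity - m) / spec.error) ** 2))
    return total / (n - 1)


# --------------------------------------------------------------------------
# global fit
# --------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class QensGlobalFit:
    """Result of the global multi-Q QENS fit."""

    params: QensModelParams
    errors: dict
    chi2: float
    per_q_widths: pd.DataFrame
    model_tag: str
    flags: tuple[str, ...] = field(default=())
    cost: float = float("nan")
    n_points: int = 0

    @property
    def tau_corr(self) -> float:
        """Correlation time of the Q-independent width law (== tau)."""
        return self.params.tau

    def summary(self) -> str:
        p, e = self.params, self.errors
        lines = [
            f"Global QENS fit ({self.model_tag}), {self.n_points} points, "
            f"chi2 = {self.chi2:.4g}",
            f"  p0  = {p.p0:.3f} +/- {e.get('p0', float('nan')):.3f}",
            f"  a   = {p.a:.3f} +/- {e.get('a', float('nan')):.3f} A",
            f"  tau = {p.tau:.2f} +/- {e.get('tau', float('nan')):.2f} ps",
        ]
        if self.model_tag == "jump_diffusion":
            lines.append(f"  D   = {p.d_1e8_cm2_s:.3f} +/- "
                         f"{e.get('d8', float('nan')):.3f} x1e-8 cm^2/s")
        lines.append(f"  s = {p.s:.4g}, t = {p.t:.4g}; "
                     f"C(Q) = {np.array2string(np.array(p.scale), precision=3)}")
        if self.flags:
            lines.append(f"  flags: {', '.join(self.flags)}")
        return "\n".join(lines)

    def plot(self, data: QensDataset, q: float | None = None, ax=None):
        """Plot one spectrum and its fitted model curve (default: first Q)."""
        import matplotlib.pyplot as plt

        if q is None:
            q = data.spectra[0].q
        spec = next(s for s in data.spectra if np.isclose(s.q, q))
        idx = int(np.argmin(np.abs(data.q_values - q)))
        ev = ConvolvedQensModel(spec.q, spec.omega, data.resolution_at(spec.q))
        gamma = None
        if self.model_tag == "constant_width":
            gamma = HBAR_UEV_PS / self.params.tau
        curve = ev.intensity(self.params, scale=self.params.scale[idx], gamma=gamma)
        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(spec.omega, spec.intensity, spec.error, fmt="o", ms=3,
                    label="data")
        ax.plot(spec.omega, curve, label=f"fit ({self.model_tag})")
        ax.set_xlabel(r"$\hbar\omega$ [$\mu$eV]")
        ax.set_ylabel("S(Q, $\\omega$)")
        ax.set_yscale("log")
        ax.set_title(f"Q = {spec.q:.2f} $\\mathrm{{\\AA^{{-1}}}}$")
        ax.legend()
        return ax


class QensGlobalModel:
    """Global multi-Q QENS model (shared physics, free per-Q scales).

    width_law : "jump_diffusion" (Gamma = hbar D Q^2/(1 + D Q^2 tau)) or
                "constant_width" (Gamma = hbar/tau, no D parameter).

    The optimizer is bounded least squares on standardized residuals with
    multi-start: the first start is a data-driven heuristic (scales from the
    spectrum integrals, mid-range physics parameters), the rest are drawn
    from a seeded Latin hypercube over the bounds.
    """

    def __init__(self, data: QensDataset, width_law: str = "jump_diffusion",
                 bounds: Mapping[str, tuple[float, float]] | None = None):
        if width_law not in ("jump_diffusion", "constant_width"):
            raise ParameterError(f"unknown width law: {width_law!r}")
        if len(data.spectra) < 3:
            raise ParameterError("global fit requires >= 3 Q values")
        if data.resolution is None:
            raise ParameterError("dataset must carry fitted resolution parameters")
        self.data = data
        self.width_law = width_law
        self.bounds = dict(GLOBAL_BOUNDS)
        if bounds:
            self.bounds.update(bounds)
        self._evals = [ConvolvedQensModel(s.q, s.omega, data.resolution_at(s.q))
                       for s in data.spectra]
        # data-driven scale heuristic: total area above the low-intensity floor
        self._c0 = []
        for s in data.spectra:
            floor = float(np.percentile(s.intensity, 5))
            area = float(np.trapezoid(np.clip(s.intensity - floor, 0, None),
                                      s.omega))
            self._c0.append(max(area, 1e-6))

    # parameter vector layout: [p0, a, tau, (d8), s, t, c_1..c_n]
    @property
    def _has_d(self) -> bool:
        return self.width_law == "jump_diffusion"

    def _unpack(self, x: np.ndarray):
        if self._has_d:
            p0, a, tau, d8, s, t = x[:6]
            c = x[6:]
            d = d8 * D_UNIT_A2_PS
        else:
            p0, a, tau, s, t = x[:5]
            c = x[5:]
            d = None
        return p0, a, tau, d, s, t, c

    def _model_curves(self, x: np.ndarray) -> list[np.ndarray]:
        p0, a, tau, d, s, t, c = self._unpack(x)
        curves = []
        for ev, ci in zip(self._evals, c):
            a0 = float(models.eisf_sphere(ev.q, a, p0))
            bg = s * ev.q + t
            elastic = a0 * ev._res_elastic
            if a0 >= 1.0 - 1e-12:
                curves.append(ci * elastic + bg)
                continue
            if d is None:
                gamma = HBAR_UEV_PS / tau
            else:
                gamma = float(models.jump_diffusion_hwhm(ev.q, d, tau))
            curves.append(ci * (elastic + (1.0 - a0) * ev.quasielastic(gamma)) + bg)
        return curves

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        curves = self._model_curves(x)
        return np.concatenate([
            (spec.intensity - m) / spec.error
            for spec, m in zip(self.data.spectra, curves)])

    def _bounds_arrays(self, n_scale: int):
        names = ["p0", "a", "tau"] + (["d8"] if self._has_d else []) + ["s", "t"]
        lo = [self.bounds[n][0] for n in names]
        hi = [self.bounds[n][1] for n in names]
        lo += [c * 1e-4 for c in self._c0]
        hi += [c * 1e4 for c in self._c0]
        return np.array(lo), np.array(hi), names

    def _starts(self, n_starts: int, seed: int | None):
        mid = {"p0": 0.5, "a": 1.0, "tau": 20.0, "d8": 5.0, "s": 0.0, "t": 0.0}
        names = ["p0", "a", "tau"] + (["d8"] if self._has_d else []) + ["s", "t"]
        first = np.array([mid[n] for n in names] + self._c0)
        starts = [first]
        if n_starts > 1:
            sampler = qmc.LatinHypercube(d=len(names), seed=seed)
            unit = sampler.random(n=n_starts - 1)
            lo = np.array([self.bounds[n][0] for n in names])
            hi = np.array([self.bounds[n][1] for n in names])
            for row in unit:
                phys = lo + row * (hi - lo)
                # keep tau/d8 on a log scale so small values are explored too
                for i, n in enumerate(names):
                    if n in ("tau", "d8"):
                        phys[i] = 10 ** (np.log10(lo[i])
                                         + row[i] * (np.log10(hi[i]) - np.log10(lo[i])))
                starts.append(np.concatenate([phys, self._c0]))
        return starts

    def fit(self, n_starts: int = 5, seed: int | None = 0) -> QensGlobalFit:
        n_scale = len(self.data.spectra)
        lo, hi, names = self._bounds_arrays(n_scale)
        best = None
        for x0 in self._starts(n_starts, seed):
            x0 = np.clip(x0, lo, hi)
            sol = least_squares(self._residuals, x0, bounds=(lo, hi),
                                method="trf", x_scale="jac", max_nfev=400 * len(x0))
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not np.all(np.isfinite(best.x)):
            raise FitError("global QENS fit failed to converge")
        x = best.x
        p0, a, tau, d, s, t, c = self._unpack(x)

        # covariance of the standardized-residual least squares problem
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(jtj)
        perr = np.sqrt(np.clip(np.diag(cov), 0, None))
        errors = dict(zip(names, perr[:len(names)]))

        flags = []
        if p0 >= 0.99:
            flags += ["p0_at_upper_bound", "quasielastic_weight_zero",
                      "width_unidentifiable"]
        elif p0 <= 1e-6:
            flags.append("p0_at_lower_bound")

        d_internal = d if d is not None else 1.0 * D_UNIT_A2_PS
        params = QensModelParams(p0=float(np.clip(p0, 0, 1)), a=float(a),
                                 tau=float(tau), d=float(d_internal),
                                 s=float(s), t=float(t), scale=tuple(c))
        qs = self.data.q_values
        if self._has_d:
            widths = models.jump_diffusion_hwhm(qs, params.d, params.tau)
        else:
            widths = np.full(qs.shape, HBAR_UEV_PS / params.tau)
        per_q = pd.DataFrame({"q": qs, "gamma_ueV": widths, "scale": list(c)})

        curves = self._model_curves(x)
        chi2 = chi_squared(self.data, curves)
        return QensGlobalFit(params=params, errors=errors, chi2=chi2,
                             per_q_widths=per_q, model_tag=self.width_law,
                             flags=tuple(flags), cost=float(best.cost),
                             n_points=sum(len(s) for s in self.data.spectra))


def global_fit(data: QensDataset, width_law: str = "jump_diffusion",
               n_starts: int = 5, seed: int | None = 0) -> QensGlobalFit:
    """Convenience wrapper around :class:`QensGlobalModel`."""
    return QensGlobalModel(data, width_law=width_law).fit(n_starts=n_starts,
                                                          seed=seed)


# --------------------------------------------------------------------------
# width-law comparison
# --------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class WidthLawComparison:
    """Both global fits plus the chi^2 ordering."""

    jump_diffusion: QensGlobalFit | None
    constant_width: QensGlobalFit | None
    failures: tuple[str, ...] = ()

    @property
    def chi2_ratio(self) -> float:
        """chi^2(constant width) / chi^2(jump diffusion)."""
        if self.jump_diffusion is None or self.constant_width is None:
            return float("nan")
        return self.constant_width.chi2 / self.jump_diffusion.chi2

    @property
    def preferred(self) -> str:
        if self.jump_diffusion is None:
            return "constant_width" if self.constant_width else "none"
        if self.constant_width is None:
            return "jump_diffusion"
        return ("jump_diffusion"
                if self.jump_diffusion.chi2 <= self.constant_width.chi2
                else "constant_width")

    def summary(self) -> str:
        parts = []
        for tag, fit in (("jump_diffusion", self.jump_diffusion),
                         ("constant_width", self.constant_width)):
            parts.append(f"{tag}: chi2 = "
                         f"{fit.chi2:.4g}" if fit else f"{tag}: FAILED")
        parts.append(f"preferred: {self.preferred}")
        return " | ".join(parts)


def compare_width_models(data: QensDataset, n_starts: int = 5,
                         seed: int | None = 0) -> WidthLawComparison:
    """Fit both width laws and report which one the data prefer (lower chi^2)."""
    fits = {}
    failures = []
    for tag in ("jump_diffusion", "constant_width"):
        try:
            fits[tag] = global_fit(data, width_law=tag, n_starts=n_starts,
                                   seed=seed)
        except FitError as exc:
            fits[tag] = None
            failures.append(f"{tag}: {exc}")
            warnings.warn(f"width-law fit failed for {tag}: {exc}", stacklevel=2)
    return WidthLawComparison(jump_diffusion=fits["jump_diffusion"],
                              constant_width=fits["constant_width"],
                              failures=tuple(failures))
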