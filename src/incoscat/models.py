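"""Forward spectral models for incoherent neutron scattering.

Pure functions (and one small convolution engine) shared by the elastic-scan
fits, the quasi-elastic global fit and the synthetic-data generators:

* elastic intensity under the Gaussian approximation, S(Q) = S(0) exp(-Q^2 <u2>/3);
* elastic intensity under the heterogeneity (Gamma-distribution) model,
  S(Q) = S(0) (1 + Q^2 <r2>/beta)^(-beta), which recovers the Gaussian form
  as beta -> infinity;
* the Gamma density of the squared position fluctuation lambda = r^2/<r2>;
* the asymmetric elastic-peak (vanadium resolution) profile;
* the unit-area Lorentzian quasi-elastic line;
* the jump-diffusion width law Gamma(Q) = hbar D Q^2 / (1 + D Q^2 tau) and the
  Q-independent alternative Gamma = hbar/tau;
* the diffusion-inside-a-sphere EISF with an immobile fraction p0;
* the full convolved QENS model
  S(Q, w) = C(Q) [A0(Q) R(w) + (1 - A0(Q)) (L (x) R)(w)] + s Q + t.

Units: Q in 1/Angstrom, energies in micro-eV, times in ps, diffusion
coefficients internally in Angstrom^2/ps (1e-8 cm^2/s = 1e-4 A^2/ps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import spherical_jn
from scipy.stats import gamma as _gamma_dist

from .exceptions import GridError, ParameterError

#: hbar in micro-eV * ps; converts a rate in 1/ps to an energy HWHM in micro-eV.
HBAR_UEV_PS = 658.2119

#: multiply a diffusion coefficient quoted in 1e-8 cm^2/s by this to get A^2/ps.
D_UNIT_A2_PS = 1.0e-4

#: FWHM/sigma ratio of a Gaussian.
GAUSSIAN_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))

__all__ = [
    "HBAR_UEV_PS",
    "D_UNIT_A2_PS",
    "GaussianEinsParams",
    "MspfParams",
    "ResolutionParams",
    "QensModelParams",
    "eins_gaussian_intensity",
    "eins_mspf_intensity",
    "gamma_fluctuation_pdf",
    "resolution_profile",
    "lorentzian_profile",
    "jump_diffusion_hwhm",
    "constant_hwhm",
    "eisf_sphere",
    "qens_model_intensity",
    "ConvolvedQensModel",
]


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianEinsParams:
    """Parameters of the Gaussian elastic-scan model.

    s0 : elastic amplitude at Q=0 (dimensionless, > 0)
    u2 : mean square displacement <u2> in A^2 (>= 0)
    """

    s0: float
    u2: float

    def __post_init__(self):
        if not (self.s0 > 0):
            raise ParameterError(f"s0 must be > 0, got {self.s0}")
        if self.u2 < 0:
            raise ParameterError(f"u2 must be >= 0, got {self.u2}")


@dataclass(frozen=True)
class MspfParams:
    """Parameters of the heterogeneity (Gamma) elastic-scan model.

    s0   : elastic amplitude (> 0)
    r2   : mean-square position fluctuation <r2> in A^2 (>= 0)
    beta : heterogeneity parameter (> 0); larger beta = more homogeneous
    """

    s0: float
    r2: float
    beta: float

    def __post_init__(self):
        if not (self.s0 > 0):
            raise ParameterError(f"s0 must be > 0, got {self.s0}")
        if self.r2 < 0:
            raise ParameterError(f"r2 must be >= 0, got {self.r2}")
        if not (self.beta > 0):
            raise ParameterError(f"beta must be > 0, got {self.beta}")


@dataclass(frozen=True)
class ResolutionParams:
    """Asymmetric elastic-peak (vanadium resolution) parameters.

    amp    : peak amplitude A (> 0)
    omega0 : elastic peak position in micro-eV
    sigma  : Gaussian standard deviation in micro-eV (> 0)
    xi     : asymmetry parameter (>= 0); xi = 0 gives a symmetric Gaussian
    bg     : constant background
    """

    amp: float
    omega0: float
    sigma: float
    xi: float
    bg: float

    def __post_init__(self):
        if not (self.amp > 0):
            raise ParameterError(f"amp must be > 0, got {self.amp}")
        if not (self.sigma > 0):
            raise ParameterError(f"sigma must be > 0, got {self.sigma}")
        if self.xi < 0:
            raise ParameterError(f"xi must be >= 0, got {self.xi}")


@dataclass(frozen=True, eq=False)
class QensModelParams:
    """Shared parameters of the global QENS model plus per-Q scale factors.

    p0    : immobile fraction in [0, 1]
    a     : sphere radius in Angstrom (> 0)
    tau   : residence time in ps (> 0)
    d     : jump diffusion coefficient in A^2/ps (> 0); the conventional
            report unit is 1e-8 cm^2/s (`d_1e8_cm2_s`)
    s, t  : linear-in-Q background, B(Q) = s*Q + t (flat in omega)
    scale : per-Q scale factors C(Q), each > 0
    """

    p0: float
    a: float
    tau: float
    d: float
    s: float
    t: float
    scale: tuple[float, ...] = field(default=(1.0,))

    def __post_init__(self):
        if not (0.0 <= self.p0 <= 1.0):
            raise ParameterError(f"p0 must be in [0, 1], got {self.p0}")
        for name in ("a", "tau", "d"):
            v = getattr(self, name)
            if not (v > 0):
                raise ParameterError(f"{name} must be > 0, got {v}")
        object.__setattr__(self, "scale", tuple(float(c) for c in np.atleast_1d(self.scale)))
        if any(c <= 0 for c in self.scale):
            raise ParameterError("all scale factors C(Q) must be > 0")

    @property
    def d_1e8_cm2_s(self) -> float:
        """Jump diffusion coefficient in units of 1e-8 cm^2/s."""
        return self.d / D_UNIT_A2_PS


# --------------------------------------------------------------------------
# elastic-scan forward models
# --------------------------------------------------------------------------

def eins_gaussian_intensity(q, params: GaussianEinsParams) -> np.ndarray:
    """Elastic intensity under the Gaussian approximation.

    S(Q) = s0 * exp(-Q^2 <u2> / 3); strictly decreasing in Q for u2 > 0.
    """
    q = np.asarray(q, dtype=float)
    return params.s0 * np.exp(-q * q * params.u2 / 3.0)


def eins_mspf_intensity(q, params: MspfParams) -> np.ndarray:
    """Elastic intensity under the heterogeneity model.

    S(Q) = s0 * (1 + Q^2 <r2> / beta)^(-beta).  For beta -> infinity this
    converges to s0 * exp(-Q^2 <r2>) (note: no factor 1/3 — <r2> is the full
    mean-square position fluctuation entering the exponent directly).
    """
    q = np.asarray(q, dtype=float)
    # exp(-beta*log1p(x)) is accurate for huge beta where (1+x)^-beta overflows
    x = q * q * params.r2 / params.beta
    return params.s0 * np.exp(-params.beta * np.log1p(x))


def gamma_fluctuation_pdf(lam, beta: float) -> np.ndarray:
    """Gamma density of lambda = r^2/<r2> with unit mean.

    p(lambda; beta) = beta * exp(-beta*lambda) * (beta*lambda)^(beta-1) / Gamma(beta),
    i.e. a Gamma(shape=beta, rate=beta) distribution.
    """
    if not (beta > 0):
        raise ParameterError(f"beta must be > 0, got {beta}")
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ParameterError("lambda must be >= 0")
    return _gamma_dist.pdf(lam, a=beta, scale=1.0 / beta)


def gamma_fluctuation_cdf(lam, beta: float) -> np.ndarray:
    """CDF companion of :func:`gamma_fluctuation_pdf` (used by the partition)."""
    if not (beta > 0):
        raise ParameterError(f"beta must be > 0, got {beta}")
    lam = np.asarray(lam, dtype=float)
    return _gamma_dist.cdf(lam, a=beta, scale=1.0 / beta)


# --------------------------------------------------------------------------
# quasi-elastic building blocks
# --------------------------------------------------------------------------

def resolution_profile(omega, params: ResolutionParams) -> np.ndarray:
    """Asymmetric elastic-peak profile of the instrument resolution.

    The branch below the peak position is broadened,

        A * exp(-D^2 / (2 sigma^2 + xi*|D|)),   D = w - w0 < 0,

    while the branch above is a plain Gaussian A * exp(-D^2 / (2 sigma^2));
    a constant background is added.  xi = 0 recovers a symmetric Gaussian.
    For large |D| the broadened branch decays like exp(-|D|/xi), giving the
    peak an exponential low-energy tail.
    """
    omega = np.asarray(omega, dtype=float)
    delta = omega - params.omega0
    sig2 = 2.0 * params.sigma ** 2
    left = np.exp(-delta * delta / (sig2 + params.xi * np.abs(delta)))
    right = np.exp(-delta * delta / sig2)
    return params.amp * np.where(delta < 0.0, left, right) + params.bg


def lorentzian_profile(omega, gamma: float) -> np.ndarray:
    """Unit-area Lorentzian centered at zero with half width gamma (micro-eV)."""
    if not (gamma > 0):
        raise ParameterError(f"gamma must be > 0, got {gamma}")
    omega = np.asarray(omega, dtype=float)
    return (gamma / np.pi) / (omega * omega + gamma * gamma)


def jump_diffusion_hwhm(q, d: float, tau: float) -> np.ndarray:
    """Jump-diffusion Lorentzian HWHM in micro-eV.

    Gamma(Q) = hbar * D Q^2 / (1 + D Q^2 tau) with D in A^2/ps and tau in ps.
    Monotone nondecreasing in Q, bounded by hbar/tau; ~ hbar*D*Q^2 as Q -> 0.
    """
    if not (d > 0):
        raise ParameterError(f"d must be > 0, got {d}")
    if not (tau > 0):
        raise ParameterError(f"tau must be > 0, got {tau}")
    q = np.asarray(q, dtype=float)
    dq2 = d * q * q
    return HBAR_UEV_PS * dq2 / (1.0 + dq2 * tau)


def constant_hwhm(tau: float) -> float:
    """Q-independent width law: Gamma = hbar / tau (micro-eV, tau in ps)."""
    if not (tau > 0):
        raise ParameterError(f"tau must be > 0, got {tau}")
    return HBAR_UEV_PS / tau


def _sphere_form(x: np.ndarray) -> np.ndarray:
    """(3 j1(x)/x), evaluated by series below x = 1e-3 to avoid 0/0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-3
    xs = x[small]
    # 3 j1(x)/x = 1 - x^2/10 + x^4/280 - ...
    out[small] = 1.0 - xs * xs / 10.0 + xs ** 4 / 280.0
    xl = x[~small]
    out[~small] = 3.0 * spherical_jn(1, xl) / xl
    return out


def eisf_sphere(q, a: float, p0: float) -> np.ndarray:
    """Elastic incoherent structure factor of diffusion inside a sphere.

    A0(Q) = (1 - p0) * (3 j1(Qa)/(Qa))^2 + p0, bounded in [p0, 1]; A0(0) = 1.
    """
    if not (a > 0):
        raise ParameterError(f"a must be > 0, got {a}")
    if not (0.0 <= p0 <= 1.0):
        raise ParameterError(f"p0 must be in [0, 1], got {p0}")
    q = np.asarray(q, dtype=float)
    f = _sphere_form(q * a)
    return (1.0 - p0) * f * f + p0


# --------------------------------------------------------------------------
# convolved QENS model
# --------------------------------------------------------------------------

def _check_uniform(omega: np.ndarray) -> float:
    omega = np.asarray(omega, dtype=float)
    if omega.ndim != 1 or omega.size < 3:
        raise GridError("omega grid must be a 1-d array with >= 3 points")
    d = np.diff(omega)
    if d[0] <= 0 or np.max(np.abs(d - d[0])) > 1e-6 * abs(d[0]):
        raise GridError("omega grid must be uniform and increasing "
                        "(relative tolerance 1e-6)")
    return float(d[0])


class ConvolvedQensModel:
    """Evaluator of the convolved QENS model at one Q on a fixed omega grid.

    The resolution shape (background removed) is normalized to unit area and
    cached, both as the analytic elastic term R(w) on the measurement grid and
    as a discrete convolution kernel.  The delta-function component is handled
    analytically (delta (x) R = R); only the Lorentzian is convolved, on a
    grid padded well beyond the measurement window and then cropped.  The
    discretized Lorentzian is renormalized to unit area on the padded grid so
    that convolution conserves area and the Gamma -> 0 limit recovers the
    purely elastic spectrum.
    """

    #: hard cap on the pad half-width (micro-eV), to bound work for extreme widths
    MAX_PAD_UEV = 1500.0

    def __init__(self, q: float, omega, resolution: ResolutionParams):
        self.q = float(q)
        self.omega = np.asarray(omega, dtype=float)
        self.resolution = resolution
        self.domega = _check_uniform(self.omega)
        center = 0.5 * (self.omega[0] + self.omega[-1])
        if abs(resolution.omega0 - center) > 0.5 * (self.omega[-1] - self.omega[0]):
            warnings.warn(
                f"resolution center omega0={resolution.omega0} micro-eV lies far "
                f"from the spectral window midpoint {center}; convolution may clip",
                stacklevel=2,
            )
        # kernel half-width: cover the Gaussian core plus the exponential tail
        half = max(5.0 * resolution.sigma + 12.0 * resolution.xi, 10.0)
        self._kernel_half = half
        nk = int(np.ceil(half / self.domega))
        xk = (np.arange(2 * nk + 1) - nk) * self.domega
        shape = resolution_profile(xk + resolution.omega0, resolution) - resolution.bg
        # recenter: kernel index nk corresponds to energy omega0
        norm = np.trapezoid(shape, dx=self.domega)
        self._kernel = shape / norm
        self._res_elastic = (resolution_profile(self.omega, resolution)
                             - resolution.bg) / norm

    # -- components ---------------------------------------------------------
    def quasielastic(self, gamma: float) -> np.ndarray:
        """(L (x) R)(omega) for a Lorentzian of HWHM gamma, unit area."""
        if not (gamma > 0):
            raise ParameterError(f"gamma must be > 0, got {gamma}")
        pad = min(max(40.0 * gamma, self._kernel_half), self.MAX_PAD_UEV)
        npad = int(np.ceil(pad / self.domega))
        left = self.omega[0] - np.arange(npad, 0, -1) * self.domega
        right = self.omega[-1] + np.arange(1, npad + 1) * self.domega
        grid = np.concatenate([left, self.omega, right])
        lor = lorentzian_profile(grid - self.resolution.omega0, gamma)
        lor /= np.trapezoid(lor, dx=self.domega)
        conv = np.convolve(lor, self._kernel, mode="same") * self.domega
        return conv[npad:npad + self.omega.size]

    def intensity(self, params: QensModelParams, scale: float | None = None,
                  gamma: float | None = None) -> np.ndarray:
        """Model spectrum C [A0 R + (1-A0) L(x)R] + s*q + t.

        `scale` overrides params.scale (which is per-dataset); `gamma`
        overrides the jump-diffusion width (used for the Q-independent law).
        """
        c = float(params.scale[0]) if scale is None else float(scale)
        a0 = float(eisf_sphere(self.q, params.a, params.p0))
        bg = params.s * self.q + params.t
        elastic = a0 * self._res_elastic
        if gamma is None:
            gamma = float(jump_diffusion_hwhm(self.q, params.d, params.tau))
        if a0 >= 1.0 - 1e-12:
            return c * elastic + bg
        return c * (elastic + (1.0 - a0) * self.quasielastic(gamma)) + bg


def qens_model_intensity(q: float, omega, params: QensModelParams,
                         res: ResolutionParams, scale: float | None = None,
                         gamma: float | None = None) -> np.ndarray:
    """One-shot evaluation of the convolved QENS model (see ConvolvedQensModel)."""
    return ConvolvedQensModel(q, omega, res).intensity(params, scale=scale,
                                                       gamma=gamma)
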