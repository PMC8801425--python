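"""Seeded synthetic-data generators with known ground truth.

Emulates thermal-backscattering (IN13-like) measurements on hydrated protein
powders: elastic temperature scans on Q in 0.2-4.9 1/A, quasi-elastic spectra
on energy transfers -80..+85 micro-eV with an ~8 micro-eV elastic resolution,
and counting-statistics noise (Gaussian with sigma = c * sqrt(intensity),
i.e. a relative error of c at unit intensity).

Presets named after the two lysozyme fibril polymorphs wire the generator to
the published global-fit parameter rows (LP27: fibrils formed at pH 2.7;
LP60: pH 6.0) and to a qualitative elastic-scan truth profile in which the
heterogeneity parameter beta falls above ~250 K.  Presets are test fixtures
with known truth, not claims about the measured samples.

Seeds are mandatory; there is no hidden global randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .eins import EinsCurve, EinsSeries
from .exceptions import ParameterError
from .models import (ConvolvedQensModel, D_UNIT_A2_PS, GAUSSIAN_FWHM,
                     MspfParams, QensModelParams, ResolutionParams,
                     eins_mspf_intensity, resolution_profile)
from .qens import QensDataset, QensSpectrum

__all__ = [
    "EinsTruth",
    "QensTruth",
    "generate_eins_series",
    "generate_vanadium_spectrum",
    "generate_qens_dataset",
    "eins_truth_preset",
    "qens_truth_preset",
    "default_resolution",
    "GLOBAL_FIT_PRESETS",
    "DEFAULT_Q_VALUES",
]

#: published global-fit parameter rows used as ground-truth presets
#: (p0, sphere radius a [A], residence time tau [ps], D [1e-8 cm^2/s])
GLOBAL_FIT_PRESETS = {
    "LP27": {"p0": 0.41, "a": 1.1, "tau": 21.4, "d8": 4.7},
    "LP60": {"p0": 0.45, "a": 1.3, "tau": 18.0, "d8": 7.6},
}

#: default QENS momentum transfers (1/A); Q = 1.67 is always included
DEFAULT_Q_VALUES = (0.5, 1.0, 1.67, 2.0, 2.5, 3.0, 3.5, 4.0, 4.25, 4.5)

#: elastic energy resolution (FWHM, micro-eV) of the emulated instrument
INSTRUMENT_RESOLUTION_UEV = 8.0


def default_resolution(amp: float = 1.0, omega0: float = 0.0,
                       xi: float = 2.77, bg: float = 0.002) -> ResolutionParams:
    """Asymmetric elastic-peak truth with sigma set from the 8 ueV resolution."""
    sigma = INSTRUMENT_RESOLUTION_UEV / GAUSSIAN_FWHM
    return ResolutionParams(amp=amp, omega0=omega0, sigma=sigma, xi=xi, bg=bg)


def _noise_sigma(model: np.ndarray, level: float) -> np.ndarray:
    """Counting-statistics sigma = level * sqrt(intensity), floored away from 0."""
    return np.maximum(level * np.sqrt(np.clip(model, 0.0, None)), 1e-12)


def _add_noise(model: np.ndarray, level: float, rng: np.random.Generator
               ) -> tuple[np.ndarray, np.ndarray]:
    """Return (noisy intensity, error column).

    With level = 0 the model is returned exactly and the error column is set
    to one (uniform weights), keeping downstream weighted fits well posed.
    """
    if level < 0:
        raise ParameterError("noise level must be >= 0")
    if level == 0.0:
        return model.copy(), np.ones_like(model)
    sigma = _noise_sigma(model, level)
    return model + rng.normal(size=model.shape) * sigma, sigma


# --------------------------------------------------------------------------
# elastic temperature series
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EinsTruth:
    """Ground truth of an elastic temperature series (relative to the lowest T).

    temperatures/r2/beta : per-temperature heterogeneity-model truth
    q_min, q_max, n_q    : Q grid specification (1/A)
    noise                : relative sigma at unit intensity (counting statistics)
    """

    temperatures: tuple[float, ...]
    r2: tuple[float, ...]
    beta: tuple[float, ...]
    q_min: float = 0.2
    q_max: float = 4.9
    n_q: int = 30
    noise: float = 0.01

    def __post_init__(self):
        t = tuple(float(x) for x in self.temperatures)
        r2 = tuple(float(x) for x in self.r2)
        b = tuple(float(x) for x in self.beta)
        if not (len(t) == len(r2) == len(b)) or not t:
            raise ParameterError("temperatures, r2 and beta must be nonempty, equal length")
        if any(t2 <= t1 for t1, t2 in zip(t, t[1:])):
            raise ParameterError("temperatures must be strictly increasing")
        if any(x < 0 for x in r2) or any(x <= 0 for x in b):
            raise ParameterError("need r2 >= 0 and beta > 0")
        if not (0 < self.q_min < self.q_max) or self.n_q < 4:
            raise ParameterError("invalid Q grid specification")
        for name, val in (("temperatures", t), ("r2", r2), ("beta", b)):
            object.__setattr__(self, name, val)


def generate_eins_series(truth: EinsTruth, seed: int) -> EinsSeries:
    """Normalized elastic curves from heterogeneity-model truth plus noise.

    The curves are generated relative to the reference temperature (S(0) = 1),
    i.e. already in the normalized convention used by the MSD/MSPF fits; pass
    a truth row with r2 = 0 at the lowest temperature to emulate the
    identically-one reference curve.
    """
    rng = np.random.default_rng(seed)
    q = np.linspace(truth.q_min, truth.q_max, truth.n_q)
    curves = []
    for temp, r2, beta in zip(truth.temperatures, truth.r2, truth.beta):
        model = eins_mspf_intensity(q, MspfParams(s0=1.0, r2=r2, beta=beta))
        intensity, error = _add_noise(model, truth.noise, rng)
        curves.append(EinsCurve(q=q, intensity=np.clip(intensity, 0.0, None),
                                error=error, temperature=temp))
    return EinsSeries(curves=tuple(curves),
                      resolution_ueV=INSTRUMENT_RESOLUTION_UEV, normalized=True)


def eins_truth_preset(noise: float = 0.01, n_q: int = 30) -> EinsTruth:
    """Elastic-scan truth ladder tracing the qualitative published profile.

    The mean-square fluctuation grows with temperature while the
    heterogeneity parameter beta collapses above ~250 K (increasingly
    heterogeneous amplitudes); at 306 K the truth is <r2> = 0.86 A^2 with
    beta = 1.5.
    """
    return EinsTruth(
        temperatures=(24.0, 96.0, 147.0, 200.0, 252.0, 284.0, 295.0, 306.0),
        r2=(0.0, 0.05, 0.12, 0.22, 0.45, 0.65, 0.75, 0.86),
        beta=(1.0e6, 100.0, 50.0, 20.0, 5.0, 2.5, 2.0, 1.5),
        noise=noise, n_q=n_q)


# --------------------------------------------------------------------------
# vanadium (resolution) spectra
# --------------------------------------------------------------------------

def _omega_grid(omega_min: float, omega_max: float, n_omega: int) -> np.ndarray:
    if n_omega < 15 or not (omega_min < omega_max):
        raise ParameterError("invalid omega grid specification")
    return np.linspace(omega_min, omega_max, n_omega)


def generate_vanadium_spectrum(res_truth: Mapping[float, ResolutionParams],
                               noise: float, seed: int,
                               omega_min: float = -80.0, omega_max: float = 85.0,
                               n_omega: int = 111,
                               temperature: float = 300.0) -> QensDataset:
    """Vanadium-like elastic peaks from asymmetric-profile truth plus noise."""
    rng = np.random.default_rng(seed)
    omega = _omega_grid(omega_min, omega_max, n_omega)
    spectra = []
    for q in sorted(res_truth):
        model = resolution_profile(omega, res_truth[q])
        intensity, error = _add_noise(model, noise, rng)
        spectra.append(QensSpectrum(q=float(q), omega=omega,
                                    intensity=intensity, error=error))
    return QensDataset(spectra=tuple(spectra), temperature=temperature,
                       resolution=dict(res_truth))


# --------------------------------------------------------------------------
# quasi-elastic datasets
# --------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class QensTruth:
    """Ground truth of a synthetic QENS dataset.

    params     : shared model truth (scale must have one entry per Q)
    resolution : per-Q resolution truth (a single ResolutionParams is
                 broadcast to every Q)
    q_values   : momentum transfers (1/A)
    omega grid : -80..+85 micro-eV by default
    noise      : relative sigma at unit intensity
    """

    params: QensModelParams
    resolution: ResolutionParams | Mapping[float, ResolutionParams] = field(
        default_factory=default_resolution)
    q_values: tuple[float, ...] = DEFAULT_Q_VALUES
    omega_min: float = -80.0
    omega_max: float = 85.0
    n_omega: int = 111
    noise: float = 0.02
    temperature: float = 300.0

    def __post_init__(self):
        q = tuple(float(x) for x in self.q_values)
        if len(set(q)) != len(q) or not q:
            raise ParameterError("q_values must be nonempty and distinct")
        object.__setattr__(self, "q_values", q)
        if len(self.params.scale) not in (1, len(q)):
            raise ParameterError("params.scale must have one entry (broadcast) "
                                 "or one per Q value")

    def resolution_map(self) -> dict[float, ResolutionParams]:
        if isinstance(self.resolution, ResolutionParams):
            return {q: self.resolution for q in self.q_values}
        return {float(q): self.resolution[q] for q in self.resolution}

    def scale_at(self, i: int) -> float:
        return self.params.scale[i if len(self.params.scale) > 1 else 0]


def generate_qens_dataset(truth: QensTruth, seed: int) -> QensDataset:
    """Convolved QENS model spectra plus counting noise; carries the
    resolution truth used for the synthesis."""
    rng = np.random.default_rng(seed)
    omega = _omega_grid(truth.omega_min, truth.omega_max, truth.n_omega)
    resmap = truth.resolution_map()
    spectra = []
    for i, q in enumerate(truth.q_values):
        ev = ConvolvedQensModel(q, omega, resmap[q])
        model = ev.intensity(truth.params, scale=truth.scale_at(i))
        intensity, error = _add_noise(model, truth.noise, rng)
        spectra.append(QensSpectrum(q=q, omega=omega, intensity=intensity,
                                    error=error))
    return QensDataset(spectra=tuple(spectra), temperature=truth.temperature,
                       resolution=resmap)


def qens_truth_preset(name: str = "LP60", noise: float = 0.02,
                      n_omega: int = 111, scale: float = 20.0,
                      s: float = 0.002, t: float = 0.02,
                      q_values: tuple[float, ...] = DEFAULT_Q_VALUES,
                      resolution: ResolutionParams | None = None) -> QensTruth:
    """QENS truth wired to a published polymorph parameter row.

    The default per-Q scale (C = 20 for every Q) puts the elastic peak near
    unit intensity, so `noise` is approximately the relative error at the
    peak.  D is given in 1e-8 cm^2/s in the preset table and stored
    internally in A^2/ps.
    """
    if name not in GLOBAL_FIT_PRESETS:
        raise ParameterError(f"unknown preset {name!r}; "
                             f"choose from {sorted(GLOBAL_FIT_PRESETS)}")
    row = GLOBAL_FIT_PRESETS[name]
    params = QensModelParams(p0=row["p0"], a=row["a"], tau=row["tau"],
                             d=row["d8"] * D_UNIT_A2_PS, s=s, t=t,
                             scale=(scale,) * len(q_values))
    return QensTruth(params=params,
                     resolution=resolution or default_resolution(),
                     q_values=q_values, n_omega=n_omega, noise=noise)
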