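"""Analytic powder-averaged compartment signals for soma/neurite imaging.

The composite model decomposes the direction-averaged (powder) PGSE signal
into three compartments::

    S̄/S₀ = f_neurite · A_stick(b, D_in)
          + f_soma    · A_sphere(G, δ, Δ; R, D_is)
          + f_extra   · A_gauss(b, D_ec)

* ``stick``: zero-radius cylinder (neurites).  Its powder average is
  ``√(π/(4bD)) · erf(√(bD))``.
* ``sphere``: restricted diffusion inside a reflecting sphere of radius R
  (cell bodies), evaluated with the Gaussian-phase-distribution (GPD)
  series of Murday–Cotts/Balinov.  Orientation independent.
* ``ball``/``zeppelin``: isotropic or axially symmetric Gaussian tensor
  (extra-cellular water).

Units: b in s/mm², diffusivities in μm²/ms, G in mT/m, δ/Δ in ms, R in μm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf

from .acquisition import GYROMAGNETIC_RATIO, AcquisitionScheme

__all__ = [
    "SANDIParameters",
    "NoiseModel",
    "stick_powder_signal",
    "ball_signal",
    "zeppelin_powder_signal",
    "sphere_gpd_signal",
    "sphere_gpd_roots",
    "sandi_powder_signal",
    "add_rician_noise",
]

#: conversion: b [s/mm²] × D [μm²/ms] → dimensionless bD
_BD_SCALE = 1e-3


class TruncationWarning(UserWarning):
    """GPD series not converged at the requested number of roots."""


@dataclass(frozen=True)
class SANDIParameters:
    """Ground-truth or fitted compartment parameters.

    Fractions are signal fractions summing to one.  ``D_ec`` may be a
    scalar (isotropic extra-cellular water, "ball") or a ``(D_par,
    D_perp)`` pair ("zeppelin").
    """

    f_neurite: float
    f_soma: float
    f_extra: float
    D_in: float = 2.4       # intra-neurite diffusivity, μm²/ms
    D_is: float = 3.0       # intra-soma diffusivity, μm²/ms
    D_ec: float | tuple[float, float] = 3.0
    R_s: float = 8.0        # soma radius, μm

    def __post_init__(self):
        f = np.array([self.f_neurite, self.f_soma, self.f_extra])
        if np.any(f < 0):
            raise ValueError("fractions must be >= 0")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {f.sum()}")
        d_ec = np.atleast_1d(np.asarray(self.D_ec, dtype=float))
        for D in (self.D_in, self.D_is, *d_ec):
            if not (0 < D <= 3.0):
                raise ValueError(f"diffusivity {D} outside (0, 3.0] μm²/ms")
        if not (0 < self.R_s <= 20):
            raise ValueError(f"soma radius {self.R_s} outside (0, 20] μm")


@dataclass(frozen=True)
class NoiseModel:
    """Rician noise level, parametrized by SNR at b=0.

    ``sigma`` is the standard deviation of each Gaussian channel,
    ``S(b=0)/snr``; for unit-normalized signals ``sigma = 1/snr``.
    """

    snr: float
    s0: float = 1.0

    def __post_init__(self):
        if not self.snr > 0:
            raise ValueError("snr must be > 0")

    @property
    def sigma(self) -> float:
        return self.s0 / self.snr


def stick_powder_signal(b, D_in):
    """Direction-averaged signal of a stick compartment.

    Ā(b, D) = √(π/(4bD)) · erf(√(bD)); continuous limit 1 at bD = 0.
    Depends on b and D only through the product bD.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be >= 0")
    if np.any(np.asarray(D_in) <= 0):
        raise ValueError("D_in must be > 0")
    bd = b * D_in * _BD_SCALE
    out = np.ones_like(bd)
    nz = bd > 0
    out[nz] = np.sqrt(np.pi / (4 * bd[nz])) * erf(np.sqrt(bd[nz]))
    return out if out.ndim else float(out)


def ball_signal(b, D):
    """Isotropic Gaussian compartment: exp(−bD)."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0) or np.any(np.asarray(D) < 0):
        raise ValueError("b and D must be >= 0")
    out = np.exp(-b * D * _BD_SCALE)
    return out if out.ndim else float(out)


def zeppelin_powder_signal(b, D_par, D_perp):
    """Direction-averaged axially symmetric Gaussian tensor.

    exp(−b·D_perp) · √(π/(4b(D_par−D_perp))) · erf(√(b(D_par−D_perp)));
    reduces to the ball when D_par = D_perp and to the stick when
    D_perp = 0.
    """
    if D_par < D_perp:
        raise ValueError("zeppelin requires D_par >= D_perp")
    if D_perp < 0:
        raise ValueError("D_perp must be >= 0")
    b = np.asarray(b, dtype=float)
    dd = D_par - D_perp
    if dd == 0:
        out = np.exp(-b * D_par * _BD_SCALE)
        return out if out.ndim else float(out)
    out = np.asarray(ball_signal(b, D_perp)) * np.asarray(stick_powder_signal(b, dd))
    return out if out.ndim else float(out)


@lru_cache(maxsize=None)
def sphere_gpd_roots(n_roots: int = 20) -> np.ndarray:
    """First ``n_roots`` positive roots a_m of d/dx[j₁(x)] = 0.

    These are the radial eigenvalues of diffusion in a reflecting sphere
    (a₁ ≈ 2.0816).  Found by bracketed root-finding on
    f(x) = (x² − 2)·sin x + 2x·cos x, which is x³·j₁′(x).
    """

    def f(x):
        return (x * x - 2.0) * np.sin(x) + 2.0 * x * np.cos(x)

    roots = []
    x = 1.0
    step = 0.05
    prev = f(x)
    while len(roots) < n_roots:
        x2 = x + step
        cur = f(x2)
        if prev == 0.0:
            roots.append(x)
        elif np.sign(prev) != np.sign(cur):
            roots.append(brentq(f, x, x2, xtol=1e-14, rtol=1e-15))
        x, prev = x2, cur
    return np.array(roots)


def sphere_gpd_signal(G, delta, Delta, R, D_is, n_roots: int = 20,
                      truncation_tol: float = 1e-8):
    """GPD signal of water restricted in a reflecting sphere.

    Parameters
    ----------
    G : float or array
        Gradient amplitude, mT/m.
    delta, Delta : float
        Pulse duration and separation, ms.
    R : float
        Sphere radius, μm.
    D_is : float
        Intra-sphere diffusivity, μm²/ms.

    Returns the normalized signal in (0, 1]; exactly 1 at G = 0.  The
    attenuation exponent is the Murday–Cotts/Balinov series over the
    reflecting-sphere eigenmodes a_m = α_m·R::

        −ln Ā = 2γ²G² Σ_m [2Dα²δ − 2 + 2e^{−Dα²δ} + 2e^{−Dα²Δ}
                           − e^{−Dα²(Δ−δ)} − e^{−Dα²(Δ+δ)}]
                         / [D²α⁶(a_m² − 2)]

    The signal is its own powder average (orientation independent) and
    tends to 1 as R → 0 (motional narrowing).
    """
    G = np.asarray(G, dtype=float)
    if np.any(G < 0):
        raise ValueError("G must be >= 0")
    if delta <= 0 or Delta < delta or R <= 0 or D_is <= 0:
        raise ValueError("require delta > 0, Delta >= delta, R > 0, D_is > 0")
    # SI units
    G_si = G * 1e-3            # T/m
    d = delta * 1e-3           # s
    Dl = Delta * 1e-3          # s
    R_si = R * 1e-6            # m
    D = D_is * 1e-9            # m²/s

    a = sphere_gpd_roots(n_roots)          # dimensionless a_m
    alpha = a / R_si                       # 1/m
    Da2 = D * alpha ** 2                   # 1/s
    num = (
        2 * Da2 * d - 2
        + 2 * np.exp(-Da2 * d)
        + 2 * np.exp(-Da2 * Dl)
        - np.exp(-Da2 * (Dl - d))
        - np.exp(-Da2 * (Dl + d))
    )
    terms = num / (D ** 2 * alpha ** 6 * (a ** 2 - 2.0))
    total = terms.sum()
    if total > 0 and abs(terms[-1]) / total > truncation_tol:
        warnings.warn(
            f"GPD series last term ratio {abs(terms[-1]) / total:.2e} exceeds "
            f"tolerance {truncation_tol:.0e} at n_roots={n_roots}",
            TruncationWarning,
        )
    attenuation = 2 * GYROMAGNETIC_RATIO ** 2 * G_si ** 2 * total
    out = np.exp(-attenuation)
    return out if out.ndim else float(out)


def sandi_powder_signal(scheme: AcquisitionScheme, params: SANDIParameters) -> np.ndarray:
    """Per-shell powder-averaged composite signal, S̄/S₀.

    One value per b-shell (sorted ascending), equal to 1 at the b=0
    shell.  The extra-cellular compartment is a ball when ``D_ec`` is a
    scalar, a zeppelin when it is a (D_par, D_perp) pair.
    """
    shells = scheme.shells()
    if not any(b > scheme.shell_tolerance for b, _ in shells):
        raise ValueError("scheme needs at least one non-zero shell")
    out = np.empty(len(shells))
    for k, (b, idx) in enumerate(shells):
        if b <= scheme.shell_tolerance:
            out[k] = 1.0
            continue
        G = float(np.mean([scheme.measurements[i].G for i in idx]))
        delta = scheme.measurements[idx[0]].delta
        Delta = scheme.measurements[idx[0]].Delta
        stick = stick_powder_signal(b, params.D_in)
        sphere = sphere_gpd_signal(G, delta, Delta, params.R_s, params.D_is)
        d_ec = params.D_ec
        if np.isscalar(d_ec):
            extra = ball_signal(b, d_ec)
        else:
            extra = zeppelin_powder_signal(b, d_ec[0], d_ec[1])
        out[k] = (params.f_neurite * stick + params.f_soma * sphere
                  + params.f_extra * extra)
    return out


def add_rician_noise(signals, noise: NoiseModel, rng) -> np.ndarray:
    """Replace each signal S by √((S+ε₁)² + ε₂²), ε ~ N(0, σ²).

    This is the magnitude-reconstruction noise of an MR scanner; at S = 0
    the output follows a Rayleigh distribution with mean σ√(π/2).
    ``rng`` is an integer seed or a ``numpy.random.Generator``.
    """
    signals = np.asarray(signals, dtype=float)
    if np.any(signals < 0):
        raise ValueError("signals must be >= 0")
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sigma = noise.sigma
    if sigma == 0 or np.isinf(noise.snr):
        return signals.copy()
    e1 = gen.normal(0.0, sigma, size=signals.shape)
    e2 = gen.normal(0.0, sigma, size=signals.shape)
    return np.sqrt((signals + e1) ** 2 + e2 ** 2)
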