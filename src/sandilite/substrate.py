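"""Substrate signal synthesis: analytic mixtures and a Monte-Carlo walker.

A substrate is a mixture of geometric components (restricted sphere,
stick, Gaussian tensor) with signal fractions summing to one.  Signals
can be synthesised two ways:

* **analytic** — each component's closed-form signal (GPD sphere, stick /
  tensor with a randomly drawn orientation per component) evaluated per
  measurement; the default for experiment-scale runs.
* **Monte Carlo** — a random-walk PGSE simulator with specular reflection
  at the sphere wall; the independent oracle used to validate the
  analytic sphere model.

The MC phase is accumulated as φ = γ ∫ G(t)·x(t) dt over the two
gradient pulses with alternating sign; the signal is |⟨e^{iφ}⟩| across
walkers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .acquisition import GYROMAGNETIC_RATIO, AcquisitionScheme
from .forward_models import (
    NoiseModel,
    add_rician_noise,
    ball_signal,
    sphere_gpd_signal,
)

__all__ = [
    "SubstrateComponent",
    "Substrate",
    "WalkerConfig",
    "mc_sphere_signal",
    "mc_stick_signal",
    "simulate_substrate_signal",
]

_BD_SCALE = 1e-3  # (s/mm²)·(μm²/ms) → dimensionless


@dataclass(frozen=True)
class SubstrateComponent:
    """One mixture component.

    kind ∈ {"sphere", "stick", "tensor"}; ``radius`` (μm) applies to
    spheres, ``diffusivity`` (μm²/ms) to spheres and sticks,
    ``eigenvalues`` = (D_par, D_perp) to tensors.
    """

    kind: str
    fraction: float
    diffusivity: float = 3.0
    radius: float | None = None
    eigenvalues: tuple[float, float] | None = None

    def __post_init__(self):
        if self.kind not in {"sphere", "stick", "tensor"}:
            raise ValueError(f"unknown component kind {self.kind!r}")
        if self.fraction < 0:
            raise ValueError("fraction must be >= 0")
        if self.kind == "sphere" and (self.radius is None or self.radius <= 0):
            raise ValueError("sphere component needs a positive radius")
        if self.kind == "tensor":
            if self.eigenvalues is None:
                raise ValueError("tensor component needs (D_par, D_perp)")
            if self.eigenvalues[0] < self.eigenvalues[1] or self.eigenvalues[1] < 0:
                raise ValueError("tensor requires D_par >= D_perp >= 0")


@dataclass(frozen=True)
class Substrate:
    components: tuple[SubstrateComponent, ...]

    def __post_init__(self):
        total = sum(c.fraction for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component fractions must sum to 1, got {total}")


@dataclass(frozen=True)
class WalkerConfig:
    """Monte-Carlo settings.

    ``steps_per_delta`` sets the time step dt = δ/steps_per_delta; the
    default δ/20 keeps the per-step displacement well below the sphere
    radius for the radii of interest.
    """

    n_walkers: int = 100_000
    steps_per_delta: int = 20
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_walkers < 1000:
            raise ValueError("n_walkers must be >= 1000 for oracle use")
        if self.steps_per_delta < 10:
            raise ValueError("step duration must be <= delta/10")


def _pulse_weights(n_steps: int, dt: float, delta: float, Delta: float) -> np.ndarray:
    """Signed effective gradient duty per time step.

    Weight_i ∈ [−1, 1] is the overlap fraction of step i with the first
    pulse [0, δ) minus its overlap with the second pulse [Δ, Δ+δ).
    """
    t0 = np.arange(n_steps) * dt
    t1 = t0 + dt

    def overlap(a, b):
        return np.clip(np.minimum(t1, b) - np.maximum(t0, a), 0.0, None) / dt

    return overlap(0.0, delta) - overlap(Delta, Delta + delta)


def _reflect_into_sphere(pos: np.ndarray, new: np.ndarray, R: float) -> np.ndarray:
    """Specular reflection of the step pos→new at the sphere |x| = R.

    Splits the sub-step at the wall crossing and reflects the remaining
    displacement about the tangent plane; iterates for (rare) multiple
    crossings.
    """
    out = new.copy()
    for _ in range(10):
        r = np.linalg.norm(out, axis=1)
        bad = r > R
        if not np.any(bad):
            break
        p, q = pos[bad], out[bad]
        d = q - p
        # solve |p + s d|² = R² for s in (0, 1]
        a = np.sum(d * d, axis=1)
        bq = np.sum(p * d, axis=1)
        c = np.sum(p * p, axis=1) - R * R
        disc = np.sqrt(np.maximum(bq * bq - a * c, 0.0))
        s = (-bq + disc) / np.maximum(a, 1e-300)
        s = np.clip(s, 0.0, 1.0)
        hit = p + s[:, None] * d
        n = hit / np.maximum(np.linalg.norm(hit, axis=1, keepdims=True), 1e-300)
        rem = q - hit
        refl = rem - 2 * np.sum(rem * n, axis=1, keepdims=True) * n
        out[bad] = hit + refl
        pos = pos.copy()
        pos[bad] = hit
    else:  # pragma: no cover - pathological geometry
        out = out * np.minimum(1.0, (R - 1e-12) / np.linalg.norm(out, axis=1))[:, None]
    return out


def _phase_integral_sphere(R: float, D: float, delta: float, Delta: float,
                           config: WalkerConfig, adaptive: bool = True) -> np.ndarray:
    """Per-walker ∫ s(t)·z(t) dt (μm·ms) inside a reflecting sphere.

    Trajectories are independent of G, so one set serves every shell that
    shares (δ, Δ).  With ``adaptive`` (default) the time step is refined
    below δ/steps_per_delta until the rms step length √(6·D·dt) is at
    most R/5, which a convergence study shows removes discretization bias
    at small radii.
    """
    rng = np.random.default_rng(config.rng_seed)
    dt = delta / config.steps_per_delta
    if adaptive:
        dt = min(dt, R * R / (150.0 * D))
    n_steps = int(np.ceil((Delta + delta) / dt))
    step_sigma = np.sqrt(2.0 * D * dt)  # per-axis, μm
    if np.sqrt(6.0 * D * dt) > R / 5.0:
        warnings.warn(
            f"MC step length {np.sqrt(6 * D * dt):.2f} μm exceeds R/5 = {R / 5:.2f} μm; "
            "refine steps_per_delta", UserWarning,
        )
    # uniform initialization inside the sphere
    pos = rng.normal(size=(config.n_walkers, 3))
    pos *= (R * rng.random(config.n_walkers) ** (1 / 3)
            / np.linalg.norm(pos, axis=1))[:, None]
    w = _pulse_weights(n_steps, dt, delta, Delta)
    integral = np.zeros(config.n_walkers)
    for i in range(n_steps):
        new = pos + rng.normal(scale=step_sigma, size=pos.shape)
        new = _reflect_into_sphere(pos, new, R)
        # midpoint z over the step
        integral += w[i] * 0.5 * (pos[:, 2] + new[:, 2]) * dt
        pos = new
    return integral


def _signal_from_integral(integral: np.ndarray, G: float) -> tuple[float, float]:
    """(signal, SE) for gradient amplitude G (mT/m), integral in μm·ms."""
    # γ[rad/s/T] · G[T/m] · ∫z dt [m·s] ; μm·ms → m·s is 1e-9
    phase = GYROMAGNETIC_RATIO * (G * 1e-3) * integral * 1e-9
    c = np.cos(phase)
    s = np.sin(phase)
    sig = float(np.hypot(np.mean(c), np.mean(s)))
    se = float(np.std(c, ddof=1) / np.sqrt(len(c)))
    return sig, se


def _grouped(scheme: AcquisitionScheme):
    """Yield ((delta, Delta), indices) groups of measurements."""
    keys = {}
    for i, m in enumerate(scheme.measurements):
        keys.setdefault((m.delta, m.Delta), []).append(i)
    return keys.items()


def mc_sphere_signal(R: float, D: float, scheme: AcquisitionScheme,
                     config: WalkerConfig = WalkerConfig(),
                     adaptive: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo signal of a reflecting sphere, per measurement.

    Returns ``(signal, standard_error)`` arrays over the scheme.  The
    sphere signal is orientation independent, so measurements sharing
    (G, δ, Δ) reuse one estimate.
    """
    signals = np.empty(len(scheme))
    ses = np.empty(len(scheme))
    for (delta, Delta), idx in _grouped(scheme):
        integral = _phase_integral_sphere(R, D, delta, Delta, config, adaptive=adaptive)
        cache: dict[float, tuple[float, float]] = {}
        for i in idx:
            G = scheme.measurements[i].G
            if G not in cache:
                cache[G] = _signal_from_integral(integral, G)
            signals[i], ses[i] = cache[G]
    return signals, ses


def mc_stick_signal(D: float, scheme: AcquisitionScheme,
                    config: WalkerConfig = WalkerConfig()) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo stick signal: 1-D free diffusion along per-walker
    random orientations, so each measurement's estimate converges to the
    analytic powder average.  Returns ``(signal, standard_error)``.
    """
    rng = np.random.default_rng(config.rng_seed)
    u = rng.normal(size=(config.n_walkers, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    signals = np.empty(len(scheme))
    ses = np.empty(len(scheme))
    for (delta, Delta), idx in _grouped(scheme):
        dt = delta / config.steps_per_delta
        n_steps = int(np.ceil((Delta + delta) / dt))
        w = _pulse_weights(n_steps, dt, delta, Delta)
        x = np.zeros(config.n_walkers)
        integral = np.zeros(config.n_walkers)
        step_sigma = np.sqrt(2.0 * D * dt)
        for i in range(n_steps):
            new = x + rng.normal(scale=step_sigma, size=x.shape)
            integral += w[i] * 0.5 * (x + new) * dt
            x = new
        for i in idx:
            m = scheme.measurements[i]
            proj = u @ np.asarray(m.direction)
            phase = GYROMAGNETIC_RATIO * (m.G * 1e-3) * (integral * proj) * 1e-9
            c, s = np.cos(phase), np.sin(phase)
            signals[i] = float(np.hypot(np.mean(c), np.mean(s)))
            ses[i] = float(np.std(c, ddof=1) / np.sqrt(len(c)))
    return signals, ses


def _analytic_component_signal(comp: SubstrateComponent, scheme: AcquisitionScheme,
                               rng: np.random.Generator) -> np.ndarray:
    """Noise-free per-measurement signal of one component.

    Sticks and tensors get a random orientation (drawn from ``rng``);
    averaging over the scheme's directions then reproduces the powder
    signal.  Spheres are orientation independent (GPD).
    """
    b = scheme.bvals
    dirs = scheme.bvecs.T
    if comp.kind == "sphere":
        out = np.empty(len(scheme))
        for _, idx in _grouped(scheme):
            sub = np.asarray(idx)
            m0 = scheme.measurements[sub[0]]
            G = np.array([scheme.measurements[i].G for i in sub])
            out[sub] = np.where(
                G > 0,
                sphere_gpd_signal(G, m0.delta, m0.Delta, comp.radius, comp.diffusivity),
                1.0,
            )
        return out
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    cos2 = (dirs @ u) ** 2
    if comp.kind == "stick":
        return np.exp(-b * comp.diffusivity * cos2 * _BD_SCALE)
    d_par, d_perp = comp.eigenvalues
    return np.exp(-b * (d_perp + (d_par - d_perp) * cos2) * _BD_SCALE)


def simulate_substrate_signal(
    substrate: Substrate,
    scheme: AcquisitionScheme,
    noise: NoiseModel | None = None,
    seed: int = 0,
    sphere_mode: str = "analytic",
    walker_config: WalkerConfig | None = None,
) -> np.ndarray:
    """Noisy per-measurement signal of a substrate.

    Components are combined as a fraction-weighted sum, then Rician noise
    is applied per measurement (``noise=None`` or infinite SNR leaves the
    signal noiseless).  ``sphere_mode`` selects the analytic GPD model
    (default) or the ``"mc"`` random-walk oracle for sphere components.
    Deterministic for a given seed.
    """
    if sphere_mode not in {"analytic", "mc"}:
        raise ValueError("sphere_mode must be 'analytic' or 'mc'")
    rng = np.random.default_rng(seed)
    total = np.zeros(len(scheme))
    for comp in substrate.components:
        if comp.kind == "sphere" and sphere_mode == "mc":
            cfg = walker_config or WalkerConfig(rng_seed=seed)
            sig, _ = mc_sphere_signal(comp.radius, comp.diffusivity, scheme, cfg)
        else:
            sig = _analytic_component_signal(comp, scheme, rng)
        total += comp.fraction * sig
    if noise is None or np.isinf(noise.snr):
        return total
    return add_rician_noise(total, noise, rng)
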