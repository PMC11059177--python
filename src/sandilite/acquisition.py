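"""Pulsed-gradient spin-echo (PGSE) acquisition schemes.

A diffusion measurement is described by its b-value (s/mm²), gradient
direction, gradient amplitude G (mT/m) and the pulse timings δ (pulse
duration) and Δ (pulse separation), both in ms.  The Stejskal–Tanner
relation ties them together::

    b = γ² G² δ² (Δ − δ/3)

with γ the proton gyromagnetic ratio.  Two protocols are bundled: the
clinical 3T protocol (80 mT/m gradient cap, b up to 3000 s/mm²) and a
representative high-gradient research protocol (300 mT/m cap, b up to
10000 s/mm²) of the kind used to develop soma imaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GYROMAGNETIC_RATIO",
    "Measurement",
    "AcquisitionScheme",
    "b_value_from_gradient",
    "gradient_from_b",
    "prisma_protocol",
    "connectom_like_protocol",
    "load_gradient_table",
    "write_gradient_table",
    "load_scheme_file",
    "write_scheme_file",
    "group_shells",
    "sphere_directions",
]

#: Proton gyromagnetic ratio, rad s⁻¹ T⁻¹.
GYROMAGNETIC_RATIO = 2.6751e8

#: Default b-value tolerance for shell grouping, s/mm².
DEFAULT_SHELL_TOLERANCE = 50.0


class InvalidTimingError(ValueError):
    """δ/Δ pulse timings violate Δ ≥ δ > 0."""


class GradientTableError(ValueError):
    """Malformed bval/bvec or scheme file."""


def _check_timings(delta: float, Delta: float) -> None:
    if delta <= 0:
        raise InvalidTimingError(f"pulse duration delta must be > 0, got {delta}")
    if Delta < delta:
        raise InvalidTimingError(
            f"pulse separation Delta ({Delta}) must be >= delta ({delta})"
        )


def b_value_from_gradient(G, delta: float, Delta: float):
    """b-value (s/mm²) from gradient amplitude G (mT/m) and timings (ms).

    Implements b = γ²G²δ²(Δ − δ/3) with unit bookkeeping done in SI and
    the result converted to the conventional s/mm².
    """
    G = np.asarray(G, dtype=float)
    if np.any(G < 0):
        raise ValueError("gradient amplitude must be >= 0")
    _check_timings(delta, Delta)
    G_si = G * 1e-3          # mT/m -> T/m
    d_si = delta * 1e-3      # ms -> s
    D_si = Delta * 1e-3
    b_si = (GYROMAGNETIC_RATIO ** 2) * G_si ** 2 * d_si ** 2 * (D_si - d_si / 3.0)
    return b_si * 1e-6       # s/m² -> s/mm²


def gradient_from_b(b, delta: float, Delta: float):
    """Inverse of :func:`b_value_from_gradient`: G (mT/m) from b (s/mm²)."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-value must be >= 0")
    _check_timings(delta, Delta)
    d_si = delta * 1e-3
    D_si = Delta * 1e-3
    b_si = b * 1e6
    G_si = np.sqrt(b_si / ((GYROMAGNETIC_RATIO ** 2) * d_si ** 2 * (D_si - d_si / 3.0)))
    return G_si * 1e3        # T/m -> mT/m


@dataclass(frozen=True)
class Measurement:
    """A single PGSE measurement.

    Attributes
    ----------
    b : float
        Diffusion weighting, s/mm².
    direction : tuple of 3 floats
        Unit gradient direction (arbitrary for b=0).
    G : float
        Gradient amplitude, mT/m.
    delta, Delta : float
        Pulse duration δ and separation Δ, ms.
    """

    b: float
    direction: tuple[float, float, float]
    G: float
    delta: float
    Delta: float

    def __post_init__(self):
        if self.b < 0:
            raise ValueError("b must be >= 0")
        _check_timings(self.delta, self.Delta)
        n = float(np.linalg.norm(self.direction))
        if self.b > 0 and abs(n - 1.0) > 1e-6:
            raise ValueError(f"direction must be unit length at b>0 (norm={n})")
        b_check = b_value_from_gradient(self.G, self.delta, self.Delta)
        scale = max(self.b, 1.0)
        if abs(b_check - self.b) > 0.01 * scale:
            raise ValueError(
                f"b ({self.b}) inconsistent with G/delta/Delta (implies {b_check:.1f})"
            )


@dataclass
class AcquisitionScheme:
    """An ordered set of PGSE measurements with b-shell grouping."""

    measurements: list[Measurement]
    shell_tolerance: float = DEFAULT_SHELL_TOLERANCE

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def bvals(self) -> np.ndarray:
        return np.array([m.b for m in self.measurements])

    @property
    def bvecs(self) -> np.ndarray:
        """Directions as a (3, n) array, FSL layout."""
        return np.array([m.direction for m in self.measurements]).T

    @property
    def gradient_amplitudes(self) -> np.ndarray:
        return np.array([m.G for m in self.measurements])

    def shells(self) -> list[tuple[float, np.ndarray]]:
        return group_shells(self)

    def shell_bvalues(self) -> np.ndarray:
        return np.array([b for b, _ in self.shells()])

    def has_b0(self) -> bool:
        return bool(np.any(self.bvals <= self.shell_tolerance))


def group_shells(scheme: AcquisitionScheme) -> list[tuple[float, np.ndarray]]:
    """Partition measurements into b-shells.

    Measurements whose b-values differ by at most ``shell_tolerance`` from
    a shell's running members are merged.  Returns ``(b_center, indices)``
    pairs sorted by ascending b, with ``b_center`` the mean member b.
    The partition is exhaustive and disjoint.
    """
    if len(scheme) == 0:
        raise ValueError("empty scheme")
    b = scheme.bvals
    order = np.argsort(b, kind="stable")
    shells: list[list[int]] = []
    for i in order:
        if shells and abs(b[i] - np.mean(b[shells[-1]])) <= scheme.shell_tolerance:
            shells[-1].append(int(i))
        else:
            shells.append([int(i)])
    return [(float(np.mean(b[idx])), np.array(sorted(idx))) for idx in shells]


def sphere_directions(n: int, seed: int = 0, n_iter: int = 120) -> np.ndarray:
    """n quasi-uniform unit vectors by electrostatic repulsion.

    Points are initialised on a Fibonacci spiral (deterministic; ``seed``
    rotates the spiral phase) and relaxed by a few steps of antipodally
    symmetric Coulomb repulsion, the standard construction for diffusion
    direction tables.  Returns an (n, 3) array.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n)
    golden = (1 + 5 ** 0.5) / 2
    phi = 2 * np.pi * (i / golden + seed * 0.01)
    z = 1 - (2 * i + 1) / n
    r = np.sqrt(np.maximum(0.0, 1 - z ** 2))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    if n == 1:
        return pts
    step = 0.1
    for _ in range(n_iter):
        # antipodal symmetry: forces from both x_j and -x_j
        force = np.zeros_like(pts)
        for sgn in (1.0, -1.0):
            d = pts[:, None, :] - sgn * pts[None, :, :]
            dist2 = np.sum(d ** 2, axis=-1)
            np.fill_diagonal(dist2, np.inf)
            dist2 = np.maximum(dist2, 1e-12)
            force += np.sum(d / dist2[..., None] ** 1.5, axis=1)
        # project onto tangent plane and renormalize
        force -= pts * np.sum(force * pts, axis=1, keepdims=True)
        pts = pts + step * force / n
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def _build_scheme(
    shell_bs: list[float],
    shell_ns: list[int],
    delta: float,
    Delta: float,
    shell_tolerance: float = DEFAULT_SHELL_TOLERANCE,
) -> AcquisitionScheme:
    measurements: list[Measurement] = []
    for k, (b, n) in enumerate(zip(shell_bs, shell_ns)):
        if b <= shell_tolerance:
            dirs = np.tile([0.0, 0.0, 0.0], (n, 1))
        else:
            dirs = sphere_directions(n, seed=k)
        G = float(gradient_from_b(b, delta, Delta))
        for d in dirs:
            measurements.append(
                Measurement(b=float(b), direction=tuple(d), G=G if b > 0 else 0.0,
                            delta=delta, Delta=Delta)
            )
    return AcquisitionScheme(measurements, shell_tolerance=shell_tolerance)


def prisma_protocol() -> AcquisitionScheme:
    """The clinical 3T protocol: b = 0/700/1000/2000/3000 s/mm² with
    12/6/20/45/66 directions, δ = 19 ms, Δ = 36 ms (80 mT/m-class system)."""
    return _build_scheme(
        [0.0, 700.0, 1000.0, 2000.0, 3000.0], [12, 6, 20, 45, 66],
        delta=19.0, Delta=36.0,
    )


def connectom_like_protocol(scheme_path=None) -> AcquisitionScheme:
    """A representative high-gradient (300 mT/m-class) research protocol.

    The exact research scheme is not redistributable here, so a bundled
    stand-in with the same b-range and gradient ceiling is used: δ = 8 ms,
    Δ = 29 ms, shells 0/1000/2000/3000/5000/7000/10000 s/mm² with
    12/12/32/48/60/60/60 directions (peak gradient ≈ 288 mT/m at the top
    shell).  Pass ``scheme_path`` to load a real scheme file instead
    (see :func:`load_scheme_file`).
    """
    if scheme_path is not None:
        return load_scheme_file(scheme_path)
    return _build_scheme(
        [0.0, 1000.0, 2000.0, 3000.0, 5000.0, 7000.0, 10000.0],
        [12, 12, 32, 48, 60, 60, 60],
        delta=8.0, Delta=29.0,
    )


def load_gradient_table(
    bval_path, bvec_path, delta: float, Delta: float,
    shell_tolerance: float = DEFAULT_SHELL_TOLERANCE,
) -> AcquisitionScheme:
    """Read an FSL-dialect bval (one row) / bvec (three rows) pair."""
    bvals = np.loadtxt(bval_path, ndmin=2)
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvals.shape[0] != 1:
        raise GradientTableError(f"bval file must have one row, got {bvals.shape[0]}")
    bvals = bvals[0]
    if bvecs.shape[0] != 3:
        raise GradientTableError(f"bvec file must have three rows, got {bvecs.shape[0]}")
    if bvecs.shape[1] != bvals.shape[0]:
        raise GradientTableError(
            f"bval/bvec column mismatch: {bvals.shape[0]} vs {bvecs.shape[1]}"
        )
    measurements = []
    for b, v in zip(bvals, bvecs.T):
        n = float(np.linalg.norm(v))
        if b > shell_tolerance:
            if n == 0:
                raise GradientTableError(f"zero direction at b={b}")
            if abs(n - 1.0) > 1e-6:
                warnings.warn(f"non-unit bvec at b={b} (norm {n:.4f}); normalizing")
                v = v / n
            G = float(gradient_from_b(b, delta, Delta))
        else:
            v = np.zeros(3)
            G = float(gradient_from_b(b, delta, Delta)) if b > 0 else 0.0
        measurements.append(
            Measurement(b=float(b), direction=tuple(v), G=G, delta=delta, Delta=Delta)
        )
    return AcquisitionScheme(measurements, shell_tolerance=shell_tolerance)


def write_gradient_table(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    """Inverse of :func:`load_gradient_table`."""
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs, fmt="%.8f")


def load_scheme_file(path, shell_tolerance: float = DEFAULT_SHELL_TOLERANCE) -> AcquisitionScheme:
    """Read a plain-text scheme file: one measurement per line,
    ``gx gy gz |G|(T/m) Delta(s) delta(s) TE(s)``; comment lines start with #."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "VERSION")):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise GradientTableError(f"scheme line needs 7 fields, got {len(parts)}")
            rows.append([float(x) for x in parts])
    if not rows:
        raise GradientTableError("empty scheme file")
    measurements = []
    for gx, gy, gz, G_si, Delta_s, delta_s, _te in rows:
        G = G_si * 1e3          # T/m -> mT/m
        delta = delta_s * 1e3   # s -> ms
        Delta = Delta_s * 1e3
        b = float(b_value_from_gradient(G, delta, Delta))
        v = np.array([gx, gy, gz])
        n = float(np.linalg.norm(v))
        if b > shell_tolerance and n > 0:
            v = v / n
        measurements.append(
            Measurement(b=b, direction=tuple(v), G=G, delta=delta, Delta=Delta)
        )
    return AcquisitionScheme(measurements, shell_tolerance=shell_tolerance)


def write_scheme_file(scheme: AcquisitionScheme, path, te_s: float = 0.075) -> None:
    """Inverse of :func:`load_scheme_file`."""
    with open(path, "w") as fh:
        fh.write("# gx gy gz |G|(T/m) Delta(s) delta(s) TE(s)\n")
        for m in scheme.measurements:
            fh.write(
                f"{m.direction[0]:.8f} {m.direction[1]:.8f} {m.direction[2]:.8f} "
                f"{m.G * 1e-3:.8f} {m.Delta * 1e-3:.6f} {m.delta * 1e-3:.6f} {te_s:.6f}\n"
            )
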