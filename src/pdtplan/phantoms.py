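"""Synthetic abscess phantoms and subject optical-property draws.

Clinical abscess cavities span roughly 1–8 cm, are often lobulated, and
show very wide inter-subject variation in wall optical properties at
665 nm — particularly the post-methylene-blue absorption coefficient,
which varies over more than two orders of magnitude between subjects.
This module generates cavity masks and per-subject optical draws with
that statistical structure, standing in for (unreleased) patient CT
segmentations and diffuse-reflectance spectroscopy measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import sph_harm_y

__all__ = [
    "PhantomSpec",
    "SubjectOptics",
    "OpticsRanges",
    "make_cavity_mask",
    "sample_subject_optics",
    "clinical_power_rule",
    "POWER_CAP_MW",
]

POWER_CAP_MW = 10_000.0
MAX_GRID = 512


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one synthetic cavity.

    ``semi_axes_mm`` are the ellipsoid semi-axes (all equal for a sphere;
    the first is the base radius of a lobulated shape). Lobulation
    perturbs the radius with seeded low-order spherical harmonics whose
    peak relative amplitude is ``lobe_amplitude``.
    """

    shape: str = "sphere"  # sphere | ellipsoid | lobulated
    semi_axes_mm: tuple[float, float, float] = (10.0, 10.0, 10.0)
    n_lobes: int = 3
    lobe_amplitude: float = 0.0
    pitch_mm: float = 0.5
    padding_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "ellipsoid", "lobulated"):
            raise ValueError(f"unknown phantom shape {self.shape!r}")
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError("semi-axes must be positive")
        if self.pitch_mm <= 0:
            raise ValueError("pitch must be positive")
        if self.padding_mm < 2 * self.pitch_mm:
            raise ValueError("padding must be at least 2 voxels of tissue margin")
        if not 0.0 <= self.lobe_amplitude <= 0.5:
            raise ValueError("lobe amplitude must lie in [0, 0.5] to keep the surface star-shaped")
        if self.n_lobes < 0:
            raise ValueError("lobe count must be non-negative")


@dataclass(frozen=True)
class SubjectOptics:
    """Per-subject 665 nm optical measurements and clinical dose settings.

    ``pre`` values are native tissue (before methylene blue instillation),
    ``post`` values include the photosensitizer's strong 665 nm absorption.
    All coefficients in cm⁻¹. ``power_mw`` is the laser power delivered
    clinically; ``intralipid_pct`` the intra-cavity scatterer concentration
    used clinically (1% in the trial protocol).
    """

    pre_mua: float
    pre_musp: float
    post_mua: float
    post_musp: float
    power_mw: float
    intralipid_pct: float = 1.0

    def __post_init__(self) -> None:
        for name in ("pre_mua", "pre_musp", "post_mua", "post_musp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.power_mw <= POWER_CAP_MW:
            raise ValueError(f"delivered power must lie in (0, {POWER_CAP_MW}] mW")


@dataclass(frozen=True)
class OpticsRanges:
    """Sampling ranges for synthetic subjects (all positive intervals).

    Absorption ranges are sampled log-uniformly: measured post-MB wall
    absorption spans more than two decades across subjects. Reduced
    scattering is sampled uniformly.
    """

    pre_mua: tuple[float, float] = (0.02, 2.0)
    post_mua: tuple[float, float] = (0.2, 50.0)
    pre_musp: tuple[float, float] = (1.0, 15.0)
    post_musp: tuple[float, float] = (1.0, 15.0)
    power_mw: tuple[float, float] = (200.0, 5000.0)

    def __post_init__(self) -> None:
        for name in ("pre_mua", "post_mua", "pre_musp", "post_musp", "power_mw"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"range {name} must be a positive, non-inverted interval")


def _real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real spherical harmonic (polar angle theta, azimuth phi)."""
    y = sph_harm_y(l, abs(m), theta, phi)
    if m > 0:
        return math.sqrt(2.0) * (-1) ** m * y.real
    if m < 0:
        return math.sqrt(2.0) * (-1) ** m * y.imag
    return y.real


def make_cavity_mask(spec: PhantomSpec) -> tuple[np.ndarray, float]:
    """Voxelize a cavity shape; returns ``(mask, pitch_mm)``.

    The cavity is centered on the grid; the grid extends ``padding_mm``
    beyond the largest possible cavity radius on every side. Masks are
    reproducible bit-for-bit for a fixed ``spec`` (including the seed).
    """
    a, b, c = spec.semi_axes_mm
    if spec.shape == "lobulated":
        max_r = np.array([a, a, a]) * (1.0 + spec.lobe_amplitude)
    else:
        max_r = np.array([a, b, c], dtype=float)
    half_extent = max_r + spec.padding_mm
    dims = np.ceil(2 * half_extent / spec.pitch_mm).astype(int)
    if (dims > MAX_GRID).any():
        raise ValueError(
            f"requested grid {tuple(dims)} exceeds the {MAX_GRID}-voxel limit per axis; "
            "increase the pitch or shrink the cavity"
        )

    coords = [
        (np.arange(n) + 0.5) * spec.pitch_mm - n * spec.pitch_mm / 2.0 for n in dims
    ]
    dx, dy, dz = np.meshgrid(*coords, indexing="ij", sparse=True)

    if spec.shape in ("sphere", "ellipsoid"):
        if spec.shape == "sphere":
            b = c = a
        mask = (dx / a) ** 2 + (dy / b) ** 2 + (dz / c) ** 2 <= 1.0
    else:
        r = np.sqrt(dx**2 + dy**2 + dz**2)
        cos_theta = np.divide(dz, r, out=np.ones(r.shape), where=r > 0)
        theta = np.arccos(np.clip(cos_theta, -1, 1))
        phi = np.arctan2(dy, dx)
        mask = r <= a * (1.0 + spec.lobe_amplitude * _lobe_field(spec, theta, phi))

    from . import geometry  # local import to avoid a cycle at package init

    geometry._check_mask(mask)  # single 6-connected component
    return mask, spec.pitch_mm


def _lobe_field(spec: PhantomSpec, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Seeded low-order spherical-harmonic perturbation, normalized to peak 1."""
    if spec.lobe_amplitude == 0.0 or spec.n_lobes == 0:
        return np.zeros(np.broadcast_shapes(theta.shape, phi.shape))
    rng = np.random.default_rng(spec.seed)
    degrees = [2, 3]
    terms = [(l, m) for l in degrees for m in range(-l, l + 1)]
    rng.shuffle(terms)
    terms = terms[: max(1, spec.n_lobes)]
    coeffs = rng.standard_normal(len(terms))
    f = np.zeros(np.broadcast_shapes(theta.shape, phi.shape))
    for (l, m), cf in zip(terms, coeffs):
        f = f + cf * _real_sph_harm(l, m, theta, phi)
    # normalize the peak over a dense angular sample so |perturbation| <= amplitude
    tt, pp = np.meshgrid(
        np.linspace(0, np.pi, 91), np.linspace(-np.pi, np.pi, 181), indexing="ij"
    )
    ref = np.zeros_like(tt)
    for (l, m), cf in zip(terms, coeffs):
        ref += cf * _real_sph_harm(l, m, tt, pp)
    peak = np.abs(ref).max()
    if peak == 0:
        return np.zeros_like(f)
    return f / peak


def sample_subject_optics(
    seed: int,
    ranges: OpticsRanges | None = None,
    shortest_axis_cm: float | None = None,
    target_mw_cm2: float = 20.0,
) -> SubjectOptics:
    """Draw one synthetic subject's optical properties (reproducible per seed).

    Absorption coefficients are drawn log-uniformly, reduced scattering
    uniformly, from ``ranges``. If ``shortest_axis_cm`` is given, the
    clinically delivered power follows :func:`clinical_power_rule` for that
    dimension; otherwise it is drawn uniformly from ``ranges.power_mw``.
    """
    ranges = ranges or OpticsRanges()
    rng = np.random.default_rng(seed)

    def log_uniform(lo: float, hi: float) -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    pre_mua = log_uniform(*ranges.pre_mua)
    post_mua = log_uniform(*ranges.post_mua)
    pre_musp = float(rng.uniform(*ranges.pre_musp))
    post_musp = float(rng.uniform(*ranges.post_musp))
    if shortest_axis_cm is not None:
        power = clinical_power_rule(shortest_axis_cm, target_mw_cm2)
    else:
        power = float(rng.uniform(*ranges.power_mw))
    return SubjectOptics(
        pre_mua=pre_mua,
        pre_musp=pre_musp,
        post_mua=post_mua,
        post_musp=post_musp,
        power_mw=power,
        intralipid_pct=1.0,
    )


def clinical_power_rule(shortest_axis_cm: float, target_mw_cm2: float = 20.0) -> float:
    """Laser power chosen clinically from the abscess's shortest CT axis.

    The clinical protocol targets a fluence rate (default 20 mW cm⁻²) at
    the shortest axis of the cavity, without knowledge of the subject's
    optical properties. This adopts the lossless-vacuum reading: the power
    that produces the target on a sphere of diameter equal to the shortest
    axis, ``P = target x 4 pi (d/2)^2``, capped at 10,000 mW. The formula is
    isolated here so a different clinical rule can be swapped in.
    """
    if shortest_axis_cm <= 0:
        raise ValueError("shortest axis must be positive")
    if target_mw_cm2 < 0:
        raise ValueError("target fluence rate must be non-negative")
    power = target_mw_cm2 * 4.0 * math.pi * (shortest_axis_cm / 2.0) ** 2
    return min(power, POWER_CAP_MW)
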