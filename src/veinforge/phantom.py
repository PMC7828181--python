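"""Synthetic fundus-like phantoms with known vessel ground truth.

The generator draws a branching set of vessel centerlines (straight or
quadratic-Bezier polylines) with Gaussian cross-sections on a flat
background, restricted to a circular field of view (FOV), and corrupts the
result with unit-mean multiplicative square-root-Gamma amplitude speckle of
configurable number of looks ``L`` plus optional additive Gaussian noise.

Every downstream stage of the segmentation pipeline can therefore be tested
against an exactly known clean image and vessel mask without any external
dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy.special import gammaln

__all__ = [
    "VesselSegment",
    "PhantomSpec",
    "NoiseSpec",
    "generate_phantom",
    "apply_speckle",
    "speckle_multiplier_mean",
    "speckle_multiplier_var",
    "default_phantom_spec",
]

#: ground-truth support half-width, in units of the cross-section sigma
TRUTH_SIGMA_FACTOR = 2.0


@dataclass
class VesselSegment:
    """One vessel branch: a centerline with a Gaussian intensity profile.

    ``points`` holds 2 endpoints for a straight segment or 3 control points
    for a quadratic Bezier, as (row, col) pairs.  ``amplitude`` is the
    centerline contrast above background and ``sigma`` the cross-section
    standard deviation in pixels.
    """

    points: list
    amplitude: float
    sigma: float

    def polyline(self, n: int = 64) -> np.ndarray:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape[0] == 2:
            return pts
        if pts.shape[0] == 3:  # quadratic Bezier
            t = np.linspace(0.0, 1.0, n)[:, None]
            return ((1 - t) ** 2 * pts[0] + 2 * (1 - t) * t * pts[1]
                    + t ** 2 * pts[2])
        raise ValueError("segment needs 2 endpoints or 3 Bezier control points")


@dataclass
class PhantomSpec:
    width: int = 256
    height: int = 256
    background_level: float = 0.4
    vessel_segments: list = field(default_factory=list)
    polarity: str = "bright"  # 'bright' or 'dark' vessels vs background
    fov_radius_fraction: float = 0.94
    seed: int = 0

    def validate(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("zero-size image")
        if not 0.0 <= self.background_level <= 1.0:
            raise ValueError("background_level must be in [0, 1]")
        if self.polarity not in ("bright", "dark"):
            raise ValueError("polarity must be 'bright' or 'dark'")
        for seg in self.vessel_segments:
            if seg.sigma <= 0:
                raise ValueError("cross-section sigma must be > 0")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self))

    @classmethod
    def from_yaml(cls, text: str) -> "PhantomSpec":
        d = yaml.safe_load(text)
        d["vessel_segments"] = [VesselSegment(**s) for s in d.get("vessel_segments", [])]
        return cls(**d)


@dataclass
class NoiseSpec:
    """Speckle order ``looks`` (L) and optional additive Gaussian sigma."""

    looks: float = 4.0
    additive_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.looks > 0:
            raise ValueError("looks L must be > 0")
        if self.additive_sigma < 0:
            raise ValueError("additive_sigma must be >= 0")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self))

    @classmethod
    def from_yaml(cls, text: str) -> "NoiseSpec":
        return cls(**yaml.safe_load(text))


def speckle_multiplier_mean(looks: float) -> float:
    """Mean of the raw amplitude-speckle multiplier sqrt(G), G ~ Gamma(L, 1/L).

    Equals Gamma(L + 1/2) / (Gamma(L) * sqrt(L)).
    """
    if np.isinf(looks):
        return 1.0
    return float(np.exp(gammaln(looks + 0.5) - gammaln(looks) - 0.5 * np.log(looks)))


def speckle_multiplier_var(looks: float) -> float:
    """Variance of the *unit-mean* amplitude-speckle multiplier.

    The raw multiplier has second moment exactly 1, so after dividing by its
    mean m1 the variance is 1/m1^2 - 1.  Infinite looks means no speckle.
    """
    if np.isinf(looks):
        return 0.0
    m1 = speckle_multiplier_mean(looks)
    return 1.0 / (m1 * m1) - 1.0


def _distance_to_polyline(rows: np.ndarray, cols: np.ndarray,
                          poly: np.ndarray) -> np.ndarray:
    """Min Euclidean distance of each pixel to a polyline of (row,col) points."""
    d2 = np.full(rows.shape, np.inf)
    for a, b in zip(poly[:-1], poly[1:]):
        ab = b - a
        denom = float(ab @ ab)
        pr = rows - a[0]
        pc = cols - a[1]
        if denom == 0.0:
            d2 = np.minimum(d2, pr * pr + pc * pc)
            continue
        t = np.clip((pr * ab[0] + pc * ab[1]) / denom, 0.0, 1.0)
        dr = pr - t * ab[0]
        dc = pc - t * ab[1]
        d2 = np.minimum(d2, dr * dr + dc * dc)
    return np.sqrt(d2)


def generate_phantom(spec: PhantomSpec):
    """Render (clean, truth_mask, fov) for a phantom specification.

    The clean image is ``background + max_over_segments(A * exp(-d^2/2s^2))``
    for bright polarity (inverted afterwards for dark), the truth mask is the
    set of pixels within ``TRUTH_SIGMA_FACTOR * sigma`` of any centerline,
    and the FOV is a centered disc.  Fully deterministic.
    """
    spec.validate()
    h, w = spec.height, spec.width
    rows, cols = np.mgrid[0:h, 0:w].astype(float)

    ridge = np.zeros((h, w))
    truth = np.zeros((h, w), dtype=bool)
    for seg in spec.vessel_segments:
        d = _distance_to_polyline(rows, cols, seg.polyline())
        ridge = np.maximum(ridge, seg.amplitude * np.exp(-d * d / (2.0 * seg.sigma ** 2)))
        truth |= d <= TRUTH_SIGMA_FACTOR * seg.sigma

    clean = spec.background_level + ridge
    if clean.max() > 1.0 + 1e-12:
        warnings.warn("phantom intensities exceed 1; clipping to [0, 1]")
        clean = np.clip(clean, 0.0, 1.0)
    if spec.polarity == "dark":
        clean = 1.0 - clean

    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    radius = spec.fov_radius_fraction * min(h, w) / 2.0
    fov = (rows - cr) ** 2 + (cols - cc) ** 2 <= radius ** 2
    truth &= fov
    # dark FOV border, as in real fundus photographs
    clean = np.where(fov, clean, 0.0)
    return clean, truth, fov


def apply_speckle(clean: np.ndarray, noise: NoiseSpec, clip01: bool = False) -> np.ndarray:
    """Multiply by unit-mean square-root-Gamma speckle, add optional Gaussian noise.

    Each pixel z(k) = x(k) * u(k) where u(k)^2 ~ Gamma(shape L, scale 1/L)
    rescaled so E[u] = 1 exactly.  Deterministic given ``noise.seed``.
    """
    noise.validate()
    rng = np.random.default_rng(noise.seed)
    if np.isinf(noise.looks):
        u = np.ones_like(clean)
    else:
        raw = np.sqrt(rng.gamma(noise.looks, 1.0 / noise.looks, size=clean.shape))
        u = raw / speckle_multiplier_mean(noise.looks)
    out = clean * u
    if noise.additive_sigma > 0:
        out = out + rng.normal(0.0, noise.additive_sigma, size=clean.shape)
    out = np.clip(out, 0.0, None)
    if clip01:
        out = np.clip(out, 0.0, 1.0)
    return out


def default_phantom_spec(width: int = 256, height: int = 256, seed: int = 0,
                         polarity: str = "bright") -> PhantomSpec:
    """A branching vessel tree with thick / medium / thin branches.

    Two arched main vessels (sigma ~2.6 px) branch into medium (sigma ~1.7)
    and thin (sigma ~1.0) offshoots; amplitudes taper with caliber the way
    vessel contrast does in fundus photographs.  Geometry is drawn from the
    seed, so the phantom is reproducible and varied across seeds.
    """
    rng = np.random.default_rng(seed)
    h, w = height, width
    segs: list[VesselSegment] = []

    def jitter(scale):
        return rng.uniform(-scale, scale)

    # two main arcades entering near the left edge
    for sign in (-1.0, 1.0):
        start = np.array([h * (0.5 + 0.08 * sign + 0.02 * jitter(1)), w * 0.08])
        ctrl = np.array([h * (0.5 + 0.45 * sign + 0.05 * jitter(1)), w * (0.5 + 0.08 * jitter(1))])
        end = np.array([h * (0.5 + 0.18 * sign + 0.05 * jitter(1)), w * 0.93])
        main = VesselSegment([start.tolist(), ctrl.tolist(), end.tolist()],
                             amplitude=0.42 + 0.03 * jitter(1), sigma=2.6)
        segs.append(main)
        poly = main.polyline(64)
        # medium branches off the arcade
        for frac in (0.25, 0.5, 0.75):
            i = int(frac * (len(poly) - 1))
            p0 = poly[i]
            direction = rng.uniform(0, 2 * np.pi)
            length = rng.uniform(0.18, 0.3) * min(h, w)
            p1 = p0 + length * np.array([np.cos(direction), np.sin(direction)])
            p1 = np.clip(p1, [4, 4], [h - 5, w - 5])
            branch = VesselSegment([p0.tolist(), p1.tolist()],
                                   amplitude=0.33 + 0.03 * jitter(1), sigma=1.7)
            segs.append(branch)
            # a thin twig off each medium branch
            q0 = 0.5 * (p0 + p1)
            tdir = direction + rng.uniform(0.5, 1.2) * rng.choice([-1, 1])
            q1 = q0 + rng.uniform(0.1, 0.18) * min(h, w) * np.array([np.cos(tdir), np.sin(tdir)])
            q1 = np.clip(q1, [4, 4], [h - 5, w - 5])
            segs.append(VesselSegment([q0.tolist(), q1.tolist()],
                                      amplitude=0.26 + 0.03 * jitter(1), sigma=1.0))

    return PhantomSpec(width=width, height=height, background_level=0.4,
                       vessel_segments=segs, polarity=polarity,
                       fov_radius_fraction=0.94, seed=seed)
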