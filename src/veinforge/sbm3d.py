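"""Speckle-adapted BM3D (S-BM3D) collaborative filter.

The filter runs in the amplitude domain on images corrupted by unit-mean
multiplicative square-root-Gamma speckle of order ``L`` (number of looks).
It follows the classic two-pass BM3D architecture:

1. group similar patches by a probabilistic (likelihood-ratio) distance,
   D = sum_k [(2L-1) log(a_s/a_t + a_t/a_s) + gamma (x_s-x_t)^2/(x_s x_t)],
   where the second (prior) term is active only once a clean estimate
   exists; denoise each 3-D group by LLMMSE shrinkage in a redundant
   (stationary) 2-D wavelet domain combined with an orthonormal Haar
   transform along the stacking axis; aggregate overlapping estimates into
   a prior image;
2. re-group using the full distance (data + prior term) and apply an
   empirical Wiener filter, X = X'^2/(X'^2 + <V^2>) Z, with the stage-1
   coefficients X' as the signal-power prior; aggregate again.

Aggregation is a per-pixel weighted mean with per-group weights
w = 1/(1 + residual variance), which preserves constants exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
import pywt
import yaml
from numba import njit

from .phantom import speckle_multiplier_var

__all__ = [
    "DenoiserParams",
    "PatchGroup",
    "PixelAggregator",
    "patch_distance",
    "block_match",
    "stage1_llmmse",
    "stage2_wiener",
    "aggregate",
    "sbm3d_denoise",
]

#: amplitude clamp applied before any log-ratio (the distance is undefined at 0)
EPS_AMPLITUDE = 1e-6


@dataclass
class DenoiserParams:
    """One S-BM3D parameterization.

    ``block_size`` and ``search_window`` are the knobs varied by the
    ensemble; the rest follow SAR-BM3D conventions.  ``looks`` is the
    speckle order L of the input; ``gamma`` weighs the prior term of the
    patch distance in the second pass.
    """

    block_size: int = 8
    search_window: int = 39
    step: int = 3
    max_group: int = 16
    looks: float = 4.0
    gamma: float = 4.0
    wavelet_name: str = "db8"
    levels: int = 2
    group_transform: str = "haar"

    def validate(self) -> None:
        if self.block_size > self.search_window:
            raise ValueError("block_size must be <= search_window")
        if self.max_group < 1 or self.max_group & (self.max_group - 1):
            raise ValueError("max_group must be a positive power of two")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if not self.looks > 0:
            raise ValueError("looks L must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.block_size % (1 << self.levels):
            raise ValueError("block_size must be divisible by 2**levels")
        if self.group_transform != "haar":
            raise ValueError("only the Haar group transform is implemented")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DenoiserParams":
        return cls(**d)


@dataclass
class PatchGroup:
    """A reference patch plus its matched similar patches (the 3-D block)."""

    reference_location: tuple
    member_locations: list
    stack: np.ndarray  # (members, block, block)
    distances: list
    prior_stack: np.ndarray | None = None

    def __post_init__(self):
        if tuple(self.member_locations[0]) != tuple(self.reference_location):
            raise ValueError("reference must be the first member")
        d = np.asarray(self.distances)
        with np.errstate(invalid="ignore"):
            if np.any(np.diff(d) < -1e-9):
                raise ValueError("distances must be nondecreasing")


# ---------------------------------------------------------------------------
# patch distance (speckle likelihood-ratio + prior term)
# ---------------------------------------------------------------------------

def patch_distance(a_s: np.ndarray, a_t: np.ndarray,
                   prior_s: np.ndarray | None = None,
                   prior_t: np.ndarray | None = None,
                   looks: float = 4.0, gamma: float = 0.0) -> float:
    """Probabilistic distance between two amplitude patches.

    Symmetric in its arguments; the prior patches are required iff
    ``gamma > 0``.  Amplitudes are clamped at ``EPS_AMPLITUDE`` first.
    """
    a_s = np.asarray(a_s, dtype=float)
    a_t = np.asarray(a_t, dtype=float)
    if a_s.shape != a_t.shape:
        raise ValueError("patch shapes differ")
    if gamma > 0 and (prior_s is None or prior_t is None):
        raise ValueError("gamma > 0 requires prior patches")
    a_s = np.maximum(a_s, EPS_AMPLITUDE)
    a_t = np.maximum(a_t, EPS_AMPLITUDE)
    r = a_s / a_t
    d = (2.0 * looks - 1.0) * np.sum(np.log(r + 1.0 / r))
    if gamma > 0:
        ps = np.maximum(np.asarray(prior_s, float), EPS_AMPLITUDE)
        pt = np.maximum(np.asarray(prior_t, float), EPS_AMPLITUDE)
        d += gamma * np.sum((ps - pt) ** 2 / (ps * pt))
    return float(d)


@njit(cache=True)
def _match_batch(img, prior, refs_r, refs_c, b, sw, G, two_l_minus_1, gamma,
                 use_prior, out_r, out_c, out_d, counts):  # pragma: no cover
    """For each reference location keep the G-1 nearest other patches.

    Stable under ties: candidates are scanned row-major and an equal
    distance never displaces an earlier one.
    """
    H, W = img.shape
    half = (sw - b) // 2
    n = refs_r.size
    for i in range(n):
        r0 = refs_r[i]
        c0 = refs_c[i]
        rlo = max(0, r0 - half)
        rhi = min(H - b, r0 + half)
        clo = max(0, c0 - half)
        chi = min(W - b, c0 + half)
        m = 0  # filled slots among the G-1 best "others"
        kd = out_d[i]
        kr = out_r[i]
        kc = out_c[i]
        # self-distance of the reference (minimum of the likelihood term)
        dref = b * b * two_l_minus_1 * np.log(2.0)
        worst = 1e300
        if G == 1:
            rlo, rhi = 0, -1  # nothing to scan: the group is the reference alone
        for r in range(rlo, rhi + 1):
            for c in range(clo, chi + 1):
                if r == r0 and c == c0:
                    continue
                d = 0.0
                stop = False
                for dr in range(b):
                    for dc in range(b):
                        a1 = img[r0 + dr, c0 + dc]
                        a2 = img[r + dr, c + dc]
                        ratio = a1 / a2
                        d += two_l_minus_1 * np.log(ratio + 1.0 / ratio)
                        if use_prior:
                            p1 = prior[r0 + dr, c0 + dc]
                            p2 = prior[r + dr, c + dc]
                            diff = p1 - p2
                            d += gamma * diff * diff / (p1 * p2)
                    if m == G - 1 and d >= worst:
                        stop = True
                        break
                if stop:
                    continue
                if m < G - 1:
                    j = m
                    while j > 0 and kd[j - 1] > d:
                        kd[j] = kd[j - 1]
                        kr[j] = kr[j - 1]
                        kc[j] = kc[j - 1]
                        j -= 1
                    kd[j] = d
                    kr[j] = r
                    kc[j] = c
                    m += 1
                elif d < worst:
                    j = m - 1
                    while j > 0 and kd[j - 1] > d:
                        kd[j] = kd[j - 1]
                        kr[j] = kr[j - 1]
                        kc[j] = kc[j - 1]
                        j -= 1
                    kd[j] = d
                    kr[j] = r
                    kc[j] = c
                if m == G - 1:
                    worst = kd[m - 1]
        # shift others right and put the reference first
        for j in range(m, 0, -1):
            kd[j] = kd[j - 1]
            kr[j] = kr[j - 1]
            kc[j] = kc[j - 1]
        kd[0] = dref
        kr[0] = r0
        kc[0] = c0
        counts[i] = m + 1


def _match_locations(img: np.ndarray, prior: np.ndarray | None,
                     refs: np.ndarray, p: DenoiserParams):
    """Run the numba matcher over an array of reference locations."""
    G = p.max_group
    n = refs.shape[0]
    img_c = np.maximum(np.asarray(img, float), EPS_AMPLITUDE)
    use_prior = prior is not None and p.gamma > 0
    prior_c = (np.maximum(np.asarray(prior, float), EPS_AMPLITUDE)
               if use_prior else img_c)
    out_r = np.zeros((n, G), np.int64)
    out_c = np.zeros((n, G), np.int64)
    out_d = np.full((n, G), np.inf)
    counts = np.zeros(n, np.int64)
    _match_batch(img_c, prior_c, refs[:, 0].astype(np.int64),
                 refs[:, 1].astype(np.int64), p.block_size, p.search_window,
                 G, 2.0 * p.looks - 1.0, p.gamma, use_prior,
                 out_r, out_c, out_d, counts)
    return out_r, out_c, out_d, counts


def block_match(img: np.ndarray, prior: np.ndarray | None,
                ref: tuple, p: DenoiserParams) -> PatchGroup:
    """Group the patches most similar to the reference patch.

    Scans every candidate top-left position whose search window contains the
    reference (stride 1), keeps the ``max_group`` smallest distances with
    the reference always first.
    """
    p.validate()
    b = p.block_size
    H, W = img.shape
    r0, c0 = ref
    if not (0 <= r0 <= H - b and 0 <= c0 <= W - b):
        raise ValueError("reference patch not fully inside image")
    out_r, out_c, out_d, counts = _match_locations(img, prior,
                                                   np.array([[r0, c0]]), p)
    m = int(counts[0])
    locs = [(int(out_r[0, j]), int(out_c[0, j])) for j in range(m)]
    stack = np.stack([img[r:r + b, c:c + b] for r, c in locs])
    prior_stack = None
    if prior is not None:
        prior_stack = np.stack([prior[r:r + b, c:c + b] for r, c in locs])
    return PatchGroup(reference_location=(r0, c0), member_locations=locs,
                      stack=stack, distances=list(out_d[0, :m]),
                      prior_stack=prior_stack)


# ---------------------------------------------------------------------------
# 3-D transform: orthonormal Haar along the stack, stationary wavelet in-plane
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _haar_matrix(n: int) -> np.ndarray:
    """Orthonormal Haar matrix of size n (power of two)."""
    if n == 1:
        return np.array([[1.0]])
    h = _haar_matrix(n // 2)
    top = np.kron(h, [1.0, 1.0])
    bot = np.kron(np.eye(n // 2), [1.0, -1.0])
    return np.vstack([top, bot]) / np.sqrt(2.0)


def _forward_3d(stack: np.ndarray, wavelet: str, levels: int):
    """Haar along axis -3, stationary 2-D wavelet along the last two axes.

    Returns (bands, meta) where bands is a flat list of coefficient arrays
    (approx first, then details fine-to-coarse as pywt emits them).
    """
    G = stack.shape[-3]
    hm = _haar_matrix(G)
    t = np.einsum("gh,...hij->...gij", hm, stack)
    coeffs = pywt.swtn(t, wavelet, level=levels, axes=(-2, -1),
                       trim_approx=True, norm=True)
    return coeffs


def _inverse_3d(coeffs, wavelet: str, G: int) -> np.ndarray:
    t = pywt.iswtn(coeffs, wavelet, axes=(-2, -1), norm=True)
    hm = _haar_matrix(G)
    # orthonormal: inverse along the stack axis is multiplication by hm.T
    return np.einsum("gh,...gij->...hij", hm, t)


def _iter_bands(coeffs):
    """Yield (band_key, array) over an swtn coefficient structure in place."""
    yield ("approx",), coeffs[0]
    for lev, det in enumerate(coeffs[1:]):
        for key in sorted(det):
            yield (lev, key), det[key]


@lru_cache(maxsize=None)
def _band_gains(wavelet: str, levels: int, block: int):
    """Per-band white-noise variance gain of the stationary 2-D transform.

    For white noise of variance s^2 the coefficients of band b have variance
    s^2 * gain[b]; computed exactly from the transform of all pixel
    impulses (the transform is linear and, with periodic extension,
    shift-invariant, so one output position suffices).
    """
    eye = np.eye(block * block).reshape(block * block, block, block)
    coeffs = pywt.swtn(eye, wavelet, level=levels, axes=(-2, -1),
                       trim_approx=True, norm=True)
    gains = {}
    for key, arr in _iter_bands(coeffs):
        gains[key] = float(np.sum(arr[:, 0, 0] ** 2))
    return gains


def _coefficient_noise_var(stack: np.ndarray, looks: float) -> float:
    """Pixel-domain speckle noise variance for one group.

    With z = x u, E[u]=1, Var[u]=s_u^2: Var[noise] = x^2 s_u^2 and
    E[z^2] = x^2 (1 + s_u^2), so x^2 is estimated as mean(z^2)/(1+s_u^2).
    """
    su2 = speckle_multiplier_var(looks)
    if su2 == 0.0:
        return 0.0
    return su2 * float(np.mean(stack ** 2)) / (1.0 + su2)


# ---------------------------------------------------------------------------
# collaborative shrinkage stages
# ---------------------------------------------------------------------------

def _stage1_batch(stacks: np.ndarray, p: DenoiserParams) -> np.ndarray:
    """LLMMSE shrinkage of a batch of groups, shape (N, G, b, b)."""
    N, G, b, _ = stacks.shape
    coeffs = _forward_3d(stacks, p.wavelet_name, p.levels)
    gains = _band_gains(p.wavelet_name, p.levels, b)
    su2 = speckle_multiplier_var(p.looks)
    sig_pix = (su2 * np.mean(stacks ** 2, axis=(1, 2, 3)) / (1.0 + su2)
               if su2 > 0 else np.zeros(N))  # (N,)
    for key, arr in _iter_bands(coeffs):
        # statistics per (group, Haar plane) over the b*b spatial positions
        mu = arr.mean(axis=(-2, -1), keepdims=True)
        total = arr.var(axis=(-2, -1), keepdims=True)
        sn2 = (sig_pix * gains[key]).reshape(N, 1, 1, 1)
        sx2 = np.maximum(total - sn2, 0.0)
        denom = sx2 + sn2
        factor = np.divide(sx2, denom, out=np.ones_like(sx2),
                           where=denom > 0)
        arr[...] = mu + factor * (arr - mu)
    out = _inverse_3d(coeffs, p.wavelet_name, G)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite coefficients in stage 1")
    return out


def _stage2_batch(noisy: np.ndarray, prior: np.ndarray,
                  p: DenoiserParams) -> np.ndarray:
    """Empirical Wiener shrinkage of a batch of groups using stage-1 priors."""
    if noisy.shape != prior.shape:
        raise ValueError("noisy and prior stacks differ in shape")
    G = noisy.shape[1]
    cz = _forward_3d(noisy, p.wavelet_name, p.levels)
    cp = _forward_3d(prior, p.wavelet_name, p.levels)
    for (key, z), (_, x) in zip(_iter_bands(cz), _iter_bands(cp)):
        v2 = np.mean((x - z) ** 2, axis=(1, 2, 3), keepdims=True)
        num = x * x
        denom = num + v2
        z[...] = np.divide(num, denom, out=np.zeros_like(num),
                           where=denom > 0) * z
    out = _inverse_3d(cz, p.wavelet_name, G)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite coefficients in stage 2")
    return out


def stage1_llmmse(group: PatchGroup, p: DenoiserParams) -> np.ndarray:
    """LLMMSE-shrink one patch group; returns the denoised patch stack."""
    if group.stack.shape[0] == 0:
        raise ValueError("empty group")
    stack, G = _pow2_truncate(group.stack)
    return _stage1_batch(stack[None], p)[0]


def stage2_wiener(group_noisy: PatchGroup, group_prior: np.ndarray,
                  p: DenoiserParams) -> np.ndarray:
    """Empirical Wiener filter of one group given its stage-1 prior stack."""
    stack, G = _pow2_truncate(group_noisy.stack)
    prior = np.asarray(group_prior)[:G]
    return _stage2_batch(stack[None], prior[None], p)[0]


def _pow2_truncate(stack: np.ndarray):
    n = stack.shape[0]
    G = 1 << int(np.floor(np.log2(n)))
    return stack[:G], G


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass
class PixelAggregator:
    """Accumulates weighted per-pixel estimates from overlapping groups."""

    shape: tuple
    numerator: np.ndarray = field(init=False)
    weight_total: np.ndarray = field(init=False)

    def __post_init__(self):
        self.numerator = np.zeros(self.shape)
        self.weight_total = np.zeros(self.shape)

    def add_patch(self, loc: tuple, patch: np.ndarray, weight: float) -> None:
        if weight < 0:
            raise ValueError("weights must be nonnegative")
        r, c = loc
        b0, b1 = patch.shape
        self.numerator[r:r + b0, c:c + b1] += weight * patch
        self.weight_total[r:r + b0, c:c + b1] += weight


def aggregate(agg: PixelAggregator, final_img_shape: tuple) -> np.ndarray:
    """Weighted mean of all accumulated estimates; errors on uncovered pixels."""
    if tuple(final_img_shape) != tuple(agg.shape):
        raise ValueError("aggregator shape mismatch")
    if np.any(agg.weight_total <= 0):
        raise ValueError("uncovered pixels inside the image")
    return agg.numerator / agg.weight_total


@njit(cache=True)
def _scatter_groups(num, den, est, stacks, locs_r, locs_c, b):  # pragma: no cover
    N, G = locs_r.shape
    for i in range(N):
        resid = 0.0
        for g in range(G):
            for dr in range(b):
                for dc in range(b):
                    diff = est[i, g, dr, dc] - stacks[i, g, dr, dc]
                    resid += diff * diff
        resid /= G * b * b
        w = 1.0 / (1.0 + resid)
        for g in range(G):
            r = locs_r[i, g]
            c = locs_c[i, g]
            for dr in range(b):
                for dc in range(b):
                    num[r + dr, c + dc] += w * est[i, g, dr, dc]
                    den[r + dr, c + dc] += w


# ---------------------------------------------------------------------------
# full denoiser
# ---------------------------------------------------------------------------

def _reference_grid(H: int, W: int, b: int, step: int) -> np.ndarray:
    rr = list(range(0, H - b + 1, step))
    if rr[-1] != H - b:
        rr.append(H - b)
    cc = list(range(0, W - b + 1, step))
    if cc[-1] != W - b:
        cc.append(W - b)
    rr = np.asarray(rr)
    cc = np.asarray(cc)
    grid = np.stack(np.meshgrid(rr, cc, indexing="ij"), axis=-1)
    return grid.reshape(-1, 2)


#: reference patches processed per transform batch (bounds peak memory)
_CHUNK = 2048


def _denoise_pass(img: np.ndarray, prior: np.ndarray | None,
                  p: DenoiserParams, stage: int) -> np.ndarray:
    b = p.block_size
    H, W = img.shape
    refs = _reference_grid(H, W, b, p.step)
    out_r, out_c, out_d, counts = _match_locations(img, prior, refs, p)
    G = p.max_group
    if np.any(counts < G):
        # small images: truncate uniformly to the largest common power of two
        G = 1 << int(np.floor(np.log2(counts.min())))
        out_r, out_c = out_r[:, :G], out_c[:, :G]
    num = np.zeros((H, W))
    den = np.zeros((H, W))
    for lo in range(0, refs.shape[0], _CHUNK):
        rr = out_r[lo:lo + _CHUNK]
        cc = out_c[lo:lo + _CHUNK]
        rows = rr[..., None, None] + np.arange(b)[None, None, :, None]
        cols = cc[..., None, None] + np.arange(b)[None, None, None, :]
        stacks = img[rows, cols]
        if stage == 1:
            est = _stage1_batch(stacks, p)
        else:
            est = _stage2_batch(stacks, prior[rows, cols], p)
        _scatter_groups(num, den, est, stacks, rr, cc, b)
    if np.any(den <= 0):
        raise RuntimeError("aggregation left uncovered pixels")
    return num / den


def sbm3d_denoise(img: np.ndarray, p: DenoiserParams | None = None,
                  single_stage: bool = False) -> np.ndarray:
    """Two-pass S-BM3D despeckling of an amplitude image in [0, 1].

    Pass 1 groups patches by the likelihood term only and builds the LLMMSE
    prior; pass 2 re-groups with the full data+prior distance and applies
    the empirical Wiener filter.  ``single_stage=True`` returns the stage-1
    aggregate.  Deterministic: there is no random state anywhere.
    """
    p = p or DenoiserParams()
    p.validate()
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    pad = p.search_window // 2
    padded = np.pad(np.maximum(img, EPS_AMPLITUDE), pad, mode="symmetric")
    p1 = DenoiserParams(**{**p.to_dict(), "gamma": 0.0})
    prior = _denoise_pass(padded, None, p1, stage=1)
    if single_stage:
        out = prior
    else:
        prior = np.maximum(prior, EPS_AMPLITUDE)
        out = _denoise_pass(padded, prior, p, stage=2)
    out = out[pad:pad + img.shape[0], pad:pad + img.shape[1]]
    return np.clip(out, 0.0, None)
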