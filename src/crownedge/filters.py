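"""Guidance-image construction and edge-preserving probability-map filters.

Two filters transfer edge structure from a sharper guidance image I onto a
probability map P:

* the joint bilateral filter (JBF),
  Q_i = (1/K_i) * sum_j exp(-||i-j|| / sigma_d^2) * exp(-|I_i-I_j|^2 / sigma_r^2) * P_j,
  a normalized convex combination whose range kernel is evaluated on the
  guidance rather than on P itself; and

* the guided filter (GF), which fits a local linear model Q = a_k I + b_k
  in every (2r+1)x(2r+1) window by ridge-regularized least squares
  (penalty epsilon on a_k^2) and averages the per-window predictions.

The JBF spatial kernel above carries an *unsquared* distance in the
numerator; that is deliberate and matches the formulation this package
follows. Pass ``spatial_squared=True`` for the conventional Gaussian
exp(-||i-j||^2 / sigma_d^2).

Both filters use reflect (symmetric) border padding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.transform import resize

from .classifier import ProbabilityStack
from .raster_io import GuidanceImage, HyperspectralCube

__all__ = [
    "JbfParams",
    "GfParams",
    "pca_false_color",
    "resample_guidance",
    "joint_bilateral_filter",
    "guided_filter",
    "filter_stack",
]


@dataclass(frozen=True)
class JbfParams:
    """Joint-bilateral-filter parameters.

    sigma_d: spatial kernel width in pixels; the window half-width is
    ceil(3*sigma_d). sigma_r: range kernel width in guidance-intensity units
    (guidance lives in [0, 1], so useful values are <~ 0.5).
    """

    sigma_d: float = 1.0
    sigma_r: float = 0.1
    spatial_squared: bool = False

    def __post_init__(self) -> None:
        if self.sigma_d <= 0 or self.sigma_r <= 0:
            raise ValueError("sigma_d and sigma_r must be positive")

    @property
    def half_width(self) -> int:
        return int(math.ceil(3 * self.sigma_d))


@dataclass(frozen=True)
class GfParams:
    """Guided-filter parameters: window radius r and regularizer epsilon.

    epsilon = 0 is admitted only for the self-guidance identity case; any
    smoothing use needs epsilon > 0.
    """

    r: int = 1
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError("window radius r must be >= 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")


# ---------------------------------------------------------------------------
# guidance construction
# ---------------------------------------------------------------------------


def pca_false_color(cube: HyperspectralCube) -> GuidanceImage:
    """False-color composite of the first three principal components.

    Channel c is the c-th principal-component score map over band space,
    independently min-max rescaled to [0, 1]. The sign of each component is
    fixed by requiring the largest-magnitude loading entry to be positive,
    so repeated runs are identical.
    """
    h, w, b = cube.shape
    if b < 3:
        raise ValueError(f"PCA false color needs >= 3 bands, got {b}")
    x = cube.values.reshape(-1, b)
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / max(len(xc) - 1, 1)
    total_var = float(np.trace(cov))
    if total_var <= 0:
        raise ValueError("zero-variance cube has no principal components")
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1][:3]
    channels = []
    for idx in order:
        v = eigvec[:, idx]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        score = xc @ v
        lo, hi = score.min(), score.max()
        channels.append((score - lo) / (hi - lo) if hi > lo else np.zeros_like(score))
    rgb = np.stack(channels, axis=-1).reshape(h, w, 3)
    return GuidanceImage(rgb, provenance="pca_false_color")


def resample_guidance(
    rgb: GuidanceImage, target_shape: tuple[int, int]
) -> GuidanceImage:
    """Bilinearly resample a 3-channel guidance image to the cube's H×W."""
    if rgb.values.ndim != 3:
        raise ValueError("resample_guidance expects a 3-channel image")
    h, w = target_shape
    if h < 1 or w < 1:
        raise ValueError(f"non-positive target shape {target_shape}")
    if (h, w) == rgb.spatial_shape:
        return GuidanceImage(rgb.values.copy(), provenance="rgb_resampled")
    out = resize(
        rgb.values, (h, w, 3), order=1, mode="reflect",
        anti_aliasing=False, preserve_range=True,
    )
    return GuidanceImage(np.clip(out, 0.0, 1.0), provenance="rgb_resampled")


# ---------------------------------------------------------------------------
# joint bilateral filter
# ---------------------------------------------------------------------------


def _as_guidance_array(guidance: GuidanceImage | np.ndarray) -> np.ndarray:
    g = guidance.values if isinstance(guidance, GuidanceImage) else np.asarray(guidance, float)
    if g.ndim == 2:
        g = g[:, :, None]
    return g


def joint_bilateral_filter(
    p: np.ndarray,
    guidance: GuidanceImage | np.ndarray,
    params: JbfParams,
) -> np.ndarray:
    """Filter a scalar map with spatial + guidance-range Gaussian weights.

    For 3-channel guidance the range distance |I_i - I_j|^2 is the squared
    Euclidean norm over channels. Weights are truncated to a square window
    of half-width ceil(3*sigma_d) and normalized to sum to 1, so the output
    is a convex combination of input values.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 2:
        raise ValueError("joint_bilateral_filter expects a 2-D map")
    g = _as_guidance_array(guidance)
    if g.shape[:2] != p.shape:
        raise ValueError(f"guidance shape {g.shape[:2]} != map shape {p.shape}")
    h = params.half_width
    pp = np.pad(p, h, mode="symmetric")
    gp = np.pad(g, ((h, h), (h, h), (0, 0)), mode="symmetric")
    num = np.zeros_like(p)
    den = np.zeros_like(p)
    H, W = p.shape
    inv_sd2 = 1.0 / params.sigma_d**2
    inv_sr2 = 1.0 / params.sigma_r**2
    for dy in range(-h, h + 1):
        for dx in range(-h, h + 1):
            dist = math.hypot(dy, dx)
            spatial = math.exp(-(dist**2 if params.spatial_squared else dist) * inv_sd2)
            g_shift = gp[h + dy : h + dy + H, h + dx : h + dx + W, :]
            p_shift = pp[h + dy : h + dy + H, h + dx : h + dx + W]
            range_w = np.exp(-np.sum((g[:, :, :] - g_shift) ** 2, axis=2) * inv_sr2)
            wgt = spatial * range_w
            num += wgt * p_shift
            den += wgt
    return num / den


# ---------------------------------------------------------------------------
# guided filter
# ---------------------------------------------------------------------------


def guided_filter(
    p: np.ndarray,
    guidance: GuidanceImage | np.ndarray,
    params: GfParams,
) -> np.ndarray:
    """Guided filter of a scalar map by a single-channel guidance.

    Per window k: a_k = cov(I, P) / (var(I) + epsilon), b_k = mean(P) -
    a_k * mean(I); the output at pixel i averages a_k*I_i + b_k over every
    window containing i. Window statistics are O(1) per pixel via separable
    box means; the contract is fixed by the literal per-window least-squares
    oracle used in the tests.

    3-channel guidance is reduced to Rec.601 luminance first — the filter
    itself is scalar-guided.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 2:
        raise ValueError("guided_filter expects a 2-D map")
    if isinstance(guidance, GuidanceImage):
        i_img = guidance.luminance()
    else:
        i_img = np.asarray(guidance, dtype=float)
        if i_img.ndim == 3:
            i_img = GuidanceImage(i_img).luminance()
    if i_img.shape != p.shape:
        raise ValueError(f"guidance shape {i_img.shape} != map shape {p.shape}")
    size = 2 * params.r + 1

    def box(x: np.ndarray) -> np.ndarray:
        return uniform_filter(x, size=size, mode="reflect")

    mean_i = box(i_img)
    mean_p = box(p)
    corr_ii = box(i_img * i_img)
    corr_ip = box(i_img * p)
    var_i = corr_ii - mean_i * mean_i
    cov_ip = corr_ip - mean_i * mean_p
    denom = var_i + params.epsilon
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(denom > 0, cov_ip / np.where(denom > 0, denom, 1.0), 0.0)
    b = mean_p - a * mean_i
    return box(a) * i_img + box(b)


# ---------------------------------------------------------------------------
# stack filtering
# ---------------------------------------------------------------------------


def filter_stack(
    stack: ProbabilityStack,
    guidance: GuidanceImage,
    method: str,
    params: JbfParams | GfParams,
) -> ProbabilityStack:
    """Filter each class probability map independently with one EPF.

    The filtered stack is clipped to [0, 1] but *not* renormalized: the
    maximum-probability fusion is invariant to per-pixel positive rescaling,
    and renormalizing would distort the per-class maps users inspect.
    """
    if stack.n_classes < 2:
        raise ValueError("stack must have at least 2 classes")
    if guidance.spatial_shape != stack.values.shape[:2]:
        raise ValueError("guidance and stack spatial shapes differ")
    if method == "jbf":
        if not isinstance(params, JbfParams):
            raise TypeError("method 'jbf' requires JbfParams")
        filt = lambda m: joint_bilateral_filter(m, guidance, params)
    elif method == "gf":
        if not isinstance(params, GfParams):
            raise TypeError("method 'gf' requires GfParams")
        filt = lambda m: guided_filter(m, guidance, params)
    else:
        raise ValueError(f"unknown filter method {method!r}")
    out = np.stack(
        [filt(stack.values[:, :, k]) for k in range(stack.n_classes)], axis=-1
    )
    return ProbabilityStack(np.clip(out, 0.0, 1.0), stack.legend, normalized=False)
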