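"""Independent brute-force oracles for the edge-preserving filters.

These implement the filter definitions literally — explicit double loops
over pixel pairs for the joint bilateral filter, an explicit per-window
least-squares solve for the guided filter — with no shared code with the
package's vectorized implementations. They are only usable on tiny images.
"""

from __future__ import annotations

import math

import numpy as np


def jbf_bruteforce(
    p: np.ndarray,
    guidance: np.ndarray,
    sigma_d: float,
    sigma_r: float,
    spatial_squared: bool = False,
) -> np.ndarray:
    """Literal joint bilateral filter: for every pixel i, loop over every j
    in the truncation window (half-width ceil(3*sigma_d)), with symmetric
    border extension."""
    p = np.asarray(p, dtype=float)
    g = np.asarray(guidance, dtype=float)
    if g.ndim == 2:
        g = g[:, :, None]
    h = int(math.ceil(3 * sigma_d))
    H, W = p.shape
    pp = np.pad(p, h, mode="symmetric")
    gp = np.pad(g, ((h, h), (h, h), (0, 0)), mode="symmetric")
    out = np.empty_like(p)
    for i0 in range(H):
        for i1 in range(W):
            num = 0.0
            den = 0.0
            gi = g[i0, i1]
            for dy in range(-h, h + 1):
                for dx in range(-h, h + 1):
                    d = math.hypot(dy, dx)
                    spatial = math.exp(
                        -((d * d) if spatial_squared else d) / sigma_d**2
                    )
                    gj = gp[h + i0 + dy, h + i1 + dx]
                    rng_w = math.exp(-float(np.sum((gi - gj) ** 2)) / sigma_r**2)
                    w = spatial * rng_w
                    num += w * pp[h + i0 + dy, h + i1 + dx]
                    den += w
            out[i0, i1] = num / den
    return out


def gf_bruteforce(
    p: np.ndarray, guidance: np.ndarray, r: int, epsilon: float
) -> np.ndarray:
    """Literal guided filter: solve the 2x2 regularized normal equations of
    E(a_k, b_k) = sum_{i in w_k} ((a_k I_i + b_k - P_i)^2 + eps a_k^2) in
    every window of the symmetric-padded plane, then average a_k I_i + b_k
    over all windows containing each pixel."""
    p = np.asarray(p, dtype=float)
    i_img = np.asarray(guidance, dtype=float)
    H, W = p.shape
    pad = 2 * r
    pp = np.pad(p, pad, mode="symmetric")
    ip = np.pad(i_img, pad, mode="symmetric")
    n = (2 * r + 1) ** 2
    # a, b per window center in the padded plane (only centers within pad-r
    # of the original image matter)
    a = np.zeros((H + 2 * pad, W + 2 * pad))
    b = np.zeros_like(a)
    for cy in range(r, H + 2 * pad - r):
        for cx in range(r, W + 2 * pad - r):
            iw = ip[cy - r : cy + r + 1, cx - r : cx + r + 1].ravel()
            pw = pp[cy - r : cy + r + 1, cx - r : cx + r + 1].ravel()
            # the ridge term eps*a^2 sits inside the sum over the n window
            # pixels, so it contributes n*eps to the normal equations
            lhs = np.array([[float(iw @ iw) + n * epsilon, iw.sum()],
                            [iw.sum(), float(n)]])
            rhs = np.array([float(iw @ pw), pw.sum()])
            try:
                ab = np.linalg.solve(lhs, rhs)
            except np.linalg.LinAlgError:
                ab = np.array([0.0, pw.mean()])
            a[cy, cx], b[cy, cx] = ab
    out = np.empty_like(p)
    for y in range(H):
        for x in range(W):
            cy0, cx0 = y + pad, x + pad
            acc = 0.0
            for cy in range(cy0 - r, cy0 + r + 1):
                for cx in range(cx0 - r, cx0 + r + 1):
                    acc += a[cy, cx] * i_img[y, x] + b[cy, cx]
            out[y, x] = acc / n
    return out


def spatial_kernel_blur(
    p: np.ndarray, sigma_d: float, spatial_squared: bool = False
) -> np.ndarray:
    """Direct convolution with the normalized truncated spatial kernel only
    (the sigma_r -> infinity limit of the JBF)."""
    p = np.asarray(p, dtype=float)
    h = int(math.ceil(3 * sigma_d))
    ys, xs = np.mgrid[-h : h + 1, -h : h + 1]
    d = np.hypot(ys, xs)
    kernel = np.exp(-((d**2) if spatial_squared else d) / sigma_d**2)
    kernel /= kernel.sum()
    pp = np.pad(p, h, mode="symmetric")
    H, W = p.shape
    out = np.zeros_like(p)
    for dy in range(-h, h + 1):
        for dx in range(-h, h + 1):
            out += kernel[dy + h, dx + h] * pp[h + dy : h + dy + H, h + dx : h + dx + W]
    return out


def rbf_kernel_perceptron(
    x: np.ndarray, y: np.ndarray, gamma_width: float, epochs: int = 200
) -> np.ndarray:
    """Kernel perceptron with K(a, b) = exp(-||a-b||^2 / gamma_width^2);
    returns its training predictions (labels in {-1, +1})."""
    n = len(x)
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
    gram = np.exp(-d2 / gamma_width**2)
    alpha = np.zeros(n)
    for _ in range(epochs):
        mistakes = 0
        for i in range(n):
            pred = np.sign((alpha * y) @ gram[:, i]) or 1.0
            if pred != y[i]:
                alpha[i] += 1.0
                mistakes += 1
        if mistakes == 0:
            break
    raw = (alpha * y) @ gram
    return np.where(raw >= 0, 1.0, -1.0)
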