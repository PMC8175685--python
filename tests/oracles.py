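"""Independent brute-force oracles used to cross-check the vision stack.

These deliberately avoid the gradient-voting code path: circles are
scored by an exhaustive matched filter (interior-disc mean vs
surrounding-ring mean, computed with FFT convolutions) over every centre
pixel and every radius.
"""
from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve


def _mean_kernel(mask: np.ndarray) -> np.ndarray:
    return mask.astype(float) / mask.sum()


def brute_force_circle_search(img: np.ndarray, radii) -> tuple[int, int, int, float]:
    """Exhaustive dark-disc search: argmax over (cx, cy, r) of
    ring_mean - disc_mean.  Returns (cx, cy, r, score)."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    best = None
    for r in radii:
        half = int(np.ceil(r + 2))
        yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
        d = np.hypot(xx, yy)
        disc = d <= max(r - 1.0, 1.0)
        ring = (d >= r + 1.0) & (d <= r + 2.0)
        disc_mean = fftconvolve(img, _mean_kernel(disc), mode="same")
        ring_mean = fftconvolve(img, _mean_kernel(ring), mode="same")
        score = ring_mean - disc_mean
        # exclude borders where the kernels hang off the image
        score[:half, :] = -np.inf
        score[-half:, :] = -np.inf
        score[:, :half] = -np.inf
        score[:, -half:] = -np.inf
        cy, cx = np.unravel_index(np.argmax(score), score.shape)
        s = float(score[cy, cx])
        if best is None or s > best[3]:
            best = (int(cx), int(cy), int(r), s)
    return best


def pooled_t_statistic(a, b):
    """Textbook equal-variance two-sample t statistic and two-sided p,
    written out from the pooled-variance formula (the oracle for the
    statistics module)."""
    from scipy.stats import t as tdist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
           / (na + nb - 2))
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    df = na + nb - 2
    p = 2.0 * tdist.sf(abs(t), df)
    return t, p
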