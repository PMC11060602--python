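"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the threshold oracle
scans all histogram candidates exhaustively, the labeling oracle is a plain
BFS flood fill, and the width oracle works on a fine 1D grid with circular
convolution. They are slow and simple on purpose.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def isodata_fixed_points(pixels: np.ndarray, n_bins: int = 256) -> list[float]:
    """Exhaustive scan for intermeans fixed points over all 256 candidates.

    A candidate split "values in bins <= k vs > k" is a fixed point when the
    average g of its two class means falls back into bin k. Returns every
    such g (a histogram may admit more than one); the iterative algorithm
    must land on one of them.
    """
    pix = np.asarray(pixels, dtype=float).ravel()
    vmin, vmax = pix.min(), pix.max()
    hist, edges = np.histogram(pix, bins=n_bins, range=(vmin, vmax))
    centers = 0.5 * (edges[:-1] + edges[1:])
    out = []
    for k in range(n_bins):
        lo, hi = hist[: k + 1], hist[k + 1 :]
        if lo.sum() == 0 or hi.sum() == 0:
            continue
        m_lo = float(np.average(centers[: k + 1], weights=lo))
        m_hi = float(np.average(centers[k + 1 :], weights=hi))
        g = 0.5 * (m_lo + m_hi)
        k_of_g = int(np.clip(np.searchsorted(centers, g, side="right") - 1, 0, n_bins - 1))
        if k_of_g == k:
            out.append(g)
    return out


def flood_fill_label(mask: np.ndarray) -> np.ndarray:
    """8-connected component labeling by BFS flood fill (raster order)."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    nxt = 1
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and labels[r0, c0] == 0:
                q = deque([(r0, c0)])
                labels[r0, c0] = nxt
                while q:
                    r, c = q.popleft()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < h
                                and 0 <= cc < w
                                and mask[rr, cc]
                                and labels[rr, cc] == 0
                            ):
                                labels[rr, cc] = nxt
                                q.append((rr, cc))
                nxt += 1
    return labels


def thresholded_blurred_tophat_width(
    band_width_nm: float,
    period_nm: float,
    sigma_nm: float,
    dx_nm: float = 1.0,
    n_bins: int = 256,
) -> float:
    """Width of one blurred top-hat band after IsoData thresholding (1D).

    Builds one period of a periodic top-hat train on a fine grid, blurs it
    with a circular Gaussian, finds the intermeans threshold by exhaustive
    candidate scan, and measures the distance between the two threshold
    crossings by linear interpolation.
    """
    n = int(round(period_nm / dx_nm))
    x = (np.arange(n) + 0.5) * dx_nm
    c = period_nm / 2.0
    prof = ((x >= c - band_width_nm / 2.0) & (x < c + band_width_nm / 2.0)).astype(float)
    if sigma_nm > 0:
        freqs = np.fft.fftfreq(n, d=dx_nm)
        kernel = np.exp(-2.0 * (np.pi * sigma_nm * freqs) ** 2)
        prof = np.real(np.fft.ifft(np.fft.fft(prof) * kernel))
    candidates = isodata_fixed_points(prof, n_bins=n_bins)
    if not candidates:
        raise RuntimeError("no intermeans fixed point on the profile")
    t = float(np.median(candidates))
    above = prof > t
    idx = np.flatnonzero(np.diff(above.astype(int)))
    if idx.size != 2:
        raise RuntimeError("expected exactly two threshold crossings")

    def crossing(i: int) -> float:
        y0, y1 = prof[i], prof[i + 1]
        return x[i] + (t - y0) / (y1 - y0) * dx_nm

    x_enter, x_exit = crossing(idx[0]), crossing(idx[1])
    return float(x_exit - x_enter)
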