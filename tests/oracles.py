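"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written with explicit loops and direct
DFT sums (no FFT, no shared smoothing code) so it exercises the same
mathematical definitions as the package through a different route.
"""

from __future__ import annotations

import numpy as np


def brute_cwt(x, fs, scales_s, omega0=6.0, pad_factor=4):
    """Direct-summation analytic-Morlet transform: explicit DFT of the
    zero-padded demeaned series, multiplication with the sampled
    positive-frequency Morlet window, explicit inverse sum."""
    x = np.asarray(x, float)
    n = len(x)
    dt = 1.0 / fs
    npad = pad_factor * n
    xp = np.zeros(npad)
    xp[:n] = x - x.mean()
    k = np.arange(npad)
    dft = np.array([np.sum(xp * np.exp(-2j * np.pi * kk * np.arange(npad) / npad))
                    for kk in k])
    # analytic wavelet: strictly positive frequencies (Nyquist bin excluded)
    omega = 2 * np.pi * np.where(k < npad / 2, k, k - npad) / (npad * dt)
    out = np.empty((len(scales_s), n), dtype=complex)
    for i, s in enumerate(scales_s):
        psi = np.zeros(npad)
        pos = omega > 0
        psi[pos] = (np.pi ** -0.25 * np.sqrt(2 * np.pi * s / dt)
                    * np.exp(-0.5 * (s * omega[pos] - omega0) ** 2))
        prod = dft * psi  # psi real, conjugation is a no-op
        for t in range(n):
            out[i, t] = np.sum(prod * np.exp(2j * np.pi * k * t / npad)) / npad
    return out


def brute_smooth(arr, scales_samples, scale_halfwidth):
    """Per-scale Gaussian time smoothing (explicit convolution, kernel
    truncated at +/- 8 sd, unit sum) followed by a boxcar across
    scales."""
    arr = np.asarray(arr)
    n_s, n_t = arr.shape
    sm = np.empty_like(arr)
    for i, ss in enumerate(scales_samples):
        half = int(np.ceil(8 * ss))
        kk = np.arange(-half, half + 1)
        g = np.exp(-0.5 * (kk / ss) ** 2)
        g = g / g.sum()
        row = np.zeros(n_t, dtype=arr.dtype)
        for t in range(n_t):
            lo = max(0, t - half)
            hi = min(n_t - 1, t + half)
            row[t] = np.sum(arr[i, lo:hi + 1] * g[lo - t + half: hi - t + half + 1])
        sm[i] = row
    out = np.empty_like(sm)
    m = scale_halfwidth
    for i in range(n_s):
        lo, hi = max(0, i - m), min(n_s - 1, i + m)
        out[i] = sm[lo:hi + 1].mean(axis=0)
    return out


def brute_wtc(x, y, fs, scales_s, omega0=6.0, scale_halfwidth=3):
    """Brute-force smoothed cross-spectrum coherence ratio."""
    wx = brute_cwt(x, fs, scales_s, omega0)
    wy = brute_cwt(y, fs, scales_s, omega0)
    inv_s = 1.0 / np.asarray(scales_s)[:, None]
    ss_samp = np.asarray(scales_s) * fs
    sxx = brute_smooth(np.abs(wx) ** 2 * inv_s, ss_samp, scale_halfwidth)
    syy = brute_smooth(np.abs(wy) ** 2 * inv_s, ss_samp, scale_halfwidth)
    sxy = brute_smooth(wx * np.conj(wy) * inv_s, ss_samp, scale_halfwidth)
    return np.clip(np.abs(sxy) ** 2 / (sxx * syy), 0.0, 1.0)


def brute_bh(p_values, q):
    """Step-up Benjamini-Hochberg by direct enumeration of the largest
    passing rank."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    kmax = 0
    for rank, i in enumerate(order, start=1):
        if p[i] <= rank * q / m:
            kmax = rank
    reject = [False] * m
    for rank, i in enumerate(order, start=1):
        if rank <= kmax:
            reject[i] = True
    return reject


def brute_mixed_anova(y: np.ndarray, groups: np.ndarray):
    """Textbook sums-of-squares mixed ANOVA for a balanced 2 (between)
    x 2 (within) design.  ``y`` is (n_units, 2) within-level scores.
    Returns dict effect -> (F, df_num, df_den)."""
    levels = sorted(set(groups))
    n_per = [int(np.sum(groups == g)) for g in levels]
    assert n_per[0] == n_per[1], "oracle expects a balanced design"
    n = y.shape[0]
    grand = y.mean()
    subj_mean = y.mean(axis=1)
    group_mean = {g: y[groups == g].mean() for g in levels}
    within_mean = y.mean(axis=0)
    cell_mean = {(g, w): y[groups == g, w].mean()
                 for g in levels for w in (0, 1)}
    ss_between = 2 * sum(n_per[i] * (group_mean[g] - grand) ** 2
                         for i, g in enumerate(levels))
    ss_subj = 2 * np.sum((subj_mean - np.array([group_mean[g] for g in groups])) ** 2)
    ss_within = n * sum((within_mean[w] - grand) ** 2 for w in (0, 1))
    ss_inter = sum(n_per[i] * (cell_mean[(g, w)] - group_mean[g]
                               - within_mean[w] + grand) ** 2
                   for i, g in enumerate(levels) for w in (0, 1))
    ss_total = np.sum((y - grand) ** 2)
    ss_err_w = ss_total - ss_between - ss_subj - ss_within - ss_inter
    df_sub = n - 2
    return {
        "between": (float((ss_between / 1) / (ss_subj / df_sub)), 1, df_sub),
        "within": (float((ss_within / 1) / (ss_err_w / df_sub)), 1, df_sub),
        "interaction": (float((ss_inter / 1) / (ss_err_w / df_sub)), 1, df_sub),
    }
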