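"""Numba inner loops for RF rendering and block matching."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def render_lines(beta_s, r_s, amp_s, order, line_angles, r0, dr, n_samples,
                 sigma_beta, sigma_r, k_carrier):
    """Sum Gaussian-modulated cosine echoes onto a polar RF grid.

    ``beta_s``/``r_s``/``amp_s`` are scatterer beam angles (deg), ranges (mm)
    and effective amplitudes; ``order`` sorts them by angle.  Each beam line
    integrates scatterers within 4 lateral sigmas; each scatterer contributes
    over +-4 axial sigmas of the pulse envelope.
    """
    n_lines = line_angles.shape[0]
    rf = np.zeros((n_lines, n_samples))
    ns = beta_s.shape[0]
    beta_sorted = np.empty(ns)
    for i in range(ns):
        beta_sorted[i] = beta_s[order[i]]
    r_max = r0 + (n_samples - 1) * dr
    for j in range(n_lines):
        bj = line_angles[j]
        lo = np.searchsorted(beta_sorted, bj - 4.0 * sigma_beta)
        hi = np.searchsorted(beta_sorted, bj + 4.0 * sigma_beta)
        for ii in range(lo, hi):
            s = order[ii]
            rs = r_s[s]
            if rs < r0 - 4.0 * sigma_r or rs > r_max + 4.0 * sigma_r:
                continue
            db = beta_s[s] - bj
            w = amp_s[s] * np.exp(-0.5 * (db / sigma_beta) ** 2)
            if w == 0.0:
                continue
            i0 = int(np.ceil((rs - 4.0 * sigma_r - r0) / dr))
            i1 = int(np.floor((rs + 4.0 * sigma_r - r0) / dr))
            if i0 < 0:
                i0 = 0
            if i1 > n_samples - 1:
                i1 = n_samples - 1
            for i in range(i0, i1 + 1):
                x = r0 + i * dr - rs
                rf[j, i] += w * np.exp(-0.5 * (x / sigma_r) ** 2) \
                    * np.cos(k_carrier * x)
    return rf


@njit(cache=True, fastmath=True)
def ncc_maps(img_a, img_b, node_ax, node_lat, prior_ax, prior_lat,
             ka, kl, n_lag_ax, n_lag_lat):
    """Normalized cross-correlation maps for all kernel nodes.

    Images are (lines, samples).  A kernel of ``kl`` lines x ``ka`` samples
    is centred on each node in ``img_a``; it is compared against windows of
    ``img_b`` displaced by the integer prior plus a lag grid of
    ``n_lag_lat x n_lag_ax`` centred on zero.  Returns the NCC maps
    (n_nodes, n_lag_lat, n_lag_ax) and a validity flag per node (False when
    any window leaves the image or the kernel has no variance).
    """
    n_nodes = node_ax.shape[0]
    n_lines, n_samp = img_a.shape
    maps = np.full((n_nodes, n_lag_lat, n_lag_ax), -2.0)
    valid = np.zeros(n_nodes, dtype=np.bool_)
    ha = ka // 2
    hl = kl // 2
    la0 = -(n_lag_ax // 2)
    ll0 = -(n_lag_lat // 2)
    for n in range(n_nodes):
        ax = node_ax[n]
        lt = node_lat[n]
        a0 = ax - ha
        l0 = lt - hl
        if a0 < 0 or a0 + ka > n_samp or l0 < 0 or l0 + kl > n_lines:
            continue
        # window limits in img_b across all lags
        b_ax_min = a0 + prior_ax[n] + la0
        b_ax_max = a0 + prior_ax[n] + la0 + n_lag_ax - 1 + ka
        b_lt_min = l0 + prior_lat[n] + ll0
        b_lt_max = l0 + prior_lat[n] + ll0 + n_lag_lat - 1 + kl
        if b_ax_min < 0 or b_ax_max > n_samp or b_lt_min < 0 or b_lt_max > n_lines:
            continue
        s_a = 0.0
        s_aa = 0.0
        for p in range(kl):
            for q in range(ka):
                v = img_a[l0 + p, a0 + q]
                s_a += v
                s_aa += v * v
        npix = ka * kl
        mean_a = s_a / npix
        var_a = s_aa - s_a * mean_a
        if var_a <= 1e-30:
            continue
        valid[n] = True
        for il in range(n_lag_lat):
            for ia in range(n_lag_ax):
                ob = a0 + prior_ax[n] + la0 + ia
                lb = l0 + prior_lat[n] + ll0 + il
                s_b = 0.0
                s_bb = 0.0
                s_ab = 0.0
                for p in range(kl):
                    for q in range(ka):
                        va = img_a[l0 + p, a0 + q]
                        vb = img_b[lb + p, ob + q]
                        s_b += vb
                        s_bb += vb * vb
                        s_ab += va * vb
                mean_b = s_b / npix
                var_b = s_bb - s_b * mean_b
                if var_b <= 1e-30:
                    maps[n, il, ia] = 0.0
                else:
                    maps[n, il, ia] = (s_ab - npix * mean_a * mean_b) / \
                        np.sqrt(var_a * var_b)
    return maps, valid
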