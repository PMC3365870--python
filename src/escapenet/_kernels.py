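"""Optional numba-accelerated stepping kernel for escape ensembles.

The pure-numpy fallback in :mod:`escapenet.simulate` is used when numba
is unavailable; results are statistically identical (same per-trial
noise streams, same scheme), the kernel only moves the per-step loop
into compiled code and lets a trial retire the moment its escape is
decided instead of at block boundaries.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco


@njit(cache=True)
def step_block(
    zre,
    zim,
    r2,
    crossed,
    cross_time,
    run_len,
    n_crossed,
    trial_done,
    trial_time,
    blown,
    noise,
    use_noise,
    b,
    m_adj,
    indeg,
    mu0,
    beta,
    alpha,
    dt,
    sqdt,
    rot_re,
    rot_im,
    thr,
    k_req,
    sustained,
    t0,
    blowup_r2,
):
    """Advance all not-yet-done trials through ``b`` Euler steps.

    State arrays are (m_trials, n_nodes); ``noise`` is (m_trials, b,
    2 n_nodes).  Crossing times are linearly interpolated in |z|^2; a
    trial is marked done (with its k-th order-statistic crossing time)
    as soon as ``k_req`` nodes have crossed.
    """
    m_trials, n = zre.shape
    new_re = np.empty(n)
    new_im = np.empty(n)
    for i in range(m_trials):
        if trial_done[i]:
            continue
        for s in range(b):
            t_prev = t0 + s * dt
            # pass 1: increments from the *old* state of every node
            for j in range(n):
                # coupling input: node j receives sum_k adj[k, j] z_k
                acc_re = 0.0
                acc_im = 0.0
                for k in range(n):
                    a = m_adj[k, j]
                    if a != 0.0:
                        acc_re += a * zre[i, k]
                        acc_im += a * zim[i, k]
                r2j = r2[i, j]
                gj = mu0 + r2j * (2.0 - r2j)
                dre = gj * zre[i, j] + beta * (acc_re - indeg[j] * zre[i, j])
                dim = gj * zim[i, j] + beta * (acc_im - indeg[j] * zim[i, j])
                xre = zre[i, j] + dre * dt
                xim = zim[i, j] + dim * dt
                if use_noise:
                    xre += alpha * sqdt * noise[i, s, j]
                    xim += alpha * sqdt * noise[i, s, n + j]
                # exact rigid rotation
                new_re[j] = rot_re * xre - rot_im * xim
                new_im[j] = rot_im * xre + rot_re * xim
            # pass 2: commit
            for j in range(n):
                zre[i, j] = new_re[j]
                zim[i, j] = new_im[j]
            # crossing detection (after all nodes stepped)
            for j in range(n):
                r2_new = zre[i, j] * zre[i, j] + zim[i, j] * zim[i, j]
                if r2_new > blowup_r2:
                    blown[i] = True
                    trial_done[i] = True
                    break
                if r2_new >= thr:
                    run_len[i, j] += 1
                else:
                    run_len[i, j] = 0
                if not crossed[i, j]:
                    hit = (
                        r2_new >= thr
                        if sustained == 1
                        else run_len[i, j] >= sustained
                    )
                    if hit:
                        denom = r2_new - r2[i, j]
                        frac = 1.0
                        if denom > 0.0:
                            frac = (thr - r2[i, j]) / denom
                            if frac < 0.0:
                                frac = 0.0
                            elif frac > 1.0:
                                frac = 1.0
                        tc = t_prev + frac * dt
                        if sustained > 1:
                            tc -= (sustained - 1) * dt
                        cross_time[i, j] = tc
                        crossed[i, j] = True
                        n_crossed[i] += 1
                r2[i, j] = r2_new
            if trial_done[i]:
                break
            if n_crossed[i] >= k_req:
                # k-th smallest crossing time: insertion sort of <= n values
                cnt = 0
                for j in range(n):
                    if crossed[i, j]:
                        v = cross_time[i, j]
                        pos = cnt
                        while pos > 0 and cross_time[i, n + pos - 1] > v:
                            cross_time[i, n + pos] = cross_time[i, n + pos - 1]
                            pos -= 1
                        cross_time[i, n + pos] = v
                        cnt += 1
                trial_time[i] = cross_time[i, n + k_req - 1]
                trial_done[i] = True
                break
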