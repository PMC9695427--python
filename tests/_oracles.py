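"""Independent brute-force oracles used to cross-check the package.

Everything here is written from first principles (explicit loops and
textbook formulas) and must stay independent of the implementation
paths it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def bruteforce_mixing_percent(frames, x=0.5, epsilon=10.0, strict=True):
    """Percent-mixed per frame via an explicit per-pixel double loop.

    Threshold: beta = R0 + x * (Rinf - R0) from the literal first and
    last frames; pixels with |Rinf - R0| < epsilon are excluded from the
    denominator; mixed means R > beta (or >= when strict is False).
    """
    frames = [np.asarray(f, dtype=float) for f in frames]
    T = len(frames)
    H, W = frames[0].shape
    r0 = frames[0]
    rinf = frames[-1]
    beta = np.empty((H, W))
    valid = np.empty((H, W), dtype=bool)
    for i in range(H):
        for j in range(W):
            beta[i, j] = r0[i, j] + x * (rinf[i, j] - r0[i, j])
            valid[i, j] = abs(rinf[i, j] - r0[i, j]) >= epsilon
    n_valid = int(valid.sum())
    M = []
    for k in range(T):
        count = 0
        for i in range(H):
            for j in range(W):
                if not valid[i, j]:
                    continue
                r = frames[k][i, j]
                if (r > beta[i, j]) if strict else (r >= beta[i, j]):
                    count += 1
        M.append(100.0 * count / n_valid)
    return np.array(M), n_valid


def anova_oneway_oracle(samples):
    """One-way fixed-effects ANOVA from explicit sums of squares."""
    k = len(samples)
    all_vals = np.concatenate(samples)
    grand = all_vals.mean()
    n_total = len(all_vals)
    ss_between = sum(len(s) * (np.mean(s) - grand) ** 2 for s in samples)
    ss_within = sum(((np.asarray(s) - np.mean(s)) ** 2).sum() for s in samples)
    df1, df2 = k - 1, n_total - k
    if ss_within == 0:
        return (0.0, 1.0, df1, df2) if ss_between == 0 else (np.inf, 0.0, df1, df2)
    F = (ss_between / df1) / (ss_within / df2)
    p = stats.f.sf(F, df1, df2)
    return F, p, df1, df2


def tukey_pairwise_oracle(samples):
    """Tukey-Kramer pairwise p-values from the studentized range.

    q_ij = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)), referred
    to the studentized range distribution with k groups and N-k dof.
    """
    k = len(samples)
    n_total = sum(len(s) for s in samples)
    df2 = n_total - k
    msw = sum(((np.asarray(s) - np.mean(s)) ** 2).sum() for s in samples) / df2
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            ni, nj = len(samples[i]), len(samples[j])
            se = math.sqrt(msw / 2.0 * (1.0 / ni + 1.0 / nj))
            q = abs(np.mean(samples[i]) - np.mean(samples[j])) / se
            out[(i, j)] = float(stats.studentized_range.sf(q, k, df2))
    return out


def pooled_t_oracle(a, b):
    """Classical pooled-variance two-sided Student's t-test."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    dof = na + nb - 2
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / dof
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return t, dof, p


def order_statistic_t90(crossing_times, level=90.0):
    """Continuous-time t90: smallest t with at least level% of pixels
    crossed, i.e. the ceil(level/100 * n)-th smallest crossing time."""
    flat = np.sort(np.asarray(crossing_times, dtype=float).ravel())
    m = math.ceil(level / 100.0 * flat.size)
    return float(flat[m - 1])


def grid_ceil(t, fps):
    """Round a time up to the frame grid k/fps."""
    return math.ceil(t * fps - 1e-9) / fps
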