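"""Independent oracles used to cross-check the package's estimators.

Everything here is deliberately written from first principles (textbook
formulas, brute-force enumeration, generic ODE integration) and never
calls the code paths it validates.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import solve_ivp


def ode_prey_trajectory(days, k, F, C0, mu_c, B0, rtol=1e-10, atol=1e-12):
    """Numerically integrate dB/dt = (k - F*C0*exp(mu_c*t))*B."""

    def rhs(t, y):
        return [(k - F * C0 * math.exp(mu_c * t)) * y[0]]

    sol = solve_ivp(
        rhs, (0.0, max(days)), [B0], t_eval=np.asarray(days, dtype=float),
        rtol=rtol, atol=atol, method="DOP853",
    )
    assert sol.success
    return sol.y[0]


def pooled_t_by_hand(a, b):
    """Textbook pooled-variance two-sample t statistic and df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (
        ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    ) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, na + nb - 2


def enumerate_two_sample_p(x, y):
    """Exact two-sided permutation p-value by full enumeration.

    Counts, over all distinct assignments of the pooled values into groups
    of the original sizes, how often |mean difference| is at least the
    observed |mean difference| (the observed assignment included).
    """
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    n, n0 = len(pooled), len(x)
    obs = abs(np.mean(x) - np.mean(y))
    count = total = 0
    for idx in itertools.combinations(range(n), n0):
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        stat = abs(pooled[sel].mean() - pooled[~sel].mean())
        count += stat >= obs - 1e-12 * max(obs, 1.0)
        total += 1
    return count / total, total


def brute_force_decline_window(days, prey, r2_min=0.90, min_points=3):
    """All-contiguous-runs scan for the longest strictly-decreasing,
    ln-linear (R^2 >= r2_min) prey segment; earlier window wins ties."""
    best, best_len = None, 0
    n = len(days)
    for i in range(n):
        for j in range(i + min_points - 1, n):
            seg = prey[i : j + 1]
            if any(s <= 0 for s in seg):
                continue
            if any(seg[a + 1] >= seg[a] for a in range(len(seg) - 1)):
                continue
            x = np.asarray(days[i : j + 1], float)
            y = np.log(np.asarray(seg, float))
            xm, ym = x.mean(), y.mean()
            ssxy = ((x - xm) * (y - ym)).sum()
            ssxx = ((x - xm) ** 2).sum()
            ssyy = ((y - ym) ** 2).sum()
            r2 = ssxy**2 / (ssxx * ssyy)
            if r2 < r2_min:
                continue
            if j - i + 1 > best_len:
                best_len = j - i + 1
                best = (float(days[i]), float(days[j]))
    return best
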