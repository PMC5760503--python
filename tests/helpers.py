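"""Independent oracles used by the test suite.

Everything here is deliberately written against plain dense linear algebra
(and exhaustive enumeration), not against the package's own computational
paths, so that agreement is evidence of correctness rather than tautology.
"""
from __future__ import annotations

import math

import numpy as np
from scipy import stats

_LOG_2PI = math.log(2.0 * math.pi)


def rq_cov(t1, t2, alpha, ell, s2):
    """Rational quadratic covariance, written independently (plain power form)."""
    d2 = (np.asarray(t1, float)[..., None] - np.asarray(t2, float)[None, ...]) ** 2
    return s2 * (1.0 + d2 / (2.0 * alpha * ell ** 2)) ** (-alpha)


def dense_conditional(times, values, next_time, alpha, ell, s2, sig2):
    """Predictive (mean, var) of y_{next_time} by direct joint-Gaussian
    conditioning on the full (n+1)-dimensional observation covariance."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    n = len(times)
    if n == 0:
        return 0.0, s2 + sig2
    all_t = np.concatenate([times, [float(next_time)]])
    C = rq_cov(all_t, all_t, alpha, ell, s2) + sig2 * np.eye(n + 1)
    S11 = C[n, n]
    S12 = C[n, :n]
    S22 = C[:n, :n]
    sol = np.linalg.solve(S22, values)
    mean = float(S12 @ sol)
    var = float(S11 - S12 @ np.linalg.solve(S22, S12))
    return mean, var


def dense_lml(times, values, alpha, ell, s2, sig2):
    """Log marginal likelihood via scipy's multivariate normal density."""
    times = np.asarray(times, float)
    C = rq_cov(times, times, alpha, ell, s2) + sig2 * np.eye(len(times))
    return float(stats.multivariate_normal(mean=np.zeros(len(times)),
                                           cov=C).logpdf(values))


def _conditional_logpdf_table(values, alpha, ell, s2, sig2):
    """table[(s, t)] = log p(y_t | y_s..y_{t-1}) with unit-spaced times;
    s == t gives the prior predictive."""
    n = len(values)
    table = {}
    for t in range(n):
        for s in range(t + 1):
            seg_t = np.arange(s, t)
            mean, var = dense_conditional(seg_t, values[s:t], t,
                                          alpha, ell, s2, sig2)
            table[(s, t)] = float(stats.norm(mean, math.sqrt(var)).logpdf(values[t]))
    return table


def exhaustive_runlength_posteriors(values, alpha, ell, s2, sig2, hazard):
    """Run-length posteriors p(r_t | y_1:t) for every t by enumerating every
    change/growth path (no message passing, no pruning).

    Starts from the delta state r=0 before the first observation.  Each
    observation is scored under its path's current run (the last r
    observations); a change branch (prob h) resets the run to 0, a growth
    branch (prob 1-h) extends it.  Returns a list of dicts {r: prob}.
    """
    n = len(values)
    table = _conditional_logpdf_table(np.asarray(values, float),
                                      alpha, ell, s2, sig2)
    log_h = math.log(hazard)
    log_1mh = math.log1p(-hazard)
    acc = [dict() for _ in range(n)]

    def add(d, r, logw):
        d[r] = np.logaddexp(d[r], logw) if r in d else logw

    stack = [(0, 0, 0.0)]  # (t, r_prev, log prefix weight)
    while stack:
        t, r_prev, logw = stack.pop()
        if t == n:
            continue
        lp = table[(t - r_prev, t)]  # condition on the last r_prev observations
        add(acc[t], 0, logw + log_h + lp)
        add(acc[t], r_prev + 1, logw + log_1mh + lp)
        stack.append((t + 1, 0, logw + log_h + lp))
        stack.append((t + 1, r_prev + 1, logw + log_1mh + lp))

    out = []
    for t in range(n):
        rs = sorted(acc[t])
        logs = np.array([acc[t][r] for r in rs])
        probs = np.exp(logs - np.logaddexp.reduce(logs))
        out.append(dict(zip(rs, probs)))
    return out
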