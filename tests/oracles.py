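"""Independent brute-force oracles, written symbol-by-symbol from the
estimating formulas and kept deliberately naive (pure-Python loops, no
shared code with the package implementation)."""

import math


def km_oracle(times, events, weights):
    """Product-limit curve by direct enumeration.

    Returns (event_times, survival) lists; at each distinct death time the
    survival multiplies by (1 - weighted deaths / weighted at-risk).
    """
    death_times = sorted({t for t, e in zip(times, events) if e})
    surv = []
    s = 1.0
    for tj in death_times:
        at_risk = sum(w for t, w in zip(times, weights) if t >= tj)
        deaths = sum(
            w for t, e, w in zip(times, events, weights) if e and t == tj
        )
        s = s * (1.0 - deaths / at_risk)
        surv.append(s)
    return death_times, surv


def km_survival_at(death_times, surv, t):
    s = 1.0
    for tj, sj in zip(death_times, surv):
        if tj <= t:
            s = sj
    return s


def rmst_oracle(death_times, surv, L):
    """Area under the step function on (0, L] via interval enumeration."""
    grid = [0.0] + [t for t in death_times if t < L] + [L]
    area = 0.0
    for a, b in zip(grid[:-1], grid[1:]):
        area += km_survival_at(death_times, surv, a) * (b - a)
    return area


def followup_qaly_oracle(times, events, weights, utilities, L):
    """The follow-up QALY sum:
    sum_j Qhat(t_j)[S(t_{j-1}) - S(t_j)] + Qhat(L) S(t_l), t_0=0, S(0)=1.

    Qhat(t_j) is the weighted mean of utility*t_j among deaths at t_j;
    Qhat(L) the weighted mean of utility*L among those alive at the end of
    follow-up (censored records).  The survivor term vanishes with S(t_l).
    """
    death_times, surv = km_oracle(times, events, weights)
    total = 0.0
    s_prev = 1.0
    for tj, sj in zip(death_times, surv):
        num = sum(w * u * tj for t, e, w, u in
                  zip(times, events, weights, utilities) if e and t == tj)
        den = sum(w for t, e, w in zip(times, events, weights) if e and t == tj)
        total += (num / den) * (s_prev - sj)
        s_prev = sj
    s_last = surv[-1] if surv else 1.0
    if s_last > 0:
        alive = [(w, u) for t, e, w, u in
                 zip(times, events, weights, utilities) if (not e) or t > L]
        num = sum(w * u * L for w, u in alive)
        den = sum(w for w, _ in alive)
        total += (num / den) * s_last
    return total


def weibull_sf(t, lam, beta):
    return math.exp(-((t / lam) ** beta))


def weibull_mean_quadrature(lam, beta):
    """Mean survival by adaptive quadrature of S(t) over [0, inf),
    split at the scale for robustness near the origin."""
    from scipy.integrate import quad

    f = lambda t: weibull_sf(t, lam, beta)
    lo = quad(f, 0.0, lam, epsabs=1e-11, epsrel=1e-11, limit=400)[0]
    hi = quad(f, lam, math.inf, epsabs=1e-11, epsrel=1e-11, limit=400)[0]
    return lo + hi


def weibull_loglik(lam, beta, times, events, weights):
    """Weighted right-censored Weibull log-likelihood, written directly."""
    ll = 0.0
    for t, e, w in zip(times, events, weights):
        z = t / lam
        if e:
            ll += w * (math.log(beta / lam) + (beta - 1.0) * math.log(z))
        ll -= w * z**beta
    return ll


def weibull_grid_mle(times, events, weights, lam_grid, beta_grid):
    """Dense grid search over (lam, beta) maximizing the log-likelihood."""
    best = (None, None, -math.inf)
    for lam in lam_grid:
        for beta in beta_grid:
            ll = weibull_loglik(lam, beta, times, events, weights)
            if ll > best[2]:
                best = (lam, beta, ll)
    return best
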