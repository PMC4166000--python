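"""Maximum-likelihood estimation of the supergenome (gene-pool) size.

Two pool-sampling models, both driven by inferred gene-family gains:

* uniform pool: observing P distinct families from K independent uniform
  draws out of a pool of size S has likelihood L = C(S, P) / S**K; S is the
  ML maximizer, with a 95% profile-likelihood confidence interval.
* power-law pool: family i is drawn with probability p_i = A / i**alpha
  (A normalizes the p_i to sum to 1 over i = 1..S). The expected number of
  families drawn exactly m times out of K draws is
  g_m = C(K, m) * sum_i p_i**m (1 - p_i)**(K - m); treating the observed
  multiplicity spectrum O_m as independent Poisson counts gives
  ln L = sum_m (-g_m + O_m ln g_m), maximized over (S, alpha).

A pool that yields no interior maximum below a cap (default 1000x the
pangenome size) is reported as open. Families inferred to be ancestral
(root-presence posterior > 0.5) are excluded from the spectrum and added
back to the final closed estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import gammaln

from .gene_flux_inference import BranchEventPosteriors

__all__ = [
    "GainSpectrum",
    "SupergenomeEstimate",
    "build_spectrum",
    "uniform_ml",
    "powerlaw_ml",
    "finalize_estimate",
    "expected_multiplicity_counts",
]

_CHI2_95_HALF = 1.92  # half the 95% quantile of chi-squared with 1 df


@dataclass
class GainSpectrum:
    """Gain multiplicity spectrum over non-ancestral families.

    O_m counts families whose total gain probability (sum of per-branch gain
    posteriors plus the root-presence posterior) falls in [m - 0.5, m + 0.5).
    Families with total < 0.5 form O_0 and are excluded from the spectrum.
    """

    K: float  # total gains: sum of per-family total gain probabilities
    O: dict[int, int]  # m -> number of families gained exactly m times (m >= 1)
    n_O0: int  # families whose total gain probability fell below 0.5
    A_ancestral: int  # families with root-presence posterior > 0.5

    @property
    def P(self) -> int:
        """Families in the spectrum (distinct discovered, non-ancestral)."""
        return sum(self.O.values())

    @property
    def M(self) -> int:
        """Families gained two or more times."""
        return sum(v for m, v in self.O.items() if m >= 2)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        ms = np.array(sorted(self.O))
        return ms, np.array([self.O[m] for m in ms])


@dataclass
class SupergenomeEstimate:
    model: str  # "uniform" or "power-law"
    S: Optional[float]  # estimated pool size (None when open)
    open: bool
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    alpha: Optional[float] = None
    log_likelihood: Optional[float] = None
    A_ancestral: int = 0
    b: Optional[float] = None  # S / F, supergenome size in genome units

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "S": self.S,
            "open": self.open,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "alpha": self.alpha,
            "A_ancestral": self.A_ancestral,
            "b": self.b,
        }


def build_spectrum(posteriors: BranchEventPosteriors,
                   include_ancestral: bool = False) -> GainSpectrum:
    """Bin per-family total gain probabilities into the multiplicity spectrum.

    Ancestral families (root posterior > 0.5) are counted separately and, by
    default, excluded from the spectrum and from K; their count is added back
    to the closed pool-size estimate by :func:`finalize_estimate`.
    """
    totals = posteriors.total_gain_probability
    ancestral = posteriors.p_root_present > 0.5
    A_anc = int(ancestral.sum())
    use = totals if include_ancestral else totals[~ancestral]
    m = np.floor(use + 0.5).astype(int)  # [m - 0.5, m + 0.5) half-open bins
    O: dict[int, int] = {}
    for val in m[m >= 1]:
        O[int(val)] = O.get(int(val), 0) + 1
    return GainSpectrum(K=float(use.sum()), O=O, n_O0=int((m == 0).sum()), A_ancestral=A_anc)


# -- uniform model ---------------------------------------------------------


def _uniform_loglik(S: np.ndarray, P: float, K: float) -> np.ndarray:
    """ln L = ln Gamma(S+1) - ln Gamma(S-P+1) - K ln S (constant ln P! dropped)."""
    S = np.asarray(S, dtype=float)
    with np.errstate(invalid="ignore"):
        return gammaln(S + 1.0) - gammaln(S - P + 1.0) - K * np.log(S)


def uniform_ml(P: int, K: float, s_cap_factor: float = 1e3) -> SupergenomeEstimate:
    """Maximize the uniform-pool likelihood over real S >= P.

    Returns the estimate rounded half-up to an integer with a 95%
    profile-likelihood interval, or an open call when the likelihood keeps
    increasing up to S_cap = s_cap_factor * P (or is within 0.5 log units of
    its supremum there).
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    if K < P:
        raise ValueError(f"K={K} < P={P}: impossible under the pool-sampling model")
    s_cap = s_cap_factor * P
    if K == P:
        return SupergenomeEstimate(model="uniform", S=None, open=True)

    neg = lambda logS: -float(_uniform_loglik(np.exp(logS), P, K))
    res = minimize_scalar(neg, bounds=(np.log(P), np.log(s_cap)), method="bounded",
                          options={"xatol": 1e-10})
    s_hat = float(np.exp(res.x))
    ll_hat = -res.fun
    ll_cap = float(_uniform_loglik(s_cap, P, K))
    if s_hat >= s_cap * 0.999 or ll_cap >= ll_hat - 0.5:
        return SupergenomeEstimate(model="uniform", S=None, open=True, log_likelihood=ll_hat)

    drop = ll_hat - _CHI2_95_HALF
    f = lambda S: float(_uniform_loglik(S, P, K)) - drop
    ci_low = brentq(f, P, s_hat) if f(P) < 0 else float(P)
    hi = s_hat
    step = max(s_hat, 10.0)
    while f(hi + step) > 0 and hi + step < s_cap * 10:
        hi += step
    ci_high = brentq(f, s_hat, hi + step) if f(hi + step) < 0 else float(hi + step)
    # integer report: the better of floor/ceil under the (unimodal) likelihood
    lo_i, hi_i = np.floor(s_hat), np.ceil(s_hat)
    lo_i = max(lo_i, float(P))
    s_int = float(lo_i if _uniform_loglik(lo_i, P, K) >= _uniform_loglik(hi_i, P, K) else hi_i)
    return SupergenomeEstimate(
        model="uniform", S=s_int, open=False,
        ci_low=float(ci_low), ci_high=float(ci_high), log_likelihood=ll_hat,
    )


# -- power-law model -------------------------------------------------------


def _pool_probs(S: int, alpha: float) -> np.ndarray:
    i = np.arange(1, S + 1, dtype=float)
    w = i ** (-alpha)
    return w / w.sum()


_HEAD = 2048  # pool members evaluated individually; the tail is binned
_TAIL_BINS = 256


def _binned_pool(S: int, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """(p_values, multiplicities) so that sum_i f(p_i) ~= sum_k w_k f(p_k).

    The first _HEAD members are kept exactly; beyond that, members are
    grouped into log-spaced rank bins represented by their mean probability
    (the tail p_i vary by ~2% within a bin, so the grouping error is far
    below the estimators' tolerances while keeping evaluation cost O(1) in S).
    """
    p = _pool_probs(S, alpha)
    if S <= _HEAD + _TAIL_BINS:
        return p, np.ones(S)
    edges = np.unique(np.round(np.exp(np.linspace(np.log(_HEAD), np.log(S), _TAIL_BINS + 1)))).astype(int)
    csum = np.concatenate([[0.0], np.cumsum(p)])
    counts = np.diff(edges).astype(float)
    p_bins = (csum[edges[1:]] - csum[edges[:-1]]) / counts
    return (np.concatenate([p[:_HEAD], p_bins]),
            np.concatenate([np.ones(_HEAD), counts]))


def expected_multiplicity_counts(S: int, alpha: float, K: float,
                                 ms: np.ndarray) -> np.ndarray:
    """g_m = C(K, m) sum_i p_i^m (1 - p_i)^(K - m) for each requested m.

    K may be non-integer (sums of gain probabilities); the binomial
    coefficient uses the Gamma-function generalization, in log space. Every
    summand is a binomial pmf value (<= 1), so the sum is exponentiated
    directly without further stabilization.
    """
    p, wts = _binned_pool(int(S), alpha)
    ms = np.asarray(ms, dtype=float)
    log_binom = gammaln(K + 1.0) - gammaln(ms + 1.0) - gammaln(K - ms + 1.0)
    with np.errstate(divide="ignore"):
        logp = np.log(p)
        log1m = np.log1p(-p)
    terms = log_binom[:, None] + ms[:, None] * logp[None, :] + (K - ms)[:, None] * log1m[None, :]
    return np.exp(terms) @ wts


def _powerlaw_loglik(S: int, alpha: float, spectrum: GainSpectrum) -> float:
    """ln L = sum_{m>=1} (-g_m + O_m ln g_m).

    The full sum of -g_m over m = 1..K equals -(S - g_0); only observed m
    need explicit g_m evaluation.
    """
    ms, Os = spectrum.to_arrays()
    K = spectrum.K
    p, wts = _binned_pool(int(S), alpha)
    with np.errstate(divide="ignore"):
        g0 = float(np.exp(K * np.log1p(-p)) @ wts)
    g_obs = expected_multiplicity_counts(S, alpha, K, ms)
    if np.any((g_obs <= 0) & (Os > 0)):
        return -np.inf
    ok = Os > 0
    return float(-(S - g0) + (Os[ok] * np.log(g_obs[ok])).sum())


def _golden(fun, lo: float, hi: float, tol: float = 1e-4, max_iter: int = 200) -> float:
    """Golden-section maximization of fun on [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fun(c), fun(d)
    it = 0
    while abs(b - a) > tol and it < max_iter:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fun(d)
        it += 1
    return (a + b) / 2.0


def powerlaw_ml(spectrum: GainSpectrum, s_cap_factor: float = 1e3,
                alpha_max: float = 3.0, alpha_step: float = 0.05,
                n_s_grid: int = 15) -> SupergenomeEstimate:
    """Maximize the Poisson spectrum likelihood over (S, alpha).

    Hierarchical grid search — a coarse alpha pass over the full (alpha on
    [0, alpha_max], S log-spaced from P to S_cap) box, then an alpha_step
    pass around the coarse optimum — followed by alternating golden-section
    refinement of each coordinate.
    """
    P = spectrum.P
    if P < 1:
        raise ValueError("empty spectrum")
    if spectrum.K < 1:
        raise ValueError("K must be >= 1")
    s_cap = max(s_cap_factor * P, P + 1)
    if spectrum.M == 0:
        # no repeated gains: likelihood increases in S without bound
        return SupergenomeEstimate(model="power-law", S=None, open=True)

    def s_grid(lo: float, hi: float) -> np.ndarray:
        return np.unique(np.round(np.exp(np.linspace(np.log(lo), np.log(hi), n_s_grid))).astype(int))

    def sweep(alphas: np.ndarray, s_values: np.ndarray) -> tuple[float, int, float]:
        top = (-np.inf, int(s_values[0]), float(alphas[0]))
        for a in alphas:
            for s in s_values:
                ll = _powerlaw_loglik(int(s), float(a), spectrum)
                if ll > top[0]:
                    top = (ll, int(s), float(a))
        return top

    ll_b, s_b, a_b = sweep(np.arange(0.0, alpha_max + 1e-9, 0.25), s_grid(P, s_cap))
    fine_alphas = np.arange(max(0.0, a_b - 0.25), min(alpha_max, a_b + 0.25) + 1e-9, alpha_step)
    ll_b, s_b, a_b = sweep(fine_alphas,
                           s_grid(max(P, s_b / 4), min(s_cap, s_b * 4)))

    for _ in range(3):  # alternating 1-D golden refinement
        logS = _golden(lambda x: _powerlaw_loglik(int(round(np.exp(x))), a_b, spectrum),
                       max(np.log(P), np.log(s_b) - 1.0), min(np.log(s_cap), np.log(s_b) + 1.0),
                       tol=1e-5)
        s_b = int(round(np.exp(logS)))
        a_b = _golden(lambda a: _powerlaw_loglik(s_b, a, spectrum),
                      max(0.0, a_b - 0.2), min(alpha_max, a_b + 0.2), tol=1e-5)
    ll_b = _powerlaw_loglik(s_b, a_b, spectrum)

    ll_cap = max(_powerlaw_loglik(int(s_cap), a, spectrum)
                 for a in np.arange(0.0, alpha_max + 1e-9, 0.5))
    if s_b >= 0.999 * s_cap or ll_cap >= ll_b - 0.5:
        return SupergenomeEstimate(model="power-law", S=None, open=True,
                                   alpha=a_b, log_likelihood=ll_b)
    return SupergenomeEstimate(model="power-law", S=float(s_b), open=False,
                               alpha=float(a_b), log_likelihood=ll_b)


def finalize_estimate(raw: SupergenomeEstimate, A_ancestral: int, F: float) -> SupergenomeEstimate:
    """Add the ancestral-family count to a closed estimate and express it in
    genome units b = S / F. Open estimates pass through unchanged."""
    if F <= 0:
        raise ValueError("F must be positive")
    if raw.open:
        return SupergenomeEstimate(model=raw.model, S=None, open=True, alpha=raw.alpha,
                                   log_likelihood=raw.log_likelihood, A_ancestral=A_ancestral)
    S_final = raw.S + A_ancestral
    return SupergenomeEstimate(
        model=raw.model,
        S=S_final,
        open=False,
        ci_low=None if raw.ci_low is None else raw.ci_low + A_ancestral,
        ci_high=None if raw.ci_high is None else raw.ci_high + A_ancestral,
        alpha=raw.alpha,
        log_likelihood=raw.log_likelihood,
        A_ancestral=A_ancestral,
        b=S_final / F,
    )
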