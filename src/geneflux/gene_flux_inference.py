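"""Gain-loss-duplication birth-and-death inference on a rooted species tree.

The copy number n of a gene family evolves as a continuous-time Markov chain
that decreases at rate n*mu and increases at rate kappa + n*lambda, truncated
at n_max. Global (kappa, lambda, mu) are fitted by maximum likelihood over
all families using the pruning algorithm, conditioned on each family being
observed in at least one genome. An inside-outside pass then yields, per
family and branch, posterior probabilities of the four genome-dynamics event
types (gain, loss, expansion, reduction) defined as endpoint-state
transitions, plus the posterior probability of presence at the root.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import gamma as gamma_dist

from .phyletic import PhyleticMatrix
from .trees import RootedTree

__all__ = [
    "BDIModel",
    "FitSettings",
    "BranchEventPosteriors",
    "EventTotals",
    "transition_matrix",
    "stationary_distribution",
    "fit_model",
    "posterior_events",
    "count_events",
]

_RATE_LO = 1e-8
_RATE_HI = 1e8


@dataclass
class BDIModel:
    """Birth-death-immigration parameters on the truncated state space {0..n_max}.

    kappa: family gain intensity per unit branch length; lam: per-copy
    duplication intensity; mu: per-copy loss intensity. With n_categories=2 a
    discrete-gamma rate multiplier (shape ``gamma_shape``) scales all three
    intensities; the multipliers are the means of the two equal-probability
    gamma quantile bins and average to 1.
    """

    kappa: float
    lam: float
    mu: float
    n_max: int
    n_categories: int = 1
    gamma_shape: float = 1.0
    root_prior: str = "stationary"  # or "uniform"
    log_likelihood: Optional[float] = None

    def __post_init__(self) -> None:
        if min(self.kappa, self.lam, self.mu) < 0:
            raise ValueError("rates must be non-negative")
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        if self.n_categories not in (1, 2):
            raise ValueError("n_categories must be 1 or 2")

    def category_multipliers(self) -> tuple[np.ndarray, np.ndarray]:
        """(multipliers, weights); multipliers average to 1."""
        if self.n_categories == 1:
            return np.array([1.0]), np.array([1.0])
        a = self.gamma_shape
        # means of the two equal-probability bins of Gamma(a, scale=1/a)
        med = gamma_dist.ppf(0.5, a, scale=1.0 / a)
        lower = gamma_dist.expect(lambda x: x, args=(a,), scale=1.0 / a, ub=med) * 2.0
        mult = np.array([lower, 2.0 - lower])
        return mult, np.array([0.5, 0.5])


@dataclass
class FitSettings:
    n_max: Optional[int] = None  # default: max observed count + 5
    n_categories: int = 1
    root_prior: str = "stationary"
    n_starts: int = 5
    fatol: float = 1e-6
    max_iter: int = 2000


def _generator(kappa: float, lam: float, mu: float, n_max: int) -> np.ndarray:
    n = np.arange(n_max + 1)
    Q = np.zeros((n_max + 1, n_max + 1))
    up = kappa + n[:-1] * lam
    down = n[1:] * mu
    Q[n[:-1], n[:-1] + 1] = up
    Q[n[1:], n[1:] - 1] = down
    Q[n, n] = -Q.sum(axis=1)
    return Q


def transition_matrix(model: BDIModel, t: float, multiplier: float = 1.0) -> np.ndarray:
    """exp(Q*t) on {0..n_max}, renormalized row-stochastic after truncation."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if t == 0.0:
        return np.eye(model.n_max + 1)
    Q = _generator(model.kappa * multiplier, model.lam * multiplier, model.mu * multiplier, model.n_max)
    P = expm(Q * t)
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    return P


def stationary_distribution(model: BDIModel) -> np.ndarray:
    """Stationary law of the truncated chain (detailed balance), or uniform fallback.

    pi_{n+1}/pi_n = (kappa + n*lambda) / ((n+1)*mu); undefined when mu == 0.
    """
    if model.root_prior == "uniform" or model.mu <= 0:
        return np.full(model.n_max + 1, 1.0 / (model.n_max + 1))
    log_pi = np.zeros(model.n_max + 1)
    for n in range(model.n_max):
        ratio = (model.kappa + n * model.lam) / ((n + 1) * model.mu)
        log_pi[n + 1] = log_pi[n] + (np.log(ratio) if ratio > 0 else -np.inf)
    log_pi -= log_pi.max()
    pi = np.exp(log_pi)
    return pi / pi.sum()


# -- pruning likelihood ----------------------------------------------------


def _edge_matrices(model: BDIModel, tree: RootedTree, multiplier: float) -> dict[int, np.ndarray]:
    cache: dict[float, np.ndarray] = {}
    out: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.parent is None:
            continue
        t = node.length
        if t not in cache:
            cache[t] = transition_matrix(model, t, multiplier)
        out[id(node)] = cache[t]
    return out


def _inside_pass(model: BDIModel, tree: RootedTree, leaf_counts: dict[str, np.ndarray],
                 n_fam: int, multiplier: float,
                 keep: bool = False):
    """Scaled inside (pruning) vectors for all families at once.

    Returns (log_lik per family, and if keep: dict node -> L, dict node -> message M,
    edge matrices). L[node][f, s] is the scaled conditional likelihood of data
    below `node` given state s; messages M are child->parent sums T @ L.
    """
    S = model.n_max + 1
    T = _edge_matrices(model, tree, multiplier)
    L: dict[int, np.ndarray] = {}
    M: dict[int, np.ndarray] = {}
    log_scale = np.zeros(n_fam)
    for node in tree.postorder():
        if node.is_leaf:
            counts = leaf_counts[node.name]
            vec = np.zeros((n_fam, S))
            vec[np.arange(n_fam), counts] = 1.0
        else:
            vec = np.ones((n_fam, S))
            for child in node.children:
                msg = L[id(child)] @ T[id(child)].T  # (f, i) = sum_j T[i,j] L_c[f,j]
                M[id(child)] = msg
                vec = vec * msg
                if not keep:
                    del L[id(child)]
            top = vec.max(axis=1)
            top = np.where(top > 0, top, 1.0)
            vec = vec / top[:, None]
            log_scale += np.log(top)
        L[id(node)] = vec
    prior = stationary_distribution(model)
    lik = L[id(tree.root)] @ prior
    with np.errstate(divide="ignore"):
        loglik = np.log(lik) + log_scale
    if keep:
        return loglik, L, M, T, prior
    return loglik


def _leaf_count_arrays(matrix: PhyleticMatrix, tree: RootedTree, n_max: int) -> dict[str, np.ndarray]:
    if matrix.counts.max() > n_max:
        raise ValueError(
            f"observed copy number {int(matrix.counts.max())} exceeds n_max={n_max}; raise n_max"
        )
    col = {g: j for j, g in enumerate(matrix.genome_ids)}
    return {leaf: matrix.counts[:, col[leaf]] for leaf in tree.leaf_labels()}


def log_likelihood(model: BDIModel, matrix: PhyleticMatrix, tree: RootedTree) -> float:
    """Ascertainment-corrected log-likelihood: families are conditioned on
    being present in at least one leaf (observed matrices exclude families
    that never survived anywhere)."""
    matrix.check_against_tree(tree)
    leaf_counts = _leaf_count_arrays(matrix, tree, model.n_max)
    zero_counts = {leaf: np.zeros(1, dtype=int) for leaf in tree.leaf_labels()}
    mult, wts = model.category_multipliers()
    n_fam = matrix.n_families
    per_cat = np.stack([_inside_pass(model, tree, leaf_counts, n_fam, m) for m in mult])
    per_cat_absent = np.stack([_inside_pass(model, tree, zero_counts, 1, m) for m in mult])
    logw = np.log(wts)[:, None]
    fam_ll = _logsumexp0(per_cat + logw)
    p_absent = float(np.exp(_logsumexp0(per_cat_absent + logw))[0])
    p_absent = min(p_absent, 1.0 - 1e-300)
    total = float(fam_ll.sum() - n_fam * np.log1p(-p_absent))
    if not np.isfinite(total):
        bad = int(np.flatnonzero(~np.isfinite(fam_ll))[0]) if not np.all(np.isfinite(fam_ll)) else -1
        fam = matrix.family_ids[bad] if bad >= 0 else "<conditioning term>"
        raise FloatingPointError(f"non-finite likelihood (family {fam})")
    return total


def _logsumexp0(a: np.ndarray) -> np.ndarray:
    top = a.max(axis=0)
    top = np.where(np.isfinite(top), top, 0.0)
    return top + np.log(np.exp(a - top).sum(axis=0))


def fit_model(matrix: PhyleticMatrix, tree: RootedTree,
              settings: Optional[FitSettings] = None) -> BDIModel:
    """Maximum-likelihood (kappa, lambda, mu) by Nelder-Mead over log-rates.

    Five fixed multi-starts around a moment-based initial guess; rates are
    clamped to [1e-8, 1e8]; convergence when the log-likelihood improves by
    less than ``fatol``.
    """
    settings = settings or FitSettings()
    if matrix.n_families == 0:
        raise ValueError("empty matrix")
    n_max = settings.n_max if settings.n_max is not None else int(matrix.counts.max()) + 5
    fit_shape = settings.n_categories == 2

    # moment-based anchor: mu0 from typical per-family turnover over the tree span
    from .trees import mean_root_to_leaf_depth

    depth = max(mean_root_to_leaf_depth(tree), 1e-12)
    presence_frac = matrix.presence.mean()
    mu0 = 1.0 / depth
    kappa0 = max(presence_frac, 0.05) * mu0
    lam0 = 0.3 * mu0
    anchors = [
        (kappa0, lam0, mu0),
        (kappa0 * 10, lam0, mu0 * 0.1),
        (kappa0 * 0.1, lam0, mu0 * 10),
        (kappa0, lam0 * 0.1, mu0),
        (kappa0, lam0 * 10, mu0),
    ][: settings.n_starts]

    def unpack(x: np.ndarray) -> BDIModel:
        rates = np.clip(np.exp(x[:3]), _RATE_LO, _RATE_HI)
        shape = float(np.clip(np.exp(x[3]), 0.05, 50.0)) if fit_shape else 1.0
        return BDIModel(*rates, n_max=n_max, n_categories=settings.n_categories,
                        gamma_shape=shape, root_prior=settings.root_prior)

    def nll(x: np.ndarray) -> float:
        try:
            return -log_likelihood(unpack(x), matrix, tree)
        except FloatingPointError:
            return 1e12

    best = None
    for kappa, lam, mu in anchors:
        x0 = np.log([kappa, lam, mu] + ([1.0] if fit_shape else []))
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"fatol": settings.fatol, "xatol": 1e-5,
                                "maxiter": settings.max_iter, "maxfev": settings.max_iter})
        if best is None or res.fun < best.fun:
            best = res
    model = unpack(best.x)
    model.log_likelihood = -float(best.fun)
    return model


# -- event posteriors ------------------------------------------------------


@dataclass
class BranchEventPosteriors:
    """Per family x branch posterior probabilities of the four event types.

    Branches are identified by post-order edge index (see
    :meth:`RootedTree.edges`). ``presence_counts`` records, per family, the
    number of genomes with copy number >= 1 (used for singleton handling).
    """

    family_ids: list[str]
    branch_lengths: np.ndarray  # (n_edges,)
    is_terminal: np.ndarray  # (n_edges,) bool
    p_gain: np.ndarray  # (n_fam, n_edges)
    p_loss: np.ndarray
    p_expansion: np.ndarray
    p_reduction: np.ndarray
    p_root_present: np.ndarray  # (n_fam,)
    presence_counts: np.ndarray  # (n_fam,)
    categories: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        for arr in (self.p_gain, self.p_loss, self.p_expansion, self.p_reduction):
            if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
                raise ValueError("posterior probabilities must lie in [0, 1]")
        if ((self.p_gain + self.p_loss) > 1 + 1e-6).any():
            raise ValueError("p_gain + p_loss exceeds 1 on some branch")

    @property
    def total_gain_probability(self) -> np.ndarray:
        """Per family: sum of gain posteriors over branches plus root presence."""
        return self.p_gain.sum(axis=1) + self.p_root_present

    def to_frame(self):
        import pandas as pd

        n_fam, n_edges = self.p_gain.shape
        recs = {
            "family_id": np.repeat(self.family_ids, n_edges),
            "branch": np.tile(np.arange(n_edges), n_fam),
            "p_gain": self.p_gain.ravel(),
            "p_loss": self.p_loss.ravel(),
            "p_expansion": self.p_expansion.ravel(),
            "p_reduction": self.p_reduction.ravel(),
        }
        return pd.DataFrame(recs)


@dataclass
class EventTotals:
    """Expected event counts per branch (sums of posteriors over families)."""

    branch_lengths: np.ndarray
    is_terminal: np.ndarray
    gains: np.ndarray
    losses: np.ndarray
    expansions: np.ndarray
    reductions: np.ndarray
    gains_excl_singletons: np.ndarray  # gains minus terminal-branch gains of 1-genome families
    per_family_gain: np.ndarray
    p_root_present: np.ndarray

    @property
    def totals(self) -> dict[str, float]:
        return {
            "gain": float(self.gains.sum()),
            "loss": float(self.losses.sum()),
            "expansion": float(self.expansions.sum()),
            "reduction": float(self.reductions.sum()),
        }


def posterior_events(model: BDIModel, matrix: PhyleticMatrix, tree: RootedTree) -> BranchEventPosteriors:
    """Inside-outside pass yielding per-branch joint-state event posteriors.

    On each branch the four events are endpoint-state transitions:
    gain parent=0 -> child>=1; loss parent>=1 -> child=0; expansion
    child > parent >= 1; reduction parent > child >= 1.
    """
    matrix.check_against_tree(tree)
    leaf_counts = _leaf_count_arrays(matrix, tree, model.n_max)
    n_fam = matrix.n_families
    S = model.n_max + 1
    edges = tree.edges()
    edge_index = {id(node): k for k, node in enumerate(edges)}
    mult, wts = model.category_multipliers()

    masks = _event_masks(S)
    p_gain = np.zeros((n_fam, len(edges)))
    p_loss = np.zeros_like(p_gain)
    p_exp = np.zeros_like(p_gain)
    p_red = np.zeros_like(p_gain)
    p_root = np.zeros(n_fam)

    # category posterior weights
    cat_ll = np.stack([
        _inside_pass(model, tree, leaf_counts, n_fam, m) for m in mult
    ])
    cat_logpost = cat_ll + np.log(wts)[:, None]
    cat_logpost -= _logsumexp0(cat_logpost)
    cat_weight = np.exp(cat_logpost)

    for ci, m in enumerate(mult):
        w = cat_weight[ci]
        _, L, M, T, prior = _inside_pass(model, tree, leaf_counts, n_fam, m, keep=True)
        U: dict[int, np.ndarray] = {id(tree.root): np.broadcast_to(prior, (n_fam, S)).copy()}
        for node in tree.preorder():
            u_here = U[id(node)]
            for child in node.children:
                u_excl = u_here.copy()
                for other in node.children:
                    if other is not child:
                        u_excl = u_excl * M[id(other)]
                Tc = T[id(child)]
                A = np.einsum("fi,ij,fj->fij", u_excl, Tc, L[id(child)])
                tot = A.sum(axis=(1, 2))
                tot = np.where(tot > 0, tot, 1.0)
                A /= tot[:, None, None]
                k = edge_index[id(child)]
                p_gain[:, k] += w * (A * masks["gain"]).sum(axis=(1, 2))
                p_loss[:, k] += w * (A * masks["loss"]).sum(axis=(1, 2))
                p_exp[:, k] += w * (A * masks["expansion"]).sum(axis=(1, 2))
                p_red[:, k] += w * (A * masks["reduction"]).sum(axis=(1, 2))
                # outside vector for the child: U_c[f, j] = sum_i u_excl[f, i] T[i, j];
                # rescaled per family (constants cancel in the per-edge normalization)
                u_child = u_excl @ Tc
                top = u_child.max(axis=1)
                U[id(child)] = u_child / np.where(top > 0, top, 1.0)[:, None]
        root_post = U[id(tree.root)] * L[id(tree.root)]
        root_tot = root_post.sum(axis=1)
        root_tot = np.where(root_tot > 0, root_tot, 1.0)
        p_root += w * (1.0 - root_post[:, 0] / root_tot)

    return BranchEventPosteriors(
        family_ids=list(matrix.family_ids),
        branch_lengths=np.array([e.length for e in edges]),
        is_terminal=np.array([e.is_leaf for e in edges]),
        p_gain=np.clip(p_gain, 0.0, 1.0),
        p_loss=np.clip(p_loss, 0.0, 1.0),
        p_expansion=np.clip(p_exp, 0.0, 1.0),
        p_reduction=np.clip(p_red, 0.0, 1.0),
        p_root_present=np.clip(p_root, 0.0, 1.0),
        presence_counts=matrix.presence.sum(axis=1),
        categories=matrix.categories,
    )


def _event_masks(S: int) -> dict[str, np.ndarray]:
    i = np.arange(S)[:, None]
    j = np.arange(S)[None, :]
    return {
        "gain": (i == 0) & (j >= 1),
        "loss": (i >= 1) & (j == 0),
        "expansion": (i >= 1) & (j > i),
        "reduction": (i > j) & (j >= 1),
    }


def count_events(posteriors: BranchEventPosteriors) -> EventTotals:
    """Per-branch and total expected event counts (sums of posteriors)."""
    singleton = posteriors.presence_counts == 1
    gains = posteriors.p_gain.sum(axis=0)
    excl = gains - (posteriors.p_gain[singleton, :] * posteriors.is_terminal[None, :]).sum(axis=0)
    return EventTotals(
        branch_lengths=posteriors.branch_lengths,
        is_terminal=posteriors.is_terminal,
        gains=gains,
        losses=posteriors.p_loss.sum(axis=0),
        expansions=posteriors.p_expansion.sum(axis=0),
        reductions=posteriors.p_reduction.sum(axis=0),
        gains_excl_singletons=excl,
        per_family_gain=posteriors.p_gain.sum(axis=1),
        p_root_present=posteriors.p_root_present,
    )
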