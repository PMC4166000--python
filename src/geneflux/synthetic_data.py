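"""Forward simulation of gene-family content on a species tree.

Generates inputs in exactly the formats the pipeline consumes (Newick,
copy-number TSV) together with a complete ground-truth event ledger. Gains
draw a family identity from a finite pool of size S with uniform or
power-law probabilities; each copy duplicates at rate lambda and dies at
rate mu. Simulation is exact (Gillespie event-by-event, per family, which is
valid because the pool-draw process thinned by family identity makes
families independent); it therefore doubles as a stochastic oracle for the
transition-matrix code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .phyletic import PhyleticMatrix
from .trees import RootedTree, TreeNode

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "generate_tree",
    "simulate_evolution",
    "scenario_presets",
    "PRESETS",
]


@dataclass
class SimulationConfig:
    n_leaves: int
    depth: float  # target mean root-to-leaf distance, substitutions/site
    S_true: int  # pool size
    pool: str = "uniform"  # or "power-law"
    alpha_true: float = 0.0
    kappa: float = 0.0  # total pool-draw intensity per unit branch length
    lam: float = 0.0  # per-copy duplication intensity
    mu: float = 0.0  # per-copy loss intensity
    root_families: int = 0
    root_copy_dist: str = "stationary"  # per-family stationary law given presence, or "one"
    mean_gene_length_nt: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.kappa, self.lam, self.mu) < 0:
            raise ValueError("rates must be non-negative")
        if self.S_true < self.root_families:
            raise ValueError("S_true must be >= root_families")
        if self.pool not in ("uniform", "power-law"):
            raise ValueError("pool must be 'uniform' or 'power-law'")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SimulationTruth:
    """Ground-truth event ledger, indexed by post-order edge id."""

    gains: np.ndarray
    losses: np.ndarray
    expansions: np.ndarray
    reductions: np.ndarray
    multiplicity: dict[int, int]  # pool index -> number of true gain events
    ancestral: set[int]  # pool indices present at the root
    node_presence: dict[str, int]  # node key -> number of families present
    S_true: int
    alpha_true: float
    config: Optional[SimulationConfig] = None

    @property
    def total_gains(self) -> int:
        return int(self.gains.sum())

    def totals(self) -> dict[str, int]:
        return {
            "gain": int(self.gains.sum()),
            "loss": int(self.losses.sum()),
            "expansion": int(self.expansions.sum()),
            "reduction": int(self.reductions.sum()),
        }


def generate_tree(n_leaves: int, depth: float, seed: int) -> RootedTree:
    """Random Yule (pure-birth) topology, ultrametric, with branch lengths
    rescaled so the mean root-to-leaf distance equals ``depth`` exactly."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    first = [TreeNode(length=0.0), TreeNode(length=0.0)]
    for c in first:
        root.add_child(c)
    active = list(first)
    while len(active) < n_leaves:
        wait = rng.exponential(1.0 / len(active))
        for node in active:
            node.length += wait
        k = int(rng.integers(len(active)))
        parent = active.pop(k)
        kids = [TreeNode(length=0.0), TreeNode(length=0.0)]
        for c in kids:
            parent.add_child(c)
        active.extend(kids)
    tail = rng.exponential(1.0 / n_leaves)
    for node in active:
        node.length += tail
    for i, node in enumerate(active):
        node.name = f"G{i:03d}"
    tree = RootedTree(root)
    from .trees import mean_root_to_leaf_depth

    scale = depth / mean_root_to_leaf_depth(tree)
    for node in tree.postorder():
        if node.parent is not None:
            node.length *= scale
    return tree


def _pool_probs(S: int, pool: str, alpha: float) -> Optional[np.ndarray]:
    """Explicit p_i for power-law pools; None signals exact uniform."""
    if pool == "uniform":
        return None
    i = np.arange(1, S + 1, dtype=float)
    w = i ** (-alpha)
    return w / w.sum()


def _stationary_copies_given_present(rng: np.random.Generator, g: float, lam: float,
                                     mu: float, n_cap: int = 60) -> int:
    """Sample n >= 1 from the stationary law of the per-family process.

    pi_{n+1}/pi_n = (g + n*lam)/((n+1)*mu); requires mu > 0 (and lam < mu for
    an honest stationary law; the truncation at n_cap regularizes otherwise).
    """
    log_pi = np.zeros(n_cap + 1)
    for n in range(n_cap):
        log_pi[n + 1] = log_pi[n] + np.log((g + n * lam) / ((n + 1) * mu))
    log_pi -= log_pi.max()
    pi = np.exp(log_pi)
    pi[0] = 0.0
    pi /= pi.sum()
    return int(rng.choice(n_cap + 1, p=pi))


def _evolve_family(rng: np.random.Generator, n0: int, t: float, g: float,
                   lam: float, mu: float, t_start: float = 0.0) -> tuple[int, list[int]]:
    """Exact Gillespie for one family on one branch from time t_start.

    g is the family's own pool-draw rate (a draw is a gain when absent, an
    expansion when present). Returns (final copy number, [gain, loss,
    expansion, reduction] event counts).
    """
    t_cur, n = t_start, n0
    ev = [0, 0, 0, 0]
    while True:
        rate = g + n * (lam + mu)
        if rate <= 0.0:
            break
        t_cur += rng.exponential(1.0 / rate)
        if t_cur >= t:
            break
        u = rng.random() * rate
        if u < g:
            ev[0 if n == 0 else 2] += 1
            n += 1
        elif u < g + n * lam:
            ev[2] += 1
            n += 1
        else:
            n -= 1
            ev[1 if n == 0 else 3] += 1
    return n, ev


def simulate_evolution(tree: RootedTree, config: SimulationConfig
                       ) -> tuple[PhyleticMatrix, SimulationTruth]:
    """Simulate gene content along every branch; returns the observed matrix
    (families present in at least one leaf) and the full truth ledger."""
    rng = np.random.default_rng(config.seed)
    S = config.S_true
    probs = _pool_probs(S, config.pool, config.alpha_true)
    total_len = tree.total_length()
    expected = config.kappa * total_len + config.root_families * (config.lam + config.mu) * total_len
    if expected > 1e8:
        raise ValueError(
            f"expected ~{expected:.2e} events; reduce kappa/lam/mu, tree length or pool size"
        )

    # root content: distinct families weighted by pool probabilities
    if config.root_families:
        anc = rng.choice(S, size=config.root_families, replace=False, p=probs)
    else:
        anc = np.array([], dtype=int)
    if config.root_copy_dist == "one" or config.mu <= 0:
        root_state = {int(i): 1 for i in anc}
    else:
        root_state = {
            int(i): _stationary_copies_given_present(
                rng, config.kappa * (1.0 / S if probs is None else float(probs[i])),
                config.lam, config.mu)
            for i in anc
        }

    edges = tree.edges()
    edge_index = {id(node): k for k, node in enumerate(edges)}
    n_edges = len(edges)
    gains = np.zeros(n_edges, dtype=np.int64)
    losses = np.zeros(n_edges, dtype=np.int64)
    exps = np.zeros(n_edges, dtype=np.int64)
    reds = np.zeros(n_edges, dtype=np.int64)
    multiplicity: dict[int, int] = {}
    node_presence: dict[str, int] = {}
    leaf_states: dict[str, dict[int, int]] = {}

    def node_key(node: TreeNode) -> str:
        return node.name if node.is_leaf else f"node{edge_index.get(id(node), -1)}"

    def p_of(i: int) -> float:
        return 1.0 / S if probs is None else float(probs[i])

    def branch(state: dict[int, int], t: float, k: int) -> dict[int, int]:
        new_state: dict[int, int] = {}
        ev_tot = [0, 0, 0, 0]
        # families already present simulate their full per-family process
        for fam, n0 in state.items():
            n_end, ev = _evolve_family(rng, n0, t, config.kappa * p_of(fam), config.lam, config.mu)
            if n_end > 0:
                new_state[fam] = n_end
            for a in range(4):
                ev_tot[a] += ev[a]
            if ev[0]:
                multiplicity[fam] = multiplicity.get(fam, 0) + ev[0]
        # absent families: pick those with at least one pool draw on the branch,
        # then simulate from the (truncated-exponential) first draw time
        present = set(state)
        hit: list[int] = []
        if probs is None:
            n_absent = S - len(present)
            q = -math.expm1(-config.kappa * t / S)
            n_hit = rng.binomial(n_absent, q) if n_absent > 0 else 0
            while len(hit) < n_hit:
                cand = int(rng.integers(S))
                if cand not in present and cand not in hit:
                    hit.append(cand)
        else:
            q = -np.expm1(-config.kappa * probs * t)
            draws = rng.random(S) < q
            hit = [int(i) for i in np.flatnonzero(draws) if int(i) not in present]
        for fam in hit:
            g = config.kappa * p_of(fam)
            u = rng.random()
            tau = -math.log1p(-u * -math.expm1(-g * t)) / g  # first draw | >= 1 draw
            ev0 = [1, 0, 0, 0]
            multiplicity[fam] = multiplicity.get(fam, 0) + 1
            n_end, ev = _evolve_family(rng, 1, t, g, config.lam, config.mu, t_start=tau)
            if n_end > 0:
                new_state[fam] = n_end
            for a in range(4):
                ev_tot[a] += ev0[a] + ev[a]
            if ev[0]:
                multiplicity[fam] = multiplicity.get(fam, 0) + ev[0]
        gains[k] += ev_tot[0]
        losses[k] += ev_tot[1]
        exps[k] += ev_tot[2]
        reds[k] += ev_tot[3]
        return new_state

    # preorder propagation
    states: dict[int, dict[int, int]] = {id(tree.root): root_state}
    node_presence[node_key(tree.root)] = len(root_state)
    for node in tree.preorder():
        st = states[id(node)]
        for child in node.children:
            child_state = branch(st, child.length, edge_index[id(child)])
            states[id(child)] = child_state
            node_presence[node_key(child)] = len(child_state)
            if child.is_leaf:
                leaf_states[child.name] = child_state
        del states[id(node)]

    observed = sorted(set().union(*leaf_states.values()) if leaf_states else set())
    leaves = tree.leaf_labels()
    counts = np.zeros((len(observed), len(leaves)), dtype=np.int64)
    for j, leaf in enumerate(leaves):
        st = leaf_states[leaf]
        for i, fam in enumerate(observed):
            counts[i, j] = st.get(fam, 0)
    fam_ids = [f"F{fam:06d}" for fam in observed]
    matrix = PhyleticMatrix(fam_ids, leaves, counts)
    truth = SimulationTruth(
        gains=gains, losses=losses, expansions=exps, reductions=reds,
        multiplicity=multiplicity, ancestral={int(i) for i in anc},
        node_presence=node_presence, S_true=S, alpha_true=config.alpha_true,
        config=config,
    )
    return matrix, truth


# -- presets ---------------------------------------------------------------

PRESETS: dict[str, dict] = {
    # small parasite-like group: ~900 families per genome, tight closed pool
    "chlamydia-like": dict(
        n_leaves=12, depth=0.005, S_true=1300, pool="uniform", alpha_true=0.0,
        kappa=6000.0, lam=4.0, mu=8.0, root_families=900,
        mean_gene_length_nt=1000.0,
    ),
    # large free-living-like group: big genome, pool ~9 genome equivalents
    "enterobacteria-like": dict(
        n_leaves=20, depth=0.008, S_true=37800, pool="uniform", alpha_true=0.0,
        kappa=40000.0, lam=3.0, mu=10.0, root_families=4200,
        mean_gene_length_nt=1050.0,
    ),
    # effectively unbounded pool: repeated gains essentially never happen
    "open-like": dict(
        n_leaves=15, depth=0.01, S_true=5_000_000, pool="uniform", alpha_true=0.0,
        kappa=20000.0, lam=3.0, mu=10.0, root_families=1500,
        mean_gene_length_nt=1000.0,
    ),
}


def scenario_presets(name: str, seed: int = 0) -> SimulationConfig:
    """A fully specified configuration for a documented regime."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return SimulationConfig(seed=seed, **PRESETS[name])
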