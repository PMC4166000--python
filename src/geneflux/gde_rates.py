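"""Event totals -> per-substitution rates, flux, balance, and diagnostics.

Rates are reported both per nucleotide substitution per site (total expected
events divided by total tree length) and per substitution per gene (the
per-site rate divided by the mean CDS length in nucleotides, which is a
required metadata input and never hard-coded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .comparative_stats import spearman_perm
from .gene_flux_inference import BranchEventPosteriors, EventTotals
from .trees import RootedTree, branch_midpoint_depth

__all__ = [
    "GDERateTable",
    "compute_rate_table",
    "genomic_clock",
    "depth_dependence",
    "category_flux",
]

EVENT_TYPES = ("gain", "loss", "expansion", "reduction")


@dataclass
class GDERateTable:
    rate_site: dict[str, float]  # events per nucleotide substitution per site
    rate_gene: dict[str, float]  # events per nucleotide substitution per gene
    flux_site: float
    balance: float  # (gain + expansion) / (loss + reduction); NaN if denominator 0
    mean_gene_length_nt: float
    total_tree_length: float
    dnds: Optional[float] = None

    def as_row(self) -> dict[str, float]:
        row = {}
        for ev in EVENT_TYPES:
            row[f"{ev}_site"] = self.rate_site[ev]
            row[f"{ev}_gene"] = self.rate_gene[ev]
        row["flux_site"] = self.flux_site
        row["balance"] = self.balance
        return row


def compute_rate_table(totals: EventTotals, tree: RootedTree, mean_gene_length_nt: float,
                       dnds: Optional[float] = None) -> GDERateTable:
    if mean_gene_length_nt <= 0:
        raise ValueError("mean_gene_length_nt must be positive")
    tree_length = tree.total_length()
    if tree_length <= 0:
        raise ValueError("total tree length must be positive")
    tot = totals.totals
    rate_site = {ev: tot[ev] / tree_length for ev in EVENT_TYPES}
    rate_gene = {ev: rate_site[ev] / mean_gene_length_nt for ev in EVENT_TYPES}
    denom = rate_site["loss"] + rate_site["reduction"]
    if denom > 0:
        balance = (rate_site["gain"] + rate_site["expansion"]) / denom
    else:
        warnings.warn("no loss or reduction events; balance undefined (NaN)")
        balance = float("nan")
    return GDERateTable(
        rate_site=rate_site,
        rate_gene=rate_gene,
        flux_site=sum(rate_site.values()),
        balance=balance,
        mean_gene_length_nt=mean_gene_length_nt,
        total_tree_length=tree_length,
        dnds=dnds,
    )


@dataclass
class ClockResult:
    slope: float  # log-log regression slope of event count on branch length
    intercept: float
    rho: float
    p_value: float
    n_branches: int


def genomic_clock(totals: EventTotals, tree: RootedTree,
                  exclude_terminal_singleton_gains: bool = True,
                  n_perm: int = 100_000, seed: int = 0) -> dict[str, ClockResult]:
    """Per event type: log-log regression + Spearman/permutation test of
    branch event counts against branch lengths.

    With the exclusion flag set, gain counts on terminal branches drop the
    contribution of families present in exactly one genome (singletons).
    """
    lengths = totals.branch_lengths
    if lengths.size < 3:
        raise ValueError("need at least 3 branches")
    per_type = {
        "gain": totals.gains_excl_singletons if exclude_terminal_singleton_gains else totals.gains,
        "loss": totals.losses,
        "expansion": totals.expansions,
        "reduction": totals.reductions,
    }
    out = {}
    for ev, counts in per_type.items():
        ok = (lengths > 0) & (counts > 0)
        if ok.sum() >= 3:
            slope, intercept = np.polyfit(np.log(lengths[ok]), np.log(counts[ok]), 1)
        else:
            slope = intercept = float("nan")
        rho, p = spearman_perm(lengths, counts, n_perm=n_perm, seed=seed)
        out[ev] = ClockResult(slope=float(slope), intercept=float(intercept),
                              rho=rho, p_value=p, n_branches=int(lengths.size))
    return out


@dataclass
class DepthFit:
    slope: float
    intercept: float  # of log(rate) on log(depth)
    reference_depth: float = 1e-4

    def normalized_percent(self, depth: float) -> float:
        """Fitted rate at `depth` as a percentage of the fitted rate at the
        reference depth (100% at 1e-4 substitutions per site)."""
        if depth <= 0:
            raise ValueError("depth must be positive")
        return 100.0 * (depth / self.reference_depth) ** self.slope


def depth_dependence(per_branch_rates: np.ndarray, depths: np.ndarray) -> DepthFit:
    """Log-log least-squares fit of per-branch rates against branch-midpoint depths."""
    rates = np.asarray(per_branch_rates, dtype=float)
    depths = np.asarray(depths, dtype=float)
    if (depths <= 0).any():
        raise ValueError("depths must be positive")
    ok = rates > 0
    if ok.sum() < 2:
        raise ValueError("need at least 2 branches with positive rates")
    slope, intercept = np.polyfit(np.log(depths[ok]), np.log(rates[ok]), 1)
    return DepthFit(slope=float(slope), intercept=float(intercept))


def branch_depths(tree: RootedTree) -> np.ndarray:
    """Branch-midpoint depths for every edge, in post-order edge-id order."""
    return np.array([branch_midpoint_depth(tree, k) for k in range(len(tree.edges()))])


def category_flux(posteriors: BranchEventPosteriors, categories: dict[str, str],
                  tree: RootedTree, genes_per_category: Optional[dict[str, float]] = None
                  ) -> dict[str, dict[str, float]]:
    """Per-COG-category event rates per gene of that category.

    Families without a mapping are pooled under the label ``"unknown"``.
    Categories with zero families are omitted with a warning. Events are
    normalized by total tree length and by the number of families of the
    category (or by ``genes_per_category`` when supplied).
    """
    tree_length = tree.total_length()
    fam_cat = np.array([categories.get(f, "unknown") for f in posteriors.family_ids])
    requested = set(categories.values()) | set(fam_cat)
    sums = {
        "gain": posteriors.p_gain.sum(axis=1),
        "loss": posteriors.p_loss.sum(axis=1),
        "expansion": posteriors.p_expansion.sum(axis=1),
        "reduction": posteriors.p_reduction.sum(axis=1),
    }
    out: dict[str, dict[str, float]] = {}
    for cat in sorted(requested):
        mask = fam_cat == cat
        n_in_cat = genes_per_category.get(cat) if genes_per_category else float(mask.sum())
        if not mask.any() or not n_in_cat:
            warnings.warn(f"category {cat!r} has no families; omitted")
            continue
        row = {ev: float(sums[ev][mask].sum()) / tree_length / n_in_cat for ev in EVENT_TYPES}
        row["flux"] = sum(row[ev] for ev in EVENT_TYPES)
        out[cat] = row
    return out
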