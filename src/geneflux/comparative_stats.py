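"""Cross-dataset statistics: Spearman/permutation tests, PCA of log rates,
bootstrap of medians, contingency chi-squared, group comparisons, and the
synteny shuffling-rate regression."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "spearman_perm",
    "pca_rates",
    "bootstrap_median",
    "chi2_open_lifestyle",
    "group_compare",
    "shuffling_rate",
    "SyntenyPair",
]

LIFESTYLES = ("free-living", "facultative host-associated", "obligate parasite")


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=-1)


def spearman_perm(x: Sequence[float], y: Sequence[float], n_perm: int = 100_000,
                  seed: int = 0) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with a permutation P value.

    P = (1 + #{|rho_perm| >= |rho_obs|}) / (n_perm + 1); deterministic for a
    fixed seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho undefined for a constant vector")
    rx = _rank(x)
    ry = _rank(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    rho = float(np.mean(rx * ry))

    rng = np.random.default_rng(seed)
    n = x.size
    # permute in chunks to bound memory at ~n_perm x n doubles
    exceed = 0
    chunk = max(1, min(n_perm, 20_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        perms = rng.permuted(np.broadcast_to(ry, (k, n)).copy(), axis=1)
        rho_perm = (rx[None, :] * perms).mean(axis=1)
        exceed += int((np.abs(rho_perm) >= abs(rho) - 1e-12).sum())
        done += k
    p = (1 + exceed) / (n_perm + 1)
    return rho, float(p)


@dataclass
class PCAResult:
    variance_percent: np.ndarray  # descending, sums to 100
    loadings: np.ndarray  # columns = components, rows = variables
    variables: list[str]


def pca_rates(rates: pd.DataFrame, matrix: str = "correlation",
              flip_pc1_positive: bool = True) -> PCAResult:
    """PCA of log10-transformed per-site event rates.

    ``matrix`` selects the correlation (default) or covariance matrix of the
    log rates. The PC1 sign is flipped, if needed, so that all loadings on
    the first component are positive (the overall-flux axis).
    """
    if len(rates) < 3:
        raise ValueError("need at least 3 rows")
    X = rates.to_numpy(dtype=float)
    if (X <= 0).any():
        raise ValueError("rates must be positive for the log transform")
    X = np.log10(X)
    Xc = X - X.mean(axis=0)
    if matrix == "correlation":
        Xc = Xc / Xc.std(axis=0, ddof=1)
    elif matrix != "covariance":
        raise ValueError("matrix must be 'correlation' or 'covariance'")
    C = np.cov(Xc.T, ddof=1)
    w, v = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    v = v[:, order]
    if flip_pc1_positive and (v[:, 0] <= 0).all():
        v[:, 0] = -v[:, 0]
    elif flip_pc1_positive and v[:, 0].sum() < 0:
        v[:, 0] = -v[:, 0]
    return PCAResult(
        variance_percent=100.0 * w / w.sum(),
        loadings=v,
        variables=list(rates.columns),
    )


def bootstrap_median(values: Sequence[float], n_boot: int = 1000, seed: int = 0) -> np.ndarray:
    """Medians of n_boot with-replacement resamples; deterministic given seed."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    return np.median(values[idx], axis=1)


def chi2_open_lifestyle(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Pearson chi-squared for a 2x2 table, df = 1, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.all(t == np.floor(t)):
        raise ValueError("expected a 2x2 table of non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


def group_compare(panel: pd.DataFrame, grouping: str,
                  rate_columns: Optional[Sequence[str]] = None,
                  min_group: int = 3) -> pd.DataFrame:
    """Two-sided Mann-Whitney U for every group pair and rate column.

    Groups with fewer than ``min_group`` members are skipped with a warning.
    Returns a tidy frame (rate, group_a, group_b, U, p_value, n_a, n_b).
    """
    if rate_columns is None:
        rate_columns = [c for c in panel.columns if c != grouping and
                        pd.api.types.is_numeric_dtype(panel[c])]
    groups = {}
    for name, sub in panel.groupby(grouping):
        if len(sub) < min_group:
            warnings.warn(f"group {name!r} has fewer than {min_group} members; skipped")
            continue
        groups[name] = sub
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups of sufficient size")
    rows = []
    for col in rate_columns:
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a = groups[names[i]][col].to_numpy(dtype=float)
                b = groups[names[j]][col].to_numpy(dtype=float)
                u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                rows.append({"rate": col, "group_a": names[i], "group_b": names[j],
                             "U": float(u), "p_value": float(p),
                             "n_a": len(a), "n_b": len(b)})
    return pd.DataFrame(rows)


@dataclass
class SyntenyPair:
    """A genome pair's synteny distance dY = 1 - F_s and nucleotide distance."""

    dY: float
    d_nuc: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.dY <= 1.0):
            raise ValueError("dY must lie in [0, 1]")


def shuffling_rate(pairs: Sequence[SyntenyPair], at_distance: float = 0.01
                   ) -> tuple[float, float, float]:
    """Log-log regression of synteny distance on nucleotide distance.

    Returns (rate at ``at_distance``, slope, intercept); pairs with
    non-positive dY or d_nuc are excluded with a warning.
    """
    dY = np.array([p.dY for p in pairs], dtype=float)
    d = np.array([p.d_nuc for p in pairs], dtype=float)
    ok = (dY > 0) & (d > 0)
    if (~ok).any():
        warnings.warn(f"excluded {int((~ok).sum())} pairs with non-positive values")
    if ok.sum() < 3:
        raise ValueError("need at least 3 usable pairs")
    slope, intercept = np.polyfit(np.log(d[ok]), np.log(dY[ok]), 1)
    rate = float(np.exp(intercept + slope * np.log(at_distance)))
    return rate, float(slope), float(intercept)
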