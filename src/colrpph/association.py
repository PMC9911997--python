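"""Spearman rank correlation between platelet count and FXIII activity.

Midranks are used for ties; rho is the Pearson correlation of the rank
vectors.  The default p-value is the classical t approximation
``t = rho * sqrt((n-2)/(1-rho^2))`` on ``n-2`` degrees of freedom; a
seeded permutation p-value is available as a verification route.
Missing values are removed pairwise, and the pair count actually used is
reported alongside the coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["AssociationResult", "spearman"]


@dataclass
class AssociationResult:
    rho: float
    n: int
    p_value: float
    method: str
    n_permutations: int | None = None
    seed: int | None = None


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def spearman(
    x,
    y,
    method: str = "asymptotic",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> AssociationResult:
    """Spearman rank correlation with midranks for ties.

    Parameters
    ----------
    x, y : array-like
        Paired measurements; pairs with a missing value in either vector
        are dropped.  At least 3 complete pairs are required.
    method : {"asymptotic", "permutation"}
        Two-sided p-value route: the t approximation on n-2 df, or a
        seeded permutation test shuffling ``y``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rank correlation is undefined")

    rx = stats.rankdata(x)  # midranks
    ry = stats.rankdata(y)
    rho = _rank_corr(rx, ry)

    if method == "asymptotic":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
        return AssociationResult(rho=rho, n=n, p_value=float(p), method="asymptotic")
    if method == "permutation":
        rng = np.random.default_rng(seed)
        hits = 0
        ry_perm = ry.copy()
        for _ in range(n_permutations):
            rng.shuffle(ry_perm)
            if abs(_rank_corr(rx, ry_perm)) >= abs(rho) - 1e-12:
                hits += 1
        p = (1 + hits) / (1 + n_permutations)
        return AssociationResult(
            rho=rho, n=n, p_value=float(p), method="permutation",
            n_permutations=n_permutations, seed=seed,
        )
    raise ValueError(f"unknown method {method!r}")
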