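"""Spearman rank correlation of markers and model scores with endpoints.

Ties take midranks; p-values come from the t-approximation except for
small tie-free vectors (n <= 9), where the permutation distribution is
enumerated exactly.  Missing endpoint values are handled by
pairwise-complete deletion; no multiplicity correction is applied
across the correlation matrix.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .core import DataError

__all__ = ["spearman", "correlate_panel"]

_EXACT_N_MAX = 9


def _exact_p(rho: float, n: int) -> float:
    """Two-sided p by full enumeration of rank permutations (tie-free)."""
    base = np.arange(n, dtype=float)
    perms = np.array(list(permutations(range(n))), dtype=float)
    d2 = ((perms - base) ** 2).sum(axis=1)
    rhos = 1.0 - 6.0 * d2 / (n * (n**2 - 1))
    extreme = np.abs(rhos) >= abs(rho) - 1e-12
    return float(extreme.mean())


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho and two-sided p-value.

    Exact enumeration for n <= 9 without ties, otherwise the
    t-approximation with midranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DataError("x and y must have equal length")
    if x.size < 3:
        raise DataError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise DataError("rho undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    tie_free = np.unique(x).size == x.size and np.unique(y).size == y.size
    if tie_free:
        # exact closed form on integer ranks (avoids float round-off at +-1)
        d2 = float(((rx - ry) ** 2).sum())
        n = x.size
        rho = 1.0 - 6.0 * d2 / (n * (n**2 - 1))
    else:
        rho = float(np.corrcoef(rx, ry)[0, 1])
    if tie_free and x.size <= _EXACT_N_MAX:
        return rho, _exact_p(rho, x.size)
    n = x.size
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))


def correlate_panel(
    variables: pd.DataFrame, endpoints: pd.DataFrame, *, min_pairs: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlation matrix of every variable against every endpoint.

    ``variables``: samples x (marker intensities and/or model scores);
    ``endpoints``: samples x endpoint columns.  Rows are aligned on the
    shared sample index with pairwise-complete deletion per cell.
    Returns (rho, p) DataFrames shaped variables x endpoints.
    """
    shared = variables.index.intersection(endpoints.index)
    if len(shared) < min_pairs:
        raise DataError("fewer than 3 shared samples between variables and endpoints")
    v = variables.loc[shared]
    e = endpoints.loc[shared]
    rho = pd.DataFrame(index=v.columns, columns=e.columns, dtype=float)
    pval = pd.DataFrame(index=v.columns, columns=e.columns, dtype=float)
    for vc in v.columns:
        for ec in e.columns:
            pair = pd.concat([v[vc], e[ec]], axis=1).dropna()
            if len(pair) < min_pairs:
                continue
            try:
                r, p = spearman(pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy())
            except DataError:
                continue  # constant column after deletion
            rho.loc[vc, ec] = r
            pval.loc[vc, ec] = p
    return rho, pval
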