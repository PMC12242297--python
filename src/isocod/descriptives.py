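"""Exploratory statistics for amino-acid isotope tables.

Pairwise Pearson correlations (with two-sided t-test p-values and
pairwise-complete deletion) and a correlation-matrix PCA of the AA
delta-15N values. These are the descriptive views used to separate
trophic from source amino acids before any time-series modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["correlation_matrix", "correlation_square", "pca", "PCAResult"]


def correlation_matrix(records: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Pairwise Pearson correlations with significance tests.

    Returns a tidy table with one row per unordered variable pair:
    ``var1, var2, r, p, n, note``. Pairs are evaluated on pairwise-complete
    observations; a pair needs at least 3 complete observations, and a
    constant variable yields an undefined r reported as missing with the
    reason in ``note``.
    """
    missing = [v for v in variables if v not in records.columns]
    if missing:
        raise KeyError(f"variables not in table: {missing}")
    rows = []
    for a, b in combinations(variables, 2):
        sub = records[[a, b]].dropna()
        n = len(sub)
        r = p = np.nan
        note = ""
        if n < 3:
            note = f"only {n} complete pairs"
        elif sub[a].nunique() == 1 or sub[b].nunique() == 1:
            const = a if sub[a].nunique() == 1 else b
            note = f"{const} is constant; r undefined"
        else:
            res = stats.pearsonr(sub[a], sub[b])
            r, p = float(res.statistic), float(res.pvalue)
        rows.append({"var1": a, "var2": b, "r": r, "p": p, "n": n, "note": note})
    return pd.DataFrame(rows)


def correlation_square(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy correlation table into a symmetric square matrix."""
    names = sorted(set(table["var1"]) | set(table["var2"]))
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for _, row in table.iterrows():
        mat.loc[row["var1"], row["var2"]] = row["r"]
        mat.loc[row["var2"], row["var1"]] = row["r"]
    return mat


@dataclass
class PCAResult:
    """Loadings and explained-variance fractions of a correlation-matrix PCA."""

    loadings: pd.DataFrame  # variables x components
    variance_fraction: np.ndarray
    n_used: int
    n_dropped: int

    def scores(self, records: pd.DataFrame) -> pd.DataFrame:
        """Project (standardized) records onto the components."""
        X = records[self.loadings.index].dropna()
        Z = (X - X.mean()) / X.std(ddof=1)
        return pd.DataFrame(
            Z.to_numpy() @ self.loadings.to_numpy(),
            index=X.index,
            columns=self.loadings.columns,
        )


def pca(records: pd.DataFrame, variables: list[str] | None = None) -> PCAResult:
    """PCA of the correlation matrix of the AA delta-15N values.

    Rows with any missing value among ``variables`` are dropped (and
    logged). Working on the correlation matrix (centred and scaled data)
    keeps amino acids with larger variance from dominating the loadings.
    The sign of each component is fixed so its largest-magnitude loading
    is positive.
    """
    if variables is None:
        variables = list(records.columns)
    if len(variables) < 2:
        raise ValueError("PCA needs at least 2 variables")
    X = records[variables].dropna()
    n_dropped = len(records) - len(X)
    if n_dropped:
        logger.info("pca: dropped %d rows with missing values", n_dropped)
    if len(X) < 3:
        raise ValueError(f"PCA needs at least 3 complete rows, got {len(X)}")
    sd = X.std(ddof=1)
    if (sd == 0).any():
        raise ValueError(f"constant variables: {list(sd.index[sd == 0])}")
    corr = np.corrcoef((X - X.mean()) / sd, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    comps = [f"PC{j + 1}" for j in range(len(variables))]
    return PCAResult(
        loadings=pd.DataFrame(eigvec, index=variables, columns=comps),
        variance_fraction=eigval / eigval.sum(),
        n_used=len(X),
        n_dropped=n_dropped,
    )
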