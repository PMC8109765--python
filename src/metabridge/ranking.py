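"""Path-counting connectedness ranking on the bipartite correlation network.

The significant cross-fluid correlations |A| (n blood x n CSF) are embedded
in the symmetric 2n x 2n block matrix

    M = [[0, |A|], [|A|^T, 0]],

whose k-th power accumulates the strength of all length-k paths alternating
between fluids.  Summing the whole geometric series with a damping factor
alpha = 1/(0.01 + ||M||_F), which guarantees convergence because the
Frobenius norm bounds the spectral radius, gives the resolvent

    T' = M (I - alpha M)^{-1} = sum_{k>=1} alpha^{k-1} M^k.

Each metabolite's connectedness score is its column sum of T' — a Katz-style
measure of how strongly it correlates with the opposite fluid directly and
through intermediaries.  The first n columns score the blood metabolites,
the last n the CSF metabolites; only the ordering of scores is meaningful,
not their absolute scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BlockMatrix",
    "ConnectednessRanking",
    "build_block_matrix",
    "connectedness_scores",
    "truncated_series_oracle",
    "ranking_table",
    "rank_and_diff",
]

ALPHA_OFFSET = 0.01  # damping margin in alpha = 1/(offset + ||M||_F)


@dataclass
class BlockMatrix:
    """Symmetric bipartite block matrix with its damping factor."""

    M: np.ndarray  # 2n x 2n, [[0, |A|], [|A|^T, 0]]
    n: int
    alpha_scale: float
    frobenius_norm: float
    degenerate: bool = False  # True when A was all zero

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape != (2 * self.n, 2 * self.n):
            raise ValueError("M must be 2n x 2n")
        if self.alpha_scale * self.frobenius_norm >= 1.0:
            raise ValueError("alpha * ||M||_F must be < 1 for the series to converge")


@dataclass
class ConnectednessRanking:
    """Per-fluid connectedness scores (column sums of T')."""

    scores_blood: np.ndarray
    scores_csf: np.ndarray
    blood_names: list[str] | None = None
    csf_names: list[str] | None = None


def build_block_matrix(A: np.ndarray | pd.DataFrame) -> BlockMatrix:
    """Assemble M = [[0, |A|], [|A|^T, 0]] and its damping factor.

    ``A`` is the significance-masked adjacency (blood rows, CSF columns);
    only magnitudes enter, since connectedness measures the ability of one
    metabolite to track another regardless of correlation sign.  An all-zero
    A is valid but flagged degenerate (alpha = 1/0.01 = 100).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be a square matrix (shared metabolites)")
    if not np.all(np.isfinite(A)):
        raise ValueError("A contains non-finite entries")
    n = A.shape[0]
    absA = np.abs(A)
    M = np.zeros((2 * n, 2 * n))
    M[:n, n:] = absA
    M[n:, :n] = absA.T
    fro = float(np.linalg.norm(M))
    alpha = 1.0 / (ALPHA_OFFSET + fro)
    degenerate = fro == 0.0
    if degenerate:
        warnings.warn("all-zero adjacency: connectedness scores will all be zero", stacklevel=2)
    return BlockMatrix(M=M, n=n, alpha_scale=alpha, frobenius_norm=fro, degenerate=degenerate)


def connectedness_scores(B: BlockMatrix) -> ConnectednessRanking:
    """Column sums of T' = M (I - alpha M)^{-1}, split into blood and CSF scores.

    The resolvent is evaluated by an LU solve, never an explicit inverse.
    Because M is symmetric, column sums equal row sums and the score vector
    solves (I - alpha M) s = M 1.  Rows/columns of M that are entirely zero
    are excluded from the solve and scored exactly 0 (the resolvent preserves
    the zero support, and dropping zero rows/columns changes neither the
    Frobenius norm nor the remaining scores), so a metabolite with no
    significant cross-fluid correlation scores exactly zero.
    """
    M, alpha = B.M, B.alpha_scale
    m = M.shape[0]
    scores = np.zeros(m)
    active = np.flatnonzero(M.any(axis=0))
    if active.size:
        Ma = M[np.ix_(active, active)]
        radius = float(np.max(np.abs(np.linalg.eigvalsh(Ma))))
        if alpha * radius >= 1.0:  # cannot happen: ||M||_F bounds the radius
            raise ValueError("spectral radius of alpha*M is >= 1; series diverges")
        rhs = Ma.sum(axis=1)  # M 1 restricted to the active support
        scores[active] = np.linalg.solve(np.eye(active.size) - alpha * Ma, rhs)
    n = B.n
    return ConnectednessRanking(scores_blood=scores[:n].copy(), scores_csf=scores[n:].copy())


def truncated_series_oracle(B: BlockMatrix, K: int) -> np.ndarray:
    """Column sums of sum_{k=1..K} alpha^{k-1} M^k, the finite path-count sum.

    Converges to the resolvent scores as K grows; used as an independent
    cross-check of :func:`connectedness_scores`.  Returns the full 2n score
    vector (blood first).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    M, alpha = B.M, B.alpha_scale
    ones = np.ones(M.shape[0])
    damped = alpha * M
    term = ones @ M  # alpha^{k-1} * column sums of M^k; decays since alpha||M|| < 1
    total = term.copy()
    for _ in range(2, K + 1):
        term = term @ damped
        total += term
    return total


def ranking_table(
    scores: np.ndarray, names: list[str], fluid: str | None = None
) -> pd.DataFrame:
    """Scores sorted descending; ties broken by metabolite name; 1-based rank."""
    df = pd.DataFrame({"metabolite": names, "score": np.asarray(scores, dtype=float)})
    if fluid is not None:
        df.insert(1, "fluid", fluid)
    df = df.sort_values(["score", "metabolite"], ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def rank_and_diff(
    scores_group1: pd.Series | dict[str, float],
    scores_group2: pd.Series | dict[str, float],
    labels: tuple[str, str] = ("group1", "group2"),
) -> pd.DataFrame:
    """Per-metabolite score comparison between two groups.

    Both inputs map metabolite name -> score over the same name set.  The
    difference column is group2 - group1 (e.g. APP - WT when called with
    (WT, APP)).  Rows are sorted by descending absolute difference, ties by
    name.
    """
    s1 = pd.Series(scores_group1, dtype=float)
    s2 = pd.Series(scores_group2, dtype=float)
    if set(s1.index) != set(s2.index):
        raise ValueError("metabolite name lists differ between groups")
    s2 = s2.reindex(s1.index)
    l1, l2 = labels
    df = pd.DataFrame(
        {
            "metabolite": s1.index,
            f"score_{l1}": s1.to_numpy(),
            f"score_{l2}": s2.to_numpy(),
        }
    )
    df["difference"] = df[f"score_{l2}"] - df[f"score_{l1}"]
    df = df.sort_values(
        ["difference", "metabolite"], ascending=[False, True], kind="stable",
        key=lambda col: col.abs() if col.name == "difference" else col,
    )
    return df.reset_index(drop=True)
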