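"""Cross-fluid Spearman correlation networks and differential correlation.

For matched blood/CSF sample pools, the network matrix ``rho`` holds the
Spearman correlation of every shared metabolite in blood (rows) with every
shared metabolite in CSF (columns); within-fluid correlations are never
computed.  Entries with a two-sided p-value at or below alpha form the
adjacency matrix A (the correlation value where significant, zero
elsewhere).

p-values: for n <= 9 samples the permutation null is enumerated exactly
(all n! assignments, two-sided on |rho|, correct under ties via average
ranks); above that the usual t approximation
t = r sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom is used.

Genotype comparison: the pairs significant in either genotype's network are
harmonized into a common list, and the difference of each pair's
correlations is tested with the Fisher z-transformation,
z = atanh(r), SE = sqrt(1/(n1-3) + 1/(n2-3)), two-sided normal p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationNetwork",
    "spearman_rho_pvalue",
    "spearman_matrix",
    "significance_filter",
    "harmonize_pairs",
    "differential_correlations",
    "fisher_z_test",
    "EXACT_P_MAX_N",
]

EXACT_P_MAX_N = 9  # exact permutation enumeration up to this sample size


@dataclass
class CorrelationNetwork:
    """Blood x CSF Spearman network for one group of matched sample pools."""

    blood_names: list[str]
    csf_names: list[str]
    rho: np.ndarray  # rho[i, j]: metabolite i in blood vs metabolite j in CSF
    pvals: np.ndarray
    n_samples: int
    alpha: float | None = None
    A: np.ndarray | None = None  # rho masked at alpha; None until filtered

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        self.pvals = np.asarray(self.pvals, dtype=float)
        expected = (len(self.blood_names), len(self.csf_names))
        if self.rho.shape != expected or self.pvals.shape != expected:
            raise ValueError("rho/pvals shape inconsistent with name lists")
        if np.any(np.abs(self.rho) > 1 + 1e-12):
            raise ValueError("|rho| > 1")

    def transpose(self) -> "CorrelationNetwork":
        """The CSF -> blood view of the same network (M^T bookkeeping)."""
        return CorrelationNetwork(
            blood_names=list(self.csf_names),
            csf_names=list(self.blood_names),
            rho=self.rho.T.copy(),
            pvals=self.pvals.T.copy(),
            n_samples=self.n_samples,
            alpha=self.alpha,
            A=None if self.A is None else self.A.T.copy(),
        )


@lru_cache(maxsize=16)
def _perm_matrix(n: int) -> np.ndarray:
    """All n! permutations of range(n) as an (n!, n) index matrix."""
    return np.array(list(permutations(range(n))), dtype=np.int8)


@lru_cache(maxsize=16)
def _tie_free_null(n: int) -> np.ndarray:
    """Sorted |cross-product| null for tie-free ranks (depends only on n)."""
    r = np.arange(1, n + 1, dtype=float)
    rc = r - r.mean()
    nums = rc[_perm_matrix(n)] @ rc
    return np.sort(np.abs(nums))


def _exact_pvalue(rx: np.ndarray, ry: np.ndarray, ties: bool) -> float:
    """Two-sided exact permutation p-value from centered rank vectors."""
    n = rx.size
    obs = abs(float(rx @ ry))
    if ties:
        nums = ry[_perm_matrix(n)] @ rx
        sorted_abs = np.sort(np.abs(nums))
    else:
        sorted_abs = _tie_free_null(n)
    tol = 1e-9 * max(1.0, sorted_abs[-1])
    count = sorted_abs.size - np.searchsorted(sorted_abs, obs - tol, side="left")
    return float(count) / sorted_abs.size


def spearman_rho_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) and its two-sided p-value.

    Exact permutation enumeration for n <= 9; t approximation otherwise.
    Zero-variance input gives (0.0, 1.0) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y lengths differ")
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    nx, ny = np.linalg.norm(rxc), np.linalg.norm(ryc)
    if nx == 0 or ny == 0:
        warnings.warn("zero-variance input to Spearman correlation", stacklevel=2)
        return 0.0, 1.0
    rho = float(rxc @ ryc / (nx * ny))
    rho = max(-1.0, min(1.0, rho))
    if n <= EXACT_P_MAX_N:
        ties = np.unique(rx).size < n or np.unique(ry).size < n
        p = _exact_pvalue(rxc, ryc, ties)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def _matched_values(
    blood: pd.DataFrame, csf: pd.DataFrame, shared: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Value matrices for the shared metabolites with rows paired by sample_id."""
    b_ids = list(blood["sample_id"])
    c_ids = list(csf["sample_id"])
    if len(set(b_ids)) != len(b_ids) or len(set(c_ids)) != len(c_ids):
        raise ValueError("duplicate sample_id within a fluid's table")
    if set(b_ids) != set(c_ids):
        missing = sorted(set(b_ids).symmetric_difference(c_ids))
        raise ValueError(f"unmatched sample ids between fluids: {missing}")
    b = blood.set_index("sample_id").loc[sorted(b_ids), shared].to_numpy(dtype=float)
    c = csf.set_index("sample_id").loc[sorted(b_ids), shared].to_numpy(dtype=float)
    return b, c


def spearman_matrix(
    blood: pd.DataFrame,
    csf: pd.DataFrame,
    shared: list[str] | None = None,
) -> CorrelationNetwork:
    """Blood x CSF Spearman matrix over the shared metabolites of one group.

    ``blood`` and ``csf`` are concentration tables for the same sample pools
    (matched via ``sample_id``).  ``shared`` defaults to the metabolite
    columns present in both tables, in blood-table order.
    """
    from .tables import metabolite_columns

    if shared is None:
        csf_cols = set(metabolite_columns(csf))
        shared = [c for c in metabolite_columns(blood) if c in csf_cols]
    missing = [m for m in shared if m not in blood.columns or m not in csf.columns]
    if missing:
        raise ValueError(f"shared metabolites absent from a table: {missing}")
    if not shared:
        raise ValueError("no shared metabolites between the two tables")
    b, c = _matched_values(blood, csf, shared)
    n = b.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 matched samples, got {n}")
    k = len(shared)
    rho = np.zeros((k, k))
    pvals = np.ones((k, k))
    for i in range(k):
        for j in range(k):
            rho[i, j], pvals[i, j] = spearman_rho_pvalue(b[:, i], c[:, j])
    return CorrelationNetwork(list(shared), list(shared), rho, pvals, n_samples=n)


def significance_filter(net: CorrelationNetwork, alpha: float = 0.05) -> CorrelationNetwork:
    """Populate the adjacency A: rho where p <= alpha, zero elsewhere."""
    A = np.where(net.pvals <= alpha, net.rho, 0.0)
    return replace(net, alpha=alpha, A=A)


def harmonize_pairs(
    net_a: CorrelationNetwork, net_b: CorrelationNetwork
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Union of pairs significant in either network, with each network's own rho.

    Both returned tables list the same (blood, csf) pairs, sorted by name, so
    that the two groups (typically WT and APP) can be compared pair by pair;
    a pair significant in only one group still carries the other group's raw
    correlation.  Both networks must be significance-filtered first.
    """
    if net_a.blood_names != net_b.blood_names or net_a.csf_names != net_b.csf_names:
        raise ValueError("networks have different metabolite name lists")
    if net_a.alpha is None or net_b.alpha is None:
        raise ValueError("run significance_filter on both networks first")
    sig = (net_a.pvals <= net_a.alpha) | (net_b.pvals <= net_b.alpha)
    rows_a, rows_b = [], []
    idx = sorted(
        zip(*np.nonzero(sig)),
        key=lambda ij: (net_a.blood_names[ij[0]], net_a.csf_names[ij[1]]),
    )
    for i, j in idx:
        pair = {"blood": net_a.blood_names[i], "csf": net_a.csf_names[j]}
        rows_a.append({**pair, "rho": net_a.rho[i, j]})
        rows_b.append({**pair, "rho": net_b.rho[i, j]})
    cols = ["blood", "csf", "rho"]
    return (
        pd.DataFrame(rows_a, columns=cols),
        pd.DataFrame(rows_b, columns=cols),
    )


def fisher_z_test(
    r1: np.ndarray | float, r2: np.ndarray | float, n1: int, n2: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided normal test for the difference of two independent correlations.

    Correlations with |r| = 1 are clamped to 1 - 1e-10 in magnitude (with a
    warning) so the z-transform stays finite.
    """
    if n1 < 4 or n2 < 4:
        raise ValueError(
            "both groups need n >= 4: the Fisher z variance is 1/(n-3)"
        )
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    clip = 1.0 - 1e-10
    if np.any(np.abs(r1) >= 1.0) or np.any(np.abs(r2) >= 1.0):
        warnings.warn("|r| = 1 clamped before Fisher z-transform", stacklevel=2)
    z1 = np.arctanh(np.clip(r1, -clip, clip))
    z2 = np.arctanh(np.clip(r2, -clip, clip))
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    stat = (z1 - z2) / se
    p = 2.0 * stats.norm.sf(np.abs(stat))
    return stat, p


def differential_correlations(
    pairs_1: pd.DataFrame,
    pairs_2: pd.DataFrame,
    n_1: int,
    n_2: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher-z test of every harmonized pair's correlation between two groups.

    ``pairs_1``/``pairs_2`` are the outputs of :func:`harmonize_pairs`
    (identical pair lists, per-group rho).  Returns a table with columns
    blood, csf, r_group1, r_group2, z_stat, p_value, significant.
    """
    key_cols = ["blood", "csf"]
    if not pairs_1[key_cols].reset_index(drop=True).equals(
        pairs_2[key_cols].reset_index(drop=True)
    ):
        raise ValueError("pair lists differ; harmonize the networks first")
    if pairs_1.empty:
        return pd.DataFrame(
            columns=["blood", "csf", "r_group1", "r_group2", "z_stat", "p_value", "significant"]
        )
    stat, p = fisher_z_test(
        pairs_1["rho"].to_numpy(), pairs_2["rho"].to_numpy(), n_1, n_2
    )
    out = pairs_1[key_cols].copy()
    out["r_group1"] = pairs_1["rho"].to_numpy()
    out["r_group2"] = pairs_2["rho"].to_numpy()
    out["z_stat"] = stat
    out["p_value"] = p
    out["significant"] = p <= alpha
    return out
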