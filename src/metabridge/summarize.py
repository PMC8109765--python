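"""Group-level concentration summaries and consensus feature selection.

Three summaries of a concentration table:

* per-metabolite, per-group log10 ratio of late to early mean concentration
  (temporal trajectory direction and magnitude);
* one-way ANOVA ranking of metabolites by genotype (or any grouping) effect;
* L2-regularized (ridge) logistic regression on standardized concentrations,
  with the consensus of the top-k ANOVA and top-k ridge lists selected as
  the robust feature set.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .tables import metabolite_columns

__all__ = ["log_ratio_table", "anova_rank", "ridge_consensus"]


def log_ratio_table(table: pd.DataFrame) -> pd.DataFrame:
    """log10(mean late / mean early) per metabolite and sex x genotype group.

    The convention is late over early: positive values mean the metabolite's
    mean concentration rose with age.  Groups missing an age point raise;
    nonpositive group means yield NaN with a warning.
    """
    mets = metabolite_columns(table)
    rows = []
    for (sex, genotype), grp in table.groupby(["sex", "genotype"], sort=True):
        ages = set(grp["age_point"])
        if not {"early", "late"} <= ages:
            raise ValueError(
                f"group {sex}/{genotype} lacks an age point (has {sorted(ages)})"
            )
        early = grp.loc[grp["age_point"] == "early", mets].mean()
        late = grp.loc[grp["age_point"] == "late", mets].mean()
        for met in mets:
            e, l = float(early[met]), float(late[met])
            if e <= 0 or l <= 0:
                warnings.warn(
                    f"nonpositive mean for {met} in {sex}/{genotype}; log ratio set to NaN",
                    stacklevel=2,
                )
                ratio = np.nan
            else:
                ratio = np.log10(l / e)
            rows.append(
                {
                    "metabolite": met,
                    "sex": sex,
                    "genotype": genotype,
                    "log10_late_over_early": ratio,
                }
            )
    return pd.DataFrame(rows)


def anova_rank(table: pd.DataFrame, grouping: str = "genotype") -> pd.DataFrame:
    """One-way ANOVA F and p per metabolite across the levels of ``grouping``.

    Returns metabolites sorted by descending F.  Every level needs at least
    2 samples.
    """
    mets = metabolite_columns(table)
    levels = sorted(table[grouping].unique())
    if len(levels) < 2:
        raise ValueError(f"grouping {grouping!r} has fewer than 2 levels")
    groups = [table.loc[table[grouping] == lev, mets] for lev in levels]
    small = [lev for lev, g in zip(levels, groups) if len(g) < 2]
    if small:
        raise ValueError(f"levels with fewer than 2 samples: {small}")
    rows = []
    for met in mets:
        samples = [g[met].to_numpy(dtype=float) for g in groups]
        if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
            f_stat, p = 0.0, 1.0  # identical constant groups
        else:
            f_stat, p = stats.f_oneway(*samples)
        rows.append({"metabolite": met, "F": float(f_stat), "p": float(p)})
    out = pd.DataFrame(rows).sort_values(
        ["F", "metabolite"], ascending=[False, True], kind="stable"
    )
    return out.reset_index(drop=True)


def ridge_consensus(
    table: pd.DataFrame,
    grouping: str = "genotype",
    ridge_lambda: float = 1.0,
    k: int = 10,
) -> dict[str, list[str]]:
    """Consensus feature selection: intersection of top-k ANOVA and top-k ridge lists.

    The ridge ranking fits L2-penalized logistic regression (penalty strength
    ``ridge_lambda``) on standardized concentrations for a binary grouping
    and orders metabolites by absolute coefficient.  Returns a dict with the
    ``anova_top``, ``ridge_top`` and ``consensus`` name lists (consensus in
    ANOVA order).
    """
    mets = metabolite_columns(table)
    labels = table[grouping]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(
            f"ridge consensus needs exactly 2 classes in {grouping!r}, got {classes}"
        )
    if k < 0:
        raise ValueError("k must be nonnegative")
    if k == 0:
        return {"anova_top": [], "ridge_top": [], "consensus": []}
    anova = anova_rank(table, grouping=grouping)
    anova_top = anova["metabolite"].head(k).tolist()

    X = StandardScaler().fit_transform(table[mets].to_numpy(dtype=float))
    y = (labels == classes[1]).to_numpy(dtype=int)
    # default penalty is L2; strength = 1/C
    model = LogisticRegression(C=1.0 / ridge_lambda, solver="lbfgs", max_iter=5000)
    model.fit(X, y)
    coef = np.abs(model.coef_.ravel())
    order = np.lexsort((mets, -coef))  # by |coef| desc, ties by name
    ridge_top = [mets[i] for i in order[:k]]

    consensus = [m for m in anova_top if m in set(ridge_top)]
    return {"anova_top": anova_top, "ridge_top": ridge_top, "consensus": consensus}
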