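"""Slope-class community statistics: indicator values, SIMPER and test tables.

IndVal follows the Dufrene–Legendre (1997) group-mean form: for syntaxon j
and group g,

    A_gj = mean abundance of j in g / sum over groups of mean abundances
    B_gj = share of group-g transects where j occurs
    IndVal_gj = A_gj * B_gj            (in [0, 1])

and the reported value for a syntaxon is the maximum over groups; its
significance comes from permuting group labels.  A group-equalised variant
(abundance totals instead of means) is exposed as an option.  SIMPER
decomposes the average between-group Bray-Curtis dissimilarity into
per-syntaxon contributions.  Spearman correlations and Kruskal-Wallis /
Mann-Whitney comparisons delegate to scipy.
"""
from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: A syntaxon is flagged as an indicator of its best group at these cut-offs.
INDVAL_MIN = 0.50
INDVAL_ALPHA = 0.05

__all__ = [
    "indval",
    "indval_pvalue",
    "indval_table",
    "simper",
    "correlation_table",
    "group_comparison",
]


def _as_matrix(matrix: pd.DataFrame, groups) -> tuple[np.ndarray, np.ndarray, list, list]:
    X = matrix.to_numpy(dtype=float)
    g = np.asarray(groups)
    if len(g) != X.shape[0]:
        raise ValueError("groups must label every transect (row)")
    labels = sorted(pd.unique(g))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for lab in labels:
        if (g == lab).sum() == 0:
            raise ValueError(f"group {lab!r} is empty")
    return X, g, labels, list(matrix.columns)


def _indval_matrix(X: np.ndarray, g: np.ndarray, labels, abundance_base: str = "mean") -> np.ndarray:
    """(n_groups, n_syntaxa) IndVal array; columns of an all-zero syntaxon are NaN.

    ``abundance_base="mean"`` is the Dufrene-Legendre specificity (group
    means, insensitive to unequal group sizes); ``"total"`` uses raw group
    abundance totals instead.
    """
    if abundance_base == "mean":
        spec_base = np.stack([X[g == lab].mean(axis=0) for lab in labels])
    elif abundance_base == "total":
        spec_base = np.stack([X[g == lab].sum(axis=0) for lab in labels])
    else:
        raise ValueError(f"unknown abundance_base: {abundance_base!r}")
    denom = spec_base.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(denom > 0, spec_base / np.where(denom > 0, denom, 1.0), np.nan)
    B = np.stack([(X[g == lab] > 0).mean(axis=0) for lab in labels])
    return A * B


def indval(
    matrix: pd.DataFrame,
    groups,
    abundance_base: str = "mean",
) -> pd.DataFrame:
    """Per-syntaxon, per-group indicator values.

    ``matrix`` is transects x syntaxa (relative covers), ``groups`` a label
    per transect.  Returns a groups x syntaxa DataFrame; syntaxa absent from
    every transect are dropped with a log entry.
    """
    X, g, labels, cols = _as_matrix(matrix, groups)
    present = X.sum(axis=0) > 0
    absent = [c for c, p in zip(cols, present) if not p]
    if absent:
        logger.info("syntaxa absent everywhere skipped: %s", absent)
    iv = _indval_matrix(X[:, present], g, labels, abundance_base)
    return pd.DataFrame(iv, index=labels, columns=[c for c, p in zip(cols, present) if p])


def indval_pvalue(
    matrix: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    abundance_base: str = "mean",
) -> pd.Series:
    """Permutation p-value per syntaxon for its maximum-over-groups IndVal.

    p = (r + 1) / (n_perm + 1) with r the number of label permutations whose
    max IndVal is >= the observed one.
    """
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    X, g, labels, cols = _as_matrix(matrix, groups)
    present = X.sum(axis=0) > 0
    Xp = X[:, present]
    obs = np.nanmax(_indval_matrix(Xp, g, labels, abundance_base), axis=0)
    rng = np.random.default_rng(seed)
    r = np.zeros(Xp.shape[1], dtype=int)
    gp = g.copy()
    for _ in range(n_perm):
        rng.shuffle(gp)
        perm = np.nanmax(_indval_matrix(Xp, gp, labels, abundance_base), axis=0)
        r += perm >= obs - 1e-12
    p = (r + 1) / (n_perm + 1)
    return pd.Series(p, index=[c for c, keep in zip(cols, present) if keep], name="p_value")


def indval_table(
    matrix: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Indicator-analysis summary: best group, IndVal, p, occurrences, indicator flag."""
    iv = indval(matrix, groups)
    p = indval_pvalue(matrix, groups, n_perm=n_perm, seed=seed)
    best = iv.idxmax(axis=0)
    val = iv.max(axis=0)
    n_occ = (matrix[iv.columns] > 0).sum(axis=0)
    out = pd.DataFrame(
        {
            "syntaxon_code": iv.columns,
            "best_group": best.values,
            "indval": val.values,
            "p_value": p.loc[iv.columns].values,
            "n_occurrences": n_occ.values,
        }
    )
    out["indicator"] = (out["indval"] >= INDVAL_MIN) & (out["p_value"] < INDVAL_ALPHA)
    return out.sort_values(["best_group", "indval"], ascending=[True, False]).reset_index(drop=True)


def simper(matrix: pd.DataFrame, groups) -> dict[tuple, pd.DataFrame]:
    """Per-syntaxon contributions to between-group Bray-Curtis dissimilarity.

    For every pair of groups, the Bray-Curtis dissimilarity of each
    between-group transect pair is split per syntaxon as
    |x_ik - x_jk| / sum_k (x_ik + x_jk) and averaged over pairs, so the
    contributions sum exactly to the mean pairwise dissimilarity.  Returns
    a DataFrame per group pair, ranked by contribution, with percent and
    cumulative-percent columns (empty when the groups are identical).
    """
    X, g, labels, cols = _as_matrix(matrix, groups)
    out: dict[tuple, pd.DataFrame] = {}
    for g1, g2 in itertools.combinations(labels, 2):
        A = X[g == g1]
        B = X[g == g2]
        diff = np.abs(A[:, None, :] - B[None, :, :])          # (n1, n2, k)
        tot = (A[:, None, :] + B[None, :, :]).sum(axis=2)     # (n1, n2)
        with np.errstate(invalid="ignore", divide="ignore"):
            contrib = np.where(tot[:, :, None] > 0, diff / tot[:, :, None], 0.0)
        per_syn = contrib.mean(axis=(0, 1))
        overall = per_syn.sum()
        df = pd.DataFrame({"syntaxon_code": cols, "contribution": per_syn})
        df = df.sort_values("contribution", ascending=False).reset_index(drop=True)
        if overall > 0:
            df["contribution_pct"] = 100.0 * df["contribution"] / overall
            df["cumulative_pct"] = df["contribution_pct"].cumsum()
        else:
            df = df.iloc[0:0]
        df.attrs["overall_dissimilarity"] = float(overall)
        out[(g1, g2)] = df
    return out


def correlation_table(
    indices: pd.DataFrame,
    env: pd.DataFrame,
    show_max_p: float = 0.1,
    flag_min_p: float = 0.05,
) -> pd.DataFrame:
    """Spearman rank correlations of each macrophyte index against each environmental variable.

    Rows with p above ``show_max_p`` are hidden (``shown`` False), and rows
    with p in [``flag_min_p``, ``show_max_p``) carry a ``non_significant``
    flag — the conventional reporting rule for these tables.  Constant
    variables yield undefined rho and are reported missing (NaN).
    """
    records = []
    for iv in indices.columns:
        for ev in env.columns:
            x = indices[iv].to_numpy(dtype=float)
            y = env[ev].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 4:
                raise ValueError(f"fewer than 4 paired observations for {iv} vs {ev}")
            if np.all(x[ok] == x[ok][0]) or np.all(y[ok] == y[ok][0]):
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(x[ok], y[ok])
            records.append(
                {
                    "index": iv,
                    "env_var": ev,
                    "rho": rho,
                    "p_value": p,
                    "n": int(ok.sum()),
                    "shown": bool(p < show_max_p) if np.isfinite(p) else False,
                    "non_significant": bool(flag_min_p <= p < show_max_p) if np.isfinite(p) else True,
                }
            )
    return pd.DataFrame(records)


def group_comparison(metric, slope_classes) -> dict:
    """Kruskal-Wallis H across slope classes plus pairwise Mann-Whitney follow-ups.

    Classes with fewer than 2 members are excluded from the pairwise step
    with a warning.  Returns {"H", "p_value", "n", "pairwise": DataFrame}.
    """
    x = np.asarray(metric, dtype=float)
    g = np.asarray(slope_classes)
    ok = ~np.isnan(x)
    x, g = x[ok], g[ok]
    labels = [lab for lab in pd.unique(g) if (g == lab).sum() > 0]
    if len(labels) < 2:
        raise ValueError("need at least two non-empty classes")
    samples = [x[g == lab] for lab in labels]
    H, p = stats.kruskal(*samples)
    pair_labels = [lab for lab in labels if (g == lab).sum() >= 2]
    skipped = set(labels) - set(pair_labels)
    if skipped:
        logger.warning("classes with <2 members excluded from pairwise tests: %s", sorted(skipped))
    rows = []
    for a, b in itertools.combinations(pair_labels, 2):
        u, pu = stats.mannwhitneyu(x[g == a], x[g == b], alternative="two-sided")
        rows.append({"class_a": a, "class_b": b, "U": float(u), "p_value": float(pu)})
    return {
        "H": float(H),
        "p_value": float(p),
        "n": int(len(x)),
        "pairwise": pd.DataFrame(rows),
    }
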