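"""Diversity metrics, Spearman-distance PCoA, one-sided rank tests, and
covariate-adjusted per-feature association.

Alpha diversity covers observed species, Shannon (-sum p ln p), Simpson
(1 - sum p^2), Chao1 and ICE richness (which need integer counts), the
Gini inequality coefficient of the nonzero abundance vector, and Faith's
phylogenetic diversity on a supplied tree.

Ordination is classical PCoA on the distance 1 - Spearman rank
correlation between sample abundance vectors. Cohort comparisons use the
one-sided Wilcoxon rank-sum test, exact by enumeration for small groups.

The association step is a deliberately simple covariate-adjusted linear
model (a stand-in for multivariate-association frameworks such as
MaAsLin2): per feature, ordinary least squares of log(relative abundance
+ half the minimum nonzero value) on the target variable plus adjustment
covariates, Benjamini-Hochberg correction across features, and the
TransCo transform |coefficient| x sign(coefficient) — numerically the
coefficient itself; the formula is applied as printed for fidelity to the
published ranking.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["alpha_diversity", "chao1", "ice", "gini", "faith_pd",
           "pcoa_spearman", "wilcoxon_one_sided", "associate"]


# ------------------------------------------------------------ alpha metrics


def shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def simpson(p: np.ndarray) -> float:
    return float(1.0 - (p ** 2).sum())


def chao1(counts: np.ndarray) -> float:
    """Chao1 richness: S_obs + f1^2 / (2 f2), with the bias-corrected
    f1 (f1 - 1) / 2 form when there are no doubletons."""
    counts = np.asarray(counts)
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        return s_obs + f1 ** 2 / (2 * f2)
    return s_obs + f1 * (f1 - 1) / 2


def ice(counts: np.ndarray, rare_threshold: int = 10) -> float:
    """Coverage-based richness estimator over rare species (counts <=
    ``rare_threshold``), after Chao & Lee; falls back to Chao1 when the
    rare group is all singletons (undefined sample coverage)."""
    counts = np.asarray(counts)
    counts = counts[counts > 0]
    rare = counts[counts <= rare_threshold]
    s_abund = int((counts > rare_threshold).sum())
    s_rare = len(rare)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    if n_rare == 0:
        return float(s_abund)
    coverage = 1.0 - f1 / n_rare
    if coverage == 0 or n_rare < 2:
        return float(chao1(counts))
    fis = np.array([(rare == i).sum() for i in range(1, rare_threshold + 1)])
    ks = np.arange(1, rare_threshold + 1)
    gamma2 = max(
        s_rare / coverage * (ks * (ks - 1) * fis).sum() / (n_rare * (n_rare - 1)) - 1.0,
        0.0,
    )
    return float(s_abund + s_rare / coverage + f1 / coverage * gamma2)


def gini(abundances: np.ndarray) -> float:
    """Gini inequality coefficient of the nonzero abundance vector
    (0 = perfectly even community)."""
    x = np.sort(np.asarray(abundances, dtype=float))
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("gini: no nonzero abundances")
    n = x.size
    return float((2 * np.arange(1, n + 1) - n - 1).dot(x) / (n * x.sum()))


def faith_pd(present_features: list[str], tree) -> float:
    """Total branch length of the subtree spanning the observed features
    and the root, on a scikit-bio TreeNode."""
    import skbio

    if isinstance(tree, str):
        tree = skbio.TreeNode.read(StringIO(tree))
    tips = {t.name: t for t in tree.tips()}
    missing = [f for f in present_features if f not in tips]
    if missing:
        raise KeyError(f"features missing from tree: {missing}")
    covered = set()
    for f in present_features:
        node = tips[f]
        while node is not None and node not in covered:
            covered.add(node)
            node = node.parent
    return float(sum(n.length or 0.0 for n in covered))


def alpha_diversity(matrix: pd.DataFrame, counts: pd.DataFrame | None = None,
                    tree=None, rare_threshold: int = 10) -> pd.DataFrame:
    """Per-sample diversity report.

    ``matrix`` holds relative abundances (samples x features; an
    ``unassigned`` column is ignored). Chao1/ICE require the integer count
    matrix ``counts``; Faith's PD requires ``tree``. Metrics whose inputs
    are absent come back as NaN.
    """
    feats = [c for c in matrix.columns if c != "unassigned"]
    rel = matrix[feats]
    rows = {}
    for sample in matrix.index:
        p = rel.loc[sample].to_numpy(dtype=float)
        if p.sum() > 0:
            p = p / p.sum()
        row = {
            "observed_species": int((p > 0).sum()),
            "shannon": shannon(p),
            "simpson": simpson(p),
            "gini": gini(p) if (p > 0).any() else np.nan,
            "chao1": np.nan,
            "ice": np.nan,
            "faith_pd": np.nan,
        }
        if counts is not None:
            c = counts.loc[sample, feats].to_numpy()
            row["chao1"] = chao1(c)
            row["ice"] = ice(c, rare_threshold)
        if tree is not None:
            present = [f for f, v in zip(feats, p) if v > 0]
            row["faith_pd"] = faith_pd(present, tree)
        rows[sample] = row
    return pd.DataFrame(rows).T


# -------------------------------------------------------------------- PCoA


def pcoa_spearman(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical PCoA on 1 - Spearman correlation between samples.

    Returns (coordinates indexed by sample, explained-variance fractions
    over the retained positive-eigenvalue axes). Negative eigenvalues are
    dropped with a warning.
    """
    if len(matrix) < 3:
        raise ValueError("PCoA needs at least 3 samples")
    feats = [c for c in matrix.columns if c != "unassigned"]
    data = matrix[feats]
    const = data.std(axis=1) == 0
    if const.any():
        raise ValueError("constant abundance vector (Spearman undefined) in "
                         f"samples: {list(data.index[const])}")
    rho = data.T.corr(method="spearman").to_numpy()
    d = 1.0 - rho
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-10 * max(1.0, abs(evals[0]))
    if (evals < -tol).any():
        warnings.warn(f"dropping {(evals < -tol).sum()} negative eigenvalue(s)")
    keep = evals > tol
    coords = evecs[:, keep] * np.sqrt(evals[keep])
    explained = evals[keep] / evals[keep].sum()
    cols = [f"PCo{i + 1}" for i in range(keep.sum())]
    return pd.DataFrame(coords, index=matrix.index, columns=cols), explained


# ---------------------------------------------------------------- Wilcoxon


def wilcoxon_one_sided(x, y, alternative: str = "less") -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum test of x against y.

    Exact p by enumerating all rank assignments when n + m <= 12
    (midranks handle ties); otherwise the normal approximation with tie
    and continuity corrections. Returns (rank-sum statistic of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n].sum())
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical across both groups; p = 1")
        return w, 1.0
    if n + m <= 12:
        total = 0
        extreme = 0
        for combo in itertools.combinations(range(n + m), n):
            ws = ranks[list(combo)].sum()
            total += 1
            if alternative == "less":
                extreme += ws <= w + 1e-9
            else:
                extreme += ws >= w - 1e-9
        return w, extreme / total
    mean = n * (n + m + 1) / 2.0
    big_n = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / ((big_n) * (big_n - 1))
    var = n * m / 12.0 * ((big_n + 1) - tie_term)
    if var <= 0:
        warnings.warn("degenerate rank variance; p = 1")
        return w, 1.0
    if alternative == "less":
        z = (w - mean + 0.5) / math.sqrt(var)
        return w, float(sps.norm.cdf(z))
    z = (w - mean - 0.5) / math.sqrt(var)
    return w, float(sps.norm.sf(z))


# ------------------------------------------------------------- association


def associate(matrix: pd.DataFrame, design: pd.DataFrame,
              target: str = "habitat", adjust_for: list[str] | None = None,
              pseudocount: float | None = None) -> pd.DataFrame:
    """Covariate-adjusted per-feature association with a cohort variable.

    Per feature: OLS of log(abundance + pseudocount) on dummy-coded
    ``target`` plus ``adjust_for`` covariates; p from the target
    coefficient's t-test (joint F-test when the target has more than two
    levels, reporting the dummy with the largest |t| as the coefficient);
    Benjamini-Hochberg q across features; TransCo and the significance
    tier (+++ q<1e-3, ++ q<0.01, + q in 0.01-0.05).

    ``pseudocount`` defaults to half the minimum nonzero abundance.
    """
    import statsmodels.api as sm
    from statsmodels.stats.multitest import multipletests

    adjust_for = list(adjust_for or [])
    if target in adjust_for:
        raise ValueError("target cannot also be an adjustment variable")
    design = design.set_index("sample_id").loc[matrix.index]
    feats = [c for c in matrix.columns if c != "unassigned"]
    values = matrix[feats].to_numpy(dtype=float)
    if pseudocount is None:
        nz = values[values > 0]
        if nz.size == 0:
            raise ValueError("abundance matrix is all zero")
        pseudocount = nz.min() / 2.0

    parts = [pd.Series(1.0, index=matrix.index, name="intercept")]
    target_cols: list[str] = []
    for var in [target] + adjust_for:
        dummies = pd.get_dummies(design[var], prefix=var, drop_first=True,
                                 dtype=float)
        if var == target:
            target_cols = list(dummies.columns)
        parts.append(dummies)
    if not target_cols:
        raise ValueError(f"target {target!r} has a single level")
    x = pd.concat(parts, axis=1)
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        raise ValueError("confounded design: target collinear with adjustments")

    rows = []
    for i, feat in enumerate(feats):
        y = np.log(values[:, i] + pseudocount)
        if np.ptp(y) == 0:  # constant feature: no association by definition
            rows.append({"feature": feat, "coefficient": 0.0, "p_value": 1.0})
            continue
        res = sm.OLS(y, x).fit()
        if len(target_cols) == 1:
            coef = res.params[target_cols[0]]
            p = res.pvalues[target_cols[0]]
        else:
            contrast = np.zeros((len(target_cols), x.shape[1]))
            for j, col in enumerate(target_cols):
                contrast[j, x.columns.get_loc(col)] = 1.0
            p = float(res.f_test(contrast).pvalue)
            tvals = res.tvalues[target_cols]
            coef = res.params[tvals.abs().idxmax()]
        rows.append({"feature": feat, "coefficient": float(coef),
                     "p_value": float(p)})
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["trans_co"] = out["coefficient"].abs() * np.sign(out["coefficient"])
    out["significance"] = [
        "+++" if q < 1e-3 else "++" if q < 0.01 else "+" if q < 0.05 else ""
        for q in out["q_value"]
    ]
    return out.sort_values("q_value").reset_index(drop=True)
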