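"""Statistical primitives for repertoire analysis.

Contains the multi-J logistic model, Benjamini-Hochberg adjustment,
a two-sided Wilcoxon rank-sum test with an exact small-sample mode,
the Gini coefficient, Chatterjee's rank correlation xi with a
trend-screening wrapper, and Pearson/Spearman convenience wrappers.

The multi-J model relates the probability p_i that contig i shows
multi-J mapping to its cell type, its 5'-end J gene, V-gene presence
and translation-inhibitor treatment:

    logit(p_i) = beta_cell[c(i)] + beta_J[j(i)] + beta_V * xV_i
                 + beta_cyclo * xV_i * xTreat_i

The treatment indicator enters only through the interaction with V
presence: inhibiting translation can only rescue multi-J transcripts
that would otherwise be translated (V present) and degraded by
nonsense-mediated decay; V-less transcripts are never translated, so
treatment cannot act on them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import ParameterError


# ---------------------------------------------------------------------------
# multiple testing

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ParameterError("p must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(adjusted[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# rank-sum test

def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def wilcoxon_rank_sum(a, b, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns ``(W, p)`` where W is the rank sum of sample ``a`` (midranks
    for ties).  ``mode='exact'`` enumerates every assignment of the
    pooled observations to the two groups — feasible for small samples
    and exact even under ties; ``mode='normal'`` uses the tie-corrected
    normal approximation with continuity correction.  ``'auto'`` picks
    the exact mode when the pooled size is at most 12 and tie-free.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ParameterError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    n1, n = len(a), len(pooled)
    ranks = _midranks(pooled)
    w = float(ranks[:n1].sum())
    has_ties = len(np.unique(pooled)) < n
    if mode == "auto":
        mode = "exact" if (n <= 12 and not has_ties) else "normal"
    if mode == "exact":
        total = 0
        n_le = n_ge = 0
        eps = 1e-9
        for idx in itertools.combinations(range(n), n1):
            ws = ranks[list(idx)].sum()
            total += 1
            if ws <= w + eps:
                n_le += 1
            if ws >= w - eps:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / total)
        return w, p
    if mode != "normal":
        raise ParameterError(f"unknown mode '{mode}'")
    n2 = n - n1
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    diff = w - mu
    z = (diff - np.sign(diff) * 0.5) / np.sqrt(var)
    return w, float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# Gini coefficient

def gini(x) -> float:
    """Population Gini coefficient of a non-negative sample.

    G = sum_ij |x_i - x_j| / (2 n^2 mean); 0 by convention when the mean
    is zero.  Computed via the O(n log n) sorted form.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ParameterError("x must be a non-empty one-dimensional array")
    if np.any(x < 0):
        raise ParameterError("Gini is defined for non-negative values only")
    total = x.sum()
    if total == 0:
        return 0.0
    n = len(x)
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    return float(2.0 * np.sum(i * xs) / (n * total) - (n + 1) / n)


# ---------------------------------------------------------------------------
# Chatterjee's xi

def chatterjee_xi(x, y, seed: int = 0, alternative: str = "greater") -> tuple[float, float]:
    """Chatterjee's rank correlation xi with an asymptotic p-value.

    Sensitive to any functional (not just monotone) dependence of y on
    x.  Ties in x are broken uniformly at random (seeded, so the result
    is reproducible); ties in y use the tie-corrected form of the
    statistic.  The null distribution sqrt(n) xi -> N(0, 2/5) gives a
    right-tail p for ``alternative='greater'`` (the screening direction)
    or a doubled two-sided p; under y-ties the p-value is approximate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ParameterError("x and y must be paired")
    if n < 3:
        raise ParameterError("need at least 3 observations")
    if np.all(y == y[0]):
        raise ParameterError("y is constant; xi undefined")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    order = perm[np.argsort(x[perm], kind="stable")]
    y_ord = y[order]
    r = sps.rankdata(y_ord, method="max")          # #{j: y_j <= y_i}
    ell = sps.rankdata(-y_ord, method="max")       # #{j: y_j >= y_i}
    num = n * np.sum(np.abs(np.diff(r)))
    denom = 2.0 * np.sum(ell * (n - ell))
    xi = float(1.0 - num / denom)
    z = xi * np.sqrt(n / 0.4)
    if alternative == "greater":
        p = float(sps.norm.sf(z))
    elif alternative == "two-sided":
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    else:
        raise ParameterError(f"unknown alternative '{alternative}'")
    return xi, p


# ---------------------------------------------------------------------------
# logistic model of multi-J mapping

@dataclass
class LogisticFit:
    params: pd.DataFrame        # term, estimate, se, z, pvalue, padj
    converged: bool
    n_iter: int
    deviance_path: list[float]
    n_obs: int


def build_multij_design(data: pd.DataFrame,
                        response: str = "is_multij",
                        celltype: str = "cell_type",
                        jgene: str = "j_gene",
                        v_present: str = "v_gene_present",
                        treatment: str = "treatment",
                        reference: str | None = None,
                        ) -> tuple[pd.DataFrame, np.ndarray]:
    """Assemble the multi-J design matrix.

    One indicator column per cell-type level (the cell-type block absorbs
    the intercept), J-gene indicators with the reference level dropped
    (most frequent by default), the V-presence indicator, and the
    V x treatment interaction.
    """
    for col in (response, celltype, jgene, v_present):
        if col not in data.columns:
            raise ParameterError(f"column '{col}' missing from design data")
    y = data[response].astype(bool).to_numpy().astype(float)
    if y.min() == y.max():
        raise ParameterError("response is constant; model not estimable")
    cols = {}
    for level in sorted(data[celltype].astype(str).unique()):
        cols[f"cell[{level}]"] = (data[celltype].astype(str) == level).astype(float)
    j = data[jgene].astype(str)
    ref = reference if reference is not None else j.value_counts().idxmax()
    for level in sorted(j.unique()):
        if level == ref:
            continue
        cols[f"J[{level}]"] = (j == level).astype(float)
    xv = data[v_present].astype(bool).astype(float)
    cols["V_present"] = xv
    if treatment in data.columns:
        xt = data[treatment].astype(bool).astype(float)
        cols["V_present:treatment"] = xv * xt
    X = pd.DataFrame(cols, index=data.index)
    return X, y


def fit_multij_logistic(data: pd.DataFrame, **design_kwargs) -> LogisticFit:
    """Maximum-likelihood fit of the multi-J logistic model.

    The fit is by iteratively reweighted least squares (statsmodels GLM,
    binomial family); Wald two-tailed p-values per coefficient are
    BH-adjusted across all reported coefficients.  Rank-deficient
    designs and separation raise with the offending term named.
    """
    X, y = build_multij_design(data, **design_kwargs)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify a dependent column for the error message
        culprit = None
        base = np.zeros((len(X), 0))
        for name in X.columns:
            cand = np.column_stack([base, X[name].to_numpy()])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                culprit = name
                break
            base = cand
        raise ParameterError(
            f"design matrix is rank deficient (collinear term: {culprit})")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=100)
    except Exception as exc:  # statsmodels PerfectSeparation and friends
        raise ParameterError(f"logistic fit failed: {exc}") from exc
    se = np.asarray(res.bse)
    if not np.all(np.isfinite(se)) or np.any(np.abs(res.params) > 30):
        big = X.columns[int(np.argmax(np.abs(res.params)))]
        raise ParameterError(f"separation suspected for term '{big}'")
    pvals = np.asarray(res.pvalues)
    params = pd.DataFrame({
        "term": list(X.columns),
        "estimate": np.asarray(res.params),
        "se": se,
        "z": np.asarray(res.tvalues),
        "pvalue": pvals,
        "padj": bh_adjust(pvals),
    })
    history = [float(d) for d in res.fit_history.get("deviance", [])]
    return LogisticFit(params=params, converged=bool(res.converged),
                       n_iter=int(res.fit_history.get("iteration", len(history))),
                       deviance_path=history, n_obs=len(y))


# ---------------------------------------------------------------------------
# trend screening along pseudotime

def screen_trends(expr: pd.DataFrame, pseudotime, min_cells: int = 50,
                  alpha: float = 0.05, xi_min: float = 0.1,
                  seed: int = 0, n_bins: int = 100,
                  return_binned: bool = False):
    """Screen genes for pseudotime-dependent expression with Chatterjee's xi.

    ``expr`` is genes x cells, aligned to ``pseudotime``.  Genes detected
    in fewer than ``min_cells`` cells, or with constant expression, are
    excluded (with a recorded reason).  Remaining genes get xi and its
    right-tail p, BH-adjusted across tested genes; a gene passes when
    adjusted p < ``alpha`` and xi > ``xi_min``.  Optionally also returns
    mean expression over ``n_bins`` equal pseudotime bins per gene.
    """
    pt = np.asarray(pseudotime, dtype=float)
    if expr.shape[1] != len(pt):
        raise ParameterError("expression columns must align to pseudotime")
    rows = []
    for gene, values in expr.iterrows():
        v = values.to_numpy(dtype=float)
        n_expressed = int((v > 0).sum())
        if n_expressed < min_cells:
            rows.append((gene, n_expressed, np.nan, np.nan, "low_expression"))
            continue
        if np.all(v == v[0]):
            rows.append((gene, n_expressed, np.nan, np.nan, "constant"))
            continue
        xi, p = chatterjee_xi(pt, v, seed=seed, alternative="greater")
        rows.append((gene, n_expressed, xi, p, ""))
    out = pd.DataFrame(rows, columns=["gene", "n_cells_expressed", "xi", "pvalue", "excluded"])
    tested = out["excluded"] == ""
    out["padj"] = np.nan
    if tested.any():
        out.loc[tested, "padj"] = bh_adjust(out.loc[tested, "pvalue"].to_numpy())
    out["passed"] = tested & (out["padj"] < alpha) & (out["xi"] > xi_min)
    if not tested.any():
        import warnings
        warnings.warn("no gene passed the expression filter", stacklevel=2)
    if not return_binned:
        return out
    edges = np.linspace(pt.min(), pt.max(), n_bins + 1)
    which = np.clip(np.digitize(pt, edges[1:-1]), 0, n_bins - 1)
    binned = pd.DataFrame(
        {b: expr.iloc[:, np.where(which == b)[0]].mean(axis=1) if (which == b).any() else np.nan
         for b in range(n_bins)})
    return out, binned


# ---------------------------------------------------------------------------
# plain correlation wrappers

def pearson(x, y) -> tuple[float, float]:
    r = sps.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def spearman(x, y) -> tuple[float, float]:
    r = sps.spearmanr(x, y)
    return float(r.statistic), float(r.pvalue)
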