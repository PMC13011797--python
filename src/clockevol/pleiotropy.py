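"""Pleiotropy scores and the Box-Cox regression of substitution rate on them.

Pleiotropy is proxied two ways: the number of distinct GO Biological Process
terms annotated to a gene, and the gene's degree in a deduplicated undirected
interaction graph.  The association with the nonsynonymous rate (gene-wide Ka
or the windowed maximum Ka*) is assessed by ordinary least squares on a
Box-Cox-transformed response, with the transformation parameter lambda chosen
by profile log-likelihood on a fixed grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigurationError

BOXCOX_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.05), 10)


def go_score(go_table: pd.DataFrame, gene_id: str) -> int:
    """Distinct GO Biological Process terms annotated to `gene_id`."""
    sub = go_table[
        (go_table["gene_id"] == gene_id)
        & (go_table["namespace"].str.lower().isin(["biological_process", "bp"]))
    ]
    if sub.empty and gene_id not in set(go_table["gene_id"]):
        warnings.warn(f"gene {gene_id} absent from GO table; score 0", stacklevel=2)
    return int(sub["term_id"].nunique())


def interaction_score(edges: pd.DataFrame, gene_id: str) -> int:
    """Degree of `gene_id` in the deduplicated undirected interaction graph."""
    lo = edges[["gene_a", "gene_b"]].min(axis=1)
    hi = edges[["gene_a", "gene_b"]].max(axis=1)
    dedup = pd.DataFrame({"a": lo, "b": hi}).drop_duplicates()
    partners = set(dedup.loc[dedup["a"] == gene_id, "b"]) | set(
        dedup.loc[dedup["b"] == gene_id, "a"]
    )
    return len(partners)


@dataclass(frozen=True)
class RegressionResult:
    lam: float
    intercept: float
    slope: float
    f_statistic: float
    df1: int
    df2: int
    p_value: float
    r_squared: float
    adj_r_squared: float
    n: int
    zero_offset: float


def _boxcox_transform(y: np.ndarray, lam: float) -> np.ndarray:
    if abs(lam) < 1e-12:
        return np.log(y)
    return (np.power(y, lam) - 1.0) / lam


def _boxcox_profile_loglik(y: np.ndarray, X: np.ndarray, lam: float) -> float:
    """Profile log-likelihood of lambda given the regression design X."""
    z = _boxcox_transform(y, lam)
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ beta
    n = len(y)
    sigma2 = float(resid @ resid) / n
    if sigma2 <= 0:
        return -np.inf
    return -0.5 * n * np.log(sigma2) + (lam - 1.0) * float(np.sum(np.log(y)))


def boxcox_regression(
    response: np.ndarray,
    predictor: np.ndarray,
    lam: float | None = None,
) -> RegressionResult:
    """OLS of the Box-Cox-transformed response on one predictor.

    Masked (nan) responses are dropped; zero responses are offset by half the
    smallest positive value (Box-Cox requires positivity).  ``lam=None``
    selects lambda on the profile-likelihood grid [-2, 2] step 0.05; passing
    ``lam`` (e.g. 1.0) forces the transformation.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    keep = np.isfinite(y) & np.isfinite(x)
    y, x = y[keep], x[keep]
    if len(y) < 10:
        raise ConfigurationError("need at least 10 usable records")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raise ConfigurationError("constant response or predictor")
    offset = 0.0
    if (y <= 0).any():
        positive = y[y > 0]
        if positive.size == 0:
            raise ConfigurationError("response has no positive values")
        offset = 0.5 * float(positive.min())
        y = y + offset
    X = sm.add_constant(x)
    if lam is None:
        lls = [_boxcox_profile_loglik(y, X, l) for l in BOXCOX_GRID]
        lam = float(BOXCOX_GRID[int(np.argmax(lls))])
    z = _boxcox_transform(y, lam)
    model = sm.OLS(z, X).fit()
    return RegressionResult(
        lam=float(lam),
        intercept=float(model.params[0]),
        slope=float(model.params[1]),
        f_statistic=float(model.fvalue),
        df1=int(model.df_model),
        df2=int(model.df_resid),
        p_value=float(model.f_pvalue),
        r_squared=float(model.rsquared),
        adj_r_squared=float(model.rsquared_adj),
        n=int(model.nobs),
        zero_offset=offset,
    )


def pleiotropy_table(
    genes: list[str],
    go_table: pd.DataFrame | None = None,
    edges: pd.DataFrame | None = None,
    ka_gene: dict[str, float] | None = None,
    ka_star: dict[str, float] | None = None,
    clock_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Per-gene score/rate table feeding the regression and ranking reports."""
    clock_genes = clock_genes or set()
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for g in genes:
            rows.append(
                {
                    "gene_id": g,
                    "go_bp_count": go_score(go_table, g) if go_table is not None else np.nan,
                    "interaction_count": (
                        interaction_score(edges, g) if edges is not None else np.nan
                    ),
                    "ka_gene": (ka_gene or {}).get(g, np.nan),
                    "ka_star": (ka_star or {}).get(g, np.nan),
                    "is_clock_gene": g in clock_genes,
                }
            )
    return pd.DataFrame(rows)


def top_decile_report(table: pd.DataFrame, score_col: str = "go_bp_count") -> pd.DataFrame:
    """Genes in the top 10% of the pleiotropy score; ties at the cut included."""
    cut = table[score_col].quantile(0.9)
    return (
        table[table[score_col] >= cut]
        .sort_values(score_col, ascending=False, kind="stable")
        .reset_index(drop=True)
    )
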