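"""Copy-number association analyses: expression correlation, SNP effects, LD.

Correlations are Pearson product-moment with two-sided p-values from the t
approximation; multiple testing uses Benjamini-Hochberg FDR.  FDR families
are never pooled: one family across genes (transcriptome-wide screen), a
separate family across tissues (per-tissue screen of a single gene).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegressionResult",
    "log_transform",
    "correlate_cn_expression",
    "tissue_screen",
    "dosage_effect",
    "ld_r2",
]

_LOG_BASES = {2: np.log2, 10: np.log10, "e": np.log, np.e: np.log}


@dataclass(frozen=True)
class RegressionResult:
    """OLS slope of a response on allele dosage, with its t-test."""

    beta: float
    se: float
    t: float
    p: float
    n: int
    intercept: float


def log_transform(x: pd.DataFrame, offset: float = 1.0, base=2) -> pd.DataFrame:
    """Elementwise ``log_base(x + offset)``; input must be non-negative."""
    if base not in _LOG_BASES:
        raise ValueError("base must be 2, 10 or 'e'")
    arr = x.to_numpy(dtype=float)
    if np.nanmin(arr) < 0:
        raise ValueError("expression values must be non-negative")
    return pd.DataFrame(_LOG_BASES[base](arr + offset), index=x.index, columns=x.columns)


def _pearson_with_p(x: np.ndarray, y2d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Pearson r and two-sided t-approximation p per column of y2d."""
    n = len(x)
    xc = x - x.mean()
    yc = y2d - y2d.mean(axis=0)
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(t)] = np.nan
    p[np.isinf(t)] = 0.0
    return r, p


def correlate_cn_expression(cn: pd.Series, expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Pearson correlation of (log) expression with copy number.

    ``expr`` is samples x genes, already log transformed.  Samples are
    intersected on index; genes need >= 3 complete pairs and non-zero
    variance to be testable.  Benjamini-Hochberg q-values are computed over
    the testable genes only.  Returns a gene-indexed frame with columns
    ``r``, ``p``, ``q``, ``n``, ``testable``.
    """
    shared = expr.index.intersection(cn.dropna().index)
    x = cn.loc[shared].to_numpy(dtype=float)
    mat = expr.loc[shared]
    out = pd.DataFrame(
        index=mat.columns,
        data={"r": np.nan, "p": np.nan, "q": np.nan, "n": 0, "testable": False},
    )
    complete = ~mat.isna().any(axis=0)
    variant = mat.std(axis=0, ddof=0) > 0
    clean_cols = mat.columns[complete & variant]
    dirty_cols = mat.columns[~complete]

    if len(x) >= 3 and np.std(x) > 0 and len(clean_cols):
        r, p = _pearson_with_p(x, mat[clean_cols].to_numpy(dtype=float))
        out.loc[clean_cols, "r"] = r
        out.loc[clean_cols, "p"] = p
        out.loc[clean_cols, "n"] = len(x)
        out.loc[clean_cols, "testable"] = True
    for gene in dirty_cols:  # per-gene complete-case fallback
        pair = pd.DataFrame({"x": cn, "y": expr[gene]}).dropna()
        if len(pair) < 3 or pair["x"].std() == 0 or pair["y"].std() == 0:
            continue
        res = stats.pearsonr(pair["x"], pair["y"])
        out.loc[gene, ["r", "p", "n", "testable"]] = [
            res.statistic, res.pvalue, len(pair), True,
        ]
    testable = out.index[out["testable"].astype(bool)]
    if len(testable):
        out.loc[testable, "q"] = multipletests(
            out.loc[testable, "p"].to_numpy(dtype=float), method="fdr_bh"
        )[1]
    return out


def tissue_screen(
    cn: pd.Series,
    tissues: dict[str, pd.DataFrame],
    gene: str,
    min_samples: int = 5,
) -> pd.DataFrame:
    """Correlation of one gene with copy number, per tissue, FDR across tissues.

    Tissues lacking the gene or with fewer than ``min_samples`` overlapping
    samples are dropped with a warning.
    """
    rows = []
    for tissue, expr in tissues.items():
        if gene not in expr.columns:
            warnings.warn(f"tissue {tissue!r} lacks gene {gene!r}; dropped", stacklevel=2)
            continue
        pair = pd.DataFrame({"x": cn, "y": expr[gene]}).dropna()
        if len(pair) < min_samples:
            warnings.warn(
                f"tissue {tissue!r} has {len(pair)} samples < {min_samples}; dropped",
                stacklevel=2,
            )
            continue
        res = stats.pearsonr(pair["x"], pair["y"])
        rows.append((tissue, len(pair), res.statistic, res.pvalue))
    df = pd.DataFrame(rows, columns=["tissue", "n", "r", "p"]).set_index("tissue")
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["q"] = []
    return df


def dosage_effect(dosage, y) -> RegressionResult:
    """OLS of a response on 0/1/2 allele dosage (with intercept).

    Used both with log expression and with copy-number estimates as the
    response.  Raises on constant dosage ("no allele variation") or fewer
    than 3 paired samples.
    """
    pair = pd.DataFrame({"d": pd.Series(dosage), "y": pd.Series(y)}).dropna()
    if len(pair) < 3:
        raise ValueError(f"need >= 3 paired samples, got {len(pair)}")
    d = pair["d"].to_numpy(dtype=float)
    resp = pair["y"].to_numpy(dtype=float)
    if np.all(d == d[0]):
        raise ValueError("no allele variation: dosage is constant")
    fit = stats.linregress(d, resp)
    t = fit.slope / fit.stderr if fit.stderr > 0 else np.inf * np.sign(fit.slope)
    return RegressionResult(
        beta=float(fit.slope),
        se=float(fit.stderr),
        t=float(t),
        p=float(fit.pvalue),
        n=len(pair),
        intercept=float(fit.intercept),
    )


def ld_r2(dos_a, dos_b) -> float:
    """Composite LD: squared Pearson correlation of genotype dosages.

    Returns NaN (undefined) when either vector is constant.
    """
    pair = pd.DataFrame({"a": pd.Series(dos_a), "b": pd.Series(dos_b)}).dropna()
    a = pair["a"].to_numpy(dtype=float)
    b = pair["b"].to_numpy(dtype=float)
    if len(pair) < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
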