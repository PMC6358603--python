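"""Microarray-style expression statistics.

The chain mirrors a standard bead-array workflow: drop probes never detected
above negative controls, variance-stabilise and quantile-normalise, compare
treatment groups with a moderated t statistic (method-of-moments empirical
shrinkage of gene variances) under Benjamini-Hochberg FDR control, and test
promoter-element category enrichment of the regulated set against background
ratios with a chi-square goodness-of-fit.

The variance stabilisation here is ``log2(x + c)``; bead-level variance
modelling is out of scope.  Promoter categories (CRE-TATA / CRE-NoTATA /
Others) are an input annotation, not computed from sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix", "DEResult", "EnrichmentResult", "CATEGORIES",
    "filter_detection", "normalize", "quantile_normalize",
    "differential_expression", "cre_enrichment",
]

CATEGORIES = ("CRE-TATA", "CRE-NoTATA", "Others")


@dataclass
class ExpressionMatrix:
    """Genes x samples intensities with detection p-values and annotations."""

    values: pd.DataFrame
    detection_p: pd.DataFrame
    groups: pd.Series                  # sample -> group label
    gene_annotation: pd.Series | None = None   # gene -> promoter category

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.detection_p.index) or \
                not self.values.columns.equals(self.detection_p.columns):
            raise ValueError("values and detection_p must share genes and samples")
        if not set(self.values.columns) <= set(self.groups.index):
            raise ValueError("every sample needs a group label")
        bad = (self.detection_p.to_numpy() < 0) | (self.detection_p.to_numpy() > 1)
        if bad.any():
            raise ValueError("detection p-values must lie in [0, 1]")

    def samples_of(self, *group_names: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] in group_names]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        ann = None if self.gene_annotation is None else self.gene_annotation.loc[genes]
        return ExpressionMatrix(self.values.loc[genes],
                                self.detection_p.loc[genes],
                                self.groups, ann)


@dataclass
class DEResult:
    """Per-gene differential-expression table plus moderation diagnostics."""

    table: pd.DataFrame        # columns: log2fc, t, p, q, direction
    group_a: str
    group_b: str
    prior_df: float
    prior_var: float

    def significant(self, q_max: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] < q_max]


@dataclass
class EnrichmentResult:
    observed: dict[str, int]
    expected: dict[str, float]
    obs_over_exp: dict[str, float]
    chi2: float
    df: int
    p: float
    low_expected_warning: bool = False


# ---------------------------------------------------------------------------
# filtering and normalisation


def filter_detection(
    matrix: ExpressionMatrix,
    alpha: float = 0.01,
    samples: list[str] | None = None,
) -> tuple[ExpressionMatrix, dict]:
    """Drop never-detected genes.

    A gene is removed only if its detection p-value exceeds ``alpha`` in
    *all* of the given samples (default: all samples), i.e. it was never
    distinguishable from the negative controls in the comparison subgroup.
    Returns the filtered matrix and a kept/dropped report.
    """
    cols = samples if samples is not None else list(matrix.values.columns)
    undetected = (matrix.detection_p[cols] > alpha).all(axis=1)
    kept = matrix.values.index[~undetected]
    report = {"n_input": len(matrix.values), "n_kept": int((~undetected).sum()),
              "n_dropped": int(undetected.sum()), "alpha": alpha}
    return matrix.subset_genes(kept), report


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalisation.

    Each column's order statistics are replaced by the mean order statistic
    across columns, making all column distributions identical.  Idempotent.
    """
    arr = values.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="stable")
    mean_sorted = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        out[order[:, j], j] = mean_sorted
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def normalize(
    matrix: ExpressionMatrix,
    method: str = "vst",
    offset: float = 1.0,
    quantile: bool = True,
) -> ExpressionMatrix:
    """Variance-stabilise then quantile-normalise intensities.

    ``method='vst'`` applies ``log2(x + offset)`` as the stabilising
    transform; ``method='log2'`` is an alias with the same behaviour and is
    kept so the transform choice is explicit at call sites.
    """
    if method not in ("vst", "log2"):
        raise ValueError(f"unknown normalisation method {method!r}")
    vals = np.log2(matrix.values + offset)
    if quantile:
        vals = quantile_normalize(vals)
    return replace(matrix, values=vals)


# ---------------------------------------------------------------------------
# moderated t


def _invert_trigamma(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        step = tri * (1 - tri / y) / special.polygamma(2, x)
        x -= step
        if abs(step) < tol * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of a scaled inverse-chi-square variance prior.

    Matches the mean and variance of log sample variances: with residual df
    ``d``, ``log s2`` has variance ``trigamma(d/2) + trigamma(d0/2)`` about
    ``log s0^2`` (after digamma bias correction), which is inverted for the
    prior df ``d0`` and prior variance ``s0^2``.
    """
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 2:
        return np.inf, float(np.median(s2)) if len(s2) else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    excess = z.var(ddof=1) - special.polygamma(1, df / 2)
    if excess <= 0:
        d0 = np.inf
        log_s0 = e.mean()
    else:
        half_d0 = _invert_trigamma(excess)
        d0 = 2 * half_d0
        log_s0 = e.mean() + special.digamma(half_d0) - np.log(half_d0)
    return float(d0), float(np.exp(log_s0))


def differential_expression(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    moderated: bool = True,
) -> DEResult:
    """Moderated two-sample t test per gene, BH-adjusted.

    Input values are assumed on a log2 scale (post :func:`normalize`), so
    the mean difference ``group_a - group_b`` is the log2 fold change.
    Gene-wise variances are shrunk toward a common prior estimated by the
    method of moments on log variances; the t statistic uses the posterior
    variance with ``df + prior_df`` degrees of freedom.  With
    ``moderated=False`` this reduces to the ordinary pooled-variance t test.
    """
    cols_a = matrix.samples_of(group_a)
    cols_b = matrix.samples_of(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs at least two samples")
    a = matrix.values[cols_a].to_numpy(dtype=float)
    b = matrix.values[cols_b].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    df_res = na + nb - 2
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    lfc = mean_a - mean_b
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + \
         ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_res

    if moderated:
        d0, s0 = _fit_variance_prior(s2, df_res)
    else:
        d0, s0 = 0.0, 0.0
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.inf
    elif d0 > 0:
        s2_post = (d0 * s0 + df_res * s2) / (d0 + df_res)
        df_total = d0 + df_res
    else:
        s2_post = s2
        df_total = df_res

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame({
        "log2fc": lfc, "t": t, "p": p, "q": q,
        "direction": np.where(lfc > 0, "up", np.where(lfc < 0, "down", "flat")),
    }, index=matrix.values.index)
    return DEResult(table=table, group_a=group_a, group_b=group_b,
                    prior_df=float(d0), prior_var=float(s0))


# ---------------------------------------------------------------------------
# category enrichment


def cre_enrichment(
    de_categories: pd.Series,
    background_categories: pd.Series,
    categories: tuple[str, ...] = CATEGORIES,
) -> EnrichmentResult:
    """Chi-square enrichment of promoter categories in a regulated gene set.

    Expected counts per category are the background category ratios (over
    all detected genes in the comparison) times the number of regulated
    genes; the statistic is the usual goodness-of-fit chi-square with
    ``len(categories) - 1`` degrees of freedom.  Observed/expected ratios
    are reported per category.  A flag is raised when any expected count is
    below 5, where the chi-square approximation is unreliable.
    """
    de_categories = pd.Series(de_categories)
    background_categories = pd.Series(background_categories)
    unknown = set(de_categories.unique()) - set(categories)
    if unknown:
        raise ValueError(f"regulated genes carry unknown categories: {unknown}")
    n_de = len(de_categories)
    if n_de == 0:
        raise ValueError("empty regulated gene set")
    bg_counts = background_categories.value_counts()
    bg_total = int(bg_counts.sum())
    observed = {c: int((de_categories == c).sum()) for c in categories}
    expected = {c: bg_counts.get(c, 0) / bg_total * n_de for c in categories}
    if any(e == 0 for e in expected.values()):
        raise ValueError("a category has zero background frequency")
    chi2 = sum((observed[c] - expected[c]) ** 2 / expected[c] for c in categories)
    dof = len(categories) - 1
    p = float(stats.chi2.sf(chi2, dof))
    low = any(e < 5 for e in expected.values())
    if low:
        warnings.warn("expected count < 5; chi-square approximation unreliable",
                      stacklevel=2)
    return EnrichmentResult(
        observed=observed, expected=expected,
        obs_over_exp={c: observed[c] / expected[c] for c in categories},
        chi2=float(chi2), df=dof, p=p, low_expected_warning=low)
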