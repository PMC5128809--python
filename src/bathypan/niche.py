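"""Environmental niche statistics for the two genome-dominant sample groups.

The workhorse is a Mann-Whitney-Wilcoxon (MWW) rank-sum test implemented
exactly (dynamic-programming null distribution of U) for small tie-free
samples and by the tie-corrected, continuity-corrected normal approximation
otherwise.  On top of it: per-parameter group comparisons between samples
dominated by each genome, a PCA of standardized environmental covariates,
and the concordance between amplicon (metabarcode) counts and the summed
relative genomic abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EXACT_LIMIT = 16  # exact U null by DP when n_a + n_b <= this and no ties


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of group a: number of (a, b) pairs with a > b, ties counting 1/2."""
    ranks = stats.rankdata(np.concatenate([a, b]))
    ra = ranks[: len(a)].sum()
    return float(ra - len(a) * (len(a) + 1) / 2.0)


def _u_null_counts(n: int, m: int) -> np.ndarray:
    """Exact tie-free null: counts[u] = #labelings with U = u, u in 0..n*m.

    Counts subsets of ranks {1..n+m} of size n by rank sum via the standard
    subset-sum recurrence; U = ranksum - n(n+1)/2.
    """
    N = n + m
    max_sum = n * N
    dp = np.zeros((n + 1, max_sum + 1), dtype=np.int64)
    dp[0, 0] = 1
    for j in range(1, N + 1):
        for k in range(min(j, n), 0, -1):
            dp[k, j:] += dp[k - 1, : max_sum + 1 - j]
    offset = n * (n + 1) // 2
    return dp[n, offset : offset + n * m + 1]


def mww_test(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney-Wilcoxon test; returns (U_a, p).

    Exact when the combined sample size is <= 16 with no ties (two-sided
    p = 2 x min tail of the enumerated U null, capped at 1); otherwise the
    normal approximation with tie and continuity corrections.  Degenerate
    inputs where every value is tied give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n, m = len(a), len(b)
    u = _u_statistic(a, b)
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < n + m

    if n + m <= EXACT_LIMIT and not has_ties:
        counts = _u_null_counts(n, m)
        total = counts.sum()
        ui = int(round(u))
        lower = counts[: ui + 1].sum() / total
        upper = counts[ui:].sum() / total
        return u, float(min(1.0, 2.0 * min(lower, upper)))

    mu = n * m / 2.0
    N = n + m
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (N * (N - 1))
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return u, 1.0
    z = max(abs(u - mu) - 0.5, 0.0) / np.sqrt(var)
    return u, float(min(1.0, 2.0 * stats.norm.sf(z)))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1].clip(max=1.0)
    out = np.empty(n)
    out[order] = adj
    return out


@dataclass
class PcaResult:
    loadings: pd.DataFrame  # parameters x components
    scores: pd.DataFrame  # samples x components
    variance_explained: np.ndarray
    dropped_parameters: list[str]
    n_dropped_samples: int
    significance: pd.DataFrame | None = None


def pca_env(
    table: pd.DataFrame,
    parameters: list[str] | None = None,
    groups: pd.Series | None = None,
    alpha: float = 0.05,
) -> PcaResult:
    """PCA of standardized environmental covariates.

    Rows with missing values are dropped (count reported); zero-variance
    parameters are dropped with a warning.  Components come from the spectral
    decomposition of the correlation matrix with a deterministic sign
    convention (largest-magnitude loading positive).  When ``groups`` maps
    samples to the two dominance groups, each parameter gets an MWW p-value
    and a Benjamini-Hochberg significance flag at ``alpha`` — the "starred"
    parameters that discriminate the two genomes.
    """
    params = list(parameters) if parameters is not None else list(table.columns)
    sub = table[params].dropna(axis=0)
    n_dropped = len(table) - len(sub)
    if len(sub) < 3 or len(params) < 2:
        raise ValueError("need >= 3 complete samples and >= 2 parameters")
    sd = sub.std(ddof=1)
    dead = list(sd.index[sd <= 0])
    if dead:
        warnings.warn(f"dropping zero-variance parameters: {dead}", stacklevel=2)
        sub = sub.drop(columns=dead)
    z = (sub - sub.mean()) / sub.std(ddof=1)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order].clip(min=0.0), eigvec[:, order]
    # sign convention: the largest-magnitude loading of each component is positive
    flip = np.sign(eigvec[np.abs(eigvec).argmax(axis=0), np.arange(eigvec.shape[1])])
    eigvec = eigvec * np.where(flip == 0, 1.0, flip)
    comp = [f"PC{i + 1}" for i in range(eigvec.shape[1])]
    loadings = pd.DataFrame(eigvec, index=sub.columns, columns=comp)
    scores = pd.DataFrame(z.to_numpy() @ eigvec, index=sub.index, columns=comp)

    significance = None
    if groups is not None:
        rows = {}
        g = groups.reindex(sub.index)
        labels = [lab for lab in pd.unique(g.dropna()) if lab is not None]
        if len(labels) == 2:
            ga, gb = sorted(labels)
            pvals = []
            for par in sub.columns:
                _, p = mww_test(
                    sub.loc[g == ga, par].to_numpy(), sub.loc[g == gb, par].to_numpy()
                )
                pvals.append(p)
            significance = pd.DataFrame(
                {"p": pvals, "significant": bh_adjust(pvals) <= alpha}, index=sub.columns
            )
    return PcaResult(
        loadings=loadings,
        scores=scores,
        variance_explained=eigval / eigval.sum(),
        dropped_parameters=dead,
        n_dropped_samples=n_dropped,
        significance=significance,
    )


def niche_summary(
    abund: pd.DataFrame,
    profiles: pd.DataFrame,
    parameters: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-parameter ranges, means and MWW tests between dominance groups.

    ``abund`` must carry the per-sample ``class`` column (see
    :func:`bathypan.abundance.relative_abundance`); only A_dominant and
    B_dominant samples enter — co-occurring, mixed and below-floor samples
    are excluded.  Raw p-values are reported alongside Benjamini-Hochberg
    flags at ``alpha``.
    """
    from .simulate import ENV_PARAMETERS

    params = parameters or [p for p in ENV_PARAMETERS if p in profiles.columns]
    idx_a = abund.index[abund["class"] == "A_dominant"]
    idx_b = abund.index[abund["class"] == "B_dominant"]
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("need at least one A-dominant and one B-dominant sample")
    rows = []
    for par in params:
        va = profiles.loc[idx_a, par].dropna().to_numpy()
        vb = profiles.loc[idx_b, par].dropna().to_numpy()
        u, p = mww_test(va, vb)
        rows.append(
            {
                "parameter": par,
                "mean_a": va.mean(),
                "mean_b": vb.mean(),
                "min_a": va.min(),
                "max_a": va.max(),
                "min_b": vb.min(),
                "max_b": vb.max(),
                "U": u,
                "p": p,
                "n_a": len(va),
                "n_b": len(vb),
            }
        )
    out = pd.DataFrame(rows).set_index("parameter")
    out["significant_bh"] = bh_adjust(out["p"].to_numpy()) <= alpha
    return out


def barcode_correlation(
    barcode: pd.Series, abund_sum: pd.Series
) -> tuple[float, float, int]:
    """Concordance of amplicon counts with summed genomic abundance.

    Returns (Spearman rho, Pearson r, n) over samples present in both
    series.  The marker is shared by the two genomes, so only their summed
    abundance is comparable.  Constant input leaves the correlation
    undefined (NaN, with a warning).
    """
    common = barcode.index.intersection(abund_sum.index)
    if len(common) < 3:
        raise ValueError("need >= 3 samples with both measurements")
    x = barcode.loc[common].to_numpy(dtype=float)
    y = abund_sum.loc[common].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: correlation undefined", stacklevel=2)
        return float("nan"), float("nan"), len(common)
    rho = stats.spearmanr(x, y).statistic
    r = stats.pearsonr(x, y).statistic
    return float(rho), float(r), len(common)
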