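"""Count normalization, differential abundance, clustering, correlation.

Normalization follows the TMM recipe: per-column scaling factors from the
weighted trimmed mean of per-gene log2 ratios (M-values) against a reference
column, trimming 30 % of M and 5 % of A, precision weights from the binomial
delta method, factors rescaled to geometric mean 1.  Differential abundance
between two stages uses the conditional negative-binomial exact test on
group-summed counts scaled to a common library size, with a single common
dispersion (0 gives the binomial limit) and Benjamini–Hochberg adjustment
within each contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .io import SampleSheet

__all__ = [
    "CountMatrix",
    "DEResult",
    "cpm",
    "tmm_factors",
    "estimate_common_dispersion",
    "exact_test_pair",
    "all_pairwise_tests",
    "log2_ratio_matrix",
    "hierarchical_cluster",
    "spearman_matrix",
]


@dataclass
class CountMatrix:
    """miRNA × library raw counts plus design metadata and norm factors."""

    counts: pd.DataFrame  # rows: miRNA ids, columns: library ids
    sheet: SampleSheet
    norm_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        lib_ids = set(self.sheet.library_ids)
        if set(self.counts.columns) != lib_ids:
            raise ValueError("count columns do not match the sample sheet")
        # column order follows the sheet
        self.counts = self.counts[self.sheet.library_ids]
        if self.norm_factors is None:
            self.norm_factors = pd.Series(1.0, index=self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def columns_for_stage(self, stage: str) -> list[str]:
        return [l.library_id for l in self.sheet.by_stage(stage)]

    def with_tmm(self, **kw) -> "CountMatrix":
        return CountMatrix(self.counts, self.sheet, tmm_factors(self.counts, **kw))


def cpm(matrix: CountMatrix, use_norm_factors: bool = True) -> pd.DataFrame:
    """Counts per million over effective library size (column sum × factor)."""
    sizes = matrix.library_sizes.astype(float)
    if (sizes == 0).any():
        raise ValueError("zero column sum; cpm undefined")
    if use_norm_factors:
        sizes = sizes * matrix.norm_factors
    return matrix.counts / sizes * 1e6


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, logratio_trim: float = 0.3,
              sum_trim: float = 0.05, a_cutoff: float = -1e10) -> float:
    """TMM factor of one column against the reference (log2 scale inside)."""
    n_o, n_r = obs.sum(), ref.sum()
    if n_o == 0:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2((obs / n_o) / (ref / n_r))
        a = 0.5 * np.log2((obs / n_o) * (ref / n_r))
    keep = np.isfinite(m) & np.isfinite(a) & (a > a_cutoff)
    m, a = m[keep], a[keep]
    o, r = obs[keep], ref[keep]
    if m.size == 0 or np.allclose(m, m[0], atol=1e-6):
        return 1.0
    w = (n_o - o) / (n_o * o) + (n_r - r) / (n_r * r)
    n = m.size
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
    lo_a, hi_a = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
    rank_m = stats.rankdata(m, method="average")
    rank_a = stats.rankdata(a, method="average")
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame,
    ref_column: str | None = None,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> pd.Series:
    """Per-column TMM normalization factors, geometric mean 1.

    The reference column (when not given) is the one whose 75th percentile of
    cpm is closest to the mean 75th percentile across columns.  All-zero
    columns get factor 1 with a warning.
    """
    x = counts.to_numpy(dtype=float)
    sizes = x.sum(axis=0)
    if (sizes == 0).any():
        warnings.warn("column(s) with all-zero counts get norm factor 1")
    if ref_column is None:
        with np.errstate(invalid="ignore", divide="ignore"):
            q = np.array(
                [np.quantile(x[:, j][x[:, j] > 0] / s, 0.75) if s > 0 else 0.0
                 for j, s in enumerate(sizes)]
            )
        ref_idx = int(np.argmin(np.abs(q - q.mean())))
    else:
        ref_idx = list(counts.columns).index(ref_column)
    ref = x[:, ref_idx]
    factors = np.array(
        [
            1.0 if sizes[j] == 0 else _tmm_pair(x[:, j], ref, logratio_trim, sum_trim)
            for j in range(x.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


def estimate_common_dispersion(matrix: CountMatrix, by_stage: bool = True) -> float:
    """Method-of-moments common NB dispersion on size-scaled counts.

    Counts are scaled to the mean effective library size; within each stage
    (or globally) the excess of variance over mean yields a per-gene moment
    estimate (var − mean)/mean², pooled by the median over informative genes.
    """
    sizes = matrix.library_sizes * matrix.norm_factors
    scaled = matrix.counts / sizes.values * float(sizes.mean())
    groups = (
        [matrix.columns_for_stage(s) for s in matrix.sheet.stages]
        if by_stage
        else [list(matrix.counts.columns)]
    )
    ests = []
    for cols in groups:
        if len(cols) < 2:
            continue
        sub = scaled[cols].to_numpy()
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 1
        if ok.any():
            ests.append((v[ok] - m[ok]) / m[ok] ** 2)
    if not ests:
        return 0.0
    pooled = np.concatenate(ests)
    return float(max(0.0, np.median(pooled)))


@dataclass(frozen=True)
class DEResult:
    mirna: str
    contrast: tuple[str, str]
    log2_fold_change: float
    p_value: float
    fdr: float

    @property
    def significant(self) -> bool:
        return self.fdr < 0.05


def _exact_nb_pvalue_impl(ya: int, yb: int, na: int, nb: int, dispersion: float) -> float:
    """Two-sided conditional exact p-value for a count split.

    Conditional on the total s = ya + yb, enumerate P(Ya = y) ∝
    f_a(y) f_b(s − y) where group sums are NB with means proportional to
    group size and size parameter n_group/φ; the p-value sums probabilities
    no larger than the observed split's (double tail).  φ = 0 is the Poisson
    limit, where the conditional law is binomial.
    """
    s = ya + yb
    if s == 0:
        return 1.0
    y = np.arange(s + 1)
    pa = na / (na + nb)
    if dispersion <= 0:
        logp = stats.binom.logpmf(y, s, pa)
    else:
        mu = s / (na + nb)
        ra, rb = na / dispersion, nb / dispersion
        la = stats.nbinom.logpmf(y, ra, ra / (ra + na * mu))
        lb = stats.nbinom.logpmf(s - y, rb, rb / (rb + nb * mu))
        logp = la + lb
        logp = logp - logsumexp(logp)
    p_obs = logp[ya]
    keep = logp <= p_obs + 1e-12
    p = float(np.exp(logsumexp(logp[keep])))
    # numerically complete tails are exactly 1
    return 1.0 if p > 1.0 - 1e-9 else p


def exact_test_pair(
    matrix: CountMatrix,
    stage_a: str,
    stage_b: str,
    dispersion: float | str = "auto",
    pseudo_count: float = 0.5,
) -> list[DEResult]:
    """Pairwise exact test between two stages on normalized counts.

    Per-library counts are scaled to the geometric-mean effective library
    size, summed within each stage, and the split tested conditionally on its
    total (see :func:`_exact_nb_pvalue_impl`).  BH adjustment is applied
    across miRNAs within the contrast; the fold change is the log2 ratio of
    normalized group means with a 0.5 pseudo-count.
    """
    cols_a = matrix.columns_for_stage(stage_a)
    cols_b = matrix.columns_for_stage(stage_b)
    if not cols_a or not cols_b:
        raise ValueError(f"contrast ({stage_a}, {stage_b}) has an empty group")
    if dispersion == "auto":
        dispersion = estimate_common_dispersion(matrix)
    sizes = (matrix.library_sizes * matrix.norm_factors).astype(float)
    common = float(np.exp(np.mean(np.log(sizes[cols_a + cols_b]))))
    scaled = matrix.counts[cols_a + cols_b] / sizes[cols_a + cols_b] * common
    ya = scaled[cols_a].sum(axis=1).round().astype(int)
    yb = scaled[cols_b].sum(axis=1).round().astype(int)
    na, nb = len(cols_a), len(cols_b)
    pvals = np.array(
        [
            _exact_nb_pvalue_impl(int(a), int(b), na, nb, float(dispersion))
            for a, b in zip(ya, yb)
        ]
    )
    fdr = multipletests(pvals, method="fdr_bh")[1]
    mean_a = scaled[cols_a].mean(axis=1)
    mean_b = scaled[cols_b].mean(axis=1)
    lfc = np.log2((mean_a + pseudo_count) / (mean_b + pseudo_count))
    return [
        DEResult(gene, (stage_a, stage_b), float(l), float(p), float(q))
        for gene, l, p, q in zip(matrix.counts.index, lfc, pvals, fdr)
    ]


def all_pairwise_tests(
    matrix: CountMatrix,
    contrasts: Sequence[tuple[str, str]] | None = None,
    dispersion: float | str = "auto",
) -> pd.DataFrame:
    """Exact tests for every (default: all unordered) stage pair, long form."""
    if contrasts is None:
        contrasts = list(combinations(matrix.sheet.stages, 2))
    if dispersion == "auto":
        dispersion = estimate_common_dispersion(matrix)
    rows = []
    for a, b in contrasts:
        for r in exact_test_pair(matrix, a, b, dispersion=dispersion):
            rows.append(
                {
                    "mirna": r.mirna,
                    "stage_a": a,
                    "stage_b": b,
                    "log2_fold_change": r.log2_fold_change,
                    "p_value": r.p_value,
                    "fdr": r.fdr,
                    "significant": r.significant,
                }
            )
    return pd.DataFrame(rows)


def log2_ratio_matrix(
    matrix: CountMatrix,
    contrasts: Sequence[tuple[str, str]] | None = None,
    pseudo_count: float = 0.5,
) -> pd.DataFrame:
    """log2 of stage-mean cpm ratios for each contrast (heatmap input).

    Stage means use the available replicates only, so a missing library
    simply shrinks its stage's denominator.
    """
    if contrasts is None:
        contrasts = list(combinations(matrix.sheet.stages, 2))
    c = cpm(matrix)
    stage_means = {
        s: c[matrix.columns_for_stage(s)].mean(axis=1) for s in matrix.sheet.stages
    }
    out = {}
    for a, b in contrasts:
        out[f"{a}/{b}"] = np.log2(
            (stage_means[a] + pseudo_count) / (stage_means[b] + pseudo_count)
        )
    return pd.DataFrame(out)


def hierarchical_cluster(
    ratio_matrix: pd.DataFrame, method: str = "complete", metric: str = "euclidean"
) -> tuple[list[str], np.ndarray]:
    """Agglomerative clustering of rows; returns (leaf order, linkage)."""
    if len(ratio_matrix) < 2:
        raise ValueError("need at least two rows to cluster")
    Z = hierarchy.linkage(ratio_matrix.to_numpy(), method=method, metric=metric)
    order = hierarchy.leaves_list(Z)
    return [ratio_matrix.index[i] for i in order], Z


def spearman_matrix(
    cpm_a: pd.DataFrame,
    cpm_b: pd.DataFrame,
    orthologs: Iterable,
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Spearman rho between every library pair across species, over orthologs.

    ``orthologs`` yields objects with ``species_a_id`` / ``species_b_id`` (or
    plain (a, b) tuples) indexing rows of the two cpm tables.  Cells with
    fewer than ``min_pairs`` informative ortholog pairs report NaN rho with
    ``defined`` False.
    """
    pairs = []
    for o in orthologs:
        a, b = (o.species_a_id, o.species_b_id) if hasattr(o, "species_a_id") else o
        if a in cpm_a.index and b in cpm_b.index:
            pairs.append((a, b))
    rows = []
    for col_a in cpm_a.columns:
        for col_b in cpm_b.columns:
            xs, ys = [], []
            for a, b in pairs:
                va, vb = cpm_a.at[a, col_a], cpm_b.at[b, col_b]
                if np.isfinite(va) and np.isfinite(vb):
                    xs.append(va)
                    ys.append(vb)
            if len(xs) < min_pairs:
                rows.append(
                    dict(library_a=col_a, library_b=col_b, rho=np.nan,
                         p_value=np.nan, n_pairs=len(xs), defined=False)
                )
                continue
            rho, p = stats.spearmanr(xs, ys)
            rows.append(
                dict(library_a=col_a, library_b=col_b, rho=float(rho),
                     p_value=float(p), n_pairs=len(xs), defined=True)
            )
    return pd.DataFrame(rows)
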