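"""TRAP/qPCR statistics: reference-gene stability, dCT/ddCT, enrichment tests.

The workflow mirrors standard relative-quantification practice.  Technical
replicates are averaged per sample.  Candidate reference (housekeeping) genes
are ranked by four stability measures — a NormFinder-style model-based
variance decomposition, a geNorm-style pairwise M value, the raw CT standard
deviation, and the comparative-dCt mean pairwise SD — and the ranks are
aggregated by geometric mean.  Among the top-ranked candidates the selected
*pair* is the one whose signed intergroup differences best cancel
("countervailing" pair), so the pair mean is maximally robust to the
experimental contrast.  Target genes are normalized to the arithmetic mean of
the pair (dCT), group contrasts use the ddCT method with first-order error
propagation, and the pair itself is sanity-checked via its group expression
ratio and signed fold change.

All hypothesis tests run on dCT values: a Welch two-sample t per contrast, a
one-sample t against 0 for cell-marker enrichment (affinity-purified vs input
fractions), and step-down Holm–Sidak correction across each gene family.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "aggregate_replicates",
    "stability_model_based",
    "stability_pairwise_m",
    "stability_raw_sd",
    "stability_comparative_dct",
    "stability_aggregate",
    "select_pair",
    "pair_group_ratio",
    "fold_change_convert",
    "delta_ct",
    "ddct_fold_change",
    "ddct_from_summary",
    "FoldChangeResult",
    "enrichment_vs_input",
    "group_test",
    "holm_sidak",
    "ReferenceGeneSelector",
]

GROUPS = ("sleep", "SD")


# ---------------------------------------------------------------------------
# replicate aggregation and pivoting
# ---------------------------------------------------------------------------

def aggregate_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates to one row per gene x sample.

    Returns columns gene, sample, group, region, fraction, CT (replicate
    mean), ct_sd (replicate sample SD, a QC column; NaN for single
    replicates), n_replicates.
    """
    required = {"gene", "sample", "CT"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"CT table lacks columns {sorted(missing)}")
    keys = [c for c in ("gene", "sample", "group", "region", "fraction")
            if c in table.columns]
    out = (
        table.groupby(keys, as_index=False, sort=False)
        .agg(CT=("CT", "mean"), ct_sd=("CT", "std"), n_replicates=("CT", "size"))
    )
    return out


def _ct_matrix(agg: pd.DataFrame, genes: list[str]) -> tuple[pd.DataFrame, pd.Series]:
    """Pivot to genes x samples; return matrix and per-sample group labels."""
    sub = agg[agg["gene"].isin(genes)]
    mat = sub.pivot_table(index="gene", columns="sample", values="CT")
    mat = mat.reindex(index=genes)
    if mat.isna().any().any():
        missing = mat.columns[mat.isna().any(axis=0)].tolist()
        raise ValueError(f"samples with missing candidate genes: {missing}")
    groups = sub.drop_duplicates("sample").set_index("sample")["group"]
    return mat, groups.reindex(mat.columns)


def _maybe_aggregate(table: pd.DataFrame) -> pd.DataFrame:
    if "replicate" in table.columns:
        return aggregate_replicates(table)
    return table


# ---------------------------------------------------------------------------
# stability measures
# ---------------------------------------------------------------------------

def stability_model_based(
    table: pd.DataFrame, candidate_genes: list[str]
) -> pd.DataFrame:
    """Model-based (NormFinder-style) stability per candidate gene.

    Within each group the gene x sample CT matrix is decomposed two-way:
    residuals after removing gene means and per-sample loadings estimate the
    intragroup variance (bias-corrected for the rank lost to centering), and
    the gene-by-group interaction of group means gives the intergroup
    difference d_gj (a gene's group shift relative to the average candidate).
    The combined stability value is mean_j(|d_gj| + sigma_gj / sqrt(n_j));
    lower is more stable.  The signed column ``intergroup_diff`` is
    d_g,SD - d_g,sleep (cycles): a countervailing pair has opposite signs.
    """
    if len(candidate_genes) < 3:
        raise ValueError("model-based decomposition needs >= 3 candidate genes")
    agg = _maybe_aggregate(table)
    mat, groups = _ct_matrix(agg, list(candidate_genes))
    uniq = [g for g in GROUPS if g in set(groups)] or sorted(set(groups))
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")

    G = len(candidate_genes)
    group_means = {}
    intra_var = {}
    n_per_group = {}
    for grp in uniq:
        cols = groups.index[groups == grp]
        if len(cols) < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 samples")
        sub = mat[cols].to_numpy(dtype=float)  # G x n
        n = sub.shape[1]
        n_per_group[grp] = n
        gene_mean = sub.mean(axis=1, keepdims=True)
        sample_mean = sub.mean(axis=0, keepdims=True)
        resid = sub - gene_mean - sample_mean + sub.mean()
        # E[sum resid^2 per gene] = sigma^2 (n-1)(G-1)/G for homoscedastic noise
        ss = (resid**2).sum(axis=1)
        intra_var[grp] = ss * G / ((n - 1) * (G - 1))
        group_means[grp] = gene_mean.ravel()

    # gene x group interaction of (sample-loading-free) group means
    gm = np.column_stack([group_means[g] for g in uniq])      # G x K
    gm = gm - gm.mean(axis=0, keepdims=True)                  # centre across genes
    inter = gm - gm.mean(axis=1, keepdims=True)               # centre across groups
    d = {grp: inter[:, k] for k, grp in enumerate(uniq)}

    stability = np.zeros(G)
    for grp in uniq:
        stability += np.abs(d[grp]) + np.sqrt(intra_var[grp] / n_per_group[grp])
    stability /= len(uniq)

    out = pd.DataFrame(index=pd.Index(candidate_genes, name="gene"))
    out["intragroup_var"] = np.mean([intra_var[g] for g in uniq], axis=0)
    for grp in uniq:
        out[f"intergroup_diff_{grp}"] = d[grp]
    if set(GROUPS) <= set(uniq):
        out["intergroup_diff"] = d["SD"] - d["sleep"]
    else:
        out["intergroup_diff"] = d[uniq[-1]] - d[uniq[0]]
    out["stability"] = stability
    return out


def stability_pairwise_m(
    table: pd.DataFrame, candidate_genes: list[str]
) -> pd.Series:
    """geNorm-style M value: mean over other genes of SD of pairwise log ratios.

    M_g = mean_h SD_samples(CT_g - CT_h); invariant to per-gene constant
    shifts.  Lower is more stable.
    """
    if len(candidate_genes) < 2:
        raise ValueError("pairwise M needs >= 2 candidate genes")
    agg = _maybe_aggregate(table)
    mat, _ = _ct_matrix(agg, list(candidate_genes))
    arr = mat.to_numpy(dtype=float)
    G = arr.shape[0]
    m = np.zeros(G)
    for i in range(G):
        sds = [np.std(arr[i] - arr[j], ddof=1) for j in range(G) if j != i]
        m[i] = float(np.mean(sds))
    return pd.Series(m, index=pd.Index(candidate_genes, name="gene"), name="M")


def stability_raw_sd(table: pd.DataFrame, candidate_genes: list[str]) -> pd.Series:
    """BestKeeper-style raw variability: SD of per-sample CT across all samples."""
    agg = _maybe_aggregate(table)
    mat, _ = _ct_matrix(agg, list(candidate_genes))
    sd = mat.std(axis=1, ddof=1)
    sd.name = "raw_sd"
    return sd


def stability_comparative_dct(
    table: pd.DataFrame, candidate_genes: list[str]
) -> pd.Series:
    """Comparative-dCt stability: mean SD of a gene's pairwise CT differences.

    Shares its computational core with the pairwise M value (no iterative
    exclusion); kept as a distinct rank column of the four-method aggregate.
    """
    s = stability_pairwise_m(table, candidate_genes)
    s.name = "comparative_dct"
    return s


def stability_aggregate(ranks: pd.DataFrame) -> pd.Series:
    """Aggregate per-method ranks by geometric mean (RefFinder-style).

    ``ranks`` has one column per method, genes on the index; the first column
    breaks ties.  Returns the aggregated rank (1 = most stable).
    """
    if ranks.shape[1] < 2:
        raise ValueError("need >= 2 method rank columns")
    geo = np.exp(np.log(ranks.to_numpy(dtype=float)).mean(axis=1))
    order = pd.DataFrame(
        {"geo": geo, "tie": ranks.iloc[:, 0].to_numpy()}, index=ranks.index
    )
    agg = order.sort_values(["geo", "tie"]).assign(rank=np.arange(1, len(order) + 1))
    return agg["rank"].reindex(ranks.index).rename("aggregated_rank")


def select_pair(
    stability: pd.DataFrame, top_k: int = 4
) -> tuple[str, str]:
    """Pick the countervailing housekeeping pair among top-ranked candidates.

    ``stability`` needs columns ``aggregated_rank``, ``intergroup_diff`` and
    ``stability``.  Among the ``top_k`` genes by aggregated rank, the pair
    minimizing |d1 + d2| (sum of signed intergroup differences) wins; ties
    are broken by the summed model-based stability values.
    """
    top = stability.sort_values("aggregated_rank").head(top_k)
    if len(top) < 2:
        raise ValueError("fewer than 2 candidates within top-k aggregated ranks")
    best = None
    for a, b in itertools.combinations(top.index, 2):
        cancel = abs(top.loc[a, "intergroup_diff"] + top.loc[b, "intergroup_diff"])
        tiebreak = top.loc[a, "stability"] + top.loc[b, "stability"]
        key = (round(cancel, 12), tiebreak)
        if best is None or key < best[0]:
            best = (key, (a, b))
    return best[1]


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------

def fold_change_convert(ratio: float) -> float:
    """Convert an expression ratio to a signed fold change.

    F = ratio if ratio >= 1 else -1/ratio, so |F| >= 1 and F < 0 means a
    decrease.  Antisymmetric under inversion: F(1/r) = -F(r) for r != 1.
    Report tables round to 2 decimals.
    """
    if not ratio > 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    return float(ratio) if ratio >= 1 else float(-1.0 / ratio)


def pair_group_ratio(
    table: pd.DataFrame,
    pair: tuple[str, str],
    contrast: tuple[str, str] = GROUPS,
) -> tuple[float, float]:
    """Group expression ratio of a housekeeping pair and its signed fold change.

    Per sample the pair expression is 2**(-mean CT over the two genes); the
    ratio is the second group's mean expression over the first's (SD / sleep
    by default).  Samples missing either gene are dropped with a warning.
    """
    agg = _maybe_aggregate(table)
    sub = agg[agg["gene"].isin(pair)]
    wide = sub.pivot_table(index="sample", columns="gene", values="CT")
    incomplete = wide.index[wide.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(f"dropping samples missing a pair gene: {list(incomplete)}")
        wide = wide.dropna()
    groups = sub.drop_duplicates("sample").set_index("sample")["group"]
    expr = np.power(2.0, -wide.mean(axis=1))
    ref, test = contrast
    mean_ref = expr[groups.reindex(expr.index) == ref].mean()
    mean_test = expr[groups.reindex(expr.index) == test].mean()
    if not (mean_ref > 0):
        raise ValueError(f"group {ref!r} has no usable samples")
    ratio = float(mean_test / mean_ref)
    return ratio, fold_change_convert(ratio)


def delta_ct(
    table: pd.DataFrame,
    pair: tuple[str, str],
    targets: list[str] | None = None,
) -> pd.DataFrame:
    """dCT per sample and target gene: CT_target - mean(CT of the pair).

    Samples missing a housekeeping value are dropped with a warning.  Adding a
    per-sample constant to every gene leaves dCT unchanged.
    """
    agg = _maybe_aggregate(table)
    hk = agg[agg["gene"].isin(pair)].pivot_table(
        index="sample", columns="gene", values="CT"
    )
    incomplete = hk.index[hk.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(f"dropping samples missing housekeeping CT: {list(incomplete)}")
        hk = hk.dropna()
    hk_mean = hk.mean(axis=1)
    tgt = agg[~agg["gene"].isin(pair)]
    if targets is not None:
        tgt = tgt[tgt["gene"].isin(targets)]
    tgt = tgt[tgt["sample"].isin(hk_mean.index)].copy()
    tgt["dCT"] = tgt["CT"].to_numpy() - hk_mean.reindex(tgt["sample"]).to_numpy()
    keep = [c for c in ("gene", "sample", "group", "region", "fraction", "dCT")
            if c in tgt.columns]
    return tgt[keep].reset_index(drop=True)


@dataclass(frozen=True)
class FoldChangeResult:
    """ddCT contrast with first-order error propagation.

    ``ddct`` = mean dCT(SD) - mean dCT(sleep) in cycles; ``log2_fc`` = -ddct;
    ``ratio`` = 2**(-ddct); ``fold_change`` is the signed convention (|F|>=1).
    ``se`` is the root-sum-square of the two group SEMs, in cycles — on the
    log2 scale it applies directly to log2_fc.
    """

    ddct: float
    se: float
    log2_fc: float
    ratio: float
    fold_change: float
    n_sleep: int | None = None
    n_sd: int | None = None


def ddct_from_summary(
    mean_sleep: float, sem_sleep: float, mean_sd: float, sem_sd: float,
    n_sleep: int | None = None, n_sd: int | None = None,
) -> FoldChangeResult:
    """ddCT fold change from group summary statistics (mean dCT +- SEM)."""
    ddct = mean_sd - mean_sleep
    se = float(np.hypot(sem_sleep, sem_sd))
    ratio = float(2.0 ** (-ddct))
    return FoldChangeResult(
        ddct=float(ddct), se=se, log2_fc=float(-ddct), ratio=ratio,
        fold_change=fold_change_convert(ratio), n_sleep=n_sleep, n_sd=n_sd,
    )


def ddct_fold_change(
    dct_sleep: np.ndarray, dct_sd: np.ndarray
) -> FoldChangeResult:
    """ddCT fold change from per-sample dCT values of the two groups."""
    a = np.asarray(dct_sleep, dtype=float)
    b = np.asarray(dct_sd, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 samples per group")
    return ddct_from_summary(
        a.mean(), a.std(ddof=1) / np.sqrt(len(a)),
        b.mean(), b.std(ddof=1) / np.sqrt(len(b)),
        n_sleep=len(a), n_sd=len(b),
    )


# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------

def enrichment_vs_input(
    dct_ip: pd.Series | np.ndarray,
    dct_input: pd.Series | np.ndarray,
) -> dict:
    """Cell-marker enrichment of the affinity-purified fraction versus input.

    Per biological sample the log2 enrichment is dCT_input - dCT_ip (positive
    = enriched on purified ribosomes).  Unpaired samples (NaN on either side)
    are dropped with a warning.  Returns the mean log2 enrichment, its SEM,
    and a one-sample t against 0 (df = n - 1, two-sided).  If every
    enrichment is identical the t statistic is reported as 0 with p = 1
    (documented degenerate-variance convention).
    """
    ip = pd.Series(np.asarray(dct_ip, dtype=float))
    inp = pd.Series(np.asarray(dct_input, dtype=float))
    if len(ip) != len(inp):
        raise ValueError("IP and Input must be paired per sample")
    enrich = (inp - ip).to_numpy()
    if np.isnan(enrich).any():
        warnings.warn("dropping unpaired samples with missing values")
        enrich = enrich[~np.isnan(enrich)]
    n = len(enrich)
    if n < 2:
        raise ValueError("need >= 2 paired samples")
    mean = float(enrich.mean())
    sem = float(enrich.std(ddof=1) / np.sqrt(n))
    if sem == 0.0:
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_1samp(enrich, 0.0)
    return {
        "log2_enrichment": mean, "se": sem, "t": float(t),
        "df": n - 1, "p": float(p), "n": n,
    }


def group_test(
    dct_a: np.ndarray, dct_b: np.ndarray
) -> tuple[float, float, float]:
    """Welch two-sample t on dCT values: (t, df, two-sided p).

    A documented approximation of the published post hoc framework.  If both
    groups are exactly constant the degenerate branch reports p = 1 for equal
    means and p = 0 otherwise.
    """
    a = np.asarray(dct_a, dtype=float)
    b = np.asarray(dct_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 samples per group")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        equal = np.isclose(a.mean(), b.mean())
        return (0.0 if equal else np.inf), float(len(a) + len(b) - 2), (1.0 if equal else 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    df = getattr(res, "df", np.nan)
    return float(res.statistic), float(df), float(res.pvalue)


def holm_sidak(
    p_values: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Holm–Sidak adjustment: (adjusted p, reject flags).

    Sorted ascending, adjusted p_i = max_{j<=i} 1 - (1 - p_(j))**(m - j + 1),
    clipped to 1 and mapped back to input order; monotone in the raw p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1D array")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    with np.errstate(divide="ignore"):  # p = 1 hits log1p(-1) internally
        reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm-sidak")
    return p_adj, reject


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class ReferenceGeneSelector(BaseEstimator):
    """Select a countervailing housekeeping pair and normalize targets by it.

    Parameters
    ----------
    candidate_genes : list of str
        Reference-gene candidates to rank.
    top_k : int, default 4
        Pair is chosen among the ``top_k`` genes by aggregated rank.

    Fitted attributes
    -----------------
    stability_ : DataFrame
        Per-gene intragroup variance, signed intergroup differences, the four
        stability values, per-method ranks and the aggregated rank.
    selected_pair_ : (str, str)
    pair_ratio_, pair_fold_change_ : float
        Final check of the selected pair: its SD/sleep expression ratio and
        signed fold change (should be near 1).
    """

    def __init__(self, candidate_genes: list[str] | None = None, top_k: int = 4):
        self.candidate_genes = candidate_genes
        self.top_k = top_k

    def fit(self, X: pd.DataFrame, y=None) -> "ReferenceGeneSelector":
        if self.candidate_genes is None or len(self.candidate_genes) < 3:
            raise ValueError("candidate_genes must list >= 3 genes")
        genes = list(self.candidate_genes)
        agg = _maybe_aggregate(X)

        model = stability_model_based(agg, genes)
        m = stability_pairwise_m(agg, genes)
        raw = stability_raw_sd(agg, genes)
        comp = stability_comparative_dct(agg, genes)

        report = model.copy()
        report["M"] = m
        report["raw_sd"] = raw
        report["comparative_dct"] = comp
        ranks = pd.DataFrame(
            {
                "rank_model": report["stability"].rank(method="min"),
                "rank_M": report["M"].rank(method="min"),
                "rank_raw_sd": report["raw_sd"].rank(method="min"),
                "rank_comparative": report["comparative_dct"].rank(method="min"),
            }
        )
        report = pd.concat([report, ranks], axis=1)
        report["aggregated_rank"] = stability_aggregate(ranks)

        self.stability_ = report
        self.selected_pair_ = select_pair(report, top_k=self.top_k)
        self.pair_ratio_, self.pair_fold_change_ = pair_group_ratio(
            agg, self.selected_pair_
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Return the dCT table of target genes normalized to the fitted pair."""
        if not hasattr(self, "selected_pair_"):
            raise RuntimeError("fit the selector before calling transform")
        return delta_ct(X, self.selected_pair_)

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)
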