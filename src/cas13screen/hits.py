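"""Gene-level hit calling for pooled knockdown screens.

The scheme follows the published negative-binomial + robust rank
aggregation approach used for pooled CRISPR screens: a mean-variance
relationship sigma^2 = mu + exp(a) * mu^b is fitted on baseline
replicates; each guide's treatment count sum is tested against the
baseline-derived null in both tails; guides are ranked per direction and
genes scored with alpha-RRA (minimum beta order-statistic CDF over guides
ranked in the top alpha fraction); gene p-values come from permutation of
normalized ranks, FDR from Benjamini-Hochberg, and genes pass at
FDR <= 0.3 as positive (enriched: knockdown increased proliferation) or
negative (depleted) hits. Equivalence with any particular external
implementation is not a goal; calibration is established by simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counts import median_ratio_normalize

GENE_COLUMNS = [
    "gene_id",
    "n_guides",
    "gene_lfc",
    "rra_score_pos",
    "p_pos",
    "fdr_pos",
    "rra_score_neg",
    "p_neg",
    "fdr_neg",
    "hit_class",
    "ambiguous",
]


@dataclass(frozen=True)
class TestConfig:
    alpha: float = 0.25
    n_perm: int = 10_000
    fdr_threshold: float = 0.3
    lfc_min: float = 0.1
    p_max: float = 0.05
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")


@dataclass(frozen=True)
class MeanVarModel:
    """sigma^2(mu) = mu + exp(a) * mu^b, never below the Poisson floor."""

    a: float
    b: float

    def variance(self, mu) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        return mu + np.exp(self.a) * np.power(mu, self.b)


def fit_mean_variance(baseline: pd.DataFrame) -> MeanVarModel:
    """Fit the overdispersion term on normalized baseline replicates.

    Least squares of log(max(var - mean, 0.01)) on log(mean) over guides
    with positive mean; requires >= 2 replicates and >= 50 usable guides.
    """
    if baseline.shape[1] < 2:
        raise ValueError("need >= 2 baseline replicates to estimate variance")
    values = baseline.to_numpy(dtype=float)
    mu = values.mean(axis=1)
    s2 = values.var(axis=1, ddof=1)
    usable = mu > 0
    if usable.sum() < 50:
        raise ValueError(f"only {int(usable.sum())} guides with positive mean; need >= 50")
    x = np.log(mu[usable])
    y = np.log(np.maximum(s2[usable] - mu[usable], 0.01))
    b, a = np.polyfit(x, y, 1)
    return MeanVarModel(a=float(a), b=float(b))


def nb_guide_test(mu, x, n_treat: int, model: MeanVarModel):
    """Two one-sided tail probabilities for a guide's treatment count sum.

    X is negative binomial with mean n_treat * mu and variance
    n_treat * sigma^2(mu), falling back to Poisson when the modeled
    variance does not exceed the mean. Returns (p_low, p_high) =
    (P(X <= x), P(X >= x)); accepts scalars or aligned arrays.
    """
    mu = np.asarray(mu, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("nb_guide_test requires mu > 0; exclude zero-mean guides")
    m = n_treat * mu
    v = n_treat * model.variance(mu)
    lo = np.floor(x)
    hi_edge = np.ceil(x) - 1.0  # P(X >= x) = sf(ceil(x) - 1)
    overdispersed = v > m
    p_low = np.empty_like(m)
    p_high = np.empty_like(m)
    pois = ~overdispersed
    if pois.any():
        p_low[pois] = stats.poisson.cdf(lo[pois], m[pois])
        p_high[pois] = stats.poisson.sf(hi_edge[pois], m[pois])
    if overdispersed.any():
        mm, vv = m[overdispersed], v[overdispersed]
        r = mm * mm / (vv - mm)
        p = r / (r + mm)
        p_low[overdispersed] = stats.nbinom.cdf(lo[overdispersed], r, p)
        p_high[overdispersed] = stats.nbinom.sf(hi_edge[overdispersed], r, p)
    p_low = np.clip(p_low, np.finfo(float).tiny, 1.0)
    p_high = np.clip(p_high, np.finfo(float).tiny, 1.0)
    if p_low.ndim == 0:
        return float(p_low), float(p_high)
    return p_low, p_high


def alpha_rra_gene_score(rhos, alpha: float = 0.25) -> float:
    """alpha-RRA score of one gene from its guides' normalized ranks.

    With the gene's n_g normalized ranks sorted ascending and restricted to
    rho <= alpha, the score is min over j of BetaCDF(rho_(j); j, n_g-j+1) —
    the probability that the j-th of n_g uniform order statistics is this
    small. Genes with no guide in the top alpha fraction score 1.
    """
    rho = np.sort(np.asarray(rhos, dtype=float))
    if rho.size == 0:
        raise ValueError("gene has no guides")
    if (rho <= 0).any() or (rho > 1).any():
        raise ValueError("normalized ranks must lie in (0, 1]")
    n_g = rho.size
    keep = rho <= alpha
    if not keep.any():
        return 1.0
    j = np.arange(1, n_g + 1)[keep]
    return float(stats.beta.cdf(rho[keep], j, n_g - j + 1).min())


def _rra_scores_matrix(rho: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorized alpha-RRA over rows of a (n, n_g) rank matrix."""
    r = np.sort(rho, axis=1)
    n_g = r.shape[1]
    j = np.arange(1, n_g + 1)
    cdf = stats.beta.cdf(r, j, n_g - j + 1)
    cdf = np.where(r <= alpha, cdf, np.inf)
    s = cdf.min(axis=1)
    return np.where(np.isfinite(s), s, 1.0)


def _sample_without_replacement(
    rng: np.random.Generator, m: int, n_g: int, n_perm: int
) -> np.ndarray:
    """(n_perm, n_g) index rows, each a without-replacement draw from 0..m-1."""
    if n_g > m:
        raise ValueError("cannot draw more ranks than the pool holds")
    out = rng.integers(0, m, size=(n_perm, n_g))
    while True:
        srt = np.sort(out, axis=1)
        bad = (np.diff(srt, axis=1) == 0).any(axis=1)
        if not bad.any():
            return out
        out[bad] = rng.integers(0, m, size=(int(bad.sum()), n_g))


def permutation_pvalues(
    observed: pd.Series,
    n_guides: pd.Series,
    rank_pool: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 1,
    alpha: float = 0.25,
) -> pd.Series:
    """Permutation p-values for gene alpha-RRA scores.

    For every distinct guide count n_g, n_perm sets of n_g normalized ranks
    are drawn without replacement from the observed rank pool and rescored;
    p = (1 + #{permuted <= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    pool = np.asarray(rank_pool, dtype=float)
    m = pool.size
    pvals = pd.Series(index=observed.index, dtype=float, name="p")
    for n_g in sorted(n_guides.unique()):
        idx = _sample_without_replacement(rng, m, int(n_g), n_perm)
        perm_scores = np.sort(_rra_scores_matrix(pool[idx], alpha))
        genes = n_guides.index[n_guides == n_g]
        obs = observed[genes].to_numpy()
        n_le = np.searchsorted(perm_scores, obs, side="right")
        pvals[genes] = (1.0 + n_le) / (n_perm + 1.0)
    return pvals


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [p, 1])."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def guide_statistics(
    counts: pd.DataFrame,
    library: pd.DataFrame,
    baseline: list[str],
    treat: list[str],
) -> tuple[pd.DataFrame, MeanVarModel]:
    """Normalize, fit the variance model and test every guide.

    Returns the guide table (crRNA_id, gene_id, base_mean, lfc, p_low,
    p_high, tested flag) plus the fitted model. Guides with zero baseline
    mean are excluded from testing but kept flagged.
    """
    missing = set(baseline + treat) - set(counts.columns)
    if missing:
        raise KeyError(f"samples absent from count matrix: {sorted(missing)}")
    normalized, _ = median_ratio_normalize(counts[baseline + treat])
    base = normalized[baseline]
    trt = normalized[treat]
    model = fit_mean_variance(base)
    mu = base.mean(axis=1)
    lfc = np.log2((trt.mean(axis=1) + 1.0) / (mu + 1.0))
    tested = mu > 0
    p_low = pd.Series(np.nan, index=counts.index)
    p_high = pd.Series(np.nan, index=counts.index)
    if tested.any():
        pl, ph = nb_guide_test(
            mu[tested].to_numpy(), trt.loc[tested].sum(axis=1).to_numpy(), len(treat), model
        )
        p_low[tested] = pl
        p_high[tested] = ph
    gene_map = library.set_index("crRNA_id")["gene_id"]
    out = pd.DataFrame(
        {
            "crRNA_id": counts.index,
            "gene_id": gene_map.reindex(counts.index).to_numpy(),
            "base_mean": mu.to_numpy(),
            "lfc": lfc.to_numpy(),
            "p_low": p_low.to_numpy(),
            "p_high": p_high.to_numpy(),
            "tested": tested.to_numpy(),
        }
    )
    if out["gene_id"].isna().any():
        raise ValueError("count matrix contains guides absent from the library")
    return out.reset_index(drop=True), model


def _normalized_ranks(guide_stats: pd.DataFrame, p_column: str) -> pd.Series:
    """Stable rank/m in (0, 1], ordered by (p, crRNA_id)."""
    tested = guide_stats[guide_stats["tested"]]
    ordered = tested.sort_values([p_column, "crRNA_id"], kind="mergesort")
    m = len(ordered)
    rho = pd.Series(np.arange(1, m + 1) / m, index=ordered["crRNA_id"])
    return rho


def test_screen(
    counts: pd.DataFrame,
    library: pd.DataFrame,
    baseline: list[str],
    treat: list[str],
    config: TestConfig = TestConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full guide- and gene-level screen test.

    Returns (guide table, gene table). The gene table carries alpha-RRA
    scores, permutation p-values and BH FDRs in both directions, the median
    guide log2 fold-change, and the hit class at the configured FDR.
    """
    guide_df, _ = guide_statistics(counts, library, baseline, treat)
    tested = guide_df[guide_df["tested"]]
    if tested.empty:
        raise ValueError("no guide could be tested (all baseline means are zero)")

    gene_rows: dict[str, dict] = {}
    direction_specs = {"pos": "p_high", "neg": "p_low"}
    rng_seeds = {"pos": config.seed, "neg": config.seed + 1}
    gene_sizes = tested.groupby("gene_id").size()
    for direction, p_col in direction_specs.items():
        rho = _normalized_ranks(guide_df, p_col)
        by_gene = tested.set_index("crRNA_id").join(rho.rename("rho"))
        scores = by_gene.groupby("gene_id")["rho"].apply(
            lambda r: alpha_rra_gene_score(r.to_numpy(), config.alpha)
        )
        pvals = permutation_pvalues(
            scores,
            gene_sizes,
            rho.to_numpy(),
            n_perm=config.n_perm,
            seed=rng_seeds[direction],
            alpha=config.alpha,
        )
        fdr = pd.Series(bh_adjust(pvals.to_numpy()), index=pvals.index)
        for gene in scores.index:
            row = gene_rows.setdefault(gene, {"gene_id": gene})
            row[f"rra_score_{direction}"] = scores[gene]
            row[f"p_{direction}"] = pvals[gene]
            row[f"fdr_{direction}"] = fdr[gene]

    gene_lfc = tested.groupby("gene_id")["lfc"].median()
    for gene, row in gene_rows.items():
        row["n_guides"] = int(gene_sizes[gene])
        row["gene_lfc"] = float(gene_lfc[gene])
    gene_df = pd.DataFrame(sorted(gene_rows.values(), key=lambda r: r["gene_id"]))
    gene_df = call_hits(gene_df, config.fdr_threshold)
    return guide_df, gene_df[GENE_COLUMNS]


def call_hits(gene_results: pd.DataFrame, fdr_threshold: float = 0.3) -> pd.DataFrame:
    """Classify genes at the FDR threshold.

    Positive if fdr_pos passes, negative if fdr_neg passes; when both pass
    the direction with the smaller permutation p wins and the gene is
    flagged ambiguous.
    """
    out = gene_results.copy()
    pos = out["fdr_pos"] <= fdr_threshold
    neg = out["fdr_neg"] <= fdr_threshold
    both = pos & neg
    hit_class = np.where(pos, "positive", np.where(neg, "negative", "none"))
    hit_class[both.to_numpy()] = np.where(
        out.loc[both, "p_pos"] <= out.loc[both, "p_neg"], "positive", "negative"
    )
    out["hit_class"] = hit_class
    out["ambiguous"] = both.to_numpy()
    return out


def flag_guides(
    guide_stats: pd.DataFrame, lfc_min: float = 0.1, p_max: float = 0.05
) -> pd.DataFrame:
    """Flag differentially represented guides (volcano-plot rule).

    Enriched when lfc > lfc_min with p_high < p_max; depleted when
    lfc < -lfc_min with p_low < p_max.
    """
    out = guide_stats.copy()
    enriched = (out["lfc"] > lfc_min) & (out["p_high"] < p_max)
    depleted = (out["lfc"] < -lfc_min) & (out["p_low"] < p_max)
    out["flag"] = np.select([enriched.fillna(False), depleted.fillna(False)],
                            ["enriched", "depleted"], default="none")
    return out


@dataclass
class RerunResult:
    initial_genes: pd.DataFrame
    filtered_genes: pd.DataFrame
    changed: pd.DataFrame  # genes whose hit_class differs between runs
    dropped_genes: list[str]  # genes that lost every guide to the filter


def rerun_after_filter(
    counts: pd.DataFrame,
    library: pd.DataFrame,
    removals: list[str],
    baseline: list[str],
    treat: list[str],
    config: TestConfig = TestConfig(),
) -> RerunResult:
    """Call hits before and after off-target removal and diff the calls."""
    removals = list(removals)
    unknown = set(removals) - set(library["crRNA_id"])
    if unknown:
        raise ValueError(f"removals not in library: {sorted(unknown)[:5]}")
    _, initial = test_screen(counts, library, baseline, treat, config)
    lib_f = library[~library["crRNA_id"].isin(removals)]
    counts_f = counts.loc[counts.index.difference(pd.Index(removals), sort=False)]
    before_genes = set(library["gene_id"])
    after_genes = set(lib_f["gene_id"])
    dropped = sorted(before_genes - after_genes)
    _, filtered = test_screen(counts_f, lib_f, baseline, treat, config)
    merged = initial.merge(filtered, on="gene_id", suffixes=("_initial", "_filtered"))
    changed = merged[merged["hit_class_initial"] != merged["hit_class_filtered"]][
        ["gene_id", "hit_class_initial", "hit_class_filtered"]
    ]
    return RerunResult(
        initial_genes=initial,
        filtered_genes=filtered,
        changed=changed.reset_index(drop=True),
        dropped_genes=dropped,
    )
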