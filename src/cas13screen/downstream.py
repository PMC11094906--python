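"""Downstream analyses: RNA half-life fits and pull-down enrichment.

Half-life: after transcription is blocked, first-order decay gives
ln(abundance) = c - k*t, so ordinary least squares of log abundance on
time (free intercept) estimates the decay constant and t_1/2 = ln(2)/k.
Allele-specific series are fitted separately and compared as a ratio.

Pull-down: per protein, a two-sided one-sample t-test of the replicate
log2 enrichment ratios against 0; proteins pass with >= 5 identified
peptides, mean log2 fold-change > 2 and p < 0.05, and passers are ranked
by mean fold-change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MIN_PEPTIDES = 5
LOG2FC_CUTOFF = 2.0
P_CUTOFF = 0.05


@dataclass(frozen=True)
class DecayFit:
    allele: str
    k_decay: float  # per hour; -slope of ln(abundance) vs t
    t_half: float  # ln(2)/k_decay, hours; inf when non-decaying
    r_squared: float
    n_points: int
    decaying: bool


def fit_decay(t_hours, rel_abundance, allele: str = "") -> DecayFit:
    """Log-linear decay fit: OLS of ln(abundance) on time, free intercept."""
    t = np.asarray(t_hours, dtype=float)
    y = np.asarray(rel_abundance, dtype=float)
    if t.size != y.size or t.size < 3:
        raise ValueError("need >= 3 (time, abundance) pairs")
    if (y <= 0).any():
        raise ValueError("abundances must be positive (log-linear fit)")
    fit = stats.linregress(t, np.log(y))
    k = -float(fit.slope)
    decaying = k > 0
    t_half = math.log(2.0) / k if decaying else math.inf
    return DecayFit(
        allele=allele,
        k_decay=k,
        t_half=t_half,
        r_squared=float(fit.rvalue**2),
        n_points=int(t.size),
        decaying=decaying,
    )


def fit_decay_table(table: pd.DataFrame) -> dict[str, DecayFit]:
    """Fit each allele's series from a (allele, t_hours, rel_abundance) table."""
    return {
        allele: fit_decay(g["t_hours"], g["rel_abundance"], allele)
        for allele, g in table.groupby("allele", sort=True)
    }


def compare_alleles(fit_risk: DecayFit, fit_protective: DecayFit) -> dict:
    """Half-life ratio risk/protective plus its log2."""
    for fit in (fit_risk, fit_protective):
        if not fit.decaying:
            raise ValueError(f"allele {fit.allele or '?'} is non-decaying; ratio undefined")
    ratio = fit_risk.t_half / fit_protective.t_half
    return {
        "ratio": ratio,
        "log2_ratio": math.log2(ratio),
        "risk": fit_risk,
        "protective": fit_protective,
    }


def rank_pulldown(table: pd.DataFrame) -> pd.DataFrame:
    """Filter and rank pull-down proteins by replicate enrichment.

    Expects columns protein, n_peptides and rep1..repN log2 ratios over the
    control pull-down. Zero-variance replicates with nonzero mean get a
    machine-floor p and a flag. Passers are ranked 1..k by mean log2
    fold-change descending; non-passers have rank <NA>.
    """
    rep_cols = [c for c in table.columns if c.startswith("rep")]
    if len(rep_cols) < 2:
        raise ValueError("need >= 2 replicate ratio columns")
    if (table["n_peptides"] < 0).any():
        raise ValueError("peptide counts must be >= 0")
    ratios = table[rep_cols].to_numpy(dtype=float)
    mean_lfc = ratios.mean(axis=1)
    sd = ratios.std(axis=1, ddof=1)
    degenerate = (sd == 0) & (mean_lfc != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p_value = stats.ttest_1samp(ratios, 0.0, axis=1)
    t_stat = np.where(degenerate, np.sign(mean_lfc) * np.inf, t_stat)
    p_value = np.where(degenerate, np.finfo(float).tiny, p_value)
    out = table[["protein", "n_peptides"]].copy()
    for c in rep_cols:
        out[c] = table[c]
    out["mean_log2fc"] = mean_lfc
    out["t_stat"] = t_stat
    out["p_value"] = p_value
    out["zero_variance"] = degenerate
    out["passes_filters"] = (
        (out["n_peptides"] >= MIN_PEPTIDES)
        & (out["mean_log2fc"] > LOG2FC_CUTOFF)
        & (out["p_value"] < P_CUTOFF)
    )
    out = out.sort_values(
        ["passes_filters", "mean_log2fc"], ascending=[False, False], kind="mergesort"
    ).reset_index(drop=True)
    rank = pd.array([pd.NA] * len(out), dtype="Int64")
    n_pass = int(out["passes_filters"].sum())
    rank[:n_pass] = np.arange(1, n_pass + 1)
    out["rank"] = rank
    return out
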