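"""Guide quantification from reads and screen library QC.

Counting is exact-match: each read is anchored at the first occurrence of
the 5' flank, the following spacer-length bases are extracted and matched
literally against the library (mismatched reads add noise downstream if
rescued, so they are discarded and tallied instead). QC mirrors the two
metrics screens are judged by — the Gini index of count evenness and
pairwise replicate correlation — plus DESeq-style median-of-ratios
normalization used before testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import numpy as np
import pandas as pd

from .core import FlankConfig


@dataclass
class QCReport:
    gini_per_sample: dict[str, float]
    correlations: dict[str, float]  # "s1|s2" -> Pearson r on log2(count+1)
    min_correlation: float
    total_reads: dict[str, int] = field(default_factory=dict)
    match_rate: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "gini_per_sample": self.gini_per_sample,
            "correlations": self.correlations,
            "min_correlation": self.min_correlation,
            "total_reads": self.total_reads,
            "match_rate": self.match_rate,
        }


def count_reads(
    reads: Iterable[tuple[str, str, str]],
    library: pd.DataFrame,
    flanks: FlankConfig = FlankConfig(),
) -> tuple[pd.Series, float, dict[str, int]]:
    """Count exact spacer occurrences anchored at the 5' flank.

    ``reads`` are (read_id, sequence, quality) tuples as returned by
    :func:`cas13screen.io.read_fastq`. Returns (per-guide counts in library
    order, match rate, discard tally by reason). Reads lacking the flank,
    truncated before a full spacer, or carrying an unknown/mismatched
    spacer are discarded.
    """
    if not flanks.flank5:
        raise ValueError("flank5 must be non-empty to anchor reads")
    spacers = library["spacer_seq"]
    if spacers.duplicated().any():
        raise ValueError("library spacers must be unique for exact-match counting")
    spacer_len = spacers.str.len()
    if spacer_len.nunique() != 1:
        raise ValueError("library spacers must share one length")
    L = int(spacer_len.iloc[0])
    lookup = dict(zip(spacers, library["crRNA_id"]))
    counts = dict.fromkeys(library["crRNA_id"], 0)
    tally = {"no_flank": 0, "truncated": 0, "unknown_spacer": 0}
    total = 0
    for _, seq, _ in reads:
        total += 1
        pos = seq.find(flanks.flank5)
        if pos < 0:
            tally["no_flank"] += 1
            continue
        start = pos + len(flanks.flank5)
        spacer = seq[start : start + L]
        if len(spacer) < L:
            tally["truncated"] += 1
            continue
        guide = lookup.get(spacer)
        if guide is None:
            tally["unknown_spacer"] += 1
            continue
        counts[guide] += 1
    if total == 0:
        warnings.warn("empty FASTQ input; returning a zero count column")
        return pd.Series(counts, name="count"), 0.0, tally
    assigned = total - sum(tally.values())
    return pd.Series(counts, name="count"), assigned / total, tally


def gini(counts) -> float:
    """Gini index of a non-negative count vector.

    G = (2 * sum_i i*x_(i)) / (n * sum x) - (n + 1)/n with x sorted
    ascending and i = 1..n; equivalently the mean absolute pairwise
    difference divided by twice the mean. 0 for perfectly even counts,
    bounded above by 1 - 1/n.
    """
    x = np.sort(np.asarray(counts, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 entries")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("Gini undefined for an all-zero vector")
    i = np.arange(1, n + 1)
    return float(2.0 * (i * x).sum() / (n * total) - (n + 1) / n)


def replicate_correlation(
    matrix: pd.DataFrame, samples: list[str] | None = None
) -> tuple[dict[str, float], float]:
    """Pairwise Pearson correlations on log2(count + 1).

    Returns (pair -> r, minimum over defined pairs). Pairs involving a
    zero-variance sample are reported as NaN and excluded from the minimum.
    """
    cols = samples if samples is not None else list(matrix.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 samples")
    log = np.log2(matrix[cols].to_numpy(dtype=float) + 1.0)
    out: dict[str, float] = {}
    defined = []
    for (i, a), (j, b) in combinations(enumerate(cols), 2):
        xi, xj = log[:, i], log[:, j]
        if xi.std() == 0 or xj.std() == 0:
            out[f"{a}|{b}"] = float("nan")
            continue
        r = float(np.corrcoef(xi, xj)[0, 1])
        out[f"{a}|{b}"] = r
        defined.append(r)
    if not defined:
        raise ValueError("no sample pair had positive variance")
    return out, min(defined)


def median_ratio_normalize(
    matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios size factors (DESeq-style) and normalized counts.

    The reference per guide is its geometric mean across samples, computed
    over guides with nonzero counts in every sample; each sample's size
    factor is the median ratio to that reference, rescaled so the factors
    have geometric mean 1 (which makes the operation exactly idempotent:
    renormalizing a normalized matrix returns unit factors).
    """
    values = matrix.to_numpy(dtype=float)
    everywhere = (values > 0).all(axis=1)
    if not everywhere.any():
        raise ValueError(
            "no guide has nonzero counts in every sample; add a pseudocount upstream"
        )
    sub = values[everywhere]
    geo = np.exp(np.log(sub).mean(axis=1))
    medians = np.median(sub / geo[:, None], axis=0)
    factors = medians / np.exp(np.log(medians).mean())
    size_factors = pd.Series(factors, index=matrix.columns, name="size_factor")
    normalized = matrix / size_factors
    return normalized, size_factors


def qc_report(
    matrix: pd.DataFrame,
    replicate_groups: dict[str, list[str]] | None = None,
    total_reads: dict[str, int] | None = None,
    match_rate: dict[str, float] | None = None,
) -> QCReport:
    """Per-sample Gini plus within-group replicate correlations."""
    ginis = {s: gini(matrix[s].to_numpy()) for s in matrix.columns}
    groups = replicate_groups or {"all": list(matrix.columns)}
    correlations: dict[str, float] = {}
    minima = []
    for members in groups.values():
        if len(members) < 2:
            continue
        pair_r, min_r = replicate_correlation(matrix, members)
        correlations.update(pair_r)
        minima.append(min_r)
    return QCReport(
        gini_per_sample=ginis,
        correlations=correlations,
        min_correlation=min(minima) if minima else float("nan"),
        total_reads=total_reads or {},
        match_rate=match_rate or {},
    )
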