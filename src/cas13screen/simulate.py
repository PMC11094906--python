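"""Synthetic inputs for every stage of the screen pipeline.

The generators emulate the data a pooled Cas13d proliferation screen
produces — a transcriptome with scored guide candidates, guide counts at
library transduction and after three weeks of growth, reads carrying the
guide cassette, actinomycin-D RNA decay series and pull-down enrichment
tables — with known ground truth so recovery can be tested end to end.

Every generator is deterministic given its parameters and seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CountMatrix, FlankConfig, rng_from_seed

CANDIDATE_COLUMNS = ["transcript_id", "gene_id", "start", "length", "target_site_seq", "quality_score"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# transcriptome + guide candidates
# ---------------------------------------------------------------------------

def simulate_transcriptome(
    n_transcripts: int,
    length_range: tuple[int, int] = (200, 2000),
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Uniform-random ACGT transcripts plus one full-extent interval each.

    Returns (sequences keyed by transcript id, interval table with BED-style
    chrom/start/end/name columns where name is the owning gene id). Each
    transcript belongs to its own gene. Sequences are checked for
    collisions, which at these lengths occur with negligible probability.
    """
    lo, hi = length_range
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    if lo < 100 or hi < lo:
        raise ValueError(f"invalid length range {length_range}; lengths must be >= 100 and lo <= hi")
    rng = rng_from_seed(seed)
    width = max(4, len(str(n_transcripts)))
    seqs: dict[str, str] = {}
    rows = []
    seen: set[str] = set()
    for i in range(n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(_BASES, size=length).tobytes().decode()
        if seq in seen:
            raise RuntimeError("random transcript collision; widen the length range")
        seen.add(seq)
        tx = f"TX{i:0{width}d}"
        gene = f"GENE{i:0{width}d}"
        seqs[tx] = seq
        rows.append((tx, 0, length, gene))
    intervals = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return seqs, intervals


def simulate_guide_scores(
    references: Mapping[str, str],
    guide_length: int = 23,
    seed: int = 0,
    gene_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Score every possible guide position on every transcript.

    Stands in for an external guide-quality predictor: one candidate per
    0-based start position 0..len-L, with quality_score drawn i.i.d.
    Uniform(0, 1). Transcripts shorter than the guide are skipped with a
    warning.
    """
    rng = rng_from_seed(seed)
    frames = []
    for tx, seq in references.items():
        n_pos = len(seq) - guide_length + 1
        if n_pos < 1:
            warnings.warn(f"transcript {tx} shorter than guide length {guide_length}; skipped")
            continue
        gene = gene_map[tx] if gene_map is not None else tx.replace("TX", "GENE", 1)
        starts = np.arange(n_pos)
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": tx,
                    "gene_id": gene,
                    "start": starts,
                    "length": guide_length,
                    "target_site_seq": [seq[s : s + guide_length] for s in starts],
                    "quality_score": rng.uniform(0.0, 1.0, size=n_pos),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=CANDIDATE_COLUMNS)
    return pd.concat(frames, ignore_index=True)[CANDIDATE_COLUMNS]


# ---------------------------------------------------------------------------
# pooled screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimParams:
    """Geometry and generative parameters of a simulated pooled screen.

    Defaults are a 1:100 desk-scale version of the screen layout (200
    genes x 10 guides sequenced to 2e5 reads instead of 18,248 guides at
    20 M reads); ``sigma_lib`` is the standard deviation of natural-log
    baseline guide abundance, ``effect_size`` the gene-level total |log2
    fold-change| delta, and guide efficacy is Beta(efficacy_alpha,
    efficacy_beta) so realized guide effects are efficacy * delta.
    """

    n_genes: int = 200
    guides_per_gene: int = 10
    n_replicates: int = 3
    coverage: int = 1000
    depth: int = 200_000
    sigma_lib: float = 0.15
    frac_positive: float = 0.1
    frac_negative: float = 0.1
    effect_size: float = 2.0
    efficacy_alpha: float = 5.0
    efficacy_beta: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "guides_per_gene", "n_replicates", "coverage", "depth"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("frac_positive", "frac_negative"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_positive + self.frac_negative > 1.0:
            raise ValueError("frac_positive + frac_negative must be <= 1")
        if self.depth < self.n_genes * self.guides_per_gene:
            raise ValueError("depth must be >= n_genes * guides_per_gene")
        if self.sigma_lib < 0:
            raise ValueError("sigma_lib must be >= 0")
        if self.efficacy_alpha <= 0 or self.efficacy_beta <= 0:
            raise ValueError("efficacy shape parameters must be > 0")


@dataclass
class ScreenTruth:
    """Ground truth attached to a simulated screen."""

    gene_class: pd.Series  # gene_id -> {'positive', 'negative', 'null'}
    gene_effect: pd.Series  # gene_id -> signed delta (log2 units)
    guide_efficacy: pd.Series  # crRNA_id -> u in [0, 1]
    guide_lfc: pd.Series  # crRNA_id -> realized u * delta

    def positives(self) -> list[str]:
        return list(self.gene_class.index[self.gene_class == "positive"])

    def negatives(self) -> list[str]:
        return list(self.gene_class.index[self.gene_class == "negative"])


def simulate_baseline_abundance(
    n_guides: int, sigma_lib: float, rng: np.random.Generator
) -> np.ndarray:
    """Natural-log baseline abundance a_i ~ Normal(0, sigma_lib^2)."""
    return rng.normal(0.0, sigma_lib, size=n_guides)


def sample_counts(
    proportions: np.ndarray, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """One sequencing sample: Multinomial(depth, proportions)."""
    p = np.asarray(proportions, dtype=float)
    p = p / p.sum()
    return rng.multinomial(depth, p)


def simulate_baseline_counts(
    n_guides: int,
    sigma_lib: float,
    depth: int,
    n_replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Baseline sequencing replicates sharing one true abundance vector.

    Replicates share the log-normal abundance draw (the same plasmid pool
    is sequenced) but are independent multinomial samples of ``depth``
    reads. Returns a guides x replicates integer DataFrame.
    """
    if depth < n_guides:
        raise ValueError("depth must be >= number of guides")
    rng = rng_from_seed(seed)
    a = simulate_baseline_abundance(n_guides, sigma_lib, rng)
    p = np.exp(a)
    cols = {f"base_r{r + 1}": sample_counts(p, depth, rng) for r in range(n_replicates)}
    idx = [f"g{i + 1:05d}" for i in range(n_guides)]
    return pd.DataFrame(cols, index=idx)


def _assign_gene_classes(
    genes: Sequence[str], params: ScreenSimParams, rng: np.random.Generator
) -> pd.Series:
    """Exact-count class assignment by the configured fractions."""
    n = len(genes)
    n_pos = int(round(params.frac_positive * n))
    n_neg = int(round(params.frac_negative * n))
    order = rng.permutation(n)
    classes = np.array(["null"] * n, dtype=object)
    classes[order[:n_pos]] = "positive"
    classes[order[n_pos : n_pos + n_neg]] = "negative"
    return pd.Series(classes, index=pd.Index(genes, name="gene_id"), name="class")


def simulate_screen(
    params: ScreenSimParams, library: pd.DataFrame
) -> tuple[CountMatrix, ScreenTruth]:
    """Simulate baseline and final guide counts for a crRNA library.

    Generative model: baseline natural-log abundance a_i ~ N(0,
    sigma_lib^2) shared by all samples; each non-control gene is assigned a
    class (positive/negative/null by the configured fractions) with signed
    effect delta_g = +/- effect_size; guide efficacy u_i ~
    Beta(efficacy_alpha, efficacy_beta); final expected proportions are
    proportional to exp(a_i) * 2^(u_i * delta_g). Baseline replicates are
    independent Multinomial(depth) draws from the shared pool. Each final
    replicate first samples the surviving cell population
    (Multinomial(coverage * n_guides) — the transduction bottleneck) and
    then sequences it (Multinomial(depth)).

    Control guides (is_control) always have a null effect.
    """
    if library.empty:
        raise ValueError("library is empty")
    if params.depth < len(library):
        raise ValueError("depth must be >= number of guides in the library")
    rng = np.random.default_rng(params.seed)
    lib = library.reset_index(drop=True)
    guide_ids = lib["crRNA_id"].to_numpy()
    gene_ids = lib["gene_id"].to_numpy()
    genes = pd.unique(gene_ids)
    is_control = (
        lib["is_control"].to_numpy(dtype=bool)
        if "is_control" in lib.columns
        else np.zeros(len(lib), dtype=bool)
    )
    control_genes = set(gene_ids[is_control])
    target_genes = [g for g in genes if g not in control_genes]

    classes = _assign_gene_classes(target_genes, params, rng)
    classes = pd.concat(
        [classes, pd.Series("null", index=pd.Index(sorted(control_genes), name="gene_id"))]
    ) if control_genes else classes
    delta = classes.map({"positive": params.effect_size, "negative": -params.effect_size, "null": 0.0})
    delta.name = "delta"

    n_guides = len(lib)
    a = simulate_baseline_abundance(n_guides, params.sigma_lib, rng)
    efficacy = rng.beta(params.efficacy_alpha, params.efficacy_beta, size=n_guides)
    guide_delta = delta.reindex(gene_ids).to_numpy()
    guide_lfc = efficacy * guide_delta

    p_base = np.exp(a)
    p_final = p_base * np.exp2(guide_lfc)

    counts: dict[str, np.ndarray] = {}
    meta = []
    for r in range(params.n_replicates):
        sid = f"base_r{r + 1}"
        counts[sid] = sample_counts(p_base, params.depth, rng)
        meta.append((sid, r + 1, "baseline"))
    n_cells = params.coverage * n_guides
    for r in range(params.n_replicates):
        sid = f"final_r{r + 1}"
        cells = sample_counts(p_final, n_cells, rng)
        counts[sid] = sample_counts(cells.astype(float), params.depth, rng)
        meta.append((sid, r + 1, "final"))

    counts_df = pd.DataFrame(counts, index=pd.Index(guide_ids, name="crRNA_id"))
    guides_df = lib[["crRNA_id", "gene_id"]].copy()
    guides_df["is_control"] = is_control
    samples_df = pd.DataFrame(meta, columns=["sample_id", "replicate", "timepoint"])
    truth = ScreenTruth(
        gene_class=classes,
        gene_effect=delta,
        guide_efficacy=pd.Series(efficacy, index=guide_ids, name="efficacy"),
        guide_lfc=pd.Series(guide_lfc, index=guide_ids, name="true_lfc"),
    )
    return CountMatrix(counts=counts_df, guides=guides_df, samples=samples_df), truth


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_fastq(
    counts: pd.Series,
    library: pd.DataFrame,
    flanks: FlankConfig = FlankConfig(),
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Emit exactly count_i reads per guide: flank5 + spacer + flank3.

    Reads are deterministically shuffled; quality is the constant 'I'
    (Q40). Returns (read_id, sequence, quality) tuples ready for
    :func:`cas13screen.io.write_fastq`.
    """
    if not flanks.flank5 or not flanks.flank3:
        raise ValueError("flank sequences must be non-empty")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    spacer = library.set_index("crRNA_id")["spacer_seq"]
    missing = counts.index.difference(spacer.index)
    if len(missing):
        raise KeyError(f"guides absent from library: {list(missing)[:5]}")
    rng = rng_from_seed(seed)
    seqs: list[str] = []
    for guide_id, n in counts.items():
        read = flanks.flank5 + spacer[guide_id] + flanks.flank3
        seqs.extend([read] * int(n))
    order = rng.permutation(len(seqs))
    qual_cache: dict[int, str] = {}
    out = []
    for i, j in enumerate(order):
        seq = seqs[j]
        qual = qual_cache.setdefault(len(seq), "I" * len(seq))
        out.append((f"read{i + 1:07d}", seq, qual))
    return out


# ---------------------------------------------------------------------------
# RNA decay
# ---------------------------------------------------------------------------

@dataclass
class DecaySimParams:
    """Allele-specific first-order RNA decay after transcription block.

    Default half-lives are 11 h (protective haplotype) and 6 h (risk
    haplotype); sampling times follow the actinomycin-D harvest schedule.
    ``noise_sd`` is the SD of multiplicative log-normal measurement noise.
    """

    half_life_hours: Mapping[str, float] = field(
        default_factory=lambda: {"protective": 11.0, "risk": 6.0}
    )
    timepoints: Sequence[float] = (0.0, 3.0, 4.0, 8.0, 12.0)
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.half_life_hours:
            raise ValueError("at least one allele half-life is required")
        if any(h <= 0 for h in self.half_life_hours.values()):
            raise ValueError("half-lives must be > 0")
        t = list(self.timepoints)
        if t[0] != 0 or any(b <= a for a, b in zip(t, t[1:])) or any(x < 0 for x in t):
            raise ValueError("timepoints must be non-negative, strictly increasing and start at 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_decay(params: DecaySimParams) -> pd.DataFrame:
    """Exponential decay series: abundance(t) = exp(-ln2 * t / t_half) * noise."""
    rng = rng_from_seed(params.seed)
    rows = []
    t = np.asarray(list(params.timepoints), dtype=float)
    for allele, half_life in params.half_life_hours.items():
        k = math.log(2.0) / half_life
        eps = rng.normal(0.0, params.noise_sd, size=len(t)) if params.noise_sd > 0 else np.zeros(len(t))
        abundance = np.exp(-k * t) * np.exp(eps)
        for ti, ab in zip(t, abundance):
            rows.append((allele, ti, ab))
    return pd.DataFrame(rows, columns=["allele", "t_hours", "rel_abundance"])


# ---------------------------------------------------------------------------
# RNA pull-down
# ---------------------------------------------------------------------------

def simulate_pulldown(
    n_proteins: int,
    n_enriched: int,
    enrich_log2fc: float = 3.0,
    noise_sd: float = 0.5,
    n_replicates: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-protein replicate log2 enrichment ratios over a control pull-down.

    Enriched proteins have mean log2 ratio ``enrich_log2fc``; the rest are
    centred at 0. Peptide counts are uniform on 1..30, with enriched
    proteins forced to have at least 5 (so the peptide filter does not mask
    the planted signal). A ``true_enriched`` truth column is included.
    """
    if n_enriched > n_proteins:
        raise ValueError("n_enriched must be <= n_proteins")
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates")
    rng = rng_from_seed(seed)
    enriched = np.zeros(n_proteins, dtype=bool)
    enriched[rng.choice(n_proteins, size=n_enriched, replace=False)] = True
    mu = np.where(enriched, enrich_log2fc, 0.0)
    ratios = rng.normal(mu[:, None], noise_sd, size=(n_proteins, n_replicates))
    peptides = rng.integers(1, 31, size=n_proteins)
    peptides[enriched] = rng.integers(5, 31, size=int(enriched.sum()))
    df = pd.DataFrame(
        {"protein": [f"P{i + 1:04d}" for i in range(n_proteins)], "n_peptides": peptides}
    )
    for r in range(n_replicates):
        df[f"rep{r + 1}"] = ratios[:, r]
    df["true_enriched"] = enriched
    return df
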