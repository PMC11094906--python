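"""crRNA library design: staged guide selection with quality relaxation.

Selection runs per transcript in up to three stages. The strict stage
greedily picks non-overlapping top-quartile candidates in score order, up
to ten per transcript. Transcripts left with fewer than five guides relax
first the quality bar (third quartile allowed, still non-overlapping) and
then the overlap bar (pairwise overlap up to 10 nt). The library table
then collapses duplicate spacers within a gene, drops spacers shared
between genes, and adds the synthesis flanks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import read_tsv, write_tsv

LIBRARY_COLUMNS = [
    "crRNA_id",
    "gene_id",
    "transcript_id",
    "spacer_seq",
    "oligo_seq",
    "is_control",
    "design_stage",
    "below_minimum",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DesignConfig:
    """Tunables of the staged selection.

    ``relax_overlap_max_nt`` reads the tolerated "5-10 nt overlap" band as
    its upper bound. ``emit_spacer_revcomp`` switches the emitted spacer
    from the target-site (protospacer) sequence to its reverse complement
    (the actual crRNA spacer); the default emits the target site.
    """

    target_per_transcript: int = 10
    min_guides: int = 5
    relax_quartile_min: int = 3
    relax_overlap_max_nt: int = 10
    guide_length: int = 23
    flank5: str = ""
    flank3: str = ""
    emit_spacer_revcomp: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.min_guides <= self.target_per_transcript:
            raise ValueError("need 1 <= min_guides <= target_per_transcript")
        if self.relax_overlap_max_nt >= self.guide_length:
            raise ValueError("relax_overlap_max_nt must be < guide_length")


def assign_quartiles(candidates: pd.DataFrame) -> pd.DataFrame:
    """Label one transcript's candidates with score quartiles (4 = top).

    Boundaries are the linear-interpolation 25/50/75th percentiles of the
    transcript's own scores; ties at a boundary resolve upward (quartile 4
    is score >= the 75th percentile). With fewer than four candidates every
    candidate is labelled quartile 4.
    """
    if candidates.empty:
        raise ValueError("no candidates")
    if candidates["transcript_id"].nunique() > 1:
        raise ValueError("assign_quartiles operates on a single transcript")
    scores = candidates["quality_score"].to_numpy(dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("non-finite quality score")
    out = candidates.copy()
    if len(scores) < 4:
        out["quartile"] = 4
        return out
    q25, q50, q75 = np.percentile(scores, [25, 50, 75])
    quart = np.select(
        [scores >= q75, scores >= q50, scores >= q25], [4, 3, 2], default=1
    )
    out["quartile"] = quart
    return out


def _greedy_pick(
    candidates: pd.DataFrame, max_overlap: int, cap: int, guide_length: int
) -> pd.DataFrame:
    """Greedy interval selection in (score desc, start asc, seq) order.

    A candidate is accepted iff its [start, start+L) interval overlaps every
    already-accepted interval by at most ``max_overlap`` nt (0 = disjoint).
    """
    ordered = candidates.sort_values(
        ["quality_score", "start", "target_site_seq"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    accepted: list[int] = []
    starts: list[int] = []
    for idx, start in zip(ordered.index, ordered["start"]):
        ok = True
        for s in starts:
            overlap = min(start, s) + guide_length - max(start, s)
            if overlap > max_overlap:
                ok = False
                break
        if ok:
            accepted.append(idx)
            starts.append(int(start))
            if len(accepted) >= cap:
                break
    return candidates.loc[accepted]


def select_guides_for_transcript(
    candidates: pd.DataFrame, config: DesignConfig = DesignConfig()
) -> tuple[pd.DataFrame, str, bool]:
    """Staged greedy selection for a single transcript.

    Returns (selected candidates, design stage, below_minimum flag). Stages:
    strict (quartile 4, disjoint), relaxed_q3 (quartile >= 3, disjoint),
    relaxed_overlap (quartile >= 3, pairwise overlap <= the configured
    band). The first stage reaching ``min_guides`` wins; if none does, the
    most permissive stage's result is returned flagged below_minimum.
    """
    if candidates.empty:
        raise ValueError("no candidates for transcript")
    if "quartile" not in candidates.columns:
        candidates = assign_quartiles(candidates)
    L = config.guide_length
    stages = [
        ("strict", candidates[candidates["quartile"] == 4], 0),
        ("relaxed_q3", candidates[candidates["quartile"] >= config.relax_quartile_min], 0),
        (
            "relaxed_overlap",
            candidates[candidates["quartile"] >= config.relax_quartile_min],
            config.relax_overlap_max_nt,
        ),
    ]
    result = None
    for stage, pool, max_overlap in stages:
        picked = _greedy_pick(pool, max_overlap, config.target_per_transcript, L)
        result = (picked, stage)
        if len(picked) >= config.min_guides:
            return picked, stage, False
    picked, stage = result
    return picked, stage, True


def design_library(
    candidates: pd.DataFrame,
    controls: list[str] | set[str] | None = None,
    config: DesignConfig = DesignConfig(),
) -> pd.DataFrame:
    """Run staged selection over all transcripts and emit the library table.

    Redundancy removal: identical spacers selected from two transcripts of
    the same gene collapse to a single record; a spacer arising in two
    different genes is ambiguous and removed entirely. crRNA ids are
    gene_id underscore rank, ranked by score within the gene.
    """
    if candidates.empty:
        raise ValueError("candidate table is empty")
    controls = set(controls or ())
    rows = []
    for tx, group in candidates.groupby("transcript_id", sort=True):
        try:
            labelled = assign_quartiles(group)
            picked, stage, below = select_guides_for_transcript(labelled, config)
        except ValueError as exc:
            warnings.warn(f"transcript {tx} skipped: {exc}")
            continue
        for _, cand in picked.iterrows():
            rows.append(
                {
                    "gene_id": cand["gene_id"],
                    "transcript_id": tx,
                    "target_site_seq": cand["target_site_seq"],
                    "quality_score": cand["quality_score"],
                    "design_stage": stage,
                    "below_minimum": below,
                }
            )
    if not rows:
        raise ValueError("no transcript yielded any guide")
    df = pd.DataFrame(rows)

    # same-gene duplicates collapse (keep best score); cross-gene duplicates drop
    df = (
        df.sort_values(["quality_score"], ascending=False, kind="mergesort")
        .drop_duplicates(subset=["gene_id", "target_site_seq"], keep="first")
    )
    genes_per_spacer = df.groupby("target_site_seq")["gene_id"].transform("nunique")
    df = df[genes_per_spacer == 1].copy()

    spacer = df["target_site_seq"].map(reverse_complement) if config.emit_spacer_revcomp else df["target_site_seq"]
    df["spacer_seq"] = spacer
    df["oligo_seq"] = config.flank5 + df["spacer_seq"] + config.flank3
    df["is_control"] = df["gene_id"].isin(controls)

    df = df.sort_values(
        ["gene_id", "quality_score", "spacer_seq"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    rank = df.groupby("gene_id").cumcount() + 1
    df["crRNA_id"] = df["gene_id"] + "_" + rank.astype(str)
    if df["crRNA_id"].duplicated().any():
        raise RuntimeError("crRNA_id collision; gene ids must not contain rank suffixes")
    return df[LIBRARY_COLUMNS]


def write_library_table(records: pd.DataFrame, path) -> None:
    """Serialize the library with stable (gene, rank) row order."""
    if records.empty:
        raise ValueError("refusing to write an empty library table")
    write_tsv(records[LIBRARY_COLUMNS], path)


def read_library_table(path) -> pd.DataFrame:
    df = read_tsv(path, dtype={"crRNA_id": str, "gene_id": str, "transcript_id": str})
    missing = set(LIBRARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"library table missing columns: {sorted(missing)}")
    return df[LIBRARY_COLUMNS]


def summarize_library(library: pd.DataFrame) -> dict[str, int]:
    """Bookkeeping tallies of a library table: crRNAs and target genes."""
    non_control = library[~library["is_control"].astype(bool)]
    return {
        "n_crRNAs": int(len(library)),
        "n_genes": int(library["gene_id"].nunique()),
        "n_target_genes": int(non_control["gene_id"].nunique()),
        "n_control_genes": int(library.loc[library["is_control"].astype(bool), "gene_id"].nunique()),
    }
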