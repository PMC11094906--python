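"""Mismatch-tolerant off-target search for crRNA spacers.

A guide is considered to have an off-target when a contiguous stretch of
it — at least 90% of its length (>= 21 nt of a 23-mer) — matches a
reference region outside its own gene with at most two mismatches,
ungapped. Matching happens in target-site sequence space; genomic
references are scanned on both strands, transcriptome references forward
only (Cas13d binds the sense transcript).

Two search paths are provided: :func:`brute_force_scan` enumerates every
(guide substring, reference window, strand) placement and is the testing
oracle; :func:`scan_offtargets` reaches the same hit set through exact
k-mer seeding (pigeonhole: a >= 21 nt placement with <= 2 mismatches
always contains an exact 7-mer) followed by Hamming verification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import reverse_complement

HIT_COLUMNS = [
    "crRNA_id",
    "ref_id",
    "strand",
    "ref_start",
    "guide_offset",
    "aligned_length",
    "mismatches",
    "coverage",
]


@dataclass(frozen=True)
class ScanConfig:
    """Off-target matching thresholds.

    ``seed_kmer_length`` of None derives the largest pigeonhole-safe seed,
    floor(ceil(min_coverage * L) / (max_mismatches + 1)), per guide length.
    """

    max_mismatches: int = 2
    min_coverage: float = 0.90
    scan_both_strands: bool = True
    seed_kmer_length: int | None = None

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if not 0.0 < self.min_coverage <= 1.0:
            raise ValueError("min_coverage must lie in (0, 1]")

    def min_aligned_length(self, guide_length: int) -> int:
        return math.ceil(self.min_coverage * guide_length)

    def kmer_length(self, guide_length: int) -> int:
        k_max = self.min_aligned_length(guide_length) // (self.max_mismatches + 1)
        k = self.seed_kmer_length if self.seed_kmer_length is not None else k_max
        if not 1 <= k <= k_max:
            raise ValueError(
                f"seed_kmer_length {k} violates the pigeonhole bound (must be in 1..{k_max})"
            )
        return k


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _own_intervals(annotation: pd.DataFrame, gene_id: str) -> pd.DataFrame:
    return annotation[annotation["name"] == gene_id]

def _overlaps_own_gene(own: pd.DataFrame, ref_id: str, start: int, end: int) -> bool:
    if own.empty:
        return False
    sel = own[own["chrom"] == ref_id]
    return bool(((sel["start"] < end) & (sel["end"] > start)).any())


def _finalize(
    placements: list[tuple[str, str, int, int, int, int]],
    guide_id: str,
    guide_length: int,
    own: pd.DataFrame,
) -> list[dict]:
    """Self-exclusion, then collapse nested placements per (ref, start, strand).

    Among co-located placements the longest wins, ties broken by fewest
    mismatches then smallest guide offset.
    """
    best: dict[tuple[str, str, int], tuple[int, int, int]] = {}
    for ref_id, strand, ref_start, offset, length, mm in placements:
        if _overlaps_own_gene(own, ref_id, ref_start, ref_start + length):
            continue
        key = (ref_id, strand, ref_start)
        cand = (-length, mm, offset)
        if key not in best or cand < best[key]:
            best[key] = cand
    hits = []
    for (ref_id, strand, ref_start), (neg_len, mm, offset) in sorted(best.items()):
        length = -neg_len
        hits.append(
            {
                "crRNA_id": guide_id,
                "ref_id": ref_id,
                "strand": strand,
                "ref_start": ref_start,
                "guide_offset": offset,
                "aligned_length": length,
                "mismatches": mm,
                "coverage": length / guide_length,
            }
        )
    return hits


def _strand_views(seq: str, config: ScanConfig) -> list[tuple[str, np.ndarray]]:
    views = [("+", _encode(seq))]
    if config.scan_both_strands:
        views.append(("-", _encode(reverse_complement(seq))))
    return views


def _plus_coord(strand: str, pos: int, length: int, ref_len: int) -> int:
    """Map a window start on the scanned orientation to + strand coordinates."""
    return pos if strand == "+" else ref_len - pos - length


def brute_force_scan(
    guide_seq: str,
    guide_id: str,
    gene_id: str,
    references: dict[str, str],
    annotation: pd.DataFrame,
    config: ScanConfig = ScanConfig(),
) -> pd.DataFrame:
    """Exhaustive placement enumeration (test oracle).

    Every guide substring of length >= ceil(min_coverage * L) is slid over
    every reference window on each scanned strand; placements with Hamming
    distance <= max_mismatches survive, minus those inside the guide's own
    gene intervals, collapsed per (ref, start, strand).
    """
    L = len(guide_seq)
    min_len = config.min_aligned_length(L)
    pad = L - min_len
    guide_arr = _encode(guide_seq)
    placements = []
    for ref_id, ref_seq in references.items():
        n = len(ref_seq)
        if n < min_len:
            continue
        for strand, ref_arr in _strand_views(ref_seq, config):
            # One full-guide window comparison per diagonal; cumulative sums
            # then yield the mismatch count of every (offset, length)
            # sub-placement, so all placements are still enumerated. The
            # zero-byte padding lets partial placements hang off either end
            # of the reference (validity is enforced on the coordinates).
            padded = np.concatenate(
                [np.zeros(pad, np.uint8), ref_arr, np.zeros(pad, np.uint8)]
            )
            if len(padded) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(padded, L)
            mism = windows != guide_arr
            cum = np.zeros((mism.shape[0], L + 1), dtype=np.int16)
            np.cumsum(mism, axis=1, out=cum[:, 1:])
            diagonals = np.arange(mism.shape[0]) - pad
            for length in range(min_len, L + 1):
                for offset in range(0, L - length + 1):
                    mm = cum[:, offset + length] - cum[:, offset]
                    starts = diagonals + offset
                    ok = (mm <= config.max_mismatches) & (starts >= 0) & (starts + length <= n)
                    for row in np.flatnonzero(ok):
                        start = _plus_coord(strand, int(starts[row]), length, n)
                        placements.append(
                            (ref_id, strand, start, offset, length, int(mm[row]))
                        )
    return pd.DataFrame(
        _finalize(placements, guide_id, L, _own_intervals(annotation, gene_id)),
        columns=HIT_COLUMNS,
    )


def _kmer_index(arr: np.ndarray, k: int) -> dict[bytes, list[int]]:
    index: dict[bytes, list[int]] = {}
    data = arr.tobytes()
    for i in range(len(data) - k + 1):
        index.setdefault(data[i : i + k], []).append(i)
    return index


def _diagonal_placements(
    guide_arr: np.ndarray,
    ref_arr: np.ndarray,
    diag: int,
    min_len: int,
    max_mm: int,
) -> list[tuple[int, int, int]]:
    """All qualifying (offset, length, mismatches) on one alignment diagonal."""
    L, n = len(guide_arr), len(ref_arr)
    jmin = max(0, -diag)
    jmax = min(L, n - diag)
    if jmax - jmin < min_len:
        return []
    mism = (guide_arr[jmin:jmax] != ref_arr[diag + jmin : diag + jmax]).astype(np.int32)
    cum = np.concatenate(([0], np.cumsum(mism)))
    out = []
    for offset in range(jmin, jmax - min_len + 1):
        for length in range(min_len, jmax - offset + 1):
            mm = int(cum[offset - jmin + length] - cum[offset - jmin])
            if mm <= max_mm:
                out.append((offset, length, mm))
    return out


def scan_guide(
    guide_seq: str,
    guide_id: str,
    gene_id: str,
    references: dict[str, str],
    annotation: pd.DataFrame,
    config: ScanConfig = ScanConfig(),
    indexes: dict[tuple[str, str], dict[bytes, list[int]]] | None = None,
) -> pd.DataFrame:
    """Seeded scan of one guide; equivalent to :func:`brute_force_scan`."""
    L = len(guide_seq)
    min_len = config.min_aligned_length(L)
    k = config.kmer_length(L)
    guide_arr = _encode(guide_seq)
    guide_bytes = guide_arr.tobytes()
    placements = []
    for ref_id, ref_seq in references.items():
        n = len(ref_seq)
        if n < min_len:
            continue
        for strand, ref_arr in _strand_views(ref_seq, config):
            if indexes is not None:
                index = indexes[(ref_id, strand)]
            else:
                index = _kmer_index(ref_arr, k)
            diagonals: set[int] = set()
            for q in range(0, L - k + 1):
                for pos in index.get(guide_bytes[q : q + k], ()):
                    diagonals.add(pos - q)
            for diag in sorted(diagonals):
                for offset, length, mm in _diagonal_placements(
                    guide_arr, ref_arr, diag, min_len, config.max_mismatches
                ):
                    start = _plus_coord(strand, diag + offset, length, n)
                    placements.append((ref_id, strand, start, offset, length, mm))
    return pd.DataFrame(
        _finalize(set(placements), guide_id, L, _own_intervals(annotation, gene_id)),
        columns=HIT_COLUMNS,
    )


def scan_offtargets(
    library: pd.DataFrame,
    references: dict[str, str],
    annotation: pd.DataFrame,
    config: ScanConfig = ScanConfig(),
) -> pd.DataFrame:
    """Seeded off-target scan of a whole library against the references."""
    if library.empty:
        return pd.DataFrame(columns=HIT_COLUMNS)
    indexes_by_k: dict[int, dict] = {}
    frames = []
    for _, rec in library.iterrows():
        k = config.kmer_length(len(rec["spacer_seq"]))
        if k not in indexes_by_k:
            indexes_by_k[k] = {
                (ref_id, strand): _kmer_index(arr, k)
                for ref_id, seq in references.items()
                for strand, arr in _strand_views(seq, config)
            }
        frames.append(
            scan_guide(
                rec["spacer_seq"],
                rec["crRNA_id"],
                rec["gene_id"],
                references,
                annotation,
                config,
                indexes=indexes_by_k[k],
            )
        )
    frames = [f for f in frames if not f.empty]
    if not frames:
        return pd.DataFrame(columns=HIT_COLUMNS)
    return pd.concat(frames, ignore_index=True)[HIT_COLUMNS]


def filter_library(
    library: pd.DataFrame, hits: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop every guide with at least one off-target hit.

    Returns (retained library, removal report). The report lists each
    removed guide with its hit count and its worst hit (fewest mismatches,
    then largest coverage).
    """
    if not hits.empty:
        unknown = set(hits["crRNA_id"]) - set(library["crRNA_id"])
        if unknown:
            raise ValueError(f"hits reference unknown guides: {sorted(unknown)[:5]}")
    if hits.empty:
        return library.copy(), pd.DataFrame(
            columns=["crRNA_id", "n_hits", "worst_ref_id", "worst_strand",
                     "worst_ref_start", "worst_aligned_length", "worst_mismatches",
                     "worst_coverage"]
        )
    report_rows = []
    for guide_id, group in hits.groupby("crRNA_id", sort=True):
        worst = group.sort_values(
            ["mismatches", "coverage"], ascending=[True, False], kind="mergesort"
        ).iloc[0]
        report_rows.append(
            {
                "crRNA_id": guide_id,
                "n_hits": len(group),
                "worst_ref_id": worst["ref_id"],
                "worst_strand": worst["strand"],
                "worst_ref_start": int(worst["ref_start"]),
                "worst_aligned_length": int(worst["aligned_length"]),
                "worst_mismatches": int(worst["mismatches"]),
                "worst_coverage": float(worst["coverage"]),
            }
        )
    report = pd.DataFrame(report_rows)
    removed = set(report["crRNA_id"])
    retained = library[~library["crRNA_id"].isin(removed)].copy()
    if retained.empty:
        import warnings

        warnings.warn("every guide in the library has an off-target hit")
    return retained, report
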