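"""Shared containers used across the screen pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Cas13d direct repeat placed 5' of the spacer in the expression cassette,
#: and the pol III terminator that follows it. Used as the default read
#: anchor for counting and for simulated reads.
DEFAULT_FLANK5 = "AACCCCTACCAACTGGTCGGGG"
DEFAULT_FLANK3 = "TTTTTTT"


@dataclass(frozen=True)
class FlankConfig:
    """Constant sequence surrounding the spacer in a sequencing read."""

    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3

    def __post_init__(self) -> None:
        for name in ("flank5", "flank3"):
            seq = getattr(self, name)
            if seq and set(seq) - set("ACGT"):
                raise ValueError(f"{name} must be an ACGT string, got {seq!r}")


@dataclass
class CountMatrix:
    """Guide-by-sample integer count table with axis metadata.

    ``counts`` is indexed by crRNA_id with one column per sample_id.
    ``guides`` carries crRNA_id, gene_id and is_control; ``samples`` carries
    sample_id, replicate and timepoint ('baseline' or 'final') plus optional
    per-sample match-rate metadata from read counting.
    """

    counts: pd.DataFrame
    guides: pd.DataFrame
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("count matrix contains negative entries")
        if not self.counts.index.equals(pd.Index(self.guides["crRNA_id"])):
            raise ValueError("count index does not match guide metadata")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_at(self, timepoint: str) -> list[str]:
        sel = self.samples.loc[self.samples["timepoint"] == timepoint, "sample_id"]
        return list(sel)

    def subset_guides(self, keep: pd.Index | list[str]) -> "CountMatrix":
        keep = pd.Index(keep)
        guides = self.guides[self.guides["crRNA_id"].isin(keep)].reset_index(drop=True)
        counts = self.counts.loc[guides["crRNA_id"]]
        return CountMatrix(counts=counts, guides=guides, samples=self.samples.copy())


def rng_from_seed(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
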