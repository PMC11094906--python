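import numpy as np
import pandas as pd
import pytest

_BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, n))


def mutate(rng: np.random.Generator, seq: str, positions) -> str:
    out = list(seq)
    for pos in positions:
        out[pos] = rng.choice([b for b in "ACGT" if b != out[pos]])
    return "".join(out)


def make_library(n_genes: int, guides_per_gene: int, seed: int = 0) -> pd.DataFrame:
    """A synthetic library table with unique random spacers."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_genes):
        gene = f"G{g:04d}"
        for i in range(guides_per_gene):
            rows.append((f"{gene}_{i + 1}", gene, random_seq(rng, 23), False))
    df = pd.DataFrame(rows, columns=["crRNA_id", "gene_id", "spacer_seq", "is_control"])
    assert not df["spacer_seq"].duplicated().any()
    return df


@pytest.fixture(scope="session")
def toy_transcriptome():
    from cas13screen import simulate_transcriptome

    return simulate_transcriptome(8, (300, 600), seed=11)


@pytest.fixture(scope="session")
def toy_candidates(toy_transcriptome):
    from cas13screen import simulate_guide_scores

    seqs, _ = toy_transcriptome
    return simulate_guide_scores(seqs, 23, seed=12)


@pytest.fixture(scope="session")
def toy_library(toy_candidates):
    from cas13screen import design_library

    return design_library(toy_candidates, controls=["GENE0007"])


@pytest.fixture(scope="session")
def small_screen():
    """A desk-scale simulated screen with truth, shared across tests."""
    from cas13screen import ScreenSimParams, simulate_screen

    lib = make_library(100, 10, seed=3)
    params = ScreenSimParams(
        n_genes=100, depth=100_000, coverage=300, frac_positive=0.1,
        frac_negative=0.1, effect_size=2.0, seed=7,
    )
    matrix, truth = simulate_screen(params, lib)
    return lib, matrix, truth
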