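import numpy as np
import pandas as pd
import pytest

from cisenrich.io import GenomeSequences, MotifMatrix
from cisenrich.scoring import BackgroundModel, ScoredMotif


@pytest.fixture
def uniform_bg():
    """Order-0 background with all base probabilities 0.25."""
    return BackgroundModel(order=0, cond=np.full((1, 4), 0.25),
                           marginal=np.full(4, 0.25))


@pytest.fixture
def strong_motif():
    """High-information width-6 motif with consensus ACGTAC."""
    counts = np.full((6, 4), 2.0)
    for i, b in enumerate("ACGTAC"):
        counts[i, "ACGT".index(b)] = 94.0
    return ScoredMotif.from_counts(MotifMatrix("strong", counts))


@pytest.fixture
def small_genome():
    rng = np.random.default_rng(42)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return GenomeSequences({
        "chr1": rng.choice(bases, size=10_000).tobytes().decode(),
        "chr2": rng.choice(bases, size=4_000).tobytes().decode(),
    })


@pytest.fixture
def gene_table():
    rows = [
        ("geneA", "chr1", 1000, 2000, "+"),
        ("geneB", "chr1", 4000, 5000, "-"),
        ("geneC", "chr1", 8000, 9000, "+"),
        ("geneD", "chr2", 500, 1500, "+"),
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                     "strand"])
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return df
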