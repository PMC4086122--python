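"""One-sided Fisher's exact tests of target-set / user-set overlap.

For a universe of N genes, a feature's target set of size K', a user set
of size n (after intersection with the universe) and an overlap of a
genes, the enrichment p-value is the upper hypergeometric tail

    p = sum_{i=a}^{min(K', n)} C(K', i) C(N-K', n-i) / C(N, n)

i.e. the probability of seeing at least the observed overlap if the user
set were a uniform random draw from the universe.  Only enrichment is
tested (one-sided); a = 0 gives p = 1.  No multiple-testing correction is
applied by default — features are ranked by raw p — but a Benjamini-
Hochberg column can be added for convenience.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .regions import TargetSet

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    feature_id: str
    configuration: str
    user_set: str
    universe_size: int
    target_size: int
    user_size: int
    overlap: int
    p_value: float
    overlap_genes: list[str] = field(default_factory=list)


def hypergeom_upper_tail(N: int, K: int, n: int, a: int) -> float:
    """P(X >= a) for X ~ Hypergeometric(N, K, n), computed via log-gamma."""
    if a <= 0:
        return 1.0
    p = float(hypergeom.sf(a - 1, N, K, n))
    return min(p, 1.0) if p > 0 else 5e-324


def fisher_enrichment(target: TargetSet, user_set: list[str] | set[str],
                      universe: list[str] | set[str],
                      user_set_name: str = "user_set") -> EnrichmentResult:
    """Test one target set against one user set within a gene universe.

    User genes absent from the universe are dropped (with a logged count):
    the universe defines the sampling frame of the test.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    user = set(user_set)
    dropped = user - universe
    if dropped:
        log.warning("user set %r: %d gene(s) absent from universe, dropped",
                    user_set_name, len(dropped))
    user &= universe
    if not user:
        raise ValueError(
            f"user set {user_set_name!r} has no genes in the universe")
    tgt = set(target.genes) & universe
    overlap = sorted(tgt & user)
    p = hypergeom_upper_tail(len(universe), len(tgt), len(user), len(overlap))
    return EnrichmentResult(
        feature_id=target.feature_id,
        configuration=target.configuration,
        user_set=user_set_name,
        universe_size=len(universe),
        target_size=len(tgt),
        user_size=len(user),
        overlap=len(overlap),
        p_value=p,
        overlap_genes=overlap,
    )


def rank_and_threshold(results: pd.DataFrame, max_p: float = 0.05
                       ) -> pd.DataFrame:
    """Rows with p <= max_p, ascending by p, ties broken by feature id."""
    if not 0 < max_p <= 1:
        raise ValueError("max_p must be in (0, 1]")
    kept = results[results["p_value"] <= max_p]
    return kept.sort_values(["p_value", "feature_id"],
                            kind="mergesort").reset_index(drop=True)


def add_bh_fdr(results: pd.DataFrame) -> pd.DataFrame:
    """Append a Benjamini-Hochberg q-value column (non-canonical extra)."""
    df = results.copy()
    p = df["p_value"].to_numpy(dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        q[i] = running
    df["bh_fdr"] = q
    return df
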