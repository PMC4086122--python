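"""Profile normalization, accessibility masking and multi-species averaging.

Raw window scores are converted to normalized scores in (0, 1] where the
best window genome-wide gets rank fraction 1/N: a window scoring in the
top 1% receives a normalized score of 0.01.  The G/C variant performs the
same ranking within equal-population bins of window G/C content so that
compositionally biased motifs are compared against windows of similar
composition.  An accessibility filter keeps only the most accessible
fraction of windows and assigns all others the worst score 1 (no binding).
Multi-species profiles are combined window-wise by phylogenetically
weighted averaging before normalization, so conserved motif presence is
scored higher.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.stats import rankdata

from .windows import ScoreProfile

log = logging.getLogger(__name__)


@dataclass
class NormalizedProfile:
    """Per-window values in (0, 1], 0 best; unscorable windows carry 1."""

    feature_id: str
    values: np.ndarray
    tag: str = "standard"      # standard | gc | filtered

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if ((self.values <= 0) | (self.values > 1)).any():
            raise ValueError("normalized values must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.values)


def _rank_fractions(values: np.ndarray) -> np.ndarray:
    # rank 1 = best (highest raw value); ties share the mean of tied ranks
    return rankdata(-values, method="average") / len(values)


def rank_normalize(profile: ScoreProfile) -> NormalizedProfile:
    """Rank-normalize a raw profile: value r/N for the r-th best window.

    Ties receive the mean of their tied ranks.  Unscorable windows are
    excluded from ranking and assigned exactly 1.
    """
    n_scorable = int(profile.scorable.sum())
    if n_scorable == 0:
        raise ValueError("no scorable windows to normalize")
    if np.isnan(profile.values[profile.scorable]).any():
        raise ValueError("cannot rank-normalize a profile with missing values")
    out = np.ones(len(profile))
    out[profile.scorable] = _rank_fractions(profile.values[profile.scorable])
    return NormalizedProfile(profile.feature_id, out, tag="standard")


def gc_bins(gc: np.ndarray, scorable: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign scorable windows to ``n_bins`` equal-population G/C bins.

    Windows are sorted by (gc, index) and split into contiguous bins whose
    sizes differ by at most 1.  Returns a per-window bin index, -1 for
    unscorable windows.
    """
    bins = np.full(len(gc), -1, dtype=np.int64)
    idx = np.nonzero(scorable)[0]
    order = idx[np.argsort(gc[idx], kind="mergesort")]
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b
    return bins


def gc_rank_normalize(profile: ScoreProfile, gc: np.ndarray,
                      n_bins: int = 20) -> NormalizedProfile:
    """Rank-normalize within equal-population G/C bins.

    With ``n_bins=1`` this is bit-identical to :func:`rank_normalize`.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(gc) != len(profile):
        raise ValueError("gc vector must align with the profile")
    n_scorable = int(profile.scorable.sum())
    if n_scorable < n_bins:
        raise ValueError(
            f"only {n_scorable} scorable windows for {n_bins} bins; "
            f"use fewer bins")
    bins = gc_bins(np.asarray(gc, dtype=float), profile.scorable, n_bins)
    out = np.ones(len(profile))
    for b in range(n_bins):
        members = np.nonzero(bins == b)[0]
        out[members] = _rank_fractions(profile.values[members])
    return NormalizedProfile(profile.feature_id, out, tag="gc")


def accessibility_filter(norm: NormalizedProfile, access: ScoreProfile,
                         retain_fraction: float = 0.10) -> NormalizedProfile:
    """Keep the top ``retain_fraction`` most accessible windows.

    The threshold is the accessibility value at the ceil(f*N)-th highest
    rank; windows at or above it keep their normalized score, all others
    are set to exactly 1 (no binding).  Ties at the threshold are retained,
    so the retained count can exceed ceil(f*N).
    """
    if not 0 < retain_fraction <= 1:
        raise ValueError("retain_fraction must be in (0, 1]")
    if len(access) != len(norm):
        raise ValueError("accessibility profile must align with the profile")
    vals = access.values
    if np.ptp(vals) == 0:
        warnings.warn("all accessibility values equal; filter retains "
                      "every window", stacklevel=2)
    k = int(np.ceil(retain_fraction * len(vals)))
    threshold = np.sort(vals)[::-1][k - 1]
    out = np.where(vals >= threshold, norm.values, 1.0)
    return NormalizedProfile(norm.feature_id, out, tag="filtered")


@dataclass
class PhyloWeights:
    """Non-negative per-species weights summing to 1."""

    weights: dict[str, float]
    reference: str

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        if min(self.weights.values()) < 0:
            raise ValueError("weights must be non-negative")
        if self.weights.get(self.reference, 0.0) <= 0:
            raise ValueError("reference species must have positive weight")


def weights_from_tree(tree_path_or_str: str, reference: str,
                      is_path: bool = True) -> PhyloWeights:
    """Derive species weights from a Newick tree.

    Each leaf's weight is proportional to its root-to-leaf path length
    (branch lengths summed), normalized to sum 1; leaves with zero total
    distance (e.g. a single-species tree) get uniform weights.  Explicit
    user-supplied weights may be passed to :func:`phylo_average` instead.
    """
    kwargs = {"path": tree_path_or_str} if is_path else {"data": tree_path_or_str}
    tree = dendropy.Tree.get(schema="newick", **kwargs)
    dists = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        dists[leaf.taxon.label] = d
    if reference not in dists:
        raise ValueError(f"reference species {reference!r} not in tree")
    total = sum(dists.values())
    if total <= 0:
        w = {s: 1.0 / len(dists) for s in dists}
    else:
        w = {s: d / total for s, d in dists.items()}
        if w[reference] <= 0:  # zero-length reference branch: give it mass
            w = {s: (d + 1e-9) / (total + 1e-9 * len(dists))
                 for s, d in dists.items()}
    return PhyloWeights(w, reference)


def phylo_average(profiles: dict[str, ScoreProfile],
                  weights: PhyloWeights) -> ScoreProfile:
    """Weighted window-wise average of per-species score profiles.

    Profiles must be aligned to the reference window set (the ortholog
    mapping is the caller's responsibility); NaN marks windows with no
    ortholog in a species and drops that species for the window, with the
    remaining weights renormalized.  The output is a raw profile that then
    feeds rank normalization.
    """
    missing = set(profiles) - set(weights.weights)
    if missing:
        raise ValueError(f"species absent from tree weights: {sorted(missing)}")
    ref = profiles[weights.reference]
    n = len(ref)
    num = np.zeros(n)
    den = np.zeros(n)
    for sp, prof in profiles.items():
        if len(prof) != n:
            raise ValueError(f"profile for {sp!r} not aligned to reference")
        w = weights.weights[sp]
        vals = prof.values
        present = np.isfinite(vals)
        num[present] += w * vals[present]
        den[present] += w
    if (den == 0).any():
        raise ValueError("some windows have no species data at all")
    return ScoreProfile(feature_id=ref.feature_id, values=num / den,
                        scorable=ref.scorable, kind=ref.kind)
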