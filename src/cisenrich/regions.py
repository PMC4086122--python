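"""Regulatory regions, per-gene feature scores and target gene sets.

A gene's regulatory region can be a fixed strand-aware span around the
TSS (e.g. 5 kb upstream / 2 kb downstream), the nearest-TSS Voronoi cell
(every position closer to this gene's TSS than to any other), or the gene
territory (gene body extended halfway to the nearest non-overlapping
neighbor on each side).  Windows belong to a region iff their midpoint
lies inside it, so each window has a single location even with 2x
overlapping tiling.

The gene score combines the best normalized window score P_g with the
region's window count w_g:

    S_g = 1 - (1 - P_g) ** w_g

i.e. the probability that the minimum of w_g iid Uniform(0,1) draws is
below P_g — small S_g means the best window is better than expected for a
region of that size.  Genes with no windows get S_g = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transforms import NormalizedProfile
from .windows import WindowSet

REGION_MODES = ("fixed", "nearest_tss", "territory")


@dataclass
class RegulatoryRegion:
    gene_id: str
    intervals: list[tuple[str, int, int]]   # (chrom, start, end)
    mode: str
    regionless: bool = False


def _fixed_regions(genes: pd.DataFrame, upstream: int, downstream: int,
                   chrom_lengths: dict[str, int]) -> list[RegulatoryRegion]:
    regions = []
    for g in genes.itertuples():
        L = chrom_lengths[g.chrom]
        if g.strand == "+":
            lo, hi = g.tss - upstream, g.tss + downstream
        else:
            lo, hi = g.tss - downstream + 1, g.tss + upstream + 1
        lo, hi = max(0, lo), min(L, hi)
        if lo >= hi:
            regions.append(RegulatoryRegion(g.gene_id, [], "fixed", True))
        else:
            regions.append(RegulatoryRegion(g.gene_id, [(g.chrom, lo, hi)],
                                            "fixed"))
    return regions


def _nearest_tss_regions(genes: pd.DataFrame, chrom_lengths: dict[str, int]
                         ) -> list[RegulatoryRegion]:
    # midpoint-Voronoi partition of each chromosome by TSS position; a
    # point equidistant from two TSSs goes to the lower-coordinate one
    out: dict[str, RegulatoryRegion] = {}
    for chrom, grp in genes.groupby("chrom", sort=False):
        L = chrom_lengths[chrom]
        grp = grp.sort_values(["tss", "gene_id"], kind="mergesort")
        tss = grp["tss"].to_numpy()
        ids = grp["gene_id"].to_list()
        bounds = [0]
        for i in range(len(tss) - 1):
            # position m belongs upstream gene iff 2m <= tss[i] + tss[i+1]
            bounds.append((tss[i] + tss[i + 1]) // 2 + 1)
        bounds.append(L)
        for i, gid in enumerate(ids):
            lo, hi = bounds[i], bounds[i + 1]
            if lo >= hi:
                out[gid] = RegulatoryRegion(gid, [], "nearest_tss", True)
            else:
                out[gid] = RegulatoryRegion(gid, [(chrom, lo, hi)],
                                            "nearest_tss")
    return [out[g] for g in genes["gene_id"]]


def _territory_regions(genes: pd.DataFrame, chrom_lengths: dict[str, int]
                       ) -> list[RegulatoryRegion]:
    out: dict[str, RegulatoryRegion] = {}
    for chrom, grp in genes.groupby("chrom", sort=False):
        L = chrom_lengths[chrom]
        grp = grp.sort_values(["start", "gene_id"], kind="mergesort")
        recs = list(grp.itertuples())
        for i, g in enumerate(recs):
            # nearest non-overlapping neighbors (overlapping genes skipped)
            left_end = None
            for j in range(i - 1, -1, -1):
                if recs[j].end <= g.start:
                    left_end = recs[j].end if left_end is None \
                        else max(left_end, recs[j].end)
            right_start = None
            for j in range(i + 1, len(recs)):
                if recs[j].start >= g.end:
                    right_start = recs[j].start if right_start is None \
                        else min(right_start, recs[j].start)
            lo = 0 if left_end is None else g.start - (g.start - left_end) // 2
            hi = L if right_start is None else g.end + (right_start - g.end) // 2
            out[g.gene_id] = RegulatoryRegion(g.gene_id, [(chrom, lo, hi)],
                                              "territory")
    return [out[g] for g in genes["gene_id"]]


def define_regions(genes: pd.DataFrame, mode: str,
                   chrom_lengths: dict[str, int],
                   upstream: int = 5000, downstream: int = 0
                   ) -> list[RegulatoryRegion]:
    """Build one regulatory region per gene.

    ``mode`` is one of ``fixed`` (strand-aware [tss-upstream, tss+downstream)
    clamped to the chromosome), ``nearest_tss`` or ``territory``.
    """
    if mode not in REGION_MODES:
        raise ValueError(f"unknown region mode {mode!r}; "
                         f"choose from {REGION_MODES}")
    missing = set(genes["chrom"]) - set(chrom_lengths)
    if missing:
        raise ValueError(f"genes on chromosomes absent from genome: "
                         f"{sorted(missing)}")
    if mode == "fixed":
        if upstream < 0 or downstream < 0:
            raise ValueError("upstream/downstream must be >= 0")
        if upstream == 0 and downstream == 0:
            raise ValueError("fixed region with zero extent")
        return _fixed_regions(genes, upstream, downstream, chrom_lengths)
    if mode == "nearest_tss":
        return _nearest_tss_regions(genes, chrom_lengths)
    return _territory_regions(genes, chrom_lengths)


def assign_windows(regions: list[RegulatoryRegion], windows: WindowSet
                   ) -> dict[str, np.ndarray]:
    """Map each gene to the indices of windows whose midpoint lies in its
    region.  A window may belong to several genes under fixed regions, but
    to exactly one under nearest_tss."""
    mids_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    mids = windows.midpoints
    for chrom in dict.fromkeys(windows.chroms):
        idx = np.nonzero(windows.chroms == chrom)[0]
        m = mids[idx]
        order = np.argsort(m, kind="mergesort")
        mids_by_chrom[chrom] = (m[order], idx[order])
    assignment: dict[str, np.ndarray] = {}
    for region in regions:
        hits: list[np.ndarray] = []
        for chrom, lo, hi in region.intervals:
            if chrom not in mids_by_chrom:
                continue
            m_sorted, idx_sorted = mids_by_chrom[chrom]
            a = np.searchsorted(m_sorted, lo, side="left")
            b = np.searchsorted(m_sorted, hi, side="left")
            hits.append(idx_sorted[a:b])
        wins = np.sort(np.concatenate(hits)) if hits else \
            np.empty(0, dtype=np.int64)
        assignment[region.gene_id] = wins
    return assignment


def gene_score(p_g: float, w_g: int) -> float:
    """S_g = 1 - (1 - P_g)^{w_g}; S_g = 1 when the region has no windows."""
    if w_g == 0:
        return 1.0
    return float(-np.expm1(w_g * np.log1p(-p_g))) if p_g < 1.0 else 1.0


def score_genes(norm: NormalizedProfile,
                assignment: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-gene (P_g, w_g, S_g) from a normalized profile and assignment.

    P_g is the minimum normalized value over the gene's windows; w_g counts
    all windows in the region, including masked ones (they carry value 1
    and cannot win the minimum but still size the region).
    """
    rows = []
    for gene_id, wins in assignment.items():
        w_g = len(wins)
        if w_g == 0:
            rows.append(dict(gene_id=gene_id, P_g=1.0, w_g=0, S_g=1.0))
            continue
        p_g = float(norm.values[wins].min())
        rows.append(dict(gene_id=gene_id, P_g=p_g, w_g=w_g,
                         S_g=gene_score(p_g, w_g)))
    return pd.DataFrame(rows, columns=["gene_id", "P_g", "w_g", "S_g"])


@dataclass
class TargetSet:
    """The K genes with the best (smallest) S_g for one feature."""

    feature_id: str
    configuration: str
    genes: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)


def build_target_set(scores: pd.DataFrame, universe: set[str] | list[str],
                     K: int = 500, feature_id: str = "",
                     configuration: str = "") -> TargetSet:
    """Top-K genes by ascending S_g, ties broken by gene id.

    Genes outside the universe are dropped first; if the universe holds
    fewer than K genes, all of them are returned in order.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    df = scores[scores["gene_id"].isin(universe)]
    df = df.sort_values(["S_g", "gene_id"], kind="mergesort")
    return TargetSet(feature_id=feature_id, configuration=configuration,
                     genes=df["gene_id"].head(K).to_list())
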