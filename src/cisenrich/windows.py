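"""Fixed-length genome tiling, per-window G/C content and signal projection.

The genome is tiled into windows of ``window_length`` bp advanced by
``shift`` bp (default 500/250, i.e. 2x overlapping tiles).  Windows are the
atomic unit every downstream score, normalization and gene assignment
operates on.  Trailing bases that cannot host a full window are left
uncovered; a chromosome shorter than one window yields a single short
window spanning the whole chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenomeSequences, SignalTrack


@dataclass
class WindowSet:
    """Ordered genome tiling; index is dense 0..n-1 in (chrom order, start)."""

    chroms: np.ndarray          # str per window
    starts: np.ndarray          # int64
    ends: np.ndarray            # int64
    window_length: int
    shift: int
    short: np.ndarray           # bool: window shorter than window_length
    chrom_order: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(chrom=self.chroms, start=self.starts,
                                 end=self.ends, index=np.arange(len(self))))

    def to_bed(self, path: str) -> None:
        df = self.to_frame()
        df["name"] = "w" + df["index"].astype(str)
        df[["chrom", "start", "end", "name"]].to_csv(
            path, sep="\t", header=False, index=False)


@dataclass
class ScoreProfile:
    """Per-window raw feature values; higher = stronger feature presence."""

    feature_id: str
    values: np.ndarray
    scorable: np.ndarray        # bool; False windows cannot carry evidence
    kind: str = "motif"         # motif | chip | accessibility

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.scorable = np.asarray(self.scorable, dtype=bool)
        if len(self.values) != len(self.scorable):
            raise ValueError("values and scorable mask must have equal length")
        # NaN is allowed and marks windows with no data (e.g. no ortholog
        # in a species); infinities are never valid scores
        if np.isinf(self.values).any():
            raise ValueError("score profile contains infinite values")

    def __len__(self) -> int:
        return len(self.values)


def export_profile_tsv(profile: "ScoreProfile | object", windows: WindowSet,
                       path: str) -> None:
    """Write per-window values (raw or normalized) alongside coordinates."""
    df = windows.to_frame()
    df["value"] = profile.values
    df[["index", "chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", index=False)


def tile_windows(chrom_lengths: dict[str, int], window_length: int = 500,
                 shift: int = 250) -> WindowSet:
    """Tile chromosomes into fixed windows.

    Starts are 0, shift, 2*shift, ... while start + window_length fits.
    A chromosome shorter than ``window_length`` contributes one short
    window covering its whole span.
    """
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    if not 1 <= shift <= window_length:
        raise ValueError("shift must satisfy 1 <= shift <= window_length")
    chroms, starts, ends, short = [], [], [], []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length")
        if length < window_length:
            chroms.append(chrom)
            starts.append(0)
            ends.append(length)
            short.append(True)
            continue
        n = (length - window_length) // shift + 1
        for i in range(n):
            chroms.append(chrom)
            starts.append(i * shift)
            ends.append(i * shift + window_length)
            short.append(False)
    return WindowSet(
        chroms=np.array(chroms, dtype=object),
        starts=np.array(starts, dtype=np.int64),
        ends=np.array(ends, dtype=np.int64),
        window_length=window_length,
        shift=shift,
        short=np.array(short, dtype=bool),
        chrom_order=list(chrom_lengths),
    )


def compute_gc(windows: WindowSet, genome: GenomeSequences
               ) -> tuple[np.ndarray, np.ndarray]:
    """Per-window G/C fraction over non-N bases.

    Returns ``(gc, all_n)`` where ``all_n`` flags windows with no non-N base
    (their gc is reported as 0 and they are excluded from G/C binning).
    """
    gc = np.zeros(len(windows))
    all_n = np.zeros(len(windows), dtype=bool)
    # per-chromosome cumulative counts so overlapping windows are cheap
    cum: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in set(windows.chroms):
        if chrom not in genome:
            raise ValueError(f"window chromosome {chrom!r} absent from genome")
        arr = np.frombuffer(genome[chrom].encode("ascii"), dtype=np.uint8)
        is_gc = np.isin(arr, np.frombuffer(b"GC", dtype=np.uint8))
        is_n = arr == ord("N")
        cum[chrom] = (np.concatenate([[0], np.cumsum(is_gc)]),
                      np.concatenate([[0], np.cumsum(is_n)]))
    for i in range(len(windows)):
        chrom, s, e = windows.chroms[i], windows.starts[i], windows.ends[i]
        cgc, cn = cum[chrom]
        if e > len(genome[chrom]) or s < 0:
            raise ValueError(f"window [{s},{e}) outside chromosome {chrom!r}")
        n_gc = cgc[e] - cgc[s]
        n_n = cn[e] - cn[s]
        denom = (e - s) - n_n
        if denom == 0:
            all_n[i] = True
            gc[i] = 0.0
        else:
            gc[i] = n_gc / denom
    return gc, all_n


def signal_to_windows(track: SignalTrack, windows: WindowSet,
                      feature_id: str = "signal",
                      kind: str = "chip") -> ScoreProfile:
    """Project interval signal onto windows as a length-weighted mean.

    Bases not covered by any interval count as value 0, so the window value
    is (sum over intervals of overlap_bp * value) / window_bp.  Linear in
    the track values and deterministic.
    """
    values = np.zeros(len(windows))
    by_chrom = {c: g for c, g in track.intervals.groupby("chrom", sort=False)}
    window_chroms = set(windows.chroms)
    extra = set(by_chrom) - window_chroms
    if extra:
        raise ValueError(f"track chromosomes absent from windows: {sorted(extra)}")
    for chrom, grp in by_chrom.items():
        istarts = grp["start"].to_numpy()
        iends = grp["end"].to_numpy()
        ivals = grp["value"].to_numpy(dtype=float)
        mask = windows.chroms == chrom
        idx = np.nonzero(mask)[0]
        ws, we = windows.starts[idx], windows.ends[idx]
        # intervals are sorted & disjoint: locate the overlap range per window
        lo = np.searchsorted(iends, ws, side="right")
        hi = np.searchsorted(istarts, we, side="left")
        for j, wi in enumerate(idx):
            a, b = lo[j], hi[j]
            if a >= b:
                continue
            ov = (np.minimum(iends[a:b], we[j])
                  - np.maximum(istarts[a:b], ws[j]))
            values[wi] = float(np.dot(ov, ivals[a:b])) / (we[j] - ws[j])
    return ScoreProfile(feature_id=feature_id, values=values,
                        scorable=np.ones(len(windows), dtype=bool), kind=kind)
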