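"""Stubb-style block-HMM window scores for motif presence.

A window is modelled as a left-to-right mixture of single background
letters (probability 1-p each, emitted from an order-k Markov background)
and motif blocks of width W (probability p, emitted as an equal mixture of
the forward and reverse-complement motif model).  The window score is the
log2 likelihood ratio of the best block probability p in [0, 0.5] against
the pure-background model (p = 0), so it integrates both strong and weak
motif matches and is always >= 0.

Forward recursion on the likelihood ratio r (background emissions cancel):

    r[0] = 1
    r[i] = r[i-1] * (1-p)  +  [i >= W] * r[i-W] * p * e[i]

where e[i] is the block emission for positions i-W+1..i divided by the
background probability of the same bases.  N bases are uninformative
(emission 1 under the background); a block overlapping an N contributes 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .io import GenomeSequences, MotifMatrix
from .windows import ScoreProfile, WindowSet

LN2 = 0.6931471805599453

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Map a nucleotide string to codes A=0 C=1 G=2 T=3, anything else 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class BackgroundModel:
    """Order-k Markov nucleotide model with add-one smoothed conditionals."""

    order: int
    cond: np.ndarray       # (4**order, 4) P(base | context)
    marginal: np.ndarray   # (4,) context-free base probabilities
    trained_on: str = ""

    def __post_init__(self) -> None:
        self.cond = np.asarray(self.cond, dtype=float)
        self.marginal = np.asarray(self.marginal, dtype=float)
        if self.cond.shape != (4 ** self.order, 4):
            raise ValueError("cond must have shape (4**order, 4)")
        if not np.allclose(self.cond.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("conditional distributions must sum to 1")
        if (self.cond <= 0).any() or (self.marginal <= 0).any():
            raise ValueError("all background probabilities must be positive")


@dataclass
class ScoredMotif:
    """Motif probability matrix theta from counts + pseudocount."""

    motif_id: str
    theta: np.ndarray      # (W, 4), rows sum to 1, all entries > 0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if not np.allclose(self.theta.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("theta rows must sum to 1")
        if (self.theta <= 0).any():
            raise ValueError("theta entries must be positive")

    @property
    def width(self) -> int:
        return self.theta.shape[0]

    @classmethod
    def from_counts(cls, motif: MotifMatrix, pseudocount: float = 0.5
                    ) -> "ScoredMotif":
        c = motif.counts + pseudocount
        return cls(motif.motif_id, c / c.sum(axis=1, keepdims=True))


def train_background(genome: GenomeSequences, order: int = 2) -> BackgroundModel:
    """Estimate the background from genome-wide non-N (k+1)-mer counts.

    Add-one smoothing guarantees every conditional is defined and positive
    even on tiny inputs.  Contexts never cross chromosome boundaries.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    k = order
    counts = np.zeros((4 ** k, 4))
    base_counts = np.zeros(4)
    total_non_n = 0
    for name in genome.names:
        codes = encode_sequence(genome[name]).astype(np.int64)
        valid = codes < 4
        total_non_n += int(valid.sum())
        base_counts += np.bincount(codes[valid], minlength=4)
        if len(codes) < k + 1:
            continue
        ctx = np.zeros(len(codes) - k, dtype=np.int64)
        ok = np.ones(len(codes) - k, dtype=bool)
        for j in range(k):
            cj = codes[j:len(codes) - k + j]
            ctx = ctx * 4 + np.where(cj < 4, cj, 0)
            ok &= cj < 4
        nxt = codes[k:]
        ok &= nxt < 4
        np.add.at(counts, (ctx[ok], nxt[ok]), 1)
    if total_non_n == 0:
        raise ValueError("genome has no non-N bases; cannot train background")
    counts += 1.0
    base_counts += 1.0
    return BackgroundModel(
        order=k,
        cond=counts / counts.sum(axis=1, keepdims=True),
        marginal=base_counts / base_counts.sum(),
        trained_on=f"genome-wide, {total_non_n} non-N bases",
    )


@njit(cache=True)
def _bg_probs(codes, cond, marg, k):
    n = codes.shape[0]
    b = np.empty(n)
    for i in range(n):
        c = codes[i]
        if c == 4:
            b[i] = 1.0
            continue
        if i < k:
            b[i] = marg[c]
            continue
        ctx = 0
        ok = True
        for j in range(i - k, i):
            cj = codes[j]
            if cj == 4:
                ok = False
                break
            ctx = ctx * 4 + cj
        b[i] = cond[ctx, c] if ok else marg[c]
    return b


@njit(cache=True)
def _block_emissions(codes, b, theta):
    n = codes.shape[0]
    W = theta.shape[0]
    e = np.zeros(n)
    for i in range(W - 1, n):
        pf = 1.0
        pr = 1.0
        pb = 1.0
        has_n = False
        for j in range(W):
            c = codes[i - W + 1 + j]
            if c == 4:
                has_n = True
                break
            pf *= theta[j, c]
            pr *= theta[W - 1 - j, 3 - c]
            pb *= b[i - W + 1 + j]
        if not has_n:
            e[i] = 0.5 * (pf + pr) / pb
    return e


@njit(cache=True)
def _loglik_ratio(e, W, p):
    n = e.shape[0]
    r = np.empty(n + 1)
    r[0] = 1.0
    logscale = 0.0
    q = 1.0 - p
    for i in range(1, n + 1):
        v = r[i - 1] * q
        if i >= W and p > 0.0:
            v += r[i - W] * p * e[i - 1]
        r[i] = v
        if v > 1e150 or v < 1e-150:
            lo = i - W
            if lo < 0:
                lo = 0
            for j in range(lo, i + 1):
                r[j] /= v
            logscale += np.log(v)
    return np.log(r[n]) + logscale


@njit(cache=True)
def _best_log_ratio(e, W):
    # golden-section maximization of the log likelihood ratio over p in [0, 0.5]
    invphi = 0.6180339887498949
    a = 0.0
    b = 0.5
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = _loglik_ratio(e, W, c)
    fd = _loglik_ratio(e, W, d)
    for _ in range(60):
        if b - a < 1e-7:
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = _loglik_ratio(e, W, c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = _loglik_ratio(e, W, d)
    best = fc if fc > fd else fd
    # p = 0 (ratio 1, log 0) is always feasible
    return best if best > 0.0 else 0.0


@njit(cache=True)
def _score_window(codes, theta, cond, marg, k):
    W = theta.shape[0]
    if codes.shape[0] < W:
        return 0.0
    b = _bg_probs(codes, cond, marg, k)
    e = _block_emissions(codes, b, theta)
    return _best_log_ratio(e, W) / LN2


@njit(cache=True)
def _score_windows(codes, starts, ends, theta, cond, marg, k):
    m = starts.shape[0]
    out = np.empty(m)
    for i in range(m):
        out[i] = _score_window(codes[starts[i]:ends[i]], theta, cond, marg, k)
    return out


def window_likelihood_ratio(seq: str, motif: ScoredMotif, bg: BackgroundModel,
                            p: float) -> float:
    """Likelihood ratio L(seq; p) / L(seq; p=0) at a fixed block probability."""
    codes = encode_sequence(seq)
    if len(codes) < motif.width:
        return (1.0 - p) ** len(codes)
    b = _bg_probs(codes, bg.cond, bg.marginal, bg.order)
    e = _block_emissions(codes, b, motif.theta)
    return float(np.exp(_loglik_ratio(e, motif.width, p)))


def stubb_window_score(seq: str, motif: ScoredMotif, bg: BackgroundModel,
                       max_width: int = 30) -> float:
    """Score one window: log2 max_p L(seq; p) / L(seq; 0), p in [0, 0.5].

    Returns exactly 0 when the window is shorter than the motif or when no
    p > 0 improves on the background-only model.
    """
    if motif.width > max_width:
        raise ValueError(
            f"motif {motif.motif_id!r} wider ({motif.width}) than max_width "
            f"{max_width}")
    codes = encode_sequence(seq)
    return float(_score_window(codes, motif.theta, bg.cond, bg.marginal,
                               bg.order))


def score_genome(genome: GenomeSequences, windows: WindowSet,
                 motif: ScoredMotif, bg: BackgroundModel,
                 max_width: int = 30) -> ScoreProfile:
    """Score every window of the genome for one motif.

    All-N windows get score 0 and are flagged unscorable.  Deterministic
    and independent of chromosome processing order.
    """
    if motif.width > max_width:
        raise ValueError(
            f"motif {motif.motif_id!r} wider ({motif.width}) than max_width "
            f"{max_width}")
    values = np.zeros(len(windows))
    scorable = np.ones(len(windows), dtype=bool)
    for chrom in dict.fromkeys(windows.chroms):  # preserves order
        codes = encode_sequence(genome[chrom])
        mask = windows.chroms == chrom
        idx = np.nonzero(mask)[0]
        values[idx] = _score_windows(
            codes, windows.starts[idx], windows.ends[idx],
            motif.theta, bg.cond, bg.marginal, bg.order)
        for wi in idx:
            if (codes[windows.starts[wi]:windows.ends[wi]] == 4).all():
                values[wi] = 0.0
                scorable[wi] = False
    return ScoreProfile(feature_id=motif.motif_id, values=values,
                        scorable=scorable, kind="motif")
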