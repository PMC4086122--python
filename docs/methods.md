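# Methods

## Window model

Chromosomes are tiled into fixed windows of `window_length` = 500 bp
advanced by `shift` = 250 bp, so interior bases are covered by exactly two
windows. Trailing bases that cannot host a full window are left uncovered:
keeping every scored unit the same length is what makes rank normalization
across windows meaningful. A chromosome shorter than one window becomes a
single short window so no sequence is silently dropped. All coordinates are
0-based half-open throughout; GTF input is converted on read, and the TSS
of a minus-strand gene is `end − 1`.

## Block-HMM motif score

A window of sequence `x₁…xₙ` is modelled as a left-to-right parse into
single background letters and motif blocks of width `W`. Each parse step
emits a letter with probability `(1−p)·b(xᵢ)` or, where a full block fits,
a block with probability `p · (½ θ_fwd + ½ θ_rev)`, where `θ` is the motif
probability matrix (counts + 0.5 pseudocount per cell, rows normalized) and
the ½/½ mixture covers both strands. The window score is

    score = log₂ [ max_{p ∈ [0, 0.5]} L(x; p) / L(x; 0) ]

computed by a forward recursion on the likelihood ratio (background
emissions cancel, with periodic rescaling against over/underflow). Because
`p = 0` is feasible the score is never negative, and a window shorter than
the motif scores exactly 0. The score integrates over all parses, so many
weak sites and one strong site both raise it — the behaviour that motivates
using a likelihood ratio rather than a match count.

Choices a user may care about:

- **`p` optimization** is golden-section search on `[0, 0.5]` with interval
  tolerance 1e−7 (≈ 40 likelihood evaluations). The likelihood is a
  polynomial in `p` with non-negative parse coefficients and is unimodal in
  practice; a derivative-free bracketing search is deterministic and needs
  no convergence heuristics, which is why it is used instead of EM.
- **Background**: order-2 Markov model trained genome-wide from non-N
  (k+1)-mer counts with add-one smoothing. Genome-wide training is
  deterministic and stable; per-window training at 500 bp is not. The first
  `k` positions of a window, and positions whose context contains an N, use
  the marginal base distribution.
- **N handling**: N emits probability 1 under both models (uninformative);
  any block overlapping an N contributes 0, so unknown sequence can never
  inflate a score. All-N windows are flagged unscorable, score 0, and are
  excluded from ranking (they receive normalized score 1 downstream).
- **Strand symmetry**: the ½/½ strand mixture makes the motif term
  symmetric, so `score(s) = score(revcomp(s))` exactly when the background
  assigns equal probability to a sequence and its reverse complement
  (e.g. any complement-symmetric composition model). Under an asymmetric
  background the two scores differ by the background's own strand bias;
  this is a property of likelihood ratios, not an implementation artifact.
- **Units** are bits (log₂); only ranks matter downstream.
- Maximum accepted motif width is 30 (configurable); wider matrices almost
  always indicate a malformed input file.

ChIP features bypass the HMM: the window value is the length-weighted mean
of the track over the window with uncovered bases counted as 0, matching
read-count semantics (absence of reads is zero signal) and making the
projection linear in the track.

## Normalization

Rank normalization maps raw scores to `r/N` where `r` is the rank among the
`N` scorable windows (1 = best, ties get the mean of their tied ranks —
this conserves the rank sum and is deterministic). The best window of
10,000 gets 0.0001; a window at the top 1% boundary gets 0.01; the worst
gets 1.

G/C normalization sorts scorable windows by G/C fraction (computed over
non-N bases), splits them into `n_bins` = 20 contiguous equal-population
bins (sizes differ by at most one; "equal-sized" is read as equal window
counts, since equal-width G/C intervals would be wildly unbalanced), and
rank-normalizes within each bin. With one bin it reduces bit-for-bit to
standard normalization. It is available for ChIP profiles as well as motif
profiles.

The accessibility filter thresholds **raw** accessibility values at the
`⌈0.10·N⌉`-th highest; windows at or above it keep their normalized score,
all others are set to exactly 1. Ties at the threshold are retained, so the
retained count can exceed 10%. Masking therefore never improves a window.

Multi-species averaging combines per-species raw scores on the reference
window grid (the ortholog window mapping is an input, not computed here)
as a weighted mean; the default weights are each leaf's root-to-leaf branch
length normalized to sum 1, a simple proxy for phylogenetic independence,
and explicit user weights are accepted because published weighting schemes
vary. Species lacking an ortholog for a window (NaN) are dropped for that
window and the remaining weights renormalized. Averaging happens **before**
normalization and masking: average → rank/G-C normalize → accessibility
filter.

## Gene scores and target sets

`S_g = 1 − (1 − P_g)^{w_g}` is the probability that the minimum of `w_g`
iid Uniform(0,1) draws falls below `P_g`; since normalized scores are
approximately uniform ranks, `S_g` is a size-corrected best-window score:
a `P_g` of 0.01 is far more surprising in a 2-window promoter region than
in a 100-window territory. It is computed as `−expm1(w·log1p(−P))` for
accuracy near 0, and saturates at double precision once `(1−P_g)^{w_g}`
drops below one ulp of 1.

Window–region membership is by window **midpoint**, not overlap: with 2×
tiling, overlap membership would double-count `w_g` at region edges.
`w_g` counts every window in the region including accessibility-masked
ones — their value 1 cannot win the minimum, but they still describe the
region's size; a flag (`w_g` restricted to unmasked windows) is available
by pre-filtering the assignment if the other reading is wanted. Genes with
no window midpoint in their region get `S_g = 1` and can never enter a
target set.

Region modes: `fixed` spans are strand-aware (`[tss−up, tss+down)` for +
genes, mirrored for −) and clamped to the chromosome; `nearest_tss` is the
integer midpoint-Voronoi partition of each chromosome by TSS, with an
equidistant point assigned to the lower-coordinate TSS; `territory` is the
gene body extended by half the gap to the nearest **non-overlapping**
neighbor on each side, and extends to the chromosome end where no neighbor
exists. Target sets take the K smallest `S_g` (default K = 500), ties
broken lexicographically by gene id for determinism.

## Enrichment test

The one-sided Fisher p-value is the upper hypergeometric tail
`P(X ≥ a)` for `X ~ Hypergeom(N, K′, n)`, evaluated via log-gamma
arithmetic (scipy's survival function), so genome-scale universes cannot
overflow. User genes missing from the universe are dropped with a logged
count — the universe defines the sampling frame, so adding them would
change the null. No multiple-testing correction is applied by default
(features are ranked by raw p); an optional Benjamini–Hochberg column is
available and clearly non-canonical. The default display threshold is
p ≤ 0.05; the all-results file always keeps every test.

## Synthetic benchmark

The generator emulates the minimal structure the method needs: an i.i.d.
genome (default 2 × 500 kb, G/C 0.41 — a fly-like composition), 200
non-overlapping genes with ≥ 2 kb spacing and random strands, one
high-information planted motif (width 8, 85/5/5/5 counts per position) with
3 consensus copies planted within 2 kb upstream of 50 randomly chosen
genes, 19 decoys obtained by permuting each position's four counts
(identical information content, different consensus), and a gamma-noise
accessibility track open over exactly the planted upstream spans at 10×
background mean. All streams derive from one master seed via named
substreams, so every component regenerates bit-identically.

What it does **not** emulate: isochore-scale composition structure,
repeats, nucleosome-scale accessibility texture, transcript isoforms, or
realistic motif co-occurrence. Passing the benchmark shows the pipeline
discriminates a real planted signal from information-matched noise at this
scale; it does not certify performance on real genomes. One deliberate
artifact: because the synthetic accessibility track is open *only* over
planted upstream regions, applying the accessibility filter makes every
feature's target set collapse onto the planted genes — a perfectly
informative mask enriches everything, which is a property of the fixture,
not of real DHS data.

Problem sizes used in the shipped tests (≈ 4,000 windows, 20 motifs,
20 seeds for the recovery benchmark; K = 100 against a 200-gene universe)
were chosen as the smallest scale at which the planted/decoy separation is
unambiguous (the planted motif's p-value sits ≥ 10⁶-fold below the median
decoy's).

## Determinism and caching

Every stage is deterministic given inputs and seed; reports are
byte-identical across reruns. A `Pipeline` caches window tilings, G/C
vectors, the background model, raw and normalized profiles and region
assignments keyed by the options that affect them, so "run all
definitions" batches share window scoring — the expensive stage — across
configurations. Each configuration's options are fingerprinted
(SHA-256 of the canonical JSON, 12 hex digits) and the fingerprint is
embedded in every output row and filename.
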