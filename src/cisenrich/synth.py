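"""Seed-deterministic synthetic inputs with known ground truth.

Generates everything the pipeline consumes — genome, gene annotation,
motif collections with planted consensus sites, accessibility tracks and
user gene sets — so each stage and the end-to-end method can be exercised
without any external data.  All randomness flows from one master seed
through named substreams, so regenerating any component with the same
seed is bit-identical.

The benchmark case plants consensus sites of one motif upstream of a
known subset of genes and pairs it with decoy motifs that are per-position
permutations of the planted matrix: identical information content,
different sequence, so recovering the planted motif tests discrimination
rather than motif strength.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GENE_COLUMNS, GenomeSequences, MotifMatrix, SignalTrack

_STREAMS = {"genome": 0, "annotation": 1, "motifs": 2, "planting": 3,
            "accessibility": 4, "user_sets": 5}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream]])


def make_genome(n_chrom: int = 2, chrom_length: int = 500_000,
                gc_target: float = 0.41, seed: int = 0) -> GenomeSequences:
    """I.i.d. nucleotide genome with P(G) + P(C) = ``gc_target``."""
    if chrom_length < 1000:
        raise ValueError("chrom_length must be >= 1000")
    if not 0 < gc_target < 1:
        raise ValueError("gc_target must be in (0, 1)")
    rng = _rng(seed, "genome")
    probs = [(1 - gc_target) / 2, gc_target / 2, gc_target / 2,
             (1 - gc_target) / 2]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequences = {}
    for c in range(n_chrom):
        draw = rng.choice(bases, size=chrom_length, p=probs)
        sequences[f"chr{c + 1}"] = draw.tobytes().decode("ascii")
    return GenomeSequences(sequences)


def make_annotation(genome: GenomeSequences, n_genes: int = 200,
                    min_spacing: int = 2000,
                    gene_length_range: tuple[int, int] = (500, 2000),
                    seed: int = 0) -> pd.DataFrame:
    """Non-overlapping genes with >= ``min_spacing`` bp between them.

    Genes are spread across chromosomes proportionally to length and
    placed uniformly subject to the spacing constraint (stick-breaking
    over the free space).  Strands are random.
    """
    rng = _rng(seed, "annotation")
    lengths = genome.lengths
    total = sum(lengths.values())
    rows = []
    gene_no = 0
    names = genome.names
    per_chrom = {c: int(round(n_genes * lengths[c] / total)) for c in names}
    # fix rounding drift on the last chromosome
    per_chrom[names[-1]] += n_genes - sum(per_chrom.values())
    for chrom in names:
        n = per_chrom[chrom]
        if n == 0:
            continue
        L = lengths[chrom]
        glens = rng.integers(gene_length_range[0], gene_length_range[1] + 1,
                             size=n)
        occupied = int(glens.sum()) + (n + 1) * min_spacing
        free = L - occupied
        if free < 0:
            raise ValueError(
                f"{n} genes do not fit on {chrom!r} ({L} bp) with "
                f"{min_spacing} bp spacing")
        # n+1 non-negative slacks summing to `free`
        cuts = np.sort(rng.integers(0, free + 1, size=n))
        slacks = np.diff(np.concatenate([[0], cuts, [free]]))
        pos = min_spacing + slacks[0]
        for i in range(n):
            start = int(pos)
            end = start + int(glens[i])
            strand = "+" if rng.random() < 0.5 else "-"
            gene_no += 1
            gid = f"g{gene_no:04d}"
            rows.append(dict(gene_id=gid, chrom=chrom, start=start, end=end,
                             strand=strand,
                             tss=start if strand == "+" else end - 1))
            pos = end + min_spacing + slacks[i + 1]
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def make_planted_motif(width: int = 8, dominance: int = 85,
                       other: int = 5, seed: int = 0,
                       motif_id: str = "planted") -> MotifMatrix:
    """High-information count matrix with a random consensus sequence."""
    rng = _rng(seed, "motifs")
    counts = np.full((width, 4), other, dtype=float)
    consensus = rng.integers(0, 4, size=width)
    counts[np.arange(width), consensus] = dominance
    return MotifMatrix(motif_id, counts)


def make_decoys(planted: MotifMatrix, n_decoys: int = 19,
                seed: int = 0) -> list[MotifMatrix]:
    """Per-position permutations of the planted counts: same information
    content, different consensus sequence."""
    rng = _rng(seed, "motifs")
    rng.integers(0, 4, size=planted.width)  # skip the consensus draw
    decoys = []
    for d in range(n_decoys):
        counts = planted.counts.copy()
        for pos in range(planted.width):
            counts[pos] = counts[pos, rng.permutation(4)]
        decoys.append(MotifMatrix(f"decoy{d + 1:02d}", counts))
    return decoys


def upstream_span(gene, span: int, chrom_length: int) -> tuple[int, int]:
    """Strand-aware [span bp upstream, TSS) interval, clamped."""
    if gene.strand == "+":
        lo, hi = gene.tss - span, gene.tss
    else:
        lo, hi = gene.tss + 1, gene.tss + 1 + span
    return max(0, lo), min(chrom_length, hi)


def plant_sites(genome: GenomeSequences, motif: MotifMatrix,
                genes: pd.DataFrame, gene_ids: list[str],
                span: int = 2000, sites_per_gene: int = 3,
                seed: int = 0) -> tuple[GenomeSequences, pd.DataFrame]:
    """Write consensus copies into the upstream span of selected genes.

    Sites are placed at random offsets on a random strand; draws that
    would overlap a gene body or a previously planted site are redrawn
    (error after 100 failed attempts).  Returns the edited genome and a
    site log with one row per planted copy.
    """
    consensus = motif.consensus()
    w = len(consensus)
    by_id = genes.set_index("gene_id")
    bodies: dict[str, list[tuple[int, int]]] = {}
    for g in genes.itertuples():
        bodies.setdefault(g.chrom, []).append((g.start, g.end))
    rng = _rng(seed, "planting")
    edited = {c: bytearray(s, "ascii") for c, s in genome.sequences.items()}
    log_rows = []
    planted: dict[str, list[tuple[int, int]]] = {}
    for gid in gene_ids:
        g = by_id.loc[gid]
        L = len(genome[g.chrom])
        lo, hi = upstream_span(g, span, L)
        if hi - lo < w:
            raise ValueError(f"upstream span of {gid!r} shorter than motif")
        for _ in range(sites_per_gene):
            for attempt in range(100):
                start = int(rng.integers(lo, hi - w + 1))
                end = start + w
                clash = any(start < be and bs < end
                            for bs, be in bodies.get(g.chrom, []))
                clash = clash or any(start < pe and ps < end
                                     for ps, pe in planted.get(g.chrom, []))
                if not clash:
                    break
            else:
                raise RuntimeError(
                    f"could not place a site for {gid!r} in 100 draws")
            strand = "+" if rng.random() < 0.5 else "-"
            site = consensus if strand == "+" else revcomp(consensus)
            edited[g.chrom][start:end] = site.encode("ascii")
            planted.setdefault(g.chrom, []).append((start, end))
            log_rows.append(dict(gene_id=gid, chrom=g.chrom, start=start,
                                 end=end, strand=strand, site=site))
    new_genome = GenomeSequences(
        {c: bytes(b).decode("ascii") for c, b in edited.items()})
    site_log = pd.DataFrame(
        log_rows, columns=["gene_id", "chrom", "start", "end", "strand",
                           "site"])
    return new_genome, site_log


def make_accessibility(chrom_lengths: dict[str, int],
                       open_regions: list[tuple[str, int, int]],
                       open_level: float = 10.0,
                       background_level: float = 1.0,
                       tile: int = 250, seed: int = 0) -> SignalTrack:
    """Gamma-noise accessibility track, ~``open_level``/``background_level``
    mean signal inside/outside the open regions (level 0 means exactly 0)."""
    rng = _rng(seed, "accessibility")
    rows = []
    for chrom, L in chrom_lengths.items():
        opens = [(s, e) for c, s, e in open_regions if c == chrom]
        for start in range(0, L, tile):
            end = min(start + tile, L)
            is_open = any(start < oe and os_ < end for os_, oe in opens)
            level = open_level if is_open else background_level
            value = float(rng.gamma(2.0, level / 2.0)) if level > 0 else 0.0
            rows.append(dict(chrom=chrom, start=start, end=end, value=value))
    return SignalTrack(pd.DataFrame(rows))


@dataclass
class BenchmarkCase:
    """A complete synthetic input with recorded ground truth."""

    genome: GenomeSequences
    genes: pd.DataFrame
    motifs: list[MotifMatrix]          # planted motif first, then decoys
    accessibility: SignalTrack
    planted_motif_id: str
    planted_genes: list[str]
    site_log: pd.DataFrame
    seed: int
    params: dict = field(default_factory=dict)


def make_benchmark_case(n_genes: int = 200, planted_fraction: float = 0.25,
                        n_decoys: int = 19, sites_per_gene: int = 3,
                        upstream_bp: int = 2000, motif_width: int = 8,
                        n_chrom: int = 2, chrom_length: int = 500_000,
                        gc_target: float = 0.41,
                        seed: int = 0) -> BenchmarkCase:
    """Compose genome + annotation + planted motif + decoys + accessibility.

    ``round(planted_fraction * n_genes)`` genes receive ``sites_per_gene``
    consensus sites each within ``upstream_bp`` of their TSS; the
    accessibility track is open over exactly those upstream spans.
    """
    genome = make_genome(n_chrom, chrom_length, gc_target, seed=seed)
    genes = make_annotation(genome, n_genes, seed=seed)
    planted_motif = make_planted_motif(motif_width, seed=seed)
    decoys = make_decoys(planted_motif, n_decoys, seed=seed)
    n_planted = int(round(planted_fraction * n_genes))
    rng = _rng(seed, "user_sets")
    planted_genes = sorted(
        rng.choice(genes["gene_id"].to_numpy(), size=n_planted,
                   replace=False).tolist())
    genome, site_log = plant_sites(genome, planted_motif, genes,
                                   planted_genes, span=upstream_bp,
                                   sites_per_gene=sites_per_gene, seed=seed)
    lengths = genome.lengths
    open_regions = []
    by_id = genes.set_index("gene_id")
    for gid in planted_genes:
        g = by_id.loc[gid]
        lo, hi = upstream_span(g, upstream_bp, lengths[g.chrom])
        open_regions.append((g.chrom, lo, hi))
    access = make_accessibility(lengths, open_regions, seed=seed)
    return BenchmarkCase(
        genome=genome, genes=genes, motifs=[planted_motif] + decoys,
        accessibility=access, planted_motif_id=planted_motif.motif_id,
        planted_genes=planted_genes, site_log=site_log, seed=seed,
        params=dict(n_genes=n_genes, planted_fraction=planted_fraction,
                    n_decoys=n_decoys, sites_per_gene=sites_per_gene,
                    upstream_bp=upstream_bp, motif_width=motif_width,
                    n_chrom=n_chrom, chrom_length=chrom_length,
                    gc_target=gc_target))


def write_fasta(genome: GenomeSequences, path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_bed6(genes: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        for g in genes.itertuples():
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t"
                     f"{g.strand}\n")


def write_jaspar(motifs: list[MotifMatrix], path: str) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.motif_id}\n")
            for bi, base in enumerate("ACGT"):
                row = " ".join(f"{v:g}" for v in m.counts[:, bi])
                fh.write(f"{base} [ {row} ]\n")


def write_bedgraph(track: SignalTrack, path: str) -> None:
    track.intervals.to_csv(path, sep="\t", header=False, index=False,
                           float_format="%.6g")


def write_gene_list(genes: list[str], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")


def write_case(case: BenchmarkCase, out_dir: str) -> dict[str, str]:
    """Write a benchmark case as standard files for CLI consumption."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "genome": os.path.join(out_dir, "genome.fa"),
        "genes": os.path.join(out_dir, "genes.bed"),
        "motifs": os.path.join(out_dir, "motifs.jaspar"),
        "accessibility": os.path.join(out_dir, "accessibility.bedgraph"),
        "user_set": os.path.join(out_dir, "user_set.txt"),
        "universe": os.path.join(out_dir, "universe.txt"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    write_fasta(case.genome, paths["genome"])
    write_bed6(case.genes, paths["genes"])
    write_jaspar(case.motifs, paths["motifs"])
    write_bedgraph(case.accessibility, paths["accessibility"])
    write_gene_list(case.planted_genes, paths["user_set"])
    write_gene_list(case.genes["gene_id"].to_list(), paths["universe"])
    case.site_log.to_csv(paths["truth"], sep="\t", index=False)
    return paths
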