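"""Readers and writers for every external format the pipeline touches.

All genomic coordinates are 0-based half-open after ingestion, regardless of
the source dialect (GTF is converted on read).  No computation happens here
beyond parsing and validation.
"""

from __future__ import annotations

import logging
import math
import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "tss"]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GenomeSequences:
    """Per-chromosome uppercase nucleotide strings (alphabet ACGTN)."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences


@dataclass
class MotifMatrix:
    """Position count matrix (width x 4, columns A,C,G,T order)."""

    motif_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ParseError(f"motif {self.motif_id}: counts must be width x 4")
        if self.counts.shape[0] < 1:
            raise ParseError(f"motif {self.motif_id}: zero-width matrix")
        if (self.counts < 0).any():
            raise ParseError(f"motif {self.motif_id}: negative counts")
        rowsums = self.counts.sum(axis=1)
        if (rowsums <= 0).any():
            pos = int(np.argmax(rowsums <= 0))
            raise ParseError(
                f"motif {self.motif_id}: position {pos + 1} has zero total count"
            )

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.counts, axis=1))


@dataclass
class SignalTrack:
    """Disjoint (chrom, start, end, value) intervals sorted by position."""

    intervals: pd.DataFrame  # columns chrom, start, end, value

    def __post_init__(self) -> None:
        df = self.intervals.reset_index(drop=True)
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        for chrom, grp in df.groupby("chrom", sort=False):
            ends = grp["end"].to_numpy()
            starts = grp["start"].to_numpy()
            if (starts[1:] < ends[:-1]).any():
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise ParseError(
                    f"overlapping intervals on {chrom}: "
                    f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
                )
        if not np.isfinite(df["value"].to_numpy(dtype=float)).all():
            raise ParseError("signal track contains non-finite values")
        self.intervals = df

    def __len__(self) -> int:
        return len(self.intervals)


def read_genome(path: str | os.PathLike) -> GenomeSequences:
    """Read a genome FASTA; sequences are uppercased and validated.

    Raises :class:`ParseError` on empty files, duplicate headers, or
    non-nucleotide characters, naming the offending record.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in sequences:
            raise ParseError(f"duplicate FASTA header: {name!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ParseError(
                f"record {name!r} contains non-nucleotide characters: {sorted(bad)}"
            )
        sequences[name] = seq
    if not sequences:
        raise ParseError(f"no FASTA records found in {path}")
    return GenomeSequences(sequences)


def _finish_annotation(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=GENE_COLUMNS)
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise ParseError(f"duplicate gene_id: {df.loc[dup, 'gene_id'].iloc[0]!r}")
    return df


def read_gene_annotation(path: str | os.PathLike, dialect: str = "bed6") -> pd.DataFrame:
    """Read gene records from BED6 or GTF into a gene table.

    Returns a DataFrame with columns gene_id, chrom, start, end, strand, tss,
    coordinates 0-based half-open.  The TSS is ``start`` for + genes and
    ``end - 1`` for - genes.  GTF 1-based closed coordinates are converted.
    """
    if dialect not in ("bed6", "gtf-gene"):
        raise ValueError(f"unknown annotation dialect: {dialect!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if dialect == "bed6":
                if len(fields) < 6:
                    raise ParseError(f"line {lineno}: BED6 needs 6 fields")
                chrom, start, end, gene_id, _score, strand = fields[:6]
                start, end = int(start), int(end)
            else:
                if len(fields) < 9:
                    raise ParseError(f"line {lineno}: GTF needs 9 fields")
                if fields[2] != "gene":
                    continue
                chrom, strand = fields[0], fields[6]
                start, end = int(fields[3]) - 1, int(fields[4])
                m = re.search(r'gene_id[ =]+"?([^";]+)"?', fields[8])
                if not m:
                    raise ParseError(f"line {lineno}: missing gene_id attribute")
                gene_id = m.group(1)
            if strand not in ("+", "-"):
                raise ParseError(f"line {lineno}: unknown strand {strand!r}")
            if start >= end:
                raise ParseError(f"line {lineno}: start >= end for {gene_id!r}")
            tss = start if strand == "+" else end - 1
            rows.append(
                dict(gene_id=gene_id, chrom=chrom, start=start, end=end,
                     strand=strand, tss=tss)
            )
    return _finish_annotation(rows)


def _dedupe_motif_ids(motifs: list[MotifMatrix]) -> list[MotifMatrix]:
    seen: dict[str, int] = {}
    out = []
    for m in motifs:
        if m.motif_id in seen:
            seen[m.motif_id] += 1
            new_id = f"{m.motif_id}_{seen[m.motif_id]}"
            log.warning("motif id collision: %r renamed to %r", m.motif_id, new_id)
            m = MotifMatrix(new_id, m.counts)
        else:
            seen[m.motif_id] = 1
        out.append(m)
    return out


def _parse_jaspar(text: str) -> list[MotifMatrix]:
    motifs = []
    header = None
    rows: dict[str, list[float]] = {}
    for line in text.splitlines() + [">"]:
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                if set(rows) != set("ACGT"):
                    raise ParseError(f"motif {header!r}: missing base rows")
                widths = {len(v) for v in rows.values()}
                if len(widths) != 1:
                    raise ParseError(f"motif {header!r}: ragged matrix rows")
                counts = np.array([rows[b] for b in "ACGT"]).T
                motifs.append(MotifMatrix(header, counts))
            header = line[1:].split()[0] if len(line) > 1 else None
            rows = {}
        else:
            m = re.match(r"^([ACGT])\s*\[?\s*([\d.eE+\-\s]*?)\s*\]?$", line)
            if not m:
                raise ParseError(f"unparseable JASPAR matrix line: {line!r}")
            rows[m.group(1)] = [float(x) for x in m.group(2).split()]
    return motifs


def _parse_transfac(text: str) -> list[MotifMatrix]:
    motifs = []
    motif_id = None
    matrix: list[list[float]] = []
    in_matrix = False
    for line in text.splitlines():
        tag = line[:2]
        if tag in ("ID", "AC", "NA") and motif_id is None:
            motif_id = line[2:].strip()
        elif tag == "P0" or tag == "PO":
            in_matrix = True
            matrix = []
        elif tag == "//":
            if motif_id is not None and matrix:
                motifs.append(MotifMatrix(motif_id, np.array(matrix)))
            motif_id, matrix, in_matrix = None, [], False
        elif in_matrix and tag.strip().isdigit():
            fields = line.split()
            vals = [float(x) for x in fields[1:5]]
            if len(vals) != 4:
                raise ParseError(f"TRANSFAC row {fields[0]}: expected 4 counts")
            matrix.append(vals)
    if motif_id is not None and matrix:
        motifs.append(MotifMatrix(motif_id, np.array(matrix)))
    return motifs


def _parse_meme(text: str) -> list[MotifMatrix]:
    motifs = []
    lines = iter(text.splitlines())
    for line in lines:
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            width, nsites = None, 20.0
            for line in lines:
                m = re.search(r"letter-probability matrix:.*w=\s*(\d+)", line)
                if m:
                    width = int(m.group(1))
                    mn = re.search(r"nsites=\s*(\d+)", line)
                    if mn:
                        nsites = float(mn.group(1))
                    break
            if width is None:
                raise ParseError(f"motif {motif_id!r}: no letter-probability matrix")
            matrix = []
            for _ in range(width):
                vals = [float(x) for x in next(lines).split()]
                if len(vals) != 4:
                    raise ParseError(f"motif {motif_id!r}: ragged matrix rows")
                matrix.append([v * nsites for v in vals])
            motifs.append(MotifMatrix(motif_id, np.array(matrix)))
    return motifs


def read_motifs(path: str | os.PathLike, dialect: str = "jaspar") -> list[MotifMatrix]:
    """Read a motif collection; counts preserved as printed in the file.

    Supported dialects: ``jaspar`` (count rows per base), ``transfac``
    (P0-delimited count blocks) and ``meme-minimal`` (probability rows,
    rescaled by nsites).  Colliding motif ids get an ``_2`` style suffix.
    """
    with open(path) as fh:
        text = fh.read()
    parsers = {"jaspar": _parse_jaspar, "transfac": _parse_transfac,
               "meme-minimal": _parse_meme}
    if dialect not in parsers:
        raise ValueError(f"unknown motif dialect: {dialect!r}")
    motifs = parsers[dialect](text)
    if not motifs:
        raise ParseError(f"no motifs found in {path}")
    return _dedupe_motif_ids(motifs)


def read_signal_track(path: str | os.PathLike) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"line {lineno}: bedGraph needs 4 columns")
            try:
                value = float(fields[3])
            except ValueError:
                raise ParseError(f"line {lineno}: malformed value {fields[3]!r}")
            if not math.isfinite(value):
                raise ParseError(f"line {lineno}: non-finite value {fields[3]!r}")
            rows.append(dict(chrom=fields[0], start=int(fields[1]),
                             end=int(fields[2]), value=value))
    if not rows:
        raise ParseError(f"no intervals in {path}")
    return SignalTrack(pd.DataFrame(rows))


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """Read a plain-text gene list, one id per line; order preserved."""
    genes = []
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.append(g)
    return genes


def _format_p(p: float) -> str:
    return f"{p:.3g}" if p >= 1e-4 else f"{p:.3e}"


def results_to_frame(results) -> pd.DataFrame:
    """Flatten EnrichmentResult records into a sortable table."""
    rows = []
    for r in results:
        rows.append(dict(
            feature_id=r.feature_id,
            configuration=r.configuration,
            user_set=r.user_set,
            universe_size=r.universe_size,
            target_size=r.target_size,
            user_size=r.user_size,
            overlap=r.overlap,
            p_value=r.p_value,
            neg_log10_p=-math.log10(r.p_value) if r.p_value > 0 else math.inf,
            overlap_genes=",".join(r.overlap_genes),
        ))
    df = pd.DataFrame(rows)
    return df.sort_values(["p_value", "feature_id"], kind="mergesort").reset_index(drop=True)


def write_reports(results_by_config: dict, out_dir: str | os.PathLike,
                  max_p: float = 0.05) -> dict[str, str]:
    """Write the summary TSV and one detail TSV per configuration.

    ``results_by_config`` maps a configuration fingerprint to a list of
    EnrichmentResult.  The detail file keeps rows with p <= ``max_p``
    (sorted ascending by p); the all-results file keeps everything.
    Returns the mapping of logical name -> written path.
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    written: dict[str, str] = {}
    summary_rows = []
    all_frames = []
    for fp, results in results_by_config.items():
        df = results_to_frame(results)
        all_frames.append(df)
        for user_set, grp in df.groupby("user_set", sort=True):
            sig = grp[grp["p_value"] <= max_p]
            top = ",".join(sig["feature_id"].head(5))
            summary_rows.append(dict(
                user_set=user_set, configuration=fp,
                n_tests=len(grp), n_significant=len(sig),
                fraction_significant=len(sig) / len(grp) if len(grp) else 0.0,
                top_features=top,
            ))
        detail = df[df["p_value"] <= max_p].copy()
        detail["p_value"] = detail["p_value"].map(_format_p)
        detail["neg_log10_p"] = detail["neg_log10_p"].map(lambda v: f"{v:.4g}")
        path = os.path.join(out_dir, f"details_{fp}.tsv")
        detail.to_csv(path, sep="\t", index=False)
        written[f"details_{fp}"] = path
    summary_path = os.path.join(out_dir, "summary.tsv")
    pd.DataFrame(summary_rows).to_csv(summary_path, sep="\t", index=False)
    written["summary"] = summary_path
    all_df = pd.concat(all_frames, ignore_index=True) if all_frames else pd.DataFrame()
    if len(all_df):
        all_df = all_df.sort_values(["p_value", "configuration", "feature_id"],
                                    kind="mergesort")
        all_df["p_value"] = all_df["p_value"].map(_format_p)
        all_df["neg_log10_p"] = all_df["neg_log10_p"].map(lambda v: f"{v:.4g}")
    all_path = os.path.join(out_dir, "all_results.tsv")
    all_df.to_csv(all_path, sep="\t", index=False)
    written["all_results"] = all_path
    return written
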