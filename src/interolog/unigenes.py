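"""Transcript-facing rules: read cleaning, unigene selection, TPM, ORFs, N50.

A de novo assembly yields many isoforms (unique transcripts) per gene
cluster; one representative "unigene" per cluster is chosen by maximizing
length × isoform percent.  Upstream, raw reads are cleaned by trimming 3'
adapter contamination and discarding reads whose fraction of unknown (N)
bases exceeds 5%.  Downstream, coding potential is estimated by a
six-frame longest-ORF scan, expression is reported in TPM, and assembly
quality in mean length / N50.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "READ1_ADAPTER",
    "READ2_ADAPTER",
    "IsoformRecord",
    "OrfCall",
    "AssemblyStats",
    "CleanReport",
    "parse_fastq",
    "clean_reads",
    "read_isoform_table",
    "select_unigenes",
    "compute_tpm",
    "find_longest_orf",
    "assembly_stats",
    "filter_by_length",
]

# Illumina TruSeq paired-end adapters (as ligated to read 3' ends)
READ1_ADAPTER = "AGATCGGAAGAGCACACGTC"
READ2_ADAPTER = "AGATCGGAAGAGCGTCGTGT"

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class IsoformRecord:
    """One transcript's length and abundance within its gene cluster."""

    transcript_id: str
    gene_id: str
    length: int
    expected_count: float
    isoform_percent: float


@dataclass(frozen=True)
class OrfCall:
    """An open reading frame reported on forward-strand coordinates.

    ``start``/``end`` are 1-based inclusive on the forward strand even for
    minus-strand calls; the stop codon, when present, is included in the
    span.  ``frame`` is the 0/1/2 reading offset on the calling strand.
    """

    unigene_id: str
    strand: str  # '+' or '-'
    frame: int
    start: int
    end: int
    protein: str
    has_stop: bool
    found: bool

    @property
    def nt_length(self) -> int:
        return self.end - self.start + 1 if self.found else 0


@dataclass(frozen=True)
class AssemblyStats:
    n_sequences: int
    mean_length: float
    n50: int
    total_nt: int


@dataclass
class CleanReport:
    total: int = 0
    kept: int = 0
    dropped_n: int = 0
    dropped_quality: int = 0
    trimmed: int = 0


# ---------------------------------------------------------------------------
# read cleaning


def parse_fastq(handle) -> Iterator[SeqRecord]:
    """FASTQ parser that localizes malformed records by index."""
    index = 0
    try:
        for rec in SeqIO.parse(handle, "fastq"):
            yield rec
            index += 1
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ at record index {index}: {exc}") from exc


def _trim_adapter(seq: str, adapter: str, min_overlap: int = 8) -> tuple[str, int]:
    """Trim the longest read suffix that exactly matches a prefix of the adapter."""
    limit = min(len(seq), len(adapter))
    for k in range(limit, min_overlap - 1, -1):
        if seq.endswith(adapter[:k]):
            return seq[: len(seq) - k], k
    return seq, 0


def clean_reads(
    reads: Iterable[SeqRecord],
    adapters: Sequence[str] = (READ1_ADAPTER, READ2_ADAPTER),
    max_unknown_fraction: float = 0.05,
    min_mean_quality: float | None = None,
    min_overlap: int = 8,
) -> tuple[list[SeqRecord], CleanReport]:
    """Adapter-trim then N-filter a read stream.

    3' adapter suffixes (exact prefix match, >= ``min_overlap`` nt) are
    removed first; a read is then dropped when its N fraction is strictly
    greater than ``max_unknown_fraction`` (default 5%), or — only if
    ``min_mean_quality`` is set — when its mean Phred quality falls below
    that threshold.  Returns the kept records and a count report.
    """
    if not 0 <= max_unknown_fraction <= 1:
        raise ValueError("max_unknown_fraction must be in [0, 1]")
    report = CleanReport()
    kept: list[SeqRecord] = []
    for rec in reads:
        report.total += 1
        seq = str(rec.seq).upper()
        quals = rec.letter_annotations.get("phred_quality")
        trimmed_total = 0
        for adapter in adapters:
            seq, cut = _trim_adapter(seq, adapter.upper(), min_overlap)
            trimmed_total += cut
            if cut:
                break
        if trimmed_total:
            report.trimmed += 1
            if quals is not None:
                quals = quals[: len(seq)]
        if len(seq) == 0 or seq.count("N") / len(seq) > max_unknown_fraction:
            report.dropped_n += 1
            continue
        if min_mean_quality is not None and quals:
            if sum(quals) / len(quals) < min_mean_quality:
                report.dropped_quality += 1
                continue
        out = SeqRecord(Seq(seq), id=rec.id, description=rec.description)
        if quals is not None:
            out.letter_annotations["phred_quality"] = quals
        kept.append(out)
        report.kept += 1
    return kept, report


# ---------------------------------------------------------------------------
# isoform table / unigene selection / TPM


def read_isoform_table(path) -> pd.DataFrame:
    """Read an RSEM-like isoform TSV.

    Recognized columns (header tolerated, case-insensitive):
    transcript_id, gene_id, length, expected_count, IsoPct.
    """
    df = pd.read_csv(path, sep="\t")
    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in ("transcript_id", "gene_id", "length", "expected_count"):
            rename[col] = key
        elif key in ("isopct", "isoform_percent"):
            rename[col] = "isoform_percent"
    df = df.rename(columns=rename)
    required = {"transcript_id", "gene_id", "length", "isoform_percent"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"isoform table missing columns: {sorted(missing)}")
    return df


def select_unigenes(records: pd.DataFrame) -> dict[str, str]:
    """Pick one representative transcript per gene by length × isoform percent.

    Ties go to the longer transcript, then to the lexicographically
    smallest transcript id.  Genes absent from the table are absent from
    the output.
    """
    if records.empty:
        raise ValueError("isoform table is empty")
    df = records.copy()
    df["_score"] = df["length"].astype(float) * df["isoform_percent"].astype(float)
    df = df.sort_values(
        by=["gene_id", "_score", "length", "transcript_id"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    best = df.drop_duplicates(subset="gene_id", keep="first")
    return dict(zip(best["gene_id"], best["transcript_id"]))


def compute_tpm(records: pd.DataFrame) -> pd.Series:
    """Transcripts-per-million from expected counts and lengths.

    TPM_i = (count_i / length_i) / sum_j (count_j / length_j) * 1e6.
    Values sum to 1e6 whenever any count is positive; an all-zero table
    yields all-zero TPM rather than a division error.
    """
    lengths = records["length"].astype(float)
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    rate = records["expected_count"].astype(float) / lengths
    total = rate.sum()
    if total == 0:
        tpm = rate * 0.0
    else:
        tpm = rate / total * 1e6
    return pd.Series(tpm.values, index=records["transcript_id"].values, name="TPM")


# ---------------------------------------------------------------------------
# ORF scanning


def _scan_strand(seq: str) -> list[tuple[int, int, int, bool]]:
    """All maximal ATG->stop ORFs on one strand.

    Returns (start0, end0, frame, has_stop) with 0-based inclusive
    coordinates on the given strand; the stop codon is included.  Per
    frame, an open ATG without a downstream in-frame stop yields one
    partial ORF truncated at the last complete codon.
    """
    n = len(seq)
    orfs = []
    for frame in range(3):
        atg_at: int | None = None
        pos = frame
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if atg_at is None:
                if codon == "ATG":
                    atg_at = pos
            elif codon in STOP_CODONS:
                orfs.append((atg_at, pos + 2, frame, True))
                atg_at = None
            pos += 3
        if atg_at is not None:
            last = atg_at + 3 * ((n - atg_at) // 3) - 1
            if last > atg_at:
                orfs.append((atg_at, last, frame, False))
    return orfs


def _translate(orf_nt: str, has_stop: bool) -> str:
    coding = orf_nt[:-3] if has_stop else orf_nt
    return str(Seq(coding).translate())


def find_longest_orf(sequence: str, unigene_id: str = "") -> OrfCall:
    """Six-frame longest-ORF call with 1-based forward-strand coordinates.

    An ORF runs from ATG to the first in-frame stop (stop included).
    Complete ORFs are preferred; only when none exists anywhere is the
    longest open ATG-to-end stretch reported (``has_stop=False``).  Ties
    are broken in favor of the forward strand, then the smallest start.
    An empty or ORF-free sequence yields ``found=False``.
    """
    seq = sequence.upper()
    n = len(seq)
    candidates: list[tuple[int, int, str, int, int, bool]] = []
    # (length, strand_rank, strand, fwd_start0, fwd_end0/frame carried via dict)
    records = []
    for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        for s0, e0, frame, has_stop in _scan_strand(s):
            if strand == "+":
                f_start, f_end = s0, e0
            else:
                f_start, f_end = n - 1 - e0, n - 1 - s0
            records.append(
                {
                    "length": e0 - s0 + 1,
                    "strand": strand,
                    "frame": frame,
                    "f_start": f_start,
                    "f_end": f_end,
                    "s0": s0,
                    "e0": e0,
                    "has_stop": has_stop,
                    "strand_seq": s,
                }
            )
    complete = [r for r in records if r["has_stop"]]
    pool = complete if complete else records
    if not pool:
        return OrfCall(unigene_id, "+", 0, 0, 0, "", False, False)
    best = min(
        pool,
        key=lambda r: (-r["length"], 0 if r["strand"] == "+" else 1, r["f_start"]),
    )
    orf_nt = best["strand_seq"][best["s0"] : best["e0"] + 1]
    protein = _translate(orf_nt, best["has_stop"])
    return OrfCall(
        unigene_id=unigene_id,
        strand=best["strand"],
        frame=best["frame"],
        start=best["f_start"] + 1,
        end=best["f_end"] + 1,
        protein=protein,
        has_stop=best["has_stop"],
        found=True,
    )


# ---------------------------------------------------------------------------
# assembly statistics


def assembly_stats(lengths: Sequence[int]) -> AssemblyStats:
    """Sequence count, mean length, N50 and total nucleotides.

    N50: scanning lengths in descending order, the first length at which
    the cumulative sum reaches at least half of the total.
    """
    if len(lengths) == 0:
        raise ValueError("assembly_stats needs a non-empty length list")
    arr = np.asarray(lengths, dtype=np.int64)
    if (arr <= 0).any():
        raise ValueError("lengths must be positive")
    total = int(arr.sum())
    desc = np.sort(arr)[::-1]
    cum = np.cumsum(desc)
    n50 = int(desc[np.searchsorted(cum, total / 2)])
    return AssemblyStats(
        n_sequences=int(arr.size),
        mean_length=float(arr.mean()),
        n50=n50,
        total_nt=total,
    )


def filter_by_length(
    records: Iterable[SeqRecord], min_length: int = 300, strict: bool = True
) -> list[SeqRecord]:
    """Keep sequences longer than ``min_length`` (strictly, by default)."""
    if strict:
        return [r for r in records if len(r.seq) > min_length]
    return [r for r in records if len(r.seq) >= min_length]
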