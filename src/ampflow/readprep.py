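"""Collapse demultiplexed read pairs into single sequences, by two paths.

Short amplicons (expected length <= 550 bp) are end-trimmed at a quality
threshold swept over a fixed ladder, overlap-joined into contigs, and
length-filtered; the trimming threshold is the one maximizing contig yield.
Long amplicons (> 550 bp), whose mates barely overlap, are hard-trimmed to a
uniform 75% of the read length and concatenated into scaffolds with a 4-N
spacer between forward read and reverse-complemented reverse read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqio import NucleotideRead, ReadPair, revcomp

__all__ = [
    "Contig",
    "SweepReport",
    "DEFAULT_SWEEP_THRESHOLDS",
    "end_trim",
    "merge_overlap",
    "sweep_join",
    "filter_contig_length",
    "long_path_prepare",
    "build_scaffold",
]

#: Quality ladder swept when choosing the short-path end-trimming threshold.
DEFAULT_SWEEP_THRESHOLDS = (0, 3, 10, 15, 20, 25, 30, 35, 36, 37, 38)


@dataclass
class Contig:
    """A joined (short path) or scaffolded (long path) amplicon sequence."""

    sequence: str
    library_id: str
    source: str  # "joined" or "scaffold"
    join_overlap: int = 0


@dataclass
class SweepReport:
    """Contig yield per candidate trimming threshold and the chosen one."""

    thresholds: list[int]
    contig_counts: list[int]
    chosen_threshold: int


def end_trim(read: NucleotideRead, q: int, rule: str = "below") -> NucleotideRead:
    """Truncate a read before its first low-quality base.

    ``rule="below"`` cuts before the first position with quality < q (so q=0
    never trims); ``rule="at_or_below"`` cuts before the first position with
    quality <= q. May return an empty read.
    """
    if q < 0:
        raise ValueError("q must be >= 0")
    if rule not in ("below", "at_or_below"):
        raise ValueError(f"unknown rule {rule!r}")
    cut = len(read)
    for i, qual in enumerate(read.qualities):
        if (qual < q) if rule == "below" else (qual <= q):
            cut = i
            break
    return read.slice(0, cut)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


_N_BYTE = ord("N")


def merge_overlap(
    fwd: NucleotideRead,
    rev: NucleotideRead,
    min_overlap: int = 6,
    max_mismatch_frac: float = 0.08,
    library_id: str = "",
) -> Contig | None:
    """Overlap-join a pair into a contig, or return None if no acceptable overlap.

    The reverse read is reverse-complemented, then every candidate overlap
    length l in [min_overlap, min(len(fwd), len(rev))] between the forward
    3' end and the reverse-complement 5' end is scored by mismatch fraction
    (N matches anything). The overlap minimizing the mismatch fraction wins,
    ties going to the longest; the join is rejected if the best fraction
    exceeds ``max_mismatch_frac``. At disagreeing columns the consensus takes
    the higher-quality base (tie: forward); consensus quality is the max.
    """
    lf, lr = len(fwd), len(rev)
    max_l = min(lf, lr)
    if max_l < min_overlap:
        return None
    rc_seq = revcomp(rev.sequence)
    rc_qual = rev.qualities[::-1]
    f = _encode(fwd.sequence)
    r = _encode(rc_seq)

    # Mismatch count for overlap l is the sum over the anti-diagonal
    # i - j == lf - l of the pairwise inequality matrix; one bincount
    # computes all candidate overlaps at once.
    neq = (f[:, None] != r[None, :]) & (f[:, None] != _N_BYTE) & (r[None, :] != _N_BYTE)
    offsets = (np.arange(lf)[:, None] - np.arange(lr)[None, :]).ravel() + (lr - 1)
    mism_by_offset = np.bincount(offsets, weights=neq.ravel(), minlength=lf + lr - 1)

    lengths = np.arange(max_l, min_overlap - 1, -1)  # descending => argmin picks longest tie
    fracs = mism_by_offset[(lf - lengths) + (lr - 1)] / lengths
    best = int(np.argmin(fracs))
    if fracs[best] > max_mismatch_frac:
        return None
    overlap = int(lengths[best])

    f_tail = fwd.sequence[lf - overlap :]
    f_tail_q = fwd.qualities[lf - overlap :]
    r_head = rc_seq[:overlap]
    r_head_q = rc_qual[:overlap]
    consensus = []
    for fb, fq, rb, rq in zip(f_tail, f_tail_q, r_head, r_head_q):
        if fb == rb:
            consensus.append(fb)
        elif fb == "N":
            consensus.append(rb)
        elif rb == "N":
            consensus.append(fb)
        else:
            consensus.append(fb if fq >= rq else rb)
    sequence = fwd.sequence[: lf - overlap] + "".join(consensus) + rc_seq[overlap:]
    return Contig(sequence, library_id, "joined", overlap)


def sweep_join(
    pairs: Sequence[tuple[str, ReadPair]],
    thresholds: Sequence[int] = DEFAULT_SWEEP_THRESHOLDS,
    min_overlap: int = 6,
    max_mismatch_frac: float = 0.08,
) -> tuple[SweepReport, list[Contig]]:
    """Choose the end-trim quality maximizing contig yield for one dataset.

    ``pairs`` are (library_id, trimmed-oriented pair). For each threshold t
    both mates are end-trimmed (rule "below"), empty reads drop the pair, and
    the survivors are overlap-joined; the threshold with the most contigs
    wins, ties going to the highest threshold. Returns the report and the
    contigs produced at the chosen threshold.
    """

    def contigs_at(q: int) -> list[Contig]:
        out = []
        for lib_id, pair in pairs:
            tf = end_trim(pair.forward, q, "below")
            tr = end_trim(pair.reverse, q, "below")
            if len(tf) == 0 or len(tr) == 0:
                continue
            contig = merge_overlap(tf, tr, min_overlap, max_mismatch_frac, lib_id)
            if contig is not None:
                out.append(contig)
        return out

    counts = [len(contigs_at(q)) for q in thresholds]
    best_count = max(counts) if counts else 0
    # Highest threshold among maximizers: equal yield, strictly better quality.
    chosen = max(q for q, c in zip(thresholds, counts) if c == best_count) if counts else 0
    report = SweepReport(list(thresholds), counts, chosen)
    return report, contigs_at(chosen)


def filter_contig_length(contigs: Sequence[Contig], expected_len: int) -> list[Contig]:
    """Keep contigs at least 75% of the dataset's approximate amplicon length."""
    if expected_len <= 0:
        raise ValueError("expected_len must be positive")
    cutoff = 0.75 * expected_len
    return [c for c in contigs if len(c.sequence) >= cutoff]


def long_path_prepare(
    pairs: Sequence[tuple[str, ReadPair]], read_len: int = 300
) -> list[tuple[str, ReadPair]]:
    """Quality-trim long-amplicon pairs to a uniform 75% of the read length.

    Both mates are end-trimmed at the first base with quality <= 3; the pair
    is discarded if either trimmed mate is shorter than ceil(0.75*read_len);
    survivors are truncated to floor(0.75*read_len), giving uniform lengths.
    """
    survive = math.ceil(0.75 * read_len)
    uniform = math.floor(0.75 * read_len)
    out = []
    for lib_id, pair in pairs:
        tf = end_trim(pair.forward, 3, "at_or_below")
        tr = end_trim(pair.reverse, 3, "at_or_below")
        if len(tf) < survive or len(tr) < survive:
            continue
        out.append((lib_id, ReadPair(tf.slice(0, uniform), tr.slice(0, uniform))))
    return out


def build_scaffold(fwd: NucleotideRead, rev: NucleotideRead, library_id: str = "") -> Contig:
    """Concatenate forward read, 4-N spacer, and reverse-complemented reverse read."""
    if len(fwd) != len(rev):
        raise ValueError("scaffold mates must have uniform length")
    return Contig(fwd.sequence + "NNNN" + revcomp(rev.sequence), library_id, "scaffold")
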