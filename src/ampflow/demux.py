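"""Assign read pairs to (dataset, library) by barcode/primer matching.

Each amplicon carries the same 5' construct on both ends:
``barcode(8) + head(16) + gene primer``. A pair is assigned to a library when
both gene primers are found (one per mate, either orientation) and the
library barcode is found on at least one mate, each component within its own
substitution-mismatch budget (default 1 per component). Pairs matching no
candidate are *unassigned*; pairs matching more than one (library,
orientation) candidate are *ambiguous* and discarded rather than resolved
arbitrarily.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .seqio import (
    DatasetSpec,
    IUPAC_SETS,
    LibrarySpec,
    NucleotideRead,
    ReadPair,
    write_fastq,
)

__all__ = [
    "MatchResult",
    "Assignment",
    "DemuxStats",
    "count_mismatches",
    "match_read_start",
    "assign_pair",
    "demultiplex",
]

BARCODE_LEN = 8
HEAD_LEN = 16


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one read's 5' construct against one library."""

    matched: bool
    barcode_mm: int = -1
    primer_mm: int = -1
    primer_role: str = ""  # "fwd" or "rev"
    payload_start: int = -1  # first base after the primer (0-based)


@dataclass
class Assignment:
    """A successfully demultiplexed pair, trimmed and oriented."""

    pair: ReadPair
    dataset_id: str
    library_id: str
    orientation: str  # "fwd_is_read1" or "fwd_is_read2"
    trimmed_pair: ReadPair


@dataclass
class DemuxStats:
    """Bookkeeping for one demultiplexing run; counts always partition."""

    total_pairs: int = 0
    assigned_pairs: int = 0
    ambiguous_pairs: int = 0
    unassigned_pairs: int = 0
    per_library: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        if self.assigned_pairs + self.ambiguous_pairs + self.unassigned_pairs != self.total_pairs:
            raise AssertionError("demux counts do not partition the input")


def count_mismatches(observed: str, pattern: str) -> int:
    """Hamming-style mismatch count of an observed read segment vs an IUPAC pattern.

    A position matches iff the observed base is in the pattern code's
    expansion; pattern N matches anything; an observed N matches only a
    pattern N (the only code whose expansion is all four bases).
    """
    if len(observed) != len(pattern):
        raise ValueError(f"length mismatch: {len(observed)} vs {len(pattern)}")
    mm = 0
    for o, p in zip(observed, pattern):
        if o == p:
            continue
        exp = IUPAC_SETS.get(p)
        if exp is None:
            raise ValueError(f"non-IUPAC pattern character {p!r}")
        if o == "N":
            if len(exp) < 4:
                mm += 1
        elif o not in exp:
            mm += 1
    return mm


def match_read_start(
    read: NucleotideRead,
    barcode: str,
    head: str,
    primer: str,
    max_bc_mm: int = 1,
    max_pr_mm: int = 1,
    check_head: bool = False,
    primer_role: str = "fwd",
) -> MatchResult:
    """Match ``barcode+head+primer`` at the 5' end of a read.

    Barcode occupies [0, 8), head [8, 24) (checked only with ``check_head``),
    primer [24, 24 + len(primer)). Substitutions only; a too-short read is
    simply unmatched.
    """
    start = BARCODE_LEN + HEAD_LEN
    end = start + len(primer)
    if len(read) < end:
        return MatchResult(False)
    bc_mm = count_mismatches(read.sequence[:BARCODE_LEN], barcode)
    if bc_mm > max_bc_mm:
        return MatchResult(False)
    if check_head:
        head_mm = count_mismatches(read.sequence[BARCODE_LEN:start], head)
        if head_mm > max_bc_mm:
            return MatchResult(False)
    pr_mm = count_mismatches(read.sequence[start:end], primer)
    if pr_mm > max_pr_mm:
        return MatchResult(False)
    return MatchResult(True, bc_mm, pr_mm, primer_role, end)


def _match_primer_only(read: NucleotideRead, primer: str, max_pr_mm: int) -> int | None:
    """Mismatch count of the primer at its fixed offset, or None if over budget."""
    start = BARCODE_LEN + HEAD_LEN
    end = start + len(primer)
    if len(read) < end:
        return None
    mm = count_mismatches(read.sequence[start:end], primer)
    return mm if mm <= max_pr_mm else None


def assign_pair(
    pair: ReadPair,
    libraries: Sequence[LibrarySpec],
    datasets: Sequence[DatasetSpec],
    max_bc_mm: int = 1,
    max_pr_mm: int = 1,
    check_head: bool = False,
) -> Assignment | str:
    """Assign one pair; returns an :class:`Assignment` or ``"ambiguous"``/``"unassigned"``.

    A candidate is a (library, orientation). It matches when the mate in the
    forward role carries the forward primer and the mate in the reverse role
    the reverse primer (both within budget), and at least one mate also
    carries the library barcode within budget. Exactly one matching candidate
    is required for assignment; candidates are evaluated in a fixed order so
    the verdict is independent of mapping-file ordering.
    """
    ds_by_id = {d.dataset_id: d for d in datasets}
    candidates: list[tuple[LibrarySpec, str, DatasetSpec]] = []
    for lib in sorted(libraries, key=lambda l: l.library_id):
        ds = ds_by_id[lib.dataset_id]
        for orientation in ("fwd_is_read1", "fwd_is_read2"):
            fwd_read = pair.forward if orientation == "fwd_is_read1" else pair.reverse
            rev_read = pair.reverse if orientation == "fwd_is_read1" else pair.forward
            m_f = match_read_start(
                fwd_read, lib.barcode, ds.head, ds.fwd_primer, max_bc_mm, max_pr_mm, check_head, "fwd"
            )
            m_r = match_read_start(
                rev_read, lib.barcode, ds.head, ds.rev_primer, max_bc_mm, max_pr_mm, check_head, "rev"
            )
            if m_f.matched and m_r.matched:
                ok = True
            elif m_f.matched:
                ok = _match_primer_only(rev_read, ds.rev_primer, max_pr_mm) is not None
            elif m_r.matched:
                ok = _match_primer_only(fwd_read, ds.fwd_primer, max_pr_mm) is not None
            else:
                ok = False
            if ok:
                candidates.append((lib, orientation, ds))

    if not candidates:
        return "unassigned"
    if len(candidates) > 1:
        return "ambiguous"

    lib, orientation, ds = candidates[0]
    fwd_read = pair.forward if orientation == "fwd_is_read1" else pair.reverse
    rev_read = pair.reverse if orientation == "fwd_is_read1" else pair.forward
    cut_f = BARCODE_LEN + HEAD_LEN + len(ds.fwd_primer)
    cut_r = BARCODE_LEN + HEAD_LEN + len(ds.rev_primer)
    trimmed = ReadPair(fwd_read.slice(cut_f, len(fwd_read)), rev_read.slice(cut_r, len(rev_read)))
    return Assignment(pair, ds.dataset_id, lib.library_id, orientation, trimmed)


def demultiplex(
    pairs: Iterable[ReadPair],
    libraries: Sequence[LibrarySpec],
    datasets: Sequence[DatasetSpec],
    out_dir: str | Path | None = None,
    max_bc_mm: int = 1,
    max_pr_mm: int = 1,
    check_head: bool = False,
    write_corrected: bool = False,
) -> tuple[DemuxStats, dict[str, list[Assignment]]]:
    """Demultiplex a run; returns stats and assignments grouped by dataset.

    When ``out_dir`` is given, writes per-dataset oriented, trimmed FASTQ
    pairs (``<dataset>/R1.fastq``, ``R2.fastq``) with the library id embedded
    in each read header, a ``demux_stats.tsv``, and (optionally) FASTQ files
    of the *expected* barcode/primer sequences per assigned pair, for
    interoperability with mapping-file-driven downstream tools.
    """
    stats = DemuxStats(per_library={lib.library_id: 0 for lib in libraries})
    by_dataset: dict[str, list[Assignment]] = {d.dataset_id: [] for d in datasets}
    for pair in pairs:
        stats.total_pairs += 1
        verdict = assign_pair(pair, libraries, datasets, max_bc_mm, max_pr_mm, check_head)
        if verdict == "unassigned":
            stats.unassigned_pairs += 1
        elif verdict == "ambiguous":
            stats.ambiguous_pairs += 1
        else:
            assert isinstance(verdict, Assignment)
            stats.assigned_pairs += 1
            stats.per_library[verdict.library_id] += 1
            by_dataset[verdict.dataset_id].append(verdict)
    stats.check()

    if out_dir is not None:
        out_dir = Path(out_dir)
        lib_by_id = {l.library_id: l for l in libraries}
        ds_by_id = {d.dataset_id: d for d in datasets}
        for ds_id, assignments in by_dataset.items():
            ds_dir = out_dir / ds_id
            ds_dir.mkdir(parents=True, exist_ok=True)
            r1, r2, bc_reads, pr_reads = [], [], [], []
            for a in assignments:
                fwd = a.trimmed_pair.forward
                rev = a.trimmed_pair.reverse
                # keep the tag inside the id token so FASTQ round-trips preserve it
                header = f"{fwd.read_id}|library={a.library_id}"
                r1.append(NucleotideRead(header, fwd.sequence, fwd.qualities))
                r2.append(NucleotideRead(header, rev.sequence, rev.qualities))
                if write_corrected:
                    lib = lib_by_id[a.library_id]
                    ds = ds_by_id[ds_id]
                    bc_reads.append(NucleotideRead(header, lib.barcode, [40] * BARCODE_LEN))
                    pr_reads.append(
                        NucleotideRead(header, ds.fwd_primer, [40] * len(ds.fwd_primer))
                    )
            write_fastq(r1, ds_dir / "R1.fastq")
            write_fastq(r2, ds_dir / "R2.fastq")
            if write_corrected:
                write_fastq(bc_reads, ds_dir / "barcodes.fastq")
                write_fastq(pr_reads, ds_dir / "primers.fastq")
        with open(out_dir / "demux_stats.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["metric", "value"])
            w.writerow(["total_pairs", stats.total_pairs])
            w.writerow(["assigned_pairs", stats.assigned_pairs])
            w.writerow(["ambiguous_pairs", stats.ambiguous_pairs])
            w.writerow(["unassigned_pairs", stats.unassigned_pairs])
            for lib_id, n in sorted(stats.per_library.items()):
                w.writerow([f"library:{lib_id}", n])

    return stats, by_dataset
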