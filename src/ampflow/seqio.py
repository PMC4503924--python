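"""Sequence I/O and the core data model shared by all pipeline stages.

FASTQ is always Phred+33 (modern Illumina); FASTA is parsed tolerantly and
uppercased on ingest. Gzip is handled transparently for paths ending in
``.gz``. Coordinates are 0-based, half-open throughout the package.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "NucleotideRead",
    "ReadPair",
    "LibrarySpec",
    "DatasetSpec",
    "DEFAULT_HEAD",
    "IUPAC_SETS",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "revcomp",
    "read_mapping",
]

#: Universal 16-nt linker between barcode and gene-specific primer.
DEFAULT_HEAD = "GCTATGCGCGAGCTGC"

#: IUPAC nucleotide codes expanded to the set of concrete bases they stand for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class MappingError(ValueError):
    """Raised when a mapping table violates a structural requirement."""


def _validate_dna(seq: str, *, what: str = "sequence") -> str:
    s = seq.upper()
    bad = set(s) - set(IUPAC_SETS)
    if bad:
        raise ValueError(f"non-IUPAC character(s) {sorted(bad)} in {what}: {seq!r}")
    return s


@dataclass
class NucleotideRead:
    """A single read: identifier, IUPAC DNA string, per-base Phred scores."""

    read_id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        self.sequence = _validate_dna(self.sequence, what=f"read {self.read_id!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, stop: int) -> "NucleotideRead":
        """Return the 0-based half-open sub-read [start, stop)."""
        return NucleotideRead(self.read_id, self.sequence[start:stop], self.qualities[start:stop])


@dataclass
class ReadPair:
    """A forward/reverse mate pair; the demultiplexing and QC unit."""

    forward: NucleotideRead
    reverse: NucleotideRead


@dataclass(frozen=True)
class LibrarySpec:
    """One amplicon library: an 8-nt barcode within a dataset."""

    library_id: str
    barcode: str
    dataset_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "barcode", _validate_dna(self.barcode, what="barcode"))
        if len(self.barcode) != 8:
            raise ValueError(f"library {self.library_id!r}: barcode must be 8 nt, got {len(self.barcode)}")


@dataclass(frozen=True)
class DatasetSpec:
    """Dataset-level metadata: primers, amplicon length, processing path.

    ``expected_len`` is the approximate amplicon length *including* primers;
    datasets over 550 bp take the scaffold (long) path, all others the
    overlap-join (short) path. ``otu_radius_pct`` is the OTU radius in
    percent (3 => 97% cluster identity); ``map_identity`` the read-to-centroid
    mapping threshold as a fraction.
    """

    dataset_id: str
    fwd_primer: str
    rev_primer: str
    expected_len: int
    head: str = DEFAULT_HEAD
    otu_radius_pct: float = 3.0
    map_identity: float = 0.97

    def __post_init__(self) -> None:
        object.__setattr__(self, "head", _validate_dna(self.head, what="head"))
        object.__setattr__(self, "fwd_primer", _validate_dna(self.fwd_primer, what="fwd_primer"))
        object.__setattr__(self, "rev_primer", _validate_dna(self.rev_primer, what="rev_primer"))
        if len(self.head) != 16:
            raise ValueError(f"dataset {self.dataset_id!r}: head must be 16 nt")
        if self.expected_len <= 0:
            raise ValueError(f"dataset {self.dataset_id!r}: expected_len must be positive")
        if not (0 < self.map_identity <= 1):
            raise ValueError(f"dataset {self.dataset_id!r}: map_identity must be in (0, 1]")

    @property
    def path(self) -> str:
        """Processing path: ``"long"`` iff expected_len > 550, else ``"short"``."""
        return "long" if self.expected_len > 550 else "short"


def revcomp(sequence: str) -> str:
    """Reverse complement with IUPAC ambiguity codes mapped to their complements."""
    s = _validate_dna(sequence)
    return s.translate(_COMPLEMENT)[::-1]


def _open_text(path: str | Path, mode: str = "rt") -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[NucleotideRead]:
    """Stream reads from a Phred+33 FASTQ file (``.gz`` transparently).

    Malformed records raise ``ValueError`` naming the (0-based) record index.
    """
    with _open_text(path) as handle:
        index = 0
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                yield NucleotideRead(
                    rec.id, str(rec.seq).upper(), list(rec.letter_annotations["phred_quality"])
                )
                index += 1
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record at index {index} in {path}: {exc}") from exc


def write_fastq(reads: Iterable[NucleotideRead], path: str | Path) -> int:
    """Write reads as 4-line Phred+33 FASTQ; returns the number written."""
    n = 0
    with _open_text(path, "wt") as handle:
        for read in reads:
            rec = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
            rec.letter_annotations["phred_quality"] = list(read.qualities)
            SeqIO.write(rec, handle, "fastq")
            n += 1
    return n


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(label, sequence)`` pairs, uppercased."""
    out = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            out.append((rec.description or rec.id, _validate_dna(str(rec.seq), what=rec.id)))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, *, wrap: int | None = None) -> int:
    """Write ``(label, sequence)`` pairs as FASTA (single-line unless ``wrap``)."""
    n = 0
    with _open_text(path, "wt") as handle:
        for label, seq in records:
            handle.write(f">{label}\n")
            if wrap:
                for i in range(0, len(seq), wrap):
                    handle.write(seq[i : i + wrap] + "\n")
            else:
                handle.write(seq + "\n")
            n += 1
    return n


_MAPPING_REQUIRED = ["library_id", "barcode", "dataset_id", "fwd_primer", "rev_primer", "expected_len"]
_MAPPING_OPTIONAL = ["head", "otu_radius_pct", "map_identity"]


def read_mapping(path: str | Path) -> tuple[list[LibrarySpec], list[DatasetSpec]]:
    """Parse the tab-separated mapping table into library and dataset specs.

    The table has a header row; ``#`` comment lines are ignored. Required
    columns: library_id, barcode, dataset_id, fwd_primer, rev_primer,
    expected_len. Optional: head, otu_radius_pct, map_identity (dataset-level
    values must agree across rows of the same dataset). Errors name the
    offending 1-based data row.
    """
    with _open_text(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise MappingError(f"mapping file {path} is empty")
    header = lines[0].split("\t")
    missing = [c for c in _MAPPING_REQUIRED if c not in header]
    if missing:
        raise MappingError(f"mapping file {path}: missing column(s) {missing}")

    libraries: list[LibrarySpec] = []
    dataset_rows: dict[str, dict] = {}
    seen_lib_ids: set[str] = set()
    seen_bc_ds: set[tuple[str, str]] = set()
    for row_no, line in enumerate(lines[1:], start=1):
        values = dict(zip(header, line.split("\t")))
        try:
            lib_id = values["library_id"]
            if lib_id in seen_lib_ids:
                raise MappingError(f"duplicate library_id {lib_id!r}")
            seen_lib_ids.add(lib_id)
            lib = LibrarySpec(lib_id, values["barcode"], values["dataset_id"])
            key = (lib.barcode, lib.dataset_id)
            if key in seen_bc_ds:
                raise MappingError(f"duplicate (barcode, dataset) {key}")
            seen_bc_ds.add(key)

            ds_kwargs: dict = {
                "dataset_id": values["dataset_id"],
                "fwd_primer": values["fwd_primer"],
                "rev_primer": values["rev_primer"],
                "expected_len": int(values["expected_len"]),
            }
            if values.get("head"):
                ds_kwargs["head"] = values["head"]
            if values.get("otu_radius_pct"):
                ds_kwargs["otu_radius_pct"] = float(values["otu_radius_pct"])
            if values.get("map_identity"):
                ds_kwargs["map_identity"] = float(values["map_identity"])
            normalized = DatasetSpec(**ds_kwargs)
            prev = dataset_rows.get(lib.dataset_id)
            if prev is None:
                dataset_rows[lib.dataset_id] = normalized
            elif prev != normalized:
                raise MappingError(f"dataset {lib.dataset_id!r}: inconsistent dataset-level fields")
            libraries.append(lib)
        except (MappingError, ValueError, KeyError) as exc:
            raise MappingError(f"mapping file {path}, data row {row_no}: {exc}") from exc

    return libraries, list(dataset_rows.values())


def write_mapping(
    libraries: Iterable[LibrarySpec], datasets: Iterable[DatasetSpec], path: str | Path
) -> None:
    """Write specs back out in the dialect accepted by :func:`read_mapping`."""
    by_ds = {d.dataset_id: d for d in datasets}
    cols = _MAPPING_REQUIRED + _MAPPING_OPTIONAL
    with _open_text(path, "wt") as handle:
        handle.write("\t".join(cols) + "\n")
        for lib in libraries:
            ds = by_ds[lib.dataset_id]
            handle.write(
                "\t".join(
                    [
                        lib.library_id,
                        lib.barcode,
                        lib.dataset_id,
                        ds.fwd_primer,
                        ds.rev_primer,
                        str(ds.expected_len),
                        ds.head,
                        str(ds.otu_radius_pct),
                        str(ds.map_identity),
                    ]
                )
                + "\n"
            )
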