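"""Synthetic two-step-PCR amplicon runs with complete ground truth.

The simulator emulates the mock-community experiment this package is built
to analyze: five reference clones mixed evenly or unevenly (76/18/5/0.7/0.09%
relative abundance), amplified for a chosen number of step-1 (gene primer)
and step-2 (barcode attachment) cycles, pooled, and sequenced as 2x300
paired reads.

Mechanisms modeled per PCR cycle:

* **Efficiency drift** - each template class amplifies with its own
  efficiency: a fixed per-class log-efficiency offset (sigma
  ``efficiency_bias_sd``), shared by all libraries built from the same
  clones, models kinetic bias and distorts community structure in
  proportion to total cycle number; an independent per-cycle lognormal
  factor (sigma ``efficiency_sd``) adds a stochastic random walk on top.
* **Chimera formation** - with probability ``chimera_rate`` per cycle a new
  class is created from a random prefix of one template and the suffix of
  another at a uniform breakpoint.
* **Cross-contamination** - during step-2 cycles only (the barcode-primer
  cross-contamination mechanism), distinct foreign templates are injected at
  Poisson(``contam_rate_per_cycle2``) per cycle with lognormal relative
  abundance; a separate step-1 knob (default 0) allows testing the absence
  of a step-1 effect.

Reads carry ``barcode + head + primer + template`` on both mates, with a
linearly decaying quality profile and quality-driven substitution errors
(error probability 10^(-Q/10) per base). Every emitted pair has exactly one
truth record. All randomness flows through one ``numpy`` Generator, so equal
seeds give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .seqio import (
    DEFAULT_HEAD,
    DatasetSpec,
    IUPAC_SETS,
    LibrarySpec,
    NucleotideRead,
    ReadPair,
    revcomp,
    write_fasta,
    write_fastq,
    write_mapping,
)

__all__ = [
    "SimulationConfig",
    "LibraryRunSpec",
    "PcrResult",
    "RunTruth",
    "EVEN_PROPORTIONS",
    "UNEVEN_PROPORTIONS",
    "DEFAULT_CYCLE_GRID",
    "make_references",
    "make_barcodes",
    "simulate_pcr",
    "simulate_reads",
    "generate_run",
]

#: Mock community mixing proportions (relative clone abundances, normalized).
UNEVEN_PROPORTIONS = tuple(np.array([76.0, 18.0, 5.0, 0.7, 0.09]) / 99.79)
EVEN_PROPORTIONS = (0.2, 0.2, 0.2, 0.2, 0.2)

#: The nine first:second step cycle-number combinations applied to each mock
#: community (the ninth resolved to 35:5 so all nine are distinct).
DEFAULT_CYCLE_GRID = (
    (10, 20),
    (15, 15),
    (20, 10),
    (25, 5),
    (25, 10),
    (30, 10),
    (30, 5),
    (35, 10),
    (35, 5),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated run; defaults emulate the real design.

    ``efficiency_bias_sd`` is the spread of fixed per-template log
    amplification efficiencies (kinetic bias); its default reproduces the
    magnitude of cycle-dependent community distortion observed in real
    two-step runs (Mantel r against total-cycle differences of roughly
    0.5-0.7 over the 9-design grid). ``efficiency_sd`` is the per-cycle
    stochastic lognormal sigma on top. Contaminant abundances are lognormal
    with median ~0.027% and a 95% range of roughly 0.005-0.15%, the scale
    observed for individual contaminant OTUs in real mock libraries.
    """

    head: str = DEFAULT_HEAD
    fwd_primer: str = "CCTACGGGNGGCWGCAG"
    rev_primer: str = "GACTACHVGGGTATCTAATCC"
    read_len: int = 300
    depth: int = 2000
    efficiency_bias_sd: float = 0.06
    efficiency_sd: float = 0.015
    chimera_rate: float = 0.01
    chimera_abundance_logmean: float = math.log(1e-3)
    chimera_abundance_logsd: float = 0.5
    contam_rate_per_cycle2: float = 0.3
    contam_rate_per_cycle1: float = 0.0
    contam_abundance_logmean: float = math.log(2.7e-4)
    contam_abundance_logsd: float = 0.85
    substitution_errors: bool = True
    quality_start: int = 38
    quality_end: int = 20
    quality_jitter_sd: float = 3.0
    quality_min: int = 2
    quality_max: int = 40
    exact_allocation: bool = False

    def noise_free(self) -> "SimulationConfig":
        """The zero-noise limit: no drift, chimeras, contamination, or errors."""
        return replace(
            self,
            efficiency_bias_sd=0.0,
            efficiency_sd=0.0,
            chimera_rate=0.0,
            contam_rate_per_cycle2=0.0,
            contam_rate_per_cycle1=0.0,
            substitution_errors=False,
            quality_start=40,
            quality_end=40,
            quality_jitter_sd=0.0,
            exact_allocation=True,
        )


@dataclass(frozen=True)
class LibraryRunSpec:
    """One simulated library: barcode, community, cycle design, depth."""

    library_id: str
    barcode: str
    community: str  # "even" | "uneven"
    cycles_step1: int
    cycles_step2: int
    depth: int


@dataclass
class ChimeraRecord:
    label: str
    parent1: str
    parent2: str
    breakpoint: int


@dataclass
class PcrResult:
    """Template pool after PCR, with the injections/chimeras that produced it."""

    abundances: dict[str, float]  # label -> relative abundance (sums to 1)
    sequences: dict[str, str]  # label -> template sequence
    injections: list[tuple[str, float]] = field(default_factory=list)
    chimeras: list[ChimeraRecord] = field(default_factory=list)


@dataclass
class RunTruth:
    """Complete ground truth for a generated run."""

    pcr: dict[str, PcrResult]  # per library
    allocations: dict[str, dict[str, int]]  # library -> label -> read count
    origins: dict[str, str]  # read id -> template label
    specs: list[LibraryRunSpec] = field(default_factory=list)


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def make_references(
    n: int,
    length: int = 460,
    min_pairwise_divergence: float = 0.10,
    seed: int | np.random.Generator | None = None,
    avoid: Sequence[str] = (),
    max_tries: int = 200,
    prefix: str = "ref",
) -> dict[str, str]:
    """Random reference templates with bounded pairwise identity.

    Every pair among the new references (and against ``avoid``) has alignment
    identity <= 1 - min_pairwise_divergence, enforced by rejection sampling.
    """
    from .otu import identity  # local import: otu imports nothing from here

    if n < 2 and not avoid:
        raise ValueError("need n >= 2 references")
    rng = _as_rng(seed)
    max_id = 1.0 - min_pairwise_divergence
    accepted: list[str] = []
    tries = 0
    while len(accepted) < n:
        tries += 1
        if tries > max_tries * n:
            raise RuntimeError(
                f"could not generate {n} references at divergence {min_pairwise_divergence}"
            )
        cand = _random_seq(length, rng)
        if all(identity(cand, s) <= max_id for s in list(avoid) + accepted):
            accepted.append(cand)
    return {f"{prefix}_{i + 1}": s for i, s in enumerate(accepted)}


def make_barcodes(
    n: int, seed: int | np.random.Generator | None = None, min_hamming: int = 3, max_tries: int = 500
) -> list[str]:
    """Random 8-nt barcodes with pairwise Hamming distance >= ``min_hamming``."""
    rng = _as_rng(seed)
    out: list[str] = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries * n:
            raise RuntimeError(f"could not generate {n} barcodes at distance {min_hamming}")
        cand = _random_seq(8, rng)
        if all(sum(a != b for a, b in zip(cand, prev)) >= min_hamming for prev in out):
            out.append(cand)
    return out


def community_proportions(community: str | Mapping[str, float], labels: Sequence[str]) -> dict[str, float]:
    """Resolve "even"/"uneven" (or an explicit mapping) to label proportions."""
    if isinstance(community, str):
        if community == "even":
            return {lab: 1.0 / len(labels) for lab in labels}
        if community == "uneven":
            if len(labels) != len(UNEVEN_PROPORTIONS):
                raise ValueError(
                    f"community 'uneven' needs {len(UNEVEN_PROPORTIONS)} references"
                )
            return dict(zip(labels, UNEVEN_PROPORTIONS))
        raise ValueError(f"unknown community {community!r}")
    total = sum(community.values())
    return {k: v / total for k, v in community.items()}


def simulate_pcr(
    community: Mapping[str, float],
    templates: Mapping[str, str],
    cycles_step1: int,
    cycles_step2: int,
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
    foreign_refs: Mapping[str, str] | None = None,
    class_log_efficiency: Mapping[str, float] | None = None,
) -> PcrResult:
    """Run the per-cycle amplification model; returns the final template pool.

    Each cycle multiplies every class abundance by exp(its fixed
    log-efficiency offset) times a stochastic lognormal factor, and may
    create a chimera class; step-2 (and optionally step-1) cycles
    additionally inject distinct foreign templates. Fixed offsets are taken
    from ``class_log_efficiency`` when given (so several libraries built
    from the same clones share the same kinetic bias), otherwise drawn once
    per class from N(0, ``efficiency_bias_sd``); new chimera/contaminant
    classes always draw theirs on creation. The returned abundances are
    renormalized to sum to 1.
    """
    rng = _as_rng(seed)

    log_eff = dict(class_log_efficiency or {})

    def _eff(label: str) -> float:
        if label not in log_eff:
            log_eff[label] = (
                rng.normal(0.0, config.efficiency_bias_sd) if config.efficiency_bias_sd > 0 else 0.0
            )
        return log_eff[label]

    abund = {k: float(v) for k, v in community.items()}
    if abs(sum(abund.values()) - 1.0) > 1e-9:
        total = sum(abund.values())
        abund = {k: v / total for k, v in abund.items()}
    seqs = dict(templates)
    foreign = dict(foreign_refs or {})
    available_foreign = [k for k in foreign if k not in abund]
    injections: list[tuple[str, float]] = []
    chimeras: list[ChimeraRecord] = []

    steps = [(1, cycles_step1), (2, cycles_step2)]
    for step, n_cycles in steps:
        inj_rate = config.contam_rate_per_cycle1 if step == 1 else config.contam_rate_per_cycle2
        for _ in range(n_cycles):
            if config.efficiency_bias_sd > 0 or config.efficiency_sd > 0:
                labels = list(abund)
                if config.efficiency_sd > 0:
                    factors = rng.lognormal(0.0, config.efficiency_sd, size=len(labels))
                else:
                    factors = np.ones(len(labels))
                for lab, f in zip(labels, factors):
                    abund[lab] *= f * math.exp(_eff(lab))
            if config.chimera_rate > 0 and len(abund) >= 2 and rng.random() < config.chimera_rate:
                labels = list(abund)
                weights = np.array([abund[l] for l in labels])
                weights = weights / weights.sum()
                p1, p2 = rng.choice(len(labels), size=2, replace=False, p=weights)
                s1, s2 = seqs[labels[p1]], seqs[labels[p2]]
                cut = int(rng.integers(1, min(len(s1), len(s2))))
                chimera_seq = s1[:cut] + s2[cut:]
                if chimera_seq not in seqs.values():
                    label = f"chimera_{len(chimeras) + 1}"
                    seqs[label] = chimera_seq
                    rel = float(rng.lognormal(config.chimera_abundance_logmean, config.chimera_abundance_logsd))
                    abund[label] = rel * sum(abund.values())
                    chimeras.append(ChimeraRecord(label, labels[p1], labels[p2], cut))
            if inj_rate > 0 and available_foreign:
                n_inj = int(rng.poisson(inj_rate))
                for _ in range(min(n_inj, len(available_foreign))):
                    pick = int(rng.integers(len(available_foreign)))
                    label = available_foreign.pop(pick)
                    rel = float(
                        rng.lognormal(config.contam_abundance_logmean, config.contam_abundance_logsd)
                    )
                    abund[label] = rel * sum(abund.values())
                    seqs[label] = foreign[label]
                    injections.append((label, rel))

    total = sum(abund.values())
    abund = {k: v / total for k, v in abund.items()}
    return PcrResult(abund, {k: seqs[k] for k in abund}, injections, chimeras)


def largest_remainder(proportions: Sequence[float], total: int) -> list[int]:
    """Deterministic apportionment of ``total`` by the largest-remainder rule."""
    p = np.asarray(proportions, dtype=float)
    p = p / p.sum()
    raw = p * total
    counts = np.floor(raw).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts.tolist()


def _concrete(primer: str, rng: np.random.Generator) -> str:
    """Replace IUPAC ambiguity codes with one concrete realization."""
    return "".join(
        b if b in "ACGT" else str(rng.choice(sorted(IUPAC_SETS[b]))) for b in primer
    )


def _quality_profile(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    base = np.linspace(config.quality_start, config.quality_end, config.read_len)
    if config.quality_jitter_sd > 0:
        base = base + rng.normal(0.0, config.quality_jitter_sd, size=config.read_len)
    return np.clip(np.rint(base), config.quality_min, config.quality_max).astype(int)


_BASES = np.array(list("ACGT"))


def _apply_errors(seq: str, quals: np.ndarray, rng: np.random.Generator) -> str:
    errs = np.nonzero(rng.random(len(seq)) < 10.0 ** (-quals / 10.0))[0]
    if errs.size == 0:
        return seq
    chars = list(seq)
    for i in errs:
        options = [b for b in "ACGT" if b != chars[i]]
        chars[i] = options[int(rng.integers(3))]
    return "".join(chars)


def simulate_reads(
    pool: PcrResult,
    library_id: str,
    barcode: str,
    fwd_primer: str,
    rev_primer: str,
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
    depth: int | None = None,
) -> tuple[list[ReadPair], list[str]]:
    """Sample paired reads from a template pool; returns (pairs, origin labels).

    Primers must be concrete (no ambiguity codes); templates are sampled
    proportionally, by largest-remainder apportionment when
    ``config.exact_allocation`` else multinomially. Reads are
    ``barcode+head+primer+template`` truncated (or 'A'/Q-min padded) to
    ``read_len``, with quality-driven substitution errors when enabled.
    """
    rng = _as_rng(seed)
    depth = config.depth if depth is None else depth
    labels = list(pool.abundances)
    props = [pool.abundances[l] for l in labels]
    prefix_f = barcode + config.head + fwd_primer
    prefix_r = barcode + config.head + rev_primer
    for label in labels:
        if len(pool.sequences[label]) < max(len(fwd_primer), len(rev_primer)):
            raise ValueError(f"template {label} shorter than the primer region")

    if config.exact_allocation:
        counts = largest_remainder(props, depth)
    else:
        counts = rng.multinomial(depth, np.asarray(props) / np.sum(props)).tolist()

    pairs: list[ReadPair] = []
    origins: list[str] = []
    read_no = 0
    for label, count in zip(labels, counts):
        template = pool.sequences[label]
        full_f = prefix_f + template
        full_r = prefix_r + revcomp(template)
        for _ in range(count):
            read_no += 1
            rid = f"{library_id}:{read_no}"
            mates = []
            for full in (full_f, full_r):
                seq = full[: config.read_len]
                if len(seq) < config.read_len:
                    seq = seq + "A" * (config.read_len - len(seq))
                quals = _quality_profile(config, rng)
                if config.substitution_errors:
                    seq = _apply_errors(seq, quals, rng)
                mates.append(NucleotideRead(rid, seq, quals.tolist()))
            pairs.append(ReadPair(mates[0], mates[1]))
            origins.append(label)
    return pairs, origins


def generate_run(
    specs: Sequence[LibraryRunSpec],
    mock_refs: Mapping[str, str],
    out_dir: str | Path | None = None,
    config: SimulationConfig = SimulationConfig(),
    seed: int | np.random.Generator | None = None,
    foreign_refs: Mapping[str, str] | None = None,
    dataset_id: str = "mock16S",
    gzip_fastq: bool = False,
) -> tuple[list[ReadPair], list[LibrarySpec], list[DatasetSpec], RunTruth]:
    """Generate a pooled multiplexed run for a list of library specs.

    Returns the shuffled pooled pairs, mapping specs, and complete truth. If
    ``out_dir`` is given, also writes R1/R2 FASTQ, ``mapping.tsv``,
    ``designs.tsv``, ``truth/`` TSVs, and ``references.fasta``.
    """
    rng = _as_rng(seed)
    seen = set()
    for s in specs:
        if (s.barcode, dataset_id) in seen:
            raise ValueError(f"duplicate (barcode, dataset) for {s.library_id}")
        seen.add((s.barcode, dataset_id))

    labels = list(mock_refs)
    template_len = len(next(iter(mock_refs.values())))
    fwd_primer = _concrete(config.fwd_primer, rng)
    rev_primer = _concrete(config.rev_primer, rng)
    expected_len = template_len + len(config.fwd_primer) + len(config.rev_primer)

    libraries = [LibrarySpec(s.library_id, s.barcode, dataset_id) for s in specs]
    dataset = DatasetSpec(
        dataset_id,
        fwd_primer=config.fwd_primer,
        rev_primer=config.rev_primer,
        expected_len=expected_len,
        head=config.head,
    )

    truth = RunTruth(pcr={}, allocations={}, origins={}, specs=list(specs))
    all_pairs: list[ReadPair] = []
    # Kinetic bias is a property of the clone, shared by every library in the run.
    log_eff = (
        {lab: float(rng.normal(0.0, config.efficiency_bias_sd)) for lab in labels}
        if config.efficiency_bias_sd > 0
        else {}
    )
    for s in specs:
        props = community_proportions(s.community, labels)
        pool = simulate_pcr(
            props, mock_refs, s.cycles_step1, s.cycles_step2, config, rng, foreign_refs, log_eff
        )
        pairs, origins = simulate_reads(
            pool, s.library_id, s.barcode, fwd_primer, rev_primer, config, rng, depth=s.depth
        )
        truth.pcr[s.library_id] = pool
        alloc: dict[str, int] = {}
        for origin, pair in zip(origins, pairs):
            alloc[origin] = alloc.get(origin, 0) + 1
            truth.origins[pair.forward.read_id] = origin
        truth.allocations[s.library_id] = alloc
        all_pairs.extend(pairs)

    order = rng.permutation(len(all_pairs))
    all_pairs = [all_pairs[i] for i in order]

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ext = ".fastq.gz" if gzip_fastq else ".fastq"
        write_fastq((p.forward for p in all_pairs), out_dir / f"R1{ext}")
        write_fastq((p.reverse for p in all_pairs), out_dir / f"R2{ext}")
        write_mapping(libraries, [dataset], out_dir / "mapping.tsv")
        with open(out_dir / "designs.tsv", "w") as fh:
            fh.write(
                "library_id\tcycles1\tcycles2\tcommunity\tpreparer\tgene_target\tamplicon_len\tmultiplier\n"
            )
            for s in specs:
                mult = 2 if expected_len > 600 else 1
                fh.write(
                    f"{s.library_id}\t{s.cycles_step1}\t{s.cycles_step2}\t{s.community}"
                    f"\tsim\t16S\t{expected_len}\t{mult}\n"
                )
        refs = list(mock_refs.items()) + list((foreign_refs or {}).items())
        write_fasta(refs, out_dir / "references.fasta")
        truth_dir = out_dir / "truth"
        truth_dir.mkdir(exist_ok=True)
        with open(truth_dir / "allocations.tsv", "w") as fh:
            fh.write("library_id\tlabel\treads\n")
            for lib_id, alloc in truth.allocations.items():
                for label, n in sorted(alloc.items()):
                    fh.write(f"{lib_id}\t{label}\t{n}\n")
        with open(truth_dir / "injections.tsv", "w") as fh:
            fh.write("library_id\tlabel\trelative_abundance\n")
            for lib_id, pool in truth.pcr.items():
                for label, rel in pool.injections:
                    fh.write(f"{lib_id}\t{label}\t{rel:.6g}\n")
        with open(truth_dir / "chimeras.tsv", "w") as fh:
            fh.write("library_id\tlabel\tparent1\tparent2\tbreakpoint\n")
            for lib_id, pool in truth.pcr.items():
                for rec in pool.chimeras:
                    fh.write(f"{lib_id}\t{rec.label}\t{rec.parent1}\t{rec.parent2}\t{rec.breakpoint}\n")

    return all_pairs, libraries, [dataset], truth
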