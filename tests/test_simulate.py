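"""Simulator: references, PCR model, read synthesis, run generation."""

import numpy as np
import pytest

from ampflow.otu import identity
from ampflow.simulate import (
    DEFAULT_CYCLE_GRID,
    EVEN_PROPORTIONS,
    UNEVEN_PROPORTIONS,
    LibraryRunSpec,
    SimulationConfig,
    community_proportions,
    generate_run,
    largest_remainder,
    make_barcodes,
    make_references,
    simulate_pcr,
    simulate_reads,
)


def test_make_references_divergence_and_determinism():
    refs = make_references(5, 200, 0.10, seed=11)
    seqs = list(refs.values())
    assert len(seqs) == 5 and all(len(s) == 200 for s in seqs)
    for i, a in enumerate(seqs):
        for b in seqs[i + 1 :]:
            assert identity(a, b) <= 0.90
    assert make_references(5, 200, 0.10, seed=11) == refs
    # divergence 0 accepts any two sequences
    assert len(make_references(2, 50, 0.0, seed=1)) == 2


def test_make_barcodes_hamming():
    bcs = make_barcodes(10, seed=3)
    assert len(set(bcs)) == 10
    for i, a in enumerate(bcs):
        for b in bcs[i + 1 :]:
            assert sum(x != y for x, y in zip(a, b)) >= 3


def test_simulate_pcr_no_noise_preserves_proportions():
    refs = {f"m{i}": "ACGT" * 50 for i in range(5)}
    props = dict(zip(refs, UNEVEN_PROPORTIONS))
    cfg = SimulationConfig().noise_free()
    pool = simulate_pcr(props, refs, 25, 10, cfg, seed=0)
    for k, v in props.items():
        assert pool.abundances[k] == pytest.approx(v)
    assert not pool.injections and not pool.chimeras


def test_simulate_pcr_injection_poisson_mean(rng):
    refs = make_references(3, 60, 0.1, rng, prefix="mock")
    foreign = make_references(40, 60, 0.1, rng, avoid=list(refs.values()), prefix="foreign")
    cfg = SimulationConfig(contam_rate_per_cycle2=0.3, efficiency_bias_sd=0, efficiency_sd=0, chimera_rate=0)
    props = {k: 1 / 3 for k in refs}
    counts = [
        len(simulate_pcr(props, refs, 5, 10, cfg, rng, foreign).injections) for _ in range(400)
    ]
    # expected Poisson mean = 0.3 * 10 cycles = 3.0
    assert np.mean(counts) == pytest.approx(3.0, abs=0.25)


def test_simulate_pcr_chimera_records(rng):
    refs = make_references(2, 80, 0.1, rng)
    cfg = SimulationConfig(chimera_rate=1.0, efficiency_bias_sd=0, efficiency_sd=0)
    pool = simulate_pcr({k: 0.5 for k in refs}, refs, 3, 2, cfg, rng)
    assert pool.chimeras
    rec = pool.chimeras[0]
    p1, p2 = pool.sequences[rec.parent1], pool.sequences[rec.parent2]
    assert pool.sequences[rec.label] == p1[: rec.breakpoint] + p2[rec.breakpoint :]


def test_largest_remainder_apportionment():
    props = np.array(UNEVEN_PROPORTIONS)
    counts = largest_remainder(props, 10000)
    assert sum(counts) == 10000
    raw = props / props.sum() * 10000
    floors = np.floor(raw)
    order = np.argsort(-(raw - floors), kind="stable")
    want = floors.astype(int)
    want[order[: 10000 - int(floors.sum())]] += 1
    assert counts == want.tolist()


def test_simulate_reads_overlap_arithmetic(rng):
    refs = make_references(2, 460, 0.1, rng)
    cfg = SimulationConfig(depth=10).noise_free()
    pool = simulate_pcr({k: 0.5 for k in refs}, refs, 5, 5, cfg, rng)
    pairs, origins = simulate_reads(pool, "lib", "AACCGGTT", "A" * 17, "C" * 21, cfg, rng)
    assert len(pairs) == len(origins) == 10
    pair = pairs[0]
    assert len(pair.forward) == len(pair.reverse) == 300
    # payloads 300-24-17=259 and 300-24-21=255 overlap on a 460-nt template
    assert (300 - 24 - 17) + (300 - 24 - 21) - 460 == 54  # joinable


def test_simulate_reads_deterministic(rng):
    refs = make_references(2, 460, 0.1, np.random.default_rng(5))
    cfg = SimulationConfig(depth=50)
    pool = simulate_pcr({k: 0.5 for k in refs}, refs, 5, 5, cfg, np.random.default_rng(7))
    a, _ = simulate_reads(pool, "lib", "AACCGGTT", "A" * 17, "C" * 21, cfg, np.random.default_rng(9))
    b, _ = simulate_reads(pool, "lib", "AACCGGTT", "A" * 17, "C" * 21, cfg, np.random.default_rng(9))
    assert all(
        x.forward.sequence == y.forward.sequence and x.forward.qualities == y.forward.qualities
        for x, y in zip(a, b)
    )


def test_exact_allocation_matches_apportionment(rng):
    refs = make_references(5, 100, 0.1, rng)
    cfg = SimulationConfig(depth=10000, exact_allocation=True).noise_free()
    props = dict(zip(refs, UNEVEN_PROPORTIONS))
    pool = simulate_pcr(props, refs, 5, 5, cfg, rng)
    _, origins = simulate_reads(pool, "lib", "AACCGGTT", "A" * 17, "C" * 21, cfg, rng)
    got = {k: origins.count(k) for k in refs}
    want = dict(zip(pool.abundances, largest_remainder(list(pool.abundances.values()), 10000)))
    assert got == want


def test_generate_run_outputs_and_truth(tmp_path, rng):
    refs = make_references(5, 460, 0.1, rng)
    bcs = make_barcodes(2, rng)
    specs = [
        LibraryRunSpec("even_1", bcs[0], "even", 10, 20, 100),
        LibraryRunSpec("uneven_1", bcs[1], "uneven", 25, 5, 100),
    ]
    cfg = SimulationConfig().noise_free()
    pairs, libs, dss, truth = generate_run(specs, refs, tmp_path, cfg, 42)
    assert len(pairs) == 200
    assert len(truth.origins) == 200  # exactly one truth record per pair
    assert sum(truth.allocations["even_1"].values()) == 100
    for name in ["R1.fastq", "R2.fastq", "mapping.tsv", "designs.tsv", "references.fasta"]:
        assert (tmp_path / name).exists()
    assert (tmp_path / "truth" / "allocations.tsv").exists()
    # duplicate (barcode, dataset) is fatal
    with pytest.raises(ValueError):
        generate_run([specs[0], specs[0]], refs, None, cfg, 42)


def test_generate_run_seed_reproducibility(rng):
    refs = make_references(3, 200, 0.1, np.random.default_rng(0))
    bcs = make_barcodes(2, np.random.default_rng(1))
    specs = [LibraryRunSpec(f"l{i}", bcs[i], "even", 10, 10, 50) for i in range(2)]
    cfg = SimulationConfig(depth=50)
    refs3 = {k: v for k, v in list(refs.items())[:3]}
    props_fix = {k: 1 / 3 for k in refs3}

    def run():
        p, *_ = generate_run(
            specs, refs3, None, cfg, seed=77,
        )
        return [(x.forward.sequence, tuple(x.forward.qualities)) for x in p]

    assert run() == run()


def test_community_proportions():
    labels = [f"m{i}" for i in range(5)]
    even = community_proportions("even", labels)
    assert even == dict(zip(labels, EVEN_PROPORTIONS))
    uneven = community_proportions("uneven", labels)
    assert sum(uneven.values()) == pytest.approx(1.0)
    custom = community_proportions({"a": 2.0, "b": 2.0}, ["a", "b"])
    assert custom == {"a": 0.5, "b": 0.5}


def test_cycle_grid_is_distinct():
    assert len(set(DEFAULT_CYCLE_GRID)) == 9


def test_drift_increases_with_cycles(rng):
    """Bray-Curtis distortion from the truth grows with total cycle number
    (kinetic bias model), monotone in expectation over a cycle ladder."""
    from ampflow.stats import bray_curtis
    from scipy.stats import spearmanr

    refs = {f"m{i}": "ACGT" * 25 for i in range(5)}
    props = {k: 0.2 for k in refs}
    cfg = SimulationConfig(chimera_rate=0, contam_rate_per_cycle2=0)
    ladder = [10, 20, 30, 40, 50]
    mean_bc = []
    for total in ladder:
        dists = []
        for _ in range(60):
            pool = simulate_pcr(props, refs, total, 0, cfg, rng)
            dists.append(bray_curtis(list(pool.abundances.values()), list(props.values())))
        mean_bc.append(np.mean(dists))
    rho, _ = spearmanr(ladder, mean_bc)
    assert rho > 0.9
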