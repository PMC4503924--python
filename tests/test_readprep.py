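"""Read preparation: end-trimming, overlap joining, sweep, scaffold path."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ampflow.readprep import (
    build_scaffold,
    end_trim,
    filter_contig_length,
    long_path_prepare,
    merge_overlap,
    sweep_join,
    Contig,
)
from ampflow.seqio import ReadPair, revcomp

from conftest import make_read, oracle_merge, random_seq


@pytest.mark.parametrize(
    "quals,q,rule,expected_len",
    [
        ([30, 30, 2, 30], 3, "below", 2),
        ([30, 30, 3, 30], 3, "at_or_below", 2),
        ([30, 30, 3, 30], 3, "below", 4),  # 3 is not < 3
        ([30, 30, 2, 30], 0, "below", 4),  # q=0 never trims
        ([1, 30, 30, 30], 3, "below", 0),  # may return empty
    ],
)
def test_end_trim_rules(quals, q, rule, expected_len):
    read = make_read("ACGT", quals)
    assert len(end_trim(read, q, rule)) == expected_len


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(0, 41), min_size=0, max_size=50),
    st.integers(0, 41),
    st.sampled_from(["below", "at_or_below"]),
)
def test_end_trim_output_is_prefix(quals, q, rule):
    seq = "A" * len(quals)
    trimmed = end_trim(make_read(seq, quals), q, rule)
    assert trimmed.sequence == seq[: len(trimmed)]
    assert trimmed.qualities == quals[: len(trimmed)]


def test_merge_overlap_too_short_returns_none(rng):
    template = random_seq(rng, 13)
    fwd = make_read(template[:8])
    rev = make_read(revcomp(template[8 - 5 :]))  # exact 5-base overlap < min 6
    assert merge_overlap(fwd, rev, min_overlap=6) is None


def test_merge_overlap_exact_ten_base_overlap(rng):
    template = random_seq(rng, 30)
    fwd = make_read(template[:20])
    rev = make_read(revcomp(template[10:30]))
    contig = merge_overlap(fwd, rev)
    assert contig is not None
    assert contig.sequence == template
    assert contig.join_overlap == 10
    assert len(contig.sequence) == len(fwd) + len(rev) - contig.join_overlap


def test_merge_overlap_consensus_takes_higher_quality_base(rng):
    template = random_seq(rng, 30)
    fwd_seq = template[:25]
    pos = 10  # one disagreement inside the 20-base overlap (5% <= 8%)
    fwd_seq = fwd_seq[:pos] + ("A" if template[pos] != "A" else "C") + fwd_seq[pos + 1 :]
    fwd = make_read(fwd_seq, [20] * 25)
    rev = make_read(revcomp(template[5:30]), [30] * 25)  # higher quality
    contig = merge_overlap(fwd, rev)
    assert contig is not None
    assert contig.join_overlap == 20
    assert contig.sequence == template  # reverse mate wins the disputed column


def _random_overlapping_pair(rng, with_noise=True):
    tlen = int(rng.integers(20, 90))
    template = random_seq(rng, tlen)
    flen = int(rng.integers(10, min(60, tlen) + 1))
    rlen = int(rng.integers(10, min(60, tlen) + 1))
    fwd_seq = list(template[:flen])
    rev_seq = list(template[tlen - rlen :])
    if with_noise:
        for seq in (fwd_seq, rev_seq):
            for _ in range(int(rng.integers(0, 3))):
                seq[rng.integers(len(seq))] = "ACGTN"[rng.integers(5)]
    fwd = make_read("".join(fwd_seq), list(np.asarray(rng.integers(2, 41, size=flen))))
    rev = make_read(revcomp("".join(rev_seq)), list(np.asarray(rng.integers(2, 41, size=rlen))))
    return fwd, rev


def test_merge_matches_bruteforce_oracle_on_random_pairs(rng):
    """Overlap choice and consensus equal the exhaustive overlap scan on
    random noisy pairs (small-scale oracle check)."""
    for _ in range(300):
        fwd, rev = _random_overlapping_pair(rng)
        got = merge_overlap(fwd, rev)
        want = oracle_merge(fwd, rev)
        if want is None:
            assert got is None
        else:
            assert got is not None
            assert (got.sequence, got.join_overlap) == want


def _pair_for_sweep(rng, template, noisy_tail=False):
    fwd_seq = template[:40]
    rev_seq = revcomp(template[20:60])
    fq = [38] * 40
    rq = [38] * 40
    if noisy_tail:
        # low-quality random 3' tail that breaks joining unless trimmed
        tail = random_seq(rng, 12)
        fwd_seq = fwd_seq[:28] + tail
        fq = [38] * 28 + [2] * 12
    return ReadPair(make_read(fwd_seq, fq), make_read(rev_seq, rq))


def test_sweep_join_error_free_ties_choose_highest_threshold(rng):
    template = random_seq(rng, 60)
    pairs = [("lib", _pair_for_sweep(rng, template)) for _ in range(5)]
    report, contigs = sweep_join(pairs)
    assert report.chosen_threshold == 38
    assert len(set(report.contig_counts)) == 1  # identical yield at all thresholds
    assert len(contigs) == 5
    assert all(c.sequence == template for c in contigs)


def test_sweep_join_noisy_tails_reward_trimming(rng):
    template = random_seq(rng, 60)
    pairs = [("lib", _pair_for_sweep(rng, template, noisy_tail=True)) for _ in range(20)]
    report, contigs = sweep_join(pairs)
    by_t = dict(zip(report.thresholds, report.contig_counts))
    assert max(report.contig_counts) > by_t[0]  # some t > 0 strictly beats no trimming
    assert by_t[report.chosen_threshold] == max(report.contig_counts)
    # chosen threshold reproduces the exhaustive argmax with highest-t tie-break
    best = max(report.contig_counts)
    assert report.chosen_threshold == max(
        t for t, c in zip(report.thresholds, report.contig_counts) if c == best
    )


def test_sweep_join_empty_dataset():
    report, contigs = sweep_join([])
    assert contigs == []
    assert all(c == 0 for c in report.contig_counts)


@pytest.mark.parametrize(
    "expected_len,length,kept",
    [(400, 300, True), (400, 299, False), (465, 349, True), (465, 348, False)],
)
def test_filter_contig_length_boundaries(expected_len, length, kept):
    contigs = [Contig("A" * length, "lib", "joined")]
    assert bool(filter_contig_length(contigs, expected_len)) is kept


def test_long_path_uniform_trimming(rng):
    good = ReadPair(make_read(random_seq(rng, 300), 40), make_read(random_seq(rng, 300), 40))
    # forward mate hits Q<=3 at position 200 -> trims below 225 -> pair dropped
    bad_quals = [40] * 200 + [3] + [40] * 99
    bad = ReadPair(make_read(random_seq(rng, 300), bad_quals), make_read(random_seq(rng, 300), 40))
    out = long_path_prepare([("a", good), ("b", bad)], read_len=300)
    assert [lib for lib, _ in out] == ["a"]
    [(_, pair)] = out
    assert len(pair.forward) == len(pair.reverse) == 225
    assert long_path_prepare([], read_len=300) == []


def test_build_scaffold(rng):
    assert build_scaffold(make_read("AC"), make_read("GT")).sequence == "ACNNNNAC"
    fwd = make_read(random_seq(rng, 225))
    rev = make_read(random_seq(rng, 225))
    scaffold = build_scaffold(fwd, rev)
    assert len(scaffold.sequence) == 454
    assert scaffold.source == "scaffold"
    # exactly one run of exactly four N characters
    import re

    runs = re.findall("N+", scaffold.sequence)
    assert runs.count("NNNN") == 1 and all(len(r) == 4 for r in runs if len(r) >= 4)
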