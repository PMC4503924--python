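"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive each operation by brute force or
plain-python dynamic programming, independent of the package's code paths,
so that equivalence tests are meaningful.
"""

from __future__ import annotations

import numpy as np
import pytest

from ampflow.seqio import IUPAC_SETS, NucleotideRead, ReadPair, revcomp

BASES = "ACGT"


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def make_read(seq: str, quals=None, read_id: str = "r") -> NucleotideRead:
    if quals is None:
        quals = [40] * len(seq)
    elif isinstance(quals, int):
        quals = [quals] * len(seq)
    return NucleotideRead(read_id, seq, list(quals))


# --- demux oracle -----------------------------------------------------------


def oracle_mismatches(observed: str, pattern: str) -> int:
    mm = 0
    for o, p in zip(observed, pattern):
        exp = IUPAC_SETS[p]
        if o == "N":
            ok = len(exp) == 4
        else:
            ok = o in exp
        mm += 0 if ok else 1
    return mm


def oracle_assign(pair: ReadPair, libraries, datasets, max_bc: int = 1, max_pr: int = 1):
    """Exhaustive candidate enumeration over every (library, orientation).

    A candidate matches iff both gene primers are within budget at their
    fixed offsets and the barcode is within budget on at least one mate.
    Returns ("assigned", library_id, orientation) or a verdict string.
    """
    ds_by_id = {d.dataset_id: d for d in datasets}
    candidates = []
    for lib in libraries:
        ds = ds_by_id[lib.dataset_id]
        for orient in ("fwd_is_read1", "fwd_is_read2"):
            f = pair.forward if orient == "fwd_is_read1" else pair.reverse
            r = pair.reverse if orient == "fwd_is_read1" else pair.forward
            if len(f) < 24 + len(ds.fwd_primer) or len(r) < 24 + len(ds.rev_primer):
                continue
            pr_f = oracle_mismatches(f.sequence[24 : 24 + len(ds.fwd_primer)], ds.fwd_primer)
            pr_r = oracle_mismatches(r.sequence[24 : 24 + len(ds.rev_primer)], ds.rev_primer)
            bc_f = oracle_mismatches(f.sequence[:8], lib.barcode)
            bc_r = oracle_mismatches(r.sequence[:8], lib.barcode)
            if pr_f <= max_pr and pr_r <= max_pr and (bc_f <= max_bc or bc_r <= max_bc):
                candidates.append((lib.library_id, orient))
    if not candidates:
        return ("unassigned",)
    if len(candidates) > 1:
        return ("ambiguous",)
    return ("assigned",) + candidates[0]


# --- overlap-join oracle ----------------------------------------------------


def oracle_merge(fwd: NucleotideRead, rev: NucleotideRead, min_overlap=6, max_frac=0.08):
    """Brute-force scan of every overlap length; returns (sequence, overlap) or None."""
    rc = revcomp(rev.sequence)
    rq = rev.qualities[::-1]
    best = None
    for length in range(min_overlap, min(len(fwd), len(rev)) + 1):
        tail = fwd.sequence[len(fwd) - length :]
        head = rc[:length]
        mism = sum(1 for x, y in zip(tail, head) if x != y and x != "N" and y != "N")
        frac = mism / length
        if best is None or frac < best[0] or (frac == best[0] and length > best[1]):
            best = (frac, length)
    if best is None or best[0] > max_frac:
        return None
    length = best[1]
    tail_q = fwd.qualities[len(fwd) - length :]
    cons = []
    for i in range(length):
        fb, rb = fwd.sequence[len(fwd) - length + i], rc[i]
        if fb == rb:
            cons.append(fb)
        elif fb == "N":
            cons.append(rb)
        elif rb == "N":
            cons.append(fb)
        else:
            cons.append(fb if tail_q[i] >= rq[i] else rb)
    return fwd.sequence[: len(fwd) - length] + "".join(cons) + rc[length:], length


# --- alignment identity oracle ----------------------------------------------


def oracle_identity(a: str, b: str) -> float:
    """Plain-python DP maximizing (score, matches, -columns) lexicographically,
    with match +1, mismatch/gap -2, end gaps charged, N a wildcard."""

    def better(x, y):
        return x if (x[0], x[1], -x[2]) >= (y[0], y[1], -y[2]) else y

    n, m = len(a), len(b)
    prev = [(-2 * j, 0, j) for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [(-2 * i, 0, i)]
        for j in range(1, m + 1):
            ai, bj = a[i - 1], b[j - 1]
            is_match = ai == bj or ai == "N" or bj == "N"
            ds, dm, dc = prev[j - 1]
            diag = (ds + 1, dm + 1, dc + 1) if is_match else (ds - 2, dm, dc + 1)
            us, um, uc = prev[j]
            ls, lm, lc = cur[j - 1]
            cur.append(better(better(diag, (us - 2, um, uc + 1)), (ls - 2, lm, lc + 1)))
        prev = cur
    _, matches, columns = prev[m]
    return matches / columns
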