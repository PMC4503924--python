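"""Dereplication, chimera screening, greedy centroid clustering, and read mapping.

Identity between two sequences is defined by a global end-to-end
Needleman-Wunsch alignment (match +1, mismatch -2, gap -2, end gaps charged)
as matching columns / total alignment columns, with N a wildcard that always
matches. Among equal-score alignments the one with the most matches (then
fewest columns) defines the identity, which makes the value deterministic.

Clustering is greedy in descending abundance order with exhaustive centroid
search: a sequence within the OTU radius of an existing centroid is absorbed;
otherwise it is discarded if it looks like a two-parent chimera of existing
centroids, else it seeds a new OTU. Abundances are then quantified by mapping
*all* length-filtered contigs/scaffolds (including the singletons excluded
from clustering) to the centroids at the dataset mapping identity, best hit
only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd
from numba import njit

from .readprep import Contig

__all__ = [
    "UniqueSequence",
    "Otu",
    "OtuTable",
    "dereplicate",
    "remove_singletons",
    "identity",
    "is_chimera",
    "cluster_greedy",
    "map_reads",
]


@dataclass(frozen=True)
class UniqueSequence:
    """A dereplicated sequence with its replicate count over a dataset."""

    sequence: str
    abundance: int


@dataclass
class Otu:
    """An OTU centroid and the dereplicated abundance it absorbed."""

    otu_id: str
    centroid: str
    member_count: int


@dataclass
class OtuTable:
    """OTU x library count matrix plus per-library unmapped counts."""

    counts: pd.DataFrame  # rows: otu_id, columns: library_id
    unmapped: pd.Series  # per library
    centroids: dict[str, str]  # otu_id -> sequence

    def check(self, inputs_per_library: dict[str, int] | None = None) -> None:
        if inputs_per_library is not None:
            for lib, n in inputs_per_library.items():
                total = int(self.counts[lib].sum() + self.unmapped[lib])
                if total != n:
                    raise AssertionError(f"library {lib}: mapped+unmapped {total} != input {n}")

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.loc["unmapped"] = self.unmapped
        out.to_csv(path, sep="\t", index_label="otu_id")


def dereplicate(contigs: Iterable[Contig | str]) -> list[UniqueSequence]:
    """Collapse exact full-length duplicates; sort by abundance desc, then sequence."""
    counts: dict[str, int] = {}
    for c in contigs:
        seq = c if isinstance(c, str) else c.sequence
        counts[seq] = counts.get(seq, 0) + 1
    return [
        UniqueSequence(seq, n)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def remove_singletons(uniques: Sequence[UniqueSequence]) -> list[UniqueSequence]:
    """Drop unique sequences observed only once."""
    return [u for u in uniques if u.abundance >= 2]


# --- alignment identity -----------------------------------------------------

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_CODE[ord("N")] = 4  # wildcard


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@njit(cache=True)
def _nw_identity(a: np.ndarray, b: np.ndarray) -> float:  # pragma: no cover - numba
    n, m = len(a), len(b)
    NEG = -(1 << 28)
    score = np.empty((n + 1, m + 1), dtype=np.int32)
    match = np.empty((n + 1, m + 1), dtype=np.int32)
    cols = np.empty((n + 1, m + 1), dtype=np.int32)
    score[0, 0] = 0
    match[0, 0] = 0
    cols[0, 0] = 0
    for j in range(1, m + 1):
        score[0, j] = -2 * j
        match[0, j] = 0
        cols[0, j] = j
    for i in range(1, n + 1):
        score[i, 0] = -2 * i
        match[i, 0] = 0
        cols[i, 0] = i
        for j in range(1, m + 1):
            ai = a[i - 1]
            bj = b[j - 1]
            is_match = ai == bj or ai == 4 or bj == 4
            if is_match:
                ds = score[i - 1, j - 1] + 1
                dm = match[i - 1, j - 1] + 1
            else:
                ds = score[i - 1, j - 1] - 2
                dm = match[i - 1, j - 1]
            dc = cols[i - 1, j - 1] + 1
            us = score[i - 1, j] - 2
            um = match[i - 1, j]
            uc = cols[i - 1, j] + 1
            ls = score[i, j - 1] - 2
            lm = match[i, j - 1]
            lc = cols[i, j - 1] + 1
            # lexicographic best of (score, matches, -cols)
            bs, bm, bc = ds, dm, dc
            if us > bs or (us == bs and (um > bm or (um == bm and uc < bc))):
                bs, bm, bc = us, um, uc
            if ls > bs or (ls == bs and (lm > bm or (lm == bm and lc < bc))):
                bs, bm, bc = ls, lm, lc
            score[i, j] = bs
            match[i, j] = bm
            cols[i, j] = bc
    return match[n, m] / cols[n, m]


def identity(a: str, b: str) -> float:
    """Global end-to-end alignment identity of two sequences (see module docs)."""
    if not a or not b:
        raise ValueError("identity of empty sequence is undefined")
    if a == b:
        return 1.0
    return float(_nw_identity(_encode(a), _encode(b)))


def _identity_upper_bound(a: str, b: str) -> float:
    """Cheap upper bound on alignment identity via edit distance.

    Any alignment spends at least editDistance columns on mismatches/gaps and
    has at most min(len) matches, so identity <= Lmin / (Lmin + d). Used to
    skip the full alignment when a sequence is provably outside a threshold.
    """
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    lmin = min(len(a), len(b))
    return lmin / (lmin + d) if d > 0 else 1.0


def _best_identity(
    seq: str, centroids: Sequence[Otu], threshold: float
) -> tuple[int, float]:
    """Best centroid index and identity, exact for all candidates that could
    reach ``threshold``; returns (-1, best_bound) if none can."""
    best_idx, best_id = -1, -1.0
    for idx, otu in enumerate(centroids):
        if seq == otu.centroid:
            cand = 1.0
        else:
            if _identity_upper_bound(seq, otu.centroid) < threshold:
                continue
            cand = identity(seq, otu.centroid)
        if cand < threshold:
            continue
        if (
            best_idx < 0
            or cand > best_id
            or (
                cand == best_id
                and (
                    centroids[idx].member_count > centroids[best_idx].member_count
                    or (
                        centroids[idx].member_count == centroids[best_idx].member_count
                        and centroids[idx].centroid < centroids[best_idx].centroid
                    )
                )
            )
        ):
            best_idx, best_id = idx, cand
    return best_idx, best_id


def best_hit(seq: str, refs: Sequence[tuple[str, str]], floor: float = 0.0) -> tuple[str, float]:
    """Label and identity of the best-matching reference (screened, exact).

    An exact string match short-circuits; otherwise references are visited in
    decreasing order of their edit-distance identity bound, and the scan
    stops as soon as no remaining reference can beat the best identity found.
    References whose bound is at most ``floor`` are never aligned: the caller
    declares identities <= floor irrelevant, so the returned value is exact
    only when it exceeds the floor (0.0 means every candidate was screened
    out).
    """
    for label, ref in refs:
        if seq == ref:
            return label, 1.0
    bounded = sorted(
        ((_identity_upper_bound(seq, ref), label, ref) for label, ref in refs), reverse=True
    )
    best_label, best_id = "", 0.0
    for bound, label, ref in bounded:
        if bound <= max(best_id, floor):
            break
        ident = identity(seq, ref)
        if ident > best_id:
            best_label, best_id = label, ident
    return best_label, best_id


# --- chimera model ----------------------------------------------------------


def _match_profile(candidate: np.ndarray, parent: np.ndarray) -> np.ndarray:
    return (candidate == parent) | (candidate == 4) | (parent == 4)


def is_chimera(
    candidate: str,
    centroids: Sequence[str],
    parent_min_id: float = 0.90,
    gain_min: float = 0.02,
) -> bool:
    """Single-breakpoint two-parent chimera test against existing centroids.

    The candidate is compared position-wise (ungapped) with every centroid of
    the same length; it is called chimeric iff some model P1[:k] + P2[k:]
    (P1 != P2) matches the candidate at least ``gain_min`` better than the
    best single parent, with both segments at >= ``parent_min_id`` identity.
    PCR chimeras in this pipeline arise between equal-length amplicons of the
    same target, so the model is ungapped; centroids of a different length
    only compete as single parents (via the alignment identity).
    """
    if not centroids:
        return False
    cand = _encode(candidate)
    L = len(candidate)

    profiles = []
    best_single = 0.0
    for c in centroids:
        if len(c) == L:
            prof = _match_profile(cand, _encode(c))
            profiles.append(prof)
            best_single = max(best_single, prof.mean())
        else:
            best_single = max(best_single, identity(candidate, c))
    if len(profiles) < 2 or L < 2:
        return False

    pref = np.zeros((len(profiles), L + 1), dtype=np.int64)
    np.cumsum(np.asarray(profiles, dtype=np.int64), axis=1, out=pref[:, 1:])
    total = pref[:, -1][:, None]
    suff = total - pref  # suffix matches from k to L

    ks = np.arange(1, L)
    lvals = pref[:, ks]  # parents x breakpoints
    rvals = suff[:, ks]
    l_order = np.argsort(-lvals, axis=0, kind="stable")[:2]
    r_order = np.argsort(-rvals, axis=0, kind="stable")[:2]
    kk = np.arange(len(ks))

    def combo(li: np.ndarray, ri: np.ndarray) -> np.ndarray:
        valid = li != ri
        m = lvals[li, kk] + rvals[ri, kk]
        seg_ok = (lvals[li, kk] / ks >= parent_min_id) & (rvals[ri, kk] / (L - ks) >= parent_min_id)
        return np.where(valid & seg_ok, m, -1)

    best = combo(l_order[0], r_order[0])
    if l_order.shape[0] > 1:
        best = np.maximum(best, combo(l_order[1], r_order[0]))
    if r_order.shape[0] > 1:
        best = np.maximum(best, combo(l_order[0], r_order[1]))
    model_id = best / L
    return bool(np.any(model_id >= best_single + gain_min))


# --- clustering and mapping -------------------------------------------------


def cluster_greedy(
    uniques: Sequence[UniqueSequence],
    radius_pct: float = 3.0,
    chimera_check: bool = True,
    parent_min_id: float = 0.90,
    gain_min: float = 0.02,
) -> tuple[list[Otu], list[UniqueSequence]]:
    """Greedy centroid clustering at the given radius; returns (otus, chimeras).

    ``uniques`` must be sorted by descending abundance (ties lexicographic),
    as produced by :func:`dereplicate` after :func:`remove_singletons`. Every
    sequence is compared against *all* existing centroids (exhaustive
    search). Discarded chimera candidates are returned for logging.
    """
    threshold = 1.0 - radius_pct / 100.0
    otus: list[Otu] = []
    chimeras: list[UniqueSequence] = []
    for u in uniques:
        idx, _ = _best_identity(u.sequence, otus, threshold)
        if idx >= 0:
            otus[idx].member_count += u.abundance
        elif chimera_check and is_chimera(
            u.sequence, [o.centroid for o in otus], parent_min_id, gain_min
        ):
            chimeras.append(u)
        else:
            otus.append(Otu(f"OTU_{len(otus) + 1}", u.sequence, u.abundance))
    return otus, chimeras


def map_reads(
    contigs: Sequence[Contig],
    otus: Sequence[Otu],
    map_identity: float = 0.97,
    library_ids: Sequence[str] | None = None,
) -> OtuTable:
    """Map all contigs/scaffolds to their single best centroid.

    A contig is counted for the centroid with the highest identity if that
    identity reaches ``map_identity`` (ties: larger OTU, then lexicographic
    centroid); otherwise it is counted as unmapped for its library.
    """
    if not otus:
        raise ValueError("map_reads requires at least one centroid")
    libs = list(library_ids) if library_ids is not None else sorted({c.library_id for c in contigs})
    lib_pos = {lib: i for i, lib in enumerate(libs)}
    count_arr = np.zeros((len(otus), len(libs)), dtype=np.int64)
    unmapped_arr = np.zeros(len(libs), dtype=np.int64)
    exact = {o.centroid: i for i, o in enumerate(otus)}
    assignment_cache: dict[str, int] = {}
    for c in contigs:
        col = lib_pos.get(c.library_id)
        if col is None:
            col = lib_pos[c.library_id] = len(libs)
            libs.append(c.library_id)
            count_arr = np.hstack([count_arr, np.zeros((len(otus), 1), dtype=np.int64)])
            unmapped_arr = np.append(unmapped_arr, 0)
        idx = exact.get(c.sequence, -1)
        if idx < 0:
            idx = assignment_cache.get(c.sequence, -2)
            if idx == -2:
                idx, _ = _best_identity(c.sequence, otus, map_identity)
                assignment_cache[c.sequence] = idx
        if idx >= 0:
            count_arr[idx, col] += 1
        else:
            unmapped_arr[col] += 1
    counts = pd.DataFrame(count_arr, index=[o.otu_id for o in otus], columns=libs)
    unmapped = pd.Series(unmapped_arr, index=libs)
    return OtuTable(counts, unmapped, {o.otu_id: o.centroid for o in otus})
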