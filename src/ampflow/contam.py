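"""Classify OTU centroids as mock-community members or contaminants.

A centroid is a *mock member* when it is at least 97% identical to a mock
reference and no non-mock reference matches it better; a *contaminant* when
some non-mock reference (a co-sequenced dataset OTU or other known foreign
sequence) is strictly more similar than the best mock reference; otherwise
*unknown*. Ties favor the designed community.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .otu import OtuTable, best_hit

__all__ = ["ContaminantCall", "classify_otu", "classify_table", "summarize_contamination"]

MOCK_MEMBER_MIN_ID = 0.97


@dataclass
class ContaminantCall:
    """Per-OTU verdict with the best identities supporting it.

    ``best_nonmock_id`` is exact whenever it determines the verdict; when
    every non-mock reference was provably too distant to beat the mock match
    (screened by an edit-distance bound), it is reported as 0.0.
    """

    otu_id: str
    verdict: str  # "mock_member" | "contaminant" | "unknown"
    best_mock_id: float
    best_nonmock_id: float
    best_nonmock_label: str


def classify_otu(
    otu_id: str,
    centroid: str,
    mock_refs: Sequence[tuple[str, str]],
    nonmock_refs: Sequence[tuple[str, str]],
    min_mock_id: float = MOCK_MEMBER_MIN_ID,
) -> ContaminantCall:
    """Classify one centroid against labeled mock and non-mock references."""
    if not mock_refs:
        raise ValueError("mock reference set must not be empty")
    _, best_mock = best_hit(centroid, mock_refs)
    # A non-mock reference only matters if it can beat the mock match, so
    # anything provably at or below best_mock can be screened out.
    nonmock_label, best_nonmock = best_hit(centroid, nonmock_refs, floor=best_mock)
    if best_nonmock > best_mock:
        verdict = "contaminant"
    elif best_mock >= min_mock_id:
        verdict = "mock_member"
    else:
        verdict = "unknown"
    return ContaminantCall(otu_id, verdict, best_mock, best_nonmock, nonmock_label)


def classify_table(
    table: OtuTable,
    mock_refs: Sequence[tuple[str, str]],
    nonmock_refs: Sequence[tuple[str, str]],
    min_mock_id: float = MOCK_MEMBER_MIN_ID,
) -> list[ContaminantCall]:
    """Classify every centroid of an OTU table."""
    return [
        classify_otu(otu_id, seq, mock_refs, nonmock_refs, min_mock_id)
        for otu_id, seq in table.centroids.items()
    ]


def summarize_contamination(
    table: OtuTable, calls: Sequence[ContaminantCall] | Mapping[str, ContaminantCall]
) -> pd.DataFrame:
    """Per-library contaminant count, relative abundance, and abundance spread.

    Count is the number of contaminant OTUs with at least one mapped read in
    the library; relative abundance is contaminant reads over all mapped
    reads. The median and 2.5/97.5 percentiles summarize the individual
    contaminant OTU relative abundances (over libraries where they occur).
    """
    call_by_id = calls if isinstance(calls, Mapping) else {c.otu_id: c for c in calls}
    missing = [otu_id for otu_id in table.counts.index if otu_id not in call_by_id]
    if missing:
        raise ValueError(f"missing contaminant call(s) for {missing}")
    contam_ids = [i for i in table.counts.index if call_by_id[i].verdict == "contaminant"]
    rows = []
    for lib in table.counts.columns:
        col = table.counts[lib]
        total = int(col.sum())
        contam_counts = col.loc[contam_ids]
        present = contam_counts[contam_counts > 0]
        fracs = (present / total).to_numpy() if total > 0 else np.array([])
        rows.append(
            {
                "library_id": lib,
                "contaminant_count": int((contam_counts > 0).sum()),
                "contaminant_fraction": float(present.sum() / total) if total > 0 else 0.0,
                "median_contaminant_abundance": float(np.median(fracs)) if fracs.size else 0.0,
                "p2.5_contaminant_abundance": float(np.percentile(fracs, 2.5)) if fracs.size else 0.0,
                "p97.5_contaminant_abundance": float(np.percentile(fracs, 97.5)) if fracs.size else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("library_id")
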