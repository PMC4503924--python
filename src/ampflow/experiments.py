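"""Desk-scale replicated experiments built on the simulator.

These drivers reproduce, at laptop scale, the two headline analyses of the
mock-community study design: the dependence of community dissimilarity on
total PCR cycle number (Mantel test) and the dependence of contaminant
burden on the number of step-2 barcoding cycles (multiple regression). They
are used both by the test suite and by ``scripts/acceptance.py``.

The contamination experiment samples template pools into per-library
sequence collections and runs the dereplication -> singleton removal ->
clustering -> mapping -> classification stages on them; read synthesis and
demultiplexing are exercised separately (they are lossless under the
conditions used here and would only add runtime).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import otu as otu_mod
from .contam import classify_table, summarize_contamination
from .readprep import Contig
from .simulate import (
    DEFAULT_CYCLE_GRID,
    SimulationConfig,
    community_proportions,
    largest_remainder,
    make_references,
    simulate_pcr,
)
from .stats import (
    CycleDesign,
    bray_curtis_matrix,
    cycle_distance_matrix,
    mantel,
    ols_fit,
)

__all__ = [
    "ContaminationExperimentResult",
    "contamination_cycle_experiment",
    "mantel_cycle_experiment",
]


@dataclass
class ContaminationExperimentResult:
    """Per-replicate step-2 slope estimates from the contamination regression."""

    table: pd.DataFrame  # columns: replicate, slope, se, covered
    true_slope: float

    @property
    def coverage(self) -> float:
        """Fraction of replicates whose slope is within 2 SE of the truth."""
        return float(self.table["covered"].mean())


def _pool_to_contigs(
    pool, library_id: str, depth: int, rng: np.random.Generator, exact: bool
) -> list[Contig]:
    labels = list(pool.abundances)
    props = [pool.abundances[l] for l in labels]
    if exact:
        counts = largest_remainder(props, depth)
    else:
        counts = rng.multinomial(depth, np.asarray(props) / np.sum(props)).tolist()
    contigs = []
    for label, n in zip(labels, counts):
        contigs.extend(Contig(pool.sequences[label], library_id, "joined") for _ in range(n))
    return contigs


def contamination_cycle_experiment(
    n_replicates: int = 100,
    seed: int | None = None,
    grid: tuple = DEFAULT_CYCLE_GRID,
    communities: tuple = ("even", "uneven"),
    contam_rate_per_cycle2: float = 0.3,
    depth_range: tuple[int, int] = (800, 1600),
    config: SimulationConfig | None = None,
    n_foreign: int = 50,
) -> ContaminationExperimentResult:
    """Recover the contaminant injection rate from the cycle-design regression.

    Each replicate simulates one library per (cycle design, community) cell,
    runs clustering + classification per library, counts contaminant OTUs
    with at least one mapped read, and fits
    ``count ~ cycles1 + cycles2 + read_depth + community`` by OLS. The step-2
    slope estimates the injection rate (contaminants per step-2 cycle).

    Contaminant abundances are raised well above the per-library detection
    floor (2 reads after dereplication) so that recovery is essentially
    complete and the regression measures the injection process rather than
    the detection limit; depths vary between libraries as in a real pool.
    """
    rng = np.random.default_rng(seed)
    base = config or SimulationConfig()
    cfg = replace(
        base,
        contam_rate_per_cycle2=contam_rate_per_cycle2,
        chimera_rate=0.0,
        contam_abundance_logmean=math.log(0.02),
        contam_abundance_logsd=0.4,
    )
    mock_refs = make_references(5, 460, 0.10, rng, prefix="mock")
    foreign_refs = make_references(
        n_foreign, 460, 0.10, rng, avoid=list(mock_refs.values()), prefix="foreign"
    )
    mock_items = list(mock_refs.items())
    foreign_items = list(foreign_refs.items())

    rows = []
    for rep in range(n_replicates):
        log_eff = (
            {lab: float(rng.normal(0.0, cfg.efficiency_bias_sd)) for lab in mock_refs}
            if cfg.efficiency_bias_sd > 0
            else {}
        )
        counts_y, designs = [], []
        for community in communities:
            for c1, c2 in grid:
                lib_id = f"{community}_{c1}_{c2}"
                depth = int(rng.integers(depth_range[0], depth_range[1] + 1))
                props = community_proportions(community, list(mock_refs))
                pool = simulate_pcr(props, mock_refs, c1, c2, cfg, rng, foreign_refs, log_eff)
                contigs = _pool_to_contigs(pool, lib_id, depth, rng, exact=True)
                uniques = otu_mod.remove_singletons(otu_mod.dereplicate(contigs))
                otus, _ = otu_mod.cluster_greedy(uniques, radius_pct=3.0)
                table = otu_mod.map_reads(contigs, otus, map_identity=0.97, library_ids=[lib_id])
                calls = classify_table(table, mock_items, foreign_items)
                summary = summarize_contamination(table, calls)
                counts_y.append(int(summary.loc[lib_id, "contaminant_count"]))
                designs.append(
                    CycleDesign(lib_id, c1, c2, community, depth)
                )
        design_df = pd.DataFrame(
            {
                "cycles1": [d.cycles_step1 for d in designs],
                "cycles2": [d.cycles_step2 for d in designs],
                "read_depth": [d.read_depth for d in designs],
                "community": [d.community for d in designs],
            }
        )
        fit = ols_fit(counts_y, design_df, anova=False)
        slope, se = float(fit.params["cycles2"]), float(fit.bse["cycles2"])
        rows.append(
            {
                "replicate": rep,
                "slope": slope,
                "se": se,
                "covered": abs(slope - contam_rate_per_cycle2) <= 2 * se,
            }
        )
    return ContaminationExperimentResult(pd.DataFrame(rows), contam_rate_per_cycle2)


def mantel_cycle_experiment(
    n_replicates: int = 200,
    seed: int | None = None,
    efficiency_bias_sd: float | None = None,
    efficiency_sd: float | None = None,
    depth: int = 2000,
    n_permutations: int = 199,
    grid: tuple = DEFAULT_CYCLE_GRID,
    community: str = "uneven",
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Mantel test of Bray-Curtis vs total-cycle differences over the 9-design grid.

    Each replicate simulates one contaminant-free library per cycle design,
    samples ``depth`` reads multinomially from each pool (so even the
    zero-drift null has sampling noise), and runs the one-sided Mantel test.
    Returns a DataFrame with one (r, p) row per replicate. With both drift
    sigmas at 0 this realizes the null: rejection at level alpha should
    occur in about an alpha fraction of replicates.
    """
    rng = np.random.default_rng(seed)
    base = config or SimulationConfig()
    cfg = replace(
        base,
        chimera_rate=0.0,
        contam_rate_per_cycle2=0.0,
        contam_rate_per_cycle1=0.0,
        efficiency_bias_sd=(
            base.efficiency_bias_sd if efficiency_bias_sd is None else efficiency_bias_sd
        ),
        efficiency_sd=base.efficiency_sd if efficiency_sd is None else efficiency_sd,
    )
    mock_refs = make_references(5, 460, 0.10, rng, prefix="mock")
    labels = list(mock_refs)
    designs = [
        CycleDesign(f"{community}_{c1}_{c2}", c1, c2, community, depth) for c1, c2 in grid
    ]
    d_cycles = cycle_distance_matrix(designs)

    rows = []
    for rep in range(n_replicates):
        log_eff = (
            {lab: float(rng.normal(0.0, cfg.efficiency_bias_sd)) for lab in labels}
            if cfg.efficiency_bias_sd > 0
            else {}
        )
        profiles = {}
        for d, (c1, c2) in zip(designs, grid):
            props = community_proportions(community, labels)
            pool = simulate_pcr(props, mock_refs, c1, c2, cfg, rng, class_log_efficiency=log_eff)
            p = np.array([pool.abundances[l] for l in labels])
            profiles[d.library_id] = rng.multinomial(depth, p / p.sum())
        bc = bray_curtis_matrix(pd.DataFrame(profiles))
        res = mantel(bc, d_cycles, n_permutations, seed=int(rng.integers(2**31)))
        rows.append({"replicate": rep, "r": res.r, "p": res.p})
    return pd.DataFrame(rows)
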