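# Methods

This note documents the models, rules, and numerical choices behind each
stage, the simulator's assumptions, and what the test suite does and does
not establish about real data.

## Demultiplexing model

Every amplicon carries `barcode(8) + head(16) + gene primer` at both ends
(the second-step PCR uses a single barcode-head primer, so both mates begin
with the same construct). A candidate assignment is a (library,
orientation) pair. It matches when:

* the mate in the forward role carries the dataset's forward primer at
  offset 24, and the mate in the reverse role the reverse primer, each
  within `max_primer_mm` substitutions (default 1); and
* the library barcode is present at offset 0 of at least one mate within
  `max_bc_mm` substitutions (default 1).

Mismatches are substitution-only (Hamming); indels would shift the fixed
offsets and are treated as failures. IUPAC codes in primers match their
expansions; an observed `N` matches only a pattern position that accepts all
four bases. The head is not checked by default (`--check-head` hardens the
rule). A pair matching exactly one candidate is assigned, oriented
(forward-primer mate first), and trimmed past the primer on both mates; zero
candidates is *unassigned*; more than one is *ambiguous* and discarded —
ties are never broken arbitrarily, which also handles barcode collisions
across datasets (resolved by primer identity when possible) and disagreeing
barcodes on the two mates. Verdicts are independent of mapping-file order.

## Read preparation

**Short path** (expected amplicon <= 550 bp): both mates are end-trimmed
before the first base with quality < t (so t = 0 is a no-op), for every t in
{0, 3, 10, 15, 20, 25, 30, 35, 36, 37, 38}; pairs with an empty mate are
dropped; the rest are overlap-joined. The t maximizing contig count is
chosen; ties go to the highest t (equal yield, strictly better bases).
Joining scans every overlap length l in [6, min(len_f, len_r)] between the
forward 3' end and the reverse-complemented reverse 5' end, scores each by
mismatch fraction (N matches anything), takes the minimum (ties to the
longest overlap), and rejects joins above an 8% mismatch fraction — the
published defaults of the classic overlap joiner whose semantics are
re-implemented here; bit-compatibility with any binary is a non-goal. At
disagreeing columns the consensus takes the higher-quality base (tie:
forward mate); against an N, the called base wins. Joined contigs shorter
than 75% of the dataset's expected amplicon length are discarded
(real-valued comparison: expected 465 keeps >= 348.75, i.e. 349).

**Long path** (> 550 bp): mates are end-trimmed at the first quality <= 3
("3 or less" — note the deliberate strict/non-strict asymmetry between the
two paths' phrasings, both implemented and selectable via the `rule`
argument of `end_trim`); a pair is dropped if either mate falls below
ceil(0.75 x read length), survivors are cut to floor(0.75 x read length)
(225 for 2x300 data; ceil for the survival test guarantees survivors reach
the uniform cut), and scaffolded as `fwd + NNNN + revcomp(rev)` — length
2x225+4 = 454, alignable because the spacer is a wildcard.

## Alignment identity

Identity between two sequences is defined by global end-to-end
Needleman-Wunsch alignment with match +1, mismatch -2, gap -2, end gaps
charged (no left/right-end forgiveness), as matching columns / total
alignment columns. N is a wildcard that counts as a match. Among
equal-score alignments the DP maximizes matches, then minimizes columns
(a lexicographic additive objective, so Bellman optimality holds), making
the value deterministic and oracle-checkable. The kernel is numba-compiled.

Exhaustive centroid search would make every comparison an O(L^2) alignment,
so a sound screen is applied first: for edit distance d (computed by edlib),
any alignment spends at least d columns on mismatches/gaps and has at most
min(L_a, L_b) matches, hence

    identity <= Lmin / (Lmin + d).

Sequences whose bound falls below the relevant threshold (cluster radius,
mapping identity, or the best hit found so far) are skipped without
aligning; the screen never changes a result, only avoids provably
unnecessary alignments. Exact string equality short-circuits to 1.0.

## OTU construction

Dereplication is exact full-length string equality; unique sequences are
sorted by abundance (descending, ties lexicographic) and singletons are
removed before clustering. Greedy clustering processes uniques in order:
the best centroid at identity >= 1 - radius/100 absorbs the sequence (ties:
larger OTU, then lexicographic centroid); otherwise a chimera check may
discard it; otherwise it seeds a new OTU (`OTU_1`, `OTU_2`, ... in creation
order). Abundances are then quantified by mapping *all* length-filtered
contigs/scaffolds — including the singletons excluded from clustering — to
centroids at the dataset mapping identity, single best hit, with
below-threshold sequences counted as unmapped; per-library column sums plus
unmapped always reconcile with the input count.

**Chimera model.** A candidate is discarded when some single-breakpoint
model `P1[:k] + P2[k:]` over two distinct existing centroids matches it at
least 0.02 better than the best single parent, with both segments at >= 0.90
identity. The two-parent scan is ungapped (position-wise) over centroids of
the candidate's length, which is exact for the substitution-dominated,
equal-length amplicons this pipeline produces and keeps the scan O(parents x
length) via prefix sums; centroids of other lengths still compete as single
parents through the alignment identity. This is a deliberately simple,
testable stand-in for reference-free chimera detection; parameters
(`parent_min_id=0.90`, `gain_min=0.02`) are exposed.

## Contaminant classification

Against labeled mock and non-mock reference sets: *contaminant* if the best
non-mock identity strictly exceeds the best mock identity; *mock member* if
the best mock identity is >= 0.97 and not beaten; otherwise *unknown*. Ties
favor the designed community ("higher similarity" is strict). Remote
database search is out of scope; the non-mock set is a user-supplied FASTA
(co-sequenced dataset OTUs, known foreign sequences, or the simulator's
foreign panel). Per-library summaries count contaminant OTUs with at least
one mapped read and report the contaminant read fraction and the
median/2.5%/97.5% of individual contaminant relative abundances. Because a
non-mock reference only matters when it can beat the mock match, references
provably at or below that identity are screened out; in that case the
reported non-mock identity is 0.0 rather than an exact (irrelevant) value.

## Statistics

* **Bray-Curtis** operates on profiles normalized to relative abundance
  first — libraries differ in depth, and the cycle comparison is only
  meaningful depth-invariantly.
* **Mantel** is one-sided (greater), Pearson on strictly-lower-triangle
  entries, 999 permutations by default, p = (1 + #{r_perm >= r_obs}) /
  (1 + n_perm), with a seeded generator recorded in the result. A constant
  lower triangle is a hard error (correlation undefined) — e.g. comparing
  libraries whose cycle totals are all equal.
* **OLS** (via statsmodels) reports classical standard errors, two-sided t
  p-values, adjusted R^2, overall F, and sequential (type-I) ANOVA;
  categorical terms are dummy-coded against the alphabetically first level;
  rank deficiency is a hard error naming a collinear term. The contamination
  models are main-effects only: `count ~ cycles1 + cycles2 + read_depth +
  community` and likewise for the contaminant proportion; post-hoc multiple
  comparisons are out of scope, and the gene-target/preparer contrasts of
  the pooling analysis are read from the dummy-coefficient t-tests.
* **Observed:expected ratios**: expected fraction = pooling multiplier /
  sum of multipliers (2 for amplicons over 600 bp, which are spiked twice;
  else 1); observed = assigned reads / total.

## Simulator

Per PCR cycle, each template class's abundance is multiplied by
`exp(gamma_c) x LogNormal(0, efficiency_sd)`:

* `gamma_c ~ N(0, efficiency_bias_sd)` is a **fixed per-template log
  amplification efficiency** (kinetic bias), drawn once per run and shared
  by every library built from the same clones. This is what makes community
  distortion grow with *total* cycle number in a consistent direction, so
  that libraries with similar totals stay similar — a purely independent
  per-library random walk, by contrast, produces dissimilarities that do
  not correlate with cycle-number differences (we verified this directly:
  Mantel r ~ 0.03-0.06 under walk-only drift).
* the lognormal factor is independent per cycle and class (stochastic
  drift), variance growing linearly in cycle count.

Defaults `efficiency_bias_sd = 0.06` and `efficiency_sd = 0.015` (log units
per cycle) were calibrated once, up front, so that the simulated Mantel
correlation between Bray-Curtis and total-cycle differences over the
9-design grid falls in the 0.47-0.67 range reported for real two-step mock
runs (simulated mean r ~ 0.65); they were not revisited afterwards.

**Chimeras** form with probability `chimera_rate` (default 0.01) per cycle:
parents sampled by abundance, breakpoint uniform, initial relative abundance
lognormal (median 0.1%); chimera classes drift like any other.
**Cross-contamination** injects distinct foreign templates during step-2
(barcode-attachment) cycles at Poisson(`contam_rate_per_cycle2`, default
0.3) per cycle, with lognormal relative abundance whose default (logmean
ln 2.7e-4, logsd 0.85) reproduces the reported real-run scale of individual
contaminant abundances (median ~0.027%, 95% range ~0.007-0.19%); a step-1
injection knob (default 0) exists to test the absence of a step-1 effect.
**Reads** are `barcode + head + primer + template` on both mates (single
second-step primer chemistry), truncated or A/Q-min padded to the read
length; qualities follow a linear Q38 -> Q20 profile with Gaussian jitter
(sd 3) clamped to [2, 40]; substitutions occur per base with probability
10^(-Q/10). Allocation of depth across classes is multinomial, or
deterministic largest-remainder when `exact_allocation` is set (ties by
remainder, stable order). All randomness flows through one generator: equal
seeds give byte-identical runs. The nine first:second cycle combinations
used throughout are 10:20, 15:15, 20:10, 25:5, 25:10, 30:10, 30:5, 35:10,
35:5.

**What the simulator does not emulate:** real 16S sequence composition
(templates are random DNA at controlled pairwise divergence, so
taxonomy-dependent effects are invisible); indel sequencing errors and
polymerase-specific error spectra (substitution-only); flow-cell cluster
density effects on long-amplicon yield; PCR-product carry-over between
steps as a mechanism distinct from primer cross-contamination (both knobs
exist, but the simulator cannot distinguish them observationally). Passing
tests therefore demonstrate the correctness of the pipeline's rules and the
recoverability of its statistics under the modeled mechanisms — not
robustness to artifacts outside this model.

## Replicated experiments (desk scale)

`experiments.contamination_cycle_experiment` simulates, per replicate, one
library per (9 cycle designs x even/uneven) cell with depths drawn from
800-1600, counts recovered contaminant OTUs through the clustering +
mapping + classification stages, and fits the count regression; the step-2
slope estimates the injection rate. Contaminant abundances are raised to
lognormal(ln 0.02, 0.4) here so every injection clears the 2-read
dereplication floor at these depths (at the real-scale default of ~0.027%
most injections receive < 2 reads at desk depths and the slope would
measure the detection limit instead of the injection process; the floor
arithmetic dictated this choice a priori). The experiment feeds the
clustering stages with exact-allocation template copies directly — read
synthesis, demultiplexing, and joining are exercised by their own lossless
zero-noise end-to-end test and would only add runtime here.

`experiments.mantel_cycle_experiment` simulates contaminant-free pools per
design, samples reads multinomially (so the zero-drift null retains
sampling noise and the test's type-I error is measurable), and runs the
Mantel test per replicate. Problem sizes used by the tests and the
acceptance script (100-1000 replicates, depths 800-2000, 199-999
permutations) were chosen as comfortable single-CPU desk-scale settings.

## Known limitations

* USEARCH/UPARSE semantics are not fully published; the alignment scoring,
  tie-breaks, and the simplified chimera model are documented readings,
  fixed exactly so tests can be exact, not bit-compatible reconstructions.
* The demultiplexer trusts fixed construct offsets; reads with 5' indels
  upstream of the primer are unassigned by design.
* `is_chimera` only models two equal-length parents and one breakpoint;
  multi-parent or gapped chimeras fall back to single-parent competition.
* The OLS layer fits linear mean models to counts and proportions (as the
  analysis it reproduces did); no GLM option is provided.
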