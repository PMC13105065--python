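# Methods

`idletrace` implements the quantitative core of a clonal lineage-tracing
study of drug-tolerant persister (DTP) cells: a stochastic multi-state
population model of the "idling" drug-tolerant state, the barcode-counting
and lineage-mapping statistics used to read clone fitness out of sequencing
data, DIP-rate dose-response analysis, calcium-flux quantification, and a
rank-based cross-omics concordance statistic. Every analysis stage is
driven by a seeded synthetic-data generator, so the whole pipeline is
testable end to end without external data.

## Population model

Cells occupy discrete phenotypic states. State `i` has division rate `b_i`
and death rate `d_i` (events/cell/hour, constant in time within a
landscape), and cells switch `i -> j` with first-order rate `k_ij`
(diagonal zero). Lineage identity is heritable and never changes. "Idling"
is the regime where `b_i` and `d_i` are individually non-zero but the
population's aggregate net growth is near zero.

Two solvers:

* **Exact stochastic simulation** (Gillespie direct method) over the
  aggregated (lineage, state) occupancy. Division adds a cell, death
  removes one, a transition moves one cell between states. One named
  `numpy` generator per trajectory; identical seeds give bit-identical
  trajectories.
* **Tau-leaping** (`method="tau"`, default step 0.5 h): Poisson event
  counts per step with removals clamped to the available cells. This is an
  approximation intended for populations of 10^5 cells and up, where the
  exact method becomes slow; it is used by the neutrality studies that
  need ~4x10^5-cell populations.

The deterministic oracle is the branching-process mean:
`E[n(t)] = exp(tA) n(0)` with `A_ii = b_i - d_i - sum_j k_ij` and
`A_ji = k_ij` (`scipy.linalg.expm`). Ensemble means from the exact
simulator agree with this within Monte-Carlo error; the test suite checks
randomized landscapes of up to 4 states over 500 replicates against a
3-SEM bar. Note that the bar is applied per (landscape, state, time) cell,
so the *maximum* z over ~30 cells has a non-trivial chance of exceeding 3
for any particular seed even when the simulator is exact; the fixed-seed
test conditions were not chosen to hide this, and the acceptance report
prints the observed maximum as-is.

**Treatment protocol.** Drug exposure is modelled as a landscape switch at
a set time: the pre-treatment landscape runs for `t_pre`, every surviving
cell is instantaneously reassigned to a drugged-landscape state by
sampling a user-supplied row-stochastic `state_map` (uniform by default —
how untreated phenotypes map onto the drug-modified landscape is not
constrained by the data the package emulates), and the drugged landscape
runs for `t_post`. Whether transitions occur during the switch is a
modelling choice; the instantaneous remap is the simplest one consistent
with cells from any untreated sub-state being able to enter any persister
sub-state. Drug pharmacokinetics are not modelled (constant-dose
protocols). The number of persister sub-states is configurable; the
shipped landscapes use two (slow- and fast-dividing), the minimum that
reproduces the phenomenology.

## Barcode library and counting

Barcodes are `prefix + SW-core` sequences: a shared 4-nt prefix and 16
strong/weak positions (S in {G, C}, W in {A, T}), hence `2^16 = 65,536`
expressible sequences; the SW alternation fixes GC content and limits PCR
amplification bias. The flanking adapter sequences are experiment-specific
configuration; the package ships documented synthetic defaults
(`ATCACGCTGA` / `GACTGTGCAT`).

Extraction locates the 5' flank (allowing <= 1 mismatch per flank by
default; exact matching available), takes the fixed-length candidate, and
requires the 3' flank immediately after. No indel search: the SW design
targets substitution-type PCR bias, and candidates must match the expected
length exactly. Pattern-violating candidates are counted and reported but
excluded in strict mode (default).

Counts are normalised to reads per million (RPM = count x 10^6 / sample
depth; the same quantity is also conventionally called CPM — one quantity,
two labels). Barcodes with **less than** 100 CPM are removed — the
boundary case at exactly 100 is retained, reading "less than" strictly —
and unique-barcode counts are reported after this filter, applied per
sample (whether to filter per replicate or after pooling is exposed simply
by choosing what a "sample" is).

Fold-changes are `log2((RPM_treated + c)/(RPM_ref + c))` with pseudocount
`c = 0.5` RPM by default; barcodes absent from both samples drop out, and
by default only barcodes passing the filter in the reference condition
contribute. Complexity/sharing statistics are set cardinalities on
filtered barcode sets; replicate sharing is reported as the Jaccard index,
and the relative complexity change is
`(unique_treated - unique_ref)/unique_ref`.

## Lineage mapping and the fitness correlation

Cell-to-lineage assignment joins two cleaned record streams on the shared
mRNA transcript ID: (transcript, cell barcode, UMI) and (transcript,
lineage barcode). Support is counted in **distinct UMIs** (not reads) to
suppress PCR duplication; the lineage with strictly maximal support wins
if support >= `min_umi` (default 1, matching permissive capture); ties and
sub-threshold support yield `UNASSIGNED` — deterministic and conservative,
appropriate for the low-MOI (0.05) regime where multiplets are rare.

Cell-cycle classes are condensed to `slow` = G1 and `fast` = S-G2-M. (The
source conventions conflict on which group is "fast"; the convention used
throughout is the one in which the fast-dividing persister cluster is the
minority S-G2-M cluster.) A cell is called fast when either the S or the
G2/M signature score is positive; exact zeros are slow. The fast fraction
of a lineage is computed among its assigned cells in the treated
condition.

The fitness readout is the Pearson correlation between per-lineage fast
fraction and log2 fold-change over the `top_n = 24` most abundant
reference lineages, with a label-permutation p-value available.

A caveat documented here because the tests rely on it: even with **no**
fitness differences, a weak positive correlation between realised growth
and realised fast-fraction is intrinsic to the model whenever the fast
state has higher turnover (`b + d`) than the slow state — high-turnover
compartments drift more, and that drift moves both axes. At the study
conditions (24 lineages of ~4,000 cells, 48 h) the effect is ~+0.05 in r,
small against the null spread of ~0.22. The neutral-scenario check
therefore uses a two-sided permutation test at alpha = 0.01, the same
level as the simulator's lineage-neutrality invariant.

## Expression scores

* **Depth scaling** multiplies each cell's counts by (median total
  molecules)/(cell total); idempotent by construction.
* **Signature scores** are bin-matched control scores in the style of
  Tirosh et al.: genes are ranked by dataset-average expression and cut
  into 25 equal-occupancy bins; each signature gene draws up to 100
  control genes from its bin; the score is mean log1p expression of the
  signature minus the controls, and signed signatures score up minus down.
  Control pools exclude the signature genes themselves — irrelevant at
  transcriptome scale but essential on the small matrices used in testing,
  where a signature would otherwise serve as its own control. This is a
  deliberate simplification of published scoring tools (VISION et al.);
  it supports the comparative use of scores, not their absolute values.
* **Baseline fold-change** tables are `log2((x_t + c)/(x_0 + c))` with
  `c = 1` by default; the baseline column is identically zero.
* **GO concordance** restricts both term tables to p < 0.05, intersects on
  term id (>= 3 shared terms required), and computes the Spearman
  correlation of the -log10 p vectors with average ranks for ties —
  invariant to monotone transforms of the p-values.

## DIP rate and dose-response

The drug-induced proliferation (DIP) rate is the OLS slope of
log2(cell count) versus time from the treatment time onward (log2
cells/hour); an optional later window start accommodates a stabilisation
lag. It is exact on exponential data and invariant to count rescaling. For
"does this population idle?" questions the unit of error is the replicate
well: a single stochastic trajectory is a random walk whose OLS confidence
interval is anticonservative, so the idling check simulates six replicate
wells (the replicate count typical of such experiments) and takes the
t-interval of the per-well rates.

Dose-response is the 4-parameter log-logistic
`E(d) = Emax + (E0 - Emax)/(1 + (d/EC50)^h)` fit by nonlinear least
squares on pooled replicate points (per-replicate fits averaged are
available by fitting subsets). EC50 is parameterised as log10(EC50);
multi-start initialisation takes E0/Emax from the extreme-dose means, EC50
from the geometric mid-dose and a few starts elsewhere, and h in
{0.5, 1, 2}; the lowest-RSS converged start wins. Zero doses are valid
(the model evaluates to E0 at d = 0). Parameter CIs come from the
asymptotic covariance; potency comparisons (`IC50_b / IC50_a`) get a
bootstrap CI by resampling effects within dose groups and refitting. The
reported IC50 is the curve midpoint EC50, matching how such curves are
conventionally annotated; an absolute zero-crossing variant
(`zero_crossing_dose`) is provided because DIP effects cross zero.

## Calcium flux

Traces follow the three-addition SOCE protocol at 1 Hz: CPA (SERCA
inhibitor, ER release) near the start, Ca2+ at 260 s (SOCE influx),
ionomycin at 530 s (maximal, cell-number-proportional signal).
Normalisation maps the minimum of a 3-sample moving average over t < 10 s
to 0 and the maximum of the smoothed signal over t > 530 s to 1 — the
averaging window is a documented choice ("lowest average intensity" is not
otherwise pinned down) — which cancels affine gain/offset differences
exactly. Peaks are rises above each phase's own pre-addition level (the
trace value at the addition instant), so ER release and SOCE are measured
against their local baselines as the two-peak reading of such traces
implies; per-phase trapezoid AUCs and group mean +/- SEM (sigma/sqrt N)
summaries are also emitted, with optional display trimming of t < 10 s and
t > 530 s. Maxima are the default significance metric, with plateaus
implicitly covered by the AUC outputs.

## Synthetic data

Generators emit every input the pipeline consumes plus ground truth
sufficient for exact scoring; all are deterministic under a fixed seed.
Noise models are the simplest consistent with each assay: multinomial read
sampling with i.i.d. substitution errors for amplicons (read position of
the cassette randomised so extraction cannot cheat), Poisson transcript
counts with a configurable droplet-doublet rate (default 0.05, the low-MOI
regime) for single-cell records, lognormal multiplicative count noise for
growth curves, and Gaussian noise with per-well gain/offset jitter for
calcium traces. The calcium template renormalises each phase's shape on
the sampled grid so the discrete peak equals the truth amplitude exactly,
making zero-noise round-trips exact rather than merely close. GO tables
use a Gaussian copula whose Pearson parameter is `2 sin(pi rho / 6)` so
the requested *Spearman* rho is achieved on shared terms.

What the generators do **not** emulate: real transcriptome structure
(gene-level biology beyond what scoring needs), PCR-cycle-explicit
amplification, indels, cell-segmentation artefacts in growth curves, or
dye kinetics beyond the piecewise two-peak template. Passing tests
demonstrate that the statistics recover what the model plants under these
idealised noise processes, not that the biology of any particular dataset
is reproduced.

## Study conditions used by tests and the acceptance report

Chosen once as desk-scale defaults and kept fixed:

* Neutral fold-change study: 50 equal lineages of 8,000 cells on the
  neutral two-state landscape, tau-leaping, 72 h, two samples of 5x10^5
  multinomial reads, 100-CPM filter, 20 seeds; the 95% t-interval is taken
  over the pooled per-lineage fold-changes (the hypothesis is about the
  fold-change *distribution's* mean; pooling also keeps the interval
  honest against the compositional coupling that read normalisation
  induces between lineages).
* Idling DIP study: one division = death = 0.03/h state, 2,000 cells, six
  replicate wells, twice-daily sampling over 150 h.
* Oracle study: four random landscapes (<= 4 states, rates U(0, 0.05)),
  40 cells/state, 500 exact replicates, checks at 12 h and 24 h.
* 4PL recovery: E0 = +0.03, Emax = -0.03 log2/h, EC50 = 1 uM, h = 2;
  8 doses spanning 10 nM-100 uM; noiseless, and 100 seeds at noise sd =
  10% of |E0 - Emax| with 6 replicates/dose.
* Lineage correlation: 24 lineages of ~4,000 cells (lognormal size sd
  0.15), per-lineage initial fast occupancy Beta(2, 8), drugged landscape
  slow/fast division 0.015/0.055 with net rates -0.02/+0.02 (coupled) or
  0/0 (neutral), switching 0.002/h, 48 h, 5x10^5 reads/sample, 4,000
  cells sampled with 5% doublets.
* SOCE comparison: ER amplitude 0.4, SOCE amplitude 0.6 (halved in the
  idling group), noise sd 0.01, 8 wells/group.

## Known limitations

* The exact simulator is event-driven Python/numpy; beyond ~10^6 expected
  events per trajectory, use tau-leaping.
* The 4PL asymptotic CIs assume homoscedastic residuals; use the
  bootstrap for potency claims.
* Barcode extraction has no indel tolerance by design.
* The signature score is a simplified stand-in for published scoring
  tools and should be used comparatively.
* Under per-state-balanced ("neutral") landscapes, state-dependent
  turnover induces the small growth/occupancy correlation described
  above; analyses of real data with very unequal turnover should treat
  weak positive correlations with corresponding care.
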