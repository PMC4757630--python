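# Methods

`foundertrace` implements quantitative phylogeographic founder analysis for
haploid markers: it asks when lineages now found in a *sink* region (e.g.
Island Southeast Asia) arrived from a designated *source* region (e.g.
Taiwan / mainland East Asia), and how much each arrival episode contributed
to the present-day gene pool. This note records the models, the parameter
choices that matter, and the limits of what the bundled synthetic
validation can show.

## Haplotype networks

Both marker systems are analysed on parsimony networks whose edges are
single mutation steps: one base change for HVS-I characters (each derived
variant over the closed range 16,051–16,400 is one binary character;
multistate positions split into one character per derived state), one
repeat unit for an STR locus. Weighted distance between states is
`sum_c w_c |Δ_c|` with character weights in [1, 10].

* **Median-joining** (multistate or binary): candidate median (Steiner)
  vectors are the character-wise medians of state triples that are mutually
  close in the ε-relaxed minimum spanning network; a median is added when
  it strictly shortens the local connection. ε defaults to 0 (the sparsest
  network — the union of all minimum spanning trees over retained states).
  After the median rounds, the retained median set is re-selected to
  minimise the spanning cost — exactly (subset enumeration) when the
  network has ≤ 40 states and ≤ 12 medians, by best-improvement greedy
  removal otherwise. Multi-step links are expanded through inferred
  intermediate nodes (binary states drop derived characters before gaining
  new ones, so intermediates are the more ancestral states; characters
  change in positional order, giving deterministic output).
* **Reduced-median** (binary only): the same construction followed by a
  reduction pass that resolves reticulations whose alternative resolutions
  differ in weighted cost, deleting one edge of the heaviest character in
  the cycle — i.e. resolving in favour of recurrence of the faster
  character. Equal-cost reticulations are retained. Conflict-free data
  yield the unique perfect phylogeny.
* **Network length** (`total_cost`) is the weight of the most-parsimonious
  spanning tree extractable from the network. The sum over *all* edges of a
  reticulated network is not a useful length (a retained 4-cycle would
  count both alternative paths), so cost accounting and the Steiner-oracle
  tests use the spanning length.

**Iterative STR weighting.** All loci start at weight 10; the network is
built, the occurrences of each locus among network edges are counted, and
counts are mapped linearly and in reverse onto [1, 10] (most changes → 1,
fewest → 10, rounded to integers; if all counts are equal, all weights stay
10). This repeats until the edge set is identical between successive
iterations (default cap 10 iterations; hitting the cap flags the scheme
unconverged rather than raising). Occurrences are counted on the full
(possibly reticulated) network, not a reduced one.

**Rooting** extracts the minimum-weighted-cost spanning tree (Kruskal with
deterministic `(cost, label)` tie-breaks) and roots it either at the node
minimising the maximum weighted path to any leaf (*midpoint*; a midpoint
inside an edge snaps to the nearer incident node so the root is always a
haplotype state) or at the node nearest to a supplied outgroup profile
(*outgroup consensus*, e.g. per-locus modal repeats of a sister clade;
observed nodes win ties).

## Founder identification and dating

Candidate founder nodes are tree states observed in the source. Under
**f1** a candidate needs at least one child subtree containing source
samples (derived diversity on the source side — the guard against
back-migration from the sink); **f2** demands two. Every sink sample is
assigned to the nearest surviving candidate on its root path; samples with
none are assigned to the root with a warning. Distances are raw
(unweighted) mutation steps on the extracted tree: weights serve topology
inference only, since clock rates are averages per site/locus and would be
incompatible with weighted steps.

For each cluster, `rho` is the mean distance to the founder and its error
follows the genealogy-aware formula `sigma^2 = sum_i b_i^2 l_i / n^2` over
branch segments (length `l_i` mutations, `b_i` members below). The
star-equivalent effective sample size `n_eff = rho / sigma^2` (≤ n,
equality iff star-like; defined as n when rho = 0) replaces n downstream.
Ages are `rho × Q` for a sequence clock with `Q` years/mutation, or
`rho / (r × n_loci)` for an STR clock with per-locus per-year rate `r`;
intervals convert `rho ± sigma` identically, flooring negative lower
bounds at 0 (logged).

Built-in clocks: HVS-I 16,677 y/mutation over 16,051–16,400; whole-mtDNA
purifying-selection-corrected 3,624 y/mutation; synonymous 7,884
y/substitution; Y-STR 4.08e-5 /locus/year (calibrated on a 3,000-year
star clade in Remote Oceania over the 19-locus panel) and 2.76e-5
/locus/year (the evolutionary rate, 6.9e-4 per 25-year generation).
STR calibration inverts the age formula: `r = rho / (age × n_loci)`.

## Migration scan and partition

Migration-time inference uses a continuous-Poisson likelihood with
effective counts: `L(T) ∝ λ^m̃ e^(−λ)` with `λ = n_eff · T / Q` (sequence)
or `λ = n_eff · T · r · n_loci` (STR) and `m̃ = n_eff · rho`. Effective
counts are non-integer by construction, hence the continuous form.
Posteriors are computed in log space and normalised per founder; the prior
over candidate times is uniform by default and configurable. A cluster
with `m̃ = 0` carries zero post-migration mutations and is resolved as a
point mass on the youngest candidate time (the grid includes T = 0, so
such clusters land there rather than failing).

The **scan** evaluates the posterior on a regular grid, 0–70 ka at
200-year intervals (351 points), as a heuristic peak finder. The
**partition** evaluates it on a small set of event times — presets
0.5/4.5/8/50 ka for mtDNA and 0.5/4.5/8/20 ka for Y-STRs (STR saturation
makes ρ dating of genuinely Pleistocene clades an underestimate, so the
oldest Y event sits at the observable ~20 ka peak). Aggregate curves and
fractions weight founder clusters by their actual sink sample counts (not
`n_eff`): the fractions describe the sampled population. Whole clusters
are partitioned probabilistically and weighted by size; the alternative
of partitioning individual sequences is not implemented.

## Out-of-Taiwan criteria

A clear-cut marker of the mid-Holocene Taiwan→ISEA dispersal should have
(a) its window of arrival in Taiwan (~6–8 ka) bracketed by the mainland
ancestral clade age above and the insular subclade age below, (b) an
insular subclade dating to 4.5–5.5 ka, (c) a founder age into ISEA within
0.5 ka of 4.5 ka, (d) a founder age from Taiwan+Philippines into the rest
of ISEA of at most 4 ka (+0.5 ka tolerance), and (e) a demographic
expansion in Taiwan that predates the ISEA expansion by at least 0.5 ka.
The point-estimate semantics with a symmetric 0.5 ka tolerance is the
loosest rule consistent with the three published verdict sets (M7c3c 5/5,
E 0/5, B4a1a 0/5); interval-overlap semantics can be supplied via a custom
config but is not the default. Expansion onsets are read from skyline
trajectories differenced onto a 100-year grid (change per 100 individuals
per 100 years); the onset is the oldest time on the contiguous rise toward
the peak at which the increment exceeds 10 % of the peak value — the
threshold is configurable since published curves are read by eye.

## Synthetic validation data

`simulate_two_deme` emits matched source/sink datasets with known truth.
Design choices and defaults:

* **Clade-structured source.** The source genealogy is not a plain
  birth-only (comb-like) tree: a comb leaves nearly every ancestral state
  at a pulse time unobserved in a finite modern sample, so founder
  identification would climb to far older nodes and dating recovery would
  fail *by construction*, which real source pools (rich in expansion
  clusters with persisting modal types) do not exhibit. Instead, 8 clade
  centres found at uniform times in [0.3, 0.9] × depth persist to the
  present while sampled lineages branch off them at recent-skewed
  (Beta(1,4)-scaled) times and mutate privately.
* **Founder draws.** Founder types for a pulse at time T are drawn
  frequency-weighted from lineage states at T carried by at least two
  sampled source lineages (fallback: maximum multiplicity). Migrations
  that leave a detectable founder cluster are founded by types segregating
  at appreciable frequency — also the premise of the f1/f2 criteria.
  Three founders per pulse by default.
* **Mutation.** HVS-I: finite sites, Poisson(T/Q) events uniform over 350
  positions, recurrent and back mutation allowed, no mutational hotspot
  spectrum (the clock is an aggregate rate over the range; hotspots would
  change variance, not means). STR: strictly single-step ±1 events at rate
  r per locus-year, reflected at one repeat, matching the network distance
  model. Because opposite steps cancel, measured STR distances sit
  slightly below the event count (≈6 % at the calibration conditions),
  which is a real property of STR dating, not an artefact.
* **Sizes.** Defaults are 300 source and 200 sink lineages (the study
  design this emulates samples the source several-fold more densely than
  the sink) with a 50 ka source depth; scan/partition recovery runs use
  100 seeded replicates. These sizes keep a full replicate (simulate →
  network → root → identify → scan) under ~0.3 s.

What passing synthetic recovery shows: the pipeline returns the truth
under its own generative assumptions (single-pulse scan modes within one
to three grid steps; 50/50 two-pulse fractions within a few points on
average; STR rate recovery within the single-step cancellation bias).
What it does not show: robustness to hotspot spectra, population structure
within regions, sex-biased or continuous (non-pulse) migration, back-
migration from sink to source, or incomplete/ambiguous sequence coverage.
Per-replicate partition fractions fluctuate substantially (±15 points is
common); only the mean over replicates is a calibrated quantity.

## Numerical and interface choices

* All randomness flows through one `numpy` Generator per scenario; the
  same seed gives byte-identical datasets.
* Posterior normalisation uses `logsumexp`; probability vectors sum to 1
  to 1e-12.
* Ties (equal-cost spanning edges, equidistant roots, equal-cost
  reticulation resolutions) break lexicographically on node labels, making
  every output deterministic for a given input ordering.
* The bundled HVS-I reference segment is a **synthetic stand-in** with the
  correct coordinates (16,051–16,400), not the rCRS sequence; variant
  calls from FASTA against it are internally consistent (write→read
  round-trips are identity) but real rCRS-aligned data must be read with a
  user-supplied reference (`reference=` in `read_hvs1`).
* The HVS-I reader requires complete, unambiguous coverage of the range;
  published datasets with partial reads must be harmonised upstream.
* DYS389II is stored as reported (not DYS389I-subtracted); DYS426 columns
  are rejected by default (`allow_excluded=True` to override).
* Insertions are ignored and deletions count as single variants: founder
  distances are mutation counts and indel weighting has no agreed
  standard.

## Known limitations

* Median-joining is exact against a brute-force Steiner oracle on small
  inputs but carries no optimality guarantee at scale.
* Maximum-likelihood branch-length dating and skyline MCMC estimation are
  out of scope; skylines are consumed as tables produced elsewhere.
* The f1/f2 operationalisation (≥1 / ≥2 source-side derived branches at
  the candidate node) follows the founder-analysis literature; other
  operationalisations exist and would shift cluster boundaries.
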