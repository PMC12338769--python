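# Methods

`semnetsim` is a recovery-simulation framework for the measurement of
individual semantic networks. It answers a psychometric question: if every
person's semantic memory were a weighted word graph, how well would the
networks re-inferred from their free associations or relatedness judgments
recover the true ones — as a function of the study design? The package
generates a population of individualized ground-truth networks, simulates
behavioral data under a factorial grid of designs, re-infers networks from
those data, and scores recovery as bias, resolution, and generalizability.

## Ground truth

The common ground truth is a cosine-similarity network over word-embedding
vectors: nodes are words, the weight of edge (i, j) is cos(v_i, v_j), and
edges below a minimum weight (default **0.2**) are absent. Real embeddings in
word2vec/fastText text format can be supplied (`load_embeddings`), together
with a word-frequency table (`load_frequencies`). The default, download-free
path uses synthetic embeddings (`synth_embeddings`): words are assigned
round-robin to `n_communities` topical communities; each vector is the
unit-normalized sum of its community's random unit center and isotropic
Gaussian noise of scale `within_noise`. Defaults — 300 words, dimension 16,
6 communities, noise 0.35 — are chosen so the 0.2-cutoff network is connected
and modular (Louvain Q > 0), i.e. it has the clustered topology that makes
narrow/broad/mixed cue sets meaningfully different. Word frequencies are
Zipfian (`synth_frequencies`, exponent 1 by default), shuffled over words and
normalized to sum 1.

Negative cosines are treated as no-edge: they lie below any non-negative
cutoff, and no absolute-value transformation is applied.

## Individualization by graph perturbation

A population of individuals is produced by perturbing the common truth
(`perturb`). The per-edge **triangle score** ts_e = Σ_t Π³ ω_i (sum over
triangles t containing e of the product of the three edge weights) localizes
clustering-relevant weight. One run:

1. sample ⌊E/2⌋ **source** edges — a proportion `p` from the above-median
   triangle-score half, `1 − p` from the below-median half (ties at the median
   count as above; when all scores tie, e.g. in triangle-free graphs, sampling
   is uniform);
2. draw k ~ Uniform(0, 1) independently for each source edge (a single shared
   k would make the reduction step degenerate);
3. a uniformly chosen `1 − r` share of sources is *reduced*: ω ← ω·(1 − k);
4. the remaining `r` share is *relocated*: k·ω moves from the source to a
   non-source target edge drawn with probability proportional to its current
   weight (including weight received from earlier relocations in the same
   run); targets are capped at weight 1, excess is discarded, keeping weights
   on the cosine scale;
5. edges with final weight below the cutoff (default 0.2) are deleted.

`p` tunes how strongly clustering is degraded; `r` tunes how much total
strength is conserved (r = 1 conserves Σω exactly while no cap binds, r = 0
only removes weight). A population (`generate_population`) runs the algorithm
over a (p, r) grid — default the 5 × 5 Cartesian product
p ∈ {0, .1875, .375, .5625, .75} × r ∈ {0, .25, .5, .75, 1} — with `reps`
runs per pair and per-run seeds derived by a stable hash, so grid cells are
statistically decoupled. `decorrelation_check` reports the Pearson
correlation between average strength and average clustering across a
population; the grid is meant to keep it near zero so the two measures can be
evaluated independently.

## Behavioral simulation

**Free association** (`simulate_fa`). The probability of producing response i
to cue j is

    P(i | j) = w_ij^γw · f_i^γf / Σ_i w_ij^γw · f_i^γf

over the cue's network neighbors (absent edges have w = 0 and thus
probability 0; the cue itself is excluded). Defaults γw = 10, γf = 1 — the
sensitivity values that best reproduce large public free-association norms.
Responses come in trials of 3 (the free-association-norm convention of first,
second and third response); within a trial sampling is without replacement
with renormalization, across trials it resets, so 30 responses means 10
independent trials. Cues that have lost all neighbors in an individual's
network are skipped and counted.

**Relatedness judgment** (`simulate_rj`). A rating of pair (i, j) on the
1–20 scale is a truncated-normal draw

    RJ(i, j) ~ TN(μ(w_ij), σ², 1, 20),   μ(w) = 1 + 19·w^γ

with defaults γ = 1 and σ = 3.85 on the rating scale. The location map is the
affine embedding of the [0, 1] weight scale into [1, 20]; the exponent acts
as a power, consistent with the free-association sensitivities. Sampling uses
the inverse CDF applied to seeded uniforms, so runs are exactly reproducible;
σ = 0 is the deterministic limit (rating = μ clipped to the scale). The
judgment budget |cues| × n_responses is spread over the |cues|(|cues|−1)/2
unordered pairs: equal shares with a random subset receiving the remainder,
or — when the budget is smaller than the number of pairs — a uniform sample
of pairs rated once. Ratings are continuous by default; integer rounding is
available (`round_ratings`).

`sensitivity_grid_search` is the generic tuning operation behind these
defaults: it evaluates a simulator over a parameter grid against a reference
response distribution and returns the correlation surface and argmax.

## Study designs

Cue sets are drawn on the *common* truth and shared by all individuals within
an instantiation. Three generators:

- **narrow** — greedy growth from a random start node, always adding the
  neighbor with the highest average edge weight to the already-included cues
  (average over existing edges only; ties broken uniformly);
- **broad** — a random walk adding an unvisited neighbor of the last added
  node; at a dead end the walk restarts from a random already-included node
  that still has unvisited neighbors (restarting blindly could cycle forever);
- **mixed** — n_b = ⌊√N⌋ seeds drawn by the broad procedure, each grown into
  its own narrow neighborhood; the remaining N − n_b cues are split into n_b
  batches as equally as possible, remainder to the earliest seeds. The √N
  split balances the number of neighborhoods against their depth, matching
  the intent of cue sets built from several groups of closely related words.

Requesting more cues than the reachable component holds is an error naming
the achieved size, never a silent truncation. The full factorial grid
(`paper_grid`) crosses 2 paradigms × 3 cue-set types × sizes {10, 100, 1000}
× responses {3, 30, 300} = 54 cells, each with 10 cue-set instantiations and
250 simulated participants.

## Network inference

**Free association** (`fa_infer`): the cue × response count matrix (columns =
all words observed as responses, lexicographic) is transformed to positive
pointwise mutual information — cell(c, r) = max(0, log₂ p(c,r)/(p(c)p(r)))
with maximum-likelihood probabilities, no smoothing, base-2 logs — and cues
are connected by the cosine similarity of their transformed rows. Raw-count
cosine is available as a variant (`use_ppmi=False`). Cues without data keep
all-zero rows and remain as isolated nodes, so node sets stay comparable
across individuals.

**Relatedness judgment** (`rj_infer`): ratings are averaged per pair and
rescaled affinely to [0, 1] by (mean − 1)/19; unjudged pairs are absent, and
a pair averaging to the scale minimum maps to weight 0 (absent).

## Network measures

Six measures with fixed conventions (`measures`):

- **edge weight** and **node strength** s_i = Σ_j w_ij (within-network);
- **average strength** = mean s_i over all nodes, isolated nodes counting 0;
- **ASPL** with per-step cost 1 − w, averaged over ordered pairs with a
  finite path (disconnected pairs dropped; undefined when none remain);
- **average CC**, Barrat-style: cc_i = 1/(s_i(k_i−1)) Σ_(j,h)
  ((w_ij+w_ih)/2)·a_ij·a_ih·a_jh over ordered neighbor pairs, computed after
  restricting to the 50% strongest edges (weights ≥ the median; quantile
  configurable, `None` disables) to avoid ceiling effects; nodes with fewer
  than 2 filtered neighbors are excluded, and the measure is undefined when
  no node qualifies;
- **modularity**: weighted Newman Q = (1/2m) Σ_ij (a_ij − s_i s_j/2m) δ(c_i,c_j)
  on Louvain communities (weighted, resolution 1, seeded; `n_restarts` keeps
  the best-Q run). The strength-based null model requires m to be total edge
  weight, not an edge count. Q is invariant to uniform rescaling of weights.

Undefined values are explicit (`None`) and propagate through `measure_panel`;
an edgeless network yields a panel with undefined ASPL/CC/modularity rather
than an exception.

## Recovery evaluation

For each design cell, measure, and reference:

- **bias** = (Π M̂_i/M_i)^{1/n} − 1, computed as exp(mean log ratio) − 1.
  Pairs with a non-positive value on either side (possible for modularity)
  have no log-scale ratio; they are excluded and counted, and bias is
  undefined if nothing remains. Acceptable when |bias| ≤ 0.3.
- **resolution** = Spearman correlation across individuals (between-network
  measures, pooled over all individual × instantiation pairs — 2,500 at full
  scale) or per individual and then averaged (within-network measures, with
  absent inferred edges entering as 0). Acceptable when r ≥ .5.
- **generalizability** re-evaluates the between-network criteria against each
  individual's *full* ground-truth network instead of the cue-set
  sub-network. Within-network measures require identical node sets and are
  therefore local-reference only.

The r ≥ .5 band is anchored by an attenuation argument (`power_simulation`):
if the estimate correlates with the truth at r, an effect of Cohen's d is
observed at ≈ d·r. Modeled as observed = true + independent Gaussian noise of
variance (1 − r²)/r², a d = 0.5 effect at r = .5 with 200 participants per
group is detected by a one-sided t-test at α = .05 in ≈ 80% of replicates.
`required_n` inverts the closed-form normal approximation, so halving
resolution quadruples the required sample size.

`run_experiment` orchestrates the whole grid from a YAML config, derives
every stage seed from the master seed via a stable hash, logs failures per
cell without aborting the run, and writes `recovery_results.csv`,
`panels.csv`, `manifest.csv`, and a log.

## What the synthetic generator does and does not emulate

The synthetic truth reproduces the features the recovery machinery is
sensitive to: a clustered cosine topology, a weight cutoff, Zipfian
frequencies, and quasi-independent population variation in strength and
clustering. It does not reproduce the scale (hundreds of words versus tens of
thousands), the heavy-tailed degree structure of real lexicons, polysemy, or
frequency–similarity correlations. Passing tests therefore certify the
*machinery* — the algorithms, their conventions, and the direction of the
recovery asymmetries — not the exact recovery percentages attainable with
real embeddings and norms.

Problem sizes in the test suite reflect that purpose: directional findings
are replicated on a 200-word truth with 20 individuals, 20-cue mixed cue
sets and 20 replicates; perturbation laws on a 100-node truth with 100 runs.
Mixed cue sets are used for the directional replication because on a small
truth a broad random walk scatters the cues across communities and leaves the
cue-set sub-network nearly edgeless, which starves between-individual
comparison of signal; with several hundred times more nodes every cue has
ample neighbors and this degeneracy disappears.

## Numerical choices and edge cases

- Edge weights are stored sparsely; zero means absent, stored weights are
  strictly positive. Edge lists round-trip exactly (repr on write, round-trip
  float parsing on read).
- Node iteration order is lexicographic wherever determinism matters; all
  randomness flows through seeded `numpy` Generators, and every derived seed
  stays below 2³¹.
- The greedy narrow generator breaks weight ties uniformly at random; the
  relocation target draw renormalizes after every relocation.
- Spearman correlations are tie-corrected; constant vectors are an explicit
  undefined-correlation error (skipped and counted in per-individual
  averaging).
- Truncated-normal endpoints are clipped after the inverse-CDF to guard
  floating-point overshoot.

## Known limitations

- The exact (p, r) pairs used at full scale are a package default, not a
  calibrated set; `decorrelation_check` is provided to calibrate a grid for a
  given truth.
- Louvain is a randomized heuristic; Q values are reproducible only through
  the recorded seed (and `n_restarts`).
- The relocation cap at 1 discards excess weight, so r = 1 conserves total
  strength only while no target saturates.
- σ = 3.85 is on the 1–20 rating scale; a 0.15 value on the [0, 1] weight
  scale appears in some tuning contexts and can be selected via config, but
  is not the default.
- `run_experiment` executes cells sequentially; the `--jobs` CLI flag is
  reserved.
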