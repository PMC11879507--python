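# Methods

## Estimation model

For an internal branch of a rooted species tree, consider the quartets
(one taxon from each of the branch's left child clade L, right child clade
R, sister clade S, and the rest O; rooted triplets L/R/S when the branch is
adjacent to the root).  Gene trees induce three topology classes with
frequencies `q1 ≥ q2 ≥ q3` after canonical sorting.  Under the
multispecies coalescent, both minor classes have probability `e^(-t)/3`
(`t` = branch length in coalescent units), so we parameterize ILS strength
as `L = e^(-t)` and gene flow as the inheritance proportion `H` of the
minor parental lineage.  The forward (expectation) model is

    q3 = L/3,   q2 = L/3 + H(1-L),   q1 = L/3 + (1-H)(1-L),

i.e. the non-ILS fraction of gene trees splits `H : 1-H` between the
introgressed topology and the species topology.  Inverting it gives the
estimators quoted in the README.  The decision between the symmetric
(ILS-only) and asymmetric branch of the estimator is a Pearson chi-square
goodness-of-fit test (1 df, no continuity correction) of equal minor-class
counts.

Assumptions worth keeping in mind:

* gene trees are independent and error-free; counts are multinomial.
  Estimating gene trees from finite alignments, or linkage between loci,
  inflates the variance beyond what the test assumes.
* the model is a *single* hybridization into one child of the branch.
  Under complex reticulation the IH index still flags gene flow
  (significant asymmetry) but its value is not the true inheritance
  proportion of any single event.
* direction of gene flow and ghost (unsampled/extinct) donors are not
  identifiable from topology frequencies alone; significant IH calls
  should be followed up with full-likelihood network methods.
* at high ILS the difference `q2 - q3` shrinks as `(1-L)`, so true gene
  flow becomes statistically undetectable; at `L = 1` it is undetectable
  in principle.  Conversely, the chi-square keeps its ~5% false-positive
  rate there, and a falsely significant replicate can produce a large IH
  value because the `(q1-q3)+(q2-q3)` denominator also vanishes — isolated
  significant IH calls on near-star branches deserve skepticism.

## Test counts and degenerate inputs

The chi-square needs counts, not proportions.  The sample size `n` for a
branch is, in order of preference: ASTRAL's `EN` annotation (effective
number of informative gene trees, possibly fractional), the sum of the
`f1/f2/f3` count annotations, or the number of votes cast by the internal
quartet counter.  When no `n` is available the indices are still computed
from the proportions but the test is skipped, `P` is reported as `NA`, the
branch is flagged untested, and the IH index is forced to 0 (fail-soft for
trees lacking `EN`).

Other conventions: `alpha` defaults to 0.05 and is configurable; an exact
`q2 = q3` tie is symmetric by definition (IH = 0); the ILS index is
clamped to [0, 100]; percentages are printed to one decimal place.  If the
species-tree topology is not the most frequent class, it is demoted by the
canonical sort, the event is recorded (`species_rank`), reported, and
flagged with `*` in plots — the indices then describe the *observed* major
topology.

## Quartet counting

Each gene tree containing at least one taxon from every class contributes.
All one-per-class combinations are enumerated when their number is at most
`max_exact` (default 10,000); otherwise `sample_size` (default 1,000)
combinations are drawn uniformly with a fixed seed, keeping runs
deterministic.  Two modes:

* `per_gene` (default): each gene tree votes once, by the majority
  topology of its combinations; ties count as unresolved.  This matches
  the "proportion of gene trees" reading of the theory.
* `per_quartet`: every resolved combination counts (ASTRAL-style
  averaging); `n` is then the number of resolved evaluations.

The two coincide for single-individual taxa on four-taxon trees.  Quartet
topologies are read off bipartitions (unrooted-safe); polytomies that
leave a quartet unresolved are excluded from the denominator.
Multi-individual taxa follow the one-taxon-per-class sampling convention.

## Simulator

The network coalescent runs backward in time over a set of populations:
tip populations (one sampled lineage each) start at time 0; a *join*
merges populations into their ancestor; a *hybridization edge* sends each
lineage of the recipient population into the donor with probability `H` at
the event time.  Within a population, pairs coalesce with exponential
waiting times at rate `1/Ne` per pair per generation.

**Units.** `Ne` is the effective number of gene copies, so one coalescent
unit equals `Ne` generations and a branch of `T` generations has ILS index
`e^(-T/Ne)`; the generation time of an internal branch is set from a
target ILS index by `T = -ln(L)·Ne`.  An ILS index of 0 is realized as a
50-coalescent-unit branch (discordance probability ~2e-22, i.e. zero at
any sample size).

The **simple hybridization model** has four taxa with species tree
`(((2,3),4),1)`, taxon 1 the outgroup; defaults Ne = 1e5, tip branches and
the root-ward branch 1e6 generations, internal branch from the target ILS
index; taxon 3's lineage traces into taxon 4's population with probability
`H` at the (2,3) divergence.  Four **reticulation fixtures**
(`ret1..ret4`, YAML configs shipped with the package) extend this to five
taxa with one hybridization (tip donor / ancestral donor) or two
successive events (hybrid of a hybrid / two pulses into one recipient);
the published schematics under-determine some event times, so these
fixtures are approximate renderings, labeled as such.

The simulator emits rooted newick with branch lengths in generations
(optionally scaled by a substitution rate).  No sequence evolution is
simulated: the indices consume topologies only, so gene-tree *estimation
error* — a real phenomenon in empirical data — is outside what these
simulations can validate.  Passing validation therefore shows estimator
correctness under the generative model, not robustness to reconstruction
noise, linkage, or missing data.

Two engines drive validation sweeps: `multinomial` draws topology counts
directly from the expectation model (seconds for the full 11×11 grid), and
`coalescent` runs the full lineage simulation, classifying each gene
tree's focal quartet straight from the coalescence history (~30 µs per
tree).  Equivalence of the fast classifier with the newick →
quartet-counter route is tested on identical trees, and the engine is
cross-checked against an independent coalescent simulator (msprime) and
against the analytic `e^(-t)/3` law.

## Validation sizes and numerical choices

Replicated sweeps default to 100 replicates of 10,000 gene trees per grid
point with percentile 2.5/97.5% CIs, IH detectability (fraction of
replicates with IH-i > 0) and species-topology error rate (fraction of
replicates in which the species topology is not the majority class); the
replicate count is a flag for users who want the original 1000.  All
randomness flows from a single integer seed; identical seeds reproduce
output files byte for byte.  SVG rendering pins fonts, hash salt and
metadata so figures are also byte-deterministic.

The acceptance script reports the mean estimated IH and ILS indices at
true (ILS, IH) = (36.8%, 40%) over 100 coalescent replicates — recovering
the published observed values (40.5%, 36.1%) within the estimator's known
small biases (order statistics depress the observed `q3`, hence ILS-i
slightly below truth and IH-i slightly above) — plus the closed-form
`q1 = q2 = 50%` pattern at maximal gene flow.

## Known limitations

* Gene flow direction, ghost introgression and multiple overlapping
  events are not identifiable; the IH index is a screening statistic.
* No multiple-testing correction across branches: each branch is tested
  independently at `alpha`, matching the method's intended per-node use;
  users scanning hundreds of branches may wish to adjust `alpha`.
* The per-branch test treats `EN` as an exact multinomial sample size;
  ASTRAL's effective numbers are themselves estimates.
* Linked gene trees (low recombination) and continuous migration are not
  modeled by the simulator.
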