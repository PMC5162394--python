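# Methods

This note documents the models, conventions and design choices behind
`barcodegap`, in the order the pipeline applies them.

## Input model

The unit of analysis is an *aligned matrix*: ≥2 equal-length DNA sequences,
each carrying a unique record id and a species label, for one barcode
region. Residues are upper-cased on read; `.` and `?` are normalised to the
gap character `-`; anything outside A/C/G/T, `-`, `N` and the IUPAC
ambiguity codes is a hard error (these are almost always alignment-export
artifacts and are cheaper to catch at the boundary). Duplicate record ids
are a hard error rather than a silent de-duplication: real datasets repeat
database accessions, and keeping or collapsing them changes every
denominator downstream, so it must be the user's explicit choice.

Species labels default to the first two underscore-separated header tokens
(`Senna_tora|KJ638426` → `Senna_tora`), because that is the most common way
species end up encoded in FASTA headers; a custom delimiter rule, an
arbitrary callable, or an external `id → species` TSV override it. Region
concatenation joins on record id, keeps the first matrix's order, and
refuses mismatched id sets — the alternative (silent intersection) hides
sampling differences between loci that materially change identification
percentages.

## Alignment summary statistics

* **G+C content** is computed over unambiguous bases only, in both numerator
  and denominator.
* **Identical sites** treats the gap as an ordinary character (an all-gap
  column counts as identical). This convention is debatable; it is isolated
  in one function and easy to switch.
* **Pairwise identity** drops gap-vs-gap comparisons per pair and counts
  gap-vs-residue as a non-identical comparison.
* **Variable / parsimony-informative sites** consider unambiguous bases
  only — gaps and ambiguity codes are missing data, consistent with their
  treatment in the distance stage. A column is variable with ≥2 base states
  present, parsimony-informative with ≥2 states each in ≥2 sequences.

## K2P distances with pairwise deletion

For each sequence pair independently, a column contributes only when both
sequences show an unambiguous base. With transition proportion *P* and
transversion proportion *Q* over the compared sites,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

A pair is **undefined** when no column is comparable or a log argument is
≤ 0 (saturation). Undefined distances are NaN with an explicit mask; they
are logged, excluded from every downstream summary and candidate set, and
the matrix build fails outright when more than half the pairs are undefined
(configurable), since at that point no summary is meaningful. Ambiguity
codes are deleted rather than partially matched — the same behaviour as the
default in the standard distance software this stage mirrors. No gamma rate
heterogeneity correction is applied; plain K2P is the convention for
barcoding-gap work and anything richer belongs to likelihood-based tree
inference, which is out of scope here.

## Gap analysis

Distances partition into intraspecific and interspecific sets by label
equality; the partition conserves the defined pair count by construction.
θ is the unweighted mean over species (with ≥2 individuals) of the mean
intraspecific distance; coalescent depth the unweighted mean of the
per-species maximum. Singleton species are excluded from intraspecific
summaries (they have no intraspecific pair) but retained on the
interspecific side, and listed. The headline diagnostic is
`gap_present = (min interspecific > max intraspecific)`; a per-species
local gap (distance to the nearest heterospecific minus the species'
maximum intraspecific distance) is also reported because a global gap can
be destroyed by a single pair while most species remain locally gapped.
All distances are stored raw (substitutions/site); rendering as
percentages is left to formatters. Histograms use left-closed right-open
bins from zero; a value exactly on an edge falls in the upper bin; both
conventional bin widths (0.005 and 0.05) are emitted by default.

## Identification criteria

All three criteria are leave-one-out over the same distance matrix — each
record is queried against all others, with no train/test split. Distance
ties are resolved with an absolute tolerance of 1e-10: the distances are
floating-point computations, and exact equality would make tie verdicts
depend on summation order. Verdicts:

* **BM** — nearest neighbours all conspecific → correct; all allospecific →
  incorrect; mixed → ambiguous.
* **BCM** — same, over candidates within a threshold; empty candidate set →
  no match. The default threshold is the nearest-rank 95th percentile of
  all intraspecific distances (rank ⌈0.95·n⌉), overridable either as a
  percentile or an explicit distance.
* **ASB** — correct iff max conspecific distance < min allospecific
  distance; equality within tolerance → ambiguous; otherwise incorrect.
  The exact tie semantics of the historical implementation are not
  published; this rule follows the usual "all conspecifics closer than all
  allospecifics" definition and the tolerance is configurable.

Singletons are kept in the denominator and can only be incorrect (BM/ASB)
or incorrect/no-match (BCM); their count is reported so that success
percentages can be re-based if desired. Queries with no defined distance to
any other record are excluded and counted. Percentages are computed at full
precision and rendered at 2 d.p.

## Trees

NJ is the standard Saitou–Nei agglomeration (delegated to scikit-bio, with
the input symmetrised against float-epsilon asymmetry); it requires a fully
defined matrix — imputing saturated distances would manufacture topology,
so the user must drop offending records instead. Negative branch lengths
are clamped to zero with the total deficit logged.

Bootstrap resamples alignment columns with replacement, rebuilds the
distance matrix and NJ tree per replicate, and assigns each internal edge
of the original tree the percentage of valid replicates containing the same
bipartition (bipartitions are normalised by the side not containing the
lexicographically smallest tip, so rootings are irrelevant). Replicates
producing any undefined distance are skipped and counted, with a warning
above 20 %. The seed is mandatory; `n_reps=0` returns the plain tree.

Monophyly on an unrooted tree: a species with ≥2 tips is monophyletic iff
some edge bipartition isolates exactly its tips (tested as clade-or-
complement under the arbitrary rooting, which enumerates every edge); on a
rooted tree only clade equality counts. Per-individual and per-species
discrimination rates are both reported because published per-individual
rates cannot generally be decomposed without knowing the singleton
convention; singletons count as discriminated by default (they trivially
occupy their own clade) and the opposite policy is one flag away. The
scorer accepts externally inferred Newick trees (with supports as internal
labels), so likelihood or Bayesian topologies can be scored without those
engines being part of this package.

## Synthetic data generator

The generator emulates the sampling regime of a barcode feasibility study
on a difficult plant group: defaults of 18 species × 3 individuals and 315
aligned columns match a typical ITS1 matrix; within-species divergence
`d_intra = 0.005` and between-species divergence `d_inter = 0.15` with
transition/transversion rate ratio κ = 2 give a clean, realistic barcoding
gap of the kind such studies report.

Mechanics: one uniform-random root sequence; one ancestor per species
evolved `(d_inter − d_intra)/2` from the root on a star phylogeny; each
individual evolved `d_intra/2` from its ancestor. Sites substitute
independently with exact (matrix-exponential) K2P transition probabilities,
so expected pairwise divergence is `d_intra` within species and `d_inter`
between species *at the individual level* — the quantities every
downstream stage actually measures. An optional crude Yule-like mode
perturbs ancestor depths for tree-stage realism; gaps are injected i.i.d.
per site after substitution (they exist only to exercise pairwise
deletion, not to model indel evolution); mislabelling reassigns a fixed
rounded fraction of individuals to a wrong species, recording the truth
first — mimicking misidentified database accessions.

What the generator does **not** emulate: coalescent variance in divergence
times, rate variation across sites and lineages, indel processes,
alignment error, and non-star species phylogenies with shared internal
structure. Passing tests on synthetic data therefore demonstrate
correctness of the *computations* under a controlled substitution process,
not robustness to every pathology of real alignments.

## Numerical and reproducibility choices

* Distance ties: absolute tolerance 1e-10 everywhere a comparison decides a
  verdict.
* Undefined distances: NaN + mask, never zero; every exclusion is counted
  in the run report.
* Histograms: `floor(d / w)` binning — edge values land in the upper bin.
* All randomness (simulation, bootstrap) flows through explicit
  `numpy.random.Generator` seeds; identical config + seed reproduces every
  artifact byte-for-byte (reports contain no timestamps, and the config
  echo omits the output directory so runs into different directories stay
  comparable).
* Problem sizes in the test suite and acceptance script (≤ 60 sequences,
  ≤ 5 kb columns, ≤ 200 bootstrap replicates) were chosen as the smallest
  sizes at which the statistical checks have adequate power; the full
  pipeline at these sizes runs in seconds.

## Known limitations

* The identical-sites and ASB tie conventions follow one defensible reading
  of under-specified historical definitions; both are isolated and
  switchable.
* NJ is the only tree builder included; external ML/Bayesian topologies are
  consumed, never computed.
* Undefined (saturated) distances abort tree building rather than being
  imputed.
* The generator's star phylogeny makes all species exchangeable; rate-equal
  configurations (`d_intra == d_inter`) produce overlap, not a realistic
  continuum of partial gaps.
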