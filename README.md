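# barcodegap

Evaluation of candidate DNA barcode loci from species-labelled alignments.

DNA barcoding identifies species from a short, standardised stretch of
sequence. Whether a locus works as a barcode for a given group — say, the
nuclear ribosomal spacers ITS1 and ITS2 in a taxonomically difficult plant
genus — is an empirical question, conventionally answered three ways:

1. **Distance-based**: do within-species (intraspecific) genetic distances
   stay clearly below between-species (interspecific) distances? The
   separation between the two distributions is the *barcoding gap*.
2. **Similarity-based**: treating each sequence as a query against all the
   others, how often does its nearest neighbour belong to the right species?
3. **Tree-based**: on a phylogeny built from the locus, do each species'
   individuals form an exclusive (monophyletic) group?

`barcodegap` implements all three evaluations over aligned multi-FASTA
matrices whose headers carry species labels, so that competing loci (ITS1
vs ITS2 vs their concatenation, or any other candidates) can be compared on
the same footing. A seeded synthetic-data generator with known ground truth
makes the whole pipeline testable end to end.

## What it computes

**Distances.** All pairwise distances use the Kimura 2-parameter model with
pairwise deletion of missing data (gaps, `N`, IUPAC ambiguity codes):

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

where *P* and *Q* are the observed proportions of transitions (A↔G, C↔T) and
transversions among the compared sites. Saturated or incomparable pairs are
flagged *undefined* and excluded downstream, never silently zeroed.

**Gap analysis.** The distance partition yields overall intra/inter means,
per-species θ (mean intraspecific distance) and coalescent depth (maximum
intraspecific distance), the largest intraspecific and smallest
interspecific pair, a per-species local gap, and plotting-ready histograms
at configurable bin widths (0.005 and 0.05 by default).

**Identification.** The three classic leave-one-out criteria of
TaxonDNA/SpeciesIdentifier, re-implemented:

- *Best Match* (BM) — species of the nearest non-self neighbour; mixed-species
  ties are ambiguous.
- *Best Close Match* (BCM) — BM restricted to neighbours within a threshold,
  by default the 95th percentile (nearest-rank) of all intraspecific
  distances; nothing within range ⇒ no match.
- *All Species Barcodes* (ASB) — correct only if every conspecific sequence is
  closer than any allospecific one.

Each yields a percentage table (correct / ambiguous / incorrect / no match),
with singleton species counted in the denominator and flagged.

**Trees.** Saitou–Nei neighbor-joining on the K2P matrix, bootstrap support
by column resampling (bipartition frequencies mapped back to the original
tree), Newick import/export (supports round-trip as internal labels), and a
monophyly scorer that reports per-species verdicts plus per-individual and
per-species discrimination rates. Externally inferred trees (ML, Bayesian)
can be scored through the same Newick interface.

## Worked example

```python
from barcodegap import (SimulationConfig, simulate, distance_matrix,
                        partition, gap_report, bcm_threshold, evaluate)
from barcodegap.tree import bootstrap, monophyly

cfg = SimulationConfig(n_species=18, individuals_per_species=3, length=315,
                       d_intra=0.005, d_inter=0.15, seed=42)
matrix, truth = simulate(cfg)

dm = distance_matrix(matrix)
part = partition(dm)
rep = gap_report(part)
print(f"max intra = {rep.max_intra:.4f} ({rep.max_intra_species})")
print(f"min inter = {rep.min_inter:.4f} {rep.min_inter_species_pair}")
print(f"gap present: {rep.gap_present}")

thr = bcm_threshold(part)
for method in ("BM", "BCM", "ASB"):
    s, _ = evaluate(dm, method, threshold=thr if method == "BCM" else None)
    print(f"{method}: correct {s.pct_correct:.2f}%")

tree, info = bootstrap(matrix, n_reps=200, seed=1)
mono = monophyly(tree, {r.id: r.species for r in matrix.records})
print(f"NJ monophyly: {100 * mono.discrimination_rate_individuals:.1f}% of individuals")
```

prints

```
max intra = 0.0193 (Synth_sp02)
min inter = 0.0982 ('Synth_sp02', 'Synth_sp18')
gap present: True
BM: correct 100.00%
BCM: correct 100.00%
ASB: correct 100.00%
NJ monophyly: 100.0% of individuals
```

The largest within-species distance (0.019) stays well below the smallest
between-species distance (0.098), so the barcoding gap is present; with that
separation every sequence's nearest neighbour is conspecific (100 % correct
under all three criteria) and every species is monophyletic on the NJ tree.
Raising `mislabel_rate` in the config degrades these numbers in ways
traceable record-by-record through the returned ground truth.

The same analyses run from the shell (`barcodegap stats / distances / gap /
identify / tree / simulate / run / compare`); `barcodegap run --config
cfg.json` executes every stage for one or more regions, evaluates the
concatenation of two regions sharing record ids, and writes all TSV/JSON/
Newick artifacts plus a provenance block into an output directory.

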