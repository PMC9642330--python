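# Methods

## Scope and data model

The toolkit evaluates a species-labelled, pre-aligned barcode library.
Input is a multi-FASTA whose headers carry `id|species|locality` (or a
GenBank-style `id Genus species ...` header); all sequences must share one
alignment length — no aligner is bundled, because curated *COI* barcodes
align without indels and a strict equal-length check catches upstream
mistakes. Sequences are uppercased with `U → T`; IUPAC ambiguity codes and
gaps are kept in the sequences and handled per-stage as described below.
The analysed alignment length is recorded in every report rather than
assumed, since trimming conventions differ between laboratories.

## Distances

Site patterns are counted under **pairwise deletion**: a site enters a
pair's comparison only if both characters are unambiguous A/C/G/T.
Transitions are A↔G and C↔T; everything else is a transversion. Four
models are available (`p`, `jc69`, `k2p`, `t92`; formulas in the README),
all held internally as proportions — reports print percent with one
decimal, which avoids double-scaling bugs between the two conventions.

Numerical choices:

* A pair whose logarithm argument is ≤ 0 (saturation), or with zero
  comparable sites, is **undefined**: stored as NaN, counted and logged,
  and excluded from every mean, minimum and identification candidate set.
  Undefined entries are never silently zeroed.
* `t92` needs the GC proportion θ; when not supplied it is estimated from
  the dataset's own pooled composition. At θ = 1/2 the model reduces
  exactly to K2P, which the tests assert.
* No gamma rate correction is applied at the distance stage; the headline
  divergence tables of barcode surveys report plain model distances.
* Distance computation uses pairwise deletion while site classification
  (below) uses complete deletion. These follow the defaults of the tools
  practitioners use for each task and are deliberately not unified.

## Population statistics

Haplotype identity is **exact string match** after normalisation; two
records differing only at an ambiguity code are different haplotypes. This
is reproducible and conservative; because curation pipelines sometimes
merge such records, the module also reports how many haplotype pairs an
IUPAC-compatibility match would merge, bounding the discrepancy.

Site classification uses **complete deletion** (a column is analysed only
when every record is unambiguous there): analysed columns are monomorphic
or variable; variable columns are parsimony-informative when ≥ 2 states
each occur in ≥ 2 records, singleton otherwise.

Haplotype diversity is Nei's estimator with the small-sample correction,
`Hd = n(1 − Σp_i²)/(n−1)`, with sampling variance
`V = (2/(n(n−1)))·(2(n−2)(Σp_i³ − (Σp_i²)²) + Σp_i² − (Σp_i²)²)`; the
square root is reported as the SD. Species with a single specimen carry an
N/C (not calculated) marker instead of a value.

## Divergence, nearest neighbours and the barcode gap

Per-species intraspecific mean/min/max are taken over all unordered
conspecific pairs with defined distances. The nearest neighbour of species
S is the heterospecific species attaining `min d(a, b)` over `a ∈ S`,
`b ∉ S`; ties at the minimum are broken lexicographically and reported in
full. The gap verdict is **strict**: `gap present ⇔ NN > max intra`, so a
species sitting exactly on the 1:1 line of the gap scatter counts as
gap-absent. Singletons take `max intra = 0` for their own verdict, still
anchor other species' NN distances, and are excluded from dataset-level
intraspecific averages. Those averages are reported two ways — mean of
per-species means and mean of per-species maxima — because both are quoted
in the literature and they differ materially (0.6% vs 1% on the packaged
survey table); neither is privileged.

Species with mean intraspecific divergence > 2% (strict) are flagged as
candidate species complexes — the conventional ceiling for insect
intraspecific *COI* variation.

## Identification criteria

Identification is **leave-one-out over the full dataset**: each sequence
queries all others; there is no query/reference split. For a query with
candidate distances `d` and threshold `t` (default 1%, the standard
barcode cutoff; alternatively the nearest-rank 95th percentile of all
pooled intraspecific distances, `index ⌈p/100·N⌉` of the sorted pool):

* **Best Match** — inspect the tie set within `tie_epsilon` (default
  1e-12, i.e. exact float ties; configurable because integer-rounding
  pipelines create ties a float pipeline misses) of `min d`: all
  conspecific → correct; mixed → ambiguous; all heterospecific →
  incorrect.
* **Best Close Match** — `min d > t` → no match; otherwise the Best Match
  verdict. "Within" is `≤ t` throughout.
* **All Species Barcodes** — `min d > t` → no match; closest candidate
  heterospecific → incorrect; correct only if every conspecific candidate
  is `≤ t` **and** strictly closer than every heterospecific candidate;
  anything else (interleaving heterospecific, or a conspecific beyond `t`)
  → ambiguous.

Singleton-species queries have only heterospecific candidates: incorrect
under Best Match, and no match under the gated criteria whenever nothing
lies within `t`. The default criterion distance is K2P to match
divergence reporting; p-distance is available and flagged in the report
header. Summary percentages are `100·count/N` rounded to one decimal.

## Delimitation

OTUs are connected components of the graph joining pairs at `d ≤
threshold` (single-linkage closure); undefined distances break edges, with
a logged count. The registry-grade refinements of production barcode-index
systems run only inside their host databases, so this module implements
plain single linkage and labels itself accordingly; what it preserves is
the comparison semantics actually reported by surveys — per species:
match, split into k OTUs, or merged with named partners (split takes
precedence when both apply).

The automatic sweep computes single-linkage merge heights, places one
candidate threshold at each midpoint between consecutive distinct heights,
and scores each candidate by the height gap it separates. This gap-width
score is a transparent stand-in for probability-based partition ranking
(hence "ASAP-inspired" in outputs); the full ranking is reported rather
than auto-accepting one partition. Because single-linkage merge order is
preserved under monotone transforms, the top partition is invariant to
the distance model when the gap is clear — asserted in the tests.

## Trees

Neighbour joining (via scikit-bio) on the full distance matrix serves as a
desk-scale surrogate for likelihood tree inference: the question a barcode
survey asks of a tree is whether species form exclusive, well-supported
clades, which NJ answers from the same distances the rest of the pipeline
uses. Negative NJ branch lengths are clamped to zero. Undefined distances
are a hard error here (remove or impute first). Bootstrap resamples
alignment columns with replacement, recomputes the matrix and tree, and
scores each original internal bipartition by its replicate percentage;
replicates with undefined distances are dropped and logged; a single
recorded seed makes runs reproducible. Monophyly asks whether some
bipartition of the unrooted tree isolates exactly the species' members, so
verdicts are invariant under rerooting; trees are unrooted, with an
outgroup option for display only.

## Synthetic communities

The generator emulates the divergence structure of a tropical mosquito
*COI* survey. Defaults: 73 species, 1–8 specimens each with four singleton
species, L = 707 sites, base composition T 0.385 / A 0.299 / C 0.159 /
G 0.157 (AT-rich, as in real mosquito *COI*), κ = 2, target intraspecific
divergence 0.5%, target interspecific divergence 8%, and one sibling pair
at 0.3% separation reproducing the classic identification failure mode.

Mechanics: one root drawn from the composition; a **star phylogeny**
between species — each species ancestor gets Poisson(δ_inter/2·L)
substitutions from the root, so a pair of species is separated by δ_inter
in expectation; each specimen gets Poisson(δ_intra/2·L) substitutions from
its ancestor. A sibling pair shares an ancestor and each sibling branch
carries Poisson(δ_sib/2·L) substitutions, so the pair's separation has
expectation δ_sib (the per-branch halving keeps all three knobs on the
same pairwise scale). Substitutions are transitions with probability
κ/(κ+2), each transversion 1/(κ+2); multiple hits are allowed. When
specimen counts are drawn from a range, non-singleton species get at least
2 specimens so that identification ground truth is well defined; an
explicit per-species count list is used verbatim. One seeded RNG stream
drives everything; a fixed seed reproduces the FASTA byte for byte.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: coalescent or demographic structure within
species (real haplotype sharing is stronger than Poisson scatter),
rate variation among sites and lineages, indels, codon structure,
pseudogenes/NUMTs, and non-star interspecific topology. Realised distances
scatter around their Poisson expectations, so generator checks use
tolerance bands (±20% on intraspecific means, ±25% on NN means at survey
scale), and the nearest-neighbour distance — a minimum over hundreds of
pairs — sits systematically below the pairwise expectation; the bands
account for this.

A consequence worth stating: with δ_intra = 0.5% and t = 1%, roughly 2–3%
of conspecific pairs exceed the threshold purely by Poisson scatter, so
All-Species-Barcodes cannot reach 100% correct on a large community at
those settings. "100% under all three criteria" holds exactly when the
realised gap brackets the threshold (max intra < t < min NN); the
end-to-end tests generate such a clear-gap community (δ_intra = 0.2%, no
singletons or siblings), assert the premise, and then the conclusion.

## Problem sizes used in the test suite

End-to-end checks run on communities of 6–73 species (up to ~360
sequences, L = 707) with 5–100 bootstrap replicates on subsets of ≤ 30
sequences; property tests use 40–60 bp toy alignments and 4–18 taxon
matrices. These sizes exercise every code path at full realism for the
statistics involved while keeping the whole suite in seconds.

## Known limitations

* Exact-match haplotypes may overcount relative to ambiguity-merging
  curation tools (the merge bound quantifies this per dataset).
* The delimitation sweep's gap score ranks clean-gap partitions well but
  is not a substitute for probability-based model selection when
  divergences grade continuously.
* NJ supports understate the resolution a maximum-likelihood analysis
  could achieve on the same data; the monophyly verdicts, not the branch
  lengths, are the supported output.
* The percentile threshold pools all intraspecific distances, so a few
  deep species complexes inflate it; the per-query report exposes
  `no_match` separately so either accounting of failures can be read off.
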