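# Methods

## The distance model

The only distance used is the uncorrected p-distance. For two aligned
sequences it is d = m / c, where c counts *comparable* sites — both
residues in {A, C, G, T} — and m counts comparable sites at which the
residues differ. Gaps and IUPAC ambiguity codes exclude a site from
both m and c; they never count as a match or a mismatch. A pair with
c = 0 has no defined distance and is an error, not a zero. No
substitution-model correction (K2P, GTR, …) is applied anywhere: the
barcoding-gap question is about observed divergence, and corrections
would only rescale both bins.

Distances are proportions in [0, 1] internally; histograms and reports
print percentage points. Percentages are rounded half away from zero to
one decimal (`format_percent`), matching how such overlap figures are
conventionally printed.

## Binning and gap detection

Every unordered pair of records is assigned to exactly one bin:
intraspecific iff genus and epithet match case-insensitively, else
interspecific. This requires species-level labels, so records with
placeholder epithets (`sp.`, `cf.`, `aff.`, with or without the dot)
must be purged first — such comparisons cannot be assigned a bin, and
`bin_comparisons` refuses them rather than guessing.

Gap detection reports three things deliberately kept separate:

* **strict gap** — max(intra) < min(inter). This is the textbook
  criterion and almost never holds on repository-scale data.
* **widest empty interval** — the largest open interval between
  consecutive values of the *pooled* distance multiset, with a record
  of whether intra and/or inter values flank each end. This captures
  the "dip" one sees in histograms even when both bins straddle it.
  The interval is category-blind by construction; ties between equally
  wide intervals resolve to the smallest lower bound.
* **overlap counts** — interspecific distances ≤ `low_threshold`
  (default 2%) and intraspecific distances > `high_threshold` (default
  5%). The boundary conventions (≤ on the low cut, strict > on the
  high cut) are one consistent choice among the several phrasings in
  use; both thresholds are config fields.

Histogram bins are half-open `[k·w, (k+1)·w)` in percentage points with
w = 0.5 by default; a final bin starting at 100 catches saturated
distances. Bin width affects only presentation — totals are conserved
by construction and tested.

## Trees, lineages, misidentification flags

Neighbor joining is implemented directly (rather than delegated) so
that its degrees of freedom are pinned: ties in the Q-matrix resolve to
the lexicographically smallest (row, column) pair, negative
branch-length estimates are clamped to zero, and the final three nodes
are joined by the closed-form three-point formulas. On additive inputs
this reproduces the generating tree exactly; the test suite verifies
that and cross-checks against scikit-bio's independent NJ
implementation. Midpoint rooting finds the longest tip-to-tip path
(ties: lexicographically smallest tip-name pair) and inserts the root
at its half-length point; the root is never placed *on* a tip, so the
tip set is invariant even for zero-length degenerate trees.

"Lineage" is formalized as a maximal clade of the rooted tree whose
members' pairwise p-distances are all below a cutoff (default 1%, a
conventional within-species scale; the drivers use 5% for the noisier
simulated data). Extraction walks the tree in preorder and stops at the
first qualifying clade on each path, so lineages always partition the
tips and singletons are allowed. Clade numbers are assigned in preorder,
mirroring how clades are numbered top-to-bottom in a plotted tree.

Clade identity is the majority label (ties: lexicographically smallest
full label, flagged as a tie). A member is flagged as a putative
misidentification when its own label differs from the majority *and*
its minimum distance to a majority-labelled member is ≤ `max_dist`
(default 1%): genetic identity plus label disagreement is the signature
of a mislabelled or contaminated record, as opposed to a genuinely
divergent intruder.

## Diagnostic nucleotides

Only pure (private) characteristic attributes are screened: state s at
column j is diagnostic for a group against a background iff every group
member has exactly s at j and no background member can have s there.
Group-side gaps/ambiguities disqualify the column (the state is not
demonstrably fixed); background-side ambiguity whose IUPAC expansion
contains s counts as presence. Both rules are conservative in the same
direction — never claim a diagnostic that uncertain data could refute.
The local screen's background is the members of the *other* lineages
sharing the focal lineage's majority species label; lineages with no
conspecific sibling get no local report. The global screen's background
is every other sequence. Global attributes are necessarily a subset of
local ones (tested). Compound/conditional attribute systems are out of
scope; positions are 1-based on the analysis alignment.

## OTU delimitation

OTUs are connected components of the graph joining pairs at distance
≤ threshold (single linkage), numbered densely by first member index.
Single linkage mirrors the chain-connectivity logic of
statistical-parsimony haplotype networks and makes the OTU count
non-increasing in the threshold (tested by sweep). The default
threshold is 3%, the common heuristic bound on intraspecific COI
variation. `regap_with_otus` re-runs the identical gap machinery with
OTU ids substituted for species labels; externally computed partitions
can be imported from TSV and re-analysed the same way.

## The synthetic-data generator

The generator emulates a curated barcode study: K species, each a tight
cluster around its own ancestor, on a gap-free alignment (curated
barcode alignments of a protein-coding locus typically contain no
indels, and none of the implemented statistics needs them). Evolution
is Jukes–Cantor, site-independent and homogeneous, on a two-level star
genealogy: root → species ancestors → individuals. Branch substitution
probabilities come from p = ¾(1 − e^(−4μ/3)); because JC composes
multiplicatively, giving each branch half the μ implied by a target
p-distance makes the *expected* tip-to-tip p-distance equal the target
(d_intra within species, d_inter between species ancestors; realized
interspecific distances run slightly above d_inter because the two
intra branches add to the path, ~0.157 vs 0.15 at the defaults).

Defaults — 20 species × 10 sequences, 500 columns, d_intra = 0.01,
d_inter = 0.15 — describe a well-behaved barcode locus with an order of
magnitude between the scales, the regime in which a gap *should* exist,
so that confounder injections isolate cause and effect.

Confounders:

* **mislabels** — ⌈rate·n⌉ records get a uniformly chosen wrong
  species label; sequences untouched.
* **cryptic lineages** — half of one species' members receive one
  shared set of JC substitutions at branch length matching the given
  depth, so divergence appears between lineages, not within them;
  within-lineage spread and all other species are untouched (tested).
* **imprecise labels** — epithet replaced by `sp.`.
* **planted diagnostics** — a column is fixed to a state in the target
  lineage and the state is resampled away everywhere else.

Every injection records its victims in the truth object, so recovery
tests are exact. What passing these tests does *not* show: robustness
to rate heterogeneity, codon structure, saturation, indels, uneven
taxon sampling, or the deeply nested phylogenies of real data — the
star genealogy was chosen precisely because the implemented statistics
depend only on the within/between distance scales, which it controls
in closed form.

## Numerical and scale choices

* Test-suite and acceptance problem sizes (200 sequences × 500 columns,
  10 replicate seeds; oracle checks at n ≤ 50) were chosen so the full
  pipeline, including the O(n³) NJ step, completes in seconds while
  keeping every comparison combinatorially non-trivial.
* The distance matrix is computed with vectorised row-vs-rest numpy
  comparisons; exact integer counts, no floating-point accumulation.
* Midpoint and Q-matrix tie-breaks are lexicographic for bit-level
  reproducibility of reruns.
* `detect_gap` uses `np.isclose` only for deciding which bins flank the
  empty interval; all distances themselves are exact ratios of small
  integers.
* Degenerate inputs are first-class: all-identical datasets yield one
  lineage; a partition with a single OTU makes the re-gap analysis
  raise the empty-bin error (surfaced, in the pipeline, as a recorded
  "undefined" result for that dataset rather than a crash).

## Known limitations

* Alignment construction is out of scope; inputs must be pre-aligned,
  and taxon subsets reuse the master alignment's columns (distance-
  identical to per-subset re-alignment when the master is gap-free).
* NJ is O(n³) in dense numpy; comfortable to a few thousand sequences,
  not beyond.
* The lineage definition is a deterministic surrogate for visual clade
  inspection; near the cutoff its boundaries can differ from what an
  expert would draw on the tree.
* Single-linkage OTUs chain: one intermediate sequence can merge two
  otherwise distinct clusters. That is faithful to the network logic it
  mirrors, but it is not a species concept.
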