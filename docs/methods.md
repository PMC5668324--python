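# Methods

This note records the models implemented in `barcodekit`, the conventions
chosen where the field's tools disagree, and what the synthetic data
generator does and does not emulate.

## Distance model

Pairwise distances use the Kimura two-parameter (K2P) model. With *P* the
proportion of transitions and *Q* the proportion of transversions among the
compared sites of a pair,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

Sites where either sequence carries a gap or an IUPAC ambiguity code are
excluded pair by pair (*pairwise deletion*); the number of compared sites is
retained alongside every distance. When `1 - 2P - Q <= 0` or `1 - 2Q <= 0`
the correction is undefined (saturation); such entries are stored as `inf`,
excluded from means, and reported as "undefined" — they are never silently
zeroed. Distances are held as proportions internally and rendered as
percentages (two decimals) in reports.

Per-species summaries report the maximum and mean intra-specific distance
and the nearest-neighbour (NN) distance — the minimum distance from any
member to any non-conspecific individual. The *barcode gap* is evaluated
per species (max intra < NN), matching the 1:1-line reading of an
intra-vs-NN scatter plot, rather than as a single global gap: coalescent
depths differ among species, so a global overlap need not compromise
identification of every species. Mean intra-specific divergence is emitted
both as mean-over-pairs and mean-of-species-means, since either convention
appears in summaries of this kind. Nearest-neighbour ties are all reported,
with the alphabetically first species as primary, for determinism.

Distance histograms bin intra- and inter-specific distances separately into
half-open intervals `[k*w, (k+1)*w)` with default width `w = 0.005`.

## Distance-based identification

Each individual is queried against all remaining references (leave-one-out):

* **Best Match (BM)** — the set of references at minimum distance decides
  (ties within a tolerance of 1e-9 on proportion distances, configurable):
  all conspecific → correct; all allospecific → misidentified; mixed →
  ambiguous.
* **Best Close Match (BCM)** — as BM, but a best distance beyond an
  intra-specific threshold yields *no match*. The threshold defaults to the
  95th percentile (linear interpolation) of all intra-specific pairwise
  distances, computed once on the full dataset even though each query is
  removed from its own reference set; this matches the batch behaviour of
  the classical tools, whose exact threshold is rarely printed, and a fixed
  percentage can be supplied instead.
* **All Species Barcodes (ASB)** — strictest criterion: correct only when
  the within-threshold match set is non-empty and consists of every
  conspecific reference and no allospecific one. When the match set is all
  conspecific but incomplete the query is scored ambiguous (not a positive
  misidentification). A flag optionally tolerates allospecifics inside the
  threshold that are farther than every conspecific, since published
  descriptions of the criterion are ambiguous on that point; the strict
  variant is the default.

Aggregate rates pool ambiguous and no-match as "not identified", so the
three percentages sum to 100.

## Character-based identification

A *pure diagnostic character* is an alignment column at which every member
of a species carries the same unambiguous base and no non-member carries
that base; gaps and ambiguity codes disqualify a column for the species.
Positions are reported as 1-based alignment columns, with degapped
per-sequence coordinates alongside (for indel-free loci the two coincide).

Rule induction replaces a stochastic metaheuristic with a deterministic
procedure having the same rule semantics: individuals are split stratified
by species (default 90% train, at least one individual on each side;
single-member species are excluded with a warning); candidate conjuncts are
the (position, state) pairs fixed and unambiguous within the species' train
slice; the emitted rule is a single pure diagnostic character when one
exists, otherwise the smallest perfect conjunction — found exhaustively when
there are at most 12 candidates, and by greedy non-member exclusion (ties
broken by lowest position) beyond that. Emitted rules have full train
coverage and zero train false positives by construction; test individuals
are assigned to the unique species whose rule matches, and test rates are
reported as correct/misidentified/not-identified.

## CAPS design

Restriction sites are matched as IUPAC-degenerate patterns on both strands
(reverse-strand hits reported on forward coordinates, overlapping hits all
reported). The default enzyme panel is BstXI (`CCANNNNNNTGG`), MnlI
(`CCTC`), HphI (`GGTGA`) and AlwI (`GGATC`), extensible in code. For every
pure diagnostic SNP the degapped majority-rule species consensus around the
SNP (site length − 1 on each side; tied columns yield `N` and the window is
skipped, because assays must rest on fixed differences) is scanned with the
target state and with each non-target species' state substituted; an assay
is emitted when presence/absence of a site overlapping the SNP differs
between the target and *every* other species. Because no cut offsets are
assumed, assays are reported as site present/absent rather than fragment
sizes.

## Phylogenetics

*Neighbour joining* uses the Saitou–Nei algorithm (via scikit-bio) on the
K2P matrix; negative branch lengths are clamped to zero and the tree is
rooted on a user-supplied outgroup. Undefined (saturated) distances are an
error rather than being imputed.

*Maximum parsimony* uses equal-weights Fitch lengths with gaps and
ambiguity codes as missing data (a gaps-as-fifth-state switch is
deliberately not offered; missing is the common default). Site patterns are
compressed and scored with vectorised set operations. Search is exact
branch-and-bound up to 12 taxa (refused above 16 without `force`), and
random-addition + tree-bisection-reconnection hill-climbing otherwise, with
all moves and addition orders seeded from a single user seed. All equally
best trees are retained up to a cap, deduplicated by bipartition set.

Homoplasy indices on a tree of length L use per-character minimum steps
m = (distinct observed states − 1) and maximum (star-tree) steps
g = (taxa with data − frequency of the commonest state):

    CI = M/L,  RI = (G - L)/(G - M),  RC = CI * RI,

with M, G the sums over characters. Both the all-characters and the
informative-characters-only variants are reported, since published values
follow either convention; the headline value uses all characters. When
G = M (no character can show homoplasy) the indices are undefined and
returned as NaN.

Strict consensus retains exactly the bipartitions common to all input
trees. Bootstrap supports resample alignment columns with replacement and
report, for each internal bipartition of the reference tree, the percentage
of replicates containing it. Species monophyly is tested on the
outgroup-rooted tree (singleton species are monophyletic by definition).

## Synthetic data

The generator emulates the design of a small barcoding study: a species
tree, per-species star radiation of individuals, and several loci of
realistic lengths. Defaults are fixed at the study conditions the package
is tested against: four species — three close ingroup species plus a more
distant outgroup analogue — with (5, 5, 5, 2) individuals, five loci of
aligned lengths 676, 751, 380, 679 and 406 bp, indels only on the two
nuclear-like loci, within-species divergence 0.002 and sister-species
divergence 0.04 (mid-scale values of the ~0–0.3% intra and ~0.4–12% inter
ranges typical of such panels), and transition/transversion ratio
kappa = 2, a standard value where none is dictated.

Sequences evolve by the exact K2P transition-probability matrix (no per-site
Bernoulli approximation); the root sequence is uniform over A/C/G/T per
site. Because the K2P correction inverts the model, the expected corrected
distance between two sequences equals their substitution path length, which
makes calibration closed-form: sister-species ancestors are separated by
`inter − intra` and each individual adds an `intra/2` tip branch, so
conspecific pairs sit at expected distance `intra` and sister-species pairs
at `inter`. The default species tree is a pectinate ladder whose successive
splits double in depth; a user newick is rescaled so its closest pair sits
at `inter − intra`. Within-species variation is a star (independent tip
branches), not a coalescent — chosen because it matches the analysis'
assumptions and keeps the calibration exact.

Injected SNPs are applied after evolution: the target species is set to the
state, non-target carriers are rewritten to the non-target majority base,
and a configuration whose state equals the non-target consensus is
rejected. Indels are overlaid as deletions: per sequence a Poisson number
of events (the locus' `indel_rate` is the expected events per sequence),
each a run of 1–3 bp (truncated geometric); adjacent events can merge into
longer observed runs. Everything is driven by one `numpy` generator seeded
from the config, so identical configs give byte-identical FASTA.

What the simulator does *not* emulate: rate heterogeneity across sites,
recombination, secondary-structure constraints on nuclear spacers,
alignment error, and sequencing artefacts. Passing tests on simulated data
therefore demonstrate correctness of the algorithms under their own model
assumptions, not robustness of the loci choices to real-data pathologies.

## Problem sizes in the test suite

Oracle-equivalence tests run on 5–7 taxa, where exhaustive enumeration
(all topologies; all internal state assignments) is feasible. Statistical
checks use 50 simulation replicates at 1000 bp for divergence recovery and
20 seeds for topology recovery (requiring ≥ 95% success with
inter = 10 × intra). The acceptance script evaluates the full 17-individual
five-locus panel; hill-climbing parsimony with 5 random-addition replicates
completes in seconds at this size.

## Known limitations

* Only the K2P model is implemented; no model selection (out of scope by
  design — the evaluation conventions of this field are K2P-based).
* TBR hill-climbing is a local search; on large panels the returned length
  is an upper bound, mitigated by multiple random-addition replicates.
* Pairwise identity offers two gap conventions (gap-vs-base as difference,
  the default, or excluded) because the convention behind published
  "pairwise identity" values is usually unstated.
* CAPS assays score recognition-site presence only; cut positions and
  fragment sizes would require per-enzyme cut offsets.
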