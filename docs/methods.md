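# Methods

## Clonality statistics

A repertoire is a per-cell table (cell, subject, clonotype id, Foxp3
lineage).  Clone identity is taken verbatim from the upstream VDJ caller —
whether clonotypes were defined at nucleotide or amino-acid level is treated
as an upstream choice the package never second-guesses.  Repertoire mass is
counted in cells (one cell = one unit), consistent with defining clonal
expansion as more than one cell per clonotype; UMI-weighted variants are out
of scope.

**R20.**  Rank the C clones of a subject by descending size, let N be the
total cell count, and find the smallest k such that the top-k cumulative
cell count is ≥ 0.2·N.  R20 = k/C.  The threshold comparison is *inclusive*:
"accounting for 20 %" includes repertoires that land exactly on the
boundary, and the implementation evaluates the threshold in exact rational
arithmetic (0.2·15 must be 3, not the binary float 3.0000000000000004, or
boundary repertoires gain a spurious extra clone).  Ties in clone size can
change which clones sit in the top k but never k itself, so the score is
deterministic without a tie rule.  A monoclonal repertoire scores 1.0 by the
formula; the summary flags it as degenerate so it is not misread as
maximally polyclonal.  For C equal-sized clones R20 = ⌈0.2·C⌉/C, which the
tests use as a closed-form oracle.

One property that intuition suggests but that is *false* in general: merging
two singleton clones into a doubleton can **increase** R20, because the
clone count C shrinks while k may not (sizes [10, 1, 1] score 1/3; merged
[10, 2] score 1/2).  The monotone quantity is k itself — concentrating mass
never increases the number of top clones needed — and that is the form the
property tests assert.

**Expansion and sharing.**  A clone is expanded iff size > 1; the expanded
fraction is over all clones of the subject.  A clone is SHARED iff it
contains ≥ 1 Treg and ≥ 1 Tconv cell, otherwise TREG_ONLY/TCONV_ONLY; the
expanded-clone composition is the category distribution restricted to
expanded clones.  Statistics are strictly per subject; cross-subject testing
(the study-level ANOVA layer) is routine statistics left to the caller.

**Subsampling.**  Because subjects contribute unequal cell numbers, the
summary layer can recompute R20 or the expanded fraction on repeated
without-replacement subsamples of fixed size (seeded), reporting the mean
and the 2.5/97.5 percentile interval.  Whether clonality should be scored on
all T cells jointly or per lineage is not fixed by the package: every scorer
accepts a pre-filtered table, and the CLI exposes a `--lineage` filter.

## Microniche detection

Cells of the included types (default DC, Tconv, Treg) are clustered with
DBSCAN semantics on Euclidean distance in µm: a core cell has ≥
`min_samples` cells (itself included) within `eps`; clusters are connected
components of core cells plus reachable border cells; everything else is
noise.  Classic DBSCAN assigns a border cell reachable from several clusters
to whichever is visited first, making the labelling depend on row order.
Here border cells go to the cluster containing their nearest core cell, with
exact-distance ties resolved toward the lower-ranked cluster (clusters
ranked by the lexicographically smallest (x, y, cell_id) of their core
members).  The output is therefore deterministic and invariant under row
permutation and rigid motion, which the tests verify against a naive
quadratic reference implementation and against scikit-learn's DBSCAN on the
(order-independent) core-point partition.

Detection parameters are not dictated by the data modality and are exposed:
defaults `eps` = 30 µm (roughly 2–3 hepatocyte diameters — cells in physical
contact across one or two intervening cells) and `min_samples` = 5 (the
2·dim + 1 heuristic).  A cluster is retained as a niche only if it contains
≥ `min_dc` = 1 DC and ≥ `min_t` = 3 T cells; this operationalises "DC–T
cell cluster" while excluding pure-T clumps, and is configurable.  The same
rule is applied regardless of whether the input cell table came from in-situ
transcriptomics or from immunofluorescence imaging — foci in the latter are
often counted manually in practice, so one explicit, configurable rule for
both keeps the two quantifications comparable.

**Whole-slide statistics.**  The nearest-DC distance is computed per T cell
(Tconv or Treg) against all DCs via a k-d tree and averaged per slide.
Focus density is niche count divided by tissue area in mm²; when no tissue
mask is supplied the area is estimated from the cell point pattern, either
as the convex-hull area (tight for convex sections) or an occupancy-grid
count (`grid_step`-sized bins containing ≥ 1 cell; coarse grids
overestimate).  A niche is *parenchymal* iff no vessel feature (point, or
polygon boundary/interior) lies within `proximity_radius` of its centroid;
the study did not quantify "close proximity", so the default is 50 µm — on
the order of one portal-tract radius — and configurable.  With no vessel
features the parenchymal fraction is 1 by definition; with no niches it is
undefined and reported as missing rather than 0.

Coordinates are µm with arbitrary origin and axis orientation; all
statistics are translation/rotation invariant.  Distances use cell
centroids (imaging resolution does not distinguish centroid vs. membrane).

## Differential expression inside vs. outside niches

Counts are normalised per cell to 10,000 total (counts-per-10k) and log1p
transformed; zero-total cells are dropped and reported.  For one cell type,
cells are split by niche membership (membership comes from the clustering,
never from hull geometry) and each gene is tested with a two-sided Wilcoxon
rank-sum test, normal approximation with tie and continuity correction — the
standard nonparametric contrast for targeted-panel counts, robust to the
counts' marginal distribution.  Genes detected in neither group are excluded
before testing and counted; Benjamini–Hochberg adjustment is applied across
the *tested* genes only (adjusting across the pre-filter panel would inflate
every q deterministically).  The log2 fold change is computed on the group
means of the normalised values with a 1e-9 pseudocount that prevents ±∞
ratios and never enters the test.  Each side must contribute ≥ 10 cells
(default): below that the normal approximation is unreliable.  A gene whose
normalised values are identical in both groups carries no evidence and is
assigned p = 1 rather than a 0/0 statistic.  Known limitation: cells are
treated as exchangeable — there is no pseudobulk/mixed-model layer and no
spatial-autocorrelation correction, so q-values on real tissue with strong
per-animal or per-section structure are anti-conservative.

## Synthetic data

The generators define the study-like conditions under which the pipeline is
validated; they are seeded and bit-reproducible.

**Repertoires.**  Clone sizes are drawn i.i.d. from a configurable law —
Zipf (power law, exponent > 1), geometric (mean 1/p), or uniform — until the
cell budget is met; the last clone is truncated so the cell count is exact
(keeping closed-form checks exact).  Lineage is drawn once per clone
(clonal coherence), except that a controlled fraction `sharing_rate` of the
expanded clones is forced to contain both lineages (one cell of the minority
lineage, the rest i.i.d. Bernoulli(p_treg)).  Shared clones are therefore a
planted quantity: `sharing_rate` = 0 guarantees zero shared clones.

**Tissues.**  Background cells follow independent homogeneous Poisson
processes per type (defaults ~90 included-type cells/mm², i.e. an expected
0.25 background cells per 30 µm-radius disc — sparse relative to niches).
Niche centers are rejection-sampled under a minimum-separation constraint
(≥ 2·radius required; generation fails explicitly after 10,000 attempts);
members are placed uniformly in discs (default radius 15 µm) with
Poisson-distributed type counts (defaults: mean 4 DC, 10 T).  Vessels are
generated as points (the classifier also accepts polygons).  Gene counts are
Poisson with mean = baseline × fold for niche members of the matching type.
No overdispersion knob is provided in this version: the DE test is
rank-based, so Poisson margins exercise the full inferential path; what
Poisson margins do *not* exercise is the variance structure of real panels,
so power estimates on synthetic data are optimistic for strongly
overdispersed genes.

**Fixture suite.**  Three repertoires mimic the postnatal trajectory —
PND4-like (geometric p = 0.92, sharing 0.05), PND7-like (p = 0.55, sharing
0.30), adult-like (p = 0.96, sharing 0.02), 800 cells each — directionally
consistent with an expansion-and-sharing wave that collapses into a
near-fully polyclonal adult repertoire; the parameters are plausible
defaults chosen once, not fitted values.  Two tissues differ only in vessel layout: the neonatal-like
tissue has 8 niches with vessels rejected within 250 µm of any niche center
(parenchymal niches), the adult-like tissue has 4 niches each with a vessel
point 20 µm away (periportal niches).  The neonatal tissue plants the
qualitative niche effects characteristic of tolerogenic DC–T clusters — DC
upregulation of Ccr7, Cd80, Pdcd1lg2, Cd274 and Cxcl10, T-cell upregulation
of Ikzf2 and Cxcr3 (folds 2.5–4) — so the DE stage must recover planted
structure with the right directions; this validates the pipeline's recovery
of injected effects, not the biology itself.

What passing on synthetic data does **not** show: robustness to segmentation
errors, cell-type misassignment, spatially varying density (zonation),
overdispersed or zero-inflated counts, or batch/animal structure — all
absent from the generator by design.

## Numerical and determinism choices

- R20 thresholds use exact rational arithmetic; all other statistics are
  double precision.
- All randomness flows through `numpy.random.default_rng(seed)`; every
  simulator, subsampler and fixture is bit-reproducible given (params, seed).
- Writers are byte-stable: JSON keys sorted, floats to 6 significant
  digits; CLI manifests isolate the timestamp so output files hash
  identically across reruns.
- Degenerate cases are explicit: monoclonal repertoires are flagged;
  collinear convex hulls raise and suggest the grid estimator; niche hull
  areas of collinear member sets are reported as undefined; the parenchymal
  fraction of an empty niche list is missing, not zero.
- Problem sizes in the test-suite simulations (e.g. 200 recovery runs of a
  1500 µm field with 3 niches; 100 DE power runs at 55/70 cells per side;
  500-gene null panels) were chosen as the smallest sizes at which the
  Monte-Carlo error of the checked rates is well below the asserted margins.
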