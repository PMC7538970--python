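# Methods

`cryptomotu` implements a complete cryptic-diversity analysis for aligned
mitochondrial barcode data (COI-style): haplotype collapsing, Kimura
two-parameter distances, four independent MOTU-delimitation methods,
concordance and geographic summary statistics, strict-clock chronogram
utilities, and interpolated genetic-landscape surfaces. A calibrated
synthetic-data generator provides datasets with known ground truth so that
every stage is testable offline.

## Distances

Pairwise divergence uses the Kimura two-parameter model,

    d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)),

with transition proportion `P` and transversion proportion `Q` computed
over columns where both sequences carry an unambiguous A/C/G/T (pairwise
deletion). A pair is *undefined* — excluded from histograms, gap detection
and clustering edges — when fewer than `min_overlap` columns are
comparable (default 300, the floor below which barcode fragments are not
assignable) or when the logarithm's argument is non-positive
(saturation). Defaults reflect datasets mixing full-length and partial
amplicons.

## Barcode-gap delimitation (ABGD-style)

Distances are sorted; given a prior maximum intraspecific distance `p`,
the baseline increment `b` is the 95th percentile of consecutive
differences among distances at or below `p`. A candidate gap is an
interval `(d_i, d_{i+1})` that ends above the prior and has at least two
distances below it; it qualifies when its width exceeds
`X * max(b, p/10, d_i)` with relative-gap factor `X = 1.5`. The last term
— the gap must also dwarf the whole intraspecific distance level beneath
it — is this package's significance rule. A purely spacing-based test
(only `b` and `p/10`) turned out to fire on noise inside genuinely
homogeneous groups whenever the prior sits below the intraspecific level,
recursively shattering true lineages; anchoring the width requirement to
`d_i` makes detection scale-aware at every recursion depth while leaving
wide, genuine gaps untouched. Groups are cut into single-linkage
components at the gap threshold and the procedure recurses inside each
component. The procedure runs over a log-spaced ladder of priors
(0.001–0.1, 10 steps) and reports as *primary partition* the grouping
stable over the longest contiguous prior run, ties resolved toward larger
priors (the conservative end).

## BIN-style clustering (RESL-like)

Full-length haplotypes (>= 500 unambiguous bases) are clustered by single
linkage at 2.2%; cluster pairs closer than the 4.4% isolation floor are
merged back unless the merged set shows an internal discontinuity. In the
refinement pass every cluster is recursively split at the dendrogram cut
maximizing mean silhouette width when that value reaches 0.5 — even below
2.2%. Candidate bipartitions are the subtree-versus-rest cuts of the
cluster's single-linkage dendrogram; mean silhouette over a precomputed
distance matrix is the discontinuity statistic (the registry's actual
refinement statistic is not published; silhouette is the standard
surrogate, deterministic and tunable). Short sequences (300–500 bases)
are ascribed to the cluster of their nearest full-length haplotype when
within 2.2%, otherwise each becomes a flagged "BIN-equivalent" singleton
MOTU; anything shorter is rejected with a report.

## Poisson tree processes

Branch lengths (substitutions/site) are modeled as two independent
exponential classes — speciation branches between species, coalescent
branches within. A delimitation is an antichain of crown nodes covering
all tips; edges strictly inside a crown subtree are within-class, all
others (crown edges, backbone, root edge) speciation-class. With `n`
edges of total length `L` in a class the plug-in rate is `n/L` and the
class log-likelihood `n ln(n/L) - n`.

Branches shorter than `1e-4` substitutions/site are excluded from both
classes. Trees estimated from barcode-length alignments cannot resolve
such branches, and without the floor the plug-in likelihood diverges by
collecting near-zero branches into one class (the fitted rate grows
without bound), which drives the ML solution toward absurd oversplits.

The ML search is exact — full antichain enumeration — whenever the tree
admits fewer than 50,000 delimitations; larger trees use deterministic
coordinate ascent: for fixed rates the optimal delimitation is computed
exactly by dynamic programming over the tree (each free node is either a
crown node or above the crowns), then rates are re-estimated from the
induced classes, iterating to a fixed point from four quantile-based rate
initializations and keeping the best optimum. Single-move greedy search
(split one crown at a time from the root) was evaluated first and stalls
on a likelihood plateau: early splits expose short backbone branches to
the speciation class and every single step is downhill even when the
global optimum is far better. The optional Bayesian sampler is
Metropolis–Hastings over delimitations with uniform split/merge proposals
and a count-based Hastings correction (defaults mirror common practice:
500,000 iterations, 10% burn-in, three runs whose modal MOTU counts are
compared; disagreement beyond 10% raises a warning, not an error).
Support values are post-burn-in frequencies of each crown subtree. For
self-contained runs the input tree is a neighbor-joining tree built from
the K2P matrix and midpoint-rooted — a documented surrogate; tree
inference proper is out of scope.

## Chronograms and the sister-clade (Lagrue) rule

A strict clock (default 0.0115 substitutions/site/My, the standard
arthropod COI rate) rescales an ultrametric tree to ages in My;
ultrametricity is checked to a relative tolerance of 1e-6. The
lineage-through-time series counts reconstructed lineages at each
internal-node age, from 2 just after the root to the tip count.

The sister-clade rule delimits MOTUs by reproductive-isolation
calibration: in post-order, two child clades that are each still a single
group merge iff their between-clade K2P distance is at or below the
cutoff (default 0.20; mate-choice experiments show random mating around
0.04 and discrimination around 0.16). Once a child is multi-group no
merge happens above it, so every MOTU is a clade. The between-clade
distance is the mean over defined haplotype pairs by default (`min` is
available); the source rule does not specify the linkage.

## Diversity statistics

The incidence table counts individuals per site x MOTU. Syntopy is the
percentage of sites with at least `min_individuals` (default 2) sampled
individuals that host >= 2 MOTUs, with the >= 3 count reported alongside.
The rare-MOTU profile is restricted to multi-MOTU sites with more than 10
individuals — a monomorphic site has no rare MOTU, so including
monomorphic sites in the denominator would conflate rarity with absence —
and reports the share of such sites whose least-frequent MOTU is at
relative frequency <= 0.2 (and <= 0.1). Range classes use the maximum
great-circle distance (haversine, R = 6371 km) among a MOTU's occupied
sites: narrow < 100 km, broad 100–1000 km, widespread > 1000 km.
Latitudinal diversity uses half-open 0.5-degree bands (a MOTU counts once
per band where it occupies a site); altitude box statistics are reported
per MOTU present at >= 3 sites.

## Genetic landscape

Sites are joined by planar Delaunay triangulation on (lon, lat); each
edge carries the mean cross-site K2P divergence (individual-weighted by
default) placed at the arithmetic midpoint; only haplotypes with > 496
unambiguous bases enter (a gap-free comparison set). The surface is
inverse-distance-weighted interpolation (power 2) of all midpoint values
on a 200 x 200 grid over the padded site bounding box, masked outside the
site convex hull; a cell coincident with a midpoint takes its value
exactly, so the surface is bounded by the input extremes and deterministic
in edge order. IDW replaces a GIS triangulated-irregular-network step:
single-pass, deterministic, and sufficient for the bounded-surface
properties the maps rely on. Planar treatment of coordinates is a
documented approximation acceptable at continental extent for a
visualization surface. A variant excludes user-specified divergent MOTUs
and reports the remaining site and haplotype counts.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes —
not sequence-level realism. `K` lineages (default 12) carry
`haplotypes_per_lineage` (default 5) haplotypes of length 530. Founder
sequences substitute `m` sites of a random root sequence, with `m` chosen
by inverting the K2P map: the observed-difference fraction `p` solving
`K2P(P = f p, Q = (1-f) p) = target_between` (transition fraction
`f = kappa/(kappa+1)`, default kappa 4) gives `m = L(1 - sqrt(1-p))`
after accounting for expected site-set overlap; founders sharing a site
receive distinct derived bases, so every union site differs and realized
founder divergence is pinned to the target (default 0.22). Within each
lineage, haplotypes evolve from the founder along a random-join genealogy
whose tip depth realizes pairwise within-lineage divergence near
`target_within` (default 0.02); per-branch substitution counts are
conditioned on their expectation (only positions and substitution types
are random). These two calibration choices matter: with freely
Poisson-realized branch lengths the sister-lineage divergence fluctuates
by ±0.02–0.03 at barcode length, which erases the margin between the
0.22 between-lineage target and the 0.20 sister-clade cutoff; the
delimitation benchmark would then measure estimator noise rather than
method behavior.

Geography: sites (default 60) occupy contiguous per-lineage longitude
blocks (endemism); with probability `syntopy_prob` (default 0.3) a site
also hosts the neighbouring block's lineage, its sampling weight drawn
from 0.05–0.5 (one lineage usually dominates, making site-level rarity
statistics informative). Individuals per site are negative-binomial
(mean 10, shape 2, minimum 1). Altitudes are block-centred with normal
scatter; all randomness flows from one seed and reruns are
byte-identical.

What passing tests on this generator do show: the four delimiters,
statistics and surfaces behave correctly when the barcode gap is real and
deep. What they do not show: performance under rate heterogeneity among
sites, recent or incomplete divergence (no barcode gap), saturation
beyond ~0.35, contamination/misidentified sequences, or uneven real-world
sampling geography.

## Numerical choices and degenerate inputs

Haplotype identity is exact string equality over the analysis window;
ambiguity codes and N are ordinary characters (deterministic and
order-independent; the upstream convention for ambiguity collapsing is
not standardized). Column coordinates are 0-based half-open everywhere.
Gap-search ties break toward the smaller threshold (defer splitting to
the recursion); PTP enumeration prefers fewer crown nodes on likelihood
ties; silhouette of a singleton group is 0; undefined distances propagate
as NaN and never create clustering edges; an all-undefined matrix is a
delimitation error rather than a silent single cluster. The exact-PTP
size bound (50,000 delimitations) and the default problem sizes used in
tests and in `scripts/acceptance.py` (K = 12, 60 sites, ~600 records)
were chosen so a full run completes in seconds on one CPU while still
exercising the heuristic (non-exact) PTP code path.

## Known limitations

The RESL stage approximates an unpublished proprietary refinement
statistic; parity with registry BIN identifiers is out of scope. The PTP
coordinate ascent is a local optimizer above the exact-search bound. The
landscape surface is planar and for visualization, not inference. The
published counts from the original continental dataset depend on that
dataset (and, for tree-based methods, on unpublished inferred trees);
this package reproduces the procedures and validates them on calibrated
synthetic data.
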