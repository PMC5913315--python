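# Methods

## Problem and model

`threatnet` analyses the drivers of species extinction and endangerment on
islands as a set of bipartite networks between biological entities and
threat classes. The input is a table of conservation assessments: each
species carries a higher taxon (one of 8), a Red List status (EX, EW, CR,
EN, VU), one or more insular region labels (15 by default), and zero or
more coded threats. Threat codes are hierarchical, dot-separated integer
paths in the style of the IUCN threat classification scheme v3.2 (e.g.
`8.1.2` = a specific invasive species problem under level-1 category 8).

Codes are aggregated into **11 major threat classes** by longest-prefix
matching against a configurable scheme. The shipped default maps the v3.2
level-1 categories to: urbanization (1), cultivation (2), energy and
mining (3), transportation (4), wildlife exploitation (5), human
disturbance (6), habitat modifications (7), biological invasions (8),
pollution (9), climate change (11), and a residual "other" class (12).
Level-1 category 10 (geological events) is deliberately unmapped: codes
under it are excluded from all analyses, which is how the count lands on
exactly 11. The mapping is plain YAML and user-replaceable; nothing in the
pipeline assumes the default beyond the class count of 11. A prefix
matches on whole dot-separated components (so `1` matches `1.2` but never
`11.2`), and among matching entries the longest wins — this lets a deeper
prefix such as `2.4` be routed to a different class than its parent.

A species' **threat profile** is the *distinct set* of classes over its
mapped codes; duplicate codes under one class collapse, unmapped codes
drop out. Species with an empty profile ("no identified cause of
decline") are retained on load but excluded from every network and
statistic.

## Filters

* **Status partition.** Extinct = EX + EW; threatened = CR + EN + VU.
  Disjoint and jointly exhaustive over the five statuses.
* **Region eligibility.** A region is kept when strictly more than
  `min_assessed` (default 50) distinct species carry its label; a species
  in k regions counts once in each of the k tallies. Species left with no
  eligible region are dropped.
* **Harsh-impact screen** (off by default). A species is kept iff at least
  one of its threat entries has scope in {whole >90%, majority 50–90%}
  AND severity in {very rapid, rapid, slow significant declines} — both
  on the *same* entry, since scope and severity qualify a particular
  threat, not the species. `unknown` never qualifies on either axis. By
  default all threats of a kept species are retained; a switch restricts
  to the qualifying entries only. The filter is idempotent and
  order-preserving.
* **Timing** is recorded but not filtered by default; an optional switch
  drops `past`-only threat entries for current-threat analyses.

## Networks

Three kinds per partition, all with the 11 class nodes always present
regardless of degree (so a species network over n species has n + 11
nodes):

* `species_unweighted` — node per species with a non-empty profile, one
  unit edge per (species, class).
* `taxa_weighted` — node per taxon; edge weight = number of *distinct*
  species of the taxon whose profile contains the class. Summing the
  species network's incidences by taxon reproduces this network exactly,
  and the test suite checks that equivalence.
* `region_weighted` — likewise per region; a species in k regions
  contributes to all k region weights, so region rows are deliberately
  non-additive to the global totals.

Entity nodes are sorted, so GEXF/GraphML/CSV exports are byte-stable
across runs. Exports carry `part` (entity/threat), `kind`, species
status/taxon, and for region networks the shipped centroid lat/lon, to
support geographic layouts in downstream tools. Layout itself is out of
scope.

## Statistics

* **Link shares**: 100 × (links of a class) / (total edges); shares sum to
  100 up to float rounding.
* **Threats per species**: mean and *sample* (n−1) standard deviation of
  profile sizes. The identity mean × n_species = n_edges holds exactly
  before rounding. Mean/sd are `None` (flagged, never silent NaN) for 0
  or 1 species. Values are carried at full precision; the one-decimal
  presentation happens only in reports.
* **Single vs association**: species are grouped by exact profile;
  size-1 profiles are "single threats", size ≥ 2 "threat associations".
  Shares are species-denominated — percent of species with ≥ 1 mapped
  class — so the two always sum to 100. (Alternative link- or
  threat-denominated readings do not produce internally consistent
  totals; this package commits to the species denominator.)
* **Top-N combinations**: sorted by species count descending, ties broken
  by smaller combination first, then lexicographic class order. The
  tie-break is a package convention; nothing downstream depends on it.
* **Group breakdowns** repeat the summary + tally per taxon, region, or
  status.

No inferential statistics are computed: the analysis is descriptive by
design, and the status breakdown merely reports per-status means without
any monotonicity claim.

## Synthetic data generator

The generator emulates a global insular Red List extract: independent
draws of taxon, status, and region(s) from categorical mixes; with
probability `p_no_threat` an empty threat list; otherwise a class count k
from a configurable distribution (support truncated to 1..11 by
rejection), k distinct classes sampled without replacement proportional
to a prevalence vector, each materialized as an entry under the class's
representative code with qualifiers drawn from scope/severity/timing
mixes. All randomness flows through one `numpy.random.Generator`, so a
seed fixes the output byte-for-byte.

The count distribution and prevalence may differ between the extinct and
threatened partitions — a deliberate extension of the otherwise single
parameter block, because real extinct species carry fewer and more
invasion-skewed threats than threatened ones.

`preset_paperlike()` is the calibrated default configuration:

* zero-truncated Poisson counts with rates solved from
  λ/(1−e^−λ) = target mean, targeting **1.5** threats/species for the
  extinct partition and **2.6** for the threatened one;
* extinct prevalence ordered invasions (0.502) > exploitation (0.241) >
  cultivation (0.126); threatened prevalence led by exploitation (0.224)
  and cultivation (0.223) with invasions third (0.160);
* taxon mix proportional to the 8-taxon composition of a global insular
  assessment pool; status mix ≈ 6.9% extinct; region mix concentrating
  ~53% of species in the three hotspot regions (Madagascar, West Indies,
  Polynesia and Micronesia) with the remainder uniform;
* qualifier mixes chosen so that roughly one in five threatened species
  with identified threats passes the harsh-impact screen;
* `p_no_threat` of 0.447 (extinct) and 0.315 (threatened), matching the
  fraction of assessments without identified causes.

What the generator does **not** emulate: joint taxon × region × threat
correlations (draws are independent), temporal structure, taxonomy, or
the empirical dispersion of threat counts — a zero-truncated Poisson with
mean 2.6 has sd ≈ 1.4, wider than real assessment data. Passing tests on
synthetic data therefore validate the *pipeline arithmetic and
invariants*, not any ecological claim about real Red List extracts.

## Numerical and design choices

* Zero-truncated Poisson rates are solved with Brent's method on
  λ/(1−e^−λ) − m over λ ∈ (0, 60]; rejection sampling keeps the support
  exactly 1..11 (the upper truncation is negligible at the calibrated
  rates but exact by construction).
* Qualifier tokens from real-world exports are coerced only through an
  explicit alias table (e.g. `Whole (>90%)` → `whole_gt90`); any other
  unrecognized token is a hard error, because silent coercion hides
  dialect drift.
* Degenerate inputs: empty record lists yield valid empty networks (11
  threat nodes, 0 edges) and summaries with flagged-undefined means.
* Pipeline runs are deterministic and idempotent; a failed stage removes
  partial outputs.
* Analysis drivers run at 10,000 synthetic species; the fixed-degree
  network reconstructions use 249 species / 382 links and 4,127 species /
  10,530 links, the sizes at which the node-count and mean-degree
  conventions are exercised. These sizes keep every run in seconds while
  leaving Monte-Carlo errors well inside the tested tolerances.

## Known limitations

* The default 11-class scheme is a reconstruction from the class names
  used in published insular-threat analyses; teams with their own
  aggregation table should supply it as YAML, which the loader treats
  identically.
* Region labels are taken as given; no GIS delimitation or reconciliation
  is attempted, and no IUCN API access is provided.
* Association shares are species-denominated by construction; figures
  computed under other denominators are not comparable one-to-one.
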