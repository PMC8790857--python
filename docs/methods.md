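# Methods

## The analysis model

`orgnet` analyses multi-layer dyadic survey data between organizations. A
*roster* of organizations (each with a type from a closed 8-category set, a
count of countries of operation 0–8, and a respondent flag) defines the node
universe and its canonical ordering (sorted by `org_id` unless an explicit
order is supplied). A *dyadic report* is one directed survey answer: the
reporting organization's value about an alter on one relation layer. Layers
and scales are fixed by the survey structure:

| layer | scale | codes |
|---|---|---|
| overall | binary | 0–1 |
| intensity | none < communication < coordination < collaboration | 0–3 |
| policy, capacity, knowledge, implementation | not at all < rarely < sometimes < often < very often | 0–4 |

Likert labels are matched case-insensitively against these exact strings
(underscores and spaces interchangeable); anything else is a hard error or a
counted drop, never a fuzzy match — silent mis-coding is worse than failure.

### Confirmation

Directed reports are perceptions, so all measures operate on *confirmed*
networks. For ordinal layers the confirmed value is `min(V, Vᵀ)` elementwise;
for the binary layer a tie requires both directions positive (equivalently,
minimum confirmation followed by binarization at the lowest positive level).
The rule is idempotent, monotone in each directed report, and dominated by
both reports. Dyads with a non-respondent on either side are *unconfirmable*:
under the default node policy (`respondents`) non-respondents are removed
from the analysed network; under `all-as-isolates` they are retained as
structural isolates with all their dyads zeroed. Either way every positive
directed report lost to missingness is counted and surfaced in the run
manifest. An absent dyad row from a respondent means reported absence (0); an
absent row from a non-respondent means missing, not zero.

A confirmed nutrition-layer tie is deliberately *not* forced to imply an
overall-layer tie: the layers are treated as independently answered
questions, and consistency between them is an empirical property of the
data, not an enforced constraint.

### Measures

On confirmed, binarized, undirected networks (binarization threshold
configurable, default ≥ 1 = any positive confirmed level):

- density = ties / (n(n−1)/2), percent; undefined for n < 2;
- normalized degree centrality = degree/(n−1), percent;
- normalized betweenness centrality = Σ pair-wise geodesic shares /
  ((n−1)(n−2)/2), percent, all geodesics counted, pairs in different
  components contributing zero (no harmonic variant); undefined for n < 3;
- Freeman centralizations with centralities as fractions: degree
  Σ(c_max−c_i)/(n−2), betweenness Σ(b_max−b_i)/(n−1); both equal 100% exactly
  on a star and 0% on any vertex-transitive graph.

Betweenness is delegated to networkx's Brandes implementation; the test
suite checks it exactly against an independent exhaustive all-geodesics BFS
enumerator on hundreds of random graphs up to 12 nodes. Computation is full
precision; reports round to one decimal in percent. The normalization base
*n* is always taken from the analysed node set of the data at hand, never
from a constant.

### Multiplexity

The four confirmed, binarized nutrition layers are stacked on an identical
node ordering (enforced, with an alignment error listing any difference) in
the fixed order policy, capacity, knowledge, implementation. The
multiplexity score of a dyad is the pointwise sum of the four binary
matrices, i.e. the number of working relationships connecting the pair
(0–4); score-0 dyads are omitted from the multiplex edge list. Multiplexity
counts layers; it does not weight by frequency level.

## Synthetic data generator

The generator emulates the data-generating situation the pipeline assumes,
and supplies ground truth for recovery tests.

**Latent structure.** Per layer, an undirected planted-partition draw over
the typed roster: a dyad is tied with probability `p_in` (same type),
`p_out` (different types), or `p_broker` (different types, at least one
endpoint a designated broker). Tied dyads receive an ordinal level from the
layer's conditional distribution. The intensity layer relabels the overall
layer's tied dyads (the survey only asks intensity where a relationship
exists); nutrition layers are drawn independently of each other — the
simplest structure that exercises multiplexity over its full 0–4 range.
Cross-layer correlation via a shared latent propensity is a stated
extension, not implemented.

**Reporting noise (discordance).** Each direction of each latent tie is
reported independently: with probability `1−d` the latent value; with
probability `d/2` the report is omitted; with probability `d/2` it is
shifted one level down (never up — under-reporting is the conservative
perturbation for a minimum-confirmation design, which already guards against
over-reporting). A one-level shift from level 1 is an omission. Default
`d = 0.10`; no empirical noise estimate exists for surveys of this kind, so
this default is asserted by the package, documented here, and configurable.

**Non-response.** An exact `round(nonresponse · n)`-sized random subset of
organizations returns no reports; default 0.14, i.e. 43 respondents of a
50-organization roster.

**Default conditions.** 50 organizations with the type mix of a regional
nutrition-actor roster (8 UN, 3 multilateral, 4 bilateral, 9 NGO, 6
academic/research, 1 intergovernmental, 5 foundation, 14 network); two
brokers (first UN and first multilateral organization) with
`p_broker = 0.35`; per-layer `(p_in, p_out)` of overall (0.45, 0.16), policy
(0.20, 0.040), capacity (0.15, 0.028), knowledge (0.30, 0.060),
implementation (0.18, 0.032), chosen once so confirmed layer densities land
in the sparse ~4–10% band with the overall layer several times denser and
knowledge the densest working relationship; frequency distribution
conditional on a tie (0.45, 0.35, 0.13, 0.07) over rarely…very often, so
most joint work is occasional; intensity distribution (0.50, 0.30, 0.20).

**Determinism.** One master seed; roster, each layer, and report emission
use substreams derived via `numpy.random.SeedSequence.spawn`, so identical
spec + seed yields byte-identical roster and report files and partial stages
can be re-run reproducibly.

**What passing tests do and do not show.** The generator produces
type-homophilous, broker-brokered, sparse ordinal layers with one-sided
noise — the features the confirmation rule and the measures are designed
around. It does not model degree heterogeneity within types, transitivity
beyond what homophily induces, correlated layers, or informant-specific
response styles; recovery results on synthetic data therefore validate the
pipeline's correctness, not the substantive conclusions one would draw from
any real survey.

## Numerical and design choices

- Duplicate directed reports for the same dyad/layer keep the maximum value
  (deterministic, order-insensitive).
- Degenerate inputs fail loudly: measures are undefined below their minimum
  n; binarization threshold 0 is rejected (it would create a complete
  graph); unknown categories, duplicate roster ids and self-reports are
  validation errors naming the offender.
- DL dialect: full matrix, `dl n=<n>`, `format = fullmatrix`, `labels
  embedded`; `read_dl(write_dl(x))` reproduces values and labels exactly.
  Node labels may not contain whitespace.
- Plot styling: three country-count shape bins (0–2, 3–5, 6–8); node size
  affine in betweenness with a floor so isolates stay visible; isolates
  parked on a bottom margin rather than left to the force layout; layout is
  `spring_layout` with a fixed seed, so coordinates are reproducible.
- Reported percentages round to one decimal; all internal arithmetic is
  double precision.
- Problem sizes in tests and the acceptance script follow the default
  50-organization conditions; brute-force oracle checks use graphs up to 12
  nodes, where exhaustive geodesic enumeration is exact and fast.

## Known limitations

- Minimum confirmation only; no maximum/mean variants and no imputation of
  unconfirmable dyads.
- Valued (non-binarized) measure variants are not provided; the binarization
  threshold is the supported knob.
- No eigenvector/closeness centrality, community detection, or tie-level
  inference (ERGM/QAP).
- The generator is not fitted to any empirical network; its defaults encode
  magnitudes, not estimates.
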