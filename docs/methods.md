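# Methods

## The knowledge base

All analyses run over a `KnowledgeBase`: diseases, gene/protein nodes,
disease–gene associations and typed gene–gene interactions, with referential
integrity enforced at load time. Identifiers are case-sensitive opaque
strings; no synonym resolution is attempted. Self-links are rejected on load
(with a warning), duplicate disease–gene associations keep the first record.
Several interaction records may connect the same pair with different link
types, which is why two connectivity statistics exist side by side:
**connected pairs** (distinct linked pairs; the default) and **link records**
(multi-typed edges counted per type). A node's **degree** counts distinct
interaction partners by default; counting link records instead is available
via `degree_mode="records"`.

Mixed gene/protein networks can be collapsed to protein level
(`collapse_to_protein_network`): links incident to a gene node are
re-attached to the protein it codes for, gene nodes removed, reassignment
self-links dropped and (pair, type) duplicates deduplicated. The operation
is idempotent; gene nodes with no protein counterpart are dropped with a
warning.

## Relation indices and the disease-pair null

For gene sets $A, B$ of two diseases: $I = |A \cap B|$,
$J = |A\cap B|/|A\cup B|$, $M = |A\cap B|/\min(|A|,|B|)$, so
$0 \le J \le M \le 1$ whenever both sets are non-empty. Degenerate empty-set
cases return a *missing* value rather than 0, so the null machinery can
exclude them instead of silently deflating the distribution. An optional
curation include/exclude gene list (default: no-op) is applied to both sets
before any index is computed.

Significance comes from an empirical null over random disease pairs:
uniform draws of unordered pairs of distinct *eligible* diseases (at least
one associated gene; ineligible diseases are discarded). The default
replicate count is 10,000 pairs; tests and the acceptance script use 2,000,
which already resolves p-values to 5·10⁻⁴. The p-value is the proportion of
null replicates with the *same or larger* value, so ties count as extreme
and p may be exactly 0; an add-one variant $(k+1)/(n+1)$ is available behind
`tie_convention="add-one"` for users who prefer never-zero estimates, but
the plain proportion is the default.

## Degree-matched connectivity null

The comorbid gene set of a disease combination is the intersection of the
diseases' gene sets; its observed statistic is the connectivity of its
induced subnetwork. The null resamples *vertices, not edges*: for each
analysed vertex $i$, the candidate set $Q_i$ holds every knowledge-base gene
with exactly the same degree; one gene is drawn per vertex, without
replacement within a replicate (a network cannot contain a gene twice), and
links between sampled genes are induced from the knowledge base. The
analysed genes themselves are not excluded from their $Q_i$.

Two implementation notes:

* In exact-degree mode $Q_i$ depends only on the vertex's degree, so any two
  candidate sets are either identical or disjoint. Sequential sampling
  without replacement is therefore *exactly* uniform over all assignments of
  distinct genes to vertices — verified in the tests against exhaustive
  enumeration of all valid assignments on a 12-gene knowledge base.
* If an exact-degree set were empty (possible only under non-default degree
  modes, since each template gene matches its own degree), the nearest
  available degree is used, ties resolved toward the smaller degree, and the
  vertex recorded as a fallback in the sampler and the run manifest.

Feasibility (enough distinct candidates per degree class) is checked up
front; the default replicate count is 1,000 networks (tests use 200–500).

## Enrichment and the connectivity rate

Term overrepresentation uses the exact hypergeometric upper tail
$P(X \ge k)$ with the whole annotation as the reference universe, followed
by Benjamini–Hochberg step-up FDR over all tested terms (terms with no study
gene are excluded; study genes outside the universe are dropped with a
warning). Note that BH is not an idempotent operator — re-adjusting
q-values can only inflate them — so the suite asserts determinism,
step-up monotonicity, $q \ge p$ and one-sided inflation instead.

Annotations load from GAF 2.1 or a plain `term_id<TAB>gene_id` TSV.
True-path ancestry propagation (following `is_a`/`part_of`) is applied only
when an OBO file is supplied; without one the map is used as-is, which suits
pre-propagated inputs.

The **connectivity rate** of a term is the fraction of its study genes'
unordered pairs directly linked in the analysed network (a multi-typed pair
counts once), missing for groups smaller than two. Ranking is by descending
CR, ties broken by ascending q-value then term id, missing-CR records last —
the tie-break is a deterministic convention chosen for reproducible reports.

## Pathway patterns

Patterns are ordered slot lists: disease slots (fixed id or a choice set) at
both ends, gene slots labelled by a partition in the interior. The partition
derives from the configured diseases: genes associated with *all* of them
are `comorbid`; genes associated with disease $D$ but not comorbid are
`specific:D`; everything else is unlabelled. Matching is a depth-first
enumeration with label and connectivity checks at each step —
disease–gene steps require an association record, gene–gene steps an
interaction record (any link type unless a filter is given) — with interior
genes pairwise distinct and output sorted lexicographically by node
sequence, so the match set is complete and deterministic. A slot label is
satisfied by a labelled gene node or by its protein node (and vice versa),
but connection checks always use the concrete node's own records. Matches
merge into a deduplicated union network whose node/link counts are invariant
to match order.

## The synthetic generator

The generator emulates what the analysis assumes of a literature-derived
knowledge base, with defaults chosen as the package's study conditions:

| parameter | default | rationale |
|---|---|---|
| diseases / genes | 60 / 1,500 | large enough for stable nulls, small enough for seconds-scale runs |
| association set sizes | log-normal, mean log 3.0, sd 0.8 | heavy tail: median ~20 genes, a few diseases with hundreds — mirroring real disease–gene catalogues; a uniform alternative exists to check the pipeline is family-agnostic |
| interaction graph | configuration model, power-law exponent 2.5, degrees 1…√n | scale-free-like molecular networks; parallel edges and self-loops erased |
| link types | categorical over the 12-type vocabulary, association most frequent | loosely follows the type inventory of curated interaction networks |
| planted pairs | 3 pairs sharing 25 genes each, ρ = 0.3 | detectable but not trivial comorbidity signal |
| comorbid pool | 30 genes | pairs sharing a focal disease draw from one pool, so the all-disease intersection is non-trivial (≈17 genes expected with three draws of 25 from 30) |

Planted shared genes are assigned to both diseases of a pair before the
remaining set members are filled uniformly, so the realized shared count is
at least `n_shared`. Interconnectivity ρ is realized by **rewiring**: each
candidate planted gene pair is decided once (probability ρ, even when it
appears in several pairs' shared sets), missing links are added, and an
equal number of background edges not incident to planted genes is removed —
preserving the total edge count so degree-matched nulls stay honest.
Planted annotation terms draw a stated fraction of their genes from the
realized comorbid core and the rest uniformly.

What the generator does *not* emulate: gene/protein duality (it emits
gene-class nodes only; the protein collapse is exercised by hand-built
fixtures), evidence weighting, correlated annotations between terms, and
literature-bias artefacts such as hub diseases sharing study attention.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated generative assumptions, not robustness to every
bias of real literature-mined data.

## Determinism and problem sizes

Every stochastic component takes an explicit seed (numpy `default_rng`);
the pipeline derives per-stage seeds from the config seed, and two runs of
the same config produce byte-identical bundles (all writers sort their rows;
the manifest contains no timestamps). The test and acceptance workloads use
2,000 disease-pair replicates, 300-network connectivity nulls and 20
generator seeds for planted-signal recovery — sizes chosen so the whole
suite completes in seconds while leaving Monte-Carlo error well below the
decision thresholds (a 2,000-replicate null resolves p = 0.05 with binomial
sd ≈ 0.005).

## Known limitations

* Empirical p-values are bounded below by 1/n; claims like "p < 0.001"
  require correspondingly large replicate counts.
* The degree-matched null conditions on degree only; it does not preserve
  clustering or community structure, so gene sets embedded in dense modules
  can appear significant for module-level rather than set-specific reasons.
* Exact-zero p-values under the default tie convention overstate evidence;
  use the add-one convention when p-values feed downstream calibrated
  procedures.
* The pathway search is exhaustive and its worst case grows with the
  product of partition-class sizes; patterns longer than the canonical five
  slots on dense knowledge bases may need link-type filters.
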