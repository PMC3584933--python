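# Methods

## The prediction problem

Given a target protein sequence for which homology searches have
already been run, predict Gene Ontology (GO) terms with confidence
scores in (0, 1]. Inputs are hit tables rather than raw sequences: a
PSI-BLAST tabular file of profile-sequence hits against an annotated
protein database, an HHSearch table of profile-profile domain-family
detections, per-species domain-assignment tables from which domain
co-occurrence networks (DCNs) are built, and entity→GO annotation
tables for proteins and for domain families. Running the search tools
themselves is out of scope; the package consumes their outputs.

## The three-level cascade

The architecture orders three evidence sources by expected reliability
and assigns each a disjoint confidence interval, so that within a
combined list stronger evidence always outranks weaker.

**Level 1 — profile-sequence transfer.** Hits with e ≤ 0.01 are ranked
by e-value and the GO terms of the single best hit are transferred with

    S₁(e) = 0.6 + 0.4 · (−log₁₀ e) / 200,  capped at 1.0, floored at 0.6.

e = 0 (including e-values that underflow double precision) maps to
exactly 1.0; the cap otherwise engages at e ≤ 1e-200. "lg" is read as
log₁₀ — the only reading under which the 200 divisor and the 0.01
cutoff produce a sensible [0.6, 1.0] band — with log base configurable.
Ties at the minimum e-value are merged (all tied subjects contribute at
the same score), since "the top one hit" is undefined under ties and
merging is input-order invariant.

**Level 2 — profile-profile transfer.** Domain families detected at
probability p ≥ 80 (percent) contribute their family-level GO
annotations with

    S₂(p) = 0.3 + 0.3 · p / 100  ∈ [0.3, 0.6],

hence [0.54, 0.6] after the p ≥ 80 filter. A term contributed by
several families keeps the maximum score: predictions are per-term, and
the maximum preserves the strongest evidence.

**Level 3 — DCN neighbor-counting.** A species' DCN has one node per
domain family observed in its proteome and an (unweighted) edge between
families co-occurring in at least one protein; the observed
co-occurrence count is kept as edge metadata but never scored. The
target's detected families (any probability — by the time level 3
runs, the p ≥ 80 filter has already failed) are placed as centers on
the DCN of the species holding the best species-tagged PSI-BLAST hit
(ties by lexicographic species id). GO terms are collected from the
radius-1 neighbors; a term annotated on k of the neighbor families,
out of T total (family, term) annotation pairs across all neighbor
families, scores

    S₃ = 0.3 · k / T,

so the scores over distinct terms always sum to exactly 0.3. The
counting unit is the neighbor family: duplicate annotation rows for one
family count once, and removing an unannotated neighbor only
renormalises. If the radius-1 ring carries no annotation at all, the
ring at distance exactly 2 is counted instead (radius-1 families are
deliberately not re-entered into the fallback denominator — they were
unannotated, so they could only have diluted nothing, but the choice is
recorded here because either reading is defensible). Centers are
excluded from their own neighbor sets: function is transferred *from
neighbors* precisely because the centers themselves are unannotated.
Detected families absent from the chosen species' network are dropped
with a logged warning.

## The three predictors

**Predictor 1** is the cascade above: union of level-1 and level-2
output; if both are empty the target is a *hard case* and two fallbacks
run: (a) default-threshold (e ≤ 10) PSI-BLAST hits scored by the
level-1 formula *without* its 0.6 floor (clipped to (0, 1]), so weak
homologs rank below genuine level-1 transfers, and (b) level-3
neighbor-counting. The floorless fallback scoring is this package's
choice — the source architecture assigns no score to default-threshold
hits — selected so the hard-case output remains ordered by evidence
strength.

**Predictor 2** pools occurrence counts instead of cascading: each GO
term accumulates weight 4 per accepted (e ≤ 0.01) PSI-BLAST hit whose
subject carries it, weight 2 per confident (p ≥ 80) domain family
carrying it, and weight 1 per annotated radius-1 DCN neighbor carrying
it (no radius-2 here). The weighted frequency is normalised by its
maximum, keeping the top term at exactly 1.0 and all scores in (0, 1].
Normalising by the maximum (rather than the sum) is a design choice:
it matches CAFA score semantics, where a confidently supported term
should score near 1 regardless of how many other terms were proposed.
Counting is per hit, not per distinct subject, mirroring predictor 3's
"among all hits" convention. When no source fires, plain frequency over
default-threshold hits is used.

**Predictor 3** is the baseline within the family: the confidence of a
term is the fraction of annotated default-threshold PSI-BLAST hits
whose subject carries it.

All predictors finish identically: duplicate terms merged keeping the
maximum confidence, sorted by confidence descending with ties broken by
GO id ascending (full determinism), truncated to 100 predictions per
target (configurable; the deterministic tie order makes within-group
truncation reproducible), confidences clipped to (0, 1]. Output is the
CAFA 3-column format, confidence printed to two decimals with a 0.01
printed minimum. No predictor uses randomness anywhere.

## Ontology handling

The GO DAG is restricted to `is_a` edges by default; `part_of` can be
added through the loader's relation set. The three namespaces are kept
separate with no artificial super-root, so propagation and similarity
never cross namespaces (a cross-namespace similarity query returns 0
with a warning — CAFA evaluates namespaces separately, and the toy
worlds use a single namespace throughout). Obsolete terms are dropped
at load time and `alt_id`s resolve to their primary term.

**Depth** is the number of nodes (both endpoints included) on a path
from a term to its namespace root, so the root has depth 1. On
multi-path DAGs the shortest path is the default convention and the
longest is available; published average-depth figures do not
disambiguate the two, so neither is asserted as canonical and the
choice is an explicit parameter everywhere depth is consumed.

**Path-overlap similarity.** A term's "path to the root" is realised
as its full ancestor closure r (the union of all root paths, term
included) — real GO terms typically have many root paths and the
closure is the natural single object. Then

    Sim(g₁, g₂) = |r₁ ∩ r₂| / max(|r₁|, |r₂|),

symmetric, in (0, 1] within a namespace (the shared root keeps it
positive), and exactly 1 iff the closures coincide.

## Evaluation

Predicted and true term sets are propagated to the root before
comparison; precision is the propagated overlap over the propagated
prediction, recall the same overlap over the propagated truth. Curve
points average per-target precision and recall over all evaluated
targets; targets whose selection is empty contribute (0, 0) rather
than being skipped (this keeps the denominator fixed at the full target
count; a flag switches to skipping). Targets with an empty truth set
are excluded with a warning.

Top-n selection (n = 1..20) groups predictions by identical confidence
and takes the n best groups whole, so ties never straddle the cut and
the selected count can exceed n. Fractional average ranks (ties share
the mean of their positions; the ranks of scores 0.9, 0.8, 0.8 are
1, 2.5, 2.5) are computed for reporting, but selection itself is purely
group-based. The threshold sweep uses t = 0, 0.01, …, 1.00 with
selection at confidence ≥ t (inclusive, so the t = 1 endpoint retains
confidence-1.0 predictions; a strict mode exists). The break-even point
is the grid point minimising |P − R|, ties to the larger t, with no
interpolation — except that points where P = R = 0 exactly (thresholds
above every confidence) are ignored unless the whole curve is zero:
the literal rule would otherwise always return the vacuous t = 1 point,
which is plainly not what a break-even between precision and recall
means.

Similarity curves reuse the top-k group selection: each selected
predicted term scores its best path-overlap similarity against any true
term (raw predicted terms, not propagated ones — the similarity already
walks to the root, and propagating first would double-count ancestors);
the *average* curve means per-term scores within a target then over
targets, the *best* curve averages the per-target maximum.

## Synthetic worlds

The fixture generator builds the complete input bundle — toy DAG,
multi-species proteomes, annotations, hit tables, truth — with targets
planted in three strata that exercise the cascade's three regimes:
easy targets carry a strong sequence hit (e-value log-uniform in
1e-100..1e-20) whose subject is annotated with all true terms plus 0–2
unrelated ones (so transfer is complete but not perfectly precise);
mid targets carry only confident domain detections (p uniform in
85..100) on annotated families whose annotations are the truth; hard
targets carry only sub-threshold evidence (e in 0.1..10, p in 30..75),
with the detected family deliberately unannotated and wired — via a
dedicated proteome protein — next to two annotated families whose
annotations are the truth, in exactly one species' network. A
species-tagged weak hit to an unannotated subject steers species
selection without contributing homology predictions. Defaults: 3
species of 40 proteins, 24 domain families (70 % annotated), 60-term
DAG, 12 targets split 6/3/3 easy/mid/hard; sizes chosen so every
stratum is populated and the whole pipeline runs in well under a second.

All randomness flows from one integer seed through a single
`numpy.random.Generator`; a seed reproduces the world and its on-disk
serialisation byte for byte. The worlds make no attempt at realistic
sequence content, GO topology, annotation sparsity or proteome scale —
passing tests on them demonstrates that the formulas, thresholds,
fallbacks and bookkeeping behave as specified, not that the method's
published accuracy on real CAFA targets is reproduced (that would
require the original target set and 2010-era databases).

## Numerical and degenerate-input choices

E-values below `sys.float_info.min` are treated as 0 (score 1.0).
Confidence comparisons in tie-grouping use exact float equality — all
predictors derive tied scores from identical arithmetic, so ties are
exact by construction. Empty hit tables, unannotated top hits and
edgeless networks all yield empty entries (logged), never errors;
empty truth sets and unknown GO terms are errors by default, with
skip-with-warning modes. GO-id-ascending tie-breaks appear at every
ordering point so that byte-identical outputs follow from identical
inputs.

## Known limitations

Information-content similarity measures (Resnik/Lin), CAFA's later
Fmax/Smin metrics, bootstrap intervals, evidence-code filtering of
truth, and propagation-aware rescoring before output are out of scope.
The hhr parser reads only the summary table, not alignments. Published
headline curves for the original 436-target CAFA set are not
reproducible from this package alone, by design.
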