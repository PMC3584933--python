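# funclevels

Three-level protein function prediction with CAFA-style evaluation.

Predicting Gene Ontology (GO) terms for an unannotated protein gets
harder as homology fades: close homologs can be found by
profile-sequence search (PSI-BLAST), remote domain relationships by
profile-profile search (HHSearch), and when both fail, a protein's
detected domain families still sit inside a species' **domain
co-occurrence network (DCN)** whose annotated neighbor families can
lend their functions. `funclevels` implements this cascade and the
evaluation machinery around it, operating on search-**hit tables**
(BLAST tabular, hhr/TSV domain detections, domain-assignment TSVs) so
the whole system runs on synthetic fixtures without any database
downloads.

## The method

Level 1 transfers the GO terms of the best PSI-BLAST hit (e ≤ 0.01) at

    S₁ = 0.6 + 0.4 · (−log₁₀ e)/200   ∈ [0.6, 1.0]   (e = 0 → 1.0)

Level 2 transfers annotations of domain families detected at
probability p ≥ 80:

    S₂ = 0.3 + 0.3 · p/100            ∈ [0.3, 0.6]

Level 3 (hard cases: levels 1–2 empty) counts GO terms over the
radius-1 (falling back to radius-2) DCN neighbors of the detected
families, in the network of the most similar species:

    S₃ = 0.3 · f,   f = occurrence frequency, Σf = 1   ⇒ S₃ ∈ (0, 0.3]

Three predictors package these tiers: **predictor 1** cascades them
into the disjoint intervals above; **predictor 2** pools GO-term
occurrences from all three sources with weights 4/2/1 and normalises by
the maximum weighted frequency; **predictor 3** scores terms by their
frequency among all default-threshold (e ≤ 10) PSI-BLAST hits.

Evaluation propagates predicted and true terms to the ontology root,
then averages per-target precision/recall over targets — by top-n tie
groups (n = 1..20, tied confidences share an average rank and enter
whole) or by a sliding confidence threshold (t = 0..1, step 0.01) with
a break-even summary — plus path-overlap semantic-similarity curves,
Sim(g₁,g₂) = |r₁∩r₂| / max(|r₁|,|r₂|) over root-path closures r.

## Worked example

Generate a 12-target synthetic world (6 easy / 3 mid / 3 hard targets),
predict with the cascade, and evaluate:

```sh
funclevels fixtures --seed 7 --out demo/world
funclevels predict --predictor 1 \
    --obo demo/world/go.obo \
    --protein-go demo/world/protein_go.tsv \
    --domain-go demo/world/domain_go.tsv \
    --psiblast demo/world/psiblast.tsv \
    --hhsearch demo/world/hhsearch.tsv \
    --fallback demo/world/fallback.tsv \
    --assignments demo/world/assignments.tsv \
    --out demo/preds.tsv
funclevels evaluate --obo demo/world/go.obo \
    --predictions demo/preds.tsv --truth demo/world/truth.tsv \
    --mode threshold --out demo/curve.tsv
```

prints

```
wrote world with 12 targets to demo/world
wrote 36 predictions for 12 targets to demo/preds.tsv
{"break_even_threshold": 0.79, "precision": 0.083, "recall": 0.083, "average": 0.083}
wrote threshold curve to demo/curve.tsv
```

`demo/preds.tsv` holds CAFA 3-column lines — target, GO id, confidence
to two decimals — e.g. `T00001  GO:0000009  0.77`: a level-1 transfer
(confidence in [0.6, 1.0] marks profile-sequence evidence; [0.54, 0.6]
would be a domain detection and (0, 0.3] a DCN inference). The
break-even line reports the threshold grid point where averaged
precision and recall meet; on this small noisy world both equal 0.083
at t = 0.79 (at t = 0 the curve starts at precision 0.937, recall 1.0 —
see `demo/curve.tsv`). The same API is available in Python:

```python
import funclevels as fl

world = fl.make_world(seed=7)
preds = fl.predictor1("T00001",
                      world.psiblast_hits["T00001"],
                      world.hhsearch_hits["T00001"],
                      world.fallback_hits["T00001"],
                      world.protein_annotations,
                      world.domain_annotations,
                      world.networks)
```

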