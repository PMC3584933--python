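"""The three predictors and CAFA-format output.

* **Predictor 1** maps the three tiers into disjoint confidence
  intervals: profile-sequence transfers in [0.6, 1.0], profile-profile
  in [0.54, 0.6] (given the p ≥ 80 filter), DCN neighbor-counting in
  (0, 0.3]. A target that gets nothing from the first two tiers is a
  *hard case*: it falls back to default-threshold (e ≤ 10) PSI-BLAST
  hits scored by the level-1 formula without its 0.6 floor, plus
  neighbor-counting on the DCN of the most similar species using all
  detected domains (any probability) as centers.

* **Predictor 2** pools GO-term occurrences from all accepted
  PSI-BLAST hits (e ≤ 0.01), all confident HHSearch domains (p ≥ 80)
  and radius-1 neighbor-counting, weighted 4 / 2 / 1 respectively; the
  weighted frequency is normalised by its maximum so the top term
  scores exactly 1.

* **Predictor 3** ranks GO terms by their occurrence frequency among
  all default-threshold PSI-BLAST hits.

Every predictor finishes with :func:`finalize`: duplicate terms merged
keeping the maximum confidence, sorted by confidence (ties by GO id),
truncated to ``max_predictions`` (default 100), confidences clipped to
(0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from .core import MIN_CONFIDENCE, AnnotationMap, HomologyHit, Prediction
from .dcn import (
    DomainNetwork,
    neighbor_counting_predict,
    neighbor_set,
    select_species,
)
from .homology import (
    DEFAULT_E_CUTOFF,
    E_CUTOFF,
    P_CUTOFF,
    level1_predict,
    level2_predict,
    score_psiblast,
)

__all__ = [
    "PredictionSet",
    "predictor1",
    "predictor2",
    "predictor3",
    "finalize",
    "write_cafa",
    "read_cafa",
]

logger = logging.getLogger(__name__)

MAX_PREDICTIONS = 100
WEIGHTS = {"psiblast": 4, "hhsearch": 2, "dcn": 1}


@dataclass
class PredictionSet:
    """Finalized predictions per target, sorted by descending confidence."""

    entries: dict[str, list[Prediction]] = field(default_factory=dict)

    def add(self, target: str, predictions: list[Prediction]) -> None:
        self.entries[target] = predictions

    def targets(self) -> list[str]:
        return sorted(self.entries)

    def __getitem__(self, target: str) -> list[Prediction]:
        return self.entries[target]

    def __len__(self) -> int:
        return len(self.entries)


def finalize(
    entry: Iterable[Prediction], max_predictions: int = MAX_PREDICTIONS
) -> list[Prediction]:
    """Merge, sort, truncate and clip a raw prediction list.

    Duplicate GO terms keep the maximum confidence; ordering is by
    confidence descending then GO id ascending (which also makes the
    truncation at ``max_predictions`` deterministic within tie groups);
    confidences above 1 are clipped to 1 and non-positive ones dropped.
    """
    best: dict[str, Prediction] = {}
    for p in entry:
        conf = min(1.0, p.confidence)
        if conf <= 0:
            continue
        prev = best.get(p.go_term)
        if prev is None or conf > prev.confidence:
            best[p.go_term] = Prediction(p.target, p.go_term, conf, p.level)
    ordered = sorted(best.values(), key=lambda p: (-p.confidence, p.go_term))
    return ordered[:max_predictions]


def _hard_case_fallback(
    target: str,
    fallback_hits: Iterable[HomologyHit],
    annotations: AnnotationMap,
    domain_annotations: AnnotationMap,
    detected_domains: set[str],
    networks: Mapping[str, DomainNetwork],
    species_hits: Iterable[HomologyHit],
    default_e: float,
) -> list[Prediction]:
    preds: list[Prediction] = []
    # (a) default-threshold homologs, scored below the genuine level-1 band
    for h in fallback_hits:
        if h.source != "psiblast" or h.evalue > default_e:
            continue
        conf = score_psiblast(h.evalue, floor=None)
        for g in annotations.get(h.subject, set()):
            preds.append(Prediction(target, g, conf, level=1))
    # (b) neighbor-counting on the DCN of the most similar species
    try:
        species = select_species(species_hits)
    except ValueError:
        species = None
    if species is not None and species in networks:
        network = networks[species]
        centers = detected_domains & network.nodes
        dropped = detected_domains - network.nodes
        if dropped:
            logger.warning(
                "%s: detected domains absent from %s DCN dropped: %s",
                target, species, sorted(dropped),
            )
        if centers:
            preds.extend(
                neighbor_counting_predict(
                    network, centers, domain_annotations, target=target
                )
            )
    return preds


def predictor1(
    target: str,
    psiblast_hits: Iterable[HomologyHit],
    hhsearch_hits: Iterable[HomologyHit],
    fallback_hits: Iterable[HomologyHit],
    annotations: AnnotationMap,
    domain_annotations: AnnotationMap,
    networks: Mapping[str, DomainNetwork],
    species_hits: Iterable[HomologyHit] | None = None,
    *,
    e_cutoff: float = E_CUTOFF,
    p_cutoff: float = P_CUTOFF,
    default_e: float = DEFAULT_E_CUTOFF,
    max_predictions: int = MAX_PREDICTIONS,
) -> list[Prediction]:
    """Three-level interval predictor for one target.

    Level-1 and level-2 predictions are combined; when both are empty
    the target is a hard case and the fallback machinery (weak homologs
    plus DCN neighbor-counting seeded by all detected domains) runs.
    """
    psiblast_hits = list(psiblast_hits)
    hhsearch_hits = list(hhsearch_hits)
    fallback_hits = list(fallback_hits)
    l1 = level1_predict(psiblast_hits, annotations, e_cutoff)
    l2, _ = level2_predict(hhsearch_hits, domain_annotations, p_cutoff)
    preds = [Prediction(target, p.go_term, p.confidence, p.level) for p in l1 + l2]
    if not preds:
        logger.info("%s: hard case (levels 1-2 empty)", target)
        detected_any = {h.subject for h in hhsearch_hits if h.source == "hhsearch"}
        preds = _hard_case_fallback(
            target,
            fallback_hits,
            annotations,
            domain_annotations,
            detected_any,
            networks,
            list(species_hits) if species_hits is not None else fallback_hits,
            default_e,
        )
    if not preds:
        logger.info("%s: no predictions at any level", target)
    return finalize(preds, max_predictions)


def predictor2(
    target: str,
    psiblast_hits: Iterable[HomologyHit],
    hhsearch_hits: Iterable[HomologyHit],
    fallback_hits: Iterable[HomologyHit],
    annotations: AnnotationMap,
    domain_annotations: AnnotationMap,
    networks: Mapping[str, DomainNetwork],
    species_hits: Iterable[HomologyHit] | None = None,
    *,
    e_cutoff: float = E_CUTOFF,
    p_cutoff: float = P_CUTOFF,
    default_e: float = DEFAULT_E_CUTOFF,
    weights: Mapping[str, int] = WEIGHTS,
    max_predictions: int = MAX_PREDICTIONS,
) -> list[Prediction]:
    """Weighted-frequency predictor for one target.

    Occurrence counts per GO term: one per accepted PSI-BLAST hit whose
    subject carries the term, one per confident HHSearch domain carrying
    it, one per annotated radius-1 DCN neighbor carrying it — weighted
    4/2/1 and normalised by the maximum weighted frequency. Falls back
    to plain frequency over default-threshold hits when no source fires.
    """
    psiblast_hits = list(psiblast_hits)
    hhsearch_hits = list(hhsearch_hits)
    fallback_hits = list(fallback_hits)

    w: dict[str, float] = {}
    for h in psiblast_hits:
        if h.source == "psiblast" and h.evalue <= e_cutoff:
            for g in annotations.get(h.subject, set()):
                w[g] = w.get(g, 0.0) + weights["psiblast"]
    confident = {h.subject for h in hhsearch_hits
                 if h.source == "hhsearch" and h.probability >= p_cutoff}
    for d in confident:
        for g in domain_annotations.get(d, set()):
            w[g] = w.get(g, 0.0) + weights["hhsearch"]
    # radius-1 neighbor counting (no radius-2 in this predictor)
    try:
        species = select_species(
            list(species_hits) if species_hits is not None
            else psiblast_hits + fallback_hits
        )
    except ValueError:
        species = None
    if species is not None and species in networks and confident:
        network = networks[species]
        centers = confident & network.nodes
        if centers:
            ring = neighbor_set(network, centers, radius=1)
            for d in ring:
                for g in domain_annotations.get(d, set()):
                    w[g] = w.get(g, 0.0) + weights["dcn"]
    if w:
        top = max(w.values())
        preds = [
            Prediction(target, g, weight / top, level=0)
            for g, weight in sorted(w.items())
        ]
        return finalize(preds, max_predictions)
    # all three sources empty: plain frequency over default-threshold hits
    return predictor3(target, fallback_hits, annotations,
                      default_e=default_e, max_predictions=max_predictions)


def predictor3(
    target: str,
    psiblast_hits_default: Iterable[HomologyHit],
    annotations: AnnotationMap,
    *,
    default_e: float = DEFAULT_E_CUTOFF,
    max_predictions: int = MAX_PREDICTIONS,
) -> list[Prediction]:
    """Plain-frequency predictor over default-threshold PSI-BLAST hits.

    A GO term's confidence is the fraction of annotated hits whose
    subject carries it; a term on every annotated hit scores 1.
    """
    hits = [h for h in psiblast_hits_default
            if h.source == "psiblast" and h.evalue <= default_e]
    annotated = [h for h in hits if annotations.get(h.subject)]
    if not annotated:
        return []
    counts: dict[str, int] = {}
    for h in annotated:
        for g in annotations[h.subject]:
            counts[g] = counts.get(g, 0) + 1
    n = len(annotated)
    preds = [
        Prediction(target, g, c / n, level=0) for g, c in sorted(counts.items())
    ]
    return finalize(preds, max_predictions)


def predict_dataset(
    predictor: int,
    psiblast_hits: Iterable[HomologyHit],
    hhsearch_hits: Iterable[HomologyHit],
    fallback_hits: Iterable[HomologyHit],
    annotations: AnnotationMap,
    domain_annotations: AnnotationMap,
    networks: Mapping[str, DomainNetwork] | None = None,
    targets: Iterable[str] | None = None,
    **kwargs,
) -> PredictionSet:
    """Run one predictor over a whole multi-target hit collection.

    Hits are grouped by query id; ``targets`` defaults to every query
    seen in any table. Keyword arguments are forwarded to the chosen
    predictor function.
    """
    if predictor not in (1, 2, 3):
        raise ValueError(f"predictor must be 1, 2 or 3, got {predictor}")
    networks = networks or {}
    by_query: dict[str, dict[str, list[HomologyHit]]] = {}

    def bucket(hits: Iterable[HomologyHit], key: str) -> None:
        for h in hits:
            by_query.setdefault(h.query, {"psi": [], "hh": [], "fb": []})[key].append(h)

    bucket(psiblast_hits, "psi")
    bucket(hhsearch_hits, "hh")
    bucket(fallback_hits, "fb")
    if targets is None:
        targets = sorted(by_query)
    ps = PredictionSet()
    for targ in targets:
        h = by_query.get(targ, {"psi": [], "hh": [], "fb": []})
        if predictor == 1:
            entry = predictor1(targ, h["psi"], h["hh"], h["fb"],
                               annotations, domain_annotations, networks, **kwargs)
        elif predictor == 2:
            entry = predictor2(targ, h["psi"], h["hh"], h["fb"],
                               annotations, domain_annotations, networks, **kwargs)
        else:
            entry = predictor3(targ, h["fb"] or h["psi"], annotations, **kwargs)
        ps.add(targ, entry)
    return ps


def write_cafa(predictions: PredictionSet, stream: IO[str]) -> None:
    """Write a CAFA-style 3-column prediction file.

    One line per prediction, ``target<TAB>GO:nnnnnnn<TAB>confidence``
    with the confidence printed to 2 decimals and floored at 0.01;
    targets sorted, then confidence descending, then GO id. Entries
    with duplicate GO terms (not finalized) are rejected.
    """
    for targ in predictions.targets():
        entry = predictions[targ]
        seen = [p.go_term for p in entry]
        if len(seen) != len(set(seen)):
            raise ValueError(f"unfinalized entry for {targ}: duplicate GO terms")
        for p in sorted(entry, key=lambda p: (-p.confidence, p.go_term)):
            conf = max(p.confidence, MIN_CONFIDENCE)
            stream.write(f"{targ}\t{p.go_term}\t{conf:.2f}\n")


def read_cafa(stream: IO[str] | Iterable[str]) -> PredictionSet:
    """Read a 3-column CAFA prediction file back into a PredictionSet."""
    ps = PredictionSet()
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"line {lineno}: expected 3 columns")
        targ, go, conf = fields[0], fields[1], float(fields[2])
        ps.entries.setdefault(targ, []).append(
            Prediction(targ, go, conf, level=0)
        )
    for targ in ps.entries:
        ps.entries[targ].sort(key=lambda p: (-p.confidence, p.go_term))
    return ps
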