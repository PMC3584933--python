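"""Homology-based prediction: profile-sequence and profile-profile tiers.

Level 1 consumes PSI-BLAST tabular hits against an annotated sequence
database (Swiss-Prot style): hits at e ≤ 0.01 are ranked by e-value and
the GO terms of the single best hit are transferred, scored

    S_psiblast(e) = 0.6 + 0.4 * (-log10 e) / 200,   clipped to [0.6, 1.0]

so that any accepted hit scores at least 0.6 and e = 0 scores exactly 1.

Level 2 consumes HHSearch domain detections against Pfam-style family
profiles: families detected at probability p ≥ 80 (percent) contribute
their annotated GO terms, scored

    S_hhsearch(p) = 0.3 + 0.3 * p / 100            in [0.3, 0.6].

The two intervals are disjoint by construction, so within a combined
prediction list every profile-sequence transfer outranks every
profile-profile transfer.
"""

from __future__ import annotations

import math
from typing import IO, Iterable

from .core import (
    MIN_CONFIDENCE,
    TINY_EVALUE,
    AnnotationMap,
    HomologyHit,
    Prediction,
)

__all__ = [
    "parse_blast_tabular",
    "parse_hhsearch_hits",
    "score_psiblast",
    "score_hhsearch",
    "level1_predict",
    "level2_predict",
]

E_CUTOFF = 0.01          # level-1 acceptance threshold
DEFAULT_E_CUTOFF = 10.0  # fallback search threshold (search-tool default)
P_CUTOFF = 80.0          # level-2 acceptance threshold, percent


def _split_subject(subject: str) -> tuple[str | None, str]:
    """Split an optional ``species|accession`` subject prefix."""
    if "|" in subject:
        species, _, accession = subject.partition("|")
        if species and accession:
            return species, accession
    return None, subject


def parse_blast_tabular(stream: IO[str] | Iterable[str]) -> list[HomologyHit]:
    """Parse BLAST/PSI-BLAST 12-column tabular output (outfmt 6 / -m 8).

    Columns: query, subject, identity, length, mismatches, gaps, qstart,
    qend, sstart, send, evalue, bitscore. The subject may carry a
    ``species|accession`` prefix, which populates the hit's species tag.
    Duplicate (query, subject) pairs are collapsed to the best (minimum)
    e-value; otherwise file order is preserved.
    """
    hits: dict[tuple[str, str], HomologyHit] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ValueError(
                f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
            )
        query, raw_subject = fields[0], fields[1]
        try:
            evalue = float(fields[10])
        except ValueError as exc:
            raise ValueError(
                f"line {lineno}: non-numeric e-value {fields[10]!r}"
            ) from exc
        species, subject = _split_subject(raw_subject)
        hit = HomologyHit(
            query=query, subject=subject, source="psiblast",
            evalue=evalue, species=species,
        )
        key = (query, subject)
        if key not in hits or evalue < hits[key].evalue:
            hits[key] = hit
    return list(hits.values())


def parse_hhsearch_hits(stream: IO[str] | Iterable[str]) -> list[HomologyHit]:
    """Parse HHSearch domain detections.

    Accepts either a full ``.hhr`` report (only the summary hit table is
    read: the ``No Hit ... Prob ...`` block; the hit name's first token
    is taken as the domain family) or a simplified 3-column TSV
    ``query<TAB>domain_family<TAB>probability``.
    """
    lines = [ln.rstrip("\n") for ln in stream]
    if any(ln.startswith("Query") for ln in lines[:10]) or any(
        ln.lstrip().startswith("No Hit") for ln in lines
    ):
        return _parse_hhr(lines)
    hits = []
    for lineno, line in enumerate(lines, start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"line {lineno}: expected 3 columns, got {len(fields)}")
        prob = float(fields[2])
        if not 0.0 <= prob <= 100.0:
            raise ValueError(
                f"line {lineno}: probability {prob} outside [0, 100]"
            )
        hits.append(
            HomologyHit(query=fields[0], subject=fields[1],
                        source="hhsearch", probability=prob)
        )
    return hits


def _parse_hhr(lines: list[str]) -> list[HomologyHit]:
    query = ""
    for ln in lines:
        if ln.startswith("Query"):
            query = ln.split(maxsplit=1)[1].split()[0] if len(ln.split()) > 1 else ""
            break
    hits: list[HomologyHit] = []
    header_idx = None
    prob_col = None
    for i, ln in enumerate(lines):
        stripped = ln.lstrip()
        if stripped.startswith("No Hit") and "Prob" in ln:
            header_idx, prob_col = i, ln.index("Prob")
            break
    if header_idx is None:
        raise ValueError("hhr stream has no summary hit table")
    for lineno, ln in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        if not ln.strip():
            break
        tokens = ln.split()
        if not tokens[0].isdigit():
            break
        family = tokens[1]
        numeric = ln[prob_col:].split()
        try:
            prob = float(numeric[0])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"line {lineno}: cannot read Prob column") from exc
        if not 0.0 <= prob <= 100.0:
            raise ValueError(f"line {lineno}: probability {prob} outside [0, 100]")
        hits.append(
            HomologyHit(query=query, subject=family,
                        source="hhsearch", probability=prob)
        )
    return hits


def score_psiblast(evalue: float, *, floor: float | None = 0.6,
                   log_base: float = 10.0) -> float:
    """Confidence of a profile-sequence hit from its e-value.

    ``0.6 + 0.4 * (-log(e)) / 200`` with log base 10, capped at 1.0 and
    floored at ``floor`` (0.6 by default). An e-value of exactly 0 —
    including underflowed values below machine-tiny — maps to 1.0.
    With ``floor=None`` (the hard-case fallback scoring) the raw formula
    is clipped to (0, 1] instead, so weak hits rank below genuine
    level-1 transfers.
    """
    if evalue < 0:
        raise ValueError(f"e-value must be >= 0, got {evalue}")
    if evalue <= TINY_EVALUE:
        return 1.0
    raw = 0.6 + 0.4 * (-math.log(evalue, log_base)) / 200.0
    lower = floor if floor is not None else MIN_CONFIDENCE
    return min(1.0, max(lower, raw))


def score_hhsearch(probability: float) -> float:
    """Confidence of a profile-profile hit: 0.3 + 0.3·p/100, in [0.3, 0.6]."""
    if not 0.0 <= probability <= 100.0:
        raise ValueError(f"probability must be in [0, 100], got {probability}")
    return 0.3 + 0.3 * probability / 100.0


def level1_predict(
    hits: Iterable[HomologyHit],
    annotations: AnnotationMap,
    e_cutoff: float = E_CUTOFF,
) -> list[Prediction]:
    """Profile-sequence transfer: GO terms of the top PSI-BLAST hit.

    Hits are filtered to e ≤ ``e_cutoff``; the hit with the minimum
    e-value wins and its subject's GO terms become predictions at
    ``score_psiblast`` of that e-value. Ties at the minimum e-value are
    merged (all tied subjects contribute, same score). Returns an empty
    list when no hit passes or the winning subject is unannotated.
    """
    accepted = [h for h in hits if h.source == "psiblast" and h.evalue <= e_cutoff]
    if not accepted:
        return []
    best_e = min(h.evalue for h in accepted)
    terms: set[str] = set()
    query = accepted[0].query
    for h in accepted:
        if h.evalue == best_e:
            terms |= annotations.get(h.subject, set())
    conf = score_psiblast(best_e)
    return [
        Prediction(target=query, go_term=g, confidence=conf, level=1)
        for g in sorted(terms)
    ]


def level2_predict(
    hits: Iterable[HomologyHit],
    domain_annotations: AnnotationMap,
    p_cutoff: float = P_CUTOFF,
) -> tuple[list[Prediction], set[str]]:
    """Profile-profile transfer: GO terms of confidently detected domains.

    Domains detected at p ≥ ``p_cutoff`` contribute their Pfam GO
    annotations at ``score_hhsearch`` of their probability; a term
    contributed by several domains keeps the maximum confidence. Also
    returns the set of retained domain families (used downstream as
    network centers).
    """
    retained = [h for h in hits if h.source == "hhsearch" and h.probability >= p_cutoff]
    detected = {h.subject for h in retained}
    best: dict[str, float] = {}
    query = retained[0].query if retained else ""
    for h in retained:
        conf = score_hhsearch(h.probability)
        for g in domain_annotations.get(h.subject, set()):
            if conf > best.get(g, 0.0):
                best[g] = conf
    preds = [
        Prediction(target=query, go_term=g, confidence=c, level=2)
        for g, c in sorted(best.items())
    ]
    return preds, detected
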