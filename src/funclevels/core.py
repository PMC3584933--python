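"""Shared record types and annotation-table readers.

The central currency of the package is the :class:`Prediction` — a
(target, GO term, confidence) triple with a provenance level recording
which tier of the three-level architecture produced it — and the
:class:`HomologyHit`, one row of a homology-search result table.
Annotation maps (protein→GO, domain-family→GO) are plain dictionaries
from entity id to a set of GO term ids.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

#: Smallest confidence ever emitted in CAFA-format output.
MIN_CONFIDENCE = 0.01

#: E-values below this are treated as exactly zero (denormal / underflow guard).
TINY_EVALUE = sys.float_info.min

#: entity id -> set of GO term ids
AnnotationMap = dict[str, set[str]]


@dataclass(frozen=True, slots=True)
class Prediction:
    """A single GO-term prediction for one target protein.

    ``level`` records provenance: 1 = profile-sequence (PSI-BLAST),
    2 = profile-profile (HHSearch), 3 = domain co-occurrence network,
    0 = frequency-combination predictors that pool several sources.
    """

    target: str
    go_term: str
    confidence: float
    level: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence <= 1.0:
            raise ValueError(
                f"confidence must be in (0, 1], got {self.confidence!r} "
                f"for {self.target}/{self.go_term}"
            )
        if self.level not in (0, 1, 2, 3):
            raise ValueError(f"level must be 0..3, got {self.level!r}")


@dataclass(frozen=True, slots=True)
class HomologyHit:
    """One homology-search hit.

    Exactly one of ``evalue`` (profile-sequence, source ``psiblast``) or
    ``probability`` (profile-profile, source ``hhsearch``, scale 0–100)
    is populated, matching ``source``.
    """

    query: str
    subject: str
    source: str
    evalue: float | None = None
    probability: float | None = None
    species: str | None = None

    def __post_init__(self) -> None:
        if self.source == "psiblast":
            if self.evalue is None or self.probability is not None:
                raise ValueError("psiblast hit must carry evalue only")
            if self.evalue < 0:
                raise ValueError(f"e-value must be >= 0, got {self.evalue}")
        elif self.source == "hhsearch":
            if self.probability is None or self.evalue is not None:
                raise ValueError("hhsearch hit must carry probability only")
            if not 0.0 <= self.probability <= 100.0:
                raise ValueError(
                    f"probability must be in [0, 100], got {self.probability}"
                )
        else:
            raise ValueError(f"unknown source {self.source!r}")


def read_annotation_map(stream: IO[str] | Iterable[str]) -> AnnotationMap:
    """Read an entity→GO annotation table.

    Accepts either a 2-column TSV ``entity<TAB>GO:nnnnnnn`` or a GAF 2.x
    file (lines starting with ``!`` are headers; columns 2 and 5 carry
    the accession and the GO id). The format is detected per-line, so
    plain TSV with extra columns also works.
    """
    out: AnnotationMap = {}
    for line in stream:
        line = line.rstrip("\n")
        if not line or line.startswith("!") or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) >= 15:  # GAF 2.x record
            entity, go = fields[1], fields[4]
        elif len(fields) >= 2:
            entity, go = fields[0], fields[1]
        else:
            raise ValueError(f"annotation line has fewer than 2 columns: {line!r}")
        out.setdefault(entity, set()).add(go)
    return out


def write_annotation_map(annotations: Mapping[str, set[str]], stream: IO[str]) -> None:
    """Write an annotation map as sorted 2-column TSV."""
    for entity in sorted(annotations):
        for go in sorted(annotations[entity]):
            stream.write(f"{entity}\t{go}\n")
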