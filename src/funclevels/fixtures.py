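"""Synthetic worlds for exercising the full three-level pipeline.

A world bundles a toy GO DAG, multi-species proteomes with domain
assignments (hence domain co-occurrence networks), protein and domain
GO annotations, and per-target homology-search tables with planted
ground truth. Targets come in three strata mirroring the architecture's
regimes:

* **easy** — a strong profile-sequence hit (e-value 1e-100..1e-20)
  whose subject is annotated with all the target's true terms plus a
  few unrelated ones, so level 1 recovers the truth at confidence
  ≥ 0.6 without being perfectly precise;
* **mid** — no significant sequence hit, but confident domain
  detections (p ≥ 85) on annotated families, so only level 2 fires;
* **hard** — neither tier fires (sequence hits only at e 0.1..10,
  domain detections only at p 30..75); the detected domain is
  deliberately unannotated but sits in one species' network next to
  annotated families that carry the true terms, so only DCN
  neighbor-counting can recover them.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; regenerating a world with the same seed and
parameters reproduces it, and its on-disk serialisation, byte for byte.
The generator makes no attempt at realistic sequences or at mimicking
real GO topology — it exists to give the thresholds something to bite
on.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .core import AnnotationMap, HomologyHit, write_annotation_map
from .dcn import (
    DomainAssignmentTable,
    DomainNetwork,
    build_dcn,
    write_assignments_tsv,
)
from .go_dag import GoDag

__all__ = ["WorldSpec", "SyntheticWorld", "make_toy_dag", "make_world"]

NAMESPACE = "biological_process"


def make_toy_dag(
    n_terms: int, branching: int = 2, seed: int = 0, namespace: str = NAMESPACE
) -> GoDag:
    """Random single-namespace DAG, acyclic by construction.

    Term i (ids ``GO:0000001`` ..) attaches to 1..``branching`` distinct
    parents drawn uniformly from the already-created terms, so the first
    term is the unique root and every term reaches it.
    """
    if n_terms < 1:
        raise ValueError(f"n_terms must be >= 1, got {n_terms}")
    if branching < 1:
        raise ValueError(f"branching must be >= 1, got {branching}")
    rng = np.random.default_rng(seed)
    ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    parents: dict[str, frozenset[str]] = {ids[0]: frozenset()}
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(branching, i) + 1))
        chosen = rng.choice(i, size=k, replace=False)
        parents[ids[i]] = frozenset(ids[j] for j in chosen)
    namespace_map = {t: namespace for t in ids}
    names = {t: f"term {t[3:].lstrip('0') or '0'}" for t in ids}
    return GoDag(parents, namespace_map, names=names)


def dag_to_obo(dag: GoDag) -> str:
    """Serialise a GoDag as an OBO 1.2 flat file (is_a edges only)."""
    chunks = ["format-version: 1.2", ""]
    for term in sorted(dag.terms):
        chunks.append("[Term]")
        chunks.append(f"id: {term}")
        chunks.append(f"name: {dag.names.get(term, term)}")
        chunks.append(f"namespace: {dag.namespace[term]}")
        for alt, primary in sorted(dag.alt_ids.items()):
            if primary == term:
                chunks.append(f"alt_id: {alt}")
        for p in sorted(dag.parents[term]):
            chunks.append(f"is_a: {p} ! {dag.names.get(p, p)}")
        chunks.append("")
    return "\n".join(chunks)


@dataclass(frozen=True)
class WorldSpec:
    """Generation parameters of a synthetic world.

    Fractions of easy/mid targets leave the remainder hard. E-value
    exponents are uniform in ``easy_evalue_exp`` (e = 10^-u); weak hits
    draw e uniformly from ``weak_evalue_range`` (all above the 0.01
    acceptance threshold); domain-detection probabilities are percent.
    """

    n_terms: int = 60
    branching: int = 2
    n_species: int = 3
    n_domains: int = 24
    n_proteins_per_species: int = 40
    n_targets: int = 12
    fraction_easy: float = 0.5
    fraction_mid: float = 0.25
    terms_per_entity: tuple[int, int] = (1, 3)
    extra_terms_per_subject: tuple[int, int] = (0, 2)
    domain_annotation_density: float = 0.7
    easy_evalue_exp: tuple[float, float] = (20.0, 100.0)
    weak_evalue_range: tuple[float, float] = (0.1, 10.0)
    strong_probability_range: tuple[float, float] = (85.0, 100.0)
    weak_probability_range: tuple[float, float] = (30.0, 75.0)


@dataclass
class SyntheticWorld:
    """A fully materialised synthetic prediction problem."""

    spec: WorldSpec
    seed: int
    dag: GoDag
    assignments: dict[str, DomainAssignmentTable]
    networks: dict[str, DomainNetwork]
    protein_annotations: AnnotationMap
    domain_annotations: AnnotationMap
    psiblast_hits: dict[str, list[HomologyHit]] = field(default_factory=dict)
    hhsearch_hits: dict[str, list[HomologyHit]] = field(default_factory=dict)
    fallback_hits: dict[str, list[HomologyHit]] = field(default_factory=dict)
    truth: AnnotationMap = field(default_factory=dict)
    strata: dict[str, str] = field(default_factory=dict)

    @property
    def targets(self) -> list[str]:
        return sorted(self.truth)

    def write(self, outdir: str | Path) -> None:
        """Write the world in the external formats of the consuming modules."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "go.obo").write_text(dag_to_obo(self.dag))
        with open(out / "protein_go.tsv", "w") as fh:
            write_annotation_map(self.protein_annotations, fh)
        with open(out / "domain_go.tsv", "w") as fh:
            write_annotation_map(self.domain_annotations, fh)
        with open(out / "assignments.tsv", "w") as fh:
            write_assignments_tsv(self.assignments, fh)
        with open(out / "truth.tsv", "w") as fh:
            write_annotation_map(self.truth, fh)
        _write_blast_tabular(self.psiblast_hits, out / "psiblast.tsv")
        _write_blast_tabular(self.fallback_hits, out / "fallback.tsv")
        with open(out / "hhsearch.tsv", "w") as fh:
            for targ in sorted(self.hhsearch_hits):
                for h in self.hhsearch_hits[targ]:
                    fh.write(f"{h.query}\t{h.subject}\t{h.probability:g}\n")
        params = {"seed": self.seed, "spec": asdict(self.spec),
                  "strata": self.strata}
        (out / "params.json").write_text(json.dumps(params, indent=1, sort_keys=True))


def _write_blast_tabular(
    hits: dict[str, list[HomologyHit]], path: Path
) -> None:
    with open(path, "w") as fh:
        for targ in sorted(hits):
            for h in hits[targ]:
                subject = f"{h.species}|{h.subject}" if h.species else h.subject
                fh.write(
                    f"{h.query}\t{subject}\t90.0\t100\t10\t0\t1\t100\t1\t100\t"
                    f"{h.evalue:.3g}\t200\n"
                )


def _draw_terms(rng: np.random.Generator, pool: list[str], lo: int, hi: int) -> set[str]:
    k = int(rng.integers(lo, hi + 1))
    idx = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
    return {pool[i] for i in idx}


def make_world(spec: WorldSpec = WorldSpec(), seed: int = 0) -> SyntheticWorld:
    """Generate a synthetic world with planted easy/mid/hard targets."""
    rng = np.random.default_rng(seed)
    dag = make_toy_dag(spec.n_terms, spec.branching, seed=int(rng.integers(2**31)))
    term_pool = sorted(dag.terms)[1:] or sorted(dag.terms)  # skip the root if possible
    lo, hi = spec.terms_per_entity

    species_ids = [f"sp{i + 1:02d}" for i in range(spec.n_species)]
    n_hard = spec.n_targets - int(round(spec.fraction_easy * spec.n_targets)) - int(
        round(spec.fraction_mid * spec.n_targets)
    )
    if n_hard < 0:
        raise ValueError("fraction_easy + fraction_mid exceed 1")

    # domain families: reserve one unannotated center per hard target, then
    # a general pool of which ~density are annotated
    n_reserved = n_hard
    if spec.n_domains < n_reserved + 2:
        raise ValueError("n_domains too small for the requested hard targets")
    domains = [f"PF{i + 1:05d}" for i in range(spec.n_domains)]
    reserved = domains[:n_reserved]
    pool = domains[n_reserved:]
    domain_annotations: AnnotationMap = {}
    for d in pool:
        if rng.random() < spec.domain_annotation_density:
            domain_annotations[d] = _draw_terms(rng, term_pool, lo, hi)
    annotated_pool = sorted(domain_annotations)
    if len(annotated_pool) < 2:
        raise ValueError(
            "infeasible spec: too few annotated domains for planted targets"
        )

    # proteomes: random multi-domain proteins from the general pool only
    assignments: dict[str, DomainAssignmentTable] = {}
    for sp in species_ids:
        table = DomainAssignmentTable(sp)
        for j in range(spec.n_proteins_per_species):
            k = int(rng.integers(1, 4))
            idx = rng.choice(len(pool), size=k, replace=False)
            table.assignments[f"{sp}_P{j + 1:04d}"] = [pool[i] for i in idx]
        assignments[sp] = table

    protein_annotations: AnnotationMap = {}
    world = SyntheticWorld(
        spec=spec, seed=seed, dag=dag, assignments=assignments, networks={},
        protein_annotations=protein_annotations,
        domain_annotations=domain_annotations,
    )

    strata = (
        ["easy"] * int(round(spec.fraction_easy * spec.n_targets))
        + ["mid"] * int(round(spec.fraction_mid * spec.n_targets))
        + ["hard"] * n_hard
    )
    hard_idx = 0
    for i, stratum in enumerate(strata):
        targ = f"T{i + 1:05d}"
        sp = species_ids[i % len(species_ids)]
        world.strata[targ] = stratum
        weak_e = lambda: float(rng.uniform(*spec.weak_evalue_range))
        if stratum == "easy":
            true_terms = _draw_terms(rng, term_pool, lo, hi)
            subject = f"SUBJ_{targ}"
            # subject carries the truth plus a few unrelated terms, so the
            # transfer is complete but not perfectly precise
            extra = _draw_terms(rng, term_pool, *spec.extra_terms_per_subject)
            protein_annotations[subject] = set(true_terms) | extra
            e = 10.0 ** -float(rng.uniform(*spec.easy_evalue_exp))
            strong = HomologyHit(targ, subject, "psiblast", evalue=e, species=sp)
            extras = _weak_hits(rng, targ, species_ids, protein_annotations,
                                term_pool, lo, hi, spec)
            world.psiblast_hits[targ] = [strong] + extras
            world.fallback_hits[targ] = [strong] + extras
            world.hhsearch_hits[targ] = []
            world.truth[targ] = true_terms
        elif stratum == "mid":
            n_dom = int(rng.integers(1, 3))
            idx = rng.choice(len(annotated_pool), size=n_dom, replace=False)
            chosen = [annotated_pool[j] for j in idx]
            true_terms: set[str] = set()
            hh = []
            for d in chosen:
                p = float(rng.uniform(*spec.strong_probability_range))
                hh.append(HomologyHit(targ, d, "hhsearch", probability=p))
                true_terms |= domain_annotations[d]
            extras = _weak_hits(rng, targ, species_ids, protein_annotations,
                                term_pool, lo, hi, spec)
            world.psiblast_hits[targ] = extras
            world.fallback_hits[targ] = extras
            world.hhsearch_hits[targ] = hh
            world.truth[targ] = true_terms
        else:  # hard
            center = reserved[hard_idx]
            hard_idx += 1
            idx = rng.choice(len(annotated_pool), size=2, replace=False)
            n1, n2 = annotated_pool[idx[0]], annotated_pool[idx[1]]
            # dedicated proteome protein wires the unannotated center next
            # to two annotated neighbors in exactly one species' network
            assignments[sp].assignments[f"{sp}_H{targ}"] = [center, n1, n2]
            p = float(rng.uniform(*spec.weak_probability_range))
            world.hhsearch_hits[targ] = [
                HomologyHit(targ, center, "hhsearch", probability=p)
            ]
            # species-tagged weak hit to an unannotated subject: selects the
            # right DCN without contributing homology predictions
            anchor = HomologyHit(targ, f"ANCH_{targ}", "psiblast",
                                 evalue=weak_e(), species=sp)
            world.psiblast_hits[targ] = [anchor]
            world.fallback_hits[targ] = [anchor]
            world.truth[targ] = (
                domain_annotations[n1] | domain_annotations[n2]
            )
        if not world.truth[targ]:
            raise RuntimeError(f"planted empty truth for {targ}")

    world.networks = {sp: build_dcn(tab) for sp, tab in assignments.items()}
    # sanity: every hard target's center must sit in its species' network
    for targ, stratum in world.strata.items():
        if stratum != "hard":
            continue
        center = world.hhsearch_hits[targ][0].subject
        sp = world.psiblast_hits[targ][0].species
        if center not in world.networks[sp].nodes:
            raise RuntimeError("infeasible spec: hard-case center not in network")
    return world


def _weak_hits(
    rng: np.random.Generator,
    targ: str,
    species_ids: list[str],
    protein_annotations: AnnotationMap,
    term_pool: list[str],
    lo: int,
    hi: int,
    spec: WorldSpec,
) -> list[HomologyHit]:
    """1-3 above-threshold hits to freshly annotated subjects (fallback fodder)."""
    out = []
    for j in range(int(rng.integers(1, 4))):
        subject = f"WEAK_{targ}_{j}"
        protein_annotations[subject] = _draw_terms(rng, term_pool, lo, hi)
        sp = species_ids[int(rng.integers(len(species_ids)))]
        out.append(
            HomologyHit(targ, subject, "psiblast",
                        evalue=float(rng.uniform(*spec.weak_evalue_range)),
                        species=sp)
        )
    return out
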