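"""Synthetic worlds: ontologies, annotated proteomes, rule-based interactomes.

A *world* bundles a generated ontology, a domain universe, per-protein
domain/GO annotations and a ground-truth interaction rule set (interacting
domain pairs and/or co-interacting level-L GO term pairs).  A pair of
proteins truly interacts iff it satisfies at least one rule; observed labels
may additionally be flipped with probability ``noise``.  Everything is
reproducible bit-for-bit from the seed, and every emitted file parses with
the matching :mod:`ppilearn.io_sources` reader.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .io_sources import PPIRecord, pair_key
from .ontology import (
    LevelAssignment,
    OntologyGraph,
    OntologyTerm,
    assign_levels,
    backtrack_annotations,
    write_obo,
)

__all__ = [
    "Proteome",
    "SyntheticWorld",
    "InteractomeSample",
    "simulate_ontology",
    "simulate_proteome",
    "make_world",
    "simulate_interactome",
    "write_world",
    "PRESETS",
]

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

#: annotation-count cap for the truncated-Poisson draw
MAX_ANNOTATIONS = 10


@dataclass
class Proteome:
    proteins: tuple[str, ...]
    domain_universe: tuple[str, ...]
    domains: dict[str, set[str]]
    go: dict[str, set[str]]


@dataclass
class SyntheticWorld:
    ontology: OntologyGraph
    levels: LevelAssignment
    proteome: Proteome
    domain_rules: tuple[tuple[str, str], ...]
    go_rules: tuple[tuple[str, str], ...]
    level: int
    noise: float
    seed: int


@dataclass
class InteractomeSample:
    positives: list[PPIRecord]
    negatives: list[PPIRecord]
    truth: set[tuple[str, str]]


def simulate_ontology(
    n_terms: int = 25,
    max_depth: int = 4,
    branching: int = 2,
    dag_extra_edges: int = 0,
    seed: int = 0,
) -> OntologyGraph:
    """Generate a rooted ontology DAG with three namespace lineages.

    Each namespace gets up to ``n_terms`` terms (root included) arranged as a
    breadth-first ``branching``-ary tree of depth ``max_depth``; with a large
    enough budget the lineage is the full tree with ``(b**d - 1) / (b - 1)``
    terms.  ``dag_extra_edges`` extra parent edges (relation drawn from the
    three supported types, parent strictly shallower) turn the tree into a
    DAG while staying acyclic by construction.
    """
    if n_terms < 1 or max_depth < 1 or branching < 1:
        raise ValueError("n_terms, max_depth and branching must be positive")
    rng = np.random.default_rng(seed)
    terms: dict[str, OntologyTerm] = {}
    counter = 0
    depth_of: dict[str, int] = {}

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"GO:{counter:07d}"

    for namespace in NAMESPACES:
        root = new_id()
        terms[root] = OntologyTerm(id=root, name=f"{namespace} root", namespace=namespace)
        depth_of[root] = 1
        budget = n_terms - 1
        frontier = [root]
        while budget > 0 and frontier:
            next_frontier = []
            for parent in frontier:
                if depth_of[parent] >= max_depth:
                    continue
                for _ in range(branching):
                    if budget <= 0:
                        break
                    child = new_id()
                    terms[child] = OntologyTerm(
                        id=child,
                        name=f"synthetic term {child[3:]}",
                        namespace=namespace,
                        parents={(parent, "is_a")},
                    )
                    depth_of[child] = depth_of[parent] + 1
                    next_frontier.append(child)
                    budget -= 1
            if not next_frontier:
                break
            frontier = next_frontier

    # extra cross edges: child gains a second parent strictly above its depth
    all_ids = sorted(terms)
    added = 0
    attempts = 0
    while added < dag_extra_edges and attempts < 100 * max(dag_extra_edges, 1):
        attempts += 1
        child = all_ids[rng.integers(len(all_ids))]
        if depth_of[child] <= 2:
            continue
        candidates = [
            t for t in all_ids
            if depth_of[t] < depth_of[child]
            and terms[t].namespace == terms[child].namespace
            and t not in {p for p, _ in terms[child].parents}
        ]
        if not candidates:
            continue
        parent = candidates[rng.integers(len(candidates))]
        relation = ("is_a", "part_of", "regulates")[rng.integers(3)]
        terms[child].parents.add((parent, relation))
        added += 1
    return OntologyGraph(terms)


def _truncated_poisson(rng: np.random.Generator, mean: float) -> int:
    if mean <= 0:
        return 0
    return int(min(rng.poisson(mean), MAX_ANNOTATIONS))


def simulate_proteome(
    n_proteins: int,
    n_domains: int,
    mean_domains_per_protein: float,
    mean_terms_per_protein: float,
    ontology: OntologyGraph,
    seed: int = 0,
) -> Proteome:
    """Draw per-protein domain and GO annotations (truncated Poisson counts).

    Terms are sampled uniformly from non-root, non-obsolete ontology terms;
    domains uniformly from a ``PFxxxxx``-style universe.
    """
    if n_proteins < 1 or n_domains < 1:
        raise ValueError("n_proteins and n_domains must be positive")
    rng = np.random.default_rng(seed)
    proteins = tuple(f"P{i:05d}" for i in range(1, n_proteins + 1))
    domain_universe = tuple(f"PF{i:05d}" for i in range(1, n_domains + 1))
    roots = set(ontology.roots)
    term_pool = sorted(
        t.id for t in ontology.terms.values() if not t.obsolete and t.id not in roots
    )
    domains: dict[str, set[str]] = {}
    go: dict[str, set[str]] = {}
    for p in proteins:
        k_dom = min(_truncated_poisson(rng, mean_domains_per_protein), n_domains)
        k_go = min(_truncated_poisson(rng, mean_terms_per_protein), len(term_pool))
        domains[p] = (
            set(rng.choice(domain_universe, size=k_dom, replace=False)) if k_dom else set()
        )
        go[p] = set(rng.choice(term_pool, size=k_go, replace=False)) if k_go else set()
    return Proteome(
        proteins=proteins, domain_universe=domain_universe, domains=domains, go=go
    )


def make_world(
    n_proteins: int = 200,
    n_domains: int = 40,
    n_domain_rules: int = 5,
    n_go_rules: int = 0,
    level: int = 2,
    noise: float = 0.0,
    seed: int = 0,
    mean_domains_per_protein: float = 3.0,
    mean_terms_per_protein: float = 3.0,
    ontology_terms: int = 25,
    ontology_depth: int = 4,
    ontology_branching: int = 2,
    ontology_extra_edges: int = 4,
) -> SyntheticWorld:
    """Build a fully seeded world with rules over observed features only."""
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ontology = simulate_ontology(
        n_terms=ontology_terms,
        max_depth=ontology_depth,
        branching=ontology_branching,
        dag_extra_edges=ontology_extra_edges,
        seed=seed,
    )
    levels = assign_levels(ontology)
    proteome = simulate_proteome(
        n_proteins,
        n_domains,
        mean_domains_per_protein,
        mean_terms_per_protein,
        ontology,
        seed=seed + 1,
    )

    used_domains = sorted({d for ds in proteome.domains.values() for d in ds})
    if n_domain_rules and len(used_domains) < 2:
        raise ValueError("not enough observed domains to draw rules from")
    max_rules = len(used_domains) * (len(used_domains) - 1) // 2
    if n_domain_rules > max_rules:
        raise ValueError(f"cannot draw {n_domain_rules} distinct rules from {max_rules} pairs")
    domain_rules: set[tuple[str, str]] = set()
    while len(domain_rules) < n_domain_rules:
        d1, d2 = rng.choice(used_domains, size=2, replace=False)
        domain_rules.add(pair_key(str(d1), str(d2)))

    go_rules: set[tuple[str, str]] = set()
    if n_go_rules:
        backtracked = backtrack_annotations(proteome.go, ontology, levels, level).mapping
        used_terms = sorted({t for ts in backtracked.values() for t in ts})
        if len(used_terms) < 2:
            raise ValueError("not enough observed level-L terms to draw rules from")
        while len(go_rules) < n_go_rules:
            t1, t2 = rng.choice(used_terms, size=2, replace=False)
            go_rules.add(pair_key(str(t1), str(t2)))

    return SyntheticWorld(
        ontology=ontology,
        levels=levels,
        proteome=proteome,
        domain_rules=tuple(sorted(domain_rules)),
        go_rules=tuple(sorted(go_rules)),
        level=level,
        noise=noise,
        seed=seed,
    )


def _matches_rules(
    feats_a: set[str], feats_b: set[str], rules: tuple[tuple[str, str], ...]
) -> bool:
    for x, y in rules:
        if (x in feats_a and y in feats_b) or (y in feats_a and x in feats_b):
            return True
    return False


def simulate_interactome(world: SyntheticWorld) -> InteractomeSample:
    """Evaluate the rules on every unordered pair, flip with prob ``noise``.

    Returns observed positives (STRING-style score 950), a balanced sample
    of observed negatives, and the noise-free ground-truth pair set.
    """
    if not world.domain_rules and not world.go_rules:
        raise ValueError("truth_rules are empty")
    proteome = world.proteome
    observed_feats = {d for ds in proteome.domains.values() for d in ds}
    backtracked = backtrack_annotations(
        proteome.go, world.ontology, world.levels, world.level
    ).mapping
    observed_terms = {t for ts in backtracked.values() for t in ts}
    for x, y in world.domain_rules:
        if x not in observed_feats or y not in observed_feats:
            raise ValueError(f"domain rule ({x}, {y}) references an absent domain")
    for x, y in world.go_rules:
        if x not in observed_terms or y not in observed_terms:
            raise ValueError(f"GO rule ({x}, {y}) references an absent level-L term")

    rng = np.random.default_rng(world.seed + 2)
    proteins = proteome.proteins
    truth: set[tuple[str, str]] = set()
    positives: list[PPIRecord] = []
    negative_pool: list[tuple[str, str]] = []
    for i in range(len(proteins)):
        a = proteins[i]
        for j in range(i + 1, len(proteins)):
            b = proteins[j]
            is_true = _matches_rules(
                proteome.domains[a] | backtracked[a],
                proteome.domains[b] | backtracked[b],
                world.domain_rules + world.go_rules,
            )
            if is_true:
                truth.add(pair_key(a, b))
            observed = is_true
            if world.noise > 0 and rng.random() < world.noise:
                observed = not observed
            if observed:
                positives.append(PPIRecord(a, b, combined_score=950, label="positive"))
            else:
                negative_pool.append((a, b))

    n_neg = min(len(positives), len(negative_pool))
    idx = rng.choice(len(negative_pool), size=n_neg, replace=False)
    negatives = [
        PPIRecord(*negative_pool[i], combined_score=None, label="negative")
        for i in sorted(idx)
    ]
    return InteractomeSample(positives=positives, negatives=negatives, truth=truth)


PRESETS: dict[str, dict] = {
    "small": dict(n_proteins=80, n_domains=25, n_domain_rules=3, n_go_rules=1,
                  ontology_terms=15, ontology_depth=3),
    "medium": dict(n_proteins=200, n_domains=40, n_domain_rules=5, n_go_rules=0),
}


def write_world(world: SyntheticWorld, outdir: str | Path) -> InteractomeSample:
    """Emit OBO + TSV artifacts consumable by the io_sources readers.

    Writes ``ontology.obo``, ``domains.tsv``, ``go.tsv`` (original, not
    backtracked, annotations), ``links.tsv`` (observed positives, score 950),
    ``proteins.txt``, ``truth.tsv`` and ``rules.tsv``; returns the sample.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sample = simulate_interactome(world)
    write_obo(world.ontology, outdir / "ontology.obo")
    proteome = world.proteome
    with open(outdir / "domains.tsv", "w") as fh:
        for p in proteome.proteins:
            for d in sorted(proteome.domains[p]):
                fh.write(f"{p}\t{d}\n")
    with open(outdir / "go.tsv", "w") as fh:
        for p in proteome.proteins:
            for t in sorted(proteome.go[p]):
                fh.write(f"{p}\t{t}\n")
    with open(outdir / "links.tsv", "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for rec in sample.positives:
            fh.write(f"{rec.protein_a}\t{rec.protein_b}\t{rec.combined_score}\n")
    (outdir / "proteins.txt").write_text("\n".join(proteome.proteins) + "\n")
    with open(outdir / "truth.tsv", "w") as fh:
        for a, b in sorted(sample.truth):
            fh.write(f"{a}\t{b}\n")
    with open(outdir / "rules.tsv", "w") as fh:
        for x, y in world.domain_rules:
            fh.write(f"domain\t{x}\t{y}\n")
        for x, y in world.go_rules:
            fh.write(f"go\t{x}\t{y}\n")
    return sample
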