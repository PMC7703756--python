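"""GO annotations: GAF/OBO parsing, true-path propagation, labels, term specificity.

Annotation rows are filtered to the Biological Process aspect, rows
with electronically-inferred (IEA) evidence or a NOT qualifier are
dropped, and the remaining gene->term assignments are propagated to all
is_a/part_of ancestors (the true-path rule). Per-term binary label
vectors over an ordered gene list feed the classifiers; two term
specificity measures are provided: Resnik information content
(-log relative annotation frequency) and the maximum path length from
the term to the ontology root.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import obonet
from Bio.UniProt import GOA

__all__ = [
    "Ontology",
    "AnnotationSet",
    "TermLabels",
    "TermSpecificity",
    "parse_obo",
    "parse_gaf",
    "propagate",
    "term_labels",
    "resnik_ic",
    "max_path_to_root",
    "term_specificity",
]

BPO_NAMESPACE = "biological_process"
DEFAULT_EXCLUDED_EVIDENCE = frozenset({"IEA"})
PROPAGATION_RELATIONS = ("is_a", "part_of")


@dataclass(frozen=True)
class Ontology:
    """A DAG of GO terms with per-term namespaces.

    ``parents`` maps a term to its is_a/part_of parents within the same
    namespace; roots have an empty parent set.
    """

    terms: frozenset[str]
    parents: dict[str, frozenset[str]]
    namespace: dict[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", frozenset(self.terms))
        parents = {t: frozenset(self.parents.get(t, ())) for t in self.terms}
        object.__setattr__(self, "parents", parents)
        for t, ps in parents.items():
            unknown = ps - self.terms
            if unknown:
                raise ValueError(f"term {t} has parents outside the ontology: {sorted(unknown)}")
        g = nx.DiGraph((t, p) for t, ps in parents.items() for p in ps)
        g.add_nodes_from(self.terms)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology parent graph contains a cycle")

    def ancestors(self, term: str) -> frozenset[str]:
        """All is_a/part_of ancestors of ``term`` (excluding itself)."""
        if term not in self.terms:
            raise KeyError(f"unknown ontology term {term!r}")
        seen: set[str] = set()
        stack = list(self.parents[term])
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(self.parents[t])
        return frozenset(seen)

    def roots(self, namespace: str | None = None) -> frozenset[str]:
        return frozenset(
            t
            for t in self.terms
            if not self.parents[t] and (namespace is None or self.namespace.get(t) == namespace)
        )


@dataclass(frozen=True)
class AnnotationSet:
    """gene -> set of GO terms; ``propagated`` marks ancestor closure."""

    gene_terms: dict[str, frozenset[str]]
    propagated: bool = False
    evidence_filtered: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "gene_terms", {g: frozenset(ts) for g, ts in self.gene_terms.items()}
        )

    @property
    def genes(self) -> list[str]:
        return sorted(self.gene_terms)

    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.gene_terms.values():
            out |= ts
        return out


@dataclass(frozen=True)
class TermLabels:
    """Binary annotation vector for one term over an ordered gene list."""

    term: str
    y: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=int)
        object.__setattr__(self, "y", y)
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary")

    @property
    def n_positive(self) -> int:
        return int(self.y.sum())


@dataclass(frozen=True)
class TermSpecificity:
    term: str
    resnik_ic: float
    max_root_path: int

    def __post_init__(self) -> None:
        if self.resnik_ic < 0:
            raise ValueError("information content cannot be negative")
        if self.max_root_path < 0:
            raise ValueError("path length cannot be negative")


def parse_obo(path: str) -> Ontology:
    """Read an OBO file, keeping is_a and part_of relations."""
    graph = obonet.read_obo(path)
    terms = set(graph.nodes)
    namespace = {
        t: data.get("namespace", "") for t, data in graph.nodes(data=True)
    }
    parents: dict[str, set[str]] = {t: set() for t in terms}
    for child, parent, rel in graph.edges(keys=True):
        if rel in PROPAGATION_RELATIONS and parent in terms:
            parents[child].add(parent)
    return Ontology(terms=frozenset(terms), parents={t: frozenset(p) for t, p in parents.items()}, namespace=namespace)


def parse_gaf(
    path: str,
    exclude_evidence: frozenset[str] | set[str] = DEFAULT_EXCLUDED_EVIDENCE,
    aspect: str = "P",
    id_field: str = "DB_Object_ID",
) -> AnnotationSet:
    """Read GAF 2.x annotations, keeping the requested aspect (default
    Biological Process) and dropping excluded evidence codes and
    NOT-qualified rows."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("!") or not line.strip():
                continue
            if len(line.rstrip("\n").split("\t")) < 15:
                raise ValueError(f"malformed GAF line {lineno}: fewer than 15 columns")
    gene_terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for rec in GOA.gafiterator(fh):
            if rec["Aspect"] != aspect:
                continue
            if rec["Evidence"] in exclude_evidence:
                continue
            if any(q.startswith("NOT") for q in rec.get("Qualifier", [])):
                continue
            gene_terms.setdefault(rec[id_field], set()).add(rec["GO_ID"])
    return AnnotationSet(
        gene_terms={g: frozenset(ts) for g, ts in gene_terms.items()},
        propagated=False,
        evidence_filtered=True,
    )


def propagate(ann: AnnotationSet, ont: Ontology) -> AnnotationSet:
    """Close every gene's term set under ancestors (true-path rule)."""
    closure: dict[str, frozenset[str]] = {}
    anc_cache: dict[str, frozenset[str]] = {}
    for gene, terms in ann.gene_terms.items():
        full: set[str] = set(terms)
        for t in terms:
            if t not in ont.terms:
                raise KeyError(f"annotated term {t!r} is not in the ontology")
            if t not in anc_cache:
                anc_cache[t] = ont.ancestors(t)
            full |= anc_cache[t]
        closure[gene] = frozenset(full)
    return replace(ann, gene_terms=closure, propagated=True)


def term_labels(ann: AnnotationSet, genes: tuple[str, ...] | list[str], term: str) -> TermLabels:
    """Binary vector y with y_i = 1 iff genes[i] is annotated with the term."""
    y = np.array([1 if term in ann.gene_terms.get(g, ()) else 0 for g in genes], dtype=int)
    return TermLabels(term=term, y=y)


def resnik_ic(ann: AnnotationSet, ont: Ontology | None = None) -> dict[str, float]:
    """Resnik information content -ln(n_t / n_annotated) per term.

    Requires propagated annotations so that annotation counts are
    monotone along the ontology (ancestors count at least as many genes
    as their descendants). Terms with zero annotations are absent.
    """
    if not ann.propagated:
        raise ValueError("resnik_ic requires propagated annotations")
    counts: dict[str, int] = {}
    for terms in ann.gene_terms.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    n_annotated = sum(1 for ts in ann.gene_terms.values() if ts)
    if n_annotated == 0:
        return {}
    return {t: float(-np.log(c / n_annotated)) for t, c in counts.items()}


def max_path_to_root(ont: Ontology, term: str) -> int:
    """Length of the longest is_a/part_of path from the term to a root."""
    if term not in ont.terms:
        raise KeyError(f"unknown ontology term {term!r}")
    memo: dict[str, int] = {}

    def longest(t: str) -> int:
        if t in memo:
            return memo[t]
        ps = ont.parents[t]
        memo[t] = 0 if not ps else 1 + max(longest(p) for p in ps)
        return memo[t]

    return longest(term)


def term_specificity(ann: AnnotationSet, ont: Ontology) -> dict[str, TermSpecificity]:
    """Both specificity measures for every annotated term."""
    ic = resnik_ic(ann, ont)
    return {
        t: TermSpecificity(term=t, resnik_ic=v, max_root_path=max_path_to_root(ont, t))
        for t, v in ic.items()
        if t in ont.terms
    }
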