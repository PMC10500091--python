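"""Human Phenotype Ontology handling.

Parses ``hp.obo`` into a rooted directed acyclic graph over ``is_a`` edges,
computes term depths (shortest path to the root), reflexive-transitive
ancestor closures, and corpus-based information content (IC).

The IC of a term is the negative natural log of the fraction of corpus
diseases annotated to the term or any of its descendants.  Terms with no
annotated descendants receive an ``inf`` sentinel and are excluded from
most-informative-common-ancestor (MICA) search.
"""
from __future__ import annotations

import math
import re
from collections import Counter, deque
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx
import obonet

TERM_ID_PATTERN = re.compile(r"^HP:\d{7}$")

__all__ = [
    "Ontology",
    "AnnotationCorpus",
    "ICTable",
    "OntologyError",
    "UnknownTermError",
    "parse_obo",
    "to_obo",
    "ancestors",
    "load_hpoa",
    "compute_ic",
    "mica",
]


class OntologyError(ValueError):
    """Structural problem in the ontology source (cycle, missing root...)."""


class UnknownTermError(KeyError):
    """A term ID that does not resolve to a live ontology term."""

    def __init__(self, term_id: str):
        super().__init__(term_id)
        self.term_id = term_id

    def __str__(self) -> str:  # KeyError quotes its arg; keep message readable
        return f"unknown or unresolvable HPO term: {self.term_id!r}"


@dataclass
class Ontology:
    """Rooted DAG of phenotype terms linked by ``is_a`` edges.

    ``parents`` maps every live term to its (possibly empty, for the root)
    set of direct parents.  ``depth`` is the shortest is-a path length to the
    root.  ``obsolete`` maps retired/alternate IDs to their live replacement.
    """

    names: dict[str, str]
    parents: dict[str, frozenset[str]]
    root: str
    depth: dict[str, int]
    obsolete: dict[str, str] = field(default_factory=dict)
    _children: dict[str, set[str]] = field(default_factory=dict, repr=False)
    _ancestors: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._children:
            self._children = {t: set() for t in self.parents}
            for child, ps in self.parents.items():
                for p in ps:
                    self._children[p].add(child)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.parents

    def __len__(self) -> int:
        return len(self.parents)

    @property
    def terms(self) -> Iterable[str]:
        return self.parents.keys()

    def children(self, term_id: str) -> frozenset[str]:
        return frozenset(self._children[self.resolve(term_id)])

    def resolve(self, term_id: str) -> str:
        """Map an ID to a live term, following obsolete/alt-ID replacements."""
        if not TERM_ID_PATTERN.match(term_id):
            raise UnknownTermError(term_id)
        if term_id in self.parents:
            return term_id
        if term_id in self.obsolete:
            return self.obsolete[term_id]
        raise UnknownTermError(term_id)

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Reflexive transitive is-a closure; always contains the term and root."""
        t = self.resolve(term_id)
        cached = self._ancestors.get(t)
        if cached is not None:
            return cached
        closure: set[str] = {t}
        stack = list(self.parents[t])
        while stack:
            cur = stack.pop()
            if cur in closure:
                continue
            cached = self._ancestors.get(cur)
            if cached is not None:
                closure |= cached
            else:
                closure.add(cur)
                stack.extend(self.parents[cur])
        result = frozenset(closure)
        self._ancestors[t] = result
        return result


def ancestors(ontology: Ontology, term_id: str) -> frozenset[str]:
    """Module-level alias for :meth:`Ontology.ancestors`."""
    return ontology.ancestors(term_id)


def parse_obo(obo_stream: IO[str] | str) -> Ontology:
    """Parse an OBO 1.2/1.4 stream into an :class:`Ontology`.

    Only ``is_a`` edges become parent links; other relationship types are
    ignored.  Obsolete terms are dropped from the graph but recorded (via
    ``replaced_by``) in the resolution map, as are ``alt_id`` aliases of live
    terms.  A cyclic is-a graph or an ambiguous/missing root is a hard error.
    """
    graph = obonet.read_obo(obo_stream, ignore_obsolete=False)

    live: dict[str, dict] = {}
    obsolete_nodes: dict[str, dict] = {}
    for node, data in graph.nodes(data=True):
        if str(data.get("is_obsolete", "")).lower() == "true":
            obsolete_nodes[node] = data
        else:
            live[node] = data

    parents: dict[str, frozenset[str]] = {}
    dag = nx.DiGraph()
    dag.add_nodes_from(live)
    for child in live:
        ps = {
            parent
            for _, parent, key in graph.out_edges(child, keys=True)
            if key == "is_a" and parent in live
        }
        parents[child] = frozenset(ps)
        dag.add_edges_from((child, p) for p in ps)

    if not nx.is_directed_acyclic_graph(dag):
        u, v, *_ = nx.find_cycle(dag)[0] + (None,)
        raise OntologyError(f"cyclic is_a graph: edge {u} -> {v} lies on a cycle")

    roots = sorted(t for t, ps in parents.items() if not ps)
    if len(roots) != 1:
        raise OntologyError(
            "expected exactly one root (parentless) term, found "
            f"{len(roots)}: {roots[:5]}"
        )
    root = roots[0]

    # BFS from the root over child edges gives shortest-path depths.
    children: dict[str, set[str]] = {t: set() for t in parents}
    for child, ps in parents.items():
        for p in ps:
            children[p].add(child)
    depth = {root: 0}
    queue = deque([root])
    while queue:
        cur = queue.popleft()
        for ch in children[cur]:
            if ch not in depth:
                depth[ch] = depth[cur] + 1
                queue.append(ch)

    obsolete: dict[str, str] = {}
    for node, data in obsolete_nodes.items():
        replacements = data.get("replaced_by") or []
        for repl in replacements:
            if repl in live:
                obsolete[node] = repl
                break
    for node, data in live.items():
        for alt in data.get("alt_id") or []:
            obsolete.setdefault(alt, node)

    names = {t: data.get("name", t) for t, data in live.items()}
    return Ontology(
        names=names, parents=parents, root=root, depth=depth, obsolete=obsolete
    )


def to_obo(ontology: Ontology) -> str:
    """Serialize an :class:`Ontology` back to OBO text (is-a edges only)."""
    lines = ["format-version: 1.2", "ontology: hp-export", ""]
    for term in sorted(ontology.parents):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {ontology.names.get(term, term)}")
        for parent in sorted(ontology.parents[term]):
            lines.append(f"is_a: {parent} ! {ontology.names.get(parent, parent)}")
        lines.append("")
    return "\n".join(lines)


@dataclass
class AnnotationCorpus:
    """Disease-to-phenotype annotations used to derive information content."""

    disease_terms: dict[str, frozenset[str]]
    disease_names: dict[str, str] = field(default_factory=dict)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_terms)


def load_hpoa(stream: IO[str] | Iterable[str], ontology: Ontology) -> AnnotationCorpus:
    """Read HPOA-style annotations: tab-delimited, ``#`` header lines skipped.

    Expected leading columns: database_id, disease_name, qualifier, hpo_id.
    Rows with qualifier ``NOT`` are dropped; term IDs are resolved through
    the ontology's obsolete map (unresolvable IDs are a hard error).
    """
    disease_terms: dict[str, set[str]] = {}
    disease_names: dict[str, str] = {}
    for raw in stream:
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 4:
            raise OntologyError(f"malformed annotation row (need 4 columns): {line!r}")
        disease_id, disease_name, qualifier, hpo_id = cols[:4]
        if qualifier.strip().upper() == "NOT":
            continue
        term = ontology.resolve(hpo_id.strip())
        disease_terms.setdefault(disease_id, set()).add(term)
        disease_names.setdefault(disease_id, disease_name)
    return AnnotationCorpus(
        disease_terms={d: frozenset(ts) for d, ts in disease_terms.items()},
        disease_names=disease_names,
    )


@dataclass
class ICTable:
    """Natural-log information content per term.

    ``ic[t] = -ln(diseases annotated at-or-below t / total diseases)``;
    terms with no annotated descendants carry ``math.inf``.
    """

    ic: dict[str, float]

    def __getitem__(self, term_id: str) -> float:
        return self.ic[term_id]

    def get(self, term_id: str, default: float = math.inf) -> float:
        return self.ic.get(term_id, default)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.ic


def compute_ic(ontology: Ontology, corpus: AnnotationCorpus) -> ICTable:
    """Disease-frequency information content over the annotation corpus."""
    if corpus.n_diseases == 0:
        raise ValueError("annotation corpus is empty; cannot compute IC")
    counts: Counter[str] = Counter()
    for terms in corpus.disease_terms.values():
        covered: set[str] = set()
        for t in terms:
            covered |= ontology.ancestors(t)
        counts.update(covered)
    n = corpus.n_diseases
    ic = {
        t: (-math.log(counts[t] / n) if counts[t] else math.inf)
        for t in ontology.terms
    }
    ic[ontology.root] = 0.0
    return ICTable(ic=ic)


def mica(
    ontology: Ontology, ic_table: ICTable, t1: str, t2: str
) -> tuple[str, float]:
    """Most informative common ancestor of two terms.

    Infinite-IC terms are excluded as candidates; the root (IC 0) is always a
    common ancestor, so the result is always defined.  Ties on IC are broken
    by greater depth, then lexicographically smaller term ID.
    """
    a = ontology.resolve(t1)
    b = ontology.resolve(t2)
    common = ontology.ancestors(a) & ontology.ancestors(b)
    candidates = [t for t in common if math.isfinite(ic_table[t])]
    best = min(candidates, key=lambda t: (-ic_table[t], -ontology.depth[t], t))
    return best, ic_table[best]
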