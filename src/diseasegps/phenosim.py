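"""Patient-versus-disease phenotype similarity.

Two term-level similarities are combined:

* **topological** — a Wu–Palmer-style depth ratio,
  ``2·depth(LCA) / (depth(t1) + depth(t2))``, where the LCA is the deepest
  common ancestor;
* **semantic** — Lin similarity over the most informative common ancestor,
  ``2·IC(MICA) / (IC(t1) + IC(t2))``.

Term sets are aggregated with a symmetric best-match average, the two
set-level scores are blended ``β·top + (1−β)·semantic`` (β defaults to 0.9)
and min–max normalized across the candidate-disease list to give each
disease a phenotype score in [0, 1].
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .ontology import ICTable, Ontology, mica
from .profiles import DiseaseProfile

__all__ = [
    "PatientPhenotype",
    "SimilarityParams",
    "PhenotypeScore",
    "PhenotypeScorer",
    "top_similarity",
    "meic_similarity",
    "set_similarity",
    "phenotype_scores",
]


@dataclass(frozen=True)
class PatientPhenotype:
    """The patient's HPO term set (duplicates collapsed, no pruning)."""

    terms: frozenset[str]

    @classmethod
    def from_ids(cls, ids: Iterable[str], ontology: Ontology) -> "PatientPhenotype":
        resolved = frozenset(ontology.resolve(t) for t in ids)
        if not resolved:
            raise ValueError("patient phenotype must contain at least one term")
        return cls(terms=resolved)


@dataclass(frozen=True)
class SimilarityParams:
    """Blend weight between topological (β) and semantic (1−β) similarity."""

    beta: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")


@dataclass(frozen=True)
class PhenotypeScore:
    disease: str
    top_component: float
    meic_component: float
    blended: float
    normalized: float


def _lca(ontology: Ontology, t1: str, t2: str) -> str:
    common = ontology.ancestors(t1) & ontology.ancestors(t2)
    return min(common, key=lambda t: (-ontology.depth[t], t))


def top_similarity(ontology: Ontology, t1: str, t2: str) -> float:
    """Depth-ratio similarity; 1 iff the terms coincide, 0 at a root-only LCA."""
    a = ontology.resolve(t1)
    b = ontology.resolve(t2)
    if a == b:
        return 1.0
    lca = _lca(ontology, a, b)
    denom = ontology.depth[a] + ontology.depth[b]
    if denom == 0:
        return 1.0  # unreachable for distinct terms; only root has depth 0
    return 2.0 * ontology.depth[lca] / denom


def meic_similarity(ontology: Ontology, ic_table: ICTable, t1: str, t2: str) -> float:
    """Lin similarity over the MICA.

    Identical terms score 1.  If either term carries the infinite-IC
    sentinel (never annotated in the corpus) the semantic score is undefined
    and the topological similarity is returned instead, so the pair is still
    comparable.  A zero IC denominator (both terms fully uninformative)
    scores 0.
    """
    a = ontology.resolve(t1)
    b = ontology.resolve(t2)
    if a == b:
        return 1.0
    ic_a, ic_b = ic_table[a], ic_table[b]
    if not (math.isfinite(ic_a) and math.isfinite(ic_b)):
        return top_similarity(ontology, a, b)
    denom = ic_a + ic_b
    if denom == 0.0:
        return 0.0
    _, ic_m = mica(ontology, ic_table, a, b)
    return min(1.0, 2.0 * ic_m / denom)


def set_similarity(
    patient_terms: Iterable[str],
    disease_terms: Iterable[str],
    term_sim: Callable[[str, str], float],
) -> float:
    """Symmetric best-match average between two non-empty term sets."""
    ps = list(patient_terms)
    ds = list(disease_terms)
    if not ps or not ds:
        raise ValueError("set_similarity requires two non-empty term sets")
    forward = sum(max(term_sim(p, d) for d in ds) for p in ps) / len(ps)
    backward = sum(max(term_sim(p, d) for p in ps) for d in ds) / len(ds)
    return 0.5 * (forward + backward)


class PhenotypeScorer:
    """Caches term-pair similarities so many cases on one ontology stay fast."""

    def __init__(self, ontology: Ontology, ic_table: ICTable):
        self.ontology = ontology
        self.ic_table = ic_table
        self._top_cache: dict[tuple[str, str], float] = {}
        self._meic_cache: dict[tuple[str, str], float] = {}

    def top(self, t1: str, t2: str) -> float:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        val = self._top_cache.get(key)
        if val is None:
            val = top_similarity(self.ontology, t1, t2)
            self._top_cache[key] = val
        return val

    def meic(self, t1: str, t2: str) -> float:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        val = self._meic_cache.get(key)
        if val is None:
            val = meic_similarity(self.ontology, self.ic_table, t1, t2)
            self._meic_cache[key] = val
        return val

    def score(
        self,
        patient: PatientPhenotype,
        candidate_diseases: Sequence[DiseaseProfile],
        params: SimilarityParams | None = None,
    ) -> list[PhenotypeScore]:
        params = params or SimilarityParams()
        if not candidate_diseases:
            raise ValueError("at least one candidate disease is required")
        scores = []
        for disease in candidate_diseases:
            top = set_similarity(patient.terms, disease.terms, self.top)
            meic = set_similarity(patient.terms, disease.terms, self.meic)
            blended = params.beta * top + (1.0 - params.beta) * meic
            scores.append((disease.disease_id, top, meic, blended))
        blends = [s[3] for s in scores]
        lo, hi = min(blends), max(blends)
        span = hi - lo
        out = []
        for disease_id, top, meic, blended in scores:
            # all-equal blends carry no ranking information: score everyone 1
            normalized = 1.0 if span <= 1e-12 else (blended - lo) / span
            out.append(
                PhenotypeScore(
                    disease=disease_id,
                    top_component=top,
                    meic_component=meic,
                    blended=blended,
                    normalized=normalized,
                )
            )
        return out


def phenotype_scores(
    patient: PatientPhenotype,
    candidate_diseases: Sequence[DiseaseProfile],
    ontology: Ontology,
    ic_table: ICTable,
    params: SimilarityParams | None = None,
    scorer: PhenotypeScorer | None = None,
) -> list[PhenotypeScore]:
    """Score the patient against every candidate disease.

    Pass a shared :class:`PhenotypeScorer` when scoring many patients on the
    same ontology/IC table to reuse the term-pair similarity cache.
    """
    if scorer is None:
        scorer = PhenotypeScorer(ontology, ic_table)
    return scorer.score(patient, candidate_diseases, params)
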