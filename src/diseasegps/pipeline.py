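"""End-to-end case analysis: filters → gene scores → phenotype scores → fusion.

Phenotype and genotype inputs are analyzed independently and either may be
absent; the candidate-disease universe is the whole annotation corpus, so
diseases without surviving gene support still compete on phenotype alone
(gene score 0) and vice versa.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .acmg import BayesParams, GeneContext, GeneScore, RulesConfig, gene_scores
from .ontology import ICTable, Ontology
from .phenosim import (
    PatientPhenotype,
    PhenotypeScore,
    PhenotypeScorer,
    SimilarityParams,
)
from .profiles import DiseaseProfile
from .ranking import FusionParams, RankedDisease, rank_diseases
from .variants import AnnotatedVariant, FilterParams, filter_af, filter_inheritance

__all__ = ["CaseResult", "rank_case", "gene_modes", "gene_disease_map"]


@dataclass
class CaseResult:
    ranked: list[RankedDisease]
    gene_scores: dict[str, GeneScore] = field(default_factory=dict)
    phenotype_scores: list[PhenotypeScore] = field(default_factory=list)
    n_variants_input: int = 0
    n_variants_after_af: int = 0
    n_variants_after_inheritance: int = 0


def gene_modes(profiles: Sequence[DiseaseProfile]) -> dict[str, set[str]]:
    """Union of inheritance modes per gene across all diseases."""
    modes: dict[str, set[str]] = {}
    for p in profiles:
        for gene, mode in p.modes.items():
            modes.setdefault(gene, set()).add(mode)
    return modes


def gene_disease_map(profiles: Sequence[DiseaseProfile]) -> dict[str, tuple[str, ...]]:
    return {p.disease_id: tuple(sorted(p.genes)) for p in profiles}


def rank_case(
    ontology: Ontology,
    ic_table: ICTable,
    profiles: Sequence[DiseaseProfile],
    hpo_terms: Iterable[str] | None = None,
    variants: Sequence[AnnotatedVariant] | None = None,
    filter_params: FilterParams | None = None,
    sim_params: SimilarityParams | None = None,
    fusion_params: FusionParams | None = None,
    bayes_params: BayesParams | None = None,
    rules_config: RulesConfig | None = None,
    gene_contexts: Mapping[str, GeneContext] | None = None,
    sex: str | None = None,
    scorer: PhenotypeScorer | None = None,
) -> CaseResult:
    """Rank all candidate diseases for one patient.

    At least one of ``hpo_terms``/``variants`` must be provided.  Pass a
    shared :class:`PhenotypeScorer` when processing many cases on the same
    ontology to reuse the similarity cache.
    """
    hpo_list = list(hpo_terms or [])
    variant_list = list(variants or [])
    if not hpo_list and not variant_list:
        raise ValueError("no input evidence: provide HPO terms, variants, or both")

    result = CaseResult(ranked=[], n_variants_input=len(variant_list))

    if variant_list:
        fp = filter_params or FilterParams()
        surviving = filter_af(variant_list, fp)
        result.n_variants_after_af = len(surviving)
        if fp.inheritance:
            by_gene = filter_inheritance(surviving, gene_modes(profiles), sex)
            surviving = [v for vs in by_gene.values() for v in vs]
        result.n_variants_after_inheritance = len(surviving)
        result.gene_scores = gene_scores(
            surviving, bayes_params, rules_config, gene_contexts
        )

    if hpo_list:
        patient = PatientPhenotype.from_ids(hpo_list, ontology)
        if scorer is None:
            scorer = PhenotypeScorer(ontology, ic_table)
        result.phenotype_scores = scorer.score(patient, list(profiles), sim_params)

    result.ranked = rank_diseases(
        result.gene_scores,
        result.phenotype_scores,
        gene_disease_map(profiles),
        fusion_params,
    )
    return result
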