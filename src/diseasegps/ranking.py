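"""Score fusion, disease/gene ranking and TOP-k benchmark evaluation.

The final score of a candidate disease is the convex combination
``γ·gene_score + (1−γ)·phenotype_score`` (γ defaults to 0.5, equal weight).
Diseases sort by combined score descending, ties broken by higher
phenotype score, then lexicographic disease ID, so repeated runs are
byte-identical.  Gene rankings derive from disease rankings by taking each
disease's best supporting gene at its first (best) appearance.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats

from .acmg import GeneScore
from .phenosim import PhenotypeScore

__all__ = [
    "FusionParams",
    "RankedDisease",
    "TopKReport",
    "rank_diseases",
    "gene_ranking",
    "topk_report",
    "compare_ranks",
    "TOPK_LEVELS",
]

TOPK_LEVELS = (1, 5, 10, 20, 50)


@dataclass(frozen=True)
class FusionParams:
    """γ weight on the gene score; (1−γ) goes to the phenotype score."""

    gamma: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma}")


@dataclass(frozen=True)
class RankedDisease:
    disease: str
    gene: str | None
    gene_score: float
    phenotype_score: float
    combined: float
    rank: int


def rank_diseases(
    gene_scores: Mapping[str, GeneScore],
    phen_scores: Sequence[PhenotypeScore],
    gene_disease: Mapping[str, Sequence[str]],
    params: FusionParams | None = None,
) -> list[RankedDisease]:
    """Fuse per-gene and per-disease scores and rank all candidates.

    Candidates are the union of phenotype-scored diseases and diseases
    linked (via ``gene_disease``: disease ID -> gene symbols) to a scored
    gene.  A missing side contributes 0, honouring the
    either-or-both-inputs contract.
    """
    params = params or FusionParams()
    phen_by_disease = {p.disease: p.normalized for p in phen_scores}

    candidates = set(phen_by_disease)
    if gene_scores:
        for disease, genes in gene_disease.items():
            if any(g in gene_scores for g in genes):
                candidates.add(disease)
    if not candidates:
        raise ValueError("no input evidence: both gene and phenotype score sets are empty")

    rows = []
    for disease in candidates:
        best_gene: str | None = None
        g_score = 0.0
        for gene in sorted(gene_disease.get(disease, ())):
            gs = gene_scores.get(gene)
            if gs is not None and (best_gene is None or gs.score > g_score):
                best_gene, g_score = gene, gs.score
        p_score = phen_by_disease.get(disease, 0.0)
        combined = params.gamma * g_score + (1.0 - params.gamma) * p_score
        rows.append((disease, best_gene, g_score, p_score, combined))

    rows.sort(key=lambda r: (-r[4], -r[3], r[0]))
    return [
        RankedDisease(
            disease=d, gene=g, gene_score=gs, phenotype_score=ps, combined=c, rank=i + 1
        )
        for i, (d, g, gs, ps, c) in enumerate(rows)
    ]


def gene_ranking(ranked: Sequence[RankedDisease]) -> list[str]:
    """Genes ordered by their best (minimum) disease rank, deduplicated."""
    seen: set[str] = set()
    out: list[str] = []
    for rd in ranked:
        if rd.gene is not None and rd.gene not in seen:
            seen.add(rd.gene)
            out.append(rd.gene)
    return out


@dataclass(frozen=True)
class TopKReport:
    """Cumulative proportions of cases solved at each rank band."""

    n_cases: int
    proportions: Mapping[str, float]

    def as_dict(self) -> dict:
        return {"n_cases": self.n_cases, **dict(self.proportions)}


def topk_report(cases: Sequence[tuple[Sequence[str], str]]) -> TopKReport:
    """TOP-k proportions over (ranked genes, causal gene) cases.

    A causal gene absent from its case's ranking counts in the >50 band.
    Proportions at TOP-1..TOP-50 are cumulative; TOP-50 + (>50) = 1.
    """
    if not cases:
        raise ValueError("topk_report requires at least one case")
    ranks: list[int | None] = []
    for ranked_genes, causal in cases:
        try:
            ranks.append(list(ranked_genes).index(causal) + 1)
        except ValueError:
            ranks.append(None)
    n = len(ranks)
    props = {
        f"top{k}": sum(1 for r in ranks if r is not None and r <= k) / n
        for k in TOPK_LEVELS
    }
    props["gt50"] = sum(1 for r in ranks if r is None or r > 50) / n
    return TopKReport(n_cases=n, proportions=props)


def compare_ranks(
    ranks_a: Sequence[float], ranks_b: Sequence[float]
) -> tuple[float, float]:
    """One-sided Wilcoxon signed-rank test that ranks_a < ranks_b (paired).

    Zero differences are handled with the zero-split policy and the normal
    approximation, so identical vectors yield p = 0.5 rather than an error.
    Returns (statistic, p-value); warns when n < 5 (underpowered).
    """
    if len(ranks_a) != len(ranks_b):
        raise ValueError(
            f"paired rank vectors differ in length: {len(ranks_a)} vs {len(ranks_b)}"
        )
    if len(ranks_a) < 5:
        warnings.warn(f"n={len(ranks_a)} pairs: the signed-rank test is underpowered")
    res = stats.wilcoxon(
        ranks_a, ranks_b, alternative="less", zero_method="zsplit", method="approx"
    )
    return float(res.statistic), float(res.pvalue)
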