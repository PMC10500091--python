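"""Synthetic fixtures: toy ontologies, annotation corpora and patient cases.

Every other module is testable offline against data this module generates:
a rooted DAG ontology in OBO text, an HPOA-style annotation corpus, a
gene–disease association table, and per-patient cases consisting of a noisy
HPO term list plus a small VCF with one spiked causal variant and a
configurable number of benign-profile background variants (common AF or
benign assertions), mimicking healthy-exome background without any real
data.

Phenotype noise has three independent knobs applied to the causal
disease's term set: ``p_drop`` (a true term is omitted), ``p_generalize``
(a term is replaced by one of its parents) and ``p_add`` (a random term is
added).  All randomness flows from one seed; per-case substreams keep the
fixtures reproducible yet independent.
"""
from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .acmg import GeneContext
from .ontology import Ontology, parse_obo
from .variants import AnnotatedVariant

__all__ = ["SynthConfig", "SynthCase", "SynthData", "make_ontology", "make_corpus_and_cases", "write_fixtures", "vcf_text"]

_AUTOSOMES = [str(c) for c in range(1, 23)]
_BASES = "ACGT"


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the generator; identical config + seed gives identical text."""

    seed: int = 0
    n_terms: int = 150
    n_diseases: int = 60
    n_genes: int = 60
    branching: int = 3
    terms_per_disease: int = 6
    n_cases: int = 100
    p_drop: float = 0.0
    p_add: float = 0.0
    p_generalize: float = 0.0
    causal_consequence: str = "stop_gained"
    causal_af: float | None = None
    n_background_variants: int = 30
    background_common_fraction: float = 0.5
    x_linked_fraction: float = 0.1
    extra_parent_prob: float = 0.25

    def __post_init__(self) -> None:
        for name in ("p_drop", "p_add", "p_generalize", "background_common_fraction",
                     "x_linked_fraction", "extra_parent_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_terms", "n_diseases", "n_genes", "branching", "terms_per_disease"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SynthCase:
    case_id: str
    hpo_terms: tuple[str, ...]
    variants: tuple[AnnotatedVariant, ...]
    vcf_text: str
    causal_disease: str
    causal_gene: str


@dataclass
class SynthData:
    hpoa_text: str
    gene_disease_text: str
    cases: list[SynthCase]
    gene_contexts: dict[str, GeneContext]
    truth_rows: list[tuple[str, str, str]]  # case_id, causal disease, causal gene


def _term_id(i: int) -> str:
    return f"HP:{i:07d}"


def make_ontology(config: SynthConfig) -> str:
    """Emit OBO text for a rooted DAG of ``n_terms`` synthetic terms.

    A ``branching``-ary tree backbone fixes every term's primary parent
    (giving predictable depth ~log_b n); a second random parent is added
    with probability ``extra_parent_prob`` so multi-parent DAG paths are
    exercised.
    """
    if config.n_terms < 2:
        raise ValueError("need at least a root and one child term")
    rng = np.random.default_rng([config.seed, 101])
    lines = ["format-version: 1.2", "ontology: hp-synthetic", ""]
    for i in range(1, config.n_terms + 1):
        lines.append("[Term]")
        lines.append(f"id: {_term_id(i)}")
        lines.append("name: " + ("All" if i == 1 else f"synthetic phenotype {i}"))
        if i > 1:
            backbone = (i - 2) // config.branching + 1
            parents = {backbone}
            if i > 2 and rng.random() < config.extra_parent_prob:
                extra = int(rng.integers(1, i))
                parents.add(extra)
            for p in sorted(parents):
                lines.append(f"is_a: {_term_id(p)} ! parent")
        lines.append("")
    return "\n".join(lines)


_VCF_INFO_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=A,Type=String,Description="Gene symbol">
##INFO=<ID=AF_POP,Number=A,Type=Float,Description="Population allele frequency">
##INFO=<ID=CSQ,Number=A,Type=String,Description="Molecular consequence">
##INFO=<ID=DMG,Number=A,Type=Float,Description="In-silico damaging score">
##INFO=<ID=CLNSIG,Number=1,Type=String,Description="Clinical assertion">
##INFO=<ID=ACMG,Number=1,Type=String,Description="Precomputed evidence codes">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT_STRING = {"het": "0/1", "hom_alt": "1/1", "hemi": "1"}


def vcf_text(variants: tuple[AnnotatedVariant, ...] | list[AnnotatedVariant]) -> str:
    """Render variants as a single-sample VCF parseable by the reader."""
    contigs = sorted({v.chrom for v in variants}, key=lambda c: (len(c), c))
    out = [_VCF_INFO_HEADER]
    for c in contigs:
        out.append(f"##contig=<ID={c}>\n")
    out.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tPROBAND\n")
    ordered = sorted(variants, key=lambda v: ((len(v.chrom), v.chrom), v.pos, v.alt))
    for v in ordered:
        info = [f"GENE={v.gene}"]
        if v.pop_af is not None:
            info.append(f"AF_POP={v.pop_af:.6g}")
        if v.consequence:
            info.append(f"CSQ={v.consequence}")
        if v.insilico is not None:
            info.append(f"DMG={v.insilico:.4g}")
        if v.assertion:
            info.append(f"CLNSIG={v.assertion}")
        if v.evidence_codes:
            info.append("ACMG=" + ",".join(v.evidence_codes))
        out.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t"
            + ";".join(info)
            + f"\tGT\t{_GT_STRING[v.genotype]}\n"
        )
    return "".join(out)


def _gene_table(config: SynthConfig) -> list[dict]:
    n_x = int(round(config.x_linked_fraction * config.n_genes))
    genes = []
    for i in range(config.n_genes):
        on_x = i < n_x
        genes.append(
            {
                "symbol": f"GENE{i + 1:04d}",
                "chrom": "X" if on_x else _AUTOSOMES[i % len(_AUTOSOMES)],
                "base_pos": (i + 1) * 1_000_000,
                "on_x": on_x,
            }
        )
    return genes


def _snv(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(0, 4)]
    alt = _BASES[rng.integers(0, 4)]
    while alt == ref:
        alt = _BASES[rng.integers(0, 4)]
    return ref, alt


def make_corpus_and_cases(config: SynthConfig, ontology: Ontology) -> SynthData:
    """Build the annotation corpus, gene–disease table and patient cases.

    Each disease gets ``terms_per_disease`` distinct non-root terms, one
    causal gene and one inheritance mode (AD/AR on autosomes, XLD/XLR on
    X).  Each case perturbs its causal disease's term set by the configured
    noise and spikes one causal variant (genotype consistent with the mode)
    among benign-profile background variants.  Cases whose noisy term set
    comes out empty are skipped with a warning.
    """
    if config.terms_per_disease > config.n_terms - 1:
        raise ValueError(
            f"terms_per_disease={config.terms_per_disease} exceeds available "
            f"non-root terms ({config.n_terms - 1})"
        )
    rng = np.random.default_rng([config.seed, 202])
    non_root = [t for t in sorted(ontology.terms) if t != ontology.root]
    genes = _gene_table(config)
    gene_order = rng.permutation(config.n_genes)

    diseases = []
    hpoa_lines = [
        "#description: synthetic disease-phenotype annotations",
        "#database_id\tdisease_name\tqualifier\thpo_id",
    ]
    gd_lines = ["gene\tdisease_id\tinheritance"]
    for d in range(config.n_diseases):
        disease_id = f"OMIM:{600000 + d}"
        name = f"Synthetic disorder {d + 1}"
        term_idx = rng.choice(len(non_root), size=config.terms_per_disease, replace=False)
        terms = sorted(non_root[j] for j in term_idx)
        gene = genes[gene_order[d % config.n_genes]]
        mode = ("XLD", "XLR")[rng.integers(0, 2)] if gene["on_x"] else ("AD", "AR")[
            rng.integers(0, 2)
        ]
        diseases.append(
            {"id": disease_id, "terms": terms, "gene": gene, "mode": mode}
        )
        for t in terms:
            hpoa_lines.append(f"{disease_id}\t{name}\tP\t{t}")
        gd_lines.append(f"{gene['symbol']}\t{disease_id}\t{mode}")

    # causal genes act through loss of function so null variants earn PVS1
    gene_contexts = {
        d["gene"]["symbol"]: GeneContext(lof_mechanism=True) for d in diseases
    }

    cases: list[SynthCase] = []
    truth: list[tuple[str, str, str]] = []
    for k in range(config.n_cases):
        case_rng = np.random.default_rng([config.seed, 303, k])
        disease = diseases[k % config.n_diseases]
        terms = _noisy_terms(disease["terms"], ontology, non_root, config, case_rng)
        if not terms:
            warnings.warn(
                f"case {k}: phenotype noise removed every term; case skipped"
            )
            continue
        case_id = f"case_{k + 1:04d}"
        variants = _case_variants(disease, genes, config, case_rng)
        cases.append(
            SynthCase(
                case_id=case_id,
                hpo_terms=tuple(terms),
                variants=variants,
                vcf_text=vcf_text(variants),
                causal_disease=disease["id"],
                causal_gene=disease["gene"]["symbol"],
            )
        )
        truth.append((case_id, disease["id"], disease["gene"]["symbol"]))

    return SynthData(
        hpoa_text="\n".join(hpoa_lines) + "\n",
        gene_disease_text="\n".join(gd_lines) + "\n",
        cases=cases,
        gene_contexts=gene_contexts,
        truth_rows=truth,
    )


def _noisy_terms(
    true_terms: list[str],
    ontology: Ontology,
    universe: list[str],
    config: SynthConfig,
    rng: np.random.Generator,
) -> list[str]:
    terms: set[str] = set()
    for t in true_terms:
        if rng.random() < config.p_drop:
            continue
        if rng.random() < config.p_generalize:
            parents = sorted(ontology.parents[t])
            if parents:
                t = parents[int(rng.integers(0, len(parents)))]
        terms.add(t)
    for _ in true_terms:
        if rng.random() < config.p_add:
            terms.add(universe[int(rng.integers(0, len(universe)))])
    terms.discard(ontology.root)
    return sorted(terms)


def _case_variants(
    disease: dict,
    genes: list[dict],
    config: SynthConfig,
    rng: np.random.Generator,
) -> tuple[AnnotatedVariant, ...]:
    gene = disease["gene"]
    mode = disease["mode"]
    genotype = {"AD": "het", "XLD": "het", "AR": "hom_alt", "XLR": "hemi"}[mode]
    ref, alt = _snv(rng)
    causal = AnnotatedVariant(
        chrom=gene["chrom"],
        pos=gene["base_pos"] + int(rng.integers(1, 10_000)),
        ref=ref,
        alt=alt,
        gene=gene["symbol"],
        genotype=genotype,
        pop_af=config.causal_af,
        consequence=config.causal_consequence,
        insilico=round(float(rng.uniform(0.85, 1.0)), 4),
    )
    used_pos = {(causal.chrom, causal.pos)}
    background: list[AnnotatedVariant] = []
    for _ in range(config.n_background_variants):
        g = genes[int(rng.integers(0, len(genes)))]
        pos = g["base_pos"] + int(rng.integers(1, 10_000))
        while (g["chrom"], pos) in used_pos:
            pos = g["base_pos"] + int(rng.integers(1, 10_000))
        used_pos.add((g["chrom"], pos))
        ref, alt = _snv(rng)
        if rng.random() < config.background_common_fraction:
            # common polymorphism: removed by the alpha screen (or BA1)
            background.append(
                AnnotatedVariant(
                    chrom=g["chrom"], pos=pos, ref=ref, alt=alt, gene=g["symbol"],
                    genotype="het",
                    pop_af=round(float(rng.uniform(0.11, 0.5)), 6),
                    consequence="missense_variant",
                    insilico=round(float(rng.uniform(0.0, 0.2)), 4),
                )
            )
        else:
            # rare but benign-looking: survives alpha, scores low
            background.append(
                AnnotatedVariant(
                    chrom=g["chrom"], pos=pos, ref=ref, alt=alt, gene=g["symbol"],
                    genotype="het",
                    pop_af=round(float(rng.uniform(1e-3, 1e-2)), 6),
                    consequence="synonymous_variant",
                    insilico=round(float(rng.uniform(0.0, 0.2)), 4),
                    assertion="benign" if rng.random() < 0.5 else None,
                )
            )
    return tuple([causal, *background])


def write_fixtures(config: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Materialize a full fixture set under ``outdir``.

    Writes hp_toy.obo, annotations.tsv, gene_disease.tsv, config.yaml (gene
    contexts for the rule engine), truth.tsv and cases/<id>.{vcf,hpo}.
    Returns the paths keyed by artifact name.
    """
    outdir = Path(outdir)
    (outdir / "cases").mkdir(parents=True, exist_ok=True)
    obo_text = make_ontology(config)
    ontology = parse_obo(io.StringIO(obo_text))
    data = make_corpus_and_cases(config, ontology)

    paths = {
        "obo": outdir / "hp_toy.obo",
        "hpoa": outdir / "annotations.tsv",
        "gene_disease": outdir / "gene_disease.tsv",
        "config": outdir / "config.yaml",
        "truth": outdir / "truth.tsv",
        "cases": outdir / "cases",
    }
    paths["obo"].write_text(obo_text)
    paths["hpoa"].write_text(data.hpoa_text)
    paths["gene_disease"].write_text(data.gene_disease_text)
    lof_genes = sorted(g for g, ctx in data.gene_contexts.items() if ctx.lof_mechanism)
    paths["config"].write_text(
        "rules: {}\ngene_contexts:\n  lof_mechanism:\n"
        + "".join(f"    - {g}\n" for g in lof_genes)
    )
    paths["truth"].write_text(
        "case_id\tcausal_disease\tcausal_gene\n"
        + "".join("\t".join(row) + "\n" for row in data.truth_rows)
    )
    for case in data.cases:
        (outdir / "cases" / f"{case.case_id}.vcf").write_text(case.vcf_text)
        (outdir / "cases" / f"{case.case_id}.hpo").write_text(
            "\n".join(case.hpo_terms) + "\n"
        )
    return paths
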