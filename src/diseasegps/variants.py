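"""Annotated-variant ingestion and screening.

Reads annotated variants from VCF (via cyvcf2) or an ANNOVAR-style
tab-delimited table, then applies two screens in fixed order:

1. population allele frequency: keep variants with AF missing or ≤ α
   (α defaults to 0.1; absence from population databases is treated as
   rarity, not as AF 0);
2. inheritance mode: per gene, the observed genotypes must be consistent
   with at least one disease-linked mode (AD/AR/XLD/XLR); the recessive
   compound-het heuristic is ≥2 distinct heterozygous variants without
   phasing.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .profiles import VALID_MODES

logger = logging.getLogger(__name__)

GENOTYPES = {"het", "hom_alt", "hemi"}

#: semantic field -> default VCF INFO key / TSV column name
DEFAULT_FIELD_MAP: dict[str, str] = {
    "gene": "GENE",
    "af": "AF_POP",
    "consequence": "CSQ",
    "insilico": "DMG",
    "assertion": "CLNSIG",
    "aa_change": "AACHG",
    "residue": "RES",
    "case_control": "CASECTRL",
    "control_hom": "CTRLHOM",
    "repeat_region": "REPEAT",
    "splice_impact": "SPLICE",
    "evidence": "ACMG",
}

__all__ = [
    "AnnotatedVariant",
    "FilterParams",
    "DEFAULT_FIELD_MAP",
    "read_variants",
    "filter_af",
    "filter_inheritance",
]


@dataclass(frozen=True)
class AnnotatedVariant:
    """One biallelic variant call with its annotations.

    ``pop_af`` of ``None`` means the variant is absent from population
    databases — deliberately distinct from an observed frequency of 0.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    genotype: str = "het"
    pop_af: float | None = None
    consequence: str | None = None
    insilico: float | None = None
    assertion: str | None = None
    aa_change: str | None = None
    residue: int | None = None
    case_control: bool = False
    control_hom: bool = False
    repeat_region: bool = False
    splice_impact: bool = False
    evidence_codes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical at {self.chrom}:{self.pos}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {sorted(GENOTYPES)}, got {self.genotype!r}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class FilterParams:
    """α screening threshold for population AF plus inheritance toggle."""

    alpha: float = 0.1
    inheritance: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")


def _per_allele(value, index: int, n_alts: int):
    """Pick the annotation slice for ALT ``index`` from a Number=A INFO value."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        return value[index] if index < len(value) else None
    if n_alts > 1 and isinstance(value, str) and "," in value:
        parts = value.split(",")
        return parts[index] if index < len(parts) else None
    return value


def _clean_float(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, str):
        value = value.strip()
        if value in {"", "."}:
            return None
        value = float(value)
    value = float(value)
    return None if math.isnan(value) else value


def _clean_str(value) -> str | None:
    if value is None:
        return None
    s = str(value).strip()
    return s or None


def _genotype_for_alt(gt_alleles: Sequence[int], allele_index: int) -> str | None:
    count = sum(1 for a in gt_alleles if a == allele_index)
    if count == 0:
        return None
    if len(gt_alleles) == 1:
        return "hemi"
    return "hom_alt" if count >= 2 else "het"


def _check_field_map(field_map: Mapping[str, str]) -> dict[str, str]:
    merged = dict(DEFAULT_FIELD_MAP)
    merged.update(field_map or {})
    missing = [f for f in ("gene", "af") if not merged.get(f)]
    if missing:
        raise ValueError(f"field map is missing required field names: {missing}")
    return merged


def _evidence_tuple(raw) -> tuple[str, ...] | None:
    s = _clean_str(raw)
    if s is None:
        return None
    return tuple(code.strip().upper() for code in s.split(",") if code.strip())


def read_variants(
    path: str,
    format: str = "vcf",
    field_map: Mapping[str, str] | None = None,
) -> list[AnnotatedVariant]:
    """Read annotated variants from a VCF or tab-delimited table.

    Multiallelic VCF records are split into one variant per ALT allele, with
    Number=A annotations distributed by allele index and the genotype taken
    from the first sample's GT.  Unparsable rows are skipped with a warning.
    """
    fmap = _check_field_map(field_map or {})
    if format == "vcf":
        return _read_vcf(path, fmap)
    if format == "tsv":
        return _read_tsv(path, fmap)
    raise ValueError(f"unknown variant format {format!r}; expected 'vcf' or 'tsv'")


def _read_vcf(path: str, fmap: Mapping[str, str]) -> list[AnnotatedVariant]:
    from cyvcf2 import VCF

    out: list[AnnotatedVariant] = []
    n_skipped = 0
    vcf = VCF(path)
    has_sample = len(vcf.samples) > 0
    for record in vcf:
        alts = record.ALT or []
        n_alts = len(alts)
        info = record.INFO
        if has_sample:
            gt_alleles = [a for a in record.genotypes[0][:-1] if a is not None and a >= 0]
        else:
            gt_alleles = []
        for i, alt in enumerate(alts):
            try:
                if has_sample:
                    genotype = _genotype_for_alt(gt_alleles, i + 1)
                    if genotype is None:
                        continue  # first sample does not carry this allele
                else:
                    genotype = "het"
                gene = _clean_str(_per_allele(info.get(fmap["gene"]), i, n_alts))
                if gene is None:
                    raise ValueError("missing gene annotation")
                out.append(
                    AnnotatedVariant(
                        chrom=record.CHROM,
                        pos=record.POS,
                        ref=record.REF,
                        alt=alt,
                        gene=gene,
                        genotype=genotype,
                        pop_af=_clean_float(_per_allele(info.get(fmap["af"]), i, n_alts)),
                        consequence=_clean_str(_per_allele(info.get(fmap["consequence"]), i, n_alts)),
                        insilico=_clean_float(_per_allele(info.get(fmap["insilico"]), i, n_alts)),
                        assertion=_clean_str(info.get(fmap["assertion"])),
                        aa_change=_clean_str(_per_allele(info.get(fmap["aa_change"]), i, n_alts)),
                        residue=_to_int(info.get(fmap["residue"])),
                        case_control=bool(info.get(fmap["case_control"])),
                        control_hom=bool(info.get(fmap["control_hom"])),
                        repeat_region=bool(info.get(fmap["repeat_region"])),
                        splice_impact=bool(info.get(fmap["splice_impact"])),
                        evidence_codes=_evidence_tuple(info.get(fmap["evidence"])),
                    )
                )
            except (ValueError, TypeError) as exc:
                n_skipped += 1
                warnings.warn(
                    f"skipping unparsable record {record.CHROM}:{record.POS} alt {alt}: {exc}"
                )
    if n_skipped:
        logger.info("read_variants: skipped %d unparsable record(s)", n_skipped)
    return out


def _to_int(value) -> int | None:
    f = _clean_float(value)
    return None if f is None else int(f)


def _read_tsv(path: str, fmap: Mapping[str, str]) -> list[AnnotatedVariant]:
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for f in ("gene", "af"):
        if fmap[f] not in table.columns:
            raise ValueError(f"variant table is missing mapped column {fmap[f]!r} for field {f!r}")

    def col(row, semantic):
        name = fmap.get(semantic)
        return row.get(name) if name in table.columns else None

    out: list[AnnotatedVariant] = []
    n_skipped = 0
    for idx, row in table.iterrows():
        try:
            genotype = _clean_str(row.get("genotype")) or "het"
            genotype = {"hom": "hom_alt", "1/1": "hom_alt", "0/1": "het", "1": "hemi"}.get(
                genotype, genotype
            )
            gene = _clean_str(col(row, "gene"))
            if not gene:
                raise ValueError("missing gene annotation")
            out.append(
                AnnotatedVariant(
                    chrom=_clean_str(row.get("chrom")) or "1",
                    pos=int(row.get("pos", 1)),
                    ref=(_clean_str(row.get("ref")) or "N").upper(),
                    alt=(_clean_str(row.get("alt")) or "A").upper(),
                    gene=gene,
                    genotype=genotype,
                    pop_af=_clean_float(col(row, "af")),
                    consequence=_clean_str(col(row, "consequence")),
                    insilico=_clean_float(col(row, "insilico")),
                    assertion=_clean_str(col(row, "assertion")),
                    aa_change=_clean_str(col(row, "aa_change")),
                    residue=_to_int(col(row, "residue")),
                    case_control=_truthy(col(row, "case_control")),
                    control_hom=_truthy(col(row, "control_hom")),
                    repeat_region=_truthy(col(row, "repeat_region")),
                    splice_impact=_truthy(col(row, "splice_impact")),
                    evidence_codes=_evidence_tuple(col(row, "evidence")),
                )
            )
        except (ValueError, TypeError) as exc:
            n_skipped += 1
            warnings.warn(f"skipping unparsable table row {idx}: {exc}")
    if n_skipped:
        logger.info("read_variants: skipped %d unparsable row(s)", n_skipped)
    return out


def _truthy(value) -> bool:
    s = _clean_str(value)
    return s is not None and s.lower() in {"1", "true", "yes", "y"}


def filter_af(
    variants: Sequence[AnnotatedVariant], params: FilterParams | None = None
) -> list[AnnotatedVariant]:
    """Keep variants with missing AF or AF ≤ α (inclusive boundary)."""
    params = params or FilterParams()
    kept = [v for v in variants if v.pop_af is None or v.pop_af <= params.alpha]
    removed = len(variants) - len(kept)
    if removed:
        logger.info("filter_af: removed %d variant(s) with AF > %g", removed, params.alpha)
    return kept


def _gene_qualifies(
    variants: Sequence[AnnotatedVariant], modes: set[str], sex: str | None
) -> bool:
    genotypes = [v.genotype for v in variants]
    for mode in modes:
        if mode in {"AD", "XLD"}:
            return True
        if mode == "AR":
            n_hom = genotypes.count("hom_alt")
            n_het = len({v.key for v in variants if v.genotype == "het"})
            if n_hom >= 1 or n_het >= 2:
                return True
        elif mode == "XLR":
            if any(g in {"hemi", "hom_alt"} for g in genotypes):
                return True
            if sex is None and "het" in genotypes:
                return True
    return False


def filter_inheritance(
    variants: Sequence[AnnotatedVariant],
    disease_modes: Mapping[str, set[str] | Iterable[str]],
    sex: str | None = None,
) -> dict[str, list[AnnotatedVariant]]:
    """Group variants by gene and drop genes inconsistent with their modes.

    Genes without mode data pass through unfiltered; unknown mode strings
    warn and count as no-data.  A qualifying gene keeps all its variants.
    """
    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v in variants:
        by_gene.setdefault(v.gene, []).append(v)

    out: dict[str, list[AnnotatedVariant]] = {}
    for gene, vs in by_gene.items():
        raw_modes = set(disease_modes.get(gene) or set())
        unknown = raw_modes - VALID_MODES
        if unknown:
            warnings.warn(
                f"gene {gene}: unknown inheritance mode(s) {sorted(unknown)}; treated as no data"
            )
        modes = raw_modes & VALID_MODES
        if not modes or _gene_qualifies(vs, modes, sex):
            out[gene] = vs
    return out
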