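"""ACMG-AMP evidence assignment and Bayesian combination.

A transparent rule table assigns the 17 evidence codes the engine scores
(PVS1; PS1, PS4; PM1, PM2, PM4, PM5; PP2, PP3, PP5; BA1; BS1, BS2; BP1,
BP3, BP4, BP6, BP7) from fields already present on the annotated variant.
Rules whose inputs are missing stay silent.  Precomputed evidence codes
(e.g. InterVar output ingested via an ``ACMG=PVS1,PM2`` column) bypass the
rule table entirely.

Evidence combines into a posterior pathogenicity probability via
exponentially tiered odds: with O the odds of pathogenicity for one
very-strong item (default 350) and prior P (default 0.1),

    odds = O ** (PP/8 + PM/4 + PS/2 + PVS − BP/8 − BS/2)
    posterior = odds·P / ((odds − 1)·P + 1)

BA1 is stand-alone: it forces classification "benign" with posterior 0
rather than entering the exponent.  The per-gene score is the maximum
posterior among the gene's surviving variants.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import yaml

from .variants import AnnotatedVariant

NULL_CONSEQUENCES = {
    "stop_gained",
    "frameshift_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
}
INFRAME_CONSEQUENCES = {"inframe_insertion", "inframe_deletion"}
MISSENSE = "missense_variant"
SYNONYMOUS = "synonymous_variant"
STOP_LOST = "stop_lost"

#: code -> strength tier attribute on EvidenceVector
CODE_TIERS: dict[str, str] = {
    "PVS1": "pvs",
    "PS1": "ps",
    "PS4": "ps",
    "PM1": "pm",
    "PM2": "pm",
    "PM4": "pm",
    "PM5": "pm",
    "PP2": "pp",
    "PP3": "pp",
    "PP5": "pp",
    "BA1": "ba",
    "BS1": "bs",
    "BS2": "bs",
    "BP1": "bp",
    "BP3": "bp",
    "BP4": "bp",
    "BP6": "bp",
    "BP7": "bp",
}
TIER_CAPS = {"pvs": 1, "ps": 2, "pm": 4, "pp": 3, "ba": 1, "bs": 2, "bp": 5}

__all__ = [
    "EvidenceVector",
    "BayesParams",
    "GeneContext",
    "RulesConfig",
    "GeneScore",
    "VariantSupport",
    "assign_evidence",
    "posterior_probability",
    "gene_scores",
    "CODE_TIERS",
]


@dataclass(frozen=True)
class EvidenceVector:
    """Counts of triggered ACMG codes by strength tier."""

    pvs: int = 0
    ps: int = 0
    pm: int = 0
    pp: int = 0
    ba: int = 0
    bs: int = 0
    bp: int = 0
    triggered: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for tier, cap in TIER_CAPS.items():
            count = getattr(self, tier)
            if not 0 <= count <= cap:
                raise ValueError(f"{tier} count {count} outside [0, {cap}]")

    @classmethod
    def from_codes(cls, codes: Iterable[str]) -> "EvidenceVector":
        known = []
        for code in codes:
            code = code.strip().upper()
            if code not in CODE_TIERS:
                warnings.warn(f"ignoring unsupported evidence code {code!r}")
                continue
            known.append(code)
        triggered = frozenset(known)
        counts: dict[str, int] = {t: 0 for t in TIER_CAPS}
        for code in triggered:
            counts[CODE_TIERS[code]] += 1
        return cls(triggered=triggered, **counts)


@dataclass(frozen=True)
class BayesParams:
    """Prior, very-strong odds, and classification bands."""

    prior: float = 0.1
    odds_pathogenic: float = 350.0
    pathogenic_min: float = 0.99
    likely_pathogenic_min: float = 0.90
    likely_benign_max: float = 0.10
    benign_max: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 < self.prior < 1.0:
            raise ValueError(f"prior must lie strictly in (0, 1), got {self.prior}")
        if self.odds_pathogenic <= 1.0:
            raise ValueError("odds_pathogenic must exceed 1")
        bands = (
            self.benign_max,
            self.likely_benign_max,
            self.likely_pathogenic_min,
            self.pathogenic_min,
        )
        if list(bands) != sorted(bands):
            raise ValueError(f"classification bands out of order: {bands}")


@dataclass(frozen=True)
class GeneContext:
    """Gene-level knowledge the rule table consults."""

    lof_mechanism: bool = False
    missense_constrained: bool = False
    truncating_mechanism: bool = False
    pathogenic_aa_changes: frozenset[str] = frozenset()
    pathogenic_residues: frozenset[int] = frozenset()
    hotspots: tuple[tuple[int, int], ...] = ()
    bs1_max_af: float | None = None


@dataclass(frozen=True)
class RulesConfig:
    """Per-rule enable flags and thresholds; malformed config fails at load."""

    enabled: frozenset[str] = frozenset(CODE_TIERS)
    pm2_max_af: float = 1e-4
    ba1_min_af: float = 0.05
    pp3_min_score: float = 0.8
    bp4_max_score: float = 0.2

    def __post_init__(self) -> None:
        unknown = set(self.enabled) - set(CODE_TIERS)
        if unknown:
            raise ValueError(f"rules config enables unknown codes: {sorted(unknown)}")
        for name in ("pm2_max_af", "ba1_min_af"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @classmethod
    def from_dict(cls, data: Mapping) -> "RulesConfig":
        if not isinstance(data, Mapping):
            raise ValueError("rules config must be a mapping")
        kwargs: dict = {}
        disabled = {c.upper() for c in data.get("disabled", [])}
        enabled = data.get("enabled")
        if enabled is not None:
            kwargs["enabled"] = frozenset(c.upper() for c in enabled)
        else:
            kwargs["enabled"] = frozenset(CODE_TIERS) - disabled
        for key in ("pm2_max_af", "ba1_min_af", "pp3_min_score", "bp4_max_score"):
            if key in data:
                kwargs[key] = float(data[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "RulesConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data.get("rules", data))


def _is_pathogenic_assertion(assertion: str | None) -> bool:
    if assertion is None:
        return False
    s = assertion.strip().lower().replace(" ", "_")
    return s in {"pathogenic", "likely_pathogenic"}


def _is_benign_assertion(assertion: str | None) -> bool:
    if assertion is None:
        return False
    s = assertion.strip().lower().replace(" ", "_")
    return s in {"benign", "likely_benign"}


def assign_evidence(
    variant: AnnotatedVariant,
    gene_context: GeneContext | None = None,
    rules_config: RulesConfig | None = None,
) -> EvidenceVector:
    """Apply the rule table to one variant; silent where inputs are missing.

    If the variant carries precomputed evidence codes they are ingested
    directly and the rule table is skipped.
    """
    if variant.evidence_codes is not None:
        return EvidenceVector.from_codes(variant.evidence_codes)

    ctx = gene_context or GeneContext()
    rules = rules_config or RulesConfig()
    csq = variant.consequence
    af = variant.pop_af
    fired: set[str] = set()

    def on(code: str) -> bool:
        return code in rules.enabled

    if on("PVS1") and csq in NULL_CONSEQUENCES and ctx.lof_mechanism:
        fired.add("PVS1")
    if on("PS1") and variant.aa_change and variant.aa_change in ctx.pathogenic_aa_changes:
        fired.add("PS1")
    if on("PS4") and variant.case_control:
        fired.add("PS4")
    if on("PM1") and any(lo <= variant.pos <= hi for lo, hi in ctx.hotspots):
        fired.add("PM1")
    if on("PM2") and (af is None or af < rules.pm2_max_af):
        fired.add("PM2")
    if on("PM4") and (
        csq == STOP_LOST or (csq in INFRAME_CONSEQUENCES and not variant.repeat_region)
    ):
        fired.add("PM4")
    if (
        on("PM5")
        and csq == MISSENSE
        and variant.residue is not None
        and variant.residue in ctx.pathogenic_residues
        and (variant.aa_change is None or variant.aa_change not in ctx.pathogenic_aa_changes)
    ):
        fired.add("PM5")
    if on("PP2") and csq == MISSENSE and ctx.missense_constrained:
        fired.add("PP2")
    if on("PP3") and variant.insilico is not None and variant.insilico >= rules.pp3_min_score:
        fired.add("PP3")
    if on("PP5") and _is_pathogenic_assertion(variant.assertion):
        fired.add("PP5")

    if on("BA1") and af is not None and af > rules.ba1_min_af:
        fired.add("BA1")
    if on("BS1") and af is not None and ctx.bs1_max_af is not None and af > ctx.bs1_max_af:
        fired.add("BS1")
    if on("BS2") and variant.control_hom:
        fired.add("BS2")
    if on("BP1") and csq == MISSENSE and ctx.truncating_mechanism:
        fired.add("BP1")
    if on("BP3") and csq in INFRAME_CONSEQUENCES and variant.repeat_region:
        fired.add("BP3")
    if on("BP4") and variant.insilico is not None and variant.insilico <= rules.bp4_max_score:
        fired.add("BP4")
    if on("BP6") and _is_benign_assertion(variant.assertion):
        fired.add("BP6")
    if on("BP7") and csq == SYNONYMOUS and not variant.splice_impact:
        fired.add("BP7")

    return EvidenceVector.from_codes(fired)


CLASS_PATHOGENIC = "pathogenic"
CLASS_LIKELY_PATHOGENIC = "likely_pathogenic"
CLASS_UNCERTAIN = "uncertain_significance"
CLASS_LIKELY_BENIGN = "likely_benign"
CLASS_BENIGN = "benign"


def posterior_probability(
    ev: EvidenceVector, params: BayesParams | None = None
) -> tuple[float, str]:
    """Posterior pathogenicity probability and classification label.

    Benign evidence enters as negative exponent terms; BA1 overrides
    everything (posterior 0, label benign).
    """
    params = params or BayesParams()
    if ev.ba > 0:
        return 0.0, CLASS_BENIGN
    exponent = ev.pp / 8 + ev.pm / 4 + ev.ps / 2 + ev.pvs - ev.bp / 8 - ev.bs / 2
    odds = params.odds_pathogenic ** exponent
    posterior = odds * params.prior / ((odds - 1.0) * params.prior + 1.0)
    if posterior >= params.pathogenic_min:
        label = CLASS_PATHOGENIC
    elif posterior >= params.likely_pathogenic_min:
        label = CLASS_LIKELY_PATHOGENIC
    elif posterior < params.benign_max:
        label = CLASS_BENIGN
    elif posterior <= params.likely_benign_max:
        label = CLASS_LIKELY_BENIGN
    else:
        label = CLASS_UNCERTAIN
    return posterior, label


@dataclass(frozen=True)
class VariantSupport:
    key: str
    posterior: float
    evidence: tuple[str, ...]


@dataclass(frozen=True)
class GeneScore:
    """Per-gene pathogenicity: the maximum posterior over its variants."""

    gene: str
    score: float
    supporting_variants: tuple[VariantSupport, ...] = ()


def gene_scores(
    variants: Sequence[AnnotatedVariant],
    params: BayesParams | None = None,
    rules_config: RulesConfig | None = None,
    gene_contexts: Mapping[str, GeneContext] | None = None,
) -> dict[str, GeneScore]:
    """Score every gene carried by the (already filtered) variants.

    Order-independent: genes sorted lexicographically, supporting variants
    by descending posterior then variant key.
    """
    params = params or BayesParams()
    contexts = gene_contexts or {}
    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v in variants:
        by_gene.setdefault(v.gene, []).append(v)

    out: dict[str, GeneScore] = {}
    for gene in sorted(by_gene):
        support = []
        for v in by_gene[gene]:
            ev = assign_evidence(v, contexts.get(gene), rules_config)
            posterior, _ = posterior_probability(ev, params)
            support.append(VariantSupport(v.key, posterior, tuple(sorted(ev.triggered))))
        support.sort(key=lambda s: (-s.posterior, s.key))
        out[gene] = GeneScore(gene=gene, score=support[0].posterior, supporting_variants=tuple(support))
    return out
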