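"""ACMG rule table, Bayesian evidence combination and gene scores."""
import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diseasegps.acmg import (
    BayesParams,
    EvidenceVector,
    GeneContext,
    RulesConfig,
    assign_evidence,
    gene_scores,
    posterior_probability,
)
from diseasegps.variants import AnnotatedVariant


def oracle_posterior(pvs, ps, pm, pp, bs, bp, prior=0.1, odds_vs=350.0):
    """Independent evaluation: per-item odds multiplied one factor at a time."""
    odds = 1.0
    for _ in range(pvs):
        odds *= odds_vs
    for _ in range(ps):
        odds *= odds_vs ** (1 / 2)
    for _ in range(pm):
        odds *= odds_vs ** (1 / 4)
    for _ in range(pp):
        odds *= odds_vs ** (1 / 8)
    for _ in range(bs):
        odds /= odds_vs ** (1 / 2)
    for _ in range(bp):
        odds /= odds_vs ** (1 / 8)
    return 1.0 / (1.0 + (1.0 - prior) / (prior * odds))


def lattice():
    return itertools.product(range(2), range(3), range(5), range(4), range(3), range(6))


class TestPosterior:
    def test_no_evidence_returns_prior(self):
        post, label = posterior_probability(EvidenceVector())
        assert post == pytest.approx(0.1)
        assert label == "likely_benign"  # 0.1 falls on the likely-benign bound

    def test_strong_pair_cancels(self):
        ev = EvidenceVector(ps=1, bs=1)
        post, _ = posterior_probability(ev)
        assert post == pytest.approx(0.1)

    def test_pvs1_plus_pm2_is_pathogenic(self):
        ev = EvidenceVector.from_codes(["PVS1", "PM2"])
        post, label = posterior_probability(ev)
        assert post == pytest.approx(oracle_posterior(1, 0, 1, 0, 0, 0), abs=1e-12)
        assert post > 0.99 and label == "pathogenic"

    def test_ba1_standalone_override(self):
        ev = EvidenceVector.from_codes(["BA1", "PVS1", "PM2"])
        post, label = posterior_probability(ev)
        assert post == 0.0 and label == "benign"

    def test_oracle_equivalence_full_lattice(self):
        for pvs, ps, pm, pp, bs, bp in lattice():
            ev = EvidenceVector(pvs=pvs, ps=ps, pm=pm, pp=pp, bs=bs, bp=bp)
            post, _ = posterior_probability(ev)
            assert post == pytest.approx(
                oracle_posterior(pvs, ps, pm, pp, bs, bp), abs=1e-12
            )
            assert 0.0 < post < 1.0

    @given(
        pvs=st.integers(0, 1),
        ps=st.integers(0, 2),
        pm=st.integers(0, 4),
        pp=st.integers(0, 3),
        bs=st.integers(0, 2),
        bp=st.integers(0, 5),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotonicity(self, pvs, ps, pm, pp, bs, bp):
        base, _ = posterior_probability(
            EvidenceVector(pvs=pvs, ps=ps, pm=pm, pp=pp, bs=bs, bp=bp)
        )
        if pm < 4:
            more, _ = posterior_probability(
                EvidenceVector(pvs=pvs, ps=ps, pm=pm + 1, pp=pp, bs=bs, bp=bp)
            )
            assert more >= base
        if bp < 5:
            less, _ = posterior_probability(
                EvidenceVector(pvs=pvs, ps=ps, pm=pm, pp=pp, bs=bs, bp=bp + 1)
            )
            assert less <= base

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BayesParams(prior=0.0)
        with pytest.raises(ValueError):
            BayesParams(odds_pathogenic=0.5)


class TestEvidenceVector:
    def test_from_codes_counts_tiers(self):
        ev = EvidenceVector.from_codes(["PVS1", "PM2", "PM1", "PP3", "BP7"])
        assert (ev.pvs, ev.pm, ev.pp, ev.bp) == (1, 2, 1, 1)
        assert ev.triggered == {"PVS1", "PM2", "PM1", "PP3", "BP7"}

    def test_unknown_code_warns_and_is_dropped(self):
        with pytest.warns(UserWarning, match="PS3"):
            ev = EvidenceVector.from_codes(["PS3", "PM2"])
        assert ev.triggered == {"PM2"}

    def test_tier_caps_enforced(self):
        with pytest.raises(ValueError):
            EvidenceVector(pvs=2)


def _variant(**kw):
    base = dict(chrom="1", pos=100, ref="A", alt="T", gene="G1")
    base.update(kw)
    return AnnotatedVariant(**base)


class TestAssignEvidence:
    def test_stop_gain_rare_in_lof_gene(self):
        v = _variant(consequence="stop_gained", pop_af=None)
        ev = assign_evidence(v, GeneContext(lof_mechanism=True))
        assert {"PVS1", "PM2"} <= ev.triggered

    def test_common_synonymous(self):
        v = _variant(consequence="synonymous_variant", pop_af=0.2)
        ev = assign_evidence(v)
        assert {"BA1", "BP7"} <= ev.triggered

    def test_all_optional_fields_missing_pm2_only(self):
        # AF absent is itself rarity evidence; everything else stays silent
        ev = assign_evidence(_variant())
        assert ev.triggered == {"PM2"}

    def test_silent_without_gene_context(self):
        v = _variant(consequence="missense_variant", pop_af=0.01)
        ev = assign_evidence(v)
        assert ev.triggered == set()

    def test_disabled_rule_never_fires(self):
        v = _variant(consequence="stop_gained", pop_af=None)
        rules = RulesConfig.from_dict({"disabled": ["PVS1"]})
        ev = assign_evidence(v, GeneContext(lof_mechanism=True), rules)
        assert "PVS1" not in ev.triggered and "PM2" in ev.triggered

    def test_precomputed_codes_bypass_rules(self):
        v = _variant(pop_af=0.5, evidence_codes=("PVS1", "PM2"))
        ev = assign_evidence(v)
        assert ev.triggered == {"PVS1", "PM2"}

    def test_pm5_different_missense_at_known_residue(self):
        ctx = GeneContext(
            pathogenic_aa_changes=frozenset({"p.R100C"}),
            pathogenic_residues=frozenset({100}),
        )
        same = _variant(consequence="missense_variant", aa_change="p.R100C",
                        residue=100, pop_af=0.01)
        different = _variant(consequence="missense_variant", aa_change="p.R100H",
                             residue=100, pop_af=0.01)
        assert "PS1" in assign_evidence(same, ctx).triggered
        assert "PM5" in assign_evidence(different, ctx).triggered
        assert "PM5" not in assign_evidence(same, ctx).triggered

    def test_insilico_thresholds(self):
        damaging = _variant(insilico=0.95, pop_af=0.01)
        benign = _variant(insilico=0.05, pop_af=0.01)
        assert "PP3" in assign_evidence(damaging).triggered
        assert "BP4" in assign_evidence(benign).triggered

    def test_malformed_rules_config_fails_at_load(self):
        with pytest.raises(ValueError):
            RulesConfig.from_dict({"enabled": ["PVS9"]})
        with pytest.raises(ValueError):
            RulesConfig.from_dict({"ba1_min_af": 2.0})


class TestGeneScores:
    def test_max_over_variant_posteriors(self):
        vs = [
            _variant(pos=1, evidence_codes=("PVS1", "PM2")),
            _variant(pos=2, evidence_codes=()),
        ]
        scores = gene_scores(vs)
        expected = oracle_posterior(1, 0, 1, 0, 0, 0)
        assert scores["G1"].score == pytest.approx(expected)
        assert len(scores["G1"].supporting_variants) == 2

    def test_two_genes_independent(self):
        vs = [
            _variant(pos=1, gene="G1", evidence_codes=("PM2",)),
            _variant(pos=2, gene="G2", evidence_codes=("BP7",)),
        ]
        scores = gene_scores(vs)
        assert set(scores) == {"G1", "G2"}
        assert scores["G1"].score > scores["G2"].score

    def test_permutation_invariant(self):
        vs = [
            _variant(pos=p, evidence_codes=codes)
            for p, codes in [(1, ("PM2",)), (2, ("PVS1",)), (3, ("BP7",))]
        ]
        assert gene_scores(vs) == gene_scores(list(reversed(vs)))

    def test_empty_input_empty_map(self):
        assert gene_scores([]) == {}
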