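"""Variant ingestion (VCF/TSV) and the AF + inheritance screens."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diseasegps.variants import (
    AnnotatedVariant,
    FilterParams,
    filter_af,
    filter_inheritance,
    read_variants,
)

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##INFO=<ID=GENE,Number=A,Type=String,Description="g">
##INFO=<ID=AF_POP,Number=A,Type=Float,Description="af">
##INFO=<ID=CSQ,Number=A,Type=String,Description="c">
##INFO=<ID=ACMG,Number=1,Type=String,Description="codes">
##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""


def _write_vcf(tmp_path, body):
    path = tmp_path / "case.vcf"
    path.write_text(VCF_HEADER + body)
    return str(path)


class TestReadVcf:
    def test_het_with_af(self, tmp_path):
        path = _write_vcf(
            tmp_path, "1\t100\t.\tA\tT\t.\t.\tGENE=G1;AF_POP=0.01\tGT\t0/1\n"
        )
        [v] = read_variants(path, "vcf")
        assert (v.genotype, v.pop_af, v.gene) == ("het", pytest.approx(0.01), "G1")

    def test_multiallelic_split(self, tmp_path):
        path = _write_vcf(
            tmp_path,
            "1\t100\t.\tA\tC,T\t.\t.\tGENE=G1,G1;AF_POP=0.01,0.3\tGT\t1/2\n",
        )
        vs = read_variants(path, "vcf")
        assert len(vs) == 2
        assert {v.alt for v in vs} == {"C", "T"}
        assert all(v.chrom == "1" and v.pos == 100 and v.ref == "A" for v in vs)
        by_alt = {v.alt: v for v in vs}
        assert by_alt["C"].pop_af == pytest.approx(0.01)
        assert by_alt["T"].pop_af == pytest.approx(0.3)

    def test_missing_af_is_none_not_zero(self, tmp_path):
        path = _write_vcf(tmp_path, "1\t100\t.\tA\tT\t.\t.\tGENE=G1\tGT\t0/1\n")
        [v] = read_variants(path, "vcf")
        assert v.pop_af is None

    def test_hom_and_hemi_genotypes(self, tmp_path):
        path = _write_vcf(
            tmp_path,
            "1\t100\t.\tA\tT\t.\t.\tGENE=G1\tGT\t1/1\n"
            "1\t200\t.\tG\tC\t.\t.\tGENE=G2\tGT\t1\n",
        )
        vs = read_variants(path, "vcf")
        assert [v.genotype for v in vs] == ["hom_alt", "hemi"]

    def test_precomputed_codes_parsed(self, tmp_path):
        path = _write_vcf(
            tmp_path, "1\t100\t.\tA\tT\t.\t.\tGENE=G1;ACMG=PVS1,PM2\tGT\t0/1\n"
        )
        [v] = read_variants(path, "vcf")
        assert v.evidence_codes == ("PVS1", "PM2")

    def test_row_missing_gene_skipped_with_warning(self, tmp_path):
        path = _write_vcf(
            tmp_path,
            "1\t100\t.\tA\tT\t.\t.\tAF_POP=0.01\tGT\t0/1\n"
            "1\t200\t.\tG\tC\t.\t.\tGENE=G1\tGT\t0/1\n",
        )
        with pytest.warns(UserWarning, match="skipping"):
            vs = read_variants(path, "vcf")
        assert len(vs) == 1 and vs[0].gene == "G1"

    def test_unmapped_required_field_is_hard_error(self, tmp_path):
        path = _write_vcf(tmp_path, "")
        with pytest.raises(ValueError, match="af"):
            read_variants(path, "vcf", {"af": ""})


class TestReadTsv:
    def test_basic_table(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(
            "chrom\tpos\tref\talt\tGENE\tAF_POP\tgenotype\tCSQ\n"
            "1\t100\tA\tT\tG1\t0.01\thet\tmissense_variant\n"
            "2\t200\tG\tC\tG2\t.\thom\tstop_gained\n"
        )
        vs = read_variants(str(path), "tsv")
        assert vs[0].pop_af == pytest.approx(0.01)
        assert vs[1].pop_af is None
        assert vs[1].genotype == "hom_alt"

    def test_missing_mapped_column_hard_error(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text("chrom\tpos\tref\talt\tGENE\n1\t100\tA\tT\tG1\n")
        with pytest.raises(ValueError, match="AF_POP"):
            read_variants(str(path), "tsv")


def _v(gene="G1", pos=100, af=None, genotype="het"):
    return AnnotatedVariant(
        chrom="1", pos=pos, ref="A", alt="T", gene=gene, genotype=genotype, pop_af=af
    )


class TestFilterAf:
    def test_boundary_and_missing(self):
        vs = [_v(pos=1, af=None), _v(pos=2, af=0.05), _v(pos=3, af=0.1), _v(pos=4, af=0.2)]
        kept = filter_af(vs, FilterParams(alpha=0.1))
        assert [v.pos for v in kept] == [1, 2, 3]

    def test_idempotent(self):
        vs = [_v(pos=p, af=a) for p, a in [(1, 0.01), (2, 0.5), (3, None)]]
        once = filter_af(vs, FilterParams(alpha=0.1))
        assert filter_af(once, FilterParams(alpha=0.1)) == once

    @given(
        afs=st.lists(
            st.one_of(st.none(), st.floats(0, 1, allow_nan=False)), max_size=20
        ),
        a1=st.floats(0, 1, allow_nan=False),
        a2=st.floats(0, 1, allow_nan=False),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_alpha(self, afs, a1, a2):
        lo, hi = sorted((a1, a2))
        vs = [_v(pos=i + 1, af=a) for i, a in enumerate(afs)]
        kept_lo = filter_af(vs, FilterParams(alpha=lo))
        kept_hi = filter_af(vs, FilterParams(alpha=hi))
        assert set(v.pos for v in kept_lo) <= set(v.pos for v in kept_hi)


class TestFilterInheritance:
    def test_ar_single_het_dropped(self):
        out = filter_inheritance([_v()], {"G1": {"AR"}})
        assert "G1" not in out

    def test_ar_compound_het_kept(self):
        vs = [_v(pos=1), _v(pos=2)]
        out = filter_inheritance(vs, {"G1": {"AR"}})
        assert out["G1"] == vs

    def test_ar_hom_kept(self):
        out = filter_inheritance([_v(genotype="hom_alt")], {"G1": {"AR"}})
        assert "G1" in out

    def test_ad_single_het_kept(self):
        out = filter_inheritance([_v()], {"G1": {"AD"}})
        assert "G1" in out

    def test_xlr_hemi_kept_het_dropped_for_female(self):
        assert "G1" in filter_inheritance([_v(genotype="hemi")], {"G1": {"XLR"}})
        assert "G1" not in filter_inheritance([_v()], {"G1": {"XLR"}}, sex="female")
        # unknown sex: het may be a manifesting carrier call, keep it
        assert "G1" in filter_inheritance([_v()], {"G1": {"XLR"}})

    def test_gene_without_mode_data_passes_through(self):
        out = filter_inheritance([_v(gene="G9")], {})
        assert out["G9"]

    def test_unknown_mode_warns_as_no_data(self):
        with pytest.warns(UserWarning, match="unknown inheritance"):
            out = filter_inheritance([_v()], {"G1": {"WEIRD"}})
        assert "G1" in out


def _brute_force_pipeline(variants, alpha, modes):
    """Independent re-application of both screen definitions."""
    kept = [v for v in variants if v.pop_af is None or v.pop_af <= alpha]
    result = {}
    by_gene = {}
    for v in kept:
        by_gene.setdefault(v.gene, []).append(v)
    for gene, vs in by_gene.items():
        ms = modes.get(gene, set())
        ok = not ms
        for m in ms:
            if m in ("AD", "XLD"):
                ok = True
            elif m == "AR" and (
                any(v.genotype == "hom_alt" for v in vs)
                or len({v.key for v in vs if v.genotype == "het"}) >= 2
            ):
                ok = True
            elif m == "XLR" and any(v.genotype in ("hemi", "hom_alt", "het") for v in vs):
                ok = True
        if ok:
            result[gene] = vs
    return result


def test_composition_matches_bruteforce_oracle():
    rng = np.random.default_rng(7)
    genes = [f"G{i}" for i in range(6)]
    mode_pool = ["AD", "AR", "XLR", "XLD"]
    for _ in range(1000):
        n = int(rng.integers(0, 10))
        variants = [
            _v(
                gene=genes[rng.integers(0, len(genes))],
                pos=int(rng.integers(1, 500)),
                af=None if rng.random() < 0.3 else float(rng.random()),
                genotype=["het", "hom_alt", "hemi"][rng.integers(0, 3)],
            )
            for _ in range(n)
        ]
        modes = {
            g: {mode_pool[rng.integers(0, 4)]}
            for g in genes
            if rng.random() < 0.7
        }
        alpha = float(rng.random())
        ours = filter_inheritance(filter_af(variants, FilterParams(alpha=alpha)), modes)
        assert ours == _brute_force_pipeline(variants, alpha, modes)
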