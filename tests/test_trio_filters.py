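"""Selection rules: published rows, reason codes, oracle equivalence,
and structural properties (monotonicity, parental symmetry, disjointness)."""

import dataclasses
import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rarecase import trio_filters, variant_io
from rarecase.trio_filters import (
    FilterThresholds,
    call_compound_het,
    call_de_novo,
    call_rare_homozygous,
    call_somatic,
    classify_all,
    group_by_gene,
)
from rarecase.variant_io import TrioRecord, VariantCall


def make_record(
    gene="G1",
    pos=100,
    maf=None,
    consequence="missense",
    **role_evidence,
):
    """role_evidence: role=(depth, alt_fraction[, genotype_class])."""
    calls = []
    for role, ev in role_evidence.items():
        depth, frac, *rest = ev
        calls.append(
            (
                role,
                VariantCall(
                    "chr1", pos, "A", "G", sample=role, depth=depth,
                    alt_fraction=frac,
                    genotype_class=rest[0] if rest else None,
                ),
            )
        )
    return TrioRecord(
        "chr1", pos, "A", "G", gene=gene, consequence=consequence,
        population_maf=maf, calls=tuple(calls),
    )


class TestSomatic:
    def test_boundary_vaf_at_low_coverage_passes(self, thresholds):
        # 20% at 15x tumor / 18x leukocyte: every threshold inclusive
        rec = make_record(tumor=(15, 0.20), patient=(18, 0.0))
        assert call_somatic(rec, thresholds) == (True, "ok")

    def test_below_vaf_threshold_fails(self, thresholds):
        rec = make_record(tumor=(100, 0.19), patient=(40, 0.0))
        assert call_somatic(rec, thresholds) == (False, "low_vaf")

    def test_shallow_tumor_fails(self, thresholds):
        rec = make_record(tumor=(9, 0.43), patient=(40, 0.0))
        assert call_somatic(rec, thresholds) == (False, "low_depth_tumor")

    def test_leukocyte_support_fails(self, thresholds):
        rec = make_record(tumor=(60, 0.45), patient=(50, 0.10))
        assert call_somatic(rec, thresholds) == (False, "normal_support")

    def test_missing_sample_is_indeterminate(self, thresholds):
        rec = make_record(tumor=(60, 0.45))
        verdict, reason = call_somatic(rec, thresholds)
        assert verdict is None and reason == "missing_sample"


class TestDeNovo:
    def test_patient_only_variant_called(self, thresholds):
        rec = make_record(patient=(30, 0.45), mother=(40, 0.0), father=(40, 0.0))
        assert call_de_novo(rec, thresholds) == (True, "ok")

    def test_inherited_variant_rejected(self, thresholds):
        rec = make_record(patient=(30, 0.45), mother=(40, 0.30), father=(40, 0.0))
        assert call_de_novo(rec, thresholds) == (False, "inherited_maternal")

    def test_fixtures_contain_no_de_novo(self, combined_records, thresholds):
        _, summary = classify_all(combined_records, thresholds)
        assert summary["de_novo"] == 0


class TestRareHomozygous:
    def test_rassf1_row_called(self, table2, thresholds):
        rec = next(r for r in table2.records if r.gene == "RASSF1")
        assert call_rare_homozygous(rec, thresholds) == (True, "ok")

    def test_common_polymorphism_rejected(self, thresholds):
        rec = make_record(
            maf=0.25, patient=(30, 1.0), mother=(40, 0.5), father=(40, 0.5)
        )
        assert call_rare_homozygous(rec, thresholds) == (False, "common_maf")

    def test_heterozygous_patient_rejected(self, thresholds):
        rec = make_record(
            maf=0.05, patient=(30, 0.5), mother=(40, 0.5), father=(40, 0.5)
        )
        verdict, reason = call_rare_homozygous(rec, thresholds)
        assert verdict is False and reason == "patient_not_homozygous"

    def test_absent_maf_treated_as_rare(self, thresholds):
        rec = make_record(
            maf=None, patient=(30, 1.0), mother=(40, 0.5), father=(40, 0.5)
        )
        assert call_rare_homozygous(rec, thresholds) == (True, "ok")


class TestCompoundHet:
    def test_published_table_reports_eleven_genes(self, table3, thresholds):
        result = call_compound_het(group_by_gene(table3.records), thresholds)
        assert len(result) == 11
        assert "C2CD3" in result and len(result["C2CD3"]) == 1

    def test_two_maternal_variants_not_reported(self, thresholds):
        records = [
            make_record(gene="CIS", pos=1, maf=0.01, patient=(50, 0.5),
                        mother=(50, 0.5), father=(50, 0.0)),
            make_record(gene="CIS", pos=2, maf=0.01, patient=(50, 0.5),
                        mother=(50, 0.45), father=(50, 0.0)),
        ]
        assert call_compound_het(group_by_gene(records), thresholds) == {}

    def test_biparental_variant_ineligible(self, thresholds):
        records = [
            make_record(gene="G", pos=1, maf=0.01, patient=(50, 0.5),
                        mother=(50, 0.5), father=(50, 0.5)),
            make_record(gene="G", pos=2, maf=0.01, patient=(50, 0.5),
                        mother=(50, 0.0), father=(50, 0.5)),
        ]
        assert call_compound_het(group_by_gene(records), thresholds) == {}

    def test_three_eligible_variants_report_all_pairs(self, thresholds):
        records = [
            make_record(gene="G", pos=1, maf=0.01, patient=(50, 0.5),
                        mother=(50, 0.5), father=(50, 0.0)),
            make_record(gene="G", pos=2, maf=0.01, patient=(50, 0.5),
                        mother=(50, 0.5), father=(50, 0.0)),
            make_record(gene="G", pos=3, maf=0.01, patient=(50, 0.5),
                        mother=(50, 0.0), father=(50, 0.5)),
        ]
        result = call_compound_het(group_by_gene(records), thresholds)
        assert len(result["G"]) == 2  # 2 maternal x 1 paternal


class TestClassifyAll:
    def test_somatic_table_with_decoys(self, table1, thresholds):
        _, summary = classify_all(list(table1.all_records), thresholds)
        assert summary["somatic"] == 15
        assert summary["somatic_protein_affecting"] == 12

    def test_homozygous_table_with_decoys(self, table2, thresholds):
        _, summary = classify_all(list(table2.all_records), thresholds)
        assert summary["rare_homozygous"] == 4

    def test_empty_input(self, thresholds):
        classified, summary = classify_all([], thresholds)
        assert classified == []
        assert summary["somatic"] == summary["rare_homozygous"] == 0

    def test_every_failure_has_reason_code(self, table1, thresholds):
        classified, _ = classify_all(list(table1.all_records), thresholds)
        for cv in classified:
            for cls in ("somatic", "de_novo", "rare_homozygous"):
                assert cls in cv.classes or cls in cv.failure_reasons


# ---------------------------------------------------------------------------
# brute-force oracle: a literal, rule-by-rule restatement of the four
# selection procedures, independent of the implementation under test


def oracle_genotype(call, th):
    if call.genotype_class is not None:
        return call.genotype_class
    if call.depth == 0:
        return "missing"
    if call.alt_fraction >= th.hom_vaf_min:
        return "hom_alt"
    if call.alt_fraction >= th.het_vaf_low:
        return "het"
    return "hom_ref"


def oracle_classify(records, th):
    result = {"somatic": set(), "de_novo": set(), "rare_homozygous": set()}
    for r in records:
        t, p, m, f = (r.call(x) for x in ("tumor", "patient", "mother", "father"))
        if t and p and t.depth >= th.min_depth and p.depth >= th.min_depth \
                and t.alt_fraction >= th.somatic_min_tumor_vaf \
                and p.alt_fraction <= th.somatic_max_normal_vaf:
            result["somatic"].add(r.key)
        if p and m and f and all(c.depth >= th.min_depth for c in (p, m, f)) \
                and p.alt_fraction >= th.denovo_min_vaf \
                and m.alt_fraction <= th.somatic_max_normal_vaf \
                and f.alt_fraction <= th.somatic_max_normal_vaf:
            result["de_novo"].add(r.key)
        if p and m and f and all(c.depth >= th.min_depth for c in (p, m, f)) \
                and oracle_genotype(p, th) == "hom_alt" \
                and oracle_genotype(m, th) == "het" \
                and oracle_genotype(f, th) == "het" \
                and (r.population_maf is None or r.population_maf <= th.rare_maf_max):
            result["rare_homozygous"].add(r.key)

    def eligible(r, carrier, other):
        p, c, o = r.call("patient"), r.call(carrier), r.call(other)
        return (
            p is not None and c is not None and o is not None
            and all(x.depth >= th.min_depth for x in (p, c, o))
            and oracle_genotype(p, th) == "het"
            and oracle_genotype(c, th) == "het"
            and c.alt_fraction > th.somatic_max_normal_vaf
            and o.alt_fraction <= th.somatic_max_normal_vaf
            and (r.population_maf is None or r.population_maf <= th.rare_maf_max)
        )

    comphet_genes = set()
    for gene, recs in itertools.groupby(
        sorted((r for r in records if r.gene), key=lambda r: r.gene),
        key=lambda r: r.gene,
    ):
        recs = list(recs)
        has_m = any(eligible(r, "mother", "father") for r in recs)
        has_f = any(eligible(r, "father", "mother") for r in recs)
        if has_m and has_f:
            comphet_genes.add(gene)
    result["compound_het_genes"] = comphet_genes
    return result


def impl_sets(records, th):
    classified, _ = classify_all(records, th)
    out = {
        cls: {cv.record.key for cv in classified if cls in cv.classes}
        for cls in ("somatic", "de_novo", "rare_homozygous")
    }
    out["compound_het_genes"] = set(
        call_compound_het(group_by_gene(records), th)
    )
    return out


fractions = st.sampled_from([0.0, 0.05, 0.15, 0.2, 0.3, 0.45, 0.5, 0.79, 0.8, 1.0])
depths = st.sampled_from([0, 5, 9, 10, 11, 30, 80])
mafs = st.one_of(st.none(), st.sampled_from([0.0, 0.01, 0.05, 0.1, 0.11, 0.3]))


@st.composite
def trio_records(draw, max_records=14):
    n = draw(st.integers(1, max_records))
    records = []
    for i in range(n):
        roles = draw(
            st.sets(st.sampled_from(["tumor", "patient", "mother", "father"]),
                    max_size=4)
        )
        evidence = {
            role: (draw(depths), draw(fractions)) for role in roles
        }
        records.append(
            make_record(
                gene=draw(st.sampled_from(["G1", "G2", "G3"])),
                pos=i + 1,
                maf=draw(mafs),
                **evidence,
            )
        )
    return records


@settings(max_examples=150, derandomize=True, deadline=None)
@given(trio_records())
def test_classification_matches_brute_force_oracle(records):
    th = FilterThresholds()
    assert impl_sets(records, th) == oracle_classify(records, th)


# ---------------------------------------------------------------------------
# structural properties


@settings(max_examples=80, derandomize=True, deadline=None)
@given(
    trio_records(),
    st.sampled_from(["min_depth", "somatic_min_tumor_vaf", "denovo_min_vaf"]),
)
def test_raising_thresholds_never_adds_calls(records, name):
    base = FilterThresholds()
    bumped = dataclasses.replace(
        base, **{name: getattr(base, name) + (5 if name == "min_depth" else 0.1)}
    )
    loose, strict = impl_sets(records, base), impl_sets(records, bumped)
    affected = {
        "min_depth": ("somatic", "de_novo", "rare_homozygous"),
        "somatic_min_tumor_vaf": ("somatic",),
        "denovo_min_vaf": ("de_novo",),
    }[name]
    for cls in affected:
        assert strict[cls] <= loose[cls]


@settings(max_examples=80, derandomize=True, deadline=None)
@given(trio_records())
def test_parental_swap_symmetry(records):
    th = FilterThresholds()

    def swap(rec):
        calls = []
        for role, call in rec.calls:
            new_role = {"mother": "father", "father": "mother"}.get(role, role)
            calls.append((new_role, dataclasses.replace(call, sample=new_role)))
        return dataclasses.replace(rec, calls=tuple(sorted(calls)))

    swapped = [swap(r) for r in records]
    assert impl_sets(records, th) == impl_sets(swapped, th)


@settings(max_examples=80, derandomize=True, deadline=None)
@given(trio_records())
def test_somatic_disjoint_from_germline_classes(records):
    th = FilterThresholds()
    sets = impl_sets(records, th)
    assert not sets["somatic"] & sets["rare_homozygous"]
    comphet_keys = set()
    for gene, pairs in call_compound_het(group_by_gene(records), th).items():
        for m, p in pairs:
            comphet_keys |= {m.key, p.key}
    assert not sets["somatic"] & comphet_keys


def test_invalid_threshold_ordering_rejected():
    with pytest.raises(ValueError):
        FilterThresholds(het_vaf_low=0.9, het_vaf_high=0.8)
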