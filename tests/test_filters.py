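"""Inheritance-model filters, damaging classification, constraint gene set."""

import dataclasses

import numpy as np
import pytest

from autozyg.filters import (
    DEFAULT_THRESHOLDS,
    DamagingClass,
    FilterStatus,
    FilterThresholds,
    GeneConstraint,
    classify_damaging,
    constraint_gene_set,
    filter_denovo,
    filter_recessive,
    filter_xlinked,
)
from autozyg.pedigree import Affection, Pedigree, Sex
from autozyg.variants import (
    Consequence,
    Genotype,
    GenotypeCall,
    VariantAnnotation,
    VariantRecord,
)

from conftest import make_individual, trio_pedigree


def ann(consequence=Consequence.MISSENSE, **kwargs):
    defaults = dict(gene="G1", metasvm=None, cadd=None, af_bravo=0.0,
                    af_gnomad=0.0, af_gme=0.0, segdup=False)
    defaults.update(kwargs)
    return VariantAnnotation(consequence=consequence, **defaults)


def record(calls, chrom="chr1", pos=1000, annotation=None, filter_pass=True,
           mapping_quality=60.0):
    return VariantRecord(chrom=chrom, pos=pos, ref="A", alt="T",
                         annotation=annotation or ann(metasvm="D"),
                         calls={c.sample: c for c in calls},
                         filter_pass=filter_pass,
                         mapping_quality=mapping_quality)


def call(sample, genotype, ref=15, alt=0, gq=90.0):
    return GenotypeCall(sample, genotype, ref, alt, gq)


class TestClassifyDamaging:
    @pytest.mark.parametrize("csq", [Consequence.STOP_GAIN,
                                     Consequence.STOP_LOSS,
                                     Consequence.FRAMESHIFT_INDEL,
                                     Consequence.CANONICAL_SPLICE,
                                     Consequence.START_LOSS])
    def test_lof_consequences(self, csq):
        assert classify_damaging(ann(csq)) is DamagingClass.LOF

    def test_missense_cadd_rescues_tolerated_metasvm(self):
        a = ann(metasvm="T", cadd=25.0)
        assert classify_damaging(a) is DamagingClass.DMIS

    def test_missense_failing_both_criteria(self):
        a = ann(metasvm="T", cadd=15.0)
        assert classify_damaging(a) is DamagingClass.NOT_DAMAGING

    def test_missense_metasvm_deleterious(self):
        assert classify_damaging(ann(metasvm="D")) is DamagingClass.DMIS

    def test_cadd_boundary_inclusive(self):
        assert classify_damaging(ann(cadd=20.0)) is DamagingClass.DMIS
        assert classify_damaging(ann(cadd=19.99)) \
            is DamagingClass.NOT_DAMAGING

    def test_nonframeshift_and_synonymous(self):
        assert classify_damaging(ann(Consequence.NONFRAMESHIFT_INDEL)) \
            is DamagingClass.NONFRAMESHIFT_INDEL
        assert classify_damaging(ann(Consequence.SYNONYMOUS)) \
            is DamagingClass.NOT_DAMAGING

    def test_missing_scores_fail_quietly(self):
        assert classify_damaging(ann()) is DamagingClass.NOT_DAMAGING


def dnv_record(pb_ref=6, pb_alt=12, fa_ref=15, fa_alt=0, mo_ref=15, mo_alt=0,
               annotation=None, pb_gt=Genotype.HET):
    return record([
        call("c1", pb_gt, pb_ref, pb_alt),
        call("fa", Genotype.HOM_REF, fa_ref, fa_alt),
        call("mo", Genotype.HOM_REF, mo_ref, mo_alt),
    ], annotation=annotation)


class TestDeNovoFilter:
    def test_clean_trio_passes(self):
        result = filter_denovo(dnv_record(), "c1", "fa", "mo")
        assert result.passed

    def test_missing_parent_not_evaluable(self):
        rec = record([call("c1", Genotype.HET, 6, 12),
                      call("fa", Genotype.HOM_REF, 15, 0)])
        result = filter_denovo(rec, "c1", "fa", "mo")
        assert result.status is FilterStatus.NOT_EVALUABLE

    @pytest.mark.parametrize("kwargs,reason", [
        (dict(pb_alt=4, pb_ref=20), "proband_alt_reads"),
        (dict(pb_alt=8, pb_ref=22), "allele_ratio"),      # 0.267 < 0.28
        (dict(pb_ref=4, pb_alt=5), "proband_depth"),
        (dict(fa_ref=9), "parent_ref_reads"),
        (dict(fa_ref=20, fa_alt=1), "parent_alt_ratio"),  # 0.048 >= 0.035
    ])
    def test_failure_reasons(self, kwargs, reason):
        result = filter_denovo(dnv_record(**kwargs), "c1", "fa", "mo")
        assert (result.status, result.reason) == (FilterStatus.FAIL, reason)

    def test_af_threshold_boundary(self):
        at = dnv_record(annotation=ann(metasvm="D", af_bravo=5e-4))
        beyond = dnv_record(annotation=ann(metasvm="D", af_bravo=5.1e-4))
        assert filter_denovo(at, "c1", "fa", "mo").passed
        result = filter_denovo(beyond, "c1", "fa", "mo")
        assert result.reason == "population_af"

    def test_alt_read_boundaries(self):
        # exactly 10 alt reads uses the 20% floor
        ten = dnv_record(pb_ref=40, pb_alt=10)   # ratio 0.20
        assert filter_denovo(ten, "c1", "fa", "mo").passed
        # 9 alt reads needs 28%
        nine = dnv_record(pb_ref=23, pb_alt=9)   # ratio 0.281
        assert filter_denovo(nine, "c1", "fa", "mo").passed
        nine_low = dnv_record(pb_ref=25, pb_alt=9)  # ratio 0.265
        assert filter_denovo(nine_low, "c1", "fa", "mo").reason \
            == "allele_ratio"

    def test_parent_ratio_boundary_exclusive(self):
        # alt ratio exactly 3.5% fails (rule is strictly below)
        rec = dnv_record(fa_ref=193, fa_alt=7)   # 7/200 = 0.035
        assert filter_denovo(rec, "c1", "fa", "mo").reason \
            == "parent_alt_ratio"
        rec2 = dnv_record(fa_ref=194, fa_alt=6)  # 0.03
        assert filter_denovo(rec2, "c1", "fa", "mo").passed

    def test_non_exonic_fails(self):
        rec = dnv_record(annotation=ann(Consequence.OTHER, metasvm="D"))
        assert filter_denovo(rec, "c1", "fa", "mo").reason == "consequence"

    def test_segdup_fails(self):
        rec = dnv_record(annotation=ann(metasvm="D", segdup=True))
        assert filter_denovo(rec, "c1", "fa", "mo").reason == "segdup"


def quad_pedigree():
    return Pedigree.from_individuals([
        make_individual("fa", sex=Sex.MALE, affected=Affection.UNAFFECTED),
        make_individual("mo", sex=Sex.FEMALE, affected=Affection.UNAFFECTED),
        make_individual("c1", father="fa", mother="mo", sex=Sex.MALE,
                        affected=Affection.AFFECTED),
        make_individual("c2", father="fa", mother="mo", sex=Sex.FEMALE,
                        affected=Affection.UNAFFECTED),
    ])


def hom_record(pos=1000, annotation=None, c2_gt=Genotype.HET):
    return record([
        call("c1", Genotype.HOM_ALT, 0, 20),
        call("fa", Genotype.HET, 10, 10),
        call("mo", Genotype.HET, 11, 9),
        call("c2", c2_gt, 10, 10 if c2_gt is Genotype.HET else 0),
    ], pos=pos, annotation=annotation)


class TestRecessiveFilter:
    def test_clean_homozygote_found(self):
        cands = filter_recessive([hom_record()], quad_pedigree(), "c1")
        assert len(cands) == 1
        assert cands[0].model == "hom_recessive"

    def test_af_above_recessive_cap_excluded(self):
        rec = hom_record(annotation=ann(metasvm="D", af_gnomad=2e-3))
        assert filter_recessive([rec], quad_pedigree(), "c1") == []

    def test_af_at_cap_retained(self):
        rec = hom_record(annotation=ann(metasvm="D", af_gnomad=1e-3))
        assert len(filter_recessive([rec], quad_pedigree(), "c1")) == 1

    def test_gme_af_excluded(self):
        rec = hom_record(annotation=ann(metasvm="D", af_gme=0.02))
        assert filter_recessive([rec], quad_pedigree(), "c1") == []

    def test_unaffected_hom_sibling_blocks(self):
        rec = record([
            call("c1", Genotype.HOM_ALT, 0, 20),
            call("fa", Genotype.HET, 10, 10),
            call("mo", Genotype.HET, 10, 10),
            call("c2", Genotype.HOM_ALT, 0, 20),
        ])
        assert filter_recessive([rec], quad_pedigree(), "c1") == []

    def test_not_damaging_excluded(self):
        rec = hom_record(annotation=ann(metasvm="T", cadd=5.0))
        assert filter_recessive([rec], quad_pedigree(), "c1") == []

    def test_low_depth_excluded(self):
        rec = record([
            call("c1", Genotype.HOM_ALT, 0, 7),   # depth 7 < 8
            call("fa", Genotype.HET, 10, 10),
            call("mo", Genotype.HET, 10, 10),
            call("c2", Genotype.HET, 10, 10),
        ])
        assert filter_recessive([rec], quad_pedigree(), "c1") == []

    def test_vqsr_fail_excluded(self):
        rec = hom_record()
        rec = dataclasses.replace(rec) if False else rec
        rec.filter_pass = False
        assert filter_recessive([rec], quad_pedigree(), "c1") == []

    def test_comp_het_trans_pair(self):
        pat = record([call("c1", Genotype.HET, 10, 10),
                      call("fa", Genotype.HET, 10, 10),
                      call("mo", Genotype.HOM_REF, 20, 0),
                      call("c2", Genotype.HOM_REF, 20, 0)], pos=100)
        mat = record([call("c1", Genotype.HET, 10, 10),
                      call("fa", Genotype.HOM_REF, 20, 0),
                      call("mo", Genotype.HET, 10, 10),
                      call("c2", Genotype.HOM_REF, 20, 0)], pos=200)
        cands = filter_recessive([pat, mat], quad_pedigree(), "c1")
        assert len(cands) == 1
        assert cands[0].model == "comp_het"
        assert len(cands[0].variant_keys) == 2
        assert "phase_unknown" not in cands[0].flags

    def test_cis_pair_rejected(self):
        v1 = record([call("c1", Genotype.HET, 10, 10),
                     call("fa", Genotype.HET, 10, 10),
                     call("mo", Genotype.HOM_REF, 20, 0),
                     call("c2", Genotype.HOM_REF, 20, 0)], pos=100)
        v2 = record([call("c1", Genotype.HET, 10, 10),
                     call("fa", Genotype.HET, 10, 10),
                     call("mo", Genotype.HOM_REF, 20, 0),
                     call("c2", Genotype.HOM_REF, 20, 0)], pos=200)
        assert filter_recessive([v1, v2], quad_pedigree(), "c1") == []

    def test_unphaseable_pair_flagged(self):
        ped = trio_pedigree()  # no genotyped second parent in the records
        v1 = record([call("c1", Genotype.HET, 10, 10),
                     call("fa", Genotype.HET, 10, 10),
                     call("mo", Genotype.MISSING, 0, 0)], pos=100)
        v2 = record([call("c1", Genotype.HET, 10, 10),
                     call("fa", Genotype.HOM_REF, 20, 0),
                     call("mo", Genotype.MISSING, 0, 0)], pos=200)
        cands = filter_recessive([v1, v2], ped, "c1")
        assert len(cands) == 1
        assert "phase_unknown" in cands[0].flags


def x_pedigree():
    return Pedigree.from_individuals([
        make_individual("fa", sex=Sex.MALE, affected=Affection.UNAFFECTED),
        make_individual("mo", sex=Sex.FEMALE, affected=Affection.UNAFFECTED),
        make_individual("c1", father="fa", mother="mo", sex=Sex.MALE,
                        affected=Affection.AFFECTED),
    ])


def x_record(annotation=None, gq=30.0, mq=60.0, pb_ref=0, pb_alt=20,
             mo_gt=Genotype.HET):
    return record([
        GenotypeCall("c1", Genotype.HEMI_ALT, pb_ref, pb_alt, gq),
        call("fa", Genotype.HEMI_REF, 20, 0),
        call("mo", mo_gt, 10, 10),
    ], chrom="chrX", annotation=annotation, mapping_quality=mq)


class TestXLinkedFilter:
    def test_clean_hemizygote_passes(self):
        assert filter_xlinked(x_record(), x_pedigree(), "c1").passed

    def test_population_af_fails(self):
        rec = x_record(annotation=ann(metasvm="D", af_bravo=1e-4))
        result = filter_xlinked(rec, x_pedigree(), "c1")
        assert result.reason == "population_af"

    def test_af_boundary(self):
        rec = x_record(annotation=ann(metasvm="D", af_bravo=5e-5))
        assert filter_xlinked(rec, x_pedigree(), "c1").passed

    def test_low_gq_fails(self):
        result = filter_xlinked(x_record(gq=15.0), x_pedigree(), "c1")
        assert result.reason == "genotype_quality"

    def test_gq_boundary(self):
        assert filter_xlinked(x_record(gq=20.0), x_pedigree(), "c1").passed

    def test_low_mq_fails(self):
        result = filter_xlinked(x_record(mq=39.0), x_pedigree(), "c1")
        assert result.reason == "mapping_quality"

    def test_mq_boundary(self):
        assert filter_xlinked(x_record(mq=40.0), x_pedigree(), "c1").passed

    def test_low_depth_fails(self):
        result = filter_xlinked(x_record(pb_alt=7), x_pedigree(), "c1")
        assert result.reason == "proband_depth"

    def test_depth_boundary(self):
        assert filter_xlinked(x_record(pb_alt=8), x_pedigree(), "c1").passed

    def test_female_proband_not_evaluable(self):
        ped = Pedigree.from_individuals([
            make_individual("mo", sex=Sex.FEMALE),
            make_individual("c1", mother="mo", sex=Sex.FEMALE,
                            affected=Affection.AFFECTED)])
        rec = record([call("c1", Genotype.HET, 10, 10),
                      call("mo", Genotype.HET, 10, 10)], chrom="chrX")
        result = filter_xlinked(rec, ped, "c1")
        assert result.status is FilterStatus.NOT_EVALUABLE

    def test_non_carrier_mother_fails(self):
        rec = x_record(mo_gt=Genotype.HOM_REF)
        result = filter_xlinked(rec, x_pedigree(), "c1")
        assert result.reason == "maternal_genotype"


class TestConstraintGeneSet:
    def make_candidate(self, gene="G1", annotations=None, model="hom_recessive"):
        from autozyg.filters import CandidateVariant
        annotations = annotations or (ann(metasvm="D", cadd=25.0),)
        n = len(annotations)
        return CandidateVariant(
            family_id="F1", gene=gene, model="comp_het" if n == 2 else model,
            variant_keys=tuple(("chr1", 100 + i, "A", "T") for i in range(n)),
            damaging=(DamagingClass.DMIS,) * n, annotations=tuple(annotations))

    def test_qualifying_missense_retained(self):
        cand = self.make_candidate()
        retained, _ = constraint_gene_set(
            [cand], {"G1": GeneConstraint(mis_z=2.5)})
        assert retained == {"G1"}

    def test_low_pli_lof_excluded(self):
        cand = self.make_candidate(
            annotations=(ann(Consequence.STOP_GAIN, metasvm=None),))
        retained, reasons = constraint_gene_set(
            [cand], {"G1": GeneConstraint(pli=0.5)})
        assert retained == set()
        assert reasons["G1"] == "pli"

    def test_pli_boundary(self):
        cand = self.make_candidate(
            annotations=(ann(Consequence.STOP_GAIN, metasvm=None),))
        retained, _ = constraint_gene_set(
            [cand], {"G1": GeneConstraint(pli=0.9)})
        assert retained == {"G1"}

    def test_comp_het_needs_both_alleles(self):
        cand = self.make_candidate(annotations=(
            ann(metasvm="D", cadd=25.0), ann(metasvm="D", cadd=20.0)))
        retained, reasons = constraint_gene_set(
            [cand], {"G1": GeneConstraint(mis_z=3.0)})
        assert retained == set()
        assert reasons["G1"] == "cadd"

    def test_missing_constraint_reported(self):
        cand = self.make_candidate()
        retained, reasons = constraint_gene_set([cand], {})
        assert retained == set()
        assert reasons["G1"] == "missing_constraint"

    def test_cadd_24_boundary(self):
        good = self.make_candidate(annotations=(ann(metasvm="D", cadd=24.0),))
        bad = self.make_candidate(annotations=(ann(metasvm="D", cadd=23.9),))
        constraints = {"G1": GeneConstraint(mis_z=2.0)}
        assert constraint_gene_set([good], constraints)[0] == {"G1"}
        assert constraint_gene_set([bad], constraints)[0] == set()


class TestMonotonicity:
    """Relaxing any single numeric threshold never shrinks the passing set."""

    def _random_dnv_records(self, rng, n=300):
        records = []
        for _ in range(n):
            records.append(dnv_record(
                pb_ref=int(rng.integers(0, 40)), pb_alt=int(rng.integers(0, 40)),
                fa_ref=int(rng.integers(0, 30)), fa_alt=int(rng.integers(0, 3)),
                mo_ref=int(rng.integers(0, 30)), mo_alt=int(rng.integers(0, 3)),
                annotation=ann(metasvm="D",
                               af_bravo=float(rng.random() * 1e-3))))
        return records

    @pytest.mark.parametrize("relaxed", [
        dict(dnv_max_af=1e-2),
        dict(dnv_min_depth=5),
        dict(dnv_min_alt_reads=2),
        dict(dnv_min_ratio=0.1, dnv_min_ratio_low_alt=0.1),
        dict(parent_min_ref_reads=3),
        dict(parent_max_alt_ratio=0.2),
    ])
    def test_denovo_relaxation_superset(self, relaxed):
        rng = np.random.default_rng(42)
        records = self._random_dnv_records(rng)
        strict = {i for i, r in enumerate(records)
                  if filter_denovo(r, "c1", "fa", "mo",
                                   DEFAULT_THRESHOLDS).passed}
        loose_thresholds = FilterThresholds(**relaxed)
        loose = {i for i, r in enumerate(records)
                 if filter_denovo(r, "c1", "fa", "mo",
                                  loose_thresholds).passed}
        assert strict <= loose
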