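"""Sample groups and quantified genotype filters (case/control logic)."""

import itertools
import math

import pytest

from vcfsieve import Dataset, GroupFilter, SampleCall, SampleGroup, \
    Zygosity, apply_filter, evaluate_group_filter, group_filter_spec, \
    parse_header, sample_matches
from vcfsieve.errors import GroupError
from vcfsieve.ingest import VariantDocument

_ZYGS = {
    Zygosity.NO_CALL: ("./.", 0),
    Zygosity.REFERENCE: ("0/0", 0),
    Zygosity.HETEROZYGOUS: ("0/1", 1),
    Zygosity.HOMOZYGOUS: ("1/1", 2),
}


def make_call(zyg: Zygosity, alt_depth=None) -> SampleCall:
    gt, count = _ZYGS[zyg]
    return SampleCall(gt_raw=gt, zygosity=zyg, alt_allele_count=count,
                      ref_depth=10 if alt_depth is not None else None,
                      alt_depth=alt_depth)


def make_doc(calls: dict) -> VariantDocument:
    return VariantDocument(chrom="1", pos=100, id=None, ref="A", alt="T",
                           qual=50.0, filter_status="PASS", calls=calls)


class TestSampleMatches:
    def test_het_with_sufficient_depth(self):
        call = make_call(Zygosity.HETEROZYGOUS, alt_depth=8)
        assert sample_matches(call, "heterozygous", 5)

    def test_depth_requirement_unsatisfiable_without_ad(self):
        call = make_call(Zygosity.HOMOZYGOUS, alt_depth=None)
        assert not sample_matches(call, "either", 3)
        assert sample_matches(call, "either", None)

    def test_reference_never_matches(self):
        assert not sample_matches(make_call(Zygosity.REFERENCE), "either")

    def test_no_call_never_matches(self):
        for req in ("either", "heterozygous", "homozygous"):
            assert not sample_matches(make_call(Zygosity.NO_CALL), req)


class TestEvaluateGroupFilter:
    def test_all_heterozygous_in_nine_samples(self):
        members = tuple(f"S{i}" for i in range(9))
        doc = make_doc({s: make_call(Zygosity.HETEROZYGOUS)
                        for s in members})
        gf = GroupFilter(group=SampleGroup("g1", members),
                         zygosity_req="heterozygous", quantifier="all")
        assert evaluate_group_filter(doc, gf)
        # one sample dropping to reference breaks "all"
        doc.calls["S3"] = make_call(Zygosity.REFERENCE)
        assert not evaluate_group_filter(doc, gf)

    def test_fraction_threshold_is_ceiling(self):
        members = ("A", "B", "C", "D")
        group = SampleGroup("g", members)
        gf = GroupFilter(group=group, zygosity_req="either",
                         quantifier="at_least_fraction", fraction=0.5)
        two = make_doc({"A": make_call(Zygosity.HETEROZYGOUS),
                        "B": make_call(Zygosity.HOMOZYGOUS),
                        "C": make_call(Zygosity.REFERENCE),
                        "D": make_call(Zygosity.REFERENCE)})
        one = make_doc({"A": make_call(Zygosity.HETEROZYGOUS),
                        "B": make_call(Zygosity.REFERENCE),
                        "C": make_call(Zygosity.REFERENCE),
                        "D": make_call(Zygosity.REFERENCE)})
        assert evaluate_group_filter(two, gf)       # ceil(0.5*4)=2
        assert not evaluate_group_filter(one, gf)

    def test_exclude_homozygous_in_any_control(self):
        controls = SampleGroup("controls", ("C1", "C2"))
        gf = GroupFilter(group=controls, zygosity_req="homozygous",
                         quantifier="any", mode="exclude")
        hom_in_one = make_doc({"C1": make_call(Zygosity.HOMOZYGOUS),
                               "C2": make_call(Zygosity.REFERENCE)})
        clean = make_doc({"C1": make_call(Zygosity.HETEROZYGOUS),
                          "C2": make_call(Zygosity.REFERENCE)})
        assert not evaluate_group_filter(hom_in_one, gf)  # excluded
        assert evaluate_group_filter(clean, gf)

    def test_absent_member_is_an_error(self):
        gf = GroupFilter(group=SampleGroup("g", ("GHOST",)))
        with pytest.raises(GroupError, match="GHOST"):
            evaluate_group_filter(make_doc({}), gf)


def _truth_table_oracle(zygs, req, quantifier, fraction, mode):
    """Hand-written independent rule: count members matching the zygosity
    requirement, compare to the quantifier threshold, negate on exclude."""
    def member_matches(z):
        if z in (Zygosity.NO_CALL, Zygosity.REFERENCE):
            return False
        if req == "either":
            return True
        if req == "heterozygous":
            return z is Zygosity.HETEROZYGOUS
        return z is Zygosity.HOMOZYGOUS
    m = sum(member_matches(z) for z in zygs)
    n = len(zygs)
    if quantifier == "any":
        need = 1
    elif quantifier == "all":
        need = n
    else:
        need = math.ceil(fraction * n)
    ok = m >= need
    return ok if mode == "require" else not ok


def test_exhaustive_truth_table_three_samples():
    """All 4^3 zygosity combinations x quantifiers x zygosity requirements
    x modes agree with the hand-written truth table."""
    members = ("A", "B", "C")
    group = SampleGroup("g", members)
    checked = 0
    for zygs in itertools.product(_ZYGS, repeat=3):
        doc = make_doc({s: make_call(z) for s, z in zip(members, zygs)})
        for req in ("either", "heterozygous", "homozygous"):
            for quant, frac in (("any", None), ("all", None),
                                ("at_least_fraction", 0.5)):
                for mode in ("require", "exclude"):
                    gf = GroupFilter(group=group, zygosity_req=req,
                                     quantifier=quant, fraction=frac,
                                     mode=mode)
                    assert evaluate_group_filter(doc, gf) == \
                        _truth_table_oracle(zygs, req, quant, frac, mode), \
                        (zygs, req, quant, mode)
                    checked += 1
    assert checked == 64 * 3 * 3 * 2


class TestInvariants:
    def _docs(self):
        members = ("A", "B", "C")
        docs = []
        for zygs in itertools.product(_ZYGS, repeat=3):
            docs.append(make_doc({s: make_call(z)
                                  for s, z in zip(members, zygs)}))
        return SampleGroup("g", members), docs

    def test_exclude_is_pointwise_negation(self):
        group, docs = self._docs()
        for req in ("either", "heterozygous", "homozygous"):
            for quant, frac in (("any", None), ("all", None),
                                ("at_least_fraction", 0.7)):
                req_f = GroupFilter(group=group, zygosity_req=req,
                                    quantifier=quant, fraction=frac)
                exc_f = GroupFilter(group=group, zygosity_req=req,
                                    quantifier=quant, fraction=frac,
                                    mode="exclude")
                for doc in docs:
                    assert evaluate_group_filter(doc, exc_f) == \
                        (not evaluate_group_filter(doc, req_f))

    def test_monotone_in_fraction(self):
        group, docs = self._docs()
        fractions = (0.2, 0.4, 0.6, 0.8, 1.0)
        for lo, hi in zip(fractions, fractions[1:]):
            f_lo = GroupFilter(group=group, quantifier="at_least_fraction",
                               fraction=lo)
            f_hi = GroupFilter(group=group, quantifier="at_least_fraction",
                               fraction=hi)
            survivors_lo = {i for i, d in enumerate(docs)
                            if evaluate_group_filter(d, f_lo)}
            survivors_hi = {i for i, d in enumerate(docs)
                            if evaluate_group_filter(d, f_hi)}
            assert survivors_hi <= survivors_lo

    def test_all_implies_any_and_fraction_one_is_all(self):
        group, docs = self._docs()
        f_any = GroupFilter(group=group, quantifier="any")
        f_all = GroupFilter(group=group, quantifier="all")
        f_one = GroupFilter(group=group, quantifier="at_least_fraction",
                            fraction=1.0)
        for doc in docs:
            a = evaluate_group_filter(doc, f_all)
            assert evaluate_group_filter(doc, f_one) == a
            if a:
                assert evaluate_group_filter(doc, f_any)


class TestGroupFilterSpec:
    def test_wrapped_spec_delegates(self, toy_dataset):
        gf = GroupFilter(group=SampleGroup("g", ("S1",)),
                         zygosity_req="either", quantifier="any")
        spec = group_filter_spec(gf)
        expected = {i for i, d in enumerate(toy_dataset.docs)
                    if evaluate_group_filter(d, gf)}
        assert apply_filter(toy_dataset, spec) == expected

    def test_degenerate_group_is_presence_filter(self, toy_dataset):
        gf = GroupFilter(group=SampleGroup("everyone", ("S1", "S2")),
                         zygosity_req="either", quantifier="any")
        spec = group_filter_spec(gf)
        expected = {i for i, d in enumerate(toy_dataset.docs)
                    if d.derived["DERIVED.sample_count"] >= 1}
        assert apply_filter(toy_dataset, spec) == expected

    def test_require_then_exclude_composes_conjunctively(self, toy_dataset):
        cases = group_filter_spec(GroupFilter(
            group=SampleGroup("cases", ("S1",)), quantifier="any"))
        controls = group_filter_spec(GroupFilter(
            group=SampleGroup("controls", ("S2",)), quantifier="any",
            mode="exclude"))
        from vcfsieve import apply_chain
        _, final = apply_chain(toy_dataset, [cases, controls])
        assert final == (apply_filter(toy_dataset, cases) &
                         apply_filter(toy_dataset, controls))


def test_group_validation_against_dataset(toy_dataset):
    with pytest.raises(GroupError, match="S9"):
        SampleGroup("g", ("S1", "S9")).validate_against(
            toy_dataset.meta.sample_ids)
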