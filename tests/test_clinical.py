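"""Clinical schema: table lookups, derived attributes, clause assembly."""

import pytest
from hypothesis import given, settings, strategies as st

from schizodoc.clinical import (
    AS_DOMAIN_FEMALE,
    AS_DOMAIN_MALE,
    RawPatientRecord,
    SUB_DOMAINS,
    age_sex_predisposition,
    build_clause,
    differential_value,
    genetic_predisposition,
    genetic_relations,
    ks1_score,
    ks2_score,
    lucidity_value,
)
from schizodoc.intervals import AttrValue, Domain, widen_to_interval

P = AttrValue.point
U = AttrValue.unknown


class TestAgeSexTable:
    @pytest.mark.parametrize(
        "age, sex, expected",
        [
            (22, "male", (0.12, 0.18)),
            (28, "female", (0.05, 0.06)),
            (70, "female", (0, 0.02)),
            (0, "male", (0, 0.18)),
            (65, "male", (0, 0.01)),  # open-ended top band starts at 65
            (64, "female", (0.02, 0.04)),
        ],
    )
    def test_band_lookup(self, age, sex, expected):
        assert age_sex_predisposition(age, sex) == expected

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            age_sex_predisposition(-1, "male")

    def test_domain_hulls_cover_all_bands(self):
        for sex, dom in (("male", AS_DOMAIN_MALE), ("female", AS_DOMAIN_FEMALE)):
            los, his = zip(*(age_sex_predisposition(a, sex) for a in range(0, 100)))
            assert min(los) == dom.lower
            assert max(his) == dom.upper


class TestGeneticTable:
    @pytest.mark.parametrize(
        "relation, expected",
        [
            ("parents", 9.2),
            ("general_population", 0.9),
            ("monozygotic_twin_living_together", 91.5),
            ("children_of_father_and_mother_schizophrenics", 39.2),
        ],
    )
    def test_lookup(self, relation, expected):
        assert genetic_predisposition(relation) == expected

    def test_unknown_category_lists_valid_labels(self):
        with pytest.raises(ValueError, match="general_population"):
            genetic_predisposition("uncle")

    def test_fifteen_categories_spanning_domain(self):
        rels = genetic_relations()
        assert len(rels) == 15
        vals = [genetic_predisposition(r) for r in rels]
        assert min(vals) == 0.9 and max(vals) == 91.5


class TestDerivedAttributes:
    def test_full_lucidity(self):
        assert lucidity_value(P(1), P(1), P(1), P(2)) == P(2.0)

    def test_zero_factor_annihilates(self):
        assert lucidity_value(P(0), P(1), P(1), P(2)) == P(0.0)
        assert differential_value(P(0), P(1), P(1)) == P(0.0)

    def test_unknown_factor_widens_product(self):
        v = lucidity_value(P(1), P(1), U(), P(2))
        assert widen_to_interval(v, Domain(0, 2)) == (0.0, 2.0)

    def test_unknown_differential_factor_is_fully_unknown(self):
        # hull [0,1] equals the whole domain, hence indistinguishable from unknown
        assert differential_value(P(1), P(1), U()).is_unknown

    def test_differential_all_present(self):
        assert differential_value(P(1), P(1), P(1)) == P(1.0)

    @pytest.mark.parametrize(
        "args, expected",
        [((P(3), P(0), P(0), P(2)), 5.0), ((P(0),) * 4, 0.0), ((P(3), P(2), P(4), P(2)), 11.0)],
    )
    def test_first_order_score(self, args, expected):
        assert ks1_score(*args) == P(expected)

    def test_second_order_score(self):
        assert ks2_score(P(0), P(0), AttrValue.interval(0.25, 0.75), P(0)) == (
            AttrValue.interval(0.25, 0.75)
        )
        assert ks2_score(P(1), P(1), P(1), P(1)) == P(4.0)
        assert ks2_score(P(0), P(0), P(0), P(0)) == P(0.0)

    def test_out_of_domain_component_rejected(self):
        with pytest.raises(ValueError, match="hallucinations"):
            ks1_score(P(0), P(0), P(5), P(0))


class TestBuildClause:
    def test_male_22_clause(self, male_22):
        c = build_clause(male_22)
        assert c.as_predisposition == AttrValue.interval(0.12, 0.18)
        assert c.g_predisposition == P(0.9)
        assert c.lucidity == P(2.0)
        assert c.differential.is_unknown
        assert c.ks1 == P(5.0)
        assert c.ks2 == AttrValue.interval(0.25, 0.75)
        assert c.as_domain == AS_DOMAIN_MALE

    def test_patient_2_clause(self, patient_2):
        c = build_clause(patient_2)
        assert c.as_predisposition == AttrValue.interval(0.05, 0.06)
        assert c.g_predisposition.is_unknown
        assert c.lucidity == P(0.0)
        assert c.differential == P(0.0)
        assert c.ks1 == P(0.0)
        assert c.ks2 == P(1.0)
        assert c.as_domain == AS_DOMAIN_FEMALE

    def test_maximal_record_hits_score_bounds(self, male_22):
        import dataclasses

        r = dataclasses.replace(
            male_22,
            thinking_alterations=P(3), passivity=P(2), hallucinations=P(4), delusions=P(2),
            delusional_intuition=P(1), perplexity=P(1),
            emotional_impoverishment=P(1), dysthymias=P(1),
        )
        c = build_clause(r)
        assert c.ks1 == P(11.0)
        assert c.ks2 == P(4.0)

    @given(data=st.data())
    @settings(derandomize=True, max_examples=100)
    def test_random_records_yield_valid_clauses(self, data):
        def cell(name):
            d = SUB_DOMAINS[name]
            kind = data.draw(st.sampled_from(["point", "interval", "unknown"]))
            if kind == "unknown":
                return U()
            a = data.draw(st.floats(d.lower, d.upper))
            if kind == "point":
                return P(a)
            b = data.draw(st.floats(a, d.upper))
            return AttrValue.interval(a, b)

        r = RawPatientRecord(
            record_id="rnd",
            age=data.draw(st.integers(0, 99)),
            sex=data.draw(st.sampled_from(["male", "female"])),
            relation=data.draw(st.sampled_from((None,) + genetic_relations())),
            **{name: cell(name) for name in SUB_DOMAINS},
        )
        c = build_clause(r)  # __post_init__ enforces every domain invariant
        for name, value, domain in c.attributes():
            lo, hi = widen_to_interval(value, domain, attribute=name)
            assert domain.lower - 1e-9 <= lo <= hi <= domain.upper + 1e-9
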