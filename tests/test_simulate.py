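"""Synthetic population generator: planted rule, masking, determinism."""

import dataclasses

import numpy as np
import pytest

from schizodoc.clinical import build_clause
from schizodoc.intervals import AttrValue
from schizodoc.pipeline import clause_to_doc
from schizodoc.simulate import (
    GeneratorConfig,
    INDETERMINATE,
    cases_to_training_data,
    generate_population,
    planted_risk,
)

P = AttrValue.point


def make_record(ks1=(0, 0, 0, 0), ks2=(0, 0, 0, 0), relation="general_population",
                age=30, sex="male", drugs=1, consciousness=2, neurological=1):
    t, pa, h, d = ks1
    di, pe, e, dy = ks2
    return dataclasses.replace(
        # reuse a fully specified base record
        _BASE,
        relation=relation, age=age, sex=sex,
        drugs=P(drugs), consciousness=P(consciousness), neurological=P(neurological),
        thinking_alterations=P(t), passivity=P(pa), hallucinations=P(h), delusions=P(d),
        delusional_intuition=P(di), perplexity=P(pe),
        emotional_impoverishment=P(e), dysthymias=P(dy),
    )


from schizodoc.clinical import RawPatientRecord  # noqa: E402

_BASE = RawPatientRecord(
    record_id="base", age=30, sex="male", relation="general_population",
    drugs=P(1), alcohol=P(1), somnolence=P(1), consciousness=P(2),
    neurological=P(1), infectious=P(1), toxic_metabolic=P(1),
    thinking_alterations=P(0), passivity=P(0), hallucinations=P(0), delusions=P(0),
    delusional_intuition=P(0), perplexity=P(0),
    emotional_impoverishment=P(0), dysthymias=P(0),
)


class TestPlantedRisk:
    def test_benign_profile_is_low_risk(self):
        risk = planted_risk(make_record())
        assert risk is not INDETERMINATE and risk < 0.1

    def test_maximal_profile_with_twin_genetics_is_high_risk(self):
        risk = planted_risk(
            make_record(ks1=(3, 2, 4, 2), ks2=(1, 1, 1, 1),
                        relation="monozygotic_twin_living_together", age=20)
        )
        assert risk is not INDETERMINATE and risk > 0.9

    @pytest.mark.parametrize("kwargs", [
        {"drugs": 0}, {"consciousness": 0}, {"neurological": 0},
    ])
    def test_zero_lucidity_or_differential_voids_diagnosis(self, kwargs):
        assert planted_risk(make_record(**kwargs)) is INDETERMINATE

    def test_monotone_in_symptom_scores_on_grid(self):
        prev = -1.0
        for t in range(4):  # thinking_alterations sweeps the Ks_1 sum
            risk = planted_risk(make_record(ks1=(t, 0, 0, 0)))
            assert risk > prev
            prev = risk
        prev = -1.0
        for k in range(5):  # number of second-order symptoms present
            ks2 = tuple(1 if i < k else 0 for i in range(4))
            risk = planted_risk(make_record(ks2=ks2))
            assert risk > prev
            prev = risk

    def test_first_order_dominates_second_order(self):
        # one unit-scale step of Ks_1 moves the risk more than all of Ks_2
        base = planted_risk(make_record())
        full_ks2 = planted_risk(make_record(ks2=(1, 1, 1, 1)))
        strong_ks1 = planted_risk(make_record(ks1=(3, 2, 4, 2)))
        assert strong_ks1 - base > full_ks2 - base

    def test_incomplete_record_rejected(self):
        with pytest.raises(ValueError):
            planted_risk(dataclasses.replace(_BASE, relation=None))


class TestGeneratePopulation:
    def test_empty_population(self):
        assert generate_population(GeneratorConfig(n=0)) == []

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n=-1)
        with pytest.raises(ValueError):
            GeneratorConfig(n=1, missing_rate=0.7, interval_rate=0.7)
        with pytest.raises(ValueError):
            GeneratorConfig(n=1, label_noise=1.5)

    def test_determinism_identical_configs(self):
        cfg = GeneratorConfig(n=200, missing_rate=0.2, interval_rate=0.1, seed=42)
        assert generate_population(cfg) == generate_population(cfg)

    def test_different_seeds_differ(self):
        a = generate_population(GeneratorConfig(n=50, seed=1))
        b = generate_population(GeneratorConfig(n=50, seed=2))
        assert a != b

    def test_complete_population_has_point_valued_derived_attributes(self):
        cases = generate_population(
            GeneratorConfig(n=300, missing_rate=0, interval_rate=0, seed=7)
        )
        assert len(cases) == 300
        for case in cases:
            d = clause_to_doc(build_clause(case.record))
            for a in d.attributes[1:]:  # age/sex stays a table interval
                assert a.doc == pytest.approx(1.0, abs=1e-12)

    def test_fully_missing_genetics_zeroes_that_doc(self):
        cfg = GeneratorConfig(
            n=100, missing_rate=0, interval_rate=0, relation_missing_rate=1.0, seed=3
        )
        for case in generate_population(cfg):
            d = clause_to_doc(build_clause(case.record))
            assert d.attribute("g_predisposition").doc == 0.0

    def test_labels_are_computed_before_masking(self):
        cfg = GeneratorConfig(n=200, missing_rate=0.4, interval_rate=0.2, seed=5)
        for case in generate_population(cfg):
            latent_risk = planted_risk(case.latent_record)
            if latent_risk is INDETERMINATE:
                assert case.label == "indeterminate"
            else:
                assert case.label == (
                    "schizophrenia" if latent_risk >= 0.5 else "not_schizophrenia"
                )

    def test_empirical_missing_fraction_tracks_rate(self):
        rate = 0.3
        cases = generate_population(
            GeneratorConfig(n=500, missing_rate=rate, interval_rate=0, seed=11)
        )
        from schizodoc.clinical import SUB_DOMAINS

        n_cells = 500 * len(SUB_DOMAINS)
        n_missing = sum(
            getattr(c.record, name).is_unknown
            for c in cases for name in SUB_DOMAINS
        )
        se = (rate * (1 - rate) / n_cells) ** 0.5
        assert abs(n_missing / n_cells - rate) < 3 * se

    def test_label_balance_in_band(self):
        cases = generate_population(
            GeneratorConfig(n=5000, missing_rate=0, interval_rate=0, seed=1)
        )
        labels = [c.label for c in cases]
        determinate = [l for l in labels if l != "indeterminate"]
        pos = determinate.count("schizophrenia") / len(labels)
        assert 0.30 <= pos <= 0.60

    def test_mean_doc_decreases_with_missing_rate(self):
        means = []
        for i, mr in enumerate((0, 0.1, 0.2, 0.3, 0.4, 0.5)):
            cases = generate_population(
                GeneratorConfig(n=300, missing_rate=mr, interval_rate=0, seed=20 + i)
            )
            docs = [clause_to_doc(build_clause(c.record)).clause_doc for c in cases]
            means.append(np.mean(docs))
        assert all(a > b for a, b in zip(means, means[1:]))


class TestTrainingData:
    def test_indeterminate_excluded_by_default(self):
        cases = generate_population(GeneratorConfig(n=400, seed=9))
        x, y, c = cases_to_training_data(cases)
        n_det = sum(1 for cs in cases if cs.label != "indeterminate")
        assert len(x) == len(y) == len(c) == n_det
        x2, y2, _ = cases_to_training_data(cases, include_indeterminate=True)
        assert len(x2) == 400
        assert y2.sum() == y.sum()  # indeterminates enter as negatives
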