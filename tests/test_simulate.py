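import numpy as np
import pytest

from medimatch import (
    SimulationConfig,
    call_detection,
    end_to_end_fixture,
    normalize_rundays,
    simulate_abundances,
    simulate_cohort,
    usage_probability,
)
from medimatch.io import ValidationError
from medimatch.simulate import DrugSpec, MetaboliteSpec, _met, render_free_text


def _single_drug_config(seed=1, n=800, **met_kwargs):
    met = dict(sensitivity=1.0, false_positive_rate=0.0, mu_user=9.0)
    met.update(met_kwargs)
    drugs = [
        DrugSpec(
            "warfarin", usage_rate=0.2, report_probability=1.0,
            metabolites=[MetaboliteSpec("10-hydroxywarfarin", **met)],
        )
    ]
    return SimulationConfig(
        n_participants=n, n_samples_linked=n, seed=seed, drugs=drugs,
        n_unknown_metabolites=0, runday_sigma=0.0,
    )


class TestUsageModel:
    @pytest.mark.parametrize(
        "age,p", [(20, 0.25), (45, 0.625), (70, 1.0), (18, 0.22), (90, 1.0)]
    )
    def test_linear_age_model(self, age, p):
        assert usage_probability(age) == pytest.approx(p)

    def test_cohort_usage_tracks_age_model(self, default_bundle):
        participants, truth = default_bundle.participants, default_bundle.truth
        for lo, hi in ((25, 34), (45, 54), (60, 69)):
            band = [p for p in participants if lo <= p.age <= hi]
            frac = np.mean(
                [len(truth.used[p.participant_id]) > 0 for p in band]
            )
            expected = np.mean([usage_probability(p.age) for p in band])
            se = np.sqrt(expected * (1 - expected) / len(band))
            assert abs(frac - expected) < 4 * se


class TestDeterminism:
    def test_same_seed_reproduces_bundle_exactly(self):
        cfg = _single_drug_config(seed=5)
        b1 = end_to_end_fixture(cfg)
        b2 = end_to_end_fixture(_single_drug_config(seed=5))
        assert b1.matrix.areas.equals(b2.matrix.areas)
        assert b1.participants == b2.participants
        assert b1.truth.used == b2.truth.used

    def test_different_seeds_differ(self):
        b1 = end_to_end_fixture(_single_drug_config(seed=5))
        b2 = end_to_end_fixture(_single_drug_config(seed=6))
        assert not b1.matrix.areas.equals(b2.matrix.areas)


class TestFreeText:
    def test_zero_noise_renders_vocabulary_names(self, vocab):
        cfg = _single_drug_config()
        cfg.typo_rate = cfg.brand_name_rate = cfg.unspecified_rate = 0.0
        participants, truth = simulate_cohort(cfg)
        rendered = render_free_text(participants, truth, cfg, vocab)
        for p in rendered:
            for entry in p.med_entries:
                assert vocab.lookup_exact(entry.casefold()) is not None

    def test_all_unspecified_renders_indication_phrases(self, vocab):
        drugs = [
            DrugSpec(
                "metformin", usage_rate=0.5, report_probability=1.0,
                indication="diabetes",
                metabolites=[_met("metformin", 1.0, 0.0)],
            )
        ]
        cfg = SimulationConfig(
            n_participants=200, n_samples_linked=200, seed=3, drugs=drugs,
            unspecified_rate=1.0, n_unknown_metabolites=0,
        )
        participants, truth = simulate_cohort(cfg)
        rendered = render_free_text(participants, truth, cfg, vocab)
        for p in rendered:
            for drug in truth.reported[p.participant_id]:
                if drug == "metformin":
                    assert "tablets for diabetes" in p.med_entries

    def test_typo_rate_recovered(self, vocab):
        cfg = _single_drug_config(n=5000)
        cfg.typo_rate, cfg.brand_name_rate, cfg.unspecified_rate = 0.2, 0.0, 0.0
        participants, truth = simulate_cohort(cfg)
        rendered = render_free_text(participants, truth, cfg, vocab)
        entries = [
            e
            for p in rendered
            for e, d in zip(p.med_entries,
                            sorted(truth.reported[p.participant_id]))
            if d == "warfarin"
        ]
        corrupted = sum(e != "warfarin" for e in entries)
        se = np.sqrt(0.2 * 0.8 / len(entries))
        assert corrupted / len(entries) == pytest.approx(0.2, abs=4 * se + 0.02)


class TestAbundances:
    def test_perfect_sensitivity_recovers_usage_matrix(self):
        cfg = _single_drug_config()
        participants, truth = simulate_cohort(cfg)
        matrix, truth = simulate_abundances(participants, truth, cfg)
        det = call_detection(matrix)
        for pid in matrix.sample_ids:
            assert det.detected.loc[pid, "10-hydroxywarfarin"] == (
                "warfarin" in truth.used[pid]
            )

    def test_false_positive_rate_recovered(self):
        cfg = _single_drug_config(sensitivity=0.0, false_positive_rate=0.05)
        cfg = SimulationConfig(
            n_participants=2000, n_samples_linked=2000, seed=2,
            drugs=cfg.drugs, n_unknown_metabolites=0,
        )
        participants, truth = simulate_cohort(cfg)
        matrix, truth = simulate_abundances(participants, truth, cfg)
        det = call_detection(matrix)
        non_users = [
            pid for pid in matrix.sample_ids
            if "warfarin" not in truth.used[pid]
        ]
        rate = np.mean(
            [det.detected.loc[pid, "10-hydroxywarfarin"] for pid in non_users]
        )
        se = np.sqrt(0.05 * 0.95 / len(non_users))
        assert rate == pytest.approx(0.05, abs=4 * se)

    def test_day_effects_removed_by_normalization(self, default_bundle):
        normalized = normalize_rundays(default_bundle.matrix)
        for _, block in normalized.areas.groupby(normalized.runday):
            med = block.median(axis=0, skipna=True).dropna()
            assert np.allclose(med, 1.0)

    def test_labels_consistent_with_areas(self, default_bundle):
        truth, matrix = default_bundle.truth, default_bundle.matrix
        present = matrix.areas.notna()
        generated = truth.true_positive | truth.false_positive
        assert present.equals(generated[present.columns])


class TestParameterRecovery:
    def test_sensitivity_recovered_within_two_se_pooled(self):
        """Pooled both/N_users across 20 seeds matches the planted 0.8."""
        both = n = 0
        for seed in range(1, 21):
            cfg = _single_drug_config(
                seed=seed, sensitivity=0.8, false_positive_rate=0.01,
                mu_user=8.0,
            )
            participants, truth = simulate_cohort(cfg)
            matrix, truth = simulate_abundances(participants, truth, cfg)
            det = call_detection(matrix)
            users = {
                pid for pid in matrix.sample_ids
                if "warfarin" in truth.used[pid]
            }
            both += len(users & det.detected_in("10-hydroxywarfarin"))
            n += len(users)
        se = np.sqrt(0.8 * 0.2 / n)
        assert both / n == pytest.approx(0.8, abs=2 * se)


class TestConfigValidation:
    def test_linked_samples_cannot_exceed_participants(self):
        with pytest.raises(ValidationError):
            SimulationConfig(n_participants=10, n_samples_linked=11)

    def test_probabilities_bounded(self):
        with pytest.raises(ValidationError):
            _met("m", 1.2, 0.0)
        with pytest.raises(ValidationError):
            DrugSpec("d", usage_rate=0.5, report_probability=1.5,
                     metabolites=[_met("m", 0.5, 0.0)])

    def test_drug_needs_a_metabolite(self):
        with pytest.raises(ValidationError):
            DrugSpec("d", usage_rate=0.1, report_probability=1.0, metabolites=[])
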