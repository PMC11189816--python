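"""Synthetic-data generator: determinism, validity, recovery calibration."""

import numpy as np
import pytest

from neuropep.fixtures import PUBLISHED_PRESENCE_CALLS, PresenceFixture, observations_from_fixture
from neuropep.io import observations_to_frame
from neuropep.mapping import map_observations
from neuropep.presence import build_presence_matrix
from neuropep.simulate import (
    GroundTruth,
    default_ground_truth,
    exact_presence_probability,
    generate,
    hierarchical_calls,
    recovery_experiment,
    synthetic_precursors,
)
from neuropep.types import ValidationError


class TestSyntheticPrecursors:
    def test_deterministic(self):
        a = synthetic_precursors()
        b = synthetic_precursors()
        assert [(p.symbol, p.sequence) for p in a] == [(p.symbol, p.sequence) for p in b]

    def test_every_fixture_peptide_maps_uniquely(self, precursors):
        by_symbol = {p.symbol: p for p in precursors}
        for symbol, start, end, _ in PUBLISHED_PRESENCE_CALLS:
            needle = by_symbol[symbol].sequence[start - 1 : end]
            hits = sum(p.sequence.count(needle) for p in precursors)
            assert hits == 1


class TestGenerate:
    def test_same_seed_gives_byte_identical_tables(self, design, precursors):
        truth = default_ground_truth(precursors, seed=5)
        a = generate(truth, design, precursors, seed=5)
        b = generate(truth, design, precursors, seed=5)
        fa = observations_to_frame(a).to_csv(sep="\t", index=False)
        fb = observations_to_frame(b).to_csv(sep="\t", index=False)
        assert fa == fb

    def test_perfect_detection_realizes_every_present_injection(self, design, precursors):
        truth = default_ground_truth(
            precursors, seed=1, detection_prob=1.0, false_detect_prob=0.0,
            decoy_fraction=0.0,
        )
        table = generate(truth, design, precursors, seed=1)
        n_present_cells = sum(
            len(design.groups[g]) * design.n_culture_reps * design.n_tech_reps
            for (key, (g, c)), present in truth.presence.items()
            if present
        )
        assert len(table) == n_present_cells
        # and none elsewhere
        for o in table:
            assert truth.is_present(
                next(p.key for p in truth.panel if p.sequence == o.sequence),
                o.group, o.condition,
            )

    def test_zero_detection_prob_gives_only_decoys(self, design, precursors):
        truth = default_ground_truth(
            precursors, seed=2, detection_prob=0.0, false_detect_prob=0.0
        )
        table = generate(truth, design, precursors, seed=2)
        assert all(o.is_decoy for o in table)

    def test_empty_panel_rejected(self, design, precursors):
        truth = default_ground_truth(precursors, seed=0)
        truth.panel = []
        with pytest.raises(ValidationError):
            generate(truth, design, precursors)

    def test_generated_tables_pass_core_validation(self, design, precursors):
        truth = default_ground_truth(precursors, seed=3)
        for o in generate(truth, design, precursors, seed=3):
            o.validate(design)

    def test_decoys_never_map_to_any_precursor(self, design, precursors):
        truth = default_ground_truth(precursors, seed=4)
        table = generate(truth, design, precursors, seed=4)
        decoys = [o for o in table if o.is_decoy]
        assert decoys
        _, unmapped = map_observations(decoys, precursors)
        assert sorted(unmapped) == sorted({o.sequence for o in decoys})


class TestFixtureRealization:
    def test_full_fixture_reconstructs_printed_matrix(
        self, design, precursors, fixture_observations
    ):
        mapping, _ = map_observations(fixture_observations, precursors)
        matrix = build_presence_matrix(fixture_observations, mapping, design)
        fixture = PresenceFixture()
        assert len(matrix.peptides) == 29
        for symbol, start, end, calls in fixture.rows:
            for call, col in zip(calls, ("SZ-KCl", "SZ-basal", "HC-KCl", "HC-basal")):
                g, c = col.split("-")
                assert matrix.calls[((symbol, start, end), (g, c))] == (call == "+")

    def test_chgb_restriction_gives_printed_hc_kcl_total(self, design, precursors):
        fixture = PresenceFixture().restrict("CHGB")
        obs = observations_from_fixture(fixture, design, precursors)
        mapping, _ = map_observations(obs, precursors)
        matrix = build_presence_matrix(obs, mapping, design)
        assert len(matrix.present("HC", "KCl")) == 18

    def test_empty_fixture_gives_empty_table(self, design, precursors):
        assert observations_from_fixture(
            PresenceFixture(rows=()), design, precursors
        ) == []


class TestRecovery:
    def test_perfect_detection_gives_perfect_recovery(self, design, precursors):
        truth = default_ground_truth(
            precursors, seed=0, detection_prob=1.0, false_detect_prob=0.0
        )
        rec = recovery_experiment(truth, design, n_sims=5, seed=0)
        for cell in rec.values():
            if cell.sensitivity is not None:
                assert cell.sensitivity == 1.0
            if cell.specificity is not None:
                assert cell.specificity == 1.0

    def test_zero_false_detection_gives_exact_specificity_one(self, design, precursors):
        truth = default_ground_truth(
            precursors, seed=0, detection_prob=0.5, false_detect_prob=0.0
        )
        rec = recovery_experiment(truth, design, n_sims=20, seed=1)
        for cell in rec.values():
            if cell.specificity is not None:
                assert cell.specificity == 1.0

    def test_oracle_composition_values(self, design):
        """Exact binomial composition: p=0.9/injection -> pair 0.99 ->
        subject ~0.999702 -> HC group essentially certain."""
        from scipy.stats import binom

        p_pair = 1 - 0.1 ** 2
        p_subject = 3 * p_pair ** 2 * (1 - p_pair) + p_pair ** 3
        expected_hc = float(binom.sf(3, 6, p_subject))
        assert exact_presence_probability(0.9, design, "HC") == pytest.approx(
            expected_hc, rel=1e-12
        )
        assert expected_hc > 0.999999

    def test_vectorized_calls_agree_with_scalar_rule(self, design):
        """The numpy hierarchy matches per-element counting."""
        rng = np.random.default_rng(123)
        det = rng.random((50, 4, 6, 3, 2)) < 0.5
        calls = hierarchical_calls(det, design, "HC")
        for sim in range(5):
            for pep in range(4):
                subj_calls = 0
                for s in range(6):
                    cults = sum(
                        det[sim, pep, s, c].sum() >= design.tech_threshold
                        for c in range(3)
                    )
                    subj_calls += cults >= design.culture_threshold
                assert calls[sim, pep] == (
                    subj_calls >= design.group_presence_threshold["HC"]
                )

    def test_n_sims_must_be_positive(self, design, precursors):
        truth = default_ground_truth(precursors, seed=0)
        with pytest.raises(ValidationError):
            recovery_experiment(truth, design, n_sims=0)

    def test_recovery_matches_generate_pipeline_on_moderate_dropout(
        self, design, precursors
    ):
        """Cross-validation of the vectorized recovery path: presence calls
        from full generated tables (no noise gates in the way: all rows pass
        the default filters' intent since detection events are what matter)
        estimate the same sensitivity as the vectorized simulation."""
        truth = default_ground_truth(
            precursors, seed=9, detection_prob=0.6, false_detect_prob=0.0,
            decoy_fraction=0.0,
        )
        n_reps = 40
        hits = 0
        trials = 0
        present_keys = [
            k for (k, cell), v in truth.presence.items()
            if v and cell == ("HC", "KCl")
        ]
        present_keys = sorted(set(present_keys))
        for rep in range(n_reps):
            table = generate(truth, design, precursors, seed=1000 + rep)
            mapping, _ = map_observations(table, precursors)
            matrix = build_presence_matrix(table, mapping, design)
            for k in present_keys:
                trials += 1
                hits += bool(matrix.calls.get((k, ("HC", "KCl")), False))
        est = hits / trials
        p = exact_presence_probability(0.6, design, "HC")
        se = (p * (1 - p) / trials) ** 0.5
        assert abs(est - p) <= 3 * se
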