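"""Hierarchical presence calling: injections -> cultures -> subjects -> groups."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from neuropep.fixtures import CALL_COLUMNS, PresenceFixture, observations_from_fixture
from neuropep.mapping import map_observations
from neuropep.presence import (
    build_presence_matrix,
    call_culture,
    call_group,
    call_subject,
)
from neuropep.types import PeptideObservation, StudyDesign, ValidationError, default_design


def _det(subject="A", group="SZ", condition="KCl", culture=1, tech=1, sequence="PEPTIDE"):
    return PeptideObservation(
        sequence=sequence, modifications=[], precursor_accession="P1",
        abundance=2e4, quality=0.9, rt_min=10.0, mz=500.0,
        subject_id=subject, group=group, condition=condition,
        culture_rep=culture, tech_rep=tech,
    )


class TestCultureCall:
    def test_one_of_two_injections_suffices(self):
        assert call_culture([_det(tech=1)], tech_threshold=1)

    def test_no_injection_is_absent(self):
        assert not call_culture([], tech_threshold=1)

    def test_repeat_detections_in_one_injection_count_once(self):
        obs = [_det(tech=1), _det(tech=1)]
        assert call_culture(obs, tech_threshold=1)
        assert not call_culture(obs, tech_threshold=2)


class TestSubjectCall:
    @pytest.mark.parametrize(
        "calls,expected",
        [((True, True, False), True), ((True, False, False), False),
         ((False, False, False), False), ((True, True, True), True)],
    )
    def test_two_of_three_cultures(self, calls, expected):
        assert call_subject(calls, culture_threshold=2) is expected

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValidationError):
            call_subject((True, True), culture_threshold=2, expected_n=3)


class TestGroupCall:
    def test_sz_five_of_seven(self, design):
        calls = {s: i < 5 for i, s in enumerate(design.groups["SZ"])}
        assert call_group(calls, "SZ", design)

    def test_sz_four_of_seven_fails(self, design):
        calls = {s: i < 4 for i, s in enumerate(design.groups["SZ"])}
        assert not call_group(calls, "SZ", design)

    def test_hc_four_of_six(self, design):
        calls = {s: i < 4 for i, s in enumerate(design.groups["HC"])}
        assert call_group(calls, "HC", design)

    def test_foreign_subject_rejected(self, design):
        with pytest.raises(ValidationError):
            call_group({"ZZ": True}, "SZ", design)


class TestExhaustiveEnumeration:
    """Each level of the rule agrees with brute-force counting over every
    boolean detection pattern."""

    def test_culture_level_all_patterns(self):
        for pattern in itertools.product([False, True], repeat=2):
            obs = [_det(tech=i + 1) for i, d in enumerate(pattern) if d]
            for thr in (1, 2):
                assert call_culture(obs, thr) == (sum(pattern) >= thr)

    def test_subject_level_all_patterns(self):
        for pattern in itertools.product([False, True], repeat=3):
            for thr in (1, 2, 3):
                assert call_subject(pattern, thr) == (sum(pattern) >= thr)

    @pytest.mark.parametrize("group,n", [("SZ", 7), ("HC", 6)])
    def test_group_level_all_patterns(self, design, group, n):
        subjects = design.groups[group]
        thr = design.group_presence_threshold[group]
        for bits in range(2 ** n):
            pattern = [(bits >> i) & 1 == 1 for i in range(n)]
            calls = dict(zip(subjects, pattern))
            assert call_group(calls, group, design) == (sum(pattern) >= thr)

    def test_extreme_thresholds_reduce_to_everywhere_and_anywhere(self):
        """Thresholds at maxima = detected everywhere; at minima = detected
        at least once in the group."""
        base = dict(groups={"SZ": list("ABCDEFG"), "HC": list("HIJKLM")})
        strict = StudyDesign(**base, group_presence_threshold={"SZ": 7, "HC": 6},
                             tech_threshold=2, culture_threshold=3)
        loose = StudyDesign(**base, group_presence_threshold={"SZ": 1, "HC": 1},
                            tech_threshold=1, culture_threshold=1)
        subjects = strict.groups["SZ"]
        # strict: every subject needs every culture and both injections
        full = [_det(subject=s, culture=c, tech=t)
                for s in subjects for c in (1, 2, 3) for t in (1, 2)]
        almost = [o for o in full if not (o.subject_id == "A" and o.culture_rep == 3
                                          and o.tech_rep == 2)]

        def group_call(observations, design):
            subj_calls = {}
            for s in subjects:
                cults = []
                for c in (1, 2, 3):
                    cults.append(call_culture(
                        [o for o in observations
                         if o.subject_id == s and o.culture_rep == c],
                        design.tech_threshold))
                subj_calls[s] = call_subject(cults, design.culture_threshold)
            return call_group(subj_calls, "SZ", design)

        assert group_call(full, strict)
        assert not group_call(almost, strict)
        single = [_det(subject="C", culture=2, tech=2)]
        assert group_call(single, loose)
        assert not group_call([], loose)


class TestMatrix:
    def test_single_cell_detection_pattern(self, design, precursors):
        chgb = next(p for p in precursors if p.symbol == "CHGB")
        seq = chgb.sequence[87:100]
        obs = [
            _det(subject=s, group="SZ", condition="KCl", culture=c, tech=t, sequence=seq)
            for s in design.groups["SZ"] for c in (1, 2, 3) for t in (1, 2)
        ]
        mapping, _ = map_observations(obs, precursors)
        matrix = build_presence_matrix(obs, mapping, design)
        key = ("CHGB", 88, 100)
        assert matrix.calls[(key, ("SZ", "KCl"))]
        assert not matrix.calls[(key, ("SZ", "basal"))]
        assert not matrix.calls[(key, ("HC", "KCl"))]
        assert not matrix.calls[(key, ("HC", "basal"))]

    def test_empty_observation_set_gives_empty_matrix(self, design, precursors):
        mapping, _ = map_observations([], precursors)
        matrix = build_presence_matrix([], mapping, design)
        assert matrix.peptides == []

    def test_fixture_reproduces_printed_matrix_exactly(
        self, design, precursors, fixture_observations
    ):
        """The minimal threshold-satisfying realization reconstructs all
        29 x 4 printed presence calls, including the all-absent rows."""
        fixture = PresenceFixture()
        mapping, _ = map_observations(fixture_observations, precursors)
        matrix = build_presence_matrix(fixture_observations, mapping, design)
        assert len(matrix.peptides) == 29
        for symbol, start, end, calls in fixture.rows:
            for col, cell in zip(CALL_COLUMNS, calls):
                group, condition = col.split("-")
                assert matrix.calls[((symbol, start, end), (group, condition))] == (
                    cell == "+"
                ), f"{symbol} {start}-{end} {col}"
        matrix.check()  # threshold-consistency invariants across levels

    def test_matrix_export_shape(self, design, precursors, fixture_observations):
        mapping, _ = map_observations(fixture_observations, precursors)
        matrix = build_presence_matrix(fixture_observations, mapping, design)
        frame = matrix.to_frame()
        assert list(frame.columns) == [
            "precursor", "peptide", "SZ-KCl", "SZ-basal", "HC-KCl", "HC-basal"
        ]
        assert len(frame) == 29
        assert set(frame["SZ-KCl"].unique()) <= {"+", "-"}

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(data=st.data())
    def test_adding_a_detection_never_flips_true_to_false(
        self, data, design, precursors
    ):
        """Monotonicity of the hierarchical rule."""
        chgb = next(p for p in precursors if p.symbol == "CHGB")
        seq = chgb.sequence[87:100]
        subjects = design.groups["SZ"] + design.groups["HC"]
        cells = [(s, c, t) for s in subjects for c in (1, 2, 3) for t in (1, 2)]
        chosen = data.draw(st.lists(st.sampled_from(cells), max_size=30, unique=True))
        extra = data.draw(st.sampled_from(cells))

        def build(detections):
            obs = [
                _det(subject=s, group=design.group_of(s), condition="KCl",
                     culture=c, tech=t, sequence=seq)
                for s, c, t in detections
            ]
            mapping, _ = map_observations(obs, precursors)
            return build_presence_matrix(obs, mapping, design)

        before = build(chosen)
        after = build(set(chosen) | {extra})
        for cell_key, value in before.calls.items():
            if value:
                assert after.calls[cell_key]
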