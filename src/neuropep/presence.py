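"""Hierarchical presence-absence calling.

A peptide is considered identified and quantified

* in a culture replicate, if detected in at least 1 of 2 technical injections;
* in a subject, if called in at least 2 of 3 culture replicates;
* in the SZ group, if called in at least 5 of 7 subjects; and
* in the HC group, if called in at least 4 of 6 subjects

(all thresholds configurable through :class:`~neuropep.types.StudyDesign`).
Peptide identity at this stage is the precursor coordinate triple
(symbol, start, end): modification states collapse onto one peptide.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .mapping import MappedPeptide
from .types import PeptideObservation, StudyDesign, ValidationError

PeptideKey = tuple[str, int, int]  # (precursor_symbol, start, end)


@dataclass(frozen=True)
class PeptideEntry:
    precursor_symbol: str
    start: int
    end: int
    sequence: str
    ambiguous: bool = False

    @property
    def key(self) -> PeptideKey:
        return (self.precursor_symbol, self.start, self.end)

    @property
    def label(self) -> str:
        return f"{self.precursor_symbol} {self.start}-{self.end}"


def call_culture(
    observations: Sequence[PeptideObservation], tech_threshold: int
) -> bool:
    """Culture-replicate call: detections must span at least ``tech_threshold``
    *distinct* technical replicates (repeat detections in one injection count
    once)."""
    return len({o.tech_rep for o in observations}) >= tech_threshold


def call_subject(
    culture_calls: Sequence[bool],
    culture_threshold: int,
    expected_n: int | None = None,
) -> bool:
    """Subject call: at least ``culture_threshold`` culture replicates called.

    When ``expected_n`` is given, the number of entries must match the design
    exactly (uncalled cultures are passed as ``False``, not omitted)."""
    if expected_n is not None and len(culture_calls) != expected_n:
        raise ValidationError(
            f"expected {expected_n} culture calls, got {len(culture_calls)}"
        )
    return sum(bool(c) for c in culture_calls) >= culture_threshold


def call_group(
    subject_calls: Mapping[str, bool], group: str, design: StudyDesign
) -> bool:
    """Group call: at least the group's subject threshold called present."""
    if group not in design.groups:
        raise ValidationError(f"unknown group {group!r}")
    members = set(design.groups[group])
    foreign = set(subject_calls) - members
    if foreign:
        raise ValidationError(f"subject(s) {sorted(foreign)} not in group {group!r}")
    n_true = sum(bool(subject_calls.get(s, False)) for s in members)
    return n_true >= design.group_presence_threshold[group]


@dataclass
class PresenceMatrix:
    """Peptide x (group, condition) boolean calls with per-subject and
    per-culture detail.

    Invariants (held by construction, re-checkable via :meth:`check`):
    a group call is true iff enough subject calls are true; a subject call is
    true iff enough culture calls are true.
    """

    peptides: list[PeptideEntry]
    calls: dict[tuple[PeptideKey, tuple[str, str]], bool]
    subject_detail: dict[tuple[PeptideKey, str, str], bool]
    culture_detail: dict[tuple[PeptideKey, str, str, int], bool]
    design: StudyDesign

    def present(self, group: str, condition: str) -> set[PeptideKey]:
        return {
            p.key
            for p in self.peptides
            if self.calls.get((p.key, (group, condition)), False)
        }

    def entry(self, key: PeptideKey) -> PeptideEntry:
        for p in self.peptides:
            if p.key == key:
                return p
        raise KeyError(key)

    def check(self) -> None:
        """Re-verify the threshold consistency invariants across levels."""
        d = self.design
        for p in self.peptides:
            for condition in d.conditions:
                for group, subjects in d.groups.items():
                    n_subj = sum(
                        self.subject_detail.get((p.key, s, condition), False)
                        for s in subjects
                    )
                    expected = n_subj >= d.group_presence_threshold[group]
                    if self.calls[(p.key, (group, condition))] != expected:
                        raise ValidationError(
                            f"group-call inconsistency at {p.label} {group}/{condition}"
                        )
                    for s in subjects:
                        n_cult = sum(
                            self.culture_detail.get((p.key, s, condition, c), False)
                            for c in range(1, d.n_culture_reps + 1)
                        )
                        expected_s = n_cult >= d.culture_threshold
                        if self.subject_detail.get((p.key, s, condition), False) != expected_s:
                            raise ValidationError(
                                f"subject-call inconsistency at {p.label} {s}/{condition}"
                            )

    # -- exports ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Presence matrix as +/- strings, one row per peptide, columns
        ordered SZ-KCl, SZ-basal, HC-KCl, HC-basal."""
        cols = [
            (g, c)
            for g in self.design.groups
            for c in self.design.conditions
        ]
        rows = []
        for p in self.peptides:
            row = {
                "precursor": p.precursor_symbol,
                "peptide": f"{p.start}-{p.end}",
            }
            for g, c in cols:
                row[f"{g}-{c}"] = "+" if self.calls[(p.key, (g, c))] else "-"
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def subject_detail_frame(self) -> pd.DataFrame:
        """Per-subject detail, one row per peptide x condition, one column
        per subject (+/-)."""
        subjects = [s for g in self.design.groups.values() for s in g]
        rows = []
        for p in self.peptides:
            for condition in self.design.conditions:
                row = {
                    "precursor": p.precursor_symbol,
                    "peptide": f"{p.start}-{p.end}",
                    "condition": condition,
                }
                for s in subjects:
                    row[s] = (
                        "+" if self.subject_detail.get((p.key, s, condition), False) else "-"
                    )
                rows.append(row)
        return pd.DataFrame(rows)


def build_presence_matrix(
    observations: Iterable[PeptideObservation],
    mapping: Mapping[str, MappedPeptide],
    design: StudyDesign,
) -> PresenceMatrix:
    """Compose the three-level rule over filtered, mapped observations.

    Decoy rows and sequences absent from ``mapping`` (unmappable peptides)
    are ignored.  Peptides detected only below threshold still appear as
    all-false rows — absence is informative and exported.
    """
    # detections[(key, subject, condition, culture)] -> set of tech reps
    detections: dict[tuple[PeptideKey, str, str, int], set[int]] = {}
    entries: dict[PeptideKey, PeptideEntry] = {}
    for obs in observations:
        if obs.is_decoy:
            continue
        mapped = mapping.get(obs.sequence)
        if mapped is None:
            continue
        key = mapped.key
        if key not in entries:
            entries[key] = PeptideEntry(
                precursor_symbol=mapped.precursor_symbol,
                start=mapped.start,
                end=mapped.end,
                sequence=mapped.sequence,
                ambiguous=mapped.ambiguous,
            )
        design.validate_coordinates(obs)
        detections.setdefault(
            (key, obs.subject_id, obs.condition, obs.culture_rep), set()
        ).add(obs.tech_rep)

    peptides = sorted(entries.values(), key=lambda p: p.key)
    culture_detail: dict[tuple[PeptideKey, str, str, int], bool] = {}
    subject_detail: dict[tuple[PeptideKey, str, str], bool] = {}
    calls: dict[tuple[PeptideKey, tuple[str, str]], bool] = {}
    for p in peptides:
        for condition in design.conditions:
            for group, subjects in design.groups.items():
                subj_calls: dict[str, bool] = {}
                for s in subjects:
                    cult_calls = []
                    for c in range(1, design.n_culture_reps + 1):
                        techs = detections.get((p.key, s, condition, c), set())
                        called = len(techs) >= design.tech_threshold
                        culture_detail[(p.key, s, condition, c)] = called
                        cult_calls.append(called)
                    subj_calls[s] = call_subject(
                        cult_calls, design.culture_threshold, design.n_culture_reps
                    )
                    subject_detail[(p.key, s, condition)] = subj_calls[s]
                calls[(p.key, (group, condition))] = call_group(
                    subj_calls, group, design
                )
    return PresenceMatrix(
        peptides=peptides,
        calls=calls,
        subject_detail=subject_detail,
        culture_detail=culture_detail,
        design=design,
    )
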