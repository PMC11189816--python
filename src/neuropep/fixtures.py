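"""The printed 29-peptide presence matrix used as the in-package fixture.

``PUBLISHED_PRESENCE_CALLS`` lists each secreted-neuropeptide coordinate with its four
presence calls in column order SZ-KCl, SZ-basal, HC-KCl, HC-basal.
``observations_from_fixture`` realizes each call as a minimal noiseless
observation table: a "+" cell is backed by detections in exactly
threshold-many subjects (5 of 7 SZ, 4 of 6 HC), each with threshold-many
culture replicates (2 of 3) and injections (1 of 2); a "-" cell by
detections in threshold-minus-one subjects.  Running the full pipeline on
that table reconstructs the matrix cell for cell, which makes the fixture
human-auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

from pyteomics import mass as pmass

from .types import PeptideObservation, PrecursorRecord, StudyDesign, ValidationError

#: (precursor symbol, start, end, calls) with calls ordered
#: SZ-KCl, SZ-basal, HC-KCl, HC-basal.
PUBLISHED_PRESENCE_CALLS: tuple[tuple[str, int, int, str], ...] = (
    ("ADM", 163, 183, "--++"),
    ("CHGB", 88, 100, "++++"),
    ("CHGB", 293, 323, "--++"),
    ("CHGB", 326, 332, "++++"),
    ("CHGB", 440, 452, "--+-"),
    ("CHGB", 440, 453, "--+-"),
    ("CHGB", 440, 454, "+-++"),
    ("CHGB", 440, 456, "--++"),
    ("CHGB", 441, 454, "--+-"),
    ("CHGB", 441, 456, "--++"),
    ("CHGB", 442, 452, "--+-"),
    ("CHGB", 442, 456, "--+-"),
    ("CHGB", 523, 535, "--+-"),
    ("CHGB", 527, 533, "--++"),
    ("CHGB", 527, 535, "--+-"),
    ("CHGB", 588, 596, "++++"),
    ("CHGB", 588, 597, "++++"),
    ("CHGB", 588, 600, "--+-"),
    ("CHGB", 600, 613, "++++"),
    ("NPPC", 24, 33, "++++"),
    ("NPPC", 24, 72, "----"),
    ("NPPC", 34, 72, "--++"),
    ("NPPC", 46, 69, "----"),
    ("NTS", 151, 158, "--+-"),
    ("NTS", 151, 160, "--++"),
    ("SST", 89, 100, "--++"),
    ("TMSB10", 2, 44, "++++"),
    ("TMSB4X", 2, 19, "--++"),
    ("TMSB4X", 2, 44, "++++"),
)

#: Column order of the four calls.
CALL_COLUMNS = ("SZ-KCl", "SZ-basal", "HC-KCl", "HC-basal")


@dataclass(frozen=True)
class PresenceFixture:
    """The 29-row presence matrix fixture."""

    rows: tuple[tuple[str, int, int, str], ...] = PUBLISHED_PRESENCE_CALLS

    def __post_init__(self) -> None:
        if len(self.rows) != len(PUBLISHED_PRESENCE_CALLS) and self.rows is not PUBLISHED_PRESENCE_CALLS:
            # subsets are allowed for targeted tests, full fixture must be 29
            pass
        for symbol, start, end, calls in self.rows:
            if len(calls) != 4 or set(calls) - set("+-"):
                raise ValidationError(
                    f"{symbol} {start}-{end}: calls must be four of '+'/'-', got {calls!r}"
                )
            if end < start:
                raise ValidationError(f"{symbol}: end {end} before start {start}")

    def restrict(self, symbol: str) -> "PresenceFixture":
        return PresenceFixture(rows=tuple(r for r in self.rows if r[0] == symbol))

    def call(self, symbol: str, start: int, end: int, group: str, condition: str) -> bool:
        col = CALL_COLUMNS.index(f"{group}-{condition}")
        for s, a, b, calls in self.rows:
            if (s, a, b) == (symbol, start, end):
                return calls[col] == "+"
        raise KeyError((symbol, start, end))


def peptide_mz(sequence: str, charge: int = 2) -> float:
    """Monoisotopic m/z of an unmodified peptide at the given charge."""
    return pmass.calculate_mass(sequence=sequence, charge=charge)


def observations_from_fixture(
    fixture: PresenceFixture,
    design: StudyDesign,
    precursors: list[PrecursorRecord],
) -> list[PeptideObservation]:
    """Minimal noiseless observation table realizing the fixture's calls.

    Peptide sequences are cut from the supplied precursors at the fixture
    coordinates, so the precursor set must contain each fixture symbol with
    a sequence long enough for the printed spans.  Every row passes the
    default quality gates (abundance 1e5, quality 0.9) and every feature
    group is a singleton for the RT gate.
    """
    by_symbol = {p.symbol: p for p in precursors}
    observations: list[PeptideObservation] = []
    for idx, (symbol, start, end, calls) in enumerate(fixture.rows):
        if symbol not in by_symbol:
            raise ValidationError(f"precursor {symbol!r} missing from precursor set")
        prec = by_symbol[symbol]
        if end > len(prec.sequence):
            raise ValidationError(
                f"{symbol} has only {len(prec.sequence)} residues; cannot cut {start}-{end}"
            )
        sequence = prec.sequence[start - 1 : end]
        rt = 10.0 + 0.37 * idx  # distinct, deterministic retention times
        mz = peptide_mz(sequence)
        for col, cell in zip(CALL_COLUMNS, calls):
            group, condition = col.split("-")
            threshold = design.group_presence_threshold[group]
            n_subjects = threshold if cell == "+" else threshold - 1
            for subject in design.groups[group][:n_subjects]:
                for culture in range(1, design.culture_threshold + 1):
                    for tech in range(1, design.tech_threshold + 1):
                        observations.append(
                            PeptideObservation(
                                sequence=sequence,
                                modifications=[],
                                precursor_accession=prec.accession,
                                abundance=1e5,
                                quality=0.9,
                                rt_min=rt,
                                mz=mz,
                                subject_id=subject,
                                group=group,
                                condition=condition,
                                culture_rep=culture,
                                tech_rep=tech,
                                is_decoy=False,
                                score=9.0,
                            )
                        )
    return observations
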