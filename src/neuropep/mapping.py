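"""Anchoring peptides to proneuropeptide precursor coordinates.

Coordinates are 1-based inclusive residue numbers over the full precursor
sequence (signal peptide included), so a 9-residue peptide starting at
residue 588 spans 588-596.  Matching is PTM-aware: methionine oxidation,
N-terminal acetylation and C-terminal amidation are mass-only and never
change the matched letters; N-terminal pyro-glutamate derives from a
genomically encoded Q or E, so the backbone letter is matched as written.
Isoleucine and leucine are kept distinct.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .types import (
    C_TERM,
    MOD_ACETYL,
    MOD_AMIDATION,
    MOD_OXIDATION,
    MOD_PYROGLU,
    N_TERM,
    Modification,
    NoMatchError,
    PeptideObservation,
    PrecursorRecord,
    ValidationError,
)


@dataclass(frozen=True)
class MappedPeptide:
    """A peptide anchored to precursor residue coordinates.

    ``all_sites`` lists every (symbol, start, end) occurrence across the
    precursor set; the primary (``precursor_symbol``, ``start``, ``end``) is
    the lexicographically smallest (symbol, start).  ``ambiguous`` is true
    when the peptide maps to more than one site or precursor.
    """

    sequence: str
    precursor_symbol: str
    start: int
    end: int
    ambiguous: bool
    all_sites: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValidationError(
                f"span {self.start}-{self.end} inconsistent with peptide length "
                f"{len(self.sequence)}"
            )

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.precursor_symbol, self.start, self.end)


def normalize_for_matching(sequence: str, modifications: Sequence[Modification]) -> str:
    """Return the unmodified backbone used for substring search.

    Validates modification/residue compatibility: oxidation requires M at
    the modified position; pyro-glu must sit at the N-terminus on Q or E;
    acetylation is N-terminal; amidation is C-terminal.
    """
    n = len(sequence)
    for mod in modifications:
        pos = mod.position
        if mod.name == MOD_OXIDATION:
            if not isinstance(pos, int):
                raise ValidationError("oxidation requires a residue index")
            if pos > n or sequence[pos - 1] != "M":
                raise ValidationError(
                    f"oxidation at position {pos} of {sequence!r}: residue is not M"
                )
        elif mod.name == MOD_PYROGLU:
            if not (pos == N_TERM or pos == 1):
                raise ValidationError("pyro-glu must be N-terminal")
            if sequence[0] not in ("Q", "E"):
                raise ValidationError(
                    f"pyro-glu on {sequence!r}: N-terminal residue is not Q or E"
                )
        elif mod.name == MOD_ACETYL:
            if not (pos == N_TERM or pos == 1):
                raise ValidationError("N-term acetylation must sit at the N-terminus")
        elif mod.name == MOD_AMIDATION:
            if not (pos == C_TERM or pos == n):
                raise ValidationError("amidation must sit at the C-terminus")
        if isinstance(pos, int) and pos > n:
            raise ValidationError(f"modification position {pos} outside peptide")
    return sequence


def _occurrences(needle: str, haystack: str) -> list[int]:
    """All (possibly overlapping) 0-based start positions of needle in haystack."""
    positions = []
    start = haystack.find(needle)
    while start != -1:
        positions.append(start)
        start = haystack.find(needle, start + 1)
    return positions


def map_peptide(backbone: str, precursors: Sequence[PrecursorRecord]) -> MappedPeptide:
    """Locate a backbone sequence in a precursor set by exhaustive substring search."""
    if not precursors:
        raise ValidationError("empty precursor set")
    sites: list[tuple[str, int, int]] = []
    for prec in precursors:
        for pos in _occurrences(backbone, prec.sequence):
            start = pos + 1
            sites.append((prec.symbol, start, start + len(backbone) - 1))
    if not sites:
        raise NoMatchError(backbone)
    sites.sort()
    symbol, start, end = sites[0]
    return MappedPeptide(
        sequence=backbone,
        precursor_symbol=symbol,
        start=start,
        end=end,
        ambiguous=len(sites) > 1,
        all_sites=tuple(sites),
    )


def map_observations(
    observations: Iterable[PeptideObservation],
    precursors: Sequence[PrecursorRecord],
) -> tuple[dict[str, MappedPeptide], list[str]]:
    """Map each distinct backbone among the observations.

    Returns ``(mapping, unmapped)``: a dict from backbone sequence to
    :class:`MappedPeptide`, and the list of sequences with no precursor hit
    (decoys land here by construction).
    """
    mapping: dict[str, MappedPeptide] = {}
    unmapped: list[str] = []
    for obs in observations:
        backbone = normalize_for_matching(obs.sequence, obs.modifications)
        if backbone in mapping or backbone in unmapped:
            continue
        try:
            mapping[backbone] = map_peptide(backbone, precursors)
        except NoMatchError:
            unmapped.append(backbone)
    return mapping, unmapped


def coverage_map(
    mapped: Sequence[MappedPeptide],
    precursor: PrecursorRecord,
    labels: Mapping[str, str] | None = None,
) -> list[list[tuple[str, str]]]:
    """Per-residue annotation track for one precursor.

    Returns a list with one entry per precursor residue (index 0 = residue
    1); each entry lists ``(sequence, label)`` for every peptide covering
    that residue.  ``labels`` maps peptide sequence to a group label such as
    ``SZ-only`` / ``HC-only`` / ``shared`` (defaults to ``""``).
    """
    track: list[list[tuple[str, str]]] = [[] for _ in precursor.sequence]
    labels = labels or {}
    for pep in mapped:
        if pep.precursor_symbol != precursor.symbol:
            raise ValidationError(
                f"peptide {pep.sequence!r} maps to {pep.precursor_symbol}, "
                f"not {precursor.symbol}"
            )
        label = labels.get(pep.sequence, "")
        for residue in range(pep.start, pep.end + 1):
            track[residue - 1].append((pep.sequence, label))
    return track


def render_coverage_text(
    mapped: Sequence[MappedPeptide],
    precursor: PrecursorRecord,
    labels: Mapping[str, str] | None = None,
    width: int = 60,
) -> str:
    """Plain-text coverage rendering: the precursor sequence in blocks with
    one line per covering peptide, annotated with its span and label."""
    labels = labels or {}
    lines = [f"# {precursor.symbol} ({len(precursor.sequence)} aa)"]
    peps = sorted(mapped, key=lambda p: (p.start, p.end))
    for block_start in range(0, len(precursor.sequence), width):
        block_end = min(block_start + width, len(precursor.sequence))
        lines.append(f"{block_start + 1:>5} {precursor.sequence[block_start:block_end]}")
        for pep in peps:
            s, e = pep.start - 1, pep.end  # 0-based half-open
            if e <= block_start or s >= block_end:
                continue
            pad = " " * (max(s, block_start) - block_start)
            bar = "=" * (min(e, block_end) - max(s, block_start))
            tag = labels.get(pep.sequence, "")
            lines.append(f"      {pad}{bar}  [{pep.start}-{pep.end}] {tag}".rstrip())
    return "\n".join(lines) + "\n"


def write_mapping_table(
    mapped: Iterable[MappedPeptide], path: str | Path
) -> pd.DataFrame:
    frame = pd.DataFrame(
        [
            {
                "sequence": m.sequence,
                "precursor_symbol": m.precursor_symbol,
                "start": m.start,
                "end": m.end,
                "ambiguous": m.ambiguous,
                "n_sites": len(m.all_sites),
            }
            for m in mapped
        ],
        columns=["sequence", "precursor_symbol", "start", "end", "ambiguous", "n_sites"],
    )
    frame.to_csv(path, sep="\t", index=False)
    return frame
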