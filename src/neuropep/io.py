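"""Readers and writers for observation tables and precursor FASTA.

The canonical observation table is a UTF-8, tab-separated file with a header
row and one identified feature-injection per row.  Column names can be
remapped for foreign exports through a :class:`Dialect`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .types import (
    ConfigError,
    Modification,
    PeptideObservation,
    PrecursorRecord,
    StudyDesign,
    ValidationError,
)

#: Canonical column order of the observation TSV.
CANONICAL_COLUMNS = (
    "sequence",
    "modifications",
    "precursor_accession",
    "abundance",
    "quality",
    "score",
    "rt_min",
    "mz",
    "subject_id",
    "group",
    "condition",
    "culture_rep",
    "tech_rep",
    "is_decoy",
)

_MANDATORY = tuple(c for c in CANONICAL_COLUMNS if c not in ("score", "is_decoy"))


@dataclass(frozen=True)
class Dialect:
    """Mapping from canonical column names to the file's column names.

    Only names that differ need to be listed.  Real exports generally lack
    an ``is_decoy`` column; rows then default to target (non-decoy).
    """

    columns: dict[str, str] = field(default_factory=dict)

    def file_column(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


CANONICAL_DIALECT = Dialect()


def format_modifications(mods: Sequence[Modification]) -> str:
    """Serialize modifications as ``name@pos`` items joined by ``;``."""
    return ";".join(f"{m.name}@{m.position}" for m in mods)


def parse_modifications(text: str) -> list[Modification]:
    if not text or (isinstance(text, float) and math.isnan(text)):
        return []
    mods = []
    for item in str(text).split(";"):
        item = item.strip()
        if not item:
            continue
        try:
            name, pos = item.rsplit("@", 1)
        except ValueError:
            raise ValidationError(f"malformed modification {item!r}") from None
        position: int | str = int(pos) if pos.lstrip("-").isdigit() else pos
        mods.append(Modification(position=position, name=name))
    return mods


@dataclass
class RowError:
    """A located row-level diagnostic from reading an observation table."""

    line: int  # 1-based line number in the file (header = line 1)
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"line {self.line}: {self.message}"


@dataclass
class ReadReport:
    observations: list[PeptideObservation]
    errors: list[RowError]


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, float) and math.isnan(value):
        return False
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE or text == "nan":
        return False
    raise ValidationError(f"cannot interpret {value!r} as boolean")


def _parse_float(value, what: str, allow_missing: bool = False) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        if allow_missing:
            return None
        raise ValidationError(f"missing {what}")
    text = str(value).strip()
    if text in ("", "NA", "nan", "NaN"):
        if allow_missing:
            return None
        raise ValidationError(f"missing {what}")
    try:
        return float(text)
    except ValueError:
        raise ValidationError(f"unparseable {what}: {value!r}") from None


def read_observations(
    path: str | Path,
    dialect: Dialect = CANONICAL_DIALECT,
    design: StudyDesign | None = None,
    on_error: str = "raise",
) -> ReadReport:
    """Read a long-format observation table.

    Every row is either parsed into a :class:`PeptideObservation` or rejected
    with a line-numbered :class:`RowError`; rows are never dropped silently.
    With ``on_error="raise"`` (default) any row error raises a
    :class:`ValidationError` carrying the full report; with ``"collect"``
    errors are returned alongside the successfully parsed rows.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"observation table not found: {path}")
    if on_error not in ("raise", "collect"):
        raise ConfigError(f"on_error must be 'raise' or 'collect', got {on_error!r}")

    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    colmap = {c: dialect.file_column(c) for c in CANONICAL_COLUMNS}
    missing = [colmap[c] for c in _MANDATORY if colmap[c] not in frame.columns]
    if missing:
        raise ConfigError(f"{path}: missing mandatory column(s) {missing}")

    observations: list[PeptideObservation] = []
    errors: list[RowError] = []
    has_score = colmap["score"] in frame.columns
    has_decoy = colmap["is_decoy"] in frame.columns

    for idx, row in enumerate(frame.itertuples(index=False)):
        line = idx + 2  # header is line 1
        rec = dict(zip(frame.columns, row))
        try:
            obs = PeptideObservation(
                sequence=str(rec[colmap["sequence"]]).strip().upper(),
                modifications=parse_modifications(rec[colmap["modifications"]]),
                precursor_accession=str(rec[colmap["precursor_accession"]]).strip(),
                abundance=_parse_float(rec[colmap["abundance"]], "abundance", allow_missing=True),
                quality=_parse_float(rec[colmap["quality"]], "quality"),
                rt_min=_parse_float(rec[colmap["rt_min"]], "rt_min"),
                mz=_parse_float(rec[colmap["mz"]], "mz"),
                subject_id=str(rec[colmap["subject_id"]]).strip(),
                group=str(rec[colmap["group"]]).strip(),
                condition=str(rec[colmap["condition"]]).strip(),
                culture_rep=int(rec[colmap["culture_rep"]]),
                tech_rep=int(rec[colmap["tech_rep"]]),
                is_decoy=_parse_bool(rec[colmap["is_decoy"]]) if has_decoy else False,
                score=_parse_float(rec[colmap["score"]], "score", allow_missing=True)
                if has_score
                else None,
            )
            obs.validate(design)
        except (ValidationError, ValueError) as exc:
            errors.append(RowError(line=line, message=str(exc)))
            continue
        observations.append(obs)

    if errors and on_error == "raise":
        preview = "; ".join(str(e) for e in errors[:5])
        raise ValidationError(
            f"{path}: {len(errors)} invalid row(s): {preview}"
            + (" ..." if len(errors) > 5 else "")
        )
    return ReadReport(observations=observations, errors=errors)


def observations_to_frame(observations: Iterable[PeptideObservation]) -> pd.DataFrame:
    rows = []
    for o in observations:
        rows.append(
            {
                "sequence": o.sequence,
                "modifications": format_modifications(o.modifications),
                "precursor_accession": o.precursor_accession,
                "abundance": "NA" if o.abundance is None else repr(o.abundance),
                "quality": repr(o.quality),
                "score": "NA" if o.score is None else repr(o.score),
                "rt_min": repr(o.rt_min),
                "mz": repr(o.mz),
                "subject_id": o.subject_id,
                "group": o.group,
                "condition": o.condition,
                "culture_rep": o.culture_rep,
                "tech_rep": o.tech_rep,
                "is_decoy": o.is_decoy,
            }
        )
    return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def write_observations(observations: Iterable[PeptideObservation], path: str | Path) -> None:
    """Write the canonical observation TSV (floats via ``repr`` for lossless round-trip)."""
    frame = observations_to_frame(observations)
    frame.to_csv(path, sep="\t", index=False)


def read_precursors(path: str | Path) -> list[PrecursorRecord]:
    """Read precursor sequences from FASTA with headers ``>ACCESSION SYMBOL [description]``.

    Sequences are normalized to uppercase.  Duplicate symbols and empty files
    are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"precursor FASTA not found: {path}")
    records: list[PrecursorRecord] = []
    seen_symbols: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        parts = entry.description.split()
        accession = entry.id
        symbol = parts[1] if len(parts) > 1 else accession
        if symbol in seen_symbols:
            raise ValidationError(f"duplicate precursor symbol {symbol!r} in {path}")
        seen_symbols.add(symbol)
        records.append(
            PrecursorRecord(accession=accession, symbol=symbol, sequence=str(entry.seq))
        )
    if not records:
        raise ValidationError(f"no FASTA entries in {path}")
    return records


def write_precursors(precursors: Iterable[PrecursorRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in precursors:
            fh.write(f">{p.accession} {p.symbol}\n")
            seq = p.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
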