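"""Domain types for the secreted-neuropeptide analysis pipeline.

The pipeline operates on long-format peptide observation tables, one row per
identified peptide feature per technical LC-MS injection, as exported by
label-free quantitation software.  Each observation carries the peptide
sequence and modifications, the extracted-ion-chromatogram (XIC) abundance,
a feature-quality score, retention time, precursor m/z, and the full design
coordinates of the study (subject, group, condition, culture replicate,
technical replicate).

The study design mirrors a case-control secretion experiment on induced
neurons: two groups (schizophrenia ``SZ`` and healthy control ``HC``), two
secretion conditions (``KCl`` depolarization and ``basal``), three cell
culture replicates per subject, and two technical injections per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

GROUPS = ("SZ", "HC")
CONDITIONS = ("KCl", "basal")

#: Recognised post-translational modification names.
MOD_OXIDATION = "oxidation"
MOD_PYROGLU = "pyro-glu"
MOD_ACETYL = "acetylation"
MOD_AMIDATION = "amidation"
MOD_NAMES = frozenset({MOD_OXIDATION, MOD_PYROGLU, MOD_ACETYL, MOD_AMIDATION})

N_TERM = "N-term"
C_TERM = "C-term"


class NeuropepError(Exception):
    """Base class for pipeline errors."""


class ValidationError(NeuropepError):
    """Raised when data violates a domain invariant."""


class ConfigError(NeuropepError):
    """Raised for configuration problems (bad thresholds, missing columns/files)."""


class NoMatchError(NeuropepError):
    """Raised when a peptide cannot be located in any precursor."""

    def __init__(self, sequence: str):
        self.sequence = sequence
        super().__init__(f"peptide {sequence!r} not found in any precursor")


@dataclass(frozen=True)
class Modification:
    """A post-translational modification on a peptide.

    ``position`` is a 1-based residue index within the peptide, or one of the
    sentinels ``"N-term"`` / ``"C-term"`` for terminal modifications.
    """

    position: int | str
    name: str

    def __post_init__(self) -> None:
        if self.name not in MOD_NAMES:
            raise ValidationError(
                f"unknown modification {self.name!r}; expected one of {sorted(MOD_NAMES)}"
            )
        if isinstance(self.position, str) and self.position not in (N_TERM, C_TERM):
            raise ValidationError(
                f"modification position must be an integer or 'N-term'/'C-term', got {self.position!r}"
            )
        if isinstance(self.position, int) and self.position < 1:
            raise ValidationError("modification residue index must be >= 1 (1-based)")


@dataclass
class PeptideObservation:
    """One identified/quantified peptide feature in one technical injection.

    ``abundance`` is the XIC area under the curve in arbitrary intensity
    units; it is ``None`` (never 0) when the feature was identified but not
    quantified, since a zero would corrupt downstream LFQ means.  ``score``
    is an optional peptide-spectrum-match score used by the optional
    target-decoy FDR gate; when absent, ``quality`` is used in its place.
    """

    sequence: str
    modifications: list[Modification]
    precursor_accession: str
    abundance: float | None
    quality: float
    rt_min: float
    mz: float
    subject_id: str
    group: str
    condition: str
    culture_rep: int
    tech_rep: int
    is_decoy: bool = False
    score: float | None = None

    def match_score(self) -> float:
        return self.quality if self.score is None else self.score

    def identity_key(self) -> tuple[str, tuple[tuple[int | str, str], ...]]:
        """Peptide identity = sequence + modification set (order-insensitive)."""
        mods = tuple(sorted(((m.position, m.name) for m in self.modifications),
                            key=lambda t: (str(t[0]), t[1])))
        return (self.sequence, mods)

    def validate(self, design: "StudyDesign | None" = None) -> None:
        """Raise :class:`ValidationError` on any invariant violation."""
        if not self.sequence:
            raise ValidationError("empty peptide sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValidationError(
                f"sequence {self.sequence!r} contains non-standard residues {sorted(bad)}"
            )
        if self.abundance is not None and self.abundance < 0:
            raise ValidationError(f"abundance must be >= 0, got {self.abundance}")
        if self.quality < 0:
            raise ValidationError(f"quality must be >= 0, got {self.quality}")
        for mod in self.modifications:
            if isinstance(mod.position, int) and mod.position > len(self.sequence):
                raise ValidationError(
                    f"modification {mod.name} at position {mod.position} outside "
                    f"peptide of length {len(self.sequence)}"
                )
        if design is not None:
            design.validate_coordinates(self)

    def key_fields(self) -> tuple:
        return (self.subject_id, self.condition, self.culture_rep, self.tech_rep)


@dataclass(frozen=True)
class PrecursorRecord:
    """A proneuropeptide precursor sequence.

    ``symbol`` is the gene-style symbol (CHGB, NPPC, NTS, SST, TMSB4X,
    TMSB10, ADM, ...) used throughout reporting; it must be unique within a
    precursor set.  ``sequence`` is the full-length precursor, signal peptide
    included, so residue coordinates are 1-based over the entire protein.
    """

    accession: str
    symbol: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"precursor {self.symbol}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass
class StudyDesign:
    """The replicate/subject structure and the hierarchical presence thresholds.

    A peptide is called present in a culture replicate if detected in at
    least ``tech_threshold`` distinct technical injections, present in a
    subject if called in at least ``culture_threshold`` culture replicates,
    and present in a group if called in at least
    ``group_presence_threshold[group]`` subjects.
    """

    groups: dict[str, list[str]]
    n_culture_reps: int = 3
    n_tech_reps: int = 2
    conditions: tuple[str, ...] = CONDITIONS
    group_presence_threshold: dict[str, int] = field(
        default_factory=lambda: {"SZ": 5, "HC": 4}
    )
    tech_threshold: int = 1
    culture_threshold: int = 2

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for group, subjects in self.groups.items():
            for s in subjects:
                if s in seen:
                    raise ValidationError(
                        f"subject {s!r} assigned to both {seen[s]!r} and {group!r}"
                    )
                seen[s] = group
        if self.tech_threshold > self.n_tech_reps:
            raise ValidationError("tech_threshold exceeds number of technical replicates")
        if self.culture_threshold > self.n_culture_reps:
            raise ValidationError("culture_threshold exceeds number of culture replicates")
        for group, thr in self.group_presence_threshold.items():
            if group in self.groups and thr > len(self.groups[group]):
                raise ValidationError(
                    f"group threshold {thr} exceeds {group} size {len(self.groups[group])}"
                )

    @property
    def subject_to_group(self) -> dict[str, str]:
        return {s: g for g, subjects in self.groups.items() for s in subjects}

    def group_of(self, subject_id: str) -> str:
        try:
            return self.subject_to_group[subject_id]
        except KeyError:
            raise ValidationError(f"unknown subject {subject_id!r}") from None

    def validate_coordinates(self, obs: PeptideObservation) -> None:
        if obs.group not in self.groups:
            raise ValidationError(f"unknown group {obs.group!r}")
        if obs.subject_id not in self.groups[obs.group]:
            raise ValidationError(
                f"subject {obs.subject_id!r} is not in group {obs.group!r}"
            )
        if obs.condition not in self.conditions:
            raise ValidationError(f"unknown condition {obs.condition!r}")
        if not 1 <= obs.culture_rep <= self.n_culture_reps:
            raise ValidationError(
                f"culture_rep {obs.culture_rep} outside 1..{self.n_culture_reps}"
            )
        if not 1 <= obs.tech_rep <= self.n_tech_reps:
            raise ValidationError(
                f"tech_rep {obs.tech_rep} outside 1..{self.n_tech_reps}"
            )


def default_design() -> StudyDesign:
    """The study's design: 7 SZ subjects (A-G) and 6 HC subjects (H-M),
    3 culture replicates, 2 technical injections, presence thresholds
    1-of-2 / 2-of-3 / 5-of-7 (SZ) / 4-of-6 (HC)."""
    return StudyDesign(
        groups={
            "SZ": list("ABCDEFG"),
            "HC": list("HIJKLM"),
        }
    )


@dataclass
class FilterConfig:
    """Observation-level quality gates.

    min_abundance
        XIC abundance must be strictly greater (default 1e4 intensity units).
    min_quality
        feature quality must be strictly greater (default 0.3).
    rt_tolerance_min
        maximum retention-time span, in minutes, tolerated across technical
        injections of the same peptide feature (default 3.0).
    fdr_max
        target-decoy false discovery rate ceiling for the optional FDR gate
        (default 0.003, i.e. 0.3%).
    ms1_ppm_tol
        maximum precursor m/z deviation from the feature-group median, in
        parts per million (default 20).
    """

    min_abundance: float = 1e4
    min_quality: float = 0.3
    rt_tolerance_min: float = 3.0
    fdr_max: float = 0.003
    ms1_ppm_tol: float = 20.0

    def __post_init__(self) -> None:
        for name in ("min_abundance", "min_quality", "rt_tolerance_min", "ms1_ppm_tol"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.fdr_max <= 1:
            raise ConfigError("fdr_max must lie in [0, 1]")
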