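"""Synthetic observation tables with known ground truth.

The generator emulates the output of peptide identification/quantitation
software at the identified-peptide level (the pipeline's input boundary):
per-injection Bernoulli detection of truly present peptides (default
probability 0.9) and spurious detection of absent ones (default 0.01),
log-normal XIC intensities, Gaussian retention-time jitter, Beta-distributed
feature quality, and a fraction of decoy rows whose shuffled sequences never
match a precursor.  The default panel and truth presence are the 29 secreted
peptides of the printed presence matrix, under the study's design
(7 SZ + 6 HC subjects, 2 conditions, 3 culture replicates, 2 injections).

Precursor sequences shipped here are *synthetic*: deterministic random
amino-acid strings with the real human proneuropeptide lengths (CHGB 677
residues, etc.), sufficient to realize the printed peptide coordinates.
They are stand-ins, not the biological sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import binom

from .fixtures import PUBLISHED_PRESENCE_CALLS, CALL_COLUMNS, PresenceFixture, peptide_mz
from .types import (
    AMINO_ACIDS,
    PeptideObservation,
    PrecursorRecord,
    StudyDesign,
    ValidationError,
)

#: Lengths (residues) of the full-length human proneuropeptide precursors.
PRECURSOR_LENGTHS = {
    "CHGB": 677,
    "NPPC": 126,
    "NTS": 170,
    "SST": 116,
    "TMSB4X": 44,
    "TMSB10": 44,
    "ADM": 185,
}

_ALPHABET = np.array(sorted(AMINO_ACIDS))


def synthetic_precursors(seed: int = 20240202) -> list[PrecursorRecord]:
    """Deterministic synthetic precursor set.

    Random sequences with the real precursor lengths, regenerated (seed
    bumped) until every fixture peptide region occurs exactly once across
    the whole set, so coordinate mapping is unambiguous by construction.
    """
    for attempt in range(100):
        rng = np.random.default_rng(seed + attempt)
        records = [
            PrecursorRecord(
                accession=f"SYN_{symbol}",
                symbol=symbol,
                sequence="".join(rng.choice(_ALPHABET, size=length)),
            )
            for symbol, length in sorted(PRECURSOR_LENGTHS.items())
        ]
        if _fixture_regions_unique(records):
            return records
    raise RuntimeError("could not generate an unambiguous synthetic precursor set")


def _fixture_regions_unique(records: Sequence[PrecursorRecord]) -> bool:
    by_symbol = {r.symbol: r for r in records}
    for symbol, start, end, _ in PUBLISHED_PRESENCE_CALLS:
        needle = by_symbol[symbol].sequence[start - 1 : end]
        hits = 0
        for rec in records:
            pos = rec.sequence.find(needle)
            while pos != -1:
                hits += 1
                pos = rec.sequence.find(needle, pos + 1)
        if hits != 1:
            return False
    return True


@dataclass(frozen=True)
class PanelPeptide:
    precursor_symbol: str
    start: int
    end: int
    sequence: str
    log_mean: float  # natural-log mean of the lognormal intensity model
    rt_mean: float   # minutes

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.precursor_symbol, self.start, self.end)


@dataclass
class GroundTruth:
    """Peptide panel, truth presence, and the noise model of the generator."""

    panel: list[PanelPeptide]
    presence: dict[tuple[tuple[str, int, int], tuple[str, str]], bool]
    detection_prob: float = 0.9
    false_detect_prob: float = 0.01
    intensity_log_sd: float = 0.5
    rt_jitter_sd_min: float = 0.5
    quality_alpha: float = 4.0   # Beta(4, 2): ~97% of draws above 0.3
    quality_beta: float = 2.0
    # match-score model (PSM-score-like, arbitrary units): targets and decoys
    # well separated, as a search engine's filtered export would show
    target_score_mean: float = 70.0
    target_score_sd: float = 10.0
    decoy_score_mean: float = 20.0
    decoy_score_sd: float = 6.0
    decoy_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("detection_prob", "false_detect_prob", "decoy_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")

    def is_present(self, key, group: str, condition: str) -> bool:
        return self.presence.get((key, (group, condition)), False)


def default_ground_truth(
    precursors: Sequence[PrecursorRecord] | None = None,
    seed: int = 0,
    **overrides,
) -> GroundTruth:
    """Ground truth reproducing the study's conditions: the 29-peptide panel
    with the printed presence matrix as truth."""
    precursors = list(precursors) if precursors is not None else synthetic_precursors()
    by_symbol = {p.symbol: p for p in precursors}
    rng = np.random.default_rng(seed + 7_654_321)
    panel = []
    presence = {}
    for idx, (symbol, start, end, calls) in enumerate(PUBLISHED_PRESENCE_CALLS):
        sequence = by_symbol[symbol].sequence[start - 1 : end]
        panel.append(
            PanelPeptide(
                precursor_symbol=symbol,
                start=start,
                end=end,
                sequence=sequence,
                # per-peptide intensity scale: 1e5..1e7 (log-uniform)
                log_mean=float(rng.uniform(np.log(1e5), np.log(1e7))),
                rt_mean=float(rng.uniform(8.0, 45.0)),
            )
        )
        for col, cell in zip(CALL_COLUMNS, calls):
            group, condition = col.split("-")
            presence[((symbol, start, end), (group, condition))] = cell == "+"
    return GroundTruth(panel=panel, presence=presence, seed=seed, **overrides)


def _shuffled_decoy(
    rng: np.random.Generator, sequence: str, precursors: Sequence[PrecursorRecord]
) -> str:
    """Length-preserving shuffle, rejection-sampled to miss every precursor."""
    letters = list(sequence)
    for _ in range(200):
        rng.shuffle(letters)
        decoy = "".join(letters)
        if decoy != sequence and not any(decoy in p.sequence for p in precursors):
            return decoy
    # pathological composition (homopolymer): substitute a residue instead
    alt = "".join(rng.choice(_ALPHABET, size=len(sequence)))
    return alt


def generate(
    truth: GroundTruth,
    design: StudyDesign,
    precursors: Sequence[PrecursorRecord] | None = None,
    seed: int | None = None,
) -> list[PeptideObservation]:
    """Sample one observation table: one row per realized detection per
    injection, plus decoy rows.  Deterministic under a fixed seed."""
    if not truth.panel:
        raise ValidationError("empty peptide panel")
    precursors = list(precursors) if precursors is not None else synthetic_precursors()
    by_symbol = {p.symbol: p for p in precursors}
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    rows: list[PeptideObservation] = []
    for pep in truth.panel:
        base_mz = peptide_mz(pep.sequence)
        accession = by_symbol[pep.precursor_symbol].accession
        for group, subjects in design.groups.items():
            for condition in design.conditions:
                p = (
                    truth.detection_prob
                    if truth.is_present(pep.key, group, condition)
                    else truth.false_detect_prob
                )
                for subject in subjects:
                    for culture in range(1, design.n_culture_reps + 1):
                        for tech in range(1, design.n_tech_reps + 1):
                            if rng.random() >= p:
                                continue
                            rows.append(
                                PeptideObservation(
                                    sequence=pep.sequence,
                                    modifications=[],
                                    precursor_accession=accession,
                                    abundance=float(
                                        np.exp(rng.normal(pep.log_mean, truth.intensity_log_sd))
                                    ),
                                    quality=float(
                                        rng.beta(truth.quality_alpha, truth.quality_beta)
                                    ),
                                    rt_min=float(
                                        rng.normal(pep.rt_mean, truth.rt_jitter_sd_min)
                                    ),
                                    mz=float(base_mz * (1.0 + rng.normal(0.0, 2e-6))),
                                    subject_id=subject,
                                    group=group,
                                    condition=condition,
                                    culture_rep=culture,
                                    tech_rep=tech,
                                    score=float(
                                        rng.normal(truth.target_score_mean,
                                                   truth.target_score_sd)
                                    ),
                                )
                            )
    n_decoys = int(round(truth.decoy_fraction * len(rows)))
    all_subjects = [(g, s) for g, subs in design.groups.items() for s in subs]
    for i in range(n_decoys):
        template = truth.panel[int(rng.integers(len(truth.panel)))]
        decoy_seq = _shuffled_decoy(rng, template.sequence, precursors)
        group, subject = all_subjects[int(rng.integers(len(all_subjects)))]
        rows.append(
            PeptideObservation(
                sequence=decoy_seq,
                modifications=[],
                precursor_accession="DECOY",
                abundance=float(np.exp(rng.normal(template.log_mean, truth.intensity_log_sd))),
                quality=float(rng.beta(1.5, 4.0)),  # decoys score low
                rt_min=float(rng.uniform(5.0, 50.0)),
                mz=float(peptide_mz(decoy_seq)),
                subject_id=subject,
                group=group,
                condition=design.conditions[int(rng.integers(len(design.conditions)))],
                culture_rep=int(rng.integers(1, design.n_culture_reps + 1)),
                tech_rep=int(rng.integers(1, design.n_tech_reps + 1)),
                is_decoy=True,
                score=float(
                    max(0.0, rng.normal(truth.decoy_score_mean, truth.decoy_score_sd))
                ),
            )
        )
    return rows


# -- presence recovery ------------------------------------------------------


def hierarchical_calls(detections: np.ndarray, design: StudyDesign, group: str) -> np.ndarray:
    """Vectorized presence hierarchy.

    ``detections`` is a boolean array whose last three axes are
    (subject, culture replicate, technical replicate) for one group; returns
    the boolean group calls with those axes reduced.
    """
    culture_calls = detections.sum(axis=-1) >= design.tech_threshold
    subject_calls = culture_calls.sum(axis=-1) >= design.culture_threshold
    return subject_calls.sum(axis=-1) >= design.group_presence_threshold[group]


def exact_presence_probability(p_detect: float, design: StudyDesign, group: str) -> float:
    """Closed-form probability that a peptide detected independently with
    probability ``p_detect`` per injection is called present at group level:
    binomial survival composed injection -> culture -> subject -> group."""
    p_culture = float(binom.sf(design.tech_threshold - 1, design.n_tech_reps, p_detect))
    p_subject = float(binom.sf(design.culture_threshold - 1, design.n_culture_reps, p_culture))
    n_subjects = len(design.groups[group])
    return float(binom.sf(design.group_presence_threshold[group] - 1, n_subjects, p_subject))


@dataclass(frozen=True)
class CellRecovery:
    group: str
    condition: str
    n_present: int
    n_absent: int
    n_sims: int
    sensitivity: float | None  # P(call + | truth +), None if no present peptides
    specificity: float | None  # P(call - | truth -), None if no absent peptides

    def sensitivity_se(self) -> float | None:
        if self.sensitivity is None:
            return None
        n = self.n_present * self.n_sims
        return float(np.sqrt(max(self.sensitivity * (1 - self.sensitivity), 0.0) / n))


def recovery_experiment(
    truth: GroundTruth,
    design: StudyDesign,
    n_sims: int,
    seed: int = 0,
) -> dict[tuple[str, str], CellRecovery]:
    """Monte-Carlo sensitivity/specificity of the presence hierarchy vs truth.

    Detection events are sampled per injection exactly as in :func:`generate`
    (Bernoulli at ``detection_prob`` for truly present peptides and
    ``false_detect_prob`` for absent ones) and run through the same
    hierarchical thresholds, vectorized over simulations.
    """
    if n_sims < 1:
        raise ValidationError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    results: dict[tuple[str, str], CellRecovery] = {}
    keys = [p.key for p in truth.panel]
    for group, subjects in design.groups.items():
        for condition in design.conditions:
            truth_vec = np.array(
                [truth.is_present(k, group, condition) for k in keys]
            )
            probs = np.where(truth_vec, truth.detection_prob, truth.false_detect_prob)
            shape = (
                n_sims,
                len(keys),
                len(subjects),
                design.n_culture_reps,
                design.n_tech_reps,
            )
            detections = rng.random(shape) < probs[None, :, None, None, None]
            calls = hierarchical_calls(detections, design, group)  # (n_sims, n_pep)
            n_present = int(truth_vec.sum())
            n_absent = int((~truth_vec).sum())
            sensitivity = (
                float(calls[:, truth_vec].mean()) if n_present else None
            )
            specificity = (
                float((~calls[:, ~truth_vec]).mean()) if n_absent else None
            )
            results[(group, condition)] = CellRecovery(
                group=group,
                condition=condition,
                n_present=n_present,
                n_absent=n_absent,
                n_sims=n_sims,
                sensitivity=sensitivity,
                specificity=specificity,
            )
    return results
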