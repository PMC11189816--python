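"""Observation-level quality gates.

Three stages, applied in order by the pipeline:

1. ``fdr_filter`` — optional target-decoy FDR cutoff on match scores.  Off by
   default for vendor exports that arrive pre-filtered; the synthetic
   generator labels decoys so the gate can be exercised end to end.
2. ``quality_filter`` — strict abundance (> 1e4) and quality (> 0.3) gates.
3. ``rt_reliability_filter`` — within each peptide identity x subject x
   condition x culture replicate, keep the largest subset of injections
   whose retention times span at most the RT tolerance (3 min) and whose
   precursor m/z deviates at most 20 ppm from the subset median.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .types import ConfigError, FilterConfig, PeptideObservation, ValidationError


@dataclass
class FeatureGroup:
    """Observations sharing one peptide identity within one design cell."""

    member_observations: list[PeptideObservation]

    def __post_init__(self) -> None:
        keys = {o.identity_key() for o in self.member_observations}
        if len(keys) > 1:
            raise ValidationError("feature group mixes peptide identities")

    @property
    def rt_span_min(self) -> float:
        rts = [o.rt_min for o in self.member_observations]
        return max(rts) - min(rts) if rts else 0.0

    @property
    def max_ppm_delta(self) -> float:
        return _max_ppm_from_median([o.mz for o in self.member_observations])


def _max_ppm_from_median(mzs: Sequence[float]) -> float:
    if len(mzs) < 2:
        return 0.0
    srt = sorted(mzs)
    n = len(srt)
    median = srt[n // 2] if n % 2 else 0.5 * (srt[n // 2 - 1] + srt[n // 2])
    return max(abs(mz - median) / median * 1e6 for mz in mzs)


@dataclass
class FilterStageReport:
    stage: str
    n_in: int
    n_out: int
    rejected: dict[str, int] = field(default_factory=dict)


def write_filter_report(reports: Iterable[FilterStageReport], path: str | Path) -> pd.DataFrame:
    rows = []
    for r in reports:
        if r.rejected:
            for reason, n in sorted(r.rejected.items()):
                rows.append({"stage": r.stage, "n_in": r.n_in, "n_out": r.n_out,
                             "reason": reason, "n_rejected": n})
        else:
            rows.append({"stage": r.stage, "n_in": r.n_in, "n_out": r.n_out,
                         "reason": "", "n_rejected": 0})
    frame = pd.DataFrame(rows, columns=["stage", "n_in", "n_out", "reason", "n_rejected"])
    frame.to_csv(path, sep="\t", index=False)
    return frame


def fdr_filter(
    observations: Sequence[PeptideObservation],
    fdr_max: float,
    key: Callable[[PeptideObservation], float] | None = None,
) -> tuple[list[PeptideObservation], float, FilterStageReport]:
    """Target-decoy FDR gate.

    Scans candidate score cutoffs and retains target observations scoring at
    least the smallest cutoff whose estimated FDR — decoys at or above the
    cutoff divided by targets at or above it — stays strictly below
    ``fdr_max``.  Decoy rows are always removed from downstream data.

    Returns ``(retained targets, cutoff, report)``.
    """
    if fdr_max <= 0:
        raise ConfigError("fdr_max must be > 0 for the FDR gate")
    key = key or (lambda o: o.match_score())
    targets = [o for o in observations if not o.is_decoy]
    decoys = [o for o in observations if o.is_decoy]
    if not targets:
        raise ValidationError("no target observations to filter")

    target_scores = sorted((key(o) for o in targets), reverse=True)
    decoy_scores = sorted((key(o) for o in decoys), reverse=True)

    cutoff = None
    # Candidate cutoffs: every observed score, highest first; pick the
    # smallest (most permissive) cutoff that still satisfies the FDR bound.
    candidates = sorted(set(target_scores) | set(decoy_scores), reverse=True)
    for c in candidates:
        n_t = sum(1 for s in target_scores if s >= c)
        n_d = sum(1 for s in decoy_scores if s >= c)
        if n_t > 0 and n_d / n_t < fdr_max:
            cutoff = c
        # keep scanning: a lower cutoff may still satisfy the bound
    if cutoff is None:
        retained: list[PeptideObservation] = []
        cutoff = float("inf")
    else:
        retained = [o for o in targets if key(o) >= cutoff]
    report = FilterStageReport(
        stage="fdr",
        n_in=len(observations),
        n_out=len(retained),
        rejected={
            "decoy": len(decoys),
            "below_score_cutoff": len(targets) - len(retained),
        },
    )
    return retained, cutoff, report


def quality_filter(
    observations: Sequence[PeptideObservation], config: FilterConfig
) -> tuple[list[PeptideObservation], FilterStageReport]:
    """Strict abundance/quality gates: abundance > min_abundance AND
    quality > min_quality.  Rows with missing abundance cannot be quantified
    and are rejected (counted separately).  Idempotent and order-independent."""
    retained = []
    rejected = {"missing_abundance": 0, "low_abundance": 0, "low_quality": 0}
    for o in observations:
        if o.abundance is None:
            rejected["missing_abundance"] += 1
        elif o.abundance <= config.min_abundance:
            rejected["low_abundance"] += 1
        elif o.quality <= config.min_quality:
            rejected["low_quality"] += 1
        else:
            retained.append(o)
    report = FilterStageReport(
        stage="quality",
        n_in=len(observations),
        n_out=len(retained),
        rejected={k: v for k, v in rejected.items() if v},
    )
    return retained, report


def _best_consistent_subset(
    group: Sequence[PeptideObservation], config: FilterConfig
) -> list[PeptideObservation]:
    """Largest subset with RT span <= rt_tolerance_min and every member's m/z
    within ms1_ppm_tol of the subset median; ties broken by total abundance,
    then earliest RT.  Group sizes are tiny (technical injections), so exact
    enumeration is affordable."""
    n = len(group)
    if n == 1:
        return list(group)

    def consistent(subset: Sequence[PeptideObservation]) -> bool:
        rts = [o.rt_min for o in subset]
        if max(rts) - min(rts) > config.rt_tolerance_min:
            return False
        return _max_ppm_from_median([o.mz for o in subset]) <= config.ms1_ppm_tol

    if n <= 12:
        for size in range(n, 0, -1):
            best = None
            for combo in itertools.combinations(range(n), size):
                subset = [group[i] for i in combo]
                if not consistent(subset):
                    continue
                score = (
                    sum(o.abundance or 0.0 for o in subset),
                    -min(o.rt_min for o in subset),
                )
                if best is None or score > best[0]:
                    best = (score, subset)
            if best is not None:
                return best[1]
        return []
    # Fallback for implausibly large groups: best RT window, greedy.
    ordered = sorted(group, key=lambda o: o.rt_min)
    best_subset: list[PeptideObservation] = [ordered[0]]
    for i in range(len(ordered)):
        window = [o for o in ordered[i:] if o.rt_min - ordered[i].rt_min <= config.rt_tolerance_min]
        window = [o for o in window
                  if _max_ppm_from_median([w.mz for w in window]) <= config.ms1_ppm_tol]
        if len(window) > len(best_subset):
            best_subset = window
    return best_subset


def rt_reliability_filter(
    observations: Sequence[PeptideObservation], config: FilterConfig
) -> tuple[list[PeptideObservation], FilterStageReport]:
    """Cross-injection feature reliability gate.

    Observations are grouped by peptide identity within
    subject x condition x culture replicate; within each group only the best
    RT/mass-consistent subset survives.  Singleton groups pass
    unconditionally."""
    groups: dict[tuple, list[PeptideObservation]] = {}
    for o in observations:
        k = (o.identity_key(), o.subject_id, o.condition, o.culture_rep)
        groups.setdefault(k, []).append(o)
    retained: list[PeptideObservation] = []
    n_dropped = 0
    for members in groups.values():
        keep = _best_consistent_subset(members, config)
        n_dropped += len(members) - len(keep)
        retained.extend(keep)
    report = FilterStageReport(
        stage="rt_reliability",
        n_in=len(observations),
        n_out=len(retained),
        rejected={"rt_or_mass_inconsistent": n_dropped} if n_dropped else {},
    )
    return retained, report
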