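"""Label-free quantitation summaries and group comparisons.

Abundances are aggregated up the nested design: technical injections are
averaged within a culture replicate, culture means are averaged to one value
per subject, and group summaries are reported as mean +/- s.e.m. (sample
standard deviation over sqrt(n)).  Group comparisons use the two-sample
pooled-variance Student's t-test (two-tailed), reflecting the similar group
variances of this data; df = n1 + n2 - 2.  No multiple-testing correction is
applied by default; Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .mapping import MappedPeptide
from .presence import PeptideKey, PresenceMatrix
from .types import PeptideObservation, StudyDesign, ValidationError


def subject_abundance(
    observations: Sequence[PeptideObservation],
) -> float | None:
    """One abundance scalar per peptide x subject x condition.

    Mean of culture-replicate values, where each culture value is the mean
    over its technical injections; injections with missing abundance are
    ignored.  Returns ``None`` (missing, never zero) when nothing is
    quantifiable.
    """
    by_culture: dict[int, list[float]] = {}
    for o in observations:
        if o.abundance is not None:
            by_culture.setdefault(o.culture_rep, []).append(o.abundance)
    culture_means = [sum(v) / len(v) for v in by_culture.values() if v]
    if not culture_means:
        return None
    return sum(culture_means) / len(culture_means)


@dataclass(frozen=True)
class GroupStats:
    n: int
    mean: float | None
    sem: float | None


def group_stats(values: Sequence[float]) -> GroupStats:
    """Mean and s.e.m. (sample sd / sqrt(n)) of subject-level abundances.

    With a single value the mean is reported and the s.e.m. is flagged
    unavailable (``None``)."""
    n = len(values)
    if n == 0:
        return GroupStats(n=0, mean=None, sem=None)
    mean = sum(values) / n
    if n == 1:
        return GroupStats(n=1, mean=mean, sem=None)
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return GroupStats(n=n, mean=mean, sem=math.sqrt(var) / math.sqrt(n))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def pooled_t_test(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Two-sample pooled-variance Student's t-test, two-tailed.

    t = (mean_a - mean_b) / sqrt(s_p^2 (1/n1 + 1/n2)) with the pooled
    variance s_p^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2); the p-value is
    twice the upper tail of the t distribution with n1+n2-2 df.

    Degenerate inputs: if both sample variances are zero and the means are
    equal, p = 1 by convention; if both are zero and the means differ, p = 0
    (with a warning) since the pooled scale is undefined.
    """
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValidationError("pooled t-test requires n >= 2 in both groups")
    mean1 = sum(a) / n1
    mean2 = sum(b) / n2
    ss1 = sum((v - mean1) ** 2 for v in a)
    ss2 = sum((v - mean2) ** 2 for v in b)
    df = n1 + n2 - 2
    pooled_var = (ss1 + ss2) / df
    if pooled_var == 0.0:
        if mean1 == mean2:
            return TTestResult(t=0.0, df=df, p=1.0)
        warnings.warn(
            "pooled t-test: zero variance in both groups with unequal means",
            RuntimeWarning,
            stacklevel=2,
        )
        t = math.inf if mean1 > mean2 else -math.inf
        return TTestResult(t=t, df=df, p=0.0)
    t = (mean1 - mean2) / math.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=t, df=df, p=p)


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Paired two-tailed t-test on per-subject differences (optional path
    for within-group condition contrasts)."""
    if len(a) != len(b):
        raise ValidationError("paired t-test requires equal-length samples")
    diffs = [x - y for x, y in zip(a, b)]
    n = len(diffs)
    if n < 2:
        raise ValidationError("paired t-test requires n >= 2 pairs")
    mean = sum(diffs) / n
    var = sum((d - mean) ** 2 for d in diffs) / (n - 1)
    df = n - 1
    if var == 0.0:
        if mean == 0.0:
            return TTestResult(t=0.0, df=df, p=1.0)
        warnings.warn("paired t-test: zero-variance differences", RuntimeWarning,
                      stacklevel=2)
        return TTestResult(t=math.inf if mean > 0 else -math.inf, df=df, p=0.0)
    t = mean / math.sqrt(var / n)
    return TTestResult(t=t, df=df, p=2.0 * stats.t.sf(abs(t), df))


def _subject_values(
    observations: Sequence[PeptideObservation],
    mapping: Mapping[str, MappedPeptide],
    design: StudyDesign,
) -> dict[tuple[PeptideKey, str, str], float]:
    """(peptide, subject, condition) -> subject-level abundance."""
    grouped: dict[tuple[PeptideKey, str, str], list[PeptideObservation]] = {}
    for o in observations:
        if o.is_decoy:
            continue
        mapped = mapping.get(o.sequence)
        if mapped is None:
            continue
        grouped.setdefault((mapped.key, o.subject_id, o.condition), []).append(o)
    values = {}
    for key, obs in grouped.items():
        v = subject_abundance(obs)
        if v is not None:
            values[key] = v
    return values


def quantify(
    observations: Sequence[PeptideObservation],
    mapping: Mapping[str, MappedPeptide],
    matrix: PresenceMatrix,
    design: StudyDesign,
    paired: bool = False,
    bh: bool = False,
) -> pd.DataFrame:
    """Per-peptide LFQ summary table with group and condition contrasts.

    Group contrasts (SZ vs HC at fixed condition) are computed only where
    the presence matrix calls the peptide present in both groups; condition
    contrasts (KCl vs basal at fixed group) only where present in both
    conditions.  Abundances of absent peptides are never imputed.
    """
    values = _subject_values(observations, mapping, design)
    rows = []
    for p in matrix.peptides:
        row: dict = {
            "precursor": p.precursor_symbol,
            "peptide": f"{p.start}-{p.end}",
            "sequence": p.sequence,
        }
        cell_values: dict[tuple[str, str], list[float]] = {}
        subj_maps: dict[tuple[str, str], dict[str, float]] = {}
        for group, subjects in design.groups.items():
            for condition in design.conditions:
                vals = {
                    s: values[(p.key, s, condition)]
                    for s in subjects
                    if (p.key, s, condition) in values
                }
                subj_maps[(group, condition)] = vals
                cell_values[(group, condition)] = list(vals.values())
                st = group_stats(list(vals.values()))
                row[f"{group}_{condition}_n"] = st.n
                row[f"{group}_{condition}_mean"] = st.mean
                row[f"{group}_{condition}_sem"] = st.sem
        # SZ vs HC at fixed condition
        for condition in design.conditions:
            present_both = matrix.calls.get((p.key, ("SZ", condition)), False) and \
                matrix.calls.get((p.key, ("HC", condition)), False)
            res = None
            if present_both:
                a = cell_values[("SZ", condition)]
                b = cell_values[("HC", condition)]
                if len(a) >= 2 and len(b) >= 2:
                    res = pooled_t_test(a, b)
            prefix = f"SZvsHC_{condition}"
            row[f"{prefix}_t"] = res.t if res else None
            row[f"{prefix}_df"] = res.df if res else None
            row[f"{prefix}_p"] = res.p if res else None
        # KCl vs basal at fixed group
        for group in design.groups:
            present_both = matrix.calls.get((p.key, (group, "KCl")), False) and \
                matrix.calls.get((p.key, (group, "basal")), False)
            res = None
            if present_both:
                if paired:
                    kcl_map = subj_maps[(group, "KCl")]
                    basal_map = subj_maps[(group, "basal")]
                    shared = sorted(set(kcl_map) & set(basal_map))
                    if len(shared) >= 2:
                        res = paired_t_test(
                            [kcl_map[s] for s in shared],
                            [basal_map[s] for s in shared],
                        )
                else:
                    a = cell_values[(group, "KCl")]
                    b = cell_values[(group, "basal")]
                    if len(a) >= 2 and len(b) >= 2:
                        res = pooled_t_test(a, b)
            prefix = f"KClvsBasal_{group}"
            row[f"{prefix}_t"] = res.t if res else None
            row[f"{prefix}_df"] = res.df if res else None
            row[f"{prefix}_p"] = res.p if res else None
        rows.append(row)
    frame = pd.DataFrame(rows)
    contrasts = [f"SZvsHC_{c}" for c in design.conditions] + [
        f"KClvsBasal_{g}" for g in design.groups
    ]
    for prefix in contrasts:
        pcol = f"{prefix}_p"
        if pcol not in frame.columns:
            continue
        if bh:
            frame[f"{prefix}_p_adj"] = _bh_adjust(frame[pcol])
            frame[f"{prefix}_significant"] = frame[f"{prefix}_p_adj"] < 0.05
        else:
            frame[f"{prefix}_significant"] = frame[pcol] < 0.05
    return frame


def _bh_adjust(pvalues: pd.Series) -> pd.Series:
    """Benjamini-Hochberg over the non-missing p-values of one contrast."""
    from statsmodels.stats.multitest import multipletests

    adjusted = pd.Series([math.nan] * len(pvalues), index=pvalues.index, dtype=float)
    mask = pvalues.notna()
    if mask.any():
        adjusted.loc[mask] = multipletests(pvalues[mask], method="fdr_bh")[1]
    return adjusted
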