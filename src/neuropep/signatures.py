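"""Set algebra over the presence matrix: group Venn partitions, condition
contrasts, per-precursor tallies, and peptide labelling.

Peptides absent in every (group, condition) cell are excluded from all
counts but retained in matrix exports; ambiguous peptides (multiple mapping
sites) are kept in totals and contrasts but excluded from per-precursor
tallies, where assignment must be unique.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .presence import PeptideKey, PresenceMatrix
from .types import ValidationError


def _check_condition(matrix: PresenceMatrix, condition: str) -> None:
    if condition not in matrix.design.conditions:
        raise ValidationError(f"unknown condition {condition!r}")


def _check_group(matrix: PresenceMatrix, group: str) -> None:
    if group not in matrix.design.groups:
        raise ValidationError(f"unknown group {group!r}")


@dataclass(frozen=True)
class GroupVenn:
    """Partition of a condition's present-peptide union between the groups."""

    condition: str
    sz_only: frozenset[PeptideKey]
    shared: frozenset[PeptideKey]
    hc_only: frozenset[PeptideKey]

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.sz_only), len(self.shared), len(self.hc_only))

    @property
    def union_size(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class ConditionVenn:
    """Partition of a group's present-peptide union across conditions."""

    group: str
    kcl_only: frozenset[PeptideKey]
    both: frozenset[PeptideKey]
    basal_only: frozenset[PeptideKey]

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.kcl_only), len(self.both), len(self.basal_only))


def group_contrast(matrix: PresenceMatrix, condition: str) -> GroupVenn:
    """SZ-vs-HC Venn partition for one condition."""
    _check_condition(matrix, condition)
    sz = matrix.present("SZ", condition)
    hc = matrix.present("HC", condition)
    return GroupVenn(
        condition=condition,
        sz_only=frozenset(sz - hc),
        shared=frozenset(sz & hc),
        hc_only=frozenset(hc - sz),
    )


def condition_contrast(matrix: PresenceMatrix, group: str) -> ConditionVenn:
    """KCl-vs-basal Venn partition for one group."""
    _check_group(matrix, group)
    kcl = matrix.present(group, "KCl")
    basal = matrix.present(group, "basal")
    return ConditionVenn(
        group=group,
        kcl_only=frozenset(kcl - basal),
        both=frozenset(kcl & basal),
        basal_only=frozenset(basal - kcl),
    )


def label_peptides(matrix: PresenceMatrix, condition: str) -> dict[PeptideKey, str]:
    """Total labelling of every matrix peptide for one condition:
    ``SZ-only`` / ``HC-only`` / ``shared`` / ``absent``."""
    _check_condition(matrix, condition)
    venn = group_contrast(matrix, condition)
    labels: dict[PeptideKey, str] = {}
    for p in matrix.peptides:
        if p.key in venn.shared:
            labels[p.key] = "shared"
        elif p.key in venn.sz_only:
            labels[p.key] = "SZ-only"
        elif p.key in venn.hc_only:
            labels[p.key] = "HC-only"
        else:
            labels[p.key] = "absent"
    return labels


def precursor_tally(matrix: PresenceMatrix, condition: str) -> pd.DataFrame:
    """Per-precursor counts for one condition: SZ, SZ_only, HC, HC_only,
    shared, total (= that precursor's share of the condition union).
    Ambiguous peptides are excluded (no unique precursor assignment)."""
    _check_condition(matrix, condition)
    venn = group_contrast(matrix, condition)
    unambiguous = {p.key for p in matrix.peptides if not p.ambiguous}
    symbols = sorted({p.precursor_symbol for p in matrix.peptides if not p.ambiguous})
    rows = []
    for symbol in symbols:
        keys = {k for k in unambiguous if k[0] == symbol}
        sz_only = len(venn.sz_only & keys)
        hc_only = len(venn.hc_only & keys)
        shared = len(venn.shared & keys)
        rows.append(
            {
                "precursor": symbol,
                "SZ": sz_only + shared,
                "SZ_only": sz_only,
                "HC": hc_only + shared,
                "HC_only": hc_only,
                "shared": shared,
                "total": sz_only + hc_only + shared,
            }
        )
    return pd.DataFrame(
        rows, columns=["precursor", "SZ", "SZ_only", "HC", "HC_only", "shared", "total"]
    )


@dataclass
class SignatureReport:
    """All set-algebra results for one presence matrix."""

    group_venns: dict[str, GroupVenn]           # condition -> partition
    condition_venns: dict[str, ConditionVenn]   # group -> partition
    tallies: dict[str, pd.DataFrame]            # condition -> per-precursor table
    labels: dict[str, dict[PeptideKey, str]]    # condition -> peptide -> label

    def validate(self) -> None:
        """Partition identities: shared + X-only = X total; union = sum of
        parts; per-precursor totals sum to the (unambiguous) condition union."""
        for condition, venn in self.group_venns.items():
            n_sz_only, n_shared, n_hc_only = venn.counts
            if venn.union_size != n_sz_only + n_shared + n_hc_only:
                raise ValidationError("union identity violated")
            tally = self.tallies[condition]
            if len(tally):
                # tallies exclude ambiguous peptides, so totals are <= union
                if int(tally["total"].sum()) > venn.union_size:
                    raise ValidationError("per-precursor totals exceed condition union")
                if not (tally["SZ_only"] + tally["shared"] == tally["SZ"]).all():
                    raise ValidationError("SZ tally identity violated")
                if not (tally["HC_only"] + tally["shared"] == tally["HC"]).all():
                    raise ValidationError("HC tally identity violated")

    def summary(self) -> dict:
        out: dict = {"conditions": {}, "groups": {}}
        for condition, venn in self.group_venns.items():
            sz_only, shared, hc_only = venn.counts
            out["conditions"][condition] = {
                "union": venn.union_size,
                "SZ_total": sz_only + shared,
                "HC_total": hc_only + shared,
                "SZ_only": sz_only,
                "HC_only": hc_only,
                "shared": shared,
            }
        for group, venn in self.condition_venns.items():
            kcl_only, both, basal_only = venn.counts
            out["groups"][group] = {
                "KCl_total": kcl_only + both,
                "basal_total": basal_only + both,
                "KCl_only": kcl_only,
                "basal_only": basal_only,
                "both_conditions": both,
            }
        return out

    def to_json(self, path: str | Path) -> None:
        def keyname(k: PeptideKey) -> str:
            return f"{k[0]} {k[1]}-{k[2]}"

        payload = self.summary()
        payload["members"] = {
            condition: {
                "SZ_only": sorted(keyname(k) for k in venn.sz_only),
                "shared": sorted(keyname(k) for k in venn.shared),
                "HC_only": sorted(keyname(k) for k in venn.hc_only),
            }
            for condition, venn in self.group_venns.items()
        }
        payload["labels"] = {
            condition: {keyname(k): v for k, v in sorted(labels.items())}
            for condition, labels in self.labels.items()
        }
        payload["tallies"] = {
            condition: tally.to_dict(orient="records")
            for condition, tally in self.tallies.items()
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def build_signature_report(matrix: PresenceMatrix) -> SignatureReport:
    report = SignatureReport(
        group_venns={c: group_contrast(matrix, c) for c in matrix.design.conditions},
        condition_venns={g: condition_contrast(matrix, g) for g in matrix.design.groups},
        tallies={c: precursor_tally(matrix, c) for c in matrix.design.conditions},
        labels={c: label_peptides(matrix, c) for c in matrix.design.conditions},
    )
    report.validate()
    return report
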