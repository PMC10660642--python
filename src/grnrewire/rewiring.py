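"""Regulation x cooperation rewiring of focal-TF edges between conditions.

For every pair (target gene from the focal gene set that is also a protein
of the cooperativity layer, mechanism protein), two condition-specific edge
weights are compared: the focal TF -> target regulatory weight and the
target <-> mechanism cooperativity weight. "Presence" of an edge means a
strictly positive weight — zero is the natural null of the z-score-like
networks (a configurable threshold is available). Each axis then changes
between control and case as gained, lost, or stable, and the pair is
classified into four reported categories keyed on the cooperation axis:

    cooperation gained / lost, each with regulation stable or changed.

Pairs whose cooperation axis is stable get the non-reported labels
``regulation_change_only`` (regulation gained or lost) or ``unchanged``
(nothing moved). The mapping is committed as an exhaustive 16-row truth
table over the presence flags; swapping case and control maps gained <->
lost on both axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grn import Grn

__all__ = [
    "RewiringRecord",
    "REPORTED_CATEGORIES",
    "axis_change",
    "classify_rewiring",
    "extract_focal_subnetwork",
    "rewiring_summary",
]

REPORTED_CATEGORIES = (
    "cooperation_gained",
    "cooperation_lost",
    "regulation_change_cooperation_gained",
    "regulation_change_cooperation_lost",
)


@dataclass
class RewiringRecord:
    cell_type: str
    target: str
    mechanism_protein: str
    reg_case: float
    reg_ctrl: float
    coop_case: float
    coop_ctrl: float
    presence_threshold: float = 0.0

    @property
    def reg_present_case(self) -> bool:
        return self.reg_case > self.presence_threshold

    @property
    def reg_present_ctrl(self) -> bool:
        return self.reg_ctrl > self.presence_threshold

    @property
    def coop_present_case(self) -> bool:
        return self.coop_case > self.presence_threshold

    @property
    def coop_present_ctrl(self) -> bool:
        return self.coop_ctrl > self.presence_threshold

    @property
    def regulation_change(self) -> str:
        return axis_change(self.reg_present_ctrl, self.reg_present_case)

    @property
    def cooperation_change(self) -> str:
        return axis_change(self.coop_present_ctrl, self.coop_present_case)

    @property
    def category(self) -> str:
        return classify_rewiring(self)


def axis_change(present_ctrl: bool, present_case: bool) -> str:
    if present_ctrl and not present_case:
        return "lost"
    if not present_ctrl and present_case:
        return "gained"
    return "stable"


def classify_rewiring(record: RewiringRecord) -> str:
    """Pure function of the two presence-flag pairs (see module docstring).

    Reported categories cover every pair whose cooperation axis changed;
    cooperation-stable pairs return ``regulation_change_only`` or
    ``unchanged``, which are excluded from the four-category report."""
    reg = record.regulation_change
    coop = record.cooperation_change
    if coop == "stable":
        return "unchanged" if reg == "stable" else "regulation_change_only"
    prefix = "" if reg == "stable" else "regulation_change_"
    return f"{prefix}cooperation_{coop}"


def _coop_lookup(coop: pd.DataFrame, a: str, b: str) -> float | None:
    if a in coop.index and b in coop.columns:
        return float(coop.loc[a, b])
    return None


def extract_focal_subnetwork(
    grn_case: Grn,
    grn_ctrl: Grn,
    coop_case: pd.DataFrame,
    coop_ctrl: pd.DataFrame,
    focal_tf: str,
    focal_gene_set: set[str],
    mechanism_proteins: list[str],
    presence_threshold: float = 0.0,
) -> list[RewiringRecord]:
    """One record per (focal-set target present in the cooperativity layer,
    mechanism protein), with weights from both conditions.

    Absent edges are looked up as 0 and reported via a warning."""
    if not mechanism_proteins:
        raise ValueError("mechanism_proteins must be non-empty")
    for grn in (grn_case, grn_ctrl):
        if focal_tf not in grn.tfs:
            raise ValueError(
                f"focal TF {focal_tf!r} missing from the {grn.condition or '?'} network"
            )
    coop_nodes = set(coop_case.index) | set(coop_ctrl.index)
    targets = sorted(focal_gene_set & coop_nodes)
    if not targets:
        warnings.warn(
            "focal gene set has no overlap with the cooperativity layer; "
            "no rewiring records produced"
        )
        return []
    w_case = grn_case.as_matrix()
    w_ctrl = grn_ctrl.as_matrix()
    records = []
    absences = []
    for tgt in targets:
        rc = float(w_case.loc[focal_tf, tgt]) if tgt in w_case.columns else 0.0
        rk = float(w_ctrl.loc[focal_tf, tgt]) if tgt in w_ctrl.columns else 0.0
        if tgt not in w_case.columns or tgt not in w_ctrl.columns:
            absences.append(("regulatory", tgt))
        for mech in mechanism_proteins:
            cc = _coop_lookup(coop_case, tgt, mech)
            ck = _coop_lookup(coop_ctrl, tgt, mech)
            if cc is None or ck is None:
                absences.append(("cooperativity", f"{tgt}~{mech}"))
            records.append(
                RewiringRecord(
                    cell_type=grn_case.cell_type,
                    target=tgt,
                    mechanism_protein=mech,
                    reg_case=rc,
                    reg_ctrl=rk,
                    coop_case=cc if cc is not None else 0.0,
                    coop_ctrl=ck if ck is not None else 0.0,
                    presence_threshold=presence_threshold,
                )
            )
    if absences:
        warnings.warn(f"edges absent (treated as 0): {absences[:10]}")
    return records


def rewiring_summary(
    records: list[RewiringRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sign-change and magnitude tables, ordered by (cell_type, target).

    Sign-change codes are '<ctrl-state>-><case-state>' per axis with states
    in {present, absent}; magnitudes are the raw weight differences."""
    if not records:
        raise ValueError("need at least one rewiring record")
    records = sorted(records, key=lambda r: (r.cell_type, r.target, r.mechanism_protein))

    def code(ctrl: bool, case: bool) -> str:
        s = {True: "present", False: "absent"}
        return f"{s[ctrl]}->{s[case]}"

    sign_rows, mag_rows = [], []
    for r in records:
        key = {
            "cell_type": r.cell_type,
            "target": r.target,
            "mechanism_protein": r.mechanism_protein,
        }
        sign_rows.append(
            {
                **key,
                "regulation": code(r.reg_present_ctrl, r.reg_present_case),
                "cooperation": code(r.coop_present_ctrl, r.coop_present_case),
                "category": r.category,
            }
        )
        mag_rows.append(
            {
                **key,
                "reg_diff": r.reg_case - r.reg_ctrl,
                "coop_diff": r.coop_case - r.coop_ctrl,
            }
        )
    return pd.DataFrame(sign_rows), pd.DataFrame(mag_rows)
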