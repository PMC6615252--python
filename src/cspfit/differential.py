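"""Differential CSP analysis between two matched conditions.

Comparing the spectrum of a domain in two contexts — e.g. the isolated
domain–ligand complex versus the same domain inside a tandem construct
bound to the same ligand — highlights residues whose environment changes
with context. The statistic is the same weighted CSP formula applied to
the inter-condition shift differences, so it is symmetric in the two
conditions and non-negative.

The default significance rule is mean + 1·SD over the observed deltas
with a 0.01 ppm minimum-effect floor; the floor keeps the upper tail of
pure measurement noise from being called significant when the two
conditions are in fact identical. Residues lacking a complete amide pair
in either condition are excluded from the comparison and reported as
"not comparable" rather than silently zeroed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .csp import WeightingScheme, weighted_csp
from .selection import SelectionRule, apply_selection
from .shift_io import NumberingOffset, ShiftTable

__all__ = [
    "DEFAULT_DIFFERENTIAL_RULE",
    "DifferentialCSPResult",
    "compare_conditions",
    "interface_patch",
]

#: Threshold rule with a minimum-effect floor of 0.01 ppm.
DEFAULT_DIFFERENTIAL_RULE = SelectionRule.threshold(1.0, min_delta=0.01)


@dataclass
class DifferentialCSPResult:
    """Residue-by-residue weighted shift differences between two conditions."""

    residues: list[int]
    delta: dict[int, float]
    significant: list[int]
    not_comparable: list[int]
    rule_used: SelectionRule
    label_A: str = "A"
    label_B: str = "B"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "residue_index": r,
                "delta_ppm": self.delta[r],
                "significant": r in set(self.significant),
                "comparable": True,
            }
            for r in self.residues
        ] + [
            {
                "residue_index": r,
                "delta_ppm": None,
                "significant": False,
                "comparable": False,
            }
            for r in self.not_comparable
        ]
        return (
            pd.DataFrame(rows)
            .sort_values("residue_index")
            .reset_index(drop=True)
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


def compare_conditions(
    table_A: ShiftTable,
    table_B: ShiftTable,
    scheme: WeightingScheme = WeightingScheme(),
    offset_B: NumberingOffset = NumberingOffset(0),
    rule: SelectionRule = DEFAULT_DIFFERENTIAL_RULE,
) -> DifferentialCSPResult:
    """Weighted shift difference per shared residue, plus a significant set.

    ``offset_B`` renumbers table B onto table A's convention before
    matching. Swapping A and B leaves every delta unchanged.
    """
    b = table_B.with_offset(offset_B)
    a_rec = table_A.by_residue()
    b_rec = b.by_residue()
    shared = sorted(set(a_rec) & set(b_rec))
    if not shared:
        raise ValueError(
            f"tables {table_A.label!r} and {table_B.label!r} share no residue "
            "after offset correction"
        )
    delta: dict[int, float] = {}
    not_comparable: list[int] = []
    for r in shared:
        ra, rb = a_rec[r], b_rec[r]
        if not (ra.complete and rb.complete):
            not_comparable.append(r)
            continue
        delta[r] = weighted_csp(
            ra.shift_H - rb.shift_H, ra.shift_N - rb.shift_N, scheme
        )
    if not delta:
        raise ValueError("no comparable residue (complete amide pair) in both tables")
    significant = apply_selection(delta, rule)
    return DifferentialCSPResult(
        residues=sorted(delta),
        delta=delta,
        significant=significant,
        not_comparable=not_comparable,
        rule_used=rule,
        label_A=table_A.label,
        label_B=table_B.label,
    )


def interface_patch(
    result: DifferentialCSPResult, exclude: Sequence[int] = ()
) -> list[int]:
    """Significant residues minus a user-supplied exclusion list, sorted.

    The exclusion list typically holds the canonical binding-cleft
    residues (known from prior structural work), leaving the patch of
    context-dependent perturbations elsewhere on the domain surface — the
    candidate docking interface.
    """
    patch = sorted(set(result.significant) - set(exclude))
    if not patch:
        warnings.warn("interface patch is empty after exclusion", stacklevel=2)
    return patch
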