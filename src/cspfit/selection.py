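"""Residue-selection rules for "significant" perturbations.

Two modes:

* ``explicit`` — a user-supplied residue list (the classical approach of
  fitting the residues in and around the binding cleft);
* ``threshold`` — residues whose value exceeds mean + k·SD of all observed
  values, optionally with a minimum-effect floor ``min_delta`` (ppm) below
  which a perturbation is never called significant regardless of the
  population statistics. The floor matters for differential comparisons,
  where the null population is pure measurement noise and a purely
  relative mean + SD cutoff would always flag the upper noise tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = ["SelectionRule", "apply_selection"]


@dataclass(frozen=True)
class SelectionRule:
    mode: str = "threshold"
    explicit_residues: Optional[tuple[int, ...]] = None
    threshold_sigmas: float = 1.0
    min_delta: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("explicit", "threshold"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if self.mode == "explicit" and not self.explicit_residues:
            raise ValueError("explicit mode requires a non-empty residue list")
        if self.min_delta < 0:
            raise ValueError("min_delta must be >= 0")

    @classmethod
    def explicit(cls, residues: Sequence[int]) -> "SelectionRule":
        return cls(mode="explicit", explicit_residues=tuple(residues))

    @classmethod
    def threshold(cls, sigmas: float = 1.0, min_delta: float = 0.0) -> "SelectionRule":
        return cls(mode="threshold", threshold_sigmas=sigmas, min_delta=min_delta)


def apply_selection(values: Mapping[int, float], rule: SelectionRule) -> list[int]:
    """Select residue indices from a residue → value map (NaN = unobserved).

    Explicit mode intersects the rule's list with the observed residues
    (warning on absentees, error on empty intersection). Threshold mode
    returns residues with value >= mean + k·SD (sample SD, n−1) and
    value > max(min_delta, 0); an all-zero map therefore selects nothing.
    """
    observed = {r: v for r, v in values.items() if v is not None and np.isfinite(v)}
    if rule.mode == "explicit":
        missing = [r for r in rule.explicit_residues if r not in observed]
        if missing:
            warnings.warn(
                f"requested residues absent from the data: {sorted(missing)}",
                stacklevel=2,
            )
        selected = [r for r in rule.explicit_residues if r in observed]
        if not selected:
            raise ValueError("no requested residue present in the data")
        return sorted(selected)
    vals = np.array(list(observed.values()))
    if vals.size == 0:
        return []
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    cutoff = mean + rule.threshold_sigmas * sd
    return sorted(
        r
        for r, v in observed.items()
        if v >= cutoff and v > rule.min_delta and v > 0
    )
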