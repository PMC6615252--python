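"""Weighted chemical-shift perturbations (CSPs).

In the fast-exchange regime a backbone amide peak moves continuously from
its free to its bound position during a titration. The per-residue
perturbation at each point is summarised by the weighted combination

    Δδ_obs = sqrt( Δδ(¹H_N)² + (Δδ(¹⁵N) / s)² )

with the nitrogen scale s = 5 by default, which compensates for the wider
¹⁵N ppm dispersion so that both nuclei contribute comparably. CSPs are
always computed relative to the ligand-free (apo) reference point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .shift_io import TitrationSeries

__all__ = ["WeightingScheme", "CSPProfile", "weighted_csp", "csp_profile", "endpoint_csp"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WeightingScheme:
    """Weighting of the ¹⁵N shift difference relative to ¹H_N.

    ``nitrogen_scale`` is the divisor applied to Δδ(¹⁵N); the conventional
    value 5 is the default, but other weights occur in the literature.
    """

    nitrogen_scale: float = 5.0

    def __post_init__(self) -> None:
        if not (self.nitrogen_scale > 0):
            raise ValueError("nitrogen_scale must be positive")


def weighted_csp(delta_H, delta_N, scheme: WeightingScheme = WeightingScheme()):
    """Weighted CSP of a (Δδ¹H, Δδ¹⁵N) pair, in ppm.

    Accepts scalars or arrays; the result is non-negative and invariant
    under sign flips of either input. Non-finite inputs raise.
    """
    delta_H = np.asarray(delta_H, dtype=float)
    delta_N = np.asarray(delta_N, dtype=float)
    if not (np.all(np.isfinite(delta_H)) and np.all(np.isfinite(delta_N))):
        raise ValueError("weighted_csp requires finite shift differences")
    out = np.hypot(delta_H, delta_N / scheme.nitrogen_scale)
    return float(out) if out.ndim == 0 else out


@dataclass
class CSPProfile:
    """Per-residue weighted CSPs across a titration, relative to apo.

    ``values[i, j]`` is the CSP of ``residues[i]`` at ``ligand_conc[j]``
    (ppm); NaN marks residues not observable at that point. The apo column
    is identically zero by construction.
    """

    residues: list[int]
    ligand_conc: np.ndarray
    values: np.ndarray
    scheme: WeightingScheme
    protein_conc: np.ndarray = field(default=None)  # mM, one per point

    def __post_init__(self) -> None:
        self.ligand_conc = np.asarray(self.ligand_conc, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.residues), len(self.ligand_conc)):
            raise ValueError("values shape does not match residues x points")
        with np.errstate(invalid="ignore"):
            if np.any(self.values[~np.isnan(self.values)] < 0):
                raise ValueError("CSP values must be non-negative")
        if self.protein_conc is not None:
            self.protein_conc = np.asarray(self.protein_conc, dtype=float)

    def row(self, residue_index: int) -> np.ndarray:
        return self.values[self.residues.index(residue_index)]

    def curve(self, residue_index: int) -> list[tuple[float, float]]:
        """(ligand_conc, Δδ_obs) pairs for one residue, missing points dropped."""
        r = self.row(residue_index)
        return [
            (float(L), float(v))
            for L, v in zip(self.ligand_conc, r)
            if not np.isnan(v)
        ]

    def endpoint(self) -> dict[int, float]:
        col = self.values[:, -1]
        return {res: float(v) for res, v in zip(self.residues, col)}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.residues, columns=self.ligand_conc)
        df.index.name = "residue_index"
        df.columns.name = "ligand_conc_mM"
        return df

    def to_csv(self, path: str | Path) -> None:
        """CSV matrix residue_index x ligand_conc, ppm to 6 decimals, missing empty."""
        self.to_frame().to_csv(path, float_format="%.6f")


def csp_profile(series: TitrationSeries, scheme: WeightingScheme = WeightingScheme()) -> CSPProfile:
    """Compute the weighted CSP of every residue at every titration point.

    A residue contributes at a point only if both its ¹H and ¹⁵N shifts are
    present at that point *and* in the apo reference; anything else is NaN
    (missing), never zero — exchange broadening can delete peaks and zeros
    would bias downstream fits.
    """
    apo = series.apo.table.by_residue()
    residues = sorted(
        idx for idx, rec in apo.items() if rec.complete
    )
    if not residues:
        raise ValueError("no residue with complete apo shifts")
    n_pts = len(series.points)
    values = np.full((len(residues), n_pts), np.nan)
    values[:, 0] = 0.0  # apo vs apo
    for j, pt in enumerate(series.points[1:], start=1):
        recs = pt.table.by_residue()
        for i, idx in enumerate(residues):
            rec = recs.get(idx)
            if rec is None or not rec.complete:
                logger.info(
                    "residue %d missing at ligand_conc %.4g mM", idx, pt.ligand_conc
                )
                continue
            ref = apo[idx]
            values[i, j] = weighted_csp(
                rec.shift_H - ref.shift_H, rec.shift_N - ref.shift_N, scheme
            )
    return CSPProfile(
        residues=residues,
        ligand_conc=np.array(series.ligand_concs()),
        values=values,
        scheme=scheme,
        protein_conc=np.array([p.protein_conc for p in series.points]),
    )


def endpoint_csp(profile: CSPProfile) -> dict[int, float]:
    """CSP at the highest ligand concentration, per residue (NaN = missing)."""
    return profile.endpoint()
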