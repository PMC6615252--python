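"""Forward model: 1:1 fast-exchange binding isotherms.

Under fast exchange the observed CSP of a residue is its saturation
amplitude Δδ_max scaled by the fraction of protein in the bound state,

    Δδ_obs(L) = Δδ_max · f_b(P, L, K_D).

Two functional forms of f_b are provided:

* ``"quadratic"`` — the exact mass-balance solution in *total*
  concentrations, which accounts for ligand depletion:

      f_b = ((P + L + K) − sqrt((P + L + K)² − 4·P·L)) / (2·P)

  This matters whenever K_D is comparable to the protein concentration,
  which is the regime of weak peptide–domain interactions (hundreds of μM
  to a few mM K_D at a few hundred μM protein).

* ``"hyperbolic"`` — the dilute-limit Langmuir form L/(L + K), which
  treats total ligand as free ligand. Kept for comparison; it converges to
  the quadratic form when P ≪ K.

Concentrations are in mM throughout; K_D is converted to μM only at
reporting boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MODEL_KINDS", "BindingParameters", "fraction_bound", "predicted_csp"]

MODEL_KINDS = ("quadratic", "hyperbolic")


@dataclass(frozen=True)
class BindingParameters:
    """Per-residue binding parameters: K_D (mM) and Δδ_max (ppm)."""

    kd_mM: float
    delta_max: float

    def __post_init__(self) -> None:
        if not (self.kd_mM > 0):
            raise ValueError("K_D must be positive")
        if self.delta_max < 0:
            raise ValueError("delta_max must be non-negative")

    @property
    def kd_uM(self) -> float:
        return self.kd_mM * 1000.0


def _check_kind(kind: str) -> None:
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


def fraction_bound(protein_conc, ligand_conc, kd_mM, kind: str = "quadratic"):
    """Fraction of protein in the bound state; scalar or array over ligand_conc.

    Monotone non-decreasing in ligand concentration, non-increasing in K_D,
    and always in [0, 1]. Tiny negative discriminant round-off (< 1e-12) is
    clamped to zero before the square root.
    """
    _check_kind(kind)
    P = float(protein_conc)
    K = float(kd_mM)
    L = np.asarray(ligand_conc, dtype=float)
    if P <= 0:
        raise ValueError("protein_conc must be positive")
    if K <= 0:
        raise ValueError("K_D must be positive")
    if np.any(L < 0):
        raise ValueError("ligand_conc must be non-negative")
    if kind == "hyperbolic":
        fb = L / (L + K)
    else:
        s = P + L + K
        disc = s * s - 4.0 * P * L
        if np.any(disc < -1e-12):
            raise FloatingPointError("negative discriminant in quadratic model")
        disc = np.clip(disc, 0.0, None)
        fb = (s - np.sqrt(disc)) / (2.0 * P)
    fb = np.clip(fb, 0.0, 1.0)
    return float(fb) if fb.ndim == 0 else fb


def predicted_csp(params: BindingParameters, protein_conc, ligand_conc, kind: str = "quadratic"):
    """Predicted weighted CSP: Δδ_max × f_b. Zero at L = 0, → Δδ_max as L → ∞."""
    return params.delta_max * fraction_bound(protein_conc, ligand_conc, params.kd_mM, kind)
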