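"""Synthetic HSQC titration generator.

Raw titration peak lists for weak peptide–PDZ interactions are rarely
deposited, so the pipeline is exercised on synthetic series that carry
the statistical structure the analysis assumes:

* fast-exchange 1:1 binding with ligand depletion (quadratic isotherm);
* a titration schedule of protein:ligand molar ratios 1:0, 1:1, 1:3,
  1:5, 1:10, 1:20, 1:30 at 0.25 mM protein (midpoint of the typical
  0.1–0.5 mM NMR sample range) — weak binders titrated on a shorter
  1:2…1:10 schedule are also representable;
* per-residue saturation amplitudes Δδ_max drawn uniformly from
  ¹H ∈ [0.02, 0.3] ppm and ¹⁵N ∈ [0.1, 1.5] ppm for a responding subset
  of residues, with random ±1 signs per residue and axis (real peaks
  move in both directions; the weighted CSP must not care);
* Gaussian peak-position noise (defaults σ_H = 0.002 ppm,
  σ_N = 0.01 ppm — typical HSQC peak-picking reproducibility);
* non-responding residues carrying noise only (the null population a
  threshold selection rule needs);
* missing residues (prolines, overlapped peaks) absent from every table.

Generation is fully deterministic given the spec's seed; the returned
:class:`SyntheticTruth` records the realised ground truth for
parameter-recovery tests.

:func:`pdz_scenarios` provides six ready-made specs spanning the K_D
range reported for PDZ2/PDZ3 peptide binding (211–2574 μM), including the
very weak 2574 μM case whose titration endpoint stays visibly below
saturation (fraction bound ≈ 0.74 at ratio 1:30).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import yaml

from .binding import fraction_bound
from .csp import WeightingScheme, weighted_csp
from .shift_io import (
    ShiftRecord,
    ShiftTable,
    TitrationPoint,
    TitrationSeries,
    write_series_manifest,
)

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate_series", "pdz_scenarios", "write_dataset"]

_NON_PROLINE = "ACDEFGHIKLMNQRSTVWY"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic titration experiment."""

    kd_true_uM: float = 286.0
    n_residues: int = 90
    protein_conc_mM: float = 0.25
    molar_ratios: tuple[float, ...] = (0.0, 1.0, 3.0, 5.0, 10.0, 20.0, 30.0)
    responding_fraction: float = 6 / 90
    delta_max_H_range: tuple[float, float] = (0.02, 0.3)
    delta_max_N_range: tuple[float, float] = (0.1, 1.5)
    delta_max: Optional[Mapping[int, tuple[float, float]]] = None
    noise_sd_H: float = 0.002
    noise_sd_N: float = 0.01
    apo_H_range: tuple[float, float] = (6.0, 10.0)
    apo_N_range: tuple[float, float] = (100.0, 135.0)
    missing_residues: tuple[int, ...] = ()
    seed: int = 0
    protein_name: str = "protein"
    ligand_sequence: str = "KRHSGSYLVTSV"

    def __post_init__(self) -> None:
        if not (self.kd_true_uM > 0):
            raise ValueError("kd_true_uM must be positive")
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if 0.0 not in self.molar_ratios:
            raise ValueError("molar_ratios must include 0 (apo reference)")
        if len(self.molar_ratios) < 3:
            raise ValueError("need >= 3 titration points")
        if not (0.0 <= self.responding_fraction <= 1.0):
            raise ValueError("responding_fraction must be in [0, 1]")
        if self.noise_sd_H < 0 or self.noise_sd_N < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.delta_max is not None:
            bad = [r for r in self.delta_max if not (1 <= r <= self.n_residues)]
            if bad:
                raise ValueError(f"delta_max keys outside 1..n_residues: {bad}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Realised ground truth of one generated series (regenerable from spec)."""

    spec: SyntheticSpec
    responding: tuple[int, ...]
    delta_max_H: dict[int, float]
    delta_max_N: dict[int, float]
    sign_H: dict[int, int]
    sign_N: dict[int, int]
    residue_types: dict[int, str]
    apo_H: dict[int, float]
    apo_N: dict[int, float]

    def weighted_delta_max(self, scheme: WeightingScheme = WeightingScheme()) -> dict[int, float]:
        """Saturation amplitude of the weighted CSP per responding residue."""
        return {
            r: weighted_csp(self.delta_max_H[r], self.delta_max_N[r], scheme)
            for r in self.responding
        }

    def to_dict(self) -> dict:
        d = asdict(self.spec)
        d["delta_max"] = (
            {int(k): list(map(float, v)) for k, v in self.spec.delta_max.items()}
            if self.spec.delta_max
            else None
        )
        d["molar_ratios"] = list(self.spec.molar_ratios)
        d["missing_residues"] = list(self.spec.missing_residues)
        return {
            "spec": d,
            "responding": list(self.responding),
            "delta_max_H": {int(k): float(v) for k, v in self.delta_max_H.items()},
            "delta_max_N": {int(k): float(v) for k, v in self.delta_max_N.items()},
            "sign_H": {int(k): int(v) for k, v in self.sign_H.items()},
            "sign_N": {int(k): int(v) for k, v in self.sign_N.items()},
            "kd_true_uM": float(self.spec.kd_true_uM),
        }

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _ratio_label(ratio: float) -> str:
    if ratio == 0:
        return "apo"
    return "ratio_1_" + f"{ratio:g}".replace(".", "p")


def generate_series(spec: SyntheticSpec) -> tuple[TitrationSeries, SyntheticTruth]:
    """Generate one titration series plus its ground truth.

    At each point the shift of a present residue is
    ``apo + sign · Δδ_max · f_b + noise`` per axis, with f_b from the
    quadratic (ligand-depletion) isotherm. Missing residues are typed as
    proline and absent from every table. Identical specs (including seed)
    generate byte-identical series.
    """
    rng = np.random.default_rng(spec.seed)
    missing = set(spec.missing_residues)
    indices = list(range(1, spec.n_residues + 1))
    present = [i for i in indices if i not in missing]
    if not present:
        raise ValueError("every residue is missing")

    # fixed draw order: types, responders, amplitudes, signs, apo, noise
    types = {
        i: ("P" if i in missing else _NON_PROLINE[rng.integers(len(_NON_PROLINE))])
        for i in indices
    }
    if spec.delta_max is not None:
        responding = tuple(sorted(r for r in spec.delta_max if r in present))
        dmax_H = {r: float(spec.delta_max[r][0]) for r in responding}
        dmax_N = {r: float(spec.delta_max[r][1]) for r in responding}
    else:
        n_resp = int(round(spec.responding_fraction * spec.n_residues))
        n_resp = min(n_resp, len(present))
        responding = tuple(sorted(rng.choice(present, size=n_resp, replace=False).tolist()))
        dmax_H = {r: float(rng.uniform(*spec.delta_max_H_range)) for r in responding}
        dmax_N = {r: float(rng.uniform(*spec.delta_max_N_range)) for r in responding}
    sign_H = {r: int(rng.choice((-1, 1))) for r in responding}
    sign_N = {r: int(rng.choice((-1, 1))) for r in responding}
    apo_H = {i: float(rng.uniform(*spec.apo_H_range)) for i in present}
    apo_N = {i: float(rng.uniform(*spec.apo_N_range)) for i in present}

    P = spec.protein_conc_mM
    kd_mM = spec.kd_true_uM / 1e3
    points = []
    for ratio in sorted(spec.molar_ratios):
        L = ratio * P
        fb = fraction_bound(P, L, kd_mM, "quadratic")
        records = []
        for i in present:
            dH = sign_H[i] * dmax_H[i] * fb if i in dmax_H else 0.0
            dN = sign_N[i] * dmax_N[i] * fb if i in dmax_N else 0.0
            nH = rng.normal(0.0, spec.noise_sd_H) if spec.noise_sd_H > 0 else 0.0
            nN = rng.normal(0.0, spec.noise_sd_N) if spec.noise_sd_N > 0 else 0.0
            records.append(
                ShiftRecord(i, types[i], apo_H[i] + dH + nH, apo_N[i] + dN + nN)
            )
        points.append(
            TitrationPoint(
                table=ShiftTable(_ratio_label(ratio), records),
                protein_conc=P,
                molar_ratio=float(ratio),
            )
        )
    series = TitrationSeries(
        protein_name=spec.protein_name,
        ligand_sequence=spec.ligand_sequence,
        points=points,
    )
    truth = SyntheticTruth(
        spec=spec, responding=responding,
        delta_max_H=dmax_H, delta_max_N=dmax_N,
        sign_H=sign_H, sign_N=sign_N,
        residue_types=types, apo_H=apo_H, apo_N=apo_N,
    )
    return series, truth


def pdz_scenarios(seed: int = 0) -> dict[str, SyntheticSpec]:
    """Six titration scenarios spanning the PDZ2/PDZ3 peptide-binding K_D range.

    Each scenario names a protein context / ligand pair with its reported
    dissociation constant as the generating truth, the standard 1:0…1:30
    schedule at 0.25 mM protein (the weak-binding PDZ3–PRK2 titration uses
    its shorter 1:2…1:10 schedule), and six responding residues. The
    ``pdz3_in_tandem_apc`` scenario (K_D = 2574 μM) is deliberately
    unsaturated at its endpoint (f_b ≈ 0.74) and should trip the
    partial-saturation flag.
    """
    apc = "KRHSGSYLVTSV"
    prk2 = "MFRDFDYIADWC"
    full = (0.0, 1.0, 3.0, 5.0, 10.0, 20.0, 30.0)
    short = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)
    rows = [
        ("pdz2_apc", "PDZ2", apc, 286.0, full),
        ("pdz3_apc", "PDZ3", apc, 721.0, full),
        ("pdz2_in_tandem_apc", "PDZ2/3 (PDZ2 site)", apc, 211.0, full),
        ("pdz3_in_tandem_apc", "PDZ2/3 (PDZ3 site)", apc, 2574.0, full),
        ("pdz2_prk2", "PDZ2", prk2, 661.0, full),
        ("pdz3_prk2", "PDZ3", prk2, 318.0, short),
    ]
    return {
        name: SyntheticSpec(
            kd_true_uM=kd,
            molar_ratios=ratios,
            protein_name=protein,
            ligand_sequence=ligand,
            seed=seed + i,
        )
        for i, (name, protein, ligand, kd, ratios) in enumerate(rows)
    }


def write_dataset(spec: SyntheticSpec, directory: str | Path) -> Path:
    """Generate a series and write manifest + tables + truth file to disk."""
    directory = Path(directory)
    series, truth = generate_series(spec)
    manifest = write_series_manifest(series, directory)
    truth.write(directory / "truth.yaml")
    return manifest
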