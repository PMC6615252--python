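"""Per-residue K_D estimation and aggregation.

The estimation pipeline mirrors standard NMR titration practice: compute
weighted CSP curves relative to apo, pick the residues with significant
perturbations (explicitly, or by a mean + k·SD threshold on the endpoint
CSPs), fit each residue's curve independently by bounded nonlinear least
squares for (K_D, Δδ_max), and report the arithmetic mean of the
per-residue K_D estimates with the sample standard deviation of those
estimates as the error — the spread of independent single-residue fits.

The optimisation is deterministic: a fixed multistart grid over K_D
(0.05, 0.2, 0.5, 2, 5 mM) with Δδ_max initialised at the endpoint CSP,
solved by ``scipy.optimize.least_squares`` (trust-region reflective) with
bounds K_D ∈ [1e-3, 1e3] mM and Δδ_max ∈ [0, 10] ppm; the lowest-cost
start wins, first-come on ties. A fit whose K_D lands on a box bound is
flagged non-identifiable (e.g. instantly saturating curves contain no
K_D information).

The statsmodels-style entry point is :class:`TitrationModel` /
:class:`TitrationResults`; :func:`fit_series` is the functional wrapper.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import least_squares

from .binding import MODEL_KINDS, fraction_bound
from .csp import CSPProfile, WeightingScheme, csp_profile
from .selection import SelectionRule, apply_selection
from .shift_io import TitrationSeries, read_series_manifest

__all__ = [
    "BindingFitResult",
    "AggregateKD",
    "SelectionRule",
    "fit_residue",
    "select_residues",
    "aggregate_kd",
    "fit_series",
    "global_fit",
    "TitrationModel",
    "TitrationResults",
]

KD_BOUNDS_MM = (1e-3, 1e3)
DMAX_BOUNDS_PPM = (0.0, 10.0)
MULTISTART_KD_MM = (0.05, 0.2, 0.5, 2.0, 5.0)


@dataclass(frozen=True)
class BindingFitResult:
    """Outcome of one per-residue curve fit."""

    residue_index: int
    kd_uM: Optional[float]
    delta_max: Optional[float]
    rss: Optional[float]
    converged: bool
    endpoint_fraction_bound: Optional[float]
    n_points_used: int
    note: str = ""


@dataclass(frozen=True)
class AggregateKD:
    """Averaged K_D over converged per-residue fits.

    ``error_uM`` is the sample standard deviation (n−1 denominator) of the
    individual estimates — 0 when only one residue converged, which the
    note flags. ``partial_saturation_flag`` is set when the median endpoint
    fraction bound falls below the saturation floor, marking titrations
    that never approached the bound state (very weak binders), whose K_D
    is correspondingly less well determined.
    """

    kd_uM: float
    error_uM: float
    residues_used: tuple[int, ...]
    n_converged: int
    partial_saturation_flag: bool
    note: str = ""


def fit_residue(
    csp_curve: Sequence[tuple[float, float]],
    protein_conc: float,
    kind: str = "quadratic",
) -> BindingFitResult:
    """Fit (K_D, Δδ_max) to one residue's (ligand_conc mM, Δδ_obs ppm) curve.

    Requires >= 3 points including the apo zero. All-zero curves return
    ``converged=False`` with note "no perturbation"; K_D estimates pinned
    to a box bound are flagged non-identifiable.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    pts = [(float(L), float(d)) for L, d in csp_curve if np.isfinite(d)]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 non-missing points, got {len(pts)}")
    if not any(L == 0 for L, _ in pts):
        raise ValueError("curve must include the apo (ligand_conc = 0) point")
    L = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    res_idx = -1  # patched by caller wrappers; standalone use keeps -1
    if np.all(y <= 0):
        return BindingFitResult(
            residue_index=res_idx, kd_uM=None, delta_max=None, rss=None,
            converged=False, endpoint_fraction_bound=None,
            n_points_used=len(pts), note="no perturbation",
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        kd, dmax = theta
        return dmax * fraction_bound(protein_conc, L, kd, kind) - y

    dmax0 = max(float(y.max()), 1e-3)
    lower = np.array([KD_BOUNDS_MM[0], DMAX_BOUNDS_PPM[0]])
    upper = np.array([KD_BOUNDS_MM[1], DMAX_BOUNDS_PPM[1]])
    best = None
    for kd0 in MULTISTART_KD_MM:
        x0 = np.array([kd0, min(dmax0, DMAX_BOUNDS_PPM[1])])
        try:
            sol = least_squares(residuals, x0, bounds=(lower, upper), method="trf")
        except Exception:
            continue
        if not sol.success:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return BindingFitResult(
            residue_index=res_idx, kd_uM=None, delta_max=None, rss=None,
            converged=False, endpoint_fraction_bound=None,
            n_points_used=len(pts), note="optimizer failure",
        )
    kd_mM, dmax = map(float, best.x)
    rss = float(np.sum(best.fun ** 2))
    at_bound = kd_mM <= KD_BOUNDS_MM[0] * (1 + 1e-6) or kd_mM >= KD_BOUNDS_MM[1] * (1 - 1e-6)
    endpoint_fb = float(fraction_bound(protein_conc, float(L.max()), kd_mM, kind))
    if at_bound:
        return BindingFitResult(
            residue_index=res_idx, kd_uM=kd_mM * 1e3, delta_max=dmax, rss=rss,
            converged=False, endpoint_fraction_bound=endpoint_fb,
            n_points_used=len(pts), note="non-identifiable (K_D at bound)",
        )
    return BindingFitResult(
        residue_index=res_idx, kd_uM=kd_mM * 1e3, delta_max=dmax, rss=rss,
        converged=True, endpoint_fraction_bound=endpoint_fb,
        n_points_used=len(pts), note="",
    )


def select_residues(profile: CSPProfile, rule: SelectionRule) -> list[int]:
    """Pick residues to fit, from endpoint CSPs (threshold) or a given list."""
    return apply_selection(profile.endpoint(), rule)


def aggregate_kd(
    fits: Sequence[BindingFitResult], saturation_floor: float = 0.8
) -> AggregateKD:
    """Average converged per-residue K_Ds; error = sample SD of the estimates."""
    conv = [f for f in fits if f.converged]
    if not conv:
        raise ValueError("no converged fits to aggregate")
    kds = np.array([f.kd_uM for f in conv])
    err = float(np.std(kds, ddof=1)) if len(kds) > 1 else 0.0
    note = "single-residue aggregate: spread undefined, error set to 0" if len(kds) == 1 else ""
    fbs = np.array([f.endpoint_fraction_bound for f in conv])
    return AggregateKD(
        kd_uM=float(np.mean(kds)),
        error_uM=err,
        residues_used=tuple(f.residue_index for f in conv),
        n_converged=len(conv),
        partial_saturation_flag=bool(np.median(fbs) < saturation_floor),
        note=note,
    )


def global_fit(
    profile: CSPProfile,
    residues: Sequence[int],
    protein_conc: float,
    kind: str = "quadratic",
) -> tuple[float, dict[int, float], float]:
    """Alternative estimator: one shared K_D, per-residue Δδ_max.

    Returns (K_D in μM, residue → Δδ_max map, total RSS). Non-default mode
    kept for comparison with the per-residue-average estimator.
    """
    curves = {r: profile.curve(r) for r in residues}
    for r, c in curves.items():
        if len(c) < 3:
            raise ValueError(f"residue {r}: need >= 3 points")
    n_res = len(residues)

    def residuals(theta: np.ndarray) -> np.ndarray:
        kd = theta[0]
        out = []
        for i, r in enumerate(residues):
            dmax = theta[1 + i]
            L = np.array([p[0] for p in curves[r]])
            y = np.array([p[1] for p in curves[r]])
            out.append(dmax * fraction_bound(protein_conc, L, kd, kind) - y)
        return np.concatenate(out)

    dmax0 = [max(max(y for _, y in curves[r]), 1e-3) for r in residues]
    lower = np.array([KD_BOUNDS_MM[0]] + [DMAX_BOUNDS_PPM[0]] * n_res)
    upper = np.array([KD_BOUNDS_MM[1]] + [DMAX_BOUNDS_PPM[1]] * n_res)
    best = None
    for kd0 in MULTISTART_KD_MM:
        sol = least_squares(
            residuals, np.array([kd0] + dmax0), bounds=(lower, upper), method="trf"
        )
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError("global fit failed to converge")
    kd_mM = float(best.x[0])
    dmax = {r: float(best.x[1 + i]) for i, r in enumerate(residues)}
    return kd_mM * 1e3, dmax, float(np.sum(best.fun ** 2))


# ---------------------------------------------------------------------------
# Model / Results

class TitrationModel:
    """1:1 fast-exchange binding model for a protein–peptide titration.

    Parameters
    ----------
    series : TitrationSeries
        Ordered titration points including the apo reference.
    scheme : WeightingScheme, optional
        CSP weighting (¹⁵N divisor, default 5).
    kind : {"quadratic", "hyperbolic"}, optional
        Isotherm form; the quadratic (ligand-depletion) form is the
        default because weak binders are titrated at protein
        concentrations comparable to K_D.

    Examples
    --------
    >>> model = TitrationModel(series)
    >>> res = model.fit(rule=SelectionRule.explicit([23, 50, 52, 73, 80, 81]))
    >>> print(res.summary())          # doctest: +SKIP
    """

    def __init__(
        self,
        series: TitrationSeries,
        scheme: WeightingScheme = WeightingScheme(),
        kind: str = "quadratic",
    ) -> None:
        if kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {kind!r}")
        self.series = series
        self.scheme = scheme
        self.kind = kind
        self.profile = csp_profile(series, scheme)

    @classmethod
    def from_manifest(cls, path: str | Path, **kwargs) -> "TitrationModel":
        return cls(read_series_manifest(path), **kwargs)

    @property
    def protein_conc(self) -> float:
        return self.series.apo.protein_conc

    def fit(
        self,
        rule: SelectionRule = SelectionRule.threshold(1.0),
        saturation_floor: float = 0.8,
    ) -> "TitrationResults":
        selected = select_residues(self.profile, rule)
        fits = []
        skipped: list[tuple[int, str]] = []
        for r in selected:
            curve = self.profile.curve(r)
            try:
                f = fit_residue(curve, self.protein_conc, self.kind)
            except ValueError as exc:
                skipped.append((r, str(exc)))
                continue
            fits.append(
                BindingFitResult(
                    residue_index=r, kd_uM=f.kd_uM, delta_max=f.delta_max,
                    rss=f.rss, converged=f.converged,
                    endpoint_fraction_bound=f.endpoint_fraction_bound,
                    n_points_used=f.n_points_used, note=f.note,
                )
            )
        aggregate = None
        agg_error = ""
        try:
            aggregate = aggregate_kd(fits, saturation_floor)
        except ValueError as exc:
            agg_error = str(exc)
        return TitrationResults(
            model=self,
            rule=rule,
            saturation_floor=saturation_floor,
            residue_fits=fits,
            aggregate=aggregate,
            skipped=skipped,
            aggregate_error=agg_error,
        )


@dataclass
class TitrationResults:
    """Fit results: per-residue estimates plus the averaged K_D.

    ``aggregate`` is ``None`` when no residue fit converged (the failure
    reason is in ``aggregate_error``); a report is still produced.
    """

    model: TitrationModel
    rule: SelectionRule
    saturation_floor: float
    residue_fits: list[BindingFitResult]
    aggregate: Optional[AggregateKD]
    skipped: list[tuple[int, str]] = field(default_factory=list)
    aggregate_error: str = ""

    @property
    def kd_uM(self) -> Optional[float]:
        return self.aggregate.kd_uM if self.aggregate else None

    @property
    def error_uM(self) -> Optional[float]:
        return self.aggregate.error_uM if self.aggregate else None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "residue_index": f.residue_index,
                "kd_uM": f.kd_uM,
                "delta_max_ppm": f.delta_max,
                "rss": f.rss,
                "converged": f.converged,
                "endpoint_fraction_bound": f.endpoint_fraction_bound,
                "n_points_used": f.n_points_used,
                "note": f.note,
            }
            for f in self.residue_fits
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        """Per-residue fit report plus a trailing aggregate summary row."""
        df = self.to_frame()
        if self.aggregate is not None:
            agg = self.aggregate
            df = pd.concat(
                [
                    df,
                    pd.DataFrame(
                        [
                            {
                                "residue_index": "aggregate",
                                "kd_uM": agg.kd_uM,
                                "delta_max_ppm": np.nan,
                                "rss": np.nan,
                                "converged": agg.n_converged > 0,
                                "endpoint_fraction_bound": np.nan,
                                "n_points_used": agg.n_converged,
                                "note": f"error_uM={agg.error_uM:.6f};"
                                f" partial_saturation={agg.partial_saturation_flag}",
                            }
                        ]
                    ),
                ],
                ignore_index=True,
            )
        df.to_csv(path, index=False, float_format="%.6f")

    def report_dict(self) -> dict:
        """Machine-readable run report: settings plus all estimates."""
        d = {
            "protein_name": self.model.series.protein_name,
            "ligand_sequence": self.model.series.ligand_sequence,
            "protein_conc_mM": float(self.model.protein_conc),
            "model_kind": self.model.kind,
            "nitrogen_scale": float(self.model.scheme.nitrogen_scale),
            "selection_rule": {
                "mode": self.rule.mode,
                "explicit_residues": (
                    list(self.rule.explicit_residues)
                    if self.rule.explicit_residues
                    else None
                ),
                "threshold_sigmas": float(self.rule.threshold_sigmas),
                "min_delta": float(self.rule.min_delta),
            },
            "saturation_floor": float(self.saturation_floor),
            "residue_fits": [asdict(f) for f in self.residue_fits],
            "skipped": [{"residue_index": r, "reason": m} for r, m in self.skipped],
        }
        if self.aggregate is not None:
            d["aggregate"] = asdict(self.aggregate)
            d["aggregate"]["residues_used"] = list(self.aggregate.residues_used)
        else:
            d["aggregate"] = None
            d["aggregate_error"] = self.aggregate_error
        return d

    def write_report(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.report_dict(), fh, sort_keys=False)

    def summary(self) -> str:
        """Human-readable summary table of the fit."""
        buf = io.StringIO()
        m = self.model
        print("1:1 fast-exchange titration fit", file=buf)
        print("=" * 64, file=buf)
        print(f"protein: {m.series.protein_name}   ligand: {m.series.ligand_sequence}", file=buf)
        print(
            f"protein conc: {m.protein_conc:.4g} mM   points: {len(m.series.points)}"
            f"   model: {m.kind}   N-scale: {m.scheme.nitrogen_scale:g}",
            file=buf,
        )
        print("-" * 64, file=buf)
        print(f"{'residue':>8} {'K_D [uM]':>12} {'dmax [ppm]':>11} {'f_b(end)':>9} {'conv':>5}", file=buf)
        for f in self.residue_fits:
            kd = f"{f.kd_uM:.1f}" if f.kd_uM is not None else "-"
            dm = f"{f.delta_max:.4f}" if f.delta_max is not None else "-"
            fb = (
                f"{f.endpoint_fraction_bound:.3f}"
                if f.endpoint_fraction_bound is not None
                else "-"
            )
            note = f"  ({f.note})" if f.note else ""
            print(f"{f.residue_index:>8} {kd:>12} {dm:>11} {fb:>9} {str(f.converged):>5}{note}", file=buf)
        print("-" * 64, file=buf)
        if self.aggregate is not None:
            a = self.aggregate
            flag = "  [PARTIAL SATURATION]" if a.partial_saturation_flag else ""
            print(
                f"K_D = {a.kd_uM:.0f} ± {a.error_uM:.0f} uM "
                f"(n = {a.n_converged} residues){flag}",
                file=buf,
            )
        else:
            print(f"no aggregate K_D: {self.aggregate_error}", file=buf)
        return buf.getvalue()

    def plot(self, residue_index: Optional[int] = None, ax=None):
        """Plot observed CSP curves and fitted isotherms (matplotlib axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fits = self.residue_fits
        if residue_index is not None:
            fits = [f for f in fits if f.residue_index == residue_index]
        P = self.model.protein_conc
        Lmax = float(np.max(self.model.profile.ligand_conc))
        grid = np.linspace(0, Lmax, 200)
        for f in fits:
            curve = self.model.profile.curve(f.residue_index)
            L = [p[0] for p in curve]
            y = [p[1] for p in curve]
            pts = ax.plot(L, y, "o", label=f"res {f.residue_index}")
            if f.converged:
                pred = f.delta_max * fraction_bound(P, grid, f.kd_uM / 1e3, self.model.kind)
                ax.plot(grid, pred, "-", color=pts[0].get_color())
        ax.set_xlabel("ligand concentration [mM]")
        ax.set_ylabel("weighted CSP [ppm]")
        ax.legend(fontsize="small")
        return ax


def fit_series(
    series: TitrationSeries,
    rule: SelectionRule = SelectionRule.threshold(1.0),
    kind: str = "quadratic",
    scheme: WeightingScheme = WeightingScheme(),
    saturation_floor: float = 0.8,
) -> tuple[list[BindingFitResult], Optional[AggregateKD]]:
    """Functional wrapper: profile → selection → per-residue fits → aggregate."""
    results = TitrationModel(series, scheme=scheme, kind=kind).fit(
        rule=rule, saturation_floor=saturation_floor
    )
    return results.residue_fits, results.aggregate
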