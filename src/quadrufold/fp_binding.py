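"""One-site quadratic (ligand-depletion) fluorescence-polarization fitting.

Fluorescence polarization (FP) of a labelled RNA rises when protein binds.
With the RNA probe at 10 nM — comparable to the dissociation constants of
Arg-rich peptides — the free-protein approximation fails, so the bound
fraction comes from the exact quadratic solution of the one-site binding
equilibrium:

    bound = (P_T + L_T + K_D - sqrt((P_T + L_T + K_D)^2 - 4 P_T L_T)) / (2 L_T)
    F_p   = F_min + (F_max - F_min) * bound

where P_T is total protein (nM), L_T total labelled RNA (nM), F_min the
polarization baseline and F_max the plateau (mP). K_D is fitted per
replicate by nonlinear least squares in log-space (the titration spans 4+
decades) and reported as mean +/- SD across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "BindingModel",
    "TitrationSeries",
    "FitReport",
    "fp_model",
    "fit_kd",
    "paper_ladder",
]

DEFAULT_LT_NM = 10.0


def paper_ladder(top_nm: float = 8000.0, n: int = 15) -> np.ndarray:
    """Two-fold dilution series, 8000 -> 0.488 nM by default (15 points)."""
    return top_nm / 2.0 ** np.arange(n)


@dataclass(frozen=True)
class BindingModel:
    """Quadratic one-site FP model parameters (mP, nM)."""

    f_min: float
    f_max: float
    kd_nm: float
    lt_nm: float = DEFAULT_LT_NM

    def __post_init__(self):
        if self.kd_nm < 0:
            raise ValueError("K_D must be >= 0")
        if self.lt_nm <= 0:
            raise ValueError("L_T must be > 0")


def fp_model(
    pt_nm: Union[float, np.ndarray], model: BindingModel
) -> Union[float, np.ndarray]:
    """Polarization (mP) at total protein concentration(s) ``pt_nm``."""
    pt = np.asarray(pt_nm, dtype=float)
    if np.any(pt < 0):
        raise ValueError("protein concentration must be >= 0")
    s = pt + model.lt_nm + model.kd_nm
    disc = s * s - 4.0 * pt * model.lt_nm
    # analytically non-negative; clamp against roundoff
    disc = np.maximum(disc, 0.0)
    bound = (s - np.sqrt(disc)) / (2.0 * model.lt_nm)
    out = model.f_min + (model.f_max - model.f_min) * bound
    return float(out) if np.isscalar(pt_nm) else out


@dataclass
class TitrationSeries:
    """FP readings (mP) per protein concentration per replicate."""

    concentrations_nm: np.ndarray
    readings_mp: np.ndarray  # shape (n_replicates, n_concentrations)
    condition: str = ""

    def __post_init__(self):
        c = np.asarray(self.concentrations_nm, dtype=float)
        y = np.atleast_2d(np.asarray(self.readings_mp, dtype=float))
        if y.shape[1] != c.size:
            raise ValueError("readings shape does not match concentrations")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        if len(np.unique(c)) < 6:
            raise ValueError("at least 6 distinct concentrations required")
        if not np.all(np.isfinite(y)):
            raise ValueError("readings must be finite")
        self.concentrations_nm = c
        self.readings_mp = y

    @classmethod
    def from_csv(cls, path, condition: str = "") -> "TitrationSeries":
        """CSV columns: protein_conc_nM, polarization_mP, replicate."""
        df = pd.read_csv(path)
        req = {"protein_conc_nM", "polarization_mP", "replicate"}
        if not req.issubset(df.columns):
            raise ValueError(f"titration CSV needs columns {sorted(req)}")
        wide = df.pivot_table(
            index="replicate", columns="protein_conc_nM",
            values="polarization_mP",
        ).sort_index(axis=1)
        return cls(
            concentrations_nm=wide.columns.to_numpy(float),
            readings_mp=wide.to_numpy(float),
            condition=condition,
        )


@dataclass
class ReplicateFit:
    model: Optional[BindingModel]
    converged: bool
    flag: str = ""
    rmsd_mp: float = float("nan")


@dataclass
class FitReport:
    """Per-replicate quadratic fits plus mean K_D +/- SD."""

    replicates: list = field(default_factory=list)
    kd_mean_nm: Optional[float] = None
    kd_sd_nm: Optional[float] = None
    lt_nm: float = DEFAULT_LT_NM

    def to_dict(self) -> dict:
        return {
            "lt_nm": self.lt_nm,
            "kd_mean_nm": self.kd_mean_nm,
            "kd_sd_nm": self.kd_sd_nm,
            "replicates": [
                {
                    "kd_nm": r.model.kd_nm if r.model else None,
                    "f_min": r.model.f_min if r.model else None,
                    "f_max": r.model.f_max if r.model else None,
                    "converged": r.converged,
                    "flag": r.flag,
                    "rmsd_mp": None if np.isnan(r.rmsd_mp) else r.rmsd_mp,
                }
                for r in self.replicates
            ],
        }


def _fit_single(
    conc: np.ndarray, y: np.ndarray, lt_nm: float
) -> ReplicateFit:
    span = float(y.max() - y.min())
    if span <= 0:
        return ReplicateFit(None, False, flag="unidentifiable: flat signal")

    # init: F_min/F_max from data extremes, K_D at the concentration whose
    # reading is nearest half-maximal
    half = y.min() + 0.5 * span
    pos = conc[conc > 0]
    kd0 = float(pos[np.argmin(np.abs(y[conc > 0] - half))]) if pos.size else 1.0
    x0 = np.array([y.min(), y.max(), np.log(max(kd0, 1e-3))])

    def resid(p):
        f_min, f_max, log_kd = p
        m = BindingModel(f_min, f_max, float(np.exp(log_kd)), lt_nm)
        return fp_model(conc, m) - y

    try:
        sol = least_squares(resid, x0, method="lm", max_nfev=5000)
    except Exception:
        return ReplicateFit(None, False, flag="optimizer failure")
    f_min, f_max, log_kd = sol.x
    model = BindingModel(float(f_min), float(f_max), float(np.exp(log_kd)), lt_nm)
    rmsd = float(np.sqrt(np.mean(sol.fun**2)))
    if not sol.success:
        return ReplicateFit(model, False, flag="non-convergence", rmsd_mp=rmsd)
    # amplitude indistinguishable from noise -> no binding signal
    if abs(f_max - f_min) < max(3.0 * rmsd, 1e-9 * max(abs(span), 1.0)):
        return ReplicateFit(
            model, False, flag="unidentifiable: no signal change", rmsd_mp=rmsd
        )
    return ReplicateFit(model, True, rmsd_mp=rmsd)


def fit_kd(series: TitrationSeries, lt_nm: float = DEFAULT_LT_NM) -> FitReport:
    """Fit the quadratic model per replicate; report mean K_D +/- SD.

    Replicates that fail to converge (or show no signal change, e.g. a
    binding-incompetent peptide) are flagged and excluded from the mean.
    With fewer than two converged replicates the SD is None.
    """
    report = FitReport(lt_nm=lt_nm)
    for rep in series.readings_mp:
        report.replicates.append(
            _fit_single(series.concentrations_nm, rep, lt_nm)
        )
    kds = [r.model.kd_nm for r in report.replicates if r.converged]
    if kds:
        report.kd_mean_nm = float(np.mean(kds))
        report.kd_sd_nm = float(np.std(kds, ddof=1)) if len(kds) >= 2 else None
    return report
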