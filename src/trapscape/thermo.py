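"""Cross-temperature thermodynamics: Gibbs energies, K_eq, van 't Hoff fits.

Landscape energies live in k_BT units until they reach this module, which is
the single place the gas constant enters: dG[kcal/mol] = dG[k_BT] * R * T.
A linear fit of dG against temperature decomposes the transition into
enthalpy and entropy via dG = dH - T dS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "R_KCAL",
    "keq_from_gibbs",
    "gibbs_from_keq",
    "kt_to_kcal",
    "kcal_to_kt",
    "EnthalpyEntropyFit",
    "fit_enthalpy_entropy",
    "assemble_series",
]

#: gas constant in kcal/(mol K)
R_KCAL = 1.98720425e-3


def keq_from_gibbs(delta_g_kcal: float, temperature: float) -> float:
    """K_eq = exp(-dG / RT) with dG in kcal/mol and T in kelvin."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return float(np.exp(-np.asarray(delta_g_kcal) / (R_KCAL * temperature)))


def gibbs_from_keq(keq: float, temperature: float) -> float:
    """Inverse of :func:`keq_from_gibbs`: dG = -RT ln K (kcal/mol)."""
    if temperature <= 0 or keq <= 0:
        raise ValueError("temperature and K must be positive")
    return float(-R_KCAL * temperature * np.log(keq))


def kt_to_kcal(delta_g_kt: float, temperature: float) -> float:
    """Convert an energy difference from k_BT units to kcal/mol at T."""
    return float(np.asarray(delta_g_kt) * R_KCAL * temperature)


def kcal_to_kt(delta_g_kcal: float, temperature: float) -> float:
    return float(np.asarray(delta_g_kcal) / (R_KCAL * temperature))


@dataclass
class EnthalpyEntropyFit:
    """dG(T) = dH - T dS by ordinary least squares, with fit standard errors.

    The quoted uncertainties are OLS standard errors from the fit covariance
    (not cross-day repeatability).  ``diagnostics`` records residual
    structure so a non-linear dG(T) — as seen for the F-E transition — is
    reported rather than silently forced onto a line.
    """

    delta_h: float          # kcal/mol (intercept)
    delta_h_se: float
    delta_s: float          # kcal/(mol K) (minus the slope)
    delta_s_se: float
    residuals: np.ndarray
    temperatures: np.ndarray
    r_squared: float

    @property
    def fit_range(self) -> tuple[float, float]:
        return float(self.temperatures.min()), float(self.temperatures.max())

    def predict(self, temperature: np.ndarray) -> np.ndarray:
        return self.delta_h - np.asarray(temperature) * self.delta_s

    @property
    def diagnostics(self) -> dict:
        r = self.residuals
        return {
            "rmse_kcal_mol": float(np.sqrt(np.mean(r**2))),
            "max_abs_residual_kcal_mol": float(np.max(np.abs(r))),
            "r_squared": self.r_squared,
            # a residual minimum in the middle of the range flags curvature
            "curvature_flag": bool(r.size >= 4 and abs(np.corrcoef(
                (self.temperatures - self.temperatures.mean())**2, r)[0, 1]) > 0.8),
        }


def fit_enthalpy_entropy(temperatures: np.ndarray,
                         delta_g_kcal: np.ndarray) -> EnthalpyEntropyFit:
    """OLS of dG (kcal/mol) on T (K): intercept = dH, minus slope = dS."""
    t = np.asarray(temperatures, dtype=float)
    g = np.asarray(delta_g_kcal, dtype=float)
    if t.size != g.size or t.size < 3:
        raise ValueError("need at least three (T, dG) points")
    if np.ptp(t) == 0:
        raise ValueError("degenerate temperature spread")
    res = stats.linregress(t, g)
    resid = g - (res.intercept + res.slope * t)
    return EnthalpyEntropyFit(
        delta_h=float(res.intercept),
        delta_h_se=float(res.intercept_stderr),
        delta_s=float(-res.slope),
        delta_s_se=float(res.stderr),
        residuals=resid,
        temperatures=t,
        r_squared=float(res.rvalue**2),
    )


def assemble_series(entries: list[dict]) -> pd.DataFrame:
    """Tabulate per-temperature features and dwell statistics, both K routes.

    Each entry carries ``temperature`` (K), ``features`` (LandscapeFeatures)
    and optionally ``residence`` (ResidenceEquilibrium) and ``trace_id``.
    Rows where the landscape and residence routes disagree by more than three
    combined standard errors are flagged.  Mixed two-/three-state entries are
    rejected: their transition series are not comparable.
    """
    if not entries:
        return pd.DataFrame(columns=[
            "temperature_K", "trace_id", "transition", "delta_g_kt",
            "delta_g_kcal_mol", "keq_landscape", "keq_residence",
            "se_log_k", "routes_disagree"])
    n_states = {e["features"].n_states for e in entries}
    if len(n_states) > 1:
        raise ValueError("cannot mix two- and three-state entries in one series")
    names = ["NF", "FE"] if n_states.pop() == 3 else ["CO"]
    rows = []
    for e in entries:
        t = float(e["temperature"])
        feats = e["features"]
        resid = e.get("residence")
        for j, name in enumerate(names):
            dg_kt = feats.delta_g(j)
            k_el = feats.keq(j)
            k_rt = se = np.nan
            flag = False
            if resid is not None:
                k_rt = float(resid.k_total[j])
                se = float(resid.se_log_k[j])
                # landscape-route K is an occupancy estimate of the same trace,
                # so its log-K s.e. is taken equal to the residence-route one
                combined = np.sqrt(2.0) * se
                flag = bool(abs(np.log(k_el) - np.log(k_rt)) > 3 * combined)
            rows.append({
                "temperature_K": t,
                "trace_id": e.get("trace_id", ""),
                "transition": name,
                "delta_g_kt": dg_kt,
                "delta_g_kcal_mol": kt_to_kcal(dg_kt, t),
                "keq_landscape": k_el,
                "keq_residence": k_rt,
                "se_log_k": se,
                "routes_disagree": flag,
            })
    return pd.DataFrame(rows)
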