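"""Van't Hoff thermodynamic decomposition of binding constants.

With Ka measured at several temperatures, linear regression of ln Ka on 1/T
(Van't Hoff plot) gives the enthalpy and entropy of binding,

    ln Ka = -dH / (R T) + dS / R,      dG = dH - T dS = -R T ln Ka,

assuming a temperature-independent enthalpy over the measured range.  A
positive dH with Ka rising with temperature (endothermic, entropy-driven
binding) points to hydrophobic contacts dominating the interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

R_GAS = 8.314  # J / (mol K)


class ThermoError(ValueError):
    pass


def gibbs_from_Ka(Ka: float, T: float) -> float:
    """Gibbs free energy change dG = -R T ln Ka, in kJ/mol (Ka in M^-1)."""
    if Ka <= 0 or T <= 0:
        raise ThermoError("Ka and T must be positive")
    return -R_GAS * T * np.log(Ka) / 1000.0


@dataclass
class ThermoResults:
    """Van't Hoff regression output.

    ``delta_G_direct`` is -RT ln Ka at each input temperature;
    ``delta_G_regression`` is dH - T dS from the fitted line.  They differ
    by the regression residual at each temperature.
    """
    temperatures: np.ndarray        # K
    delta_H: float                  # kJ/mol
    delta_H_se: float
    delta_S: float                  # J/(mol K)
    delta_S_se: float
    delta_G_direct: np.ndarray      # kJ/mol per temperature
    delta_G_direct_se: np.ndarray
    delta_G_regression: np.ndarray  # kJ/mol per temperature
    T_delta_S: np.ndarray           # kJ/mol per temperature
    r_squared: float
    gas_constant: float = R_GAS

    def summary(self) -> str:
        lines = [
            "Van't Hoff analysis",
            "-" * 66,
            f"dH = {self.delta_H:8.2f} +/- {self.delta_H_se:.2f} kJ/mol   "
            f"dS = {self.delta_S:8.2f} +/- {self.delta_S_se:.2f} J/(mol K)"
            f"   r^2 = {self.r_squared:.4f}",
            "",
            f"{'T (K)':>7} {'dG=-RTlnKa':>12} {'dG=dH-TdS':>12} "
            f"{'T dS':>9}   (kJ/mol)",
        ]
        for i, T in enumerate(self.temperatures):
            lines.append(
                f"{T:7.1f} {self.delta_G_direct[i]:12.2f} "
                f"{self.delta_G_regression[i]:12.2f} "
                f"{self.T_delta_S[i]:9.2f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "temperatures_K": list(self.temperatures),
            "delta_H_kJ_mol": self.delta_H,
            "delta_H_se": self.delta_H_se,
            "delta_S_J_molK": self.delta_S,
            "delta_S_se": self.delta_S_se,
            "delta_G_direct_kJ_mol": list(self.delta_G_direct),
            "delta_G_regression_kJ_mol": list(self.delta_G_regression),
            "T_delta_S_kJ_mol": list(self.T_delta_S),
            "r_squared": self.r_squared,
        }


class VantHoff:
    """Van't Hoff model: ln Ka linear in 1/T.

    Parameters
    ----------
    Ka_by_T : mapping {temperature K: Ka M^-1} or {T: (Ka, Ka_se)}
        At least three temperatures.
    weighted : bool, default False
        Weight the regression by 1/SE(ln Ka)^2 when Ka SEs are given.
        Unweighted by default.
    """

    def __init__(self, Ka_by_T: dict, weighted: bool = False):
        if len(Ka_by_T) < 3:
            raise ThermoError("Van't Hoff fit requires >= 3 temperatures")
        temps, kas, ses = [], [], []
        for T in sorted(Ka_by_T):
            val = Ka_by_T[T]
            if isinstance(val, (tuple, list)):
                ka, se = val
            else:
                ka, se = val, None
            if T <= 0 or ka <= 0:
                raise ThermoError("temperatures and Ka must be positive")
            temps.append(float(T))
            kas.append(float(ka))
            ses.append(se)
        self.temperatures = np.array(temps)
        self.Ka = np.array(kas)
        self.Ka_se = None if any(s is None for s in ses) else np.array(ses)
        self.weighted = weighted and self.Ka_se is not None

    def fit(self) -> ThermoResults:
        T = self.temperatures
        x = 1.0 / T
        y = np.log(self.Ka)
        if self.weighted:
            w = (self.Ka / self.Ka_se) ** 2   # var(ln Ka) = (se/Ka)^2
        else:
            w = np.ones_like(x)
        X = np.column_stack([x, np.ones_like(x)])
        W = np.diag(w)
        xtwx_inv = np.linalg.inv(X.T @ W @ X)
        beta = xtwx_inv @ X.T @ W @ y
        slope, intercept = beta
        resid = y - X @ beta
        dof = x.size - 2
        s2 = float(resid @ (w * resid)) / dof if dof > 0 else 0.0
        cov = s2 * xtwx_inv
        slope_se, intercept_se = np.sqrt(np.diag(cov))
        dH = -R_GAS * slope / 1000.0           # kJ/mol
        dS = R_GAS * intercept                 # J/(mol K)
        dG_direct = np.array([gibbs_from_Ka(k, t)
                              for k, t in zip(self.Ka, T)])
        if self.Ka_se is not None:
            dG_direct_se = R_GAS * T * (self.Ka_se / self.Ka) / 1000.0
        else:
            dG_direct_se = np.full_like(T, np.nan)
        dG_reg = dH - T * dS / 1000.0
        yhat = slope * x + intercept
        ss_res = float(np.sum(w * (y - yhat) ** 2))
        ss_tot = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return ThermoResults(
            temperatures=T, delta_H=float(dH),
            delta_H_se=float(R_GAS * slope_se / 1000.0),
            delta_S=float(dS), delta_S_se=float(R_GAS * intercept_se),
            delta_G_direct=dG_direct, delta_G_direct_se=dG_direct_se,
            delta_G_regression=dG_reg, T_delta_S=T * dS / 1000.0,
            r_squared=float(r2))


def vant_hoff_fit(Ka_by_T: dict, weighted: bool = False) -> ThermoResults:
    """Functional wrapper around :class:`VantHoff`."""
    return VantHoff(Ka_by_T, weighted=weighted).fit()
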