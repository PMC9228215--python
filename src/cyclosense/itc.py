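"""Isothermal titration calorimetry: one-site forward model and fit.

A VP-ITC-style experiment injects aliquots of anion titrant into a cell of
fixed working volume V0 containing the receptor.  With a perfusion
(displaced-volume) cell, each injection of volume v_i expels v_i of the
premixed cell content, so component moles evolve as

    n_L(i) = n_L(i-1) (1 - v_i/V0)
    n_A(i) = n_A(i-1) (1 - v_i/V0) + c_syr v_i

and the heat evolved by injection i for 1:1 complexation is

    Q_i = V0 dH ([LA]_i - [LA]_(i-1) (1 - v_i/V0)) + q_blank

where [LA] comes from the equilibrium speciation at the post-injection
composition and q_blank is the per-injection dilution heat.  The inverse
problem (K, dH, optionally q_blank) is a plain nonlinear least-squares fit
of this forward model; the entropy follows from dG = -RT ln K = dH - T dS.

Units: joules, dm^3 and mol dm^-3 internally; reports use kJ mol^-1 and
J mol^-1 K^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .equilibria import AnalyticalComposition, EquilibriumModel, solve_speciation

__all__ = [
    "R_GAS",
    "Thermogram",
    "ThermoRecord",
    "ITCModel",
    "ITCResults",
    "simulate_thermogram",
    "fit_thermogram",
    "subtract_blank",
    "derive_entropy",
    "gibbs_from_logK",
    "logK_from_gibbs",
]

R_GAS = 8.31446261815324  # J mol^-1 K^-1
LN10 = math.log(10.0)


def gibbs_from_logK(log_K: float, T: float = 298.15) -> float:
    """Standard reaction Gibbs energy (J mol^-1) from log K (molar scale)."""
    if T <= 0:
        raise ValueError("T must be positive")
    return -R_GAS * T * LN10 * log_K


def logK_from_gibbs(dG: float, T: float = 298.15) -> float:
    return -dG / (R_GAS * T * LN10)


def derive_entropy(log_K: float, dH: float, T: float = 298.15) -> float:
    """Reaction entropy (J mol^-1 K^-1) from log K and dH (J mol^-1).

    dS = (dH - dG)/T with dG = -RT ln10 log K.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    return (dH + R_GAS * T * LN10 * log_K) / T


@dataclass
class ThermoRecord:
    """Complexation thermodynamics at temperature T.

    dG, dH in J mol^-1; dS in J mol^-1 K^-1.  The record enforces the
    identities dG = -RT ln10 log K and dG = dH - T dS at construction.
    """

    log_K: float
    dH: float
    T: float = 298.15
    log_K_se: float = 0.0
    dH_se: float = 0.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("T must be positive")

    @property
    def dG(self) -> float:
        return gibbs_from_logK(self.log_K, self.T)

    @property
    def dS(self) -> float:
        return derive_entropy(self.log_K, self.dH, self.T)

    @property
    def dS_se(self) -> float:
        # propagate independent log_K and dH uncertainties through dS
        return math.hypot(self.dH_se / self.T,
                          R_GAS * LN10 * self.log_K_se)

    @classmethod
    def from_enthalpy_entropy(cls, dH: float, dS: float,
                              T: float = 298.15) -> "ThermoRecord":
        """Build a record from a printed (dH, dS) pair; K follows from dG."""
        dG = dH - T * dS
        return cls(log_K=logK_from_gibbs(dG, T), dH=dH, T=T)

    def as_dict(self) -> dict:
        return {
            "log_K": self.log_K, "dG_kJ_mol": self.dG / 1e3,
            "dH_kJ_mol": self.dH / 1e3, "dS_J_mol_K": self.dS, "T_K": self.T,
        }


@dataclass
class Thermogram:
    """Per-injection heats and the experiment geometry."""

    injection_volumes: np.ndarray   # dm^3
    heats: np.ndarray               # J
    V0: float                       # cell volume, dm^3
    c_L: float                      # cell receptor concentration, mol dm^-3
    c_A: float                      # syringe anion concentration, mol dm^-3
    T: float = 298.15

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        self.heats = np.asarray(self.heats, dtype=float)
        if len(self.injection_volumes) != len(self.heats):
            raise ValueError("injection_volumes and heats must have equal length")
        if self.V0 <= 0 or self.T <= 0:
            raise ValueError("V0 and T must be positive")
        if np.any(self.injection_volumes <= 0):
            raise ValueError("injection volumes must be positive")

    @property
    def n_injections(self) -> int:
        return len(self.heats)


def _cell_totals(volumes: np.ndarray, V0: float, c_L: float,
                 c_A: float) -> tuple[np.ndarray, np.ndarray]:
    """Total cell concentrations of L and A after each injection."""
    n_L = c_L * V0
    n_A = 0.0
    tot_L = np.empty(len(volumes))
    tot_A = np.empty(len(volumes))
    for i, v in enumerate(volumes):
        keep = 1.0 - v / V0
        n_L *= keep
        n_A = n_A * keep + c_A * v
        tot_L[i] = n_L / V0
        tot_A[i] = n_A / V0
    return tot_L, tot_A


def _complex_profile(volumes: np.ndarray, V0: float, c_L: float, c_A: float,
                     model: EquilibriumModel) -> np.ndarray:
    """[LA] in the cell after each injection (1:1 species of the model)."""
    from .equilibria import closed_form_1to1

    tot_L, tot_A = _cell_totals(volumes, V0, c_L, c_A)
    idx = next(i for i, s in enumerate(model.species) if (s.l, s.a) == (1, 1))
    pure_1to1 = len(model.species) == 1
    out = np.empty(len(volumes))
    for i in range(len(volumes)):
        if pure_1to1:  # analytic quadratic branch, exact and cheap
            out[i] = closed_form_1to1(tot_L[i], tot_A[i],
                                      10.0 ** model.species[idx].log_beta)
        else:
            st = solve_speciation(AnalyticalComposition(tot_L[i], tot_A[i]), model)
            out[i] = st.species_concentrations[idx]
    return out


def expected_heats(volumes: np.ndarray, V0: float, c_L: float, c_A: float,
                   log_K: float, dH: float, blank_offset: float = 0.0) -> np.ndarray:
    """Noise-free per-injection heats (J) of the one-site displaced-volume model."""
    model = EquilibriumModel.one_to_one(log_K)
    ca = _complex_profile(np.asarray(volumes, float), V0, c_L, c_A, model)
    prev = np.concatenate([[c_L * 0.0], ca[:-1]])
    keep = 1.0 - np.asarray(volumes, float) / V0
    return V0 * dH * (ca - prev * keep) + blank_offset


def simulate_thermogram(record: ThermoRecord, injection_volumes, *,
                        V0: float = 1.4e-3, c_L: float = 1e-4, c_A: float = 1.2e-3,
                        blank_offset: float = 0.0, noise_sigma: float = 0.0,
                        seed: int | None = None) -> Thermogram:
    """Forward-simulate a thermogram from known thermodynamics.

    Defaults mirror a VP-ITC chloride run: 1.4 cm^3 cell, receptor at
    1e-4 mol dm^-3.  Gaussian noise of ``noise_sigma`` J is added per
    injection when requested.
    """
    volumes = np.asarray(injection_volumes, dtype=float)
    q = expected_heats(volumes, V0, c_L, c_A, record.log_K, record.dH, blank_offset)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        q = q + rng.normal(0.0, noise_sigma, size=q.shape)
    return Thermogram(volumes, q, V0, c_L, c_A, record.T)


def subtract_blank(thermogram: Thermogram, blank: Thermogram) -> Thermogram:
    """Correct measured heats for titrant dilution using a blank experiment."""
    if len(blank.heats) != len(thermogram.heats) or not np.allclose(
            blank.injection_volumes, thermogram.injection_volumes):
        raise ValueError("blank injection schedule does not match thermogram")
    return Thermogram(thermogram.injection_volumes,
                      thermogram.heats - blank.heats,
                      thermogram.V0, thermogram.c_L, thermogram.c_A, thermogram.T)


@dataclass
class ITCResults:
    """One-site ITC fit output: thermodynamics, uncertainties, diagnostics."""

    record: ThermoRecord
    blank_offset: float
    residuals: np.ndarray
    ssr: float
    c_parameter: float
    success: bool
    message: str = ""
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> str:
        r = self.record
        lines = [
            "One-site ITC fit",
            "=" * 44,
            f"log K          {r.log_K:10.4f} +/- {r.log_K_se:.4f}",
            f"dG / kJ mol-1  {r.dG/1e3:10.2f}",
            f"dH / kJ mol-1  {r.dH/1e3:10.2f} +/- {r.dH_se/1e3:.2f}",
            f"dS / J mol-1K-1{r.dS:10.1f} +/- {r.dS_se:.1f}",
            f"T / K          {r.T:10.2f}",
            f"blank / J      {self.blank_offset:10.3e}",
            f"c parameter    {self.c_parameter:10.1f}",
            f"ssr / J^2      {self.ssr:10.3e}   converged: {self.success}",
        ]
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


class ITCModel:
    """Nonlinear least-squares fit of a one-site thermogram.

    Parameters are log K and dH (J mol^-1), plus an optional constant
    per-injection blank offset (fitted by default; pass
    ``fit_blank=False`` after explicit blank subtraction).
    """

    def __init__(self, thermogram: Thermogram, *, fit_blank: bool = True,
                 log_K0: float = 4.0, dH0: float | None = None):
        if thermogram.n_injections < 5:
            raise ValueError("need at least 5 injections for a one-site fit")
        self.tg = thermogram
        self.fit_blank = fit_blank
        self.log_K0 = log_K0
        self.dH0 = dH0

    def _predict(self, theta: np.ndarray) -> np.ndarray:
        log_K, dH = theta[0], theta[1]
        blank = theta[2] if self.fit_blank else 0.0
        return expected_heats(self.tg.injection_volumes, self.tg.V0,
                              self.tg.c_L, self.tg.c_A, log_K, dH, blank)

    def fit(self, max_nfev: int = 400) -> ITCResults:
        tg = self.tg
        dH0 = self.dH0
        if dH0 is None:
            # scale guess from the largest heat and the first-injection moles
            n1 = tg.c_A * tg.injection_volumes[0]
            peak = tg.heats[np.argmax(np.abs(tg.heats))]
            dH0 = peak / n1 if n1 > 0 else -1e4
        theta0 = [self.log_K0, dH0] + ([0.0] if self.fit_blank else [])

        def resid(theta):
            return self._predict(np.asarray(theta)) - tg.heats

        sol = least_squares(resid, theta0, method="lm", xtol=1e-14, ftol=1e-14,
                            max_nfev=max_nfev)
        ssr = float(np.sum(sol.fun ** 2))
        dof = max(len(tg.heats) - len(theta0), 1)
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * (ssr / dof)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            se = np.full(len(theta0), np.inf)

        log_K, dH = float(sol.x[0]), float(sol.x[1])
        blank = float(sol.x[2]) if self.fit_blank else 0.0
        c_par = 10.0 ** log_K * tg.c_L
        warnings = []
        if not (1.0 <= c_par <= 1000.0):
            warnings.append(
                f"Wiseman c parameter {c_par:.3g} outside the well-fittable "
                "range [1, 1000]; K is poorly determined")
        # non-binding flag: fitted enthalpy indistinguishable from zero
        if not np.isfinite(se[1]) or abs(dH) <= 2.0 * se[1]:
            warnings.append("fitted dH indistinguishable from 0: no detectable binding")
        record = ThermoRecord(log_K=log_K, dH=dH, T=tg.T,
                              log_K_se=float(se[0]), dH_se=float(se[1]))
        return ITCResults(record=record, blank_offset=blank, residuals=sol.fun,
                          ssr=ssr, c_parameter=c_par, success=bool(sol.success),
                          message=str(sol.message), warnings=warnings)


def fit_thermogram(thermogram: Thermogram, model: EquilibriumModel | None = None,
                   **options) -> ITCResults:
    """Functional wrapper around :class:`ITCModel`.

    ``model`` may carry a starting log K for the 1:1 species; only one-site
    fits are supported.
    """
    if model is not None:
        for s in model.species:
            if (s.l, s.a) == (1, 1):
                options.setdefault("log_K0", s.log_beta)
    max_nfev = options.pop("max_nfev", 400)
    return ITCModel(thermogram, **options).fit(max_nfev=max_nfev)
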