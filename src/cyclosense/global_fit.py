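"""Global multivariate fitting of spectroscopic and NMR titration data.

Stability constants are extracted from full-spectrum titrations by a
bilinear (variable-projection) model: the response matrix Y
(channels x titration points) is written as

    Y^T = C(log beta) . S + E

where C holds the equilibrium concentrations of the responsive species at
each titration point (from the speciation solver) and S holds the unknown
per-species molar responses (emission spectra, molar absorptivities, or
limiting chemical shifts).  For any trial of the nonlinear parameters
log beta, S is solved exactly by linear least squares; the outer search over
the free log beta values is a Levenberg-Marquardt / trust-region least-squares
minimisation with optional multistart.

For NMR titrations in the fast-exchange regime the observed shift of proton
j is the population-weighted average over all ligand-containing species,

    delta_obs,j = sum_s l_s [s] delta_s,j / c_L,

which is the same bilinear structure with C replaced by the ligand mole
fractions; both observables therefore share one fitting engine.

Model/Results layout: build a :class:`SpectralTitrationModel` or
:class:`ShiftTitrationModel` from the data, call ``fit()``, inspect the
returned :class:`TitrationResults` (estimates, standard errors, molar
responses, residuals, ``summary()``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .equilibria import (
    EquilibriumModel,
    TitrationSchedule,
    schedule_to_compositions,
    speciation_table,
)

__all__ = [
    "ResponseSeries",
    "TitrationResults",
    "SpectralTitrationModel",
    "ShiftTitrationModel",
    "IllConditionedError",
    "fit_spectral",
    "fit_nmr_shifts",
    "blank_correct",
    "estimate_uncertainties",
]


class IllConditionedError(ValueError):
    """The titration design carries no information on the fitted constants."""


@dataclass
class ResponseSeries:
    """A titration response matrix with its axes.

    channel_axis : wavelengths (nm), proton labels, or injection indices
    point_axis   : cumulative titrant volumes (dm^3)
    values       : (n_channels, n_points) response matrix
    kind         : 'fluorescence' | 'absorbance' | 'cd' | 'shift'
    anion_totals : optional per-point total anion concentration (mol dm^-3),
                   used for blank interpolation
    """

    channel_axis: np.ndarray
    point_axis: np.ndarray
    values: np.ndarray
    kind: str = "fluorescence"
    anion_totals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.point_axis = np.asarray(self.point_axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.channel_axis), len(self.point_axis)):
            raise ValueError(
                f"values shape {self.values.shape} does not match axes "
                f"({len(self.channel_axis)} channels, {len(self.point_axis)} points)")

    @property
    def n_channels(self) -> int:
        return len(self.channel_axis)

    @property
    def n_points(self) -> int:
        return len(self.point_axis)

    def window(self, lo: float, hi: float) -> "ResponseSeries":
        """Restrict to channels in [lo, hi] (numeric channel axes only)."""
        ax = np.asarray(self.channel_axis, dtype=float)
        m = (ax >= lo) & (ax <= hi)
        return ResponseSeries(ax[m], self.point_axis, self.values[m], self.kind,
                              self.anion_totals)


def blank_correct(series: ResponseSeries, blank: ResponseSeries) -> ResponseSeries:
    """Subtract the anion-concentration-dependent blank from a titration.

    Used e.g. for iodide titrations where the salt solution itself emits.
    The blank must share the channel axis; its contribution is linearly
    interpolated to each sample point's total anion concentration (falling
    back to the volume axis when concentrations are not recorded).
    """
    if len(series.channel_axis) != len(blank.channel_axis) or not np.allclose(
            np.asarray(series.channel_axis, float),
            np.asarray(blank.channel_axis, float)):
        raise ValueError("blank channel axis does not match series")
    if series.anion_totals is not None and blank.anion_totals is not None:
        x_s, x_b = series.anion_totals, blank.anion_totals
    else:
        x_s, x_b = series.point_axis, blank.point_axis
    corrected = series.values.copy()
    for i, x in enumerate(x_s):
        corrected[:, i] -= np.array(
            [np.interp(x, x_b, blank.values[ch]) for ch in range(blank.n_channels)])
    return ResponseSeries(series.channel_axis, series.point_axis, corrected,
                          series.kind, series.anion_totals)


@dataclass
class TitrationResults:
    """Estimates and diagnostics from a global titration fit."""

    model: EquilibriumModel                 # with fitted log betas substituted
    free_names: list[str]
    log_beta_estimates: np.ndarray          # free parameters only
    log_beta_se: np.ndarray
    molar_responses: np.ndarray             # (n_responsive_species, n_channels)
    responsive_labels: list[str]
    residuals: np.ndarray                   # (n_points, n_channels)
    ssr: float
    success: bool
    n_obs: int
    n_free: int
    message: str = ""
    multistart_costs: list[float] = field(default_factory=list)

    @property
    def rmse(self) -> float:
        return math.sqrt(self.ssr / self.residuals.size)

    def log_K(self, label: str = "LA") -> float:
        for s in self.model.species:
            if s.label == label:
                return s.log_beta
        raise KeyError(label)

    def summary(self) -> str:
        lines = [
            "Global titration fit (variable projection)",
            "=" * 46,
            f"observations: {self.n_obs}   free constants: {self.n_free}",
            f"sum of squared residuals: {self.ssr:.6g}   rmse: {self.rmse:.6g}",
            f"converged: {self.success}",
            "-" * 46,
            f"{'species':<10}{'log beta':>12}{'std err':>12}",
        ]
        j = 0
        for s in self.model.species:
            if s.fixed:
                lines.append(f"{s.label:<10}{s.log_beta:>12.4f}{'(fixed)':>12}")
            else:
                lines.append(
                    f"{s.label:<10}{s.log_beta:>12.4f}{self.log_beta_se[j]:>12.4f}")
                j += 1
        return "\n".join(lines)


class _VarProBase:
    """Shared variable-projection engine for spectral and shift fits."""

    #: multistart offsets applied to every free log beta, in log units
    default_starts = (0.0, 1.0, -1.0)

    def __init__(self, series: ResponseSeries, schedule: TitrationSchedule,
                 model: EquilibriumModel, *, nonnegative_responses: bool = False,
                 offset_channel: bool = False):
        if series.n_points != schedule.n_points:
            raise ValueError("series and schedule disagree on the number of points")
        self.series = series
        self.schedule = schedule
        self.model0 = model
        self.nonnegative = nonnegative_responses
        self.offset_channel = offset_channel
        self.compositions = schedule_to_compositions(schedule)
        self._free_idx = [i for i, s in enumerate(model.species) if not s.fixed]
        if series.n_points < len(self._free_idx) + 2:
            raise ValueError("need at least 2 more titration points than free constants")
        # degenerate design: no variation in the data at all
        if series.n_points > 1 and float(np.max(np.std(series.values, axis=1))) == 0.0:
            raise IllConditionedError("response has zero variance across titration points")

    # --- to be provided by subclasses -------------------------------------
    def design_matrix(self, model: EquilibriumModel) -> np.ndarray:
        """(n_points, n_responsive) concentration/mole-fraction matrix C."""
        raise NotImplementedError

    def responsive_labels(self, model: EquilibriumModel) -> list[str]:
        raise NotImplementedError

    # ----------------------------------------------------------------------
    def _model_for(self, theta: np.ndarray) -> EquilibriumModel:
        lbs = self.model0.log_betas.copy()
        lbs[self._free_idx] = theta
        return self.model0.with_log_betas(lbs)

    def project(self, C: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Exact linear solve for the molar responses; returns (S, residual)."""
        if self.offset_channel:
            C = np.hstack([C, np.ones((C.shape[0], 1))])
        if self.nonnegative:
            from scipy.optimize import nnls
            S = np.column_stack([nnls(C, Y[:, j])[0] for j in range(Y.shape[1])])
        else:
            S, *_ = np.linalg.lstsq(C, Y, rcond=None)
        return S, Y - C @ S

    def _residuals(self, theta: np.ndarray, Y: np.ndarray) -> np.ndarray:
        C = self.design_matrix(self._model_for(theta))
        _, R = self.project(C, Y)
        return R.ravel()

    def fit(self, *, multistart: int | None = None,
            max_nfev: int = 200) -> TitrationResults:
        """Run the outer nonlinear search; returns a :class:`TitrationResults`.

        multistart: number of start vectors (1 = no multistart); defaults to
        the class multistart ladder (truth, +1, -1 log-unit offsets).
        """
        Y = self.series.values.T  # (points, channels)
        theta0 = self.model0.log_betas[self._free_idx]
        offsets = self.default_starts if multistart is None else \
            self.default_starts[:max(1, multistart)]

        if not self._free_idx:
            C = self.design_matrix(self.model0)
            S, R = self.project(C, Y)
            return self._package(self.model0, np.empty(0), None, S, R, True, "no free parameters", [])

        best = None
        costs = []
        for off in offsets:
            sol = least_squares(self._residuals, theta0 + off, args=(Y,),
                                method="lm" if Y.size > len(theta0) else "trf",
                                max_nfev=max_nfev, xtol=1e-12, ftol=1e-12)
            costs.append(float(sol.cost))
            if best is None or sol.cost < best.cost:
                best = sol
        model = self._model_for(best.x)
        C = self.design_matrix(model)
        if np.linalg.cond(C) > 1e12:
            raise IllConditionedError(
                "speciation design matrix is rank deficient at the optimum")
        S, R = self.project(C, Y)
        return self._package(model, best.x, best.jac, S, R, best.success,
                             best.message, costs)

    def _package(self, model, theta, jac, S, R, success, message, costs):
        n_obs = R.size
        n_free = len(theta)
        n_linear = S.size
        dof = max(n_obs - n_free - n_linear, 1)
        ssr = float(np.sum(R * R))
        if n_free and jac is not None:
            JTJ = jac.T @ jac
            try:
                cov = np.linalg.inv(JTJ) * (ssr / dof)
                se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            except np.linalg.LinAlgError:
                se = np.full(n_free, np.inf)
        else:
            se = np.zeros(n_free)
        labels = self.responsive_labels(model)
        if self.offset_channel:
            labels = labels + ["offset"]
        return TitrationResults(
            model=model,
            free_names=[model.species[i].label for i in self._free_idx],
            log_beta_estimates=np.asarray(theta, dtype=float),
            log_beta_se=se,
            molar_responses=S,
            responsive_labels=labels,
            residuals=R,
            ssr=ssr,
            success=bool(success),
            n_obs=n_obs,
            n_free=n_free,
            message=str(message),
            multistart_costs=costs,
        )


class SpectralTitrationModel(_VarProBase):
    """Full-spectrum fluorimetric/UV titration fit.

    Responsive species: free receptor L and every receptor-containing
    complex; the free anion is assumed silent at the monitored wavelengths
    (set ``include_free_anion=True`` when it is not).
    """

    def __init__(self, series, schedule, model, *, include_free_anion: bool = False,
                 **kw):
        if series.kind not in ("fluorescence", "absorbance", "cd"):
            raise ValueError(f"unsupported series kind {series.kind!r} for spectral fit")
        self.include_free_anion = include_free_anion
        super().__init__(series, schedule, model, **kw)

    def design_matrix(self, model: EquilibriumModel) -> np.ndarray:
        tab = speciation_table(self.compositions, model)  # L, A, species...
        cols = [tab[:, 0]]
        if self.include_free_anion:
            cols.append(tab[:, 1])
        cols += [tab[:, 2 + i] for i, s in enumerate(model.species) if s.l > 0]
        return np.column_stack(cols)

    def responsive_labels(self, model: EquilibriumModel) -> list[str]:
        labels = ["L"]
        if self.include_free_anion:
            labels.append("A")
        labels += [s.label for s in model.species if s.l > 0]
        return labels


class ShiftTitrationModel(_VarProBase):
    """Fast-exchange NMR shift titration fit.

    The design matrix holds receptor mole fractions l.[s]/c_L, so the fitted
    linear parameters are per-species limiting shifts (ppm) of each proton.
    """

    def __init__(self, series, schedule, model, **kw):
        if series.kind != "shift":
            raise ValueError("ShiftTitrationModel requires kind='shift'")
        kw.setdefault("nonnegative_responses", False)
        super().__init__(series, schedule, model, **kw)

    def design_matrix(self, model: EquilibriumModel) -> np.ndarray:
        tab = speciation_table(self.compositions, model)
        totals = np.array([c.total_L for c in self.compositions])
        if np.any(totals <= 0):
            raise ValueError("shift fit requires nonzero receptor at every point")
        cols = [tab[:, 0] / totals]
        cols += [s.l * tab[:, 2 + i] / totals
                 for i, s in enumerate(model.species) if s.l > 0]
        return np.column_stack(cols)

    def responsive_labels(self, model: EquilibriumModel) -> list[str]:
        return ["L"] + [s.label for s in model.species if s.l > 0]


def fit_spectral(series: ResponseSeries, schedule: TitrationSchedule,
                 model: EquilibriumModel, **options) -> TitrationResults:
    """Functional wrapper: global fit of a fluorimetric/UV titration."""
    fit_kw = {k: options.pop(k) for k in ("multistart", "max_nfev") if k in options}
    return SpectralTitrationModel(series, schedule, model, **options).fit(**fit_kw)


def fit_nmr_shifts(series: ResponseSeries, schedule: TitrationSchedule,
                   model: EquilibriumModel, **options) -> TitrationResults:
    """Functional wrapper: fast-exchange NMR shift titration fit."""
    fit_kw = {k: options.pop(k) for k in ("multistart", "max_nfev") if k in options}
    return ShiftTitrationModel(series, schedule, model, **options).fit(**fit_kw)


def estimate_uncertainties(fit: TitrationResults,
                           replicates: list[TitrationResults] | None = None) -> dict:
    """Uncertainty report for a converged fit.

    Asymptotic standard errors come from the Jacobian at the optimum (already
    on the results object); when replicate fits are supplied (titrations are
    routinely run in triplicate) the between-replicate standard deviation of
    each log beta is reported alongside.
    """
    out = {
        "asymptotic_se": dict(zip(fit.free_names, fit.log_beta_se)),
        "singular": bool(np.any(~np.isfinite(fit.log_beta_se))),
    }
    if replicates:
        allfits = [fit] + list(replicates)
        per_name = {}
        for name in fit.free_names:
            vals = []
            for f in allfits:
                idx = f.free_names.index(name)
                vals.append(f.log_beta_estimates[idx])
            per_name[name] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        out["replicate_sd"] = per_name
        out["n_replicates"] = len(allfits)
    return out
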