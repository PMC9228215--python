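"""Equilibrium models and mass-balance speciation for receptor-anion systems.

The chemistry is a two-component system: a receptor L (here a cyclopeptide)
and an anion A, connected by a set of complexation equilibria

    l L + a A  <=>  L_l A_a,      beta_la = [L_l A_a] / ([L]^l [A]^a)

with cumulative formation constants beta expressed on the molar
(mol dm^-3) concentration scale.  The canonical model set comprises the
1:1 complex LA, the anion dimer A2 (dihydrogen phosphate self-association
in acetonitrile) and the dimer complex LA2.

Given analytical (total) concentrations of L and A, :func:`solve_speciation`
finds the free concentrations satisfying both mass balances

    c_L = [L] + sum_s l_s beta_s [L]^l_s [A]^a_s
    c_A = [A] + sum_s a_s beta_s [L]^l_s [A]^a_s

by damped Newton iteration in log-free-concentration space (which keeps the
iterates strictly positive), with a nested-bisection fallback for pathological
starting points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Species",
    "EquilibriumModel",
    "AnalyticalComposition",
    "SpeciationState",
    "TitrationSchedule",
    "SpeciationError",
    "solve_speciation",
    "schedule_to_compositions",
    "closed_form_1to1",
    "closed_form_dimer",
]


class SpeciationError(RuntimeError):
    """Raised when the mass-balance solver fails to converge."""


@dataclass(frozen=True)
class Species:
    """A complex species L_l A_a with cumulative formation constant log beta."""

    l: int
    a: int
    log_beta: float
    fixed: bool = False

    def __post_init__(self) -> None:
        if self.l < 0 or self.a < 0 or self.l + self.a < 1:
            raise ValueError(f"invalid stoichiometry ({self.l},{self.a})")
        if not math.isfinite(self.log_beta):
            raise ValueError("log_beta must be finite")

    @property
    def label(self) -> str:
        parts = []
        if self.l:
            parts.append("L" if self.l == 1 else f"L{self.l}")
        if self.a:
            parts.append("A" if self.a == 1 else f"A{self.a}")
        return "".join(parts)


@dataclass
class EquilibriumModel:
    """Set of complexation equilibria over components L (receptor) and A (anion).

    The free components L = (1,0) and A = (0,1) are implicit with
    log beta = 0 and are not listed in ``species``.
    """

    species: list[Species] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for s in self.species:
            if (s.l, s.a) in {(1, 0), (0, 1)}:
                raise ValueError("free components are implicit; do not list them")
            if (s.l, s.a) in seen:
                raise ValueError(f"duplicate species ({s.l},{s.a})")
            seen.add((s.l, s.a))
        # canonical lexicographic (l, a) ordering
        self.species = sorted(self.species, key=lambda s: (s.l, s.a))

    @classmethod
    def one_to_one(cls, log_K: float) -> "EquilibriumModel":
        return cls([Species(1, 1, log_K)])

    @classmethod
    def with_dimer(cls, log_K11: float, log_beta02: float,
                   log_beta12: float | None = None) -> "EquilibriumModel":
        """1:1 complex plus anion dimer, optionally the dimer complex LA2."""
        sp = [Species(1, 1, log_K11), Species(0, 2, log_beta02, fixed=True)]
        if log_beta12 is not None:
            sp.append(Species(1, 2, log_beta12))
        return cls(sp)

    @property
    def stoichiometry(self) -> np.ndarray:
        """(n_species, 2) integer matrix of (l, a) coefficients."""
        return np.array([[s.l, s.a] for s in self.species], dtype=float)

    @property
    def log_betas(self) -> np.ndarray:
        return np.array([s.log_beta for s in self.species], dtype=float)

    def with_log_betas(self, log_betas: np.ndarray) -> "EquilibriumModel":
        return EquilibriumModel([
            Species(s.l, s.a, float(lb), s.fixed)
            for s, lb in zip(self.species, log_betas)
        ])

    def labels(self) -> list[str]:
        return [s.label for s in self.species]


@dataclass(frozen=True)
class AnalyticalComposition:
    """Total (analytical) concentrations of the two components, mol dm^-3."""

    total_L: float
    total_A: float

    def __post_init__(self) -> None:
        if self.total_L < 0 or self.total_A < 0:
            raise ValueError("analytical concentrations must be >= 0")


@dataclass(frozen=True)
class SpeciationState:
    """Free and complex concentrations at equilibrium plus solver diagnostics."""

    free_L: float
    free_A: float
    species_concentrations: np.ndarray  # aligned with model.species
    residual: float  # max relative mass-balance error
    iterations: int = 0

    def concentration(self, model: EquilibriumModel, label: str) -> float:
        if label == "L":
            return self.free_L
        if label == "A":
            return self.free_A
        for s, c in zip(model.species, self.species_concentrations):
            if s.label == label:
                return float(c)
        raise KeyError(label)


@dataclass
class TitrationSchedule:
    """Cuvette/NMR-tube titration schedule.

    In ``dilution`` mode each aliquot of titrant (anion stock, concentration
    ``c_A_titrant``) grows the total volume, diluting the receptor.  In
    ``constant-ligand`` mode the titrant also contains the receptor at the
    working concentration, so total_L stays fixed along the titration (the
    usual NMR-titration protocol).
    """

    V0: float                      # initial volume, dm^3
    c_L_initial: float             # mol dm^-3
    c_A_titrant: float             # mol dm^-3
    cumulative_added_volumes: list[float]  # dm^3, strictly increasing
    mode: str = "dilution"         # "dilution" | "constant-ligand"
    c_L_titrant: float | None = None

    def __post_init__(self) -> None:
        if self.V0 <= 0:
            raise ValueError("V0 must be positive")
        v = np.asarray(self.cumulative_added_volumes, dtype=float)
        if v.size and (np.any(np.diff(v) <= 0) or v[0] < 0):
            raise ValueError("cumulative volumes must be non-negative and strictly increasing")
        if self.mode not in ("dilution", "constant-ligand"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "constant-ligand":
            if self.c_L_titrant is None:
                self.c_L_titrant = self.c_L_initial
            elif not math.isclose(self.c_L_titrant, self.c_L_initial, rel_tol=1e-12):
                raise ValueError("constant-ligand mode requires c_L_titrant == c_L_initial")

    @property
    def n_points(self) -> int:
        return len(self.cumulative_added_volumes)


def schedule_to_compositions(schedule: TitrationSchedule) -> list[AnalyticalComposition]:
    """Total concentrations at each titration point from dilution arithmetic."""
    out = []
    for v in schedule.cumulative_added_volumes:
        V = schedule.V0 + v
        total_A = schedule.c_A_titrant * v / V
        if schedule.mode == "constant-ligand":
            total_L = schedule.c_L_initial
        else:
            total_L = schedule.c_L_initial * schedule.V0 / V
        out.append(AnalyticalComposition(total_L, total_A))
    return out


def closed_form_1to1(total_L: float, total_A: float, K: float) -> float:
    """Analytic [LA] for a pure 1:1 model, via the physical quadratic root.

    K (x)  satisfies  K (c_L - x)(c_A - x) = x; the root on [0, min(c_L,c_A)]
    is returned using the numerically stable form of the quadratic formula.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    if total_L <= 0 or total_A <= 0:
        return 0.0
    b = total_L + total_A + 1.0 / K
    disc = b * b - 4.0 * total_L * total_A
    # stable smaller root: 2c_L c_A / (b + sqrt(disc))
    return 2.0 * total_L * total_A / (b + math.sqrt(disc))


def closed_form_dimer(total_A: float, beta2: float) -> tuple[float, float]:
    """Free [A] and [A2] for a pure dimerization model 2A <=> A2.

    Solves 2 beta2 [A]^2 + [A] - c_A = 0 on the positive branch.
    """
    if total_A <= 0:
        return 0.0, 0.0
    if beta2 <= 0:
        return total_A, 0.0
    a = 2.0 * beta2
    free_A = 2.0 * total_A / (1.0 + math.sqrt(1.0 + 4.0 * a * total_A))
    return free_A, beta2 * free_A * free_A


def _concentrations(log_free: np.ndarray, nu: np.ndarray,
                    log_betas: np.ndarray) -> np.ndarray:
    """Species concentrations from ln-free concentrations (natural log)."""
    ln10 = math.log(10.0)
    return np.exp(log_betas * ln10 + nu @ log_free)


def solve_speciation(composition: AnalyticalComposition, model: EquilibriumModel,
                     tol: float = 1e-12, max_iter: int = 200) -> SpeciationState:
    """Solve the two-component mass balance for free and complex concentrations.

    Newton iteration on x = ln([L], [A]) with step damping; falls back to
    nested bisection if Newton stalls.  Zero totals are handled by reducing
    to the remaining one-component problem.
    """
    cL, cA = composition.total_L, composition.total_A
    nu = model.stoichiometry
    lb = model.log_betas
    n_sp = len(model.species)

    if cL == 0.0 and cA == 0.0:
        return SpeciationState(0.0, 0.0, np.zeros(n_sp), 0.0)

    if cL == 0.0 or cA == 0.0:
        return _solve_one_component(cL, cA, model, tol, max_iter)

    totals = np.array([cL, cA])
    x = np.log(totals)  # start from free == total
    it = 0
    for it in range(1, max_iter + 1):
        free = np.exp(x)
        cs = _concentrations(x, nu, lb)
        calc = free + nu.T @ cs
        resid = calc / totals - 1.0
        if np.max(np.abs(resid)) < tol:
            break
        # Jacobian of calc_i wrt x_j: delta_ij*free_i + sum_s nu_si nu_sj c_s
        J = np.diag(free) + (nu.T * cs) @ nu
        J = J / totals[:, None]
        try:
            step = np.linalg.solve(J, -resid)
        except np.linalg.LinAlgError:
            step = None
        if step is None or not np.all(np.isfinite(step)):
            return _solve_bisection(composition, model, tol)
        # damp: cap log-step to avoid overshooting into overflow
        m = np.max(np.abs(step))
        if m > 3.0:
            step *= 3.0 / m
        x = x + step
    else:
        return _solve_bisection(composition, model, tol)

    free = np.exp(x)
    cs = _concentrations(x, nu, lb)
    calc = free + nu.T @ cs
    residual = float(np.max(np.abs(calc / totals - 1.0)))
    return SpeciationState(float(free[0]), float(free[1]), cs, residual, it)


def _solve_one_component(cL: float, cA: float, model: EquilibriumModel,
                         tol: float, max_iter: int) -> SpeciationState:
    """Speciation when one component is absent (its free conc is exactly 0)."""
    nu = model.stoichiometry
    lb = model.log_betas
    which = 0 if cA == 0.0 else 1          # index of the present component
    total = cL if which == 0 else cA
    # species involving the absent component have zero concentration
    active = nu[:, 1 - which] == 0
    if not np.any(active):
        free = [0.0, 0.0]
        free[which] = total
        return SpeciationState(free[0], free[1], np.zeros(len(model.species)), 0.0)

    coef = nu[active, which]
    beta = 10.0 ** lb[active]

    def calc_total(f: float) -> float:
        return f + float(np.sum(coef * beta * f ** coef))

    lo, hi = 0.0, total
    f = total
    for it in range(200):
        f = 0.5 * (lo + hi)
        if calc_total(f) > total:
            hi = f
        else:
            lo = f
        if hi - lo < tol * total:
            break
    f = 0.5 * (lo + hi)
    cs = np.zeros(len(model.species))
    cs[active] = beta * f ** coef
    free = [0.0, 0.0]
    free[which] = f
    residual = abs(calc_total(f) / total - 1.0)
    return SpeciationState(free[0], free[1], cs, residual, it + 1)


def _solve_bisection(composition: AnalyticalComposition, model: EquilibriumModel,
                     tol: float) -> SpeciationState:
    """Nested bisection fallback: outer loop on free A, inner on free L.

    Both mass-balance residuals are monotone in the respective free
    concentration, so plain bisection is globally convergent (if slow).
    """
    cL, cA = composition.total_L, composition.total_A
    nu = model.stoichiometry
    lb = model.log_betas
    beta = 10.0 ** lb

    def calc(free_L: float, free_A: float) -> tuple[float, float]:
        cs = beta * free_L ** nu[:, 0] * free_A ** nu[:, 1]
        return free_L + float(nu[:, 0] @ cs), free_A + float(nu[:, 1] @ cs)

    def solve_L(free_A: float) -> float:
        lo, hi = 0.0, cL
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if calc(mid, free_A)[0] > cL:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    lo, hi = 0.0, cA
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if calc(solve_L(mid), mid)[1] > cA:
            hi = mid
        else:
            lo = mid
    free_A = 0.5 * (lo + hi)
    free_L = solve_L(free_A)
    cs = beta * free_L ** nu[:, 0] * free_A ** nu[:, 1]
    gotL, gotA = calc(free_L, free_A)
    residual = max(abs(gotL / cL - 1.0) if cL else 0.0,
                   abs(gotA / cA - 1.0) if cA else 0.0)
    if residual > 1e-6:
        raise SpeciationError(
            f"speciation failed to converge (residual {residual:.2e}, "
            f"totals L={cL:.3e} A={cA:.3e})")
    return SpeciationState(free_L, free_A, cs, residual, 400)


def speciation_table(compositions: list[AnalyticalComposition],
                     model: EquilibriumModel) -> np.ndarray:
    """Concentration matrix C: rows = titration points, columns = all species.

    Column order: free L, free A, then ``model.species`` in canonical order.
    """
    out = np.empty((len(compositions), 2 + len(model.species)))
    for i, comp in enumerate(compositions):
        st = solve_speciation(comp, model)
        out[i, 0] = st.free_L
        out[i, 1] = st.free_A
        out[i, 2:] = st.species_concentrations
    return out
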