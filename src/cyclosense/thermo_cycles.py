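"""Solvent-transfer thermodynamic cycles for receptor-anion complexation.

Complexation of an anion A- by the receptor L in two solvents (here
acetonitrile and methanol) is connected by the transfer of every reaction
participant between the solvents:

    dtG(LA-) = dtG(A-) + dtG(L) + drG(target solvent) - drG(source solvent)

where dtG is a standard transfer Gibbs energy (source -> target) and drG a
standard complexation Gibbs energy.  The ligand leg is obtained from
saturation solubilities (same solid phase, ideal dilute solution):
dtG(L) = -RT ln(s_target / s_source).  Anion legs come from literature
single-ion transfer scales and are configuration inputs; values quoted for
the reverse direction are negated on input with the provenance recorded.

All energies are kJ mol^-1 here (reporting convention); the sign convention
is source -> target throughout, positive meaning the transfer is unfavorable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .itc import R_GAS, gibbs_from_logK

__all__ = [
    "SolubilityPair",
    "TransferCycle",
    "transfer_from_solubility",
    "gibbs_from_logK_kJ",
    "complex_transfer",
    "solve_missing_leg",
]


@dataclass(frozen=True)
class SolubilityPair:
    """Saturation solubilities of the same solid in two solvents (mol dm^-3)."""

    s_source: float
    s_target: float
    T: float = 298.15

    def __post_init__(self) -> None:
        if self.s_source <= 0 or self.s_target <= 0:
            raise ValueError("solubilities must be positive")
        if self.T <= 0:
            raise ValueError("T must be positive")


def transfer_from_solubility(pair: SolubilityPair) -> float:
    """Transfer Gibbs energy (kJ mol^-1) of a neutral solute from solubilities.

    dtG = -RT ln(s_target / s_source); equal solubility in both solvents
    means a negligible transfer energy.
    """
    return -R_GAS * pair.T * math.log(pair.s_target / pair.s_source) / 1e3


def gibbs_from_logK_kJ(log_K: float, T: float = 298.15) -> float:
    """drG (kJ mol^-1) from a molar-scale stability constant."""
    return gibbs_from_logK(log_K, T) / 1e3


@dataclass
class TransferCycle:
    """A closed transfer cycle; all legs kJ mol^-1, direction source->target.

    Closure (exact by construction when built through
    :func:`complex_transfer`):
        dtG_complex - dtG_anion - dtG_ligand - drG_target + drG_source = 0
    """

    dtG_anion: float
    dtG_ligand: float
    drG_source: float
    drG_target: float
    dtG_complex: float
    provenance: dict[str, str] = field(default_factory=dict)

    def closure(self) -> float:
        return (self.dtG_complex - self.dtG_anion - self.dtG_ligand
                - self.drG_target + self.drG_source)

    def __post_init__(self) -> None:
        if abs(self.closure()) > 1e-9:
            raise ValueError(f"cycle does not close (residual {self.closure():.3e})")

    def reversed(self) -> "TransferCycle":
        """Same cycle with the transfer direction flipped (all legs negated,
        the two reaction legs swapped)."""
        return TransferCycle(
            dtG_anion=-self.dtG_anion,
            dtG_ligand=-self.dtG_ligand,
            drG_source=self.drG_target,
            drG_target=self.drG_source,
            dtG_complex=-self.dtG_complex,
            provenance={**self.provenance, "direction": "reversed"},
        )

    def as_dict(self) -> dict:
        return {
            "dtG_anion_kJ_mol": self.dtG_anion,
            "dtG_ligand_kJ_mol": self.dtG_ligand,
            "drG_source_kJ_mol": self.drG_source,
            "drG_target_kJ_mol": self.drG_target,
            "dtG_complex_kJ_mol": self.dtG_complex,
            "closure_kJ_mol": self.closure(),
            "provenance": dict(self.provenance),
        }


def complex_transfer(*, dtG_anion: float, dtG_ligand: float,
                     drG_source: float, drG_target: float,
                     provenance: dict[str, str] | None = None) -> TransferCycle:
    """Close the cycle: compute the complex transfer leg from the other four."""
    for name, v in [("dtG_anion", dtG_anion), ("dtG_ligand", dtG_ligand),
                    ("drG_source", drG_source), ("drG_target", drG_target)]:
        if v is None or not math.isfinite(v):
            raise ValueError(f"missing or non-finite cycle leg {name}")
    dtG_complex = dtG_anion + dtG_ligand + drG_target - drG_source
    return TransferCycle(dtG_anion, dtG_ligand, drG_source, drG_target,
                         dtG_complex, provenance or {})


def solve_missing_leg(legs: dict[str, float | None]) -> TransferCycle:
    """Solve the linear closure identity for whichever single leg is None.

    ``legs`` keys: dtG_anion, dtG_ligand, drG_source, drG_target, dtG_complex.
    """
    keys = ["dtG_anion", "dtG_ligand", "drG_source", "drG_target", "dtG_complex"]
    missing = [k for k in keys if legs.get(k) is None]
    if len(missing) != 1:
        raise ValueError(f"exactly one leg must be unknown, got {missing}")
    v = {k: legs[k] for k in keys if legs.get(k) is not None}
    m = missing[0]
    if m == "dtG_complex":
        val = v["dtG_anion"] + v["dtG_ligand"] + v["drG_target"] - v["drG_source"]
    elif m == "dtG_anion":
        val = v["dtG_complex"] - v["dtG_ligand"] - v["drG_target"] + v["drG_source"]
    elif m == "dtG_ligand":
        val = v["dtG_complex"] - v["dtG_anion"] - v["drG_target"] + v["drG_source"]
    elif m == "drG_target":
        val = v["dtG_complex"] - v["dtG_anion"] - v["dtG_ligand"] + v["drG_source"]
    else:  # drG_source
        val = v["dtG_anion"] + v["dtG_ligand"] + v["drG_target"] - v["dtG_complex"]
    full = dict(v)
    full[m] = val
    return TransferCycle(full["dtG_anion"], full["dtG_ligand"], full["drG_source"],
                         full["drG_target"], full["dtG_complex"],
                         {"solved_leg": m})
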