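"""Synthetic titration, calorimetry and coordinate-ensemble generators.

Every input the analysis chain consumes can be generated here with known
ground truth, so parameter recovery is testable end to end without
instrument data.  The generators emulate the data shapes of the real
experiments:

* full-spectrum fluorimetric/UV titrations — bilinear Gaussian-band spectra
  over a cuvette dilution schedule (initial volume ~2 mL, receptor around
  1e-4 mol dm^-3), with either signal-increase or quenching on binding and
  homoscedastic Gaussian noise;
* fast-exchange NMR shift titrations on a constant-ligand schedule;
* VP-ITC style thermograms (1.4 mL cell) plus a matching dilution blank;
* jittered pseudo-cyclopeptide coordinate ensembles with an anion bound in
  the endo (over the sidechain face) or exo position, with per-frame state
  labels.

All randomness flows through an explicit integer seed; a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .equilibria import (
    EquilibriumModel,
    TitrationSchedule,
    schedule_to_compositions,
    speciation_table,
)
from .global_fit import ResponseSeries
from .itc import ThermoRecord, Thermogram, simulate_thermogram
from .ensemble_analysis import Ensemble

__all__ = [
    "SpectralConfig",
    "ShiftConfig",
    "ITCConfig",
    "EnsembleConfig",
    "spectral_recovery_config",
    "shift_recovery_config",
    "gen_spectral_titration",
    "gen_nmr_titration",
    "gen_thermogram",
    "gen_ensemble",
]


def _gaussian_band(wl: np.ndarray, center: float, width: float,
                   amplitude: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((wl - center) / width) ** 2)


def equivalents_schedule(*, V0: float, c_L: float, titrant_ratio: float,
                         equivalents: np.ndarray,
                         mode: str = "dilution") -> TitrationSchedule:
    """Schedule whose points hit the requested anion:receptor mole ratios.

    ``titrant_ratio`` is c_A(titrant)/c_L; the mole ratio at cumulative
    volume v is c_A v / (c_L V0) regardless of dilution, so
    v_i = eq_i V0 / titrant_ratio.
    """
    eq = np.asarray(equivalents, dtype=float)
    volumes = (eq * V0 / titrant_ratio).tolist()
    return TitrationSchedule(V0=V0, c_L_initial=c_L,
                             c_A_titrant=titrant_ratio * c_L,
                             cumulative_added_volumes=volumes, mode=mode)


@dataclass
class SpectralConfig:
    """Ground truth and acquisition parameters for a spectral titration."""

    log_K: float = 4.0
    c_L: float = 1e-4               # mol dm^-3 in the cuvette
    V0: float = 2e-3                # dm^3
    titrant_ratio: float = 50.0     # c_A(titrant)/c_L
    n_points: int = 15
    eq_min: float = 0.3
    eq_max: float = 3.0
    wavelengths: np.ndarray = field(
        default_factory=lambda: np.arange(250.0, 321.0, 2.0))  # nm, 2 nm pitch
    peak_L: float = 285.0           # nm, free-receptor emission maximum
    peak_LA: float = 282.0
    band_width: float = 14.0        # nm
    amp_L: float = 1.0e6            # per-molar peak response (a.u. M^-1)
    quench_factor: float = 0.35     # complex amplitude relative to free L
    quenching: bool = True          # False = signal increase on binding
    snr: float = 100.0              # peak signal over noise sigma; inf = none
    extra_species: list = field(default_factory=list)  # (l, a, log_beta, rel_amp)


def gen_spectral_titration(config: SpectralConfig | None = None,
                           seed: int | None = None
                           ) -> tuple[ResponseSeries, TitrationSchedule, dict]:
    """Bilinear spectral titration Y = C(beta_true) S + noise, with truth."""
    cfg = config or SpectralConfig()
    eq = np.geomspace(cfg.eq_min, cfg.eq_max, cfg.n_points)
    schedule = equivalents_schedule(V0=cfg.V0, c_L=cfg.c_L,
                                    titrant_ratio=cfg.titrant_ratio,
                                    equivalents=eq)
    species = [(1, 1, cfg.log_K,
                cfg.quench_factor if cfg.quenching else 1.0 / cfg.quench_factor)]
    species += list(cfg.extra_species)
    from .equilibria import Species
    model = EquilibriumModel([Species(l, a, lb) for l, a, lb, _ in species])

    wl = np.asarray(cfg.wavelengths, dtype=float)
    # molar response rows: free L then receptor-containing species
    S_rows = [_gaussian_band(wl, cfg.peak_L, cfg.band_width, cfg.amp_L)]
    labels = ["L"]
    for s, (_, _, _, rel) in zip(model.species, species):
        if s.l > 0:
            S_rows.append(_gaussian_band(wl, cfg.peak_LA, cfg.band_width,
                                         rel * cfg.amp_L))
            labels.append(s.label)
    S = np.vstack(S_rows)

    comps = schedule_to_compositions(schedule)
    tab = speciation_table(comps, model)
    cols = [tab[:, 0]] + [tab[:, 2 + i] for i, s in enumerate(model.species)
                          if s.l > 0]
    C = np.column_stack(cols)
    Y = (C @ S).T                                   # channels x points
    sigma = 0.0
    if np.isfinite(cfg.snr) and cfg.snr > 0:
        sigma = float(np.max(np.abs(Y))) / cfg.snr
        rng = np.random.default_rng(seed)
        Y = Y + rng.normal(0.0, sigma, size=Y.shape)

    anion_totals = np.array([c.total_A for c in comps])
    series = ResponseSeries(wl, schedule.cumulative_added_volumes, Y,
                            kind="fluorescence", anion_totals=anion_totals)
    truth = {"model": model, "log_K": cfg.log_K, "molar_responses": S,
             "responsive_labels": labels, "noise_sigma": sigma,
             "equivalents": eq}
    return series, schedule, truth


def spectral_recovery_config(log_K: float, snr: float = 100.0,
                             n_points: int = 15) -> SpectralConfig:
    """Titration conditions matched to an expected constant.

    Standard design rule: the anion concentration window must bracket 1/K,
    so weak binders are titrated to large excess.  The ceiling (1000
    equivalents at 1e-4 mol dm^-3 receptor) keeps the titrant a realistic
    <= 0.1 mol dm^-3 salt solution.
    """
    c_L = 1e-4
    K = 10.0 ** log_K
    eq_max = float(min(1000.0, max(3.0, 10.0 / (K * c_L))))
    ratio = max(50.0, eq_max)          # cap cumulative added volume at ~V0
    return SpectralConfig(log_K=log_K, c_L=c_L, titrant_ratio=ratio,
                          n_points=n_points, eq_min=max(0.3, eq_max / 100.0),
                          eq_max=eq_max, snr=snr)


def shift_recovery_config(log_K: float, snr: float = 100.0,
                          n_points: int = 15) -> "ShiftConfig":
    """NMR analogue of :func:`spectral_recovery_config` (c_L = 1e-3)."""
    c_L = 1e-3
    K = 10.0 ** log_K
    eq_max = float(min(200.0, max(10.0, 10.0 / (K * c_L))))
    ratio = max(50.0, eq_max)
    return ShiftConfig(log_K=log_K, c_L=c_L, titrant_ratio=ratio,
                       n_points=n_points, eq_min=max(0.3, eq_max / 100.0),
                       eq_max=eq_max, snr=snr, noise_sigma=0.0)


@dataclass
class ShiftConfig:
    """Ground truth for a fast-exchange NMR shift titration."""

    log_K: float = 2.0
    c_L: float = 1e-3               # mol dm^-3 (NMR-scale concentration)
    V0: float = 5e-4                # dm^3 in the tube
    titrant_ratio: float = 50.0
    n_points: int = 15
    eq_min: float = 0.3
    eq_max: float = 10.0
    proton_labels: tuple = ("NH", "CAH", "ArH")
    delta_free: tuple = (7.80, 4.50, 7.25)      # ppm, free receptor
    delta_complex: tuple = (8.30, 4.65, 7.20)   # ppm, limiting shifts in LA
    noise_sigma: float = 0.0        # ppm; overrides snr when > 0
    snr: float = 100.0              # max shift change over noise


def gen_nmr_titration(config: ShiftConfig | None = None, seed: int | None = None
                      ) -> tuple[ResponseSeries, TitrationSchedule, dict]:
    """Fast-exchange shift titration on a constant-ligand schedule."""
    cfg = config or ShiftConfig()
    eq = np.geomspace(cfg.eq_min, cfg.eq_max, cfg.n_points)
    schedule = equivalents_schedule(V0=cfg.V0, c_L=cfg.c_L,
                                    titrant_ratio=cfg.titrant_ratio,
                                    equivalents=eq, mode="constant-ligand")
    model = EquilibriumModel.one_to_one(cfg.log_K)
    comps = schedule_to_compositions(schedule)
    tab = speciation_table(comps, model)
    totals = np.array([c.total_L for c in comps])
    frac_bound = tab[:, 2] / totals
    d_free = np.asarray(cfg.delta_free, dtype=float)
    d_cplx = np.asarray(cfg.delta_complex, dtype=float)
    delta = np.outer(d_free, 1.0 - frac_bound) + np.outer(d_cplx, frac_bound)

    sigma = cfg.noise_sigma
    if sigma <= 0 and np.isfinite(cfg.snr) and cfg.snr > 0:
        sigma = float(np.max(np.abs(d_cplx - d_free))) / cfg.snr
    if sigma > 0:
        rng = np.random.default_rng(seed)
        delta = delta + rng.normal(0.0, sigma, size=delta.shape)

    anion_totals = np.array([c.total_A for c in comps])
    series = ResponseSeries(np.array(cfg.proton_labels, dtype=object),
                            schedule.cumulative_added_volumes, delta,
                            kind="shift", anion_totals=anion_totals)
    truth = {"model": model, "log_K": cfg.log_K, "delta_free": d_free,
             "delta_complex": d_cplx, "noise_sigma": sigma, "equivalents": eq}
    return series, schedule, truth


@dataclass
class ITCConfig:
    """Ground truth for a one-site calorimetric titration.

    Defaults describe the chloride-type run: 1.4 cm^3 cell, 25 x 10 uL
    injections, receptor 1e-4 mol dm^-3, syringe 1.2e-3 mol dm^-3 (about 2.1
    equivalents at the end).
    """

    dH: float = -15e3               # J mol^-1
    dS: float = 65.0                # J mol^-1 K^-1
    T: float = 298.15
    V0: float = 1.4e-3              # dm^3
    c_L: float = 1e-4
    c_A: float = 1.2e-3
    n_injections: int = 25
    injection_volume: float = 1e-5  # dm^3
    blank_offset: float = 2e-6      # J per injection (dilution heat)
    noise_frac: float = 0.01        # sigma as fraction of max |heat|


def gen_thermogram(config: ITCConfig | None = None, seed: int | None = None
                   ) -> tuple[Thermogram, Thermogram, dict]:
    """Noisy thermogram plus its matching blank-only run, with truth."""
    cfg = config or ITCConfig()
    record = ThermoRecord.from_enthalpy_entropy(cfg.dH, cfg.dS, cfg.T)
    volumes = np.full(cfg.n_injections, cfg.injection_volume)
    exact = simulate_thermogram(record, volumes, V0=cfg.V0, c_L=cfg.c_L,
                                c_A=cfg.c_A, blank_offset=cfg.blank_offset)
    sigma = cfg.noise_frac * float(np.max(np.abs(exact.heats)))
    rng = np.random.default_rng(seed)
    noisy = Thermogram(volumes, exact.heats + rng.normal(0, sigma, cfg.n_injections)
                       if sigma > 0 else exact.heats,
                       cfg.V0, cfg.c_L, cfg.c_A, cfg.T)
    blank_heats = np.full(cfg.n_injections, cfg.blank_offset)
    if sigma > 0:
        blank_heats = blank_heats + rng.normal(0, sigma, cfg.n_injections)
    blank = Thermogram(volumes, blank_heats, cfg.V0, 0.0, cfg.c_A, cfg.T)
    truth = {"record": record, "log_K": record.log_K, "dH": cfg.dH,
             "dS": cfg.dS, "blank_offset": cfg.blank_offset,
             "noise_sigma": sigma,
             "c_parameter": 10.0 ** record.log_K * cfg.c_L}
    return noisy, blank, truth


@dataclass
class EnsembleConfig:
    """Pseudo-cyclopentapeptide + anion ensemble parameters.

    The scaffold has 5 residues on a ring (N, H, CA, C, O and a 6-carbon
    phenyl ring each); the anion sits either endo (above the ring on the
    sidechain face, all five amide hydrogens within coordination range by
    construction) or exo (below the ring, uncoordinated).  Atomic jitter is
    Gaussian, uncorrelated per atom per frame.
    """

    n_frames: int = 200
    endo_fraction: float = 1.0
    jitter: float = 0.08            # angstrom
    anion: str = "Cl"               # 'Cl' | 'SCN'
    r_N: float = 3.0                # amide-N ring radius
    z_endo: float = 1.5             # anion height above ring plane
    z_exo: float = -4.0


def _scaffold(cfg: EnsembleConfig) -> tuple[np.ndarray, list, list]:
    """Ideal (unjittered) coordinates with names and residue ids."""
    coords, names, resids = [], [], []
    anion_pos = np.array([0.0, 0.0, cfg.z_endo])
    for k in range(5):
        th = 2.0 * np.pi * k / 5.0
        u = np.array([np.cos(th), np.sin(th), 0.0])
        perp = np.array([-np.sin(th), np.cos(th), 0.0])
        N = cfg.r_N * u
        h_dir = (anion_pos - N)
        h_dir /= np.linalg.norm(h_dir)
        H = N + 1.0 * h_dir                     # N-H bond 1.0 A toward endo site
        CA = 2.5 * u + np.array([0, 0, 0.3])
        C = 3.3 * u + 0.8 * perp + np.array([0, 0, -0.2])
        O = 3.9 * u + 1.2 * perp + np.array([0, 0, -0.9])
        res = [(N, "N"), (H, "H"), (CA, "CA"), (C, "C"), (O, "O")]
        ring_center = 6.5 * u + np.array([0, 0, 1.2])
        ring_names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
        for j, rn in enumerate(ring_names):
            ang = 2.0 * np.pi * j / 6.0
            pos = ring_center + 1.4 * (np.cos(ang) * u + np.sin(ang)
                                       * np.array([0, 0, 1.0]))
            res.append((pos, rn))
        for pos, nm in res:
            coords.append(pos)
            names.append(nm)
            resids.append(k + 1)
    return np.array(coords), names, resids


_ANION_ATOMS = {
    # name, element, z-offset from the anion anchor point (A), anchor = closest
    # atom to the amide crown
    "Cl": [("CL", "CL", 0.0)],
    "SCN": [("N1", "N", 0.0), ("C1", "C", 1.16), ("S1", "S", 2.84)],
}


def gen_ensemble(config: EnsembleConfig | None = None, seed: int | None = None
                 ) -> tuple[Ensemble, dict]:
    """Jittered two-state (endo/exo) coordinate ensemble with state labels."""
    cfg = config or EnsembleConfig()
    base, names, resids = _scaffold(cfg)
    anion_spec = _ANION_ATOMS[cfg.anion]
    rng = np.random.default_rng(seed)
    states = (rng.random(cfg.n_frames) < cfg.endo_fraction).astype(int)  # 1=endo

    frames = np.empty((cfg.n_frames, len(base) + len(anion_spec), 3))
    for f in range(cfg.n_frames):
        z0 = cfg.z_endo if states[f] == 1 else cfg.z_exo
        sign = 1.0 if states[f] == 1 else -1.0
        anion = np.array([[0.0, 0.0, z0 + sign * dz] for _, _, dz in anion_spec])
        frame = np.vstack([base, anion])
        if cfg.jitter > 0:
            frame = frame + rng.normal(0.0, cfg.jitter, size=frame.shape)
        frames[f] = frame

    all_names = list(names) + [nm for nm, _, _ in anion_spec]
    all_resids = list(resids) + [6] * len(anion_spec)
    elements = [nm if nm in ("CL",) else nm[0] for nm in all_names]
    ens = Ensemble(frames, np.array(all_names, dtype=object),
                   np.array(all_resids), np.array(elements, dtype=object))
    truth = {"states": states, "endo_fraction_empirical": float(np.mean(states)),
             "anion_resid": 6, "anion": cfg.anion, "config": cfg}
    return ens, truth
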