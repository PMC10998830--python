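"""Typed experimental datasets and seeded synthetic-data generators.

The generators emulate, with the statistical structure the analysis
assumes (true model plus Gaussian noise on the ordinate), every
experiment type the pipeline analyses: duplicate Michaelis–Menten
saturation series, tight-binding regulator titrations, stopped-flow
single-turnover traces with a 0.9 ms dead time recorded as absorbance
(epsilon_290 = 3600 1/(M*cm)), histidine dose–response curves,
differential-scanning-fluorimetry melts over 25–93 deg C, solvent
viscosity series and Eyring temperature–rate profiles.

Determinism contract: identical seed + specification produce
byte-identical datasets.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from . import mechanism, models

__all__ = [
    "NoiseSpec",
    "AssayDesign",
    "RateDataset",
    "TitrationDataset",
    "ProgressTrace",
    "DoseResponseDataset",
    "MeltCurve",
    "ViscosityDataset",
    "TemperatureProfile",
    "gen_saturation",
    "gen_titration",
    "gen_sto_trace",
    "gen_dose_response",
    "gen_melt",
    "gen_viscosity_series",
    "gen_temperature_profile",
    "gen_isotopologue_panel",
    "DEFAULT_SUBSTRATE_GRID_MM",
    "DEFAULT_MELT_GRID_C",
]

# Two-fold dilution ladder up to 1.6 mM, the holoenzyme assay range.
DEFAULT_SUBSTRATE_GRID_MM = (0.025, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6)
DEFAULT_MELT_GRID_C = tuple(np.arange(25.0, 94.0, 1.0))
DEFAULT_Z_GRID_UM = (0.0, 0.01, 0.02, 0.04, 0.08, 0.12, 0.2, 0.3, 0.4, 0.5)
DEFAULT_ETA_GRID = (1.0, 1.1, 1.2, 1.3, 1.4, 1.5)
DEFAULT_TEMP_GRID_K = tuple(np.arange(278.0, 319.0, 5.0))
DEFAULT_INHIBITOR_GRID_UM = (0.0, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0)


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    """Gaussian ordinate noise.

    kind="relative": homoscedastic with sd = sigma * max|true ordinate|
    (the "x% of max signal" convention); kind="absolute": sd = sigma in
    ordinate units; kind="proportional": per-point sd = sigma * |true|.
    """

    kind: str = "relative"
    sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("relative", "absolute", "proportional"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def apply(self, y_true: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        y_true = np.asarray(y_true, dtype=float)
        if self.sigma == 0:
            return y_true.copy()
        if self.kind == "relative":
            sd = self.sigma * float(np.max(np.abs(y_true)))
        elif self.kind == "absolute":
            sd = self.sigma
        else:
            sd = self.sigma * np.abs(y_true)
        return y_true + rng.normal(0.0, 1.0, size=y_true.shape) * sd


@dataclasses.dataclass(frozen=True)
class AssayDesign:
    """Abscissa grid, replication and instrument geometry.

    Defaults mirror the stopped-flow configuration: 0.5 cm path length,
    0.9 ms dead time, epsilon_290 = 3600 1/(M*cm); cuvette assays use a
    1 cm path.
    """

    grid: tuple[float, ...] = DEFAULT_SUBSTRATE_GRID_MM
    n_replicates: int = 2
    path_length_cm: float = 0.5
    epsilon_290: float = 3600.0
    dead_time_s: float = 9e-4

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if grid.size == 0 or np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be non-empty and strictly increasing")
        if np.any(grid < 0):
            raise ValueError("grid values must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


# ---------------------------------------------------------------------------
# dataset containers (CSV-facing field names)


@dataclasses.dataclass
class RateDataset:
    """Initial rates v/E_T vs varied substrate at fixed co-substrate."""

    substrate_mM: np.ndarray
    rate_per_s: np.ndarray
    replicate: np.ndarray
    varied_substrate: str = "PRPP"
    fixed_substrate: str = "ATP"
    fixed_conc_mM: float = 1.6
    enzyme_conc_uM: float = 0.039
    temperature_C: float = 5.0
    nucleotide: str = "ATP"
    isotopologue: str = "unlabelled"
    mass_increase_percent: float = 0.0


@dataclasses.dataclass
class TitrationDataset:
    """Rates at fixed HisG_S (G) and varying HisZ (Z)."""

    z_uM: np.ndarray
    rate_per_s: np.ndarray
    g_uM: float = 0.04
    temperature_C: float = 5.0
    glycerol_percent: float = 0.0


@dataclasses.dataclass
class ProgressTrace:
    """Time-resolved stopped-flow product signal.

    ``signal_unit`` is "AU" (absorbance) or "uM" (already converted).
    """

    time_s: np.ndarray
    signal: np.ndarray
    signal_unit: str = "AU"
    path_length_cm: float = 0.5
    epsilon_290: float = 3600.0
    dead_time_s: float = 9e-4
    enzyme_uM: float = 80.0
    substrate_uM: float = 80.0
    temperature_C: float = 5.0
    isotopologue: str = "unlabelled"


@dataclasses.dataclass
class DoseResponseDataset:
    inhibitor_uM: np.ndarray
    fractional_activity: np.ndarray
    temperature_C: float = 25.0
    isotopologue: str = "unlabelled"


@dataclasses.dataclass
class MeltCurve:
    temp_C: np.ndarray
    fluorescence: np.ndarray
    isotopologue: str = "unlabelled"


@dataclasses.dataclass
class ViscosityDataset:
    eta_rel: np.ndarray
    kcat_per_s: np.ndarray
    temperature_C: float = 5.0
    nucleotide: str = "ATP"


@dataclasses.dataclass
class TemperatureProfile:
    temp_K: np.ndarray
    kcat_per_s: np.ndarray
    enzyme: str = "HisG_S"


# ---------------------------------------------------------------------------
# generators


def _rng_for(noise: NoiseSpec | None, seed: int | None) -> tuple[NoiseSpec, np.random.Generator]:
    noise = noise if noise is not None else NoiseSpec()
    if seed is not None:
        noise = dataclasses.replace(noise, seed=int(seed))
    return noise, np.random.default_rng(noise.seed)


def gen_saturation(kcat: float, km: float, design: AssayDesign | None = None,
                   noise: NoiseSpec | None = None, seed: int | None = None,
                   **metadata) -> RateDataset:
    """Replicated Michaelis–Menten saturation data with Gaussian rate noise."""
    design = design or AssayDesign()
    noise, rng = _rng_for(noise, seed)
    grid = np.asarray(design.grid, dtype=float)
    s = np.tile(grid, design.n_replicates)
    rep = np.repeat(np.arange(1, design.n_replicates + 1), grid.size)
    v_true = models.mm_rate(s, kcat, km)
    v = noise.apply(v_true, rng)
    return RateDataset(substrate_mM=s, rate_per_s=v, replicate=rep, **metadata)


def gen_titration(vmax: float, kd_app: float, g_um: float = 0.04,
                  z_grid: Sequence[float] = DEFAULT_Z_GRID_UM,
                  n_replicates: int = 2,
                  noise: NoiseSpec | None = None, seed: int | None = None,
                  **metadata) -> TitrationDataset:
    """Quadratic tight-binding titration of HisG_S with HisZ."""
    noise = noise if noise is not None else NoiseSpec(sigma=0.03)
    noise, rng = _rng_for(noise, seed)
    z = np.tile(np.asarray(z_grid, dtype=float), n_replicates)
    v_true = models.titration_rate(z, vmax, kd_app, g_um)
    v = noise.apply(v_true, rng)
    return TitrationDataset(z_uM=z, rate_per_s=v, g_uM=g_um, **metadata)


def gen_sto_trace(es_um: float = 80.0, k2: float = 30.0, k3: float = 8.0,
                  scheme: mechanism.KineticScheme | None = None,
                  t_max_s: float = 1.0, n_points: int = 500,
                  design: AssayDesign | None = None,
                  noise: NoiseSpec | None = None, seed: int | None = None,
                  **metadata) -> ProgressTrace:
    """Single-turnover lag trace recorded as absorbance.

    The concentration signal is generated from the two-consecutive-step
    model (or from a :class:`mechanism.KineticScheme`, using its
    isomerisation and chemistry rates) and converted to absorbance via
    Beer–Lambert; samples before the instrument dead time are dropped,
    not extrapolated.
    """
    design = design or AssayDesign()
    noise = noise if noise is not None else NoiseSpec(kind="absolute", sigma=0.002)
    noise, rng = _rng_for(noise, seed)
    if scheme is not None:
        k2, k3 = scheme.k_iso, scheme.k_chem
    t = np.linspace(0.0, t_max_s, n_points)
    t = t[t >= design.dead_time_s]
    conc = models.two_step_product(t, es_um, k2, k3)
    au_true = conc * 1e-6 * design.epsilon_290 * design.path_length_cm
    au = noise.apply(au_true, rng)
    return ProgressTrace(
        time_s=t, signal=au, signal_unit="AU",
        path_length_cm=design.path_length_cm, epsilon_290=design.epsilon_290,
        dead_time_s=design.dead_time_s, enzyme_uM=es_um, substrate_uM=es_um,
        **metadata,
    )


def gen_dose_response(ic50: float, hill_n: float,
                      i_grid: Sequence[float] = DEFAULT_INHIBITOR_GRID_UM,
                      n_replicates: int = 2,
                      noise: NoiseSpec | None = None, seed: int | None = None,
                      **metadata) -> DoseResponseDataset:
    """Histidine dose–response curve (fractional activity vs inhibitor)."""
    noise = noise if noise is not None else NoiseSpec(kind="absolute", sigma=0.02)
    noise, rng = _rng_for(noise, seed)
    i = np.tile(np.asarray(i_grid, dtype=float), n_replicates)
    y = noise.apply(models.dose_response(i, ic50, hill_n), rng)
    return DoseResponseDataset(inhibitor_uM=i, fractional_activity=y, **metadata)


def gen_melt(ll: float, ul: float, tm: float, c: float,
             t_grid: Sequence[float] = DEFAULT_MELT_GRID_C,
             noise: NoiseSpec | None = None, seed: int | None = None,
             **metadata) -> MeltCurve:
    """DSF melt over the scanned range (25–93 deg C by default)."""
    noise, rng = _rng_for(noise, seed)
    t = np.asarray(t_grid, dtype=float)
    f = noise.apply(models.melt_fraction(t, ll, ul, tm, c), rng)
    return MeltCurve(temp_C=t, fluorescence=f, **metadata)


def gen_viscosity_series(scheme: mechanism.KineticScheme,
                         eta_grid: Sequence[float] = DEFAULT_ETA_GRID,
                         n_replicates: int = 2,
                         noise: NoiseSpec | None = None, seed: int | None = None,
                         **metadata) -> ViscosityDataset:
    """kcat vs relative viscosity from the mechanistic steady state."""
    noise, rng = _rng_for(noise, seed)
    eta = np.tile(np.asarray(eta_grid, dtype=float), n_replicates)
    kcat_true = np.array([
        mechanism.steady_state_kcat(mechanism.apply_viscosity(scheme, e)) for e in eta
    ])
    kcat = noise.apply(kcat_true, rng)
    return ViscosityDataset(eta_rel=eta, kcat_per_s=kcat, **metadata)


def gen_temperature_profile(scheme: mechanism.KineticScheme | None = None,
                            mmrt: models.MMRTParams | None = None,
                            t_grid_k: Sequence[float] = DEFAULT_TEMP_GRID_K,
                            n_replicates: int = 2,
                            noise: NoiseSpec | None = None, seed: int | None = None,
                            **metadata) -> TemperatureProfile:
    """Temperature–rate profile from per-step Eyring scaling or MMRT params.

    Noise is proportional (per-point sd = sigma*kcat) so the profile is
    homoscedastic after the ln(kcat/T) transform used in fitting.
    """
    if (scheme is None) == (mmrt is None):
        raise ValueError("provide exactly one of scheme or mmrt")
    noise = noise if noise is not None else NoiseSpec(kind="proportional", sigma=0.03)
    noise, rng = _rng_for(noise, seed)
    t = np.tile(np.asarray(t_grid_k, dtype=float), n_replicates)
    if scheme is not None:
        kcat_true = np.array([
            mechanism.steady_state_kcat(
                mechanism.apply_temperature(scheme, tk, strict=True)
            )
            for tk in t
        ])
    else:
        log_rate = models.mmrt_log_rate(t, mmrt.dh_t0, mmrt.ds_t0, mmrt.dcp, t0=mmrt.t0)
        kcat_true = t * np.exp(log_rate)
    kcat = noise.apply(kcat_true, rng)
    return TemperatureProfile(temp_K=t, kcat_per_s=kcat, **metadata)


# Isotopologue labels and holoenzyme mass increases used in the heavy-enzyme
# panels: natural abundance, 15N, 13C+15N, 2H+15N and 2H+13C+15N labelling.
DEFAULT_ISOTOPOLOGUES = ("unlabelled", "15N", "13C,15N", "2H,15N", "2H,13C,15N")
DEFAULT_MASS_INCREASE_PERCENT = (0.0, 0.5, 2.0, 2.6, 4.2)


def gen_isotopologue_panel(base_scheme: mechanism.KineticScheme,
                           phi_list: Sequence[float] = (1.0, 1.03, 1.30, 1.44, 1.54),
                           labels: Sequence[str] = DEFAULT_ISOTOPOLOGUES,
                           mass_percent: Sequence[float] = DEFAULT_MASS_INCREASE_PERCENT,
                           km_mm: float = 0.111,
                           design: AssayDesign | None = None,
                           noise: NoiseSpec | None = None,
                           seed: int | None = None) -> list[RateDataset]:
    """One saturation dataset per mass factor phi.

    Each panel member's true kcat comes from the mechanistic steady state
    with the mass-sensitive product isomerisation slowed by phi; Km is
    mass-independent.  Whether the downstream HE-KIE ladder tracks phi
    depends on which step limits the base scheme (the masking property).
    """
    if not (len(phi_list) == len(labels) == len(mass_percent)):
        raise ValueError("phi_list, labels and mass_percent must align")
    design = design or AssayDesign()
    noise = noise if noise is not None else NoiseSpec()
    base_seed = int(seed if seed is not None else noise.seed)
    panel = []
    for i, (phi, label, mass) in enumerate(zip(phi_list, labels, mass_percent)):
        heavy = mechanism.KineticScheme(
            k_iso=base_scheme.k_iso, k_chem=base_scheme.k_chem,
            k_prod_iso=base_scheme.k_prod_iso, k_off=base_scheme.k_off,
            mass_factor=phi, eta_rel=base_scheme.eta_rel,
            step_thermo=base_scheme.step_thermo,
        )
        kcat_true = mechanism.steady_state_kcat(heavy)
        panel.append(
            gen_saturation(
                kcat_true, km_mm, design=design, noise=noise,
                seed=base_seed + 7919 * i,
                isotopologue=label, mass_increase_percent=float(mass),
            )
        )
    return panel
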