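"""Per-experiment analysis stages and the HE-KIE panel report.

Each ``analyze_*`` function takes a typed dataset (see
:mod:`hekie.datasets` / :mod:`hekie.io`) and returns a small result
object wrapping the underlying :class:`hekie.fitting.FitResult` plus the
derived quantities an experimentalist reports: kcat and Km with fitting
errors and catalytic efficiencies; the heavy-enzyme kcat ratio
(HE-KIE) with propagated SE and a per-row Welch t-test at p < 0.01; the
solvent-viscosity slope with a diffusion-limited / viscosity-insensitive
classification; lag-vs-exponential model selection for single-turnover
traces; and Eyring-vs-MMRT selection for temperature profiles.

No multiple-testing correction is applied across isotopologue rows: the
significance flags are per-row t-tests, mirroring how such panels are
conventionally reported.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import datasets as dsets
from . import fitting, mechanism, models
from .fitting import FitResult, ModelComparison, TTestResult, ValueWithError

__all__ = [
    "SaturationAnalysis",
    "TitrationAnalysis",
    "SingleTurnoverAnalysis",
    "ViscosityAnalysis",
    "TemperatureAnalysis",
    "MeltAnalysis",
    "HekieResult",
    "HekieTable",
    "absorbance_to_conc",
    "conc_to_absorbance",
    "analyze_saturation",
    "analyze_titration",
    "analyze_single_turnover",
    "analyze_viscosity",
    "analyze_temperature_profile",
    "analyze_melt",
    "analyze_hekie",
    "hekie_from_estimates",
    "glycerol_eta_rel",
    "run_report",
]


# ---------------------------------------------------------------------------
# unit conversions


def absorbance_to_conc(trace: dsets.ProgressTrace) -> dsets.ProgressTrace:
    """Beer–Lambert conversion of a trace from AU to uM product."""
    if trace.signal_unit != "AU":
        raise ValueError(f"trace is already in {trace.signal_unit!r}")
    if trace.path_length_cm <= 0 or trace.epsilon_290 <= 0:
        raise ValueError("path length and extinction coefficient must be positive")
    conc = trace.signal / (trace.epsilon_290 * trace.path_length_cm) * 1e6
    return dataclasses.replace(trace, signal=conc, signal_unit="uM")


def conc_to_absorbance(trace: dsets.ProgressTrace) -> dsets.ProgressTrace:
    """Inverse of :func:`absorbance_to_conc`."""
    if trace.signal_unit != "uM":
        raise ValueError(f"trace is in {trace.signal_unit!r}, expected 'uM'")
    au = trace.signal * 1e-6 * trace.epsilon_290 * trace.path_length_cm
    return dataclasses.replace(trace, signal=au, signal_unit="AU")


# ---------------------------------------------------------------------------
# analysis results


@dataclasses.dataclass
class SaturationAnalysis:
    fit: FitResult
    kcat: ValueWithError
    km: ValueWithError
    efficiency: ValueWithError  # kcat/Km, 1/(M*s)


@dataclasses.dataclass
class TitrationAnalysis:
    fit: FitResult
    vmax: ValueWithError
    kd_app: ValueWithError
    holoenzyme_uM: np.ndarray  # per titration point, via the binding quadratic


@dataclasses.dataclass
class SingleTurnoverAnalysis:
    comparison: ModelComparison
    two_step: FitResult
    single_exp: FitResult

    @property
    def selected(self) -> FitResult:
        return self.two_step if self.comparison.selected_id == "two_step" else self.single_exp


@dataclasses.dataclass
class ViscosityAnalysis:
    fit: FitResult
    slope: ValueWithError
    ci95: tuple[float, float]
    classification: str  # diffusion-limited | viscosity-insensitive | partial/ambiguous


@dataclasses.dataclass
class TemperatureAnalysis:
    comparison: ModelComparison
    eyring: FitResult
    mmrt: FitResult
    t0: float
    note: str = ""

    @property
    def selected(self) -> FitResult:
        return self.mmrt if self.comparison.selected_id == "mmrt" else self.eyring


@dataclasses.dataclass
class MeltAnalysis:
    fit: FitResult
    tm: ValueWithError


@dataclasses.dataclass
class HekieResult:
    """One row of the heavy-enzyme panel table."""

    isotopologue: str
    mass_increase_percent: float
    kcat: ValueWithError
    ratio: ValueWithError  # reference kcat / this kcat
    t: float
    df: float
    p: float
    significant_at_0p01: bool


@dataclasses.dataclass
class HekieTable:
    reference: str
    rows: list[HekieResult]
    monotonic_in_mass: bool  # ratios strictly increasing with mass increase

    def __iter__(self):
        return iter(self.rows)


# ---------------------------------------------------------------------------
# per-experiment stages


def analyze_saturation(dataset: dsets.RateDataset) -> SaturationAnalysis:
    """Pooled Michaelis–Menten fit; kcat, Km and kcat/Km with errors.

    All replicate points enter one fit (lines through all shown points,
    not through replicate means).  Refuses sparse designs: at least five
    distinct substrate concentrations are needed for a trustworthy
    two-parameter saturation fit.
    """
    n_distinct = np.unique(dataset.substrate_mM).size
    if n_distinct < 5:
        raise ValueError(
            f"only {n_distinct} distinct substrate concentrations; need >= 5 "
            "(extend the dilution series rather than fitting a sparse design)"
        )
    result = fitting.fit("michaelis", dataset.substrate_mM, dataset.rate_per_s)
    kcat = result.value("kcat")
    km = result.value("km")
    eff = models.catalytic_efficiency(kcat.value, km.value)
    eff_se = eff * math.sqrt(
        (kcat.se / kcat.value) ** 2 + (km.se / km.value) ** 2
    )
    return SaturationAnalysis(
        fit=result, kcat=kcat, km=km,
        efficiency=ValueWithError(eff, eff_se, result.dof),
    )


def analyze_titration(dataset: dsets.TitrationDataset) -> TitrationAnalysis:
    """Tight-binding quadratic fit of the HisZ titration at fixed G."""
    result = fitting.fit(
        "titration", dataset.z_uM, dataset.rate_per_s, g_conc=dataset.g_uM
    )
    kd = result.estimates["kd_app"]
    holo = models.holoenzyme_conc(dataset.g_uM, dataset.z_uM, max(kd, 0.0))
    return TitrationAnalysis(
        fit=result, vmax=result.value("vmax"), kd_app=result.value("kd_app"),
        holoenzyme_uM=np.asarray(holo),
    )


def analyze_single_turnover(trace: dsets.ProgressTrace,
                            fix_amplitude: float | None = None) -> SingleTurnoverAnalysis:
    """Fit lag (two consecutive steps) and single-exponential models,
    selecting by AICc.

    A selected lag model indicates a slow step preceding the observable
    chemical step; a selected exponential indicates no resolvable lag.
    Traces in absorbance are converted to concentration first.
    """
    if trace.signal_unit == "AU":
        trace = absorbance_to_conc(trace)
    t, y = trace.time_s, trace.signal
    two_step = fitting.fit("two_step", t, y, fix_amplitude=fix_amplitude)
    single = fitting.fit("single_exp", t, y)
    comparison = fitting.compare_models([two_step, single], nested=False)
    return SingleTurnoverAnalysis(comparison=comparison, two_step=two_step,
                                  single_exp=single)


def analyze_viscosity(dataset: dsets.ViscosityDataset,
                      ci_level: float = 0.95) -> ViscosityAnalysis:
    """Slope of kcat ratios vs relative viscosity, with classification.

    Ratios are normalised to the mean rate at eta_rel = 1 (which must be
    present).  Classification by the ``ci_level`` confidence interval of
    the slope: "diffusion-limited" if it includes 1 and excludes 0 (the
    theoretical maximum slope of 1 means rate-determining diffusion),
    "viscosity-insensitive" if it includes 0 and excludes 1, else
    "partial/ambiguous".
    """
    eta = np.asarray(dataset.eta_rel, dtype=float)
    kcat = np.asarray(dataset.kcat_per_s, dtype=float)
    at_ref = np.isclose(eta, 1.0)
    if not at_ref.any():
        raise ValueError("dataset must include the eta_rel = 1 reference point")
    if np.unique(eta).size < 3:
        raise ValueError(
            "need at least three distinct viscosities for a slope with dof >= 2"
        )
    kcat0 = float(np.mean(kcat[at_ref]))
    ratios = kcat0 / kcat
    result = fitting.fit("viscosity", eta, ratios)
    slope = result.value("m")
    from scipy import stats as _stats

    half = _stats.t.ppf(0.5 + ci_level / 2.0, result.dof) * slope.se
    lo, hi = slope.value - half, slope.value + half
    contains_zero = lo <= 0.0 <= hi
    contains_one = lo <= 1.0 <= hi
    if contains_one and not contains_zero:
        label = "diffusion-limited"
    elif contains_zero and not contains_one:
        label = "viscosity-insensitive"
    else:
        label = "partial/ambiguous"
    return ViscosityAnalysis(fit=result, slope=slope, ci95=(lo, hi),
                             classification=label)


def analyze_temperature_profile(profile: dsets.TemperatureProfile,
                                t0: float = 298.0,
                                alpha: float = 0.05) -> TemperatureAnalysis:
    """Eyring vs MMRT fit of ln(kcat/T), decided by the nested F-test.

    Requires at least six temperatures.  Reports activation enthalpy,
    entropy (at T0) and heat capacity with fitting errors when the
    curved model is selected; a negative fitted heat capacity is
    annotated with its physical reading (fewer vibrational modes able to
    absorb energy in the transition state than in the ground state).
    """
    t = np.asarray(profile.temp_K, dtype=float)
    k = np.asarray(profile.kcat_per_s, dtype=float)
    if np.unique(t).size < 6:
        raise ValueError("need at least six distinct temperatures")
    if np.any(k <= 0):
        raise ValueError("kcat values must be positive for the log transform")
    y = np.log(k / t)
    eyring = fitting.fit("eyring", t, y)
    mmrt = fitting.fit("mmrt", t, y, t0=t0)
    comparison = fitting.compare_models([eyring, mmrt], nested=True, alpha=alpha)
    note = ""
    if comparison.selected_id == "mmrt" and mmrt.estimates["dcp"] < 0:
        note = (
            "negative activation heat capacity: fewer vibrational modes are "
            "available to absorb energy in the transition state than in the "
            "ground state"
        )
    return TemperatureAnalysis(comparison=comparison, eyring=eyring, mmrt=mmrt,
                               t0=t0, note=note)


def analyze_melt(curve: dsets.MeltCurve,
                 control: dsets.MeltCurve | None = None) -> MeltAnalysis:
    """Sigmoid fit of a DSF melt; optional no-protein control subtraction."""
    y = np.asarray(curve.fluorescence, dtype=float)
    if control is not None:
        if not np.array_equal(control.temp_C, curve.temp_C):
            raise ValueError("control curve must share the temperature grid")
        y = y - np.asarray(control.fluorescence, dtype=float)
    result = fitting.fit("melt", curve.temp_C, y)
    return MeltAnalysis(fit=result, tm=result.value("tm"))


# ---------------------------------------------------------------------------
# HE-KIE panel


def hekie_from_estimates(labels: Sequence[str], mass_percent: Sequence[float],
                         kcats: Sequence[float], ses: Sequence[float],
                         dofs: Sequence[float] | float = 16,
                         reference: str = "unlabelled",
                         alpha: float = 0.01) -> HekieTable:
    """HE-KIE table directly from fitted kcat estimates.

    Each row's ratio is reference kcat over that row's kcat with the SE
    propagated in quadrature; significance by a per-row Welch t-test
    against the reference at ``alpha``.  The reference row carries ratio
    exactly 1 (its SE is the self-ratio sqrt(2)*CV).  ``dofs`` may be a
    scalar applied to every fit.
    """
    labels = list(labels)
    if reference not in labels:
        raise ValueError(f"reference label {reference!r} not in panel {labels}")
    if np.isscalar(dofs):
        dofs = [float(dofs)] * len(labels)
    entries = [
        (lab, float(m), ValueWithError(float(k), float(s), float(d)))
        for lab, m, k, s, d in zip(labels, mass_percent, kcats, ses, dofs)
    ]
    ref = next(e[2] for e in entries if e[0] == reference)
    entries.sort(key=lambda e: e[1])
    rows = []
    for lab, mass, est in entries:
        ratio = fitting.propagate_ratio(ref, est)
        if lab == reference:
            ratio = ValueWithError(1.0, ratio.se)
            test = TTestResult(t=0.0, df=2 * ref.dof, p=1.0)
        else:
            test = fitting.t_test_kcat(ref, est)
        rows.append(HekieResult(
            isotopologue=lab, mass_increase_percent=mass, kcat=est, ratio=ratio,
            t=test.t, df=test.df, p=test.p,
            significant_at_0p01=(lab != reference and test.p < alpha),
        ))
    ratios = [r.ratio.value for r in rows]
    monotonic = all(b > a for a, b in zip(ratios, ratios[1:]))
    return HekieTable(reference=reference, rows=rows, monotonic_in_mass=monotonic)


def analyze_hekie(panel: Sequence[dsets.RateDataset],
                  reference: str = "unlabelled",
                  alpha: float = 0.01) -> HekieTable:
    """Full HE-KIE pipeline: per-isotopologue saturation fits, ratios,
    per-row significance, mass ordering diagnostic.

    All panel members must share temperature and nucleotide.
    """
    if not panel:
        raise ValueError("empty isotopologue panel")
    temps = {d.temperature_C for d in panel}
    nucs = {d.nucleotide for d in panel}
    if len(temps) > 1 or len(nucs) > 1:
        raise ValueError(
            f"panel mixes conditions: temperatures {sorted(temps)}, nucleotides {sorted(nucs)}"
        )
    analyses = {d.isotopologue: (d, analyze_saturation(d)) for d in panel}
    if reference not in analyses:
        raise ValueError(f"reference isotopologue {reference!r} missing from panel")
    return hekie_from_estimates(
        labels=[d.isotopologue for d in panel],
        mass_percent=[d.mass_increase_percent for d in panel],
        kcats=[analyses[d.isotopologue][1].kcat.value for d in panel],
        ses=[analyses[d.isotopologue][1].kcat.se for d in panel],
        dofs=[analyses[d.isotopologue][1].fit.dof for d in panel],
        reference=reference, alpha=alpha,
    )


# ---------------------------------------------------------------------------
# glycerol -> relative viscosity convenience lookup

#: SYNTHETIC stand-in lookup: approximate relative viscosities of aqueous
#: glycerol, % (v/v), shaped after standard glycerol/water tables.  The exact
#: conversion used for any given experiment is instrument- and buffer-specific,
#: which is why eta_rel is a required input column in viscosity datasets and
#: this table is only a documented, overridable convenience.
GLYCEROL_ETA_REL: dict[float, dict[float, float]] = {
    5.0: {0.0: 1.00, 4.0: 1.12, 8.0: 1.27, 12.0: 1.45},
    25.0: {0.0: 1.00, 4.0: 1.10, 8.0: 1.23, 12.0: 1.38},
    35.0: {0.0: 1.00, 4.0: 1.09, 8.0: 1.21, 12.0: 1.34},
}


def glycerol_eta_rel(percent_vv: float, temperature_C: float,
                     table: dict[float, dict[float, float]] | None = None) -> float:
    """Interpolate eta_rel from the bundled (synthetic stand-in) table.

    Linear in glycerol fraction within the tabulated range; the nearest
    tabulated temperature is used.  Pass ``table`` to substitute a
    calibrated conversion.
    """
    table = table if table is not None else GLYCEROL_ETA_REL
    temp = min(table, key=lambda t: abs(t - temperature_C))
    pts = sorted(table[temp].items())
    xs = [p for p, _ in pts]
    ys = [e for _, e in pts]
    if not xs[0] <= percent_vv <= xs[-1]:
        raise ValueError(
            f"glycerol {percent_vv}% outside tabulated range {xs[0]}–{xs[-1]}%"
        )
    return float(np.interp(percent_vv, xs, ys))


# ---------------------------------------------------------------------------
# report runner


_DEFAULT_CONFIG = {
    "seed": 1,
    "reference": "unlabelled",
    "km_mm": 0.111,
    "scheme": {"k_iso": 30.0, "k_chem": 8.0, "k_prod_iso": 6.0, "k_off": 72.0},
    "phi": [1.0, 1.03, 1.30, 1.44, 1.54],
    "labels": list(dsets.DEFAULT_ISOTOPOLOGUES),
    "mass_percent": list(dsets.DEFAULT_MASS_INCREASE_PERCENT),
    "noise": {"kind": "relative", "sigma": 0.02},
}


def run_report(config: dict | str | Path | None = None,
               out_dir: str | Path = "hekie_report") -> dict:
    """Run the configured HE-KIE panel end-to-end and write report files.

    ``config`` may be a dict, a YAML file path, or None for the bundled
    demonstration configuration.  Writes ``report.csv`` (Table-style
    panel), ``report.md`` and ``run_log.json`` (config echo, seeds,
    version) into ``out_dir``; reruns with the same config are
    bit-identical.  Returns the config actually used.
    """
    if config is None:
        cfg = json.loads(json.dumps(_DEFAULT_CONFIG))
    elif isinstance(config, (str, Path)):
        cfg = {**_DEFAULT_CONFIG, **yaml.safe_load(Path(config).read_text())}
    else:
        cfg = {**_DEFAULT_CONFIG, **config}

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = mechanism.KineticScheme(**cfg["scheme"])
    noise = dsets.NoiseSpec(**cfg["noise"])
    panel = dsets.gen_isotopologue_panel(
        scheme, phi_list=cfg["phi"], labels=cfg["labels"],
        mass_percent=cfg["mass_percent"], km_mm=cfg["km_mm"],
        noise=noise, seed=int(cfg["seed"]),
    )
    table = analyze_hekie(panel, reference=cfg["reference"])

    header = ("isotopologue,mass_increase_percent,kcat_per_s,kcat_se,"
              "hekie,hekie_se,t,df,p,significant_p_lt_0.01\n")
    csv_lines = [header]
    md_lines = [
        "| isotopologue | mass +% | kcat (1/s) | HE-kcat | p | sig. |",
        "|---|---|---|---|---|---|",
    ]
    for row in table:
        csv_lines.append(
            f"{row.isotopologue},{row.mass_increase_percent:g},"
            f"{row.kcat.value:.6g},{row.kcat.se:.3g},"
            f"{row.ratio.value:.6g},{row.ratio.se:.3g},"
            f"{row.t:.4g},{row.df:.4g},{row.p:.4g},{row.significant_at_0p01}\n"
        )
        md_lines.append(
            f"| {row.isotopologue} | {row.mass_increase_percent:g} "
            f"| {row.kcat.value:.2f} ± {row.kcat.se:.2f} "
            f"| {row.ratio.value:.2f} ± {row.ratio.se:.2f} "
            f"| {row.p:.2g} | {'*' if row.significant_at_0p01 else ''} |"
        )
    md_lines.append("")
    md_lines.append(
        f"Ratios strictly increasing with mass: {table.monotonic_in_mass}. "
        "Asterisks mark p < 0.01 (per-row Welch t-test against the reference)."
    )
    (out / "report.csv").write_text("".join(csv_lines), encoding="utf-8")
    (out / "report.md").write_text("\n".join(md_lines) + "\n", encoding="utf-8")

    from . import __version__

    log = {
        "config": cfg,
        "version": __version__,
        "n_rows": len(table.rows),
        "monotonic_in_mass": table.monotonic_in_mass,
        "n_significant": sum(r.significant_at_0p01 for r in table.rows),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True),
                                      encoding="utf-8")
    return cfg
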