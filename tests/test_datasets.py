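"""Synthetic-data generators: determinism, zero-noise inversion, geometry."""

import numpy as np
import pytest

from hekie import datasets as dsets
from hekie import fitting, mechanism, models
from hekie.datasets import AssayDesign, NoiseSpec


ZERO = NoiseSpec(sigma=0.0)


def test_noise_spec_validation():
    with pytest.raises(ValueError):
        NoiseSpec(kind="poisson")
    with pytest.raises(ValueError):
        NoiseSpec(sigma=-0.1)


def test_assay_design_validation():
    with pytest.raises(ValueError):
        AssayDesign(grid=(0.2, 0.1))
    with pytest.raises(ValueError):
        AssayDesign(n_replicates=0)


@pytest.mark.parametrize(
    "make",
    [
        lambda seed: dsets.gen_saturation(2.95, 0.111, seed=seed),
        lambda seed: dsets.gen_titration(3.0, 0.09, seed=seed),
        lambda seed: dsets.gen_sto_trace(seed=seed),
        lambda seed: dsets.gen_dose_response(10.0, 2.0, seed=seed),
        lambda seed: dsets.gen_melt(0.0, 1.0, 55.0, 2.0, seed=seed),
        lambda seed: dsets.gen_viscosity_series(
            mechanism.diffusion_limited_scheme(), seed=seed),
        lambda seed: dsets.gen_temperature_profile(
            mmrt=models.MMRTParams(60000.0, -35.0, -3000.0), seed=seed),
    ],
    ids=["saturation", "titration", "trace", "dose", "melt", "viscosity", "profile"],
)
def test_generators_are_deterministic_given_seed(make):
    a, b, c = make(42), make(42), make(43)
    for field in vars(a):
        va, vb = getattr(a, field), getattr(b, field)
        if isinstance(va, np.ndarray):
            np.testing.assert_array_equal(va, vb)
    # a different seed must actually change the ordinate somewhere
    changed = any(
        isinstance(getattr(a, f), np.ndarray)
        and not np.array_equal(getattr(a, f), getattr(c, f))
        for f in vars(a)
    )
    assert changed


def test_saturation_zero_noise_inversion():
    data = dsets.gen_saturation(2.95, 0.111, noise=ZERO)
    np.testing.assert_allclose(
        data.rate_per_s, models.mm_rate(data.substrate_mM, 2.95, 0.111)
    )
    res = fitting.fit("michaelis", data.substrate_mM, data.rate_per_s)
    assert res.estimates["kcat"] == pytest.approx(2.95, rel=1e-6)
    assert res.estimates["km"] == pytest.approx(0.111, rel=1e-6)


def test_saturation_replicate_structure():
    data = dsets.gen_saturation(2.95, 0.111, design=AssayDesign(n_replicates=3))
    assert set(data.replicate) == {1, 2, 3}
    assert data.substrate_mM.size == 3 * len(dsets.DEFAULT_SUBSTRATE_GRID_MM)


def test_titration_zero_noise_inversion_and_origin():
    data = dsets.gen_titration(3.0, 0.09, g_um=0.04, noise=ZERO)
    assert data.rate_per_s[data.z_uM == 0].max() == 0.0
    res = fitting.fit("titration", data.z_uM, data.rate_per_s, g_conc=0.04)
    assert res.estimates["vmax"] == pytest.approx(3.0, rel=1e-6)
    assert res.estimates["kd_app"] == pytest.approx(0.09, rel=1e-5)


def test_sto_trace_dead_time_and_beer_lambert():
    data = dsets.gen_sto_trace(es_um=80.0, k2=30.0, k3=8.0, noise=ZERO)
    assert data.time_s.min() >= 9e-4  # pre-dead-time samples dropped
    assert data.signal_unit == "AU"
    # completion amplitude: 80 uM * 3600 1/(M cm) * 0.5 cm = 0.144 AU
    assert data.signal.max() == pytest.approx(0.144, rel=1e-3)
    conc = data.signal / (data.epsilon_290 * data.path_length_cm) * 1e6
    np.testing.assert_allclose(
        conc, models.two_step_product(data.time_s, 80.0, 30.0, 8.0), rtol=1e-9
    )


def test_sto_trace_from_scheme_uses_isomerisation_and_chemistry_rates():
    scheme = mechanism.KineticScheme(30.0, 8.0, 6.0, 72.0)
    a = dsets.gen_sto_trace(scheme=scheme, noise=ZERO)
    b = dsets.gen_sto_trace(k2=30.0, k3=8.0, noise=ZERO)
    np.testing.assert_array_equal(a.signal, b.signal)


def test_dose_response_zero_noise_endpoints():
    data = dsets.gen_dose_response(10.0, 2.0, noise=ZERO)
    assert data.fractional_activity[data.inhibitor_uM == 0].max() == 1.0
    res = fitting.fit("dose_response", data.inhibitor_uM, data.fractional_activity)
    assert res.estimates["ic50"] == pytest.approx(10.0, rel=1e-6)


def test_melt_zero_noise_plateaus_and_recovery():
    data = dsets.gen_melt(0.1, 1.2, 55.0, 2.0, noise=ZERO)
    assert data.temp_C.min() == 25.0 and data.temp_C.max() == 93.0
    assert data.fluorescence[0] == pytest.approx(0.1, abs=1e-3)
    assert data.fluorescence[-1] == pytest.approx(1.2, abs=1e-3)
    res = fitting.fit("melt", data.temp_C, data.fluorescence)
    assert res.estimates["tm"] == pytest.approx(55.0, rel=1e-6)


def test_melt_tm_resolution_at_realistic_noise():
    # two melts generated 4 deg C apart are resolved well within 0.5 deg C
    a = dsets.gen_melt(0.0, 1.0, 55.0, 2.0, noise=NoiseSpec(sigma=0.02), seed=3)
    b = dsets.gen_melt(0.0, 1.0, 51.0, 2.0, noise=NoiseSpec(sigma=0.02), seed=4)
    tm_a = fitting.fit("melt", a.temp_C, a.fluorescence).estimates["tm"]
    tm_b = fitting.fit("melt", b.temp_C, b.fluorescence).estimates["tm"]
    assert tm_a - tm_b == pytest.approx(4.0, abs=0.5)


def test_viscosity_series_reflects_rate_limiting_step():
    diff = dsets.gen_viscosity_series(
        mechanism.diffusion_limited_scheme(), noise=ZERO)
    kcat0 = diff.kcat_per_s[np.isclose(diff.eta_rel, 1.0)].mean()
    m_fit = fitting.fit("viscosity", diff.eta_rel, kcat0 / diff.kcat_per_s)
    assert m_fit.estimates["m"] == pytest.approx(
        mechanism.viscosity_slope_analytic(mechanism.diffusion_limited_scheme()),
        abs=1e-6,
    )
    assert m_fit.estimates["m"] > 0.9
    vib = dsets.gen_viscosity_series(mechanism.vibration_limited_scheme(), noise=ZERO)
    kcat0 = vib.kcat_per_s[np.isclose(vib.eta_rel, 1.0)].mean()
    m_vib = fitting.fit("viscosity", vib.eta_rel, kcat0 / vib.kcat_per_s)
    assert m_vib.estimates["m"] < 0.06


def test_temperature_profile_from_mmrt_and_scheme():
    prof = dsets.gen_temperature_profile(
        mmrt=models.MMRTParams(60000.0, -35.0, 0.0), noise=ZERO)
    y = np.log(prof.kcat_per_s / prof.temp_K)
    resid = y - np.polyval(np.polyfit(1 / prof.temp_K, y, 1), 1 / prof.temp_K)
    assert np.max(np.abs(resid)) < 1e-10  # dCp=0 -> linear Eyring plot

    thermo = {name: mechanism.StepThermo(dh=dh, ds=-40.0)
              for name, dh in zip(("k_iso", "k_chem", "k_prod_iso", "k_off"),
                                  (50e3, 60e3, 55e3, 45e3))}
    base = mechanism.KineticScheme(1.0, 1.0, 1.0, 1.0, step_thermo=thermo)
    prof2 = dsets.gen_temperature_profile(scheme=base, noise=ZERO)
    expected = [
        mechanism.steady_state_kcat(mechanism.apply_temperature(base, t, strict=True))
        for t in prof2.temp_K
    ]
    np.testing.assert_allclose(prof2.kcat_per_s, expected)
    with pytest.raises(ValueError):
        dsets.gen_temperature_profile()


def test_crossover_scheme_produces_nonmonotone_rate_profile():
    # slow vibration-limited step at low T, diffusional release dominating
    # at high T: the observed kcat(T) dips where control switches hands
    thermo = {
        "k_iso": mechanism.StepThermo(dh=40e3, ds=20.0),
        "k_chem": mechanism.StepThermo(dh=40e3, ds=20.0),
        # steep vibration-limited step, fast at warm temperatures
        "k_prod_iso": mechanism.StepThermo(dh=120e3, ds=177.0),
        # release step whose heat-capacity term gives it a minimum near 298 K
        "k_off": mechanism.StepThermo(dh=10e3, ds=-217.0, dcp=9000.0),
    }
    base = mechanism.KineticScheme(1.0, 1.0, 1.0, 1.0, step_thermo=thermo)
    temps = np.arange(278.0, 309.0, 2.0)
    kcats = np.array([
        mechanism.steady_state_kcat(mechanism.apply_temperature(base, t, strict=True))
        for t in temps
    ])
    diffs = np.diff(kcats)
    assert diffs[0] > 0  # rising at cold temperatures
    assert np.any(diffs < 0)  # the dip where the rate-limiting step switches
    first_drop = int(np.argmax(diffs < 0))
    assert np.any(diffs[first_drop:] > 0)  # and kcat recovers beyond the dip


def test_isotopologue_panel_ordering_and_masking():
    vib = mechanism.KineticScheme(1000.0, 1000.0, 3.0, 1000.0)
    panel = dsets.gen_isotopologue_panel(vib, noise=ZERO)
    kcats = [fitting.fit("michaelis", d.substrate_mM, d.rate_per_s).estimates["kcat"]
             for d in panel]
    assert all(b < a for a, b in zip(kcats, kcats[1:]))  # heavier -> slower
    masked = dsets.gen_isotopologue_panel(
        mechanism.KineticScheme(1000.0, 1000.0, 1000.0, 3.0), noise=ZERO)
    kcats_masked = [fitting.fit("michaelis", d.substrate_mM, d.rate_per_s).estimates["kcat"]
                    for d in masked]
    ratios = [kcats_masked[0] / k for k in kcats_masked]
    assert max(ratios) < 1.005  # diffusional release hides the mass effect


def test_isotopologue_panel_validation():
    with pytest.raises(ValueError):
        dsets.gen_isotopologue_panel(
            mechanism.vibration_limited_scheme(), phi_list=(1.0, 1.2),
            labels=("a",), mass_percent=(0.0,))
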