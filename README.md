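# hekie

Heavy-enzyme kinetic isotope effect (HE-KIE) analysis for multi-step enzyme
kinetics, built around the allosterically activated ATP phosphoribosyltransferase
(ATPPRT) system: a catalytic subunit (HisG_S) activated by a regulatory subunit
(HisZ), where isotope-labelling of the catalytic protein (²H/¹³C/¹⁵N) slows the
observed turnover number in a mass-dependent way whenever a protein-motion-limited
step — not chemistry, not diffusion — controls k_cat.

The package is for enzymologists who need to take a panel of steady-state and
pre-steady-state experiments (substrate saturation, regulator titrations,
stopped-flow traces, viscosity series, temperature–rate profiles, DSF melts) from
raw CSV tables to a defensible statement about *which step of the catalytic cycle
the isotope effect reports on*.

## The models

All fitted models are the field-standard forms, implemented once in
`hekie.models` and exposed as scikit-learn-style estimators in `hekie.fitting`:

| quantity | model |
|---|---|
| DSF melt | F = LL + (UL−LL)/(1+e^{(T_m−T)/c}) |
| saturation | v/E_T = k_cat·S/(K_M+S) |
| HisZ titration | v = V_max·(G+Z+K_D − √((G+Z+K_D)²−4GZ))/(2G) (tight-binding quadratic) |
| dose–response | v_i/v_0 = 1/(1+(I/IC₅₀)^n) |
| single-turnover lag | P(t) = ES/(k₂−k₃)·[k₂(1−e^{−k₃t}) − k₃(1−e^{−k₂t})] |
| viscosity | k_cat⁰/k_cat^η = m(η_rel−1)+1 |
| MMRT / Eyring | ln(k_cat/T) = ln(k_B/h) − [ΔH‡+ΔC_P‡(T−T₀)]/(RT) + [ΔS‡+ΔC_P‡ln(T/T₀)]/R |
| single-turnover rise | P(t) = A(1−e^{−k_STO t}) |

The HE-KIE itself is the ratio of the natural-abundance k_cat to the heavy-enzyme
k_cat, with its standard error propagated in quadrature and each row tested
against the reference by a Welch t-test at p < 0.01.

`hekie.mechanism` integrates the sequential catalytic cycle

    C1 → C2 → E:P → (E:P)* → E + P
       iso   chem   prod-iso    off

exactly (matrix exponential of the linear rate network), with hooks that divide
the mass-sensitive product-complex isomerisation by a mass factor φ, the
diffusional release by the relative viscosity η_rel, and recompute every rate
from per-step Eyring parameters at any temperature. It serves as the mechanistic
oracle for the closed-form models and drives the synthetic-data generators in
`hekie.datasets`, so the entire pipeline is testable without any instrument data.

## Worked example

Propagating a published-style five-isotopologue k_cat column into the HE-KIE
table:

```python
from hekie import pipeline

table = pipeline.hekie_from_estimates(
    labels=["unlabelled", "15N", "13C,15N", "2H,15N", "2H,13C,15N"],
    mass_percent=[0.0, 0.5, 2.0, 2.6, 4.2],
    kcats=[2.95, 2.87, 2.27, 2.05, 1.92],
    ses=[0.03, 0.06, 0.06, 0.03, 0.04],
    dofs=16,
)
for row in table:
    star = "*" if row.significant_at_0p01 else " "
    print(f"{row.isotopologue:>11s}  +{row.mass_increase_percent:3.1f}%  "
          f"kcat {row.kcat.value:.2f} ± {row.kcat.se:.2f}  "
          f"HE-kcat {row.ratio.value:.2f} ± {row.ratio.se:.2f} {star} (p = {row.p:.2g})")
print("monotonic in mass:", table.monotonic_in_mass)
```

prints

```
 unlabelled  +0.0%  kcat 2.95 ± 0.03  HE-kcat 1.00 ± 0.01   (p = 1)
        15N  +0.5%  kcat 2.87 ± 0.06  HE-kcat 1.03 ± 0.02   (p = 0.24)
    13C,15N  +2.0%  kcat 2.27 ± 0.06  HE-kcat 1.30 ± 0.04 * (p = 4.6e-10)
     2H,15N  +2.6%  kcat 2.05 ± 0.03  HE-kcat 1.44 ± 0.03 * (p = 2.1e-20)
 2H,13C,15N  +4.2%  kcat 1.92 ± 0.04  HE-kcat 1.54 ± 0.04 * (p = 4e-19)
monotonic in mass: True
```

i.e. the isotope effect grows strictly with the mass of the catalytic subunit,
and only the three heaviest labels are significant at p < 0.01 — the 0.5% mass
increase of ¹⁵N labelling is below the resolution of the fitting errors.
Reading the table: `HE-kcat` is k_cat(light)/k_cat(heavy), so 1.54 means the
fully labelled enzyme turns over 54% slower; the asterisked rows are the ones a
per-row Welch t-test distinguishes from the unlabelled reference.

The same table can be produced from raw data end to end
(`pipeline.analyze_hekie` on a list of saturation datasets), from generated
data (`datasets.gen_isotopologue_panel`), or from the shell:

```bash
hekie report --seed 1 --out demo_report
hekie generate --kind saturation --seed 3 --out sat.csv
hekie fit-saturation sat.csv
```

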