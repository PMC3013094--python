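# zfswim

Swim-tunnel respirometry and exercise-growth analysis for adult zebrafish
(*Danio rerio*), built as a reusable pipeline for comparative exercise
physiologists: oxygen traces in, swimming economy, growth statistics and
muscle-marker expression out.

The package covers the full analysis chain of an individual swimming-fitness
experiment and a group training experiment:

1. **Respirometry** — closed-phase oxygen declines (% air saturation, 2-s
   sampling) are converted to dissolved-O₂ concentration via the
   Benson–Krause solubility relation and fitted by OLS; mass-specific uptake
   is ṀO₂ = |Δ[O₂]/Δt| · V / M (µmol O₂ g⁻¹ h⁻¹) for tunnel volume V and
   body mass M.
2. **Critical swimming speed** — Brett interpolation over stepped-velocity
   trials: U_crit = U_i + (T_i/T_ii)·U_ii, with conversion to standard body
   lengths per second and ammeter→speed motor calibration.
3. **Metabolic model** — V̇O₂(U) = SMR + aU² + bU fitted per fish on the
   %U_crit axis; SMR is the zero-speed extrapolation. Cost of transport
   COT = V̇O₂/U is fitted by a second quadratic whose vertex
   U_opt = −b₂/(2a₂) is the optimal (most economical) swimming speed, with
   COT_opt the curve value there.
4. **Growth statistics** — KS normality screening and the paired/unpaired
   Student t battery comparing swimmer and rester cohorts pre/post training,
   with percent differences on group means.
5. **qPCR expression** — triplicate-Ct QC, *rps18* normalisation per primer
   set, iterative Grubbs outlier screening, Livak 2^−ΔΔCt fold changes of
   swimmers over resters, and exact Mann–Whitney U tests.
6. **Synthetic data** — seeded generators for every input (traces, trials,
   cohorts, Ct plates) with recorded ground truth, so the whole pipeline is
   testable end to end without any measurement files.

## Worked example

Generate a synthetic study and run the economy analysis:

```sh
python analysis/01_simulate_inputs.py --seed 42
python analysis/02_swimming_economy.py
```

```
U_crit        0.548 ± 0.000 m/s (18.0 BL/s), n=10
SMR           42.15 ± 1.83 µmol/g/h (extrapolated)
RMR           41.57 ± 0.85 µmol/g/h (5% U_crit)
VO2max        80.08 ± 0.39 µmol/g/h (at U_crit)
U_opt         0.427 ± 0.004 m/s (78.0% U_crit, 14.0 BL/s)
COT at U_opt  0.0381 ± 0.0003 µmol/g/m (strict scale)
pooled curve  VO2 = 42.15 + 0.0077 U² -0.3862 U (r² = 1.000); vertex at 77.7% U_crit
```

Ten simulated fish swam a stepped trial against a true critical speed of
0.548 m/s (recovered exactly: with 0.05 m/s increments and 10-min intervals
the Brett estimate is interpolation-exact) and respired against a true
metabolic curve with SMR 43.79 µmol g⁻¹ h⁻¹; under 0.5 %AS sensor noise the
group extrapolation lands at 42.15 ± 1.83. The cost-of-transport vertex
puts the most economical speed near 78% of U_crit.

`analysis/03_growth_comparison.py` then shows the trained cohort outgrowing
the resters (+5.7% TL, +43.8% BW at the end of the experiment,
p < 1e-10/1e-16 one-tailed), and `analysis/04_muscle_expression.py` recovers
exactly the programmed expression pattern — down-regulation of *ghrb* and
*igf1ra*, up-regulation of *stnnc*, *smyhc1*, *tnni2*, *myhz2* and *mstnb* —
with all other panel genes non-significant.

The same stages are available as a CLI (`zfswim simulate|respirometry|
ucrit|growth|qpcr|validate|run`) and as plain library functions
(`zfswim.analyze_fish`, `zfswim.run_growth_battery`,
`zfswim.analyze_expression`, ...).

## Layout

- `src/zfswim/` — the library (all computation lives here)
- `analysis/` — numbered narrative drivers writing tables under `results/`
- `tests/` — pytest suite, including property tests and exactness oracles
- `docs/methods.md` — models, assumptions, parameter choices, limitations
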