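# freshlabel

Shelf-life inference for shrimp from colorimetric freshness labels.

Spoiling seafood accumulates total volatile basic nitrogen (TVB-N, in
mg/100 g), the standard freshness index; shrimp are considered spoiled
at 30 mg/100 g. A pH-sensitive anthocyanin label sealed with the product
changes color as volatile amines accumulate, and the CIE76 color
difference ΔE of the label tracks TVB-N linearly. `freshlabel` turns
that chain into a tested pipeline for researchers and packaging
developers working on quantitative intelligent labels:

- **Kinetics** — first-order TVB-N accumulation A(t) = A₀·exp(k·t),
  fitted per storage temperature by log-linear OLS, and the Arrhenius
  law k(T) = k₀·exp(−Eₐ/(R·T)) fitted across temperatures
  (Eₐ = −slope·R from the ln k vs 1/T regression).
- **Shelf-life** — the threshold model
  t_RSL = (ln 30 − ln A)/k(T), and the label-based predictor obtained by
  substituting the calibration A = 1.43·ΔE + 0.6:
  t_RSL = (3.401 − ln(1.43·ΔE + 0.6)) / (1.7×10⁹·exp(−7091.4/T)).
- **Validation** — RE = |pred − obs|/obs × 100%, MAE, RMSE, Pearson r,
  and construction of per-temperature validation tables.
- **Colorimetry** — CIE76 ΔE, pigment photodegradation bookkeeping,
  color-stability classification, water-vapor permeability
  WVP = (Δm·d)/(A·t·Δp).
- **Synthetic data** — a seeded generator emulating the full storage
  study (Arrhenius-governed trajectories, coupled label colors,
  photobleaching, validation designs), so every stage is testable
  without laboratory data.

A model can be built in two modes: the **published preset**
(`ShelfLifeModel.published()`), carrying the study constants verbatim
(k₀ = 1.7×10⁹ h⁻¹, slope −7091.4 K, numerator 3.401, calibration
1.43·ΔE + 0.6), or the **fitted mode**, deriving everything from data.
See `docs/methods.md` for the model details and design choices.

## Worked example

From the shell — a label on refrigerated shrimp reads ΔE = 6.8:

```
$ freshlabel predict --delta-e 6.8 --temp-c 4
81.2 h remaining (TVB-N est. 10.3 mg/100 g)
```

The ΔE maps to an estimated TVB-N of 1.43×6.8 + 0.6 = 10.3 mg/100 g;
at 4 °C the spoilage rate is k = 0.0131 h⁻¹, so
(3.401 − ln 10.324)/0.0131 ≈ 81.2 h remain before the 30 mg/100 g
threshold.

From Python — simulate a full storage study and recover its kinetics:

```python
import freshlabel as fl

obs = fl.simulate_tvbn_study(fl.SimulationConfig(seed=1))
fits = [fl.fit_first_order([o for o in obs if o.temperature_C == T])
        for T in (0, 4, 12, 20, 28)]
arr = fl.fit_arrhenius(fits)
print(f"Ea={arr.ea:.0f} J/mol  k0={arr.k0:.3g}  R2={arr.r_squared:.4f}")
```

```
Ea=58829 J/mol  k0=1.62e+09  R2=0.9999
```

The recovered activation energy (58 829 J/mol) sits within 0.3% of the
generator's ground truth (58 958 J/mol); per-temperature fits for this
seed have R² of 0.990–0.997, i.e. the log-linear model describes the
noisy trajectories essentially perfectly. The whole workflow is also
available as CLI subcommands: `simulate`, `fit-kinetics`, `calibrate`,
`predict`, `validate`, `report`.

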