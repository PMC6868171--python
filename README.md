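# bergfert

Iceberg iron content, melt-driven iron release, and ocean-fertilization /
carbon-export scenarios.

## The problem

Icebergs are one of the largest sources of the micronutrient iron (Fe) to the
polar oceans, where phytoplankton growth is widely Fe-limited.  But iceberg
iron is extraordinarily heterogeneous: total dissolvable Fe (TdFe) in melted
iceberg samples spans six orders of magnitude (≈2 nM to ≈2 mM), because clean
meteoric ice coexists with sediment-laden basal ice.  In the global 206-sample
dataset this package emulates, the mean is 9.3 µM while the median is only
170 nM, and 4 % of the ice holds 91 % of the iron.  Where that Fe-rich ice
sits *inside* an iceberg then controls how much iron survives the near-shore
transit and reaches open, Fe-limited waters — and ligand chemistry and export
efficiency control how much carbon the surviving iron can ultimately draw
down.

`bergfert` is a tested reimplementation of that analysis chain for
biogeochemists and modellers:

1. **`bergfert.fe_samples`** — heavy-tailed TdFe sample sets: I/O (nM/µM/mM/M),
   box-plot summaries, top-share and cumulative-mass curves, one-way ANOVA
   across catchments on log₁₀ concentrations (Holm-corrected pairwise tests),
   discharge-flux scaling (`flux = c·D`, 9.3 µM × 1100 km³ yr⁻¹ → 10 Gmol Fe
   yr⁻¹), and lithogenic particle-size summaries.
2. **`bergfert.synthetic_data`** — a seeded two-component lognormal mixture
   (clean vs sediment-rich ice, 9 % sediment-rich weight, clipped to the
   observed 2.1 nM–1.9 mM range) calibrated so n = 206 datasets reproduce the
   mean / median / top-4 %-share targets; plus iceberg size populations and
   particle-size generators.
3. **`bergfert.melt_sim`** — a daily-time-step cuboid iceberg melt model
   (wave erosion, buoyant-convection sidewall melt, forced-convection basal
   melt, shortwave surface melt with a sediment-albedo feedback) with three
   internal Fe distributions holding identical total iron — a peripheral
   **shell**, a **basal** slab, and a **Monte Carlo** random assignment drawn
   from a sample set — two wave-erosion formulations, capsize removal, and
   population-weighted ensembles over 50–1000 m icebergs.
4. **`bergfert.fertilization`** — the Fe → primary production → carbon export
   chain: ligand capping (`dissolved ≤ L/f`), mixed-layer Fe supply with a
   1/fe recycling multiplier, Fe:C quotas (3–20 µmol Fe mol⁻¹ C), the observed
   Southern Ocean efficiency relation `e = −0.3484·log₁₀(PP) + 1.2239` clamped
   to [0, 1], Fe-to-C sequestration efficiencies, and the five-scenario
   comparison table.

A `bergfert` command (`stats`, `synth`, `simulate`, `fertilize`, `full`) ties
the stages together with YAML configuration and seed-stamped CSV/JSON outputs.

## Worked example

```python
import numpy as np
from bergfert import (FeGeneratorParams, generate_fe_samples, top_share,
                      discharge_flux, FeScenarioConfig, run_ensemble,
                      generate_iceberg_population, scenario_table)

sets = [generate_fe_samples(FeGeneratorParams(seed=s), 206) for s in range(1, 21)]
mean = np.mean([s.tdfe.mean() for s in sets])
median = np.mean([np.median(s.tdfe) for s in sets])
share = np.mean([top_share(s, 0.04) for s in sets])
print(f"mean TdFe {mean*1e6:.1f} uM  median {median*1e9:.0f} nM  top-4% share {share*100:.0f}%")
print(f"Antarctic discharge flux: {discharge_flux(9.3e-6, 1100):.1f} Gmol Fe/yr")

ens = run_ensemble(generate_iceberg_population(), FeScenarioConfig(scenario="shell"))
print(f"shell-scenario ensemble Fe loss at day 81: {ens.at_residence['day_81']*100:.0f}%")
print(scenario_table(sets[0]).rounded().to_string(index=False))
```

prints

```
mean TdFe 7.7 uM  median 165 nM  top-4% share 86%
Antarctic discharge flux: 10.2 Gmol Fe/yr
shell-scenario ensemble Fe loss at day 81: 90%
scenario cap_mode  fe_to_c efficiency_mode  mean_pp  mean_efficiency  mean_export change_pct
       a   pp_cap      3.0       empirical   2200.0             0.09         83.0          -
       b   fe_cap      3.0       empirical   9500.0             0.08         63.0       -20%
       c   pp_cap     20.0       empirical   1000.0             0.28        100.0       +20%
       d   pp_cap      3.0        constant   2200.0             0.10        220.0      +170%
       e   pp_cap      3.0        constant   2200.0             0.20        440.0      +430%
```

Reading the numbers: the 20-seed averages recover the calibration targets up
to the intrinsic noise of so heavy-tailed a sample mean; the shell-distributed
iceberg ensemble has shed ~90 % of its iron by the mean 81-day fjord residence
time (the Monte Carlo distribution, by construction, only loses iron as fast
as volume); and in the scenario table the per-sample export means (row a:
83 mg C m⁻² d⁻¹) sit far below the product of the column means — export
efficiency falls as production rises, so averaging must happen per sample.

The same pipeline from the shell:

```bash
bergfert full --seed 7 --out runs/demo        # synth -> stats -> ensembles -> table + grids
bergfert simulate --scenario shell --wave-mode waterline --out runs/wl
bergfert fertilize --input samples.csv --table1 --grid --out runs/fert
```

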