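# oceanch4

Quantitative analysis of methane cycling in ocean water-mass mixing regions.

Frontal zones where western boundary currents converge — the archetype being
the Kuroshio–Oyashio Extension in the Northwest Pacific — mix water masses
with contrasting temperature, salinity, nutrients and dissolved gas loads.
That mixing shapes where methane is produced (from methylated precursors
such as DMSP and methylphosphonate), how fast it is microbially oxidized,
and how much escapes to the atmosphere.  `oceanch4` implements the
computational chain used to diagnose these processes from cruise data:

1. **Water-mass decomposition (OMP analysis).**  Each sample is modelled as
   a non-negative mixture of endmember water masses conserved in six
   properties (potential temperature *T*, salinity *S*, oxygen *O*,
   phosphate *P*, nitrate *N*, silicate *Si*):

       Σᵢ xᵢ·Tᵢ = T_obs + R_T   (one equation per property)
       Σᵢ xᵢ    = 1     + R_M   (mass conservation)
       xᵢ ≥ 0

   solved per sample by weighted non-negative least squares after
   per-property standardization.

2. **Methane-oxidation (MOx) kinetics.**  Tritiated-methane incubations
   give the first-order rate constant and volumetric rate

       k = DPM[³H-H₂O] / DPM[³H-H₂O + ³H-CH₄] · 1/t,     MOx = k·[CH₄]_in situ

   with killed-control correction on the turnover-fraction scale and
   triplicate statistics.

3. **Air–sea gas exchange.**  Equilibrator xCO₂ is converted to in situ
   pCO₂ (water-vapor correction ln f = 24.4543 − 6745.09/T_eq −
   4.8489·ln(T_eq/100) − 0.000544·S; warming correction
   e^{0.0423·(SST−T_eq)}), and fluxes follow

       F_CH4 = k_CH4 · ([CH₄]_water − [CH₄]_eq),   F_CO2 = k_CO2 · K_H · ΔpCO₂,
       k = 0.251·u²·(Sc/660)^−½  [cm h⁻¹]

   with published Schmidt-number and solubility fits kept in one
   swappable coefficient table.

4. **Conservative dilution and driver attribution.**  CH₄ is compared with
   the two-endmember mixing line in salinity (residuals below the line
   diagnose net consumption), and CH₄ variability is attributed to
   hydrographic drivers by an OLS regression with LMG (Shapley) variance
   shares.

5. **Methane loss budget.**  Depth-integrated MOx versus sea–air flux gives
   the microbial share of total methane removal,
   100·∫MOx / (∫MOx + F_CH4).

A synthetic-data generator (`oceanch4.synthetic`) produces every input
table with known ground truth, so the full chain is testable end to end,
and a thin CLI (`oceanch4 simulate|omp|mox|flux|dilution|incubation|budget|pipeline`)
chains the stages over delimited-text tables.

## Worked example

```python
from oceanch4 import estimate_mox, synthetic as syn

table = syn.generate_tracer_incubations(0.013, ch4=3.21, t=2.0, dpm_total=1e5, seed=4)
print(estimate_mox(table).iloc[0])
```

prints (seed 4):

```
estimated k   : 0.0131 +/- 0.0003 /d   (truth 0.013)
estimated MOx : 0.0420 +/- 0.0008 nmol/l/d
```

i.e. 1.3 % of the methane pool is oxidized per day, and at an ambient
concentration of 3.21 nmol l⁻¹ this removes 0.042 nmol l⁻¹ d⁻¹.  The
`examples/` directory holds one short script per capability (OMP
inversion, MOx rates, underway fluxes, dilution residuals, amendment
incubations, methane budget), each printing what it computes and what the
numbers mean.

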