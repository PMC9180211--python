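# quakeloss

Rapid post-earthquake fatality estimation for emergency response triage.

After a damaging earthquake, responders need an immediate, quantitative
answer to two questions: *roughly how many people have died, and which
emergency-response tier should be activated?*  `quakeloss` implements a
complete desk-scale pipeline for that task, aimed at Mainland-China-style
response planning but usable anywhere an analogous damaging-earthquake
catalog exists:

1. **Ground-motion simulation** — a 3-D elastic velocity–stress
   finite-difference solver (RK4 time marching with alternating one-sided
   MacCormack-type spatial operators on a collocated grid, traction-image
   free surface, Cerjan-style absorbing sponge, point moment-tensor or
   kinematic finite-fault sources) produces surface peak ground velocity
   (PGV).
2. **Intensity conversion** — PGV maps to continuous macroseismic
   intensity through a configurable log-linear law
   `I = c0 + c1·log10(PGV)` (defaults approximate the PGV branch of the
   China Seismic Intensity Scale, GB/T 17742-2020).
3. **Population exposure** — the intensity raster is overlaid with a
   LandScan-style population raster; persons are accumulated per intensity
   class `Pe(I)` with strict mass conservation.
4. **Fatality model** — expected fatalities follow a regionally
   stratified empirical model

   ```
   E = Σ_{I=V}^{XI}  r(I) · (HDI_maxyear / HDI_eventyear) · Pe(region, I)
   log10 r(I) = β + θ·I            (r clamped to ≤ 1)
   ```

   with `(β, θ)` fitted per sub-region on a historical
   damaging-earthquake catalog by minimizing

   ```
   ε = ln[(1/N) Σ (E_i − O_i)²] + (1/N) Σ [ln(E_i / O_i)]²
   ```

   and a pooled log residual `ζ = RMS(ln(E_i/O_i))`.
5. **Response levels** — uncertainty is expressed as lognormal
   probabilities `P(a < deaths ≤ b) = Φ((ln b − ln E)/ζ) − Φ((ln a − ln E)/ζ)`
   over the four NEEP tiers (IV ≤ 10, III 10–50, II 50–300, I > 300) and
   the level with the highest probability is recommended.

A synthetic-data module generates catalogs with known `(β*, θ*, ζ*)`,
clustered population rasters, HDI tables and analytic butterfly-pattern
intensity fields, so the whole pipeline is testable without any external
downloads.

## Worked example

```bash
# synthetic inputs with known ground truth
quakeloss synth hdi --out hdi.csv
quakeloss synth catalog --out catalog.csv --hdi hdi.csv --n-events 20 --zeta 0.2 --seed 5
quakeloss synth population --out pop.asc --nrows 50 --ncols 50 \
    --origin-lon 99.5 --origin-lat 24.5 --total 300000
quakeloss synth intensity --out intensity.asc --epicenter 99.75 25.0 \
    --origin-lon 99.5 --origin-lat 24.5 --nrows 50 --ncols 50 --i0 9.0 --lobe 0.5

# fit the fatality model, overlay, estimate
quakeloss fit --catalog catalog.csv --hdi hdi.csv --out params.json
quakeloss exposure --intensity intensity.asc --population pop.asc --out exposure.csv
quakeloss estimate --exposure exposure.csv --params params.json --hdi hdi.csv \
    --region a --year 2015 --out estimate.json
```

which prints

```
wrote params.json; 100.0% of events within one order of magnitude
wrote exposure.csv (total 300016 persons, 0 unassessed)
E = 253.487, level II; wrote estimate.json
```

Reading: the fit reproduced every catalog event within one order of
magnitude (this synthetic catalog is nearly noise-free); all 300,016
persons of the raster fell inside the intensity map; the scenario's
expected toll is ≈ 253 deaths, so the 50–300 fatality range is the most
probable (76.7% in `estimate.json`, which carries the full probability
split over the four NEEP ranges) and a Level II emergency response is
recommended.

A single YAML config can instead drive the whole chain — including the
wave-propagation simulation producing the intensity map — via
`quakeloss run --config scenario.yaml` (see `PipelineConfig` in
`quakeloss.pipeline`).

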