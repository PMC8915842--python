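# htpp — high-throughput phenotypic profiling screen analysis

`htpp` implements the analysis pipeline of an imaging-based high-throughput
phenotypic profiling (Cell Painting) screen, as used to characterize
reference chemicals in human neural progenitor cells: randomized 384-well
dose designs, synthetic cell-level data with recorded ground truth,
concentration–response modeling, viability gating, and global
(Mahalanobis-distance) phenotype potency estimation.

## Who it is for

Screeners and computational toxicologists who need a tested, reproducible
implementation of the benchmark-concentration (BMC) workflow for
high-content screens — or a simulator with known truth to validate one.

## The method

A screen tests each chemical at 8 half-log-spaced concentrations (two
technical replicates per plate, three culture replicates), with 24 DMSO
vehicle wells per plate and a cytotoxic positive control. Per cell, ~1,300
morphological features are measured across five organelle channels (DNA,
RNA, ER, AGP, Mito).

**Viability.** Per well: normalized cell count
`100 · n_valid / median(n_valid, vehicle)` and percent PI-positive cells.
Wells failing QC (vehicle < 50 % count, treated < 50 nuclei) are excluded.
The count response is fit with {constant, Hill} and the EC50 (the fitted
gain AC50 of a count *loss*) is its BMC; the PI response is fit with
{constant, Hill, gain–loss} at a benchmark response (BMR) of 3 × the
vehicle nMAD (nMAD = 1.4826 × median absolute deviation). The overall
viability BMC is the lower of the two; the LOEC is the lowest tested
concentration above it; only concentrations ≤ LOEC enter profiling.

**Profiling.** Cell-level features are robust-z-scored against vehicle
cells per plate, median-aggregated to wells, and re-centered/scaled against
vehicle wells, so a well-level value is "robust SDs from the vehicle
median". Feature-level potency fits nine curve shapes (constant, Hill,
poly1/2, power, exp2–5) by maximum likelihood under Student-t(4) errors,
selects by lowest AIC, and inverts the fit at |BMR| = 1. Global potency
projects well profiles onto principal axes, estimates a vehicle covariance
(Ledoit–Wolf shrinkage; half-plate cross-calibrated vehicle null), and fits
each well's Mahalanobis distance

D(w) = sqrt[(v_w − μ_veh)ᵀ Σ⁻¹ (v_w − μ_veh)]

with the same model family at a BMR of one vehicle nMAD of D. The
viability:profiling BMC ratio, with the printed-table censoring conventions
(">top", "—"), drives reference-chemical selection.

## Worked example

```python
from htpp.pipeline import simulate_demo_screen, run_screen

cells, truths, layouts, config = simulate_demo_screen(seed=1)
result = run_screen(cells, layouts)
print(result.table[["chemical_id", "cv_bmc", "pp_bmc", "ratio", "selected"]].to_string(index=False))
```

```
       chemical_id   cv_bmc   pp_bmc ratio  selected
       dna_blocker      >10 5.92E-02     —      True
       er_stressor 1.29E+00 2.59E-01   5.0     False
     mito_toxicant 1.50E+01 7.72E-01  19.5      True
        negative_a     >100     >100     —     False
        negative_b     >100     >100     —     False
      rna_toxicant 1.07E+00 2.10E-01   5.1      True
viability_positive 2.20E-02      >10     —     False
    weak_modulator     >100 2.14E+00     —      True
```

`dna_blocker` (true phenotype BMC 0.05 µM, no cytotoxicity configured) is
called at 0.0592 µM with viability censored above the top tested
concentration — the profile of a usable reference chemical. Both negative
controls are censored at both endpoints. `mito_toxicant` (true 1.0 µM) and
`rna_toxicant` (true 0.2 µM) are recovered within 0.11 and 0.02 log10 units
and selected because their viability:profiling ratios clear the default
threshold of 5; `er_stressor` displays as 5.0 but its unrounded ratio is
just below 5 and it is left out. The cytotoxic `viability_positive` control
gets a viability BMC (0.022 µM) but no phenotype call, as its retained
concentration range is truncated by the LOEC.

The same flow is scriptable from a shell:

```bash
htpp design --roster roster.yaml --seed 1 --plates 3 --out layouts.csv
htpp simulate --layout layouts.csv --truth truth.yaml --seed 1 --out cells.parquet
htpp fit-cv --cells cells.parquet --layout layouts.csv --out cv/
htpp fit-profile --cells cells.parquet --layout layouts.csv --cv-summary cv/ --out profile/
htpp report --cv cv/ --profile profile/ --min-ratio 5 --out report.csv
```

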