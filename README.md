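# endograd

Quantifying protein distribution gradients in the wheat grain endosperm from
stained light-microscopy sections.

Gluten storage proteins are not distributed evenly across the starchy
endosperm: their concentration is highest in the subaleurone cells just
inside the aleurone layer and falls towards the centre of the grain's two
lobes. This gradient matters to millers, because the protein-rich outer
endosperm tends to stay adhered to the bran during milling, and it responds
to growing conditions such as post-anthesis temperature and nitrogen supply.
`endograd` is a measurement pipeline for sections stained for protein (e.g.
with Naphthol Blue Black), aimed at plant scientists studying grain filling:

1. **Pixel classification** — supervised maximum-likelihood (Gaussian)
   classification of RGB pixels into protein vs background. Each class k is a
   multivariate normal over RGB; a pixel x is assigned to the class maximising
   `ln π_k − ½ ln|Σ_k| − ½ (x−μ_k)ᵀ Σ_k⁻¹ (x−μ_k)`. The analysis is run
   three times with independently drawn training samples to absorb operator
   variation.
2. **Concentric zonation** — K equal-width bands (default K = 5) rendered
   inward from a manually drawn endosperm outline on the Euclidean distance
   transform, yielding a per-zone protein area fraction; the zone index is
   converted to the physical mid-band distance (µm) so that differently sized
   grains are comparable.
3. **Protein-body metrics** — 8-connected stained components with area (µm²),
   centroid, and shortest Euclidean centroid-to-outline distance.
4. **Nitrogen calibration** — a per-treatment-group conversion factor
   `cf = (N% × k_N→protein / 100) / (image protein area fraction)` rescales
   area fractions so their area-weighted mean equals the chemically measured
   grain protein concentration.
5. **Gradient statistics** — per-group OLS trends of calibrated concentration
   and of ln(body area) against distance, with a distance² lack-of-fit
   F-test and descriptive slope contrasts between groups.
6. **Synthetic sections** — a generator that renders two-lobed grain sections
   with programmed gradients and exact pixel ground truth, so the whole
   pipeline is testable without real micrographs.

It also includes the small experiment-design utilities used around such
experiments: thermal-time-equivalent sampling days (degree-days above a base
temperature) and nutrient-recipe nitrogen totals.

## Worked example

Generate a synthetic section and run the full pipeline against its ground
truth:

```python
from endograd import synthgrain

config = synthgrain.SynthConfig(seed=1)       # 1500 x 1000 px section
report = synthgrain.end_to_end_recovery(config)
print(f"max per-zone fraction error: {report.zone_fraction_max_abs_error:.4f}")
print(f"body recall/precision: {report.body_recall:.3f}/{report.body_precision:.3f}")
print(f"concentration slope: {report.conc_slope:.6f} per um "
      f"(programmed {report.conc_slope_programmed})")
print(f"log body-size slope: {report.size_slope:.6f} per um "
      f"(programmed {report.size_slope_programmed})")
```

prints

```
max per-zone fraction error: 0.0000
body recall/precision: 1.000/1.000
concentration slope: -0.000146 per um (programmed -0.00015)
log body-size slope: -0.001202 per um (programmed -0.0012)
```

i.e. the classifier recovers the rendered protein pixels essentially
exactly, every placed protein body is found (one-to-one midpoint matching
within 2 px), and the fitted outer-to-inner gradients in protein area
fraction (per µm) and in log body size reproduce the values the generator
was programmed with.

The same stages run on real data from the shell:

```bash
endograd simulate --out demo --seed 1          # or point at real inputs
endograd run --config run.yaml                 # manifest-driven batch
endograd thermal-time --day-temp 20 --night-temp 15 \
    --reference-days 14 --target-day-temp 28 --target-night-temp 15
```

`endograd run` writes `per_zone.csv`, `per_body.csv`, `calibration.csv` and
`gradients.csv`; the per-observation tables keep section, replicate and zone
identifiers so the full nested mixed model can be fitted in external
statistics software.

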