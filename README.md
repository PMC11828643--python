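# floodqc

Gamma-camera flood-field uniformity QC per NEMA NU 1-2018, plus the
agreement statistics used to compare uniformity readings between QC software
packages, and a seedable synthetic flood generator so the whole chain is
testable without a scanner.

**Who it is for:** medical physicists and nuclear-medicine technologists who
run daily/weekly intrinsic-uniformity tests on SPECT gamma cameras and want
an auditable, scriptable implementation of the NEMA analysis — in particular
for cross-checking the opaque QC software integrated into scanner consoles
against an independent computation.

## The analysis

An intrinsic-uniformity acquisition images a distant point source with the
collimator removed, stopping at a fixed total count (20,000 kilocounts on a
128 × 128 matrix in routine practice). The analysis is:

1. **Pixel-size gate.** The effective pixel must lie in 6.4 mm ± 30%
   (4.48–8.32 mm). Finer images are rebinned by summing k × k pixel blocks
   ("sum method", smallest k that lands in the window); coarser images
   cannot be repaired and only trigger a warning.
2. **Field-of-view masks.** The UFOV is the bounding box of strictly
   positive pixels; edge pixels below 75% of the central mean are peeled off
   iteratively (zero and cold periphery pixels never enter the statistics).
   The CFOV is the centered sub-rectangle spanning 75% of the UFOV's linear
   dimensions.
3. **Nine-point smoothing.** The masked image is filtered with the NEMA
   kernel [[1,2,1],[2,4,2],[1,2,1]]/16, renormalizing the weights over the
   in-mask neighbours at mask edges.
4. **Uniformity statistics.** Integral uniformity
   `IU = 100 · (max − min)/(max + min)` over all in-FOV pixels; differential
   uniformity `DU` is the worst such contrast over every run of 5 contiguous
   in-FOV pixels along rows (x) or columns (y). Six numbers result:
   IU, DUx, DUy on each of CFOV and UFOV.

The agreement layer compares two software readings of the same images:
percentage deviation (mean ± SD of paired differences), the Mann–Whitney U
test (midranks, tie-corrected variance, normal approximation, no continuity
correction), and Bland–Altman 95% limits of agreement — classic
(`bias ± 1.96·SD`) and regression-based, where OLS of the differences on the
pair means gives a bias line D(m), OLS of the absolute residuals gives R(m),
and the limits are `D(m) ± 1.96·√(π/2)·R(m)`.

## Worked example

```python
from floodqc import (AnalyzerConfig, DefectModel, PhantomSpec,
                     analyze_flood, generate_flood, run_study)

# a 128x128, 20,000-kilocount acquisition with a 2% sensitivity gradient
spec = PhantomSpec(defects=(DefectModel("gradient", 0.02),), seed=42)
img = generate_flood(spec)
for key, value in analyze_flood(img).as_dict(ndigits=2).items():
    print(f"{key:10s} {value:5.2f} %")
```

```
iu_cfov     4.68 %
iu_ufov     5.39 %
du_x_cfov   3.11 %
du_x_ufov   3.11 %
du_y_cfov   3.09 %
du_y_ufov   3.19 %
```

At ~1,221 expected counts per pixel, Poisson noise (≈2.9% per pixel)
dominates the 2% injected gradient even after smoothing — which is why the
UFOV integral uniformity sits near a 5% tolerance while the CFOV, which
excludes the extreme-prone periphery, reads lower. Comparing an analysis
variant with smoothing disabled against this reference over ten acquisitions:

```python
images = [generate_flood(spec, seed=s) for s in range(10)]
report = run_study(images,
                   AnalyzerConfig(name="integrated"),
                   [AnalyzerConfig(name="unsmoothed", smoothing_enabled=False)])
print(report.deviations.round(3).to_string(index=False))
mw = report.mannwhitney["unsmoothed"]["iu_ufov"]
print(mw.u, round(mw.z, 3), mw.mean_rank_a, mw.mean_rank_b)
```

```
   variant metric  fov  mean    sd
unsmoothed     iu cfov 6.446 0.804
unsmoothed     iu ufov 6.405 0.566
unsmoothed   du_x cfov 5.488 0.635
unsmoothed   du_x ufov 5.578 0.874
unsmoothed   du_y cfov 5.625 0.624
unsmoothed   du_y ufov 5.686 0.605
0.0 -3.78 5.5 15.5
```

The unsmoothed variant reads uniformly higher (positive mean deviations on
every metric), so the two groups of ten separate completely in the rank
test: U = 0, mean ranks 5.5 vs 15.5, z = −3.780, p < 0.001 — the signature
of one analysis route systematically reporting higher nonuniformity than
the other.

A `floodqc` command-line tool wraps the same chain:

```bash
floodqc simulate --spec spec.yaml --seed 1 --out flood.csv   # or .dcm
floodqc analyze flood.csv
floodqc study --images floods/ --reference ref.yaml \
              --variants nosmooth.yaml --out report/
```

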