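# srscell

Single-cell metabolic profiling from hyperspectral stimulated Raman
scattering (SRS) image stacks.

In hyperspectral SRS microscopy every pixel carries a Raman spectrum
*I(ν)*: C–H stretches (2800–3050 cm⁻¹) report protein and lipid content,
while the cell-silent window hosts the C–D band of deuterated metabolic
tracers (glucose-d₇, palmitic-acid-d₃₁, oleic-acid-d₃₄; 2050–2350 cm⁻¹) and
the sharp alkyne C≡C peak of the fatty-acid analog ODYA near 2100 cm⁻¹.
`srscell` turns such stacks into per-cell metabolic measurements:

1. **Spectral phasor segmentation** — each pixel spectrum is embedded at its
   first-harmonic Fourier coordinates normalized by total intensity,

       g = Σₖ Iₖ cos(2πhk/N) / Σₖ Iₖ,   s = Σₖ Iₖ sin(2πhk/N) / Σₖ Iₖ,

   where chemically similar pixels cluster regardless of brightness;
   clusters mapped back to the image plane give nuclei, lipid, C≡C and C–D
   component images.  A non-negative least-squares unmixing route against
   reference spectra provides an independent cross-check.
2. **Cell outlining and droplet detection** — nucleus-seeded watershed over
   the whole-cell foreground, plus size-filtered, watershed-split lipid
   droplet puncta assigned to the cell containing their centroid.
3. **Per-cell metrics and subpopulations** — integrated intensity, mean
   intensity, signal area fraction and droplet size per cell; lipid-poor vs
   lipid-rich subpopulations detected by BIC-selected Gaussian mixtures on
   log-intensity.
4. **The metabolic index** — for paired fatty-acid-uptake signal *F* and
   glucose-anabolism signal *G* measured on the same metric,

       M = F / (F + G)  ∈ [0, 1],

   a scale-invariant, per-cell readout of the switch from glucose-derived
   anabolism to fatty-acid uptake that accompanies platinum resistance.
5. **Resistance statistics** — 4-parameter-logistic IC₅₀ fitting with
   bootstrap confidence intervals, index-vs-IC₅₀ linear regression, ROC
   classification with a Youden-J operating threshold, and the assay
   arithmetic around them (OCR slopes, FAO rate, ΔCt, tumor volume,
   Seahorse respiration metrics, group t tests).

A synthetic-data module (`srscell.synthetic`) generates hyperspectral cell
phantoms, bimodal intensity populations, dose–response tables and
sensitive/resistant cohorts with known ground truth, so every stage is
testable without imaging data.

## Worked example

```python
import srscell as sc
from srscell.synthetic import dual_probe_components, make_component_spectrum

cc, cd = dual_probe_components()
spec = sc.PhantomSpec(
    image_shape=(256, 256), n_cells=15, wavenumber_range=(2050, 2350),
    components=(cc, cd),
    component_abundances={"nucleus": {}, "cytoplasm": {},
                          "droplet": {"CC_odya": 0.3, "CD_glucose": 0.7}},
    class_droplet_scale=(1.0, 1.0), seed=5,
)
stack, truth = sc.generate_cell_phantom(spec)
refs = {"CC": make_component_spectrum(cc, spec.wavenumbers),
        "CD": make_component_spectrum(cd, spec.wavenumbers)}
um = sc.unmix_dual_probe(stack, refs)
res = sc.index_from_dual_probe(um.abundances["CC"], um.abundances["CD"],
                               truth.cell_labels, metric="integrated")
print(f"M = {res.mean:.3f} +/- {res.sem:.3f}, n = {res.n_cells}")
```

prints

```
M = 0.301 +/- 0.000, n = 15
```

i.e. the per-cell metabolic index recovers the 0.3 : 0.7 C≡C : C–D signal
ratio the phantom was rendered with — a cell population drawing 30% of its
traced carbon from fatty-acid uptake.  The `examples/` directory holds one
narrative script per capability (phantom → cell table, subpopulation
detection, metabolic index, dose–response/ROC statistics, montage
stitching); each prints the numbers it computes and what they mean.

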