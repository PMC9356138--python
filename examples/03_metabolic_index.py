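"""Dual-probe unmixing and the per-cell metabolic index M = F/(F+G).

Renders a phantom whose droplets mix the alkyne (C#C, FA-uptake) and C-D
(glucose-anabolism) components at 0.3 : 0.7, unmixes the two probes by
non-negative least squares, and computes per-cell and per-sample metabolic
indices.  The recovered mean index should sit near 0.30 — the true FA
fraction of the rendered signal.
"""

import srscell as sc
from srscell.synthetic import dual_probe_components, make_component_spectrum

cc, cd = dual_probe_components()
spec = sc.PhantomSpec(
    image_shape=(256, 256),
    n_cells=15,
    wavenumber_range=(2050.0, 2350.0),
    components=(cc, cd),
    component_abundances={
        "nucleus": {},
        "cytoplasm": {},
        "droplet": {"CC_odya": 0.3, "CD_glucose": 0.7},
    },
    class_droplet_scale=(1.0, 1.0),
    noise=(0.05, 0.02),
    seed=5,
)
stack, truth = sc.generate_cell_phantom(spec)

refs = {
    "CC": make_component_spectrum(cc, spec.wavenumbers),
    "CD": make_component_spectrum(cd, spec.wavenumbers),
}
unmix = sc.unmix_dual_probe(stack, refs)
print(f"median unmixing residual: {float(unmix.residual.mean()):.4f} (QC)")

result = sc.index_from_dual_probe(
    unmix.abundances["CC"], unmix.abundances["CD"], truth.cell_labels,
    metric="integrated",
)
print(result.per_cell.round(3).to_string(index=False))
print(f"\nsample mean index M = {result.mean:.3f} +/- {result.sem:.3f} (SEM), "
      f"n = {result.n_cells} cells, {result.n_excluded} excluded")
print("M near 0.30 recovers the rendered 0.3 : 0.7 FA : glucose signal ratio;")
print("higher M would indicate a shift toward fatty-acid uptake.")
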