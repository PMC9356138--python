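"""Phantom field -> phasor segmentation -> per-cell lipid metrics.

Generates a noise-free C-H-window phantom, segments it by spectral phasor
clustering, outlines cells by nucleus-seeded watershed, and prints the
per-cell lipid table.  Integrated lipid intensity should split into a low
(lipid-poor) and a ~10x higher (lipid-rich) group, mirroring the phantom's
two-class design.
"""

import numpy as np

import srscell as sc
from srscell.phasor import spectrum_phasor
from srscell.synthetic import make_component_spectrum

spec = sc.PhantomSpec(image_shape=(256, 256), n_cells=12, noise=(0.0, 0.0), seed=7)
stack, truth = sc.generate_cell_phantom(spec)

field = sc.phasor_transform(stack)
refs = {
    "nuclei": spectrum_phasor(
        make_component_spectrum(spec.components[0], spec.wavenumbers)
    ),
    "lipid": spectrum_phasor(
        make_component_spectrum(spec.components[1], spec.wavenumbers)
    ),
}
clustering = sc.cluster_phasor(field, method="kmeans", k=3, references=refs, seed=0)
images = sc.map_clusters_to_images(clustering, field, names=["nuclei", "lipid"])

maps = sc.segment_field(
    images["nuclei"], field.dc, images["lipid"], cell_threshold=0.1
)
maps.validate()

table = sc.quantify_cells(
    maps.cell_labels,
    maps.droplet_labels,
    {"lipid": images["lipid"]},
    droplet_to_cell=maps.droplet_to_cell,
)
print(table[["cell_id", "area_px", "integrated_lipid", "mean_lipid",
             "area_fraction_lipid", "droplet_count"]].to_string(index=False))
print(f"\n{len(table)} cells retained (edge-touching cells excluded).")
print("integrated_lipid sums each cell's lipid-map pixels; the bimodal spread")
print("separates lipid-poor from lipid-rich cells.")
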