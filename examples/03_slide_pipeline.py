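"""Preprocess a synthetic pyramidal slide into an embedding store.

Generates a small multi-resolution slide (white background, tissue blobs, a
marker-pen artifact), runs the preparation pipeline — thumbnail tissue
masking, artifact filtering, tile mapping, acceptance, augmentation,
encoding — and writes the result to an HDF5 embedding store, printing the
per-stage counters.
"""

import tempfile
from pathlib import Path

from slidemil.pipeline import PrepConfig, prep_slide
from slidemil.store import ReferenceEncoder, read_store, write_store
from slidemil.synthetic import SlideGenConfig, gen_slide

cfg = SlideGenConfig(base_size=1024, n_levels=3, n_blobs=3,
                     blob_radius_range=(0.18, 0.3))
pyramid, truth = gen_slide(cfg, seed=5)
print(f"pyramid levels: {pyramid.level_dimensions}")
print(f"true tissue fraction at base: {truth.tissue_mask.mean():.3f}")

prep_cfg = PrepConfig(magnification="5x", base_magnification="5x", encoder_d=256)
res = prep_slide(pyramid, "demo-slide", 1, prep_cfg, seed=0,
                 encoder=ReferenceEncoder(d=256))
for key, value in sorted(res.counters.items()):
    print(f"  {key}: {value}")
print(res.manifest.to_string(index=False))

with tempfile.TemporaryDirectory() as td:
    store = Path(td) / "store.h5"
    write_store(store, [res.group])
    bag = read_store(store, include_augmented=True)[0]
    print(f"\nstored bag: {bag.n} instances of length {bag.d} "
          f"(originals + 2 augmentations each), label {bag.label}")
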