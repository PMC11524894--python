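"""Tile-based inference with a stand-in segmenter.

Plans a 512 px grid over an oddly sized raster, applies a deterministic
per-pixel stand-in segmenter tile by tile, and verifies the stitched
whole-slide mask is bit-identical to applying the segmenter to the whole
raster at once — the harness adds no post-filtering or seam artifacts.
"""

import numpy as np

import lungquant as lq

legend = lq.default_legend()
rng = np.random.default_rng(0)
image = rng.integers(0, 256, size=(1300, 900)).astype(np.uint8)

grid = lq.plan_grid(*image.shape, tile_size=512)
print(f"image {image.shape} -> {len(grid.tiles)} tiles "
      f"(edge tiles are smaller, no padding)")

toy = lq.make_toy_segmenter(legend)
stitched = lq.run_inference(image, toy, grid, legend)
whole = toy(image)
print("stitched == whole-image result:",
      bool(np.array_equal(stitched.labels, whole)))
# True: for any deterministic per-pixel segmenter, tiling is lossless.
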