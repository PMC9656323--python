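# veinmap

NIR vein-image enhancement with digital hair removal, plus a synthetic
phantom harness for verifying it.

Veins image dark under near-infrared light, but the raw captures carry a
lighting gradient, sensor noise and — worst of all — body hair, which any
contrast enhancement amplifies into vein-like artifacts. This package
implements the full processing chain:

* **illumination** — background estimation with a large mean filter and
  "reverse component" flattening of nonuniform lighting;
* **morphology** — binary and grayscale dilation/erosion (plus opening,
  closing and Blackhat) built directly on the additive max/min
  definitions, with a 3×3 cross as the default structuring element;
* **hair_removal** — Blackhat detection of thin dark strokes, Otsu
  binarization, mask growth, and fill-in by fast-marching inpainting;
* **inpainting** — a from-scratch Telea-style fast-marching inpainter
  (Eikonal distance ordering; direction / distance / level-set weights);
* **enhancement** — the six-stage vein visibility pipeline: light removal,
  histogram normalization, histogram equalization, Otsu noise
  thresholding, grayscale dilation, unsharp sharpening, median smoothing;
* **phantom** — a seeded generator of synthetic NIR test images with exact
  ground truth (vessel layer drawn at gray 57–62 and 15–20 px stroke
  width, composited under an 85%-transparency base, plus hair strokes and
  a lighting tilt);
* **evaluation** — the verification protocol: binarize outputs, render
  masks as 0/255 images, score against the ground-truth vessel layer with
  SSIM (11×11 Gaussian window, σ=1.5), and average over a dataset.

Everything is deterministic: fixed seeds and configs reproduce outputs
byte-for-byte.

## CLI

```sh
# enhance one image (normal mode / hair-removal mode)
veinmap enhance in.png out.png
veinmap enhance --hair-removal --dump-stages stages/ in.png out.png

# hair detection and inpainting as standalone steps
veinmap detect-hair in.png mask.png
veinmap inpaint --mask mask.png in.png out.png

# generate a 10-image phantom dataset and score both modes on it
veinmap --seed 9 simulate --spec phantom.yaml --n 10 --out dataset/
veinmap evaluate --dataset dataset/ --hair-removal on --report report.json
```

Global flags `--config cfg.yaml` (YAML, sections `illumination`,
`inpaint`, `hair`, `enhance`, `ssim`, `phantom`) and `--seed` come before
the subcommand; CLI flags override the config file, which overrides the
built-in defaults. Exit codes: 0 success, 1 usage error, 2 processing
error.

## Tests and acceptance

```sh
python -m pytest -q                # unit + property + acceptance suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script re-runs the whole verification protocol from
scratch — brute-force oracle equivalence for morphology and Otsu,
closed-form histogram checks, inpainting and illumination contracts,
hair-removal recovery on seeded phantoms, and the directional phantom
study (hair-removal mode beats normal mode on hairy images; the enhanced
output beats the raw image on hairless ones) — logging results to stderr.
The emitted JSON is empty because the upstream SSIM tables were measured
on a private dataset against a proprietary comparator and are not
recomputable; the phantom study stands in for them.
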