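"""Write a ground-truthed synthetic H+DAB cohort to disk.

Produces PNG images plus a ground-truth CSV (image_id, tier) and JSON
(true stain matrix and full generator settings), ready for the `ihcscore
score` command or any external tool.
"""

import json
from pathlib import Path

from ihcscore import SynthConfig, generate_cohort, write_image

out = Path("synthetic_cohort")
out.mkdir(exist_ok=True)

cfg = SynthConfig(n_images=20, seed=42)
images, truth = generate_cohort(cfg)

rows = ["image_id,tier"]
for i, im in enumerate(images):
    name = f"synth_{i:04d}"
    write_image(out / f"{name}.png", im)
    rows.append(f"{name},{truth.tiers[i]}")
(out / "ground_truth.csv").write_text("\n".join(rows) + "\n")
(out / "ground_truth.json").write_text(
    json.dumps({"true_w": truth.true_w.tolist(), "seed": cfg.seed}, indent=2)
)

print(f"wrote {len(images)} images to {out}/ with ground truth")
print("score them with:  ihcscore score 'synthetic_cohort/*.png' --out scored")
# tier 1 images are near-negative controls (mean DAB optical density 0.05);
# tier 5 images are strongly stained (mean 2.5) — the spread a real
# semi-quantitative scoring study covers.
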