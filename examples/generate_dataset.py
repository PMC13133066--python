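"""Generate a small synthetic radiograph-like dataset and inspect it.

Renders image/mask pairs whose noise and contrast depend on the race-gender
subgroup, splits them 70/10/20 with demographic stratification, and writes
PNG pairs plus a metadata CSV.
"""

from collections import Counter
from pathlib import Path

from fairseg import GenerationSpec, generate_dataset, save_dataset, stratified_split

spec = GenerationSpec(n_samples=40, image_size=(64, 64), seed=0)
samples = generate_dataset(spec)
stratified_split(samples, seed=0)

out = Path("scratch/example_dataset")
save_dataset(samples, out)

print(f"wrote {len(samples)} samples to {out}")
print("group counts:", dict(Counter(r.group.code for r in samples)))
print("split counts:", dict(Counter(r.split for r in samples)))
img = samples[0].image
print(f"first sample: intensities in [{img.min():.2f}, {img.max():.2f}], "
      f"{(samples[0].mask > 0).mean():.0%} foreground pixels")
# Each race-gender group received 10 samples; splits preserve the group mix.
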