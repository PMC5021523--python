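"""Image-based simulation: the surround amplifies attention.

Tiles a synthetic 1/f scene with divisive-normalization model neurons
(excitatory Gaussian sigma 8 px, suppressive sigma 40 px), applies a
Gaussian attention field (sigma 5 px, amplitude 6) at the image centre,
and compares the attention-modulation maps with and without suppression
from outside the classical receptive field (radius 16 px).
"""

import numpy as np

from attnorm.image import make_test_image, run_image_simulation

img = make_test_image(128, seed=0)
locus = (64, 64)
maps = run_image_simulation(img, locus)

yy, xx = np.mgrid[:128, :128]
near = (yy - locus[0]) ** 2 + (xx - locus[1]) ** 2 <= 15**2

m_with = np.abs(maps["modulation"][near]).mean()
m_without = np.abs(maps["modulation_nosurround"][near]).mean()

print(f"mean |attention modulation| near the locus, with surround:    {m_with:.4f}")
print(f"mean |attention modulation| near the locus, without surround: {m_without:.4f}")
print(f"amplification ratio: {m_with / m_without:.2f}x")
print()
print("With a wide suppressive surround, the attention field boosts local")
print("excitation much more than the broadly-pooled suppression, so the")
print("response ratio moves; without a surround both pools are boosted")
print("almost equally and attention barely changes the response.")
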