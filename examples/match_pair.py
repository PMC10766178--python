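"""Score a developed latent sample against its inked control.

Generates a genuine synthetic pair (same finger: powder-developed sample and
inked control related by a known rigid transform), runs the full comparison
pipeline, and contrasts the score with an impostor comparison (a control
from a different finger).
"""

import lfpmatch as lm

genuine = lm.generate_pair(lm.SynthParams(pattern="whorl", seed=2))
other = lm.generate_pair(lm.SynthParams(pattern="whorl", seed=9))

res = lm.compare_images(genuine.sample, genuine.control)
print(f"genuine pair:  P = {res.P:.4f}  matching score = {res.percent:.2f}%  "
      f"({res.m_used} corresponding feature points)")

imp = lm.compare_images(genuine.sample, other.control)
print(f"impostor pair: P = {imp.P:.4f}  matching score = {imp.percent:.2f}%  "
      f"({imp.m_used} corresponding feature points)")
print("P close to 1 means every paired point sits at the same distance from "
      "its core in both images; the genuine pair should score higher.")
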