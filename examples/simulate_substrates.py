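"""Synthetic latent prints on the five substrate archetypes.

Generates the same finger developed on paper, metal, plastic, glass and
wood, scores each against the shared inked control, and prints the
per-substrate matching scores (the background interference differs per
substrate, so the scores differ too).
"""

import lfpmatch as lm
from lfpmatch.errors import LfpError

for substrate in lm.synthgen.SUBSTRATES:
    pair = lm.generate_pair(
        lm.SynthParams(pattern="whorl", substrate=substrate, seed=4)
    )
    try:
        res = lm.compare_images(pair.sample, pair.control)
        print(f"{substrate:8s}: matching score {res.percent:6.2f}%  (m = {res.m_used})")
    except LfpError as e:
        print(f"{substrate:8s}: comparison failed - {e}")
print("Higher scores mean the developed ridges survived that substrate's "
      "background texture better.")
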