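"""Scan a protein sequence for predicted cleavage sites.

Builds a PWM from synthetic substrates, plants one high-scoring window in a
random 60-mer, and prints every bond whose score reaches the threshold:
its P1 position, the P3-P2' window, the 10-residue context and the score.
"""

import numpy as np

from pwmcleave import (
    CVConfig, MotifSpec, generate_background, generate_substrates,
    peaked_motif, scan_sequence, train_final_model,
)

spec = MotifSpec(columns=peaked_motif("PSALD", weight=0.7), seed=1)
pwm, _ = train_final_model(generate_substrates(spec), generate_background(spec),
                           CVConfig(seed=1), enzyme="SYN")

rng = np.random.default_rng(4)
seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
seq = seq[:30] + "PSALD" + seq[35:]  # plant the motif: P1 at residue 33

print(f"threshold = {pwm.threshold:g}")
for site in scan_sequence(pwm, seq, "demo"):
    if site.above_threshold:
        print(f"P1 at {site.p1_position:3d}  window {site.window}  "
              f"context {site.context10}  score {site.score:6.2f}")
# each line is one predicted scissile bond; the planted site at P1=33
# should appear with the top score
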