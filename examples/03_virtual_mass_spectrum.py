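"""Virtual mass spectrum of a predicted digest.

Predicts cleavage sites in a synthetic protein and enumerates every
contiguous fragment between cut boundaries (partial digest) with its
neutral monoisotopic mass and a score-derived intensity: 100 * ws1 * ws2,
where each ws is the boundary's PWM score normalised to [0, 1] (protein
termini count 1.0).
"""

from pwmcleave import (
    CVConfig, MotifSpec, generate_background, generate_proteins,
    generate_substrates, peaked_motif, scan_sequence, train_final_model,
    virtual_spectrum,
)

spec = MotifSpec(columns=peaked_motif("PSALD", weight=0.7), seed=1)
pwm, _ = train_final_model(generate_substrates(spec), generate_background(spec),
                           CVConfig(seed=1), enzyme="SYN")
protein = generate_proteins(spec, n_proteins=1, length=120, sites_per_protein=2,
                            seed=1)[0]

sites = [s for s in scan_sequence(pwm, protein.sequence) if s.above_threshold]
fragments = virtual_spectrum(pwm, protein.sequence, sites, digest="partial")

n = len(sites)
print(f"{n} predicted sites -> {len(fragments)} fragments "
      f"(= (n+1)(n+2)/2 = {(n + 1) * (n + 2) // 2})")
print(f"{'span':>9}  {'mass (Da)':>12}  intensity")
for f in fragments[-8:]:
    print(f"{f.start:4d}-{f.end:<4d}  {f.mass:12.4f}  {f.intensity:9.2f}")
# the full-length fragment always has intensity 100 (both termini weigh 1.0);
# internal boundaries weigh fragments by their cleavage-site scores
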