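"""Codon and amino-acid stabilization coefficients on synthetic truth.

Plants positive effects for two codons and negative for two others, then
shows that the CSC pipeline recovers the planted signs with significance
tiers, and summarizes amino-acid-level structure.
"""

import codonstab as cs

planted = {"GTG": 8.0, "GCC": 6.0, "AGT": -8.0, "CAT": -6.0}
config = cs.SimulationConfig(n_transcripts=1000, seed=5, beta_codon=planted)

records, manifest = cs.generate_transcriptome(config)
halflives = cs.generate_halflives(manifest, config)
print(f"{config.n_transcripts} synthetic transcripts, median half-life "
      f"{halflives['half_life'].median():.2f} h (right-skewed by construction)")

csc = cs.compute_csc(manifest.codon_freq, halflives)
print("\ncodon   planted beta   CSC      p          tier")
for codon, beta in planted.items():
    row = csc.loc[codon]
    print(f"{codon}    {beta:+5.1f}        {row['csc']:+.3f}  {row['p_value']:.2e}  {row['tier']}")

n_stab = int((csc["tier"] == "stabilizing").sum())
n_destab = int((csc["tier"] == "destabilizing").sum())
print(f"\n{n_stab} stabilizing / {n_destab} destabilizing codons at p < 0.01; "
      f"{int(csc['genome_wide'].sum())} at genome-wide significance (p < 5e-8)")

aasc = cs.compute_aasc(manifest.aa_freq, halflives)
print(f"exclusive multi-codon amino acids (all synonymous CSCs share a sign): "
      f"{cs.count_exclusive_amino_acids(csc)}/18")
# Planted codon effects propagate to the encoded amino acids (Val here via
# GTG), which is why codon- and amino-acid-level coefficients travel together.
print(f"AASC of V = {aasc.loc['V','aasc']:+.3f} (GTG is a Val codon)")
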