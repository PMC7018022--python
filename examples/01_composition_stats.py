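"""Composition statistics of coding sequences.

Builds a three-ORF toy transcriptome, then prints codon frequencies, GC/GC3
content, the translation, and homopolymeric amino-acid repeats.
"""

import codonstab as cs

orfs = [
    cs.CodingSequence("toy1", "ATG" + "GTG" * 6 + "AGC" * 4),       # Val/Ser rich
    cs.CodingSequence("toy2", "ATG" + "CAGCAGCAGCAGCAGCAG" + "TTT"),  # poly-Q
    cs.CodingSequence("toy3", "ATGGCCGCTGCAGCGAAA"),                 # 4 Ala codons
]

for orf in orfs:
    protein = cs.translate_cds(orf)
    gc, gc3 = cs.composition_stats(orf)
    print(f"{orf.id}: {len(orf)//3} codons, protein {protein}")
    print(f"  GC = {gc:.3f}, GC3 = {gc3:.3f}   (fractions of bases / wobble positions that are G|C)")
    freqs = cs.codon_frequencies(orf, frame=0).freq
    top = sorted(freqs.items(), key=lambda kv: -kv[1])[:3]
    print("  top codon frequencies:", ", ".join(f"{c}={f:.2f}" for c, f in top))
    repeats = cs.find_homopolymer_repeats(protein, orf.id, min_length=5)
    for rep in repeats:
        print(f"  homopolymer: {rep.amino_acid} x {rep.length} starting at residue {rep.start}")

# The poly-Q run in toy2 (Q x 6 at residue 2) is the kind of repeat whose
# presence stratifies mRNA half-life when the repeated amino acid is
# strongly stabilizing or destabilizing.
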