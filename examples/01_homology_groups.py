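"""Group mature miRNA sequences into homolog families.

Two sequences are homologous when the Hamming distance of their global
alignment (match +5, mismatch -4, gap open -10, gap extend -0.5) is below
10 % of the alignment length; families are connected components of the
pairwise relation.
"""

from mitomirs.alignment import align_global, group_sequences, is_homologous

a = "UGAGGUAGUAGGUUGUAUAGUU"  # a let-7-style 22-mer
b = "UGAGGUAGUAGGUUGUGUAGUU"  # one substitution
c = "UGAGGUAGUAGAUUGUGUAGCU"  # three substitutions from a

res = align_global(a, b)
print(f"alignment score {res.score}, length {res.length}, differing columns {res.hamming}")
print(f"a ~ b homologous: {is_homologous(a, b)}   (1/22 = 4.5% divergence, below 10%)")
print(f"a ~ c homologous: {is_homologous(a, c)}   (3/22 = 13.6% divergence, above 10%)")

groups = group_sequences({"mir-A": a, "mir-B": b, "mir-C": c})
for g in groups:
    print(f"group {g.group_id}: {sorted(g.members)}")
# b links a and c into one family only if both pairs pass; here a~b and b~c
# decide the partition — the component is the unit of deduplication later.
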