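"""Compute the 92-dimensional NVDT natural vector of a short CDS.

The vector collects, per nucleotide k: the count n_k, the mean 1-based
position mu_k, and the second normalized central moment D2_k of the
position distribution — then appends the 16 dinucleotide and 64
trinucleotide counts that capture codon-scale composition.
"""

from nvdt import GeneSequence, natural_vector, feature_names

seq = GeneSequence("demo", "AATA")
names = feature_names("NVDT")
vec = natural_vector(seq, "NVDT")

print(f"sequence {seq.id!r} = {seq.seq}  (N = {seq.N})")
print(f"NVDT vector length: {len(vec)}")
for name, value in zip(names, vec):
    if value:
        print(f"  {name:>6s} = {value:.5f}")
# mu_A = 7/3 because A sits at positions 1, 2 and 4; D2_A = 7/18 is the
# normalized spread of those positions; AA/AT/TA and AAT/ATA are the only
# k-mer windows present, so all other 92-vector entries are zero.
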