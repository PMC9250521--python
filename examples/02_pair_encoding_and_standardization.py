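"""Encode a protein pair under the five combination schemes and Z-score it.

Cod1 = |A-B|, Cod2 = A+B, Cod3 = (|A-B|, A+B), Cod4 = A*B, Cod5 = (A, B).
Cod5 juxtaposition (184 features for NVDT) retains the most information and
is the default.  Standardization statistics come from training pairs only.
"""

import numpy as np

from nvdt import (GeneSequence, natural_vector, encode_pair, Standardizer,
                  SCHEMES)

a = natural_vector(GeneSequence("a", "ATGGCACGTTGCTAA"))
b = natural_vector(GeneSequence("b", "ATGCCCGGGAAATTT"))

for scheme in SCHEMES:
    v = encode_pair(a, b, scheme)
    print(f"{scheme}: dim {v.shape[0]}, first entries {np.round(v[:3], 3)}")

# Z-score a small 'training' matrix of pair vectors: each non-constant
# column ends up with mean 0 and population std 1.
train = np.vstack([encode_pair(a, b, "Cod5"),
                   encode_pair(b, a, "Cod5"),
                   encode_pair(a, a, "Cod5")])
std = Standardizer()
z = std.fit_transform(train)
keep = ~std.zero_variance
print(f"\nstandardized {z.shape[0]} pairs x {z.shape[1]} features; "
      f"{keep.sum()} non-constant columns")
print("max |column mean| =", float(np.abs(z[:, keep].mean(axis=0)).max()))
print("max |column std - 1| =",
      float(np.abs(z[:, keep].std(axis=0) - 1).max()))
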