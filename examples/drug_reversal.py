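"""Query drug signatures for reversal of a convergent expression signature.

Builds a collection of ranked drug signatures (three per drug, plus
vehicle nulls), queries the top/bottom convergent genes against each, and
flags reversers: NCS <= -1.00 at FDR <= 0.05.
"""

import numpy as np
import pandas as pd

from pertconv.behavior import RankedSignature, cmap_query

rng = np.random.default_rng(9)
genes = [f"g{i}" for i in range(100)]
signature_shape = np.linspace(5, -5, 100)  # the convergent DE profile

sigs = []
for drug, flip in [("mimic", 1), ("reverser", -1)]:
    for rep, mix in enumerate([1.0, 0.15, 0.1]):
        noise = rng.permutation(signature_shape)
        scores = flip * (mix * signature_shape + (1 - mix) * noise)
        sigs.append(
            RankedSignature(f"{drug}_rep{rep}", drug, pd.Series(scores, index=genes))
        )
for i in range(8):
    sigs.append(
        RankedSignature(
            f"dmso_{i}", "dmso",
            pd.Series(rng.permutation(signature_shape), index=genes), is_null=True,
        )
    )

query_up = set(genes[:10])     # genes up in the convergent signature
query_down = set(genes[-10:])  # genes down

df = cmap_query(query_up, query_down, sigs)
print(df[["group_id", "wtcs", "ncs", "fdr", "reverser"]].round(3))
reversers = df[df["reverser"]]
print(f"\nflagged reversers: {list(reversers.index)}")
print("A negative WTCS means the drug pushes the query's up-genes down")
print("and down-genes up; NCS <= -1 with low FDR marks a reverser whose")
print("connectivity is stronger than its group average and the vehicle null.")
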