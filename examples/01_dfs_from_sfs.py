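"""Compute a D frequency spectrum from a small joint SFS built by hand.

Builds a three-population joint spectrum with an engineered excess of
low-frequency derived alleles shared between P2 and P3, computes D and its
frequency-stratified decomposition, and prints the per-bin table.
"""

import numpy as np

from dfspectrum import JointSFS, dfs_from_joint_sfs

n = 8
rng = np.random.default_rng(1)

# symmetric background (pure incomplete lineage sorting: equal ABBA and BABA)
background = rng.integers(0, 40, (n + 1, n + 1, n + 1)).astype(float)
background = background + background.transpose(1, 0, 2)

# introgression-like excess: sites where the derived allele is rare in P2,
# absent in P1, and common in P3
counts = background.copy()
counts[0, 1, 6] += 1500
counts[0, 2, 7] += 700

result = dfs_from_joint_sfs(JointSFS(counts))
print(result.to_frame().to_string(index=False, float_format=lambda x: f"{x: .4f}"))
print(f"\noverall D = {result.d_overall:.4f} "
      f"(ABBA {result.abba_total:.1f}, BABA {result.baba_total:.1f})")
print("The low-frequency bins (k = 1, 2) carry the excess: exactly the "
      "signature of recent gene flow into P2, while high bins stay near zero.")
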