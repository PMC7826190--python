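"""Render the D frequency spectrum bar figure for a simulated scenario.

Simulates recent gene flow from P3 into P2 and saves the standard figure:
bars at frequency k/n with height D_k and width proportional to the bin
weight w_k, a dashed line at the overall D.
"""

from dfspectrum import dfs_from_joint_sfs, preset, save_dfs_plot, simulate_joint_sfs

sim = simulate_joint_sfs(preset("recent_geneflow"), (8, 8, 8), 50_000, seed=99)
result = dfs_from_joint_sfs(sim.sfs)
save_dfs_plot(result, "recent_geneflow_dfs.svg",
              title="Recent gene flow from P3 into P2")
print(f"overall D = {result.d_overall:.3f}; figure: recent_geneflow_dfs.svg")
print("Wide low-frequency bars with large positive D_k are the hallmark of "
      "recent introgression; the wide fixed-allele bar shows the inverted "
      "signal carried by anciently sorted variation.")
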