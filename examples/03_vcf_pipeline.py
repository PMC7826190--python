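"""Full VCF pipeline on a synthetic fixture: read, filter, polarize, bin.

Writes a small synthetic VCF with a known joint SFS, runs it through the
standard pipeline (biallelic SNP filter, call-rate filter, outgroup
polarization, hypergeometric binning) and verifies the round trip.
"""

import tempfile
from collections import Counter
from pathlib import Path

import numpy as np

from dfspectrum import (FilterConfig, PopulationMap, dfs_from_joint_sfs,
                        make_fixture_vcf, vcf_to_joint_sfs)

pops = {"P1": 3, "P2": 3, "P3": 3, "outgroup": 2}
popmap = PopulationMap({f"{role}_{i}": role
                        for role, n in pops.items() for i in range(n)})

with tempfile.TemporaryDirectory() as tmp:
    vcf = Path(tmp) / "synthetic.vcf"
    truth = make_fixture_vcf(vcf, pops, n_sites=500, seed=7, ploidy=2,
                             frac_alt_ancestral=0.4,
                             frac_outgroup_polymorphic=0.05)
    counters = Counter()
    sfs = vcf_to_joint_sfs(vcf, popmap, (6, 6, 6), FilterConfig(), counters)

print("filter / polarization accounting:")
for key, val in sorted(counters.items()):
    print(f"  {key:28s} {val}")
print("round trip exact:", bool(np.array_equal(sfs.counts, truth.sfs.counts)))

r = dfs_from_joint_sfs(sfs)
print(f"D = {r.d_overall:+.4f}; per-bin D_k = {np.round(r.d, 3)}")
print("The fixture draws each population's frequency independently, so any "
      "nonzero D here is sampling noise; the accounting shows every input "
      "site either used or attributed to a specific filter.")
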