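"""Independent per-site brute-force reference for the D frequency spectrum.

Expands a joint SFS (or an explicit site list) into individual sites and
applies the ABBA/BABA definitions site by site with plain Python floats —
no shared code with the tensorized implementation under test.
"""

import math


def sites_from_sfs(counts):
    """Expand an integer-count 3D SFS into a list of (i1, i2, i3) sites."""
    sites = []
    n1, n2, n3 = (s - 1 for s in counts.shape)
    for i1 in range(n1 + 1):
        for i2 in range(n2 + 1):
            for i3 in range(n3 + 1):
                c = counts[i1, i2, i3]
                assert float(c).is_integer(), "oracle needs integer site counts"
                sites.extend([(i1, i2, i3)] * int(c))
    return sites


def per_site_dfs(sites, n, n3):
    """Site-by-site D frequency spectrum; returns a plain dict.

    ``sites`` is an iterable of derived-allele counts (i1, i2, i3) with
    common P1/P2 sample size ``n`` and P3 size ``n3``.
    """
    abba_bins = [0.0] * (n + 1)   # indexed by i2
    baba_bins = [0.0] * (n + 1)   # indexed by i1
    for i1, i2, i3 in sites:
        p1, p2, p3 = i1 / n, i2 / n, i3 / n3
        abba_bins[i2] += (1 - p1) * p2 * p3
        baba_bins[i1] += p1 * (1 - p2) * p3
    abba_total = sum(abba_bins)
    baba_total = sum(baba_bins)
    total = abba_total + baba_total
    d = []
    w = []
    for k in range(1, n + 1):
        denom = abba_bins[k] + baba_bins[k]
        d.append((abba_bins[k] - baba_bins[k]) / denom if denom > 0 else math.nan)
        w.append(denom / total if total > 0 else 0.0)
    d_overall = (abba_total - baba_total) / total if total > 0 else math.nan
    return {
        "d": d, "w": w, "d_overall": d_overall,
        "abba_total": abba_total, "baba_total": baba_total,
    }
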