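"""The D-statistic and its stratification by derived-allele frequency (D_FS).

Given three populations and an outgroup related as (((P1, P2), P3), O), each
biallelic site contributes

    c_ABBA = (1 - p1) * p2 * p3        c_BABA = p1 * (1 - p2) * p3

where ``p_j`` is the derived-allele frequency in population ``j`` (the
outgroup is assumed fixed ancestral).  Patterson's D is the normalized
difference of the genome-wide sums:

    D = (sum c_ABBA - sum c_BABA) / (sum c_ABBA + sum c_BABA).

The D frequency spectrum partitions this signal by the derived-allele count
``k``: bin ``k`` collects ABBA contributions from sites where the derived
allele occurs ``k`` times in P2 and BABA contributions from sites where it
occurs ``k`` times in P1 (requiring equal sample sizes n1 = n2 = n).  Each
bin carries a weight ``w_k``, its share of the total ABBA+BABA mass, so that
``sum_k w_k D_k = D`` exactly.  Recent introgression from P3 into P2
concentrates positive D_k at low k; ancient introgression pushes the signal
toward the fixed bin k = n; bottlenecks and ancestral structure produce
their own characteristic shapes even when overall D is ~0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sfs import JointSFS, project_joint_sfs

logger = logging.getLogger(__name__)

__all__ = [
    "pattern_weights",
    "d_statistic",
    "dfs_from_joint_sfs",
    "DFSResult",
    "bootstrap_dfs_se",
    "DFSStandardErrors",
]


def pattern_weights(p1, p2, p3):
    """Per-site ABBA and BABA contributions from derived-allele frequencies.

    Returns ``(c_abba, c_baba)`` with ``c_abba = (1 - p1) p2 p3`` and
    ``c_baba = p1 (1 - p2) p3``.  Accepts scalars or broadcastable arrays;
    all frequencies must lie in [0, 1].
    """
    p1, p2, p3 = np.asarray(p1, float), np.asarray(p2, float), np.asarray(p3, float)
    for name, p in (("p1", p1), ("p2", p2), ("p3", p3)):
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    c_abba = (1.0 - p1) * p2 * p3
    c_baba = p1 * (1.0 - p2) * p3
    if c_abba.ndim == 0:
        return float(c_abba), float(c_baba)
    return c_abba, c_baba


def d_statistic(abba_sum: float, baba_sum: float) -> float:
    """Patterson's D from summed ABBA and BABA contributions.

    Returns NaN (the undefined-result signal) when both sums are zero.
    """
    if abba_sum < 0 or baba_sum < 0:
        raise ValueError("ABBA/BABA sums must be non-negative")
    total = abba_sum + baba_sum
    if total == 0:
        return math.nan
    return (abba_sum - baba_sum) / total


@dataclass
class DFSResult:
    """The D frequency spectrum of a polarized joint SFS.

    Attributes
    ----------
    n
        Number of frequency bins (= common haploid sample size of P1 and P2).
        Bin ``k`` corresponds to derived-allele count ``k``, i.e. frequency
        ``k / n``; the structurally empty bin k = 0 is omitted.
    d
        Length-``n`` array of stratified D values; entry ``k - 1`` holds
        ``D_k``.  NaN marks bins with no ABBA+BABA mass (undefined, not 0).
    w
        Length-``n`` array of bin weights in [0, 1]; NaN bins have weight 0;
        weights sum to 1 whenever any mass is present.
    abba_k, baba_k
        Per-bin ABBA and BABA mass (entry ``k - 1`` for bin ``k``).
    d_overall, abba_total, baba_total
        The unpartitioned D-statistic and its two component sums.
    """

    n: int
    d: np.ndarray
    w: np.ndarray
    abba_k: np.ndarray
    baba_k: np.ndarray
    d_overall: float
    abba_total: float
    baba_total: float

    @property
    def k(self) -> np.ndarray:
        return np.arange(1, self.n + 1)

    @property
    def freq(self) -> np.ndarray:
        return self.k / self.n

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of bins with positive ABBA+BABA mass."""
        return ~np.isnan(self.d)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k, "freq": self.freq, "D_k": self.d, "w_k": self.w})

    def to_tsv(self, path) -> None:
        """Write the per-bin table with a header comment carrying the totals."""
        with open(path, "w") as fh:
            fh.write(
                f"# d_overall={float(self.d_overall)!r}\tabba_total={float(self.abba_total)!r}\t"
                f"baba_total={float(self.baba_total)!r}\tn={self.n}\n"
            )
            fh.write("k\tfreq\tD_k\tw_k\n")
            for k, f, d, w in zip(self.k, self.freq, self.d, self.w):
                dtxt = "" if np.isnan(d) else repr(float(d))
                fh.write(f"{k}\t{float(f)!r}\t{dtxt}\t{float(w)!r}\n")

    @classmethod
    def from_tsv(cls, path) -> "DFSResult":
        meta = {}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for item in first[1:].strip().split("\t"):
                    key, _, val = item.partition("=")
                    meta[key.strip()] = val
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", comment="#")
        n = int(meta.get("n", len(df)))
        d = np.full(n, np.nan)
        w = np.zeros(n)
        d[df["k"].to_numpy() - 1] = df["D_k"].to_numpy()
        w[df["k"].to_numpy() - 1] = df["w_k"].to_numpy()
        abba_total = float(meta.get("abba_total", np.nan))
        baba_total = float(meta.get("baba_total", np.nan))
        d_overall = float(meta.get("d_overall", np.nan))
        return cls(n=n, d=d, w=np.nan_to_num(w), abba_k=np.full(n, np.nan),
                   baba_k=np.full(n, np.nan), d_overall=d_overall,
                   abba_total=abba_total, baba_total=baba_total)


def _pattern_tensors(n1: int, n2: int, n3: int) -> tuple[np.ndarray, np.ndarray]:
    p1 = (np.arange(n1 + 1) / n1)[:, None, None]
    p2 = (np.arange(n2 + 1) / n2)[None, :, None]
    p3 = (np.arange(n3 + 1) / n3)[None, None, :]
    return (1.0 - p1) * p2 * p3, p1 * (1.0 - p2) * p3


def dfs_from_joint_sfs(sfs: JointSFS) -> DFSResult:
    """Compute the D frequency spectrum from a polarized joint SFS.

    P1 and P2 must have equal sample sizes; if they differ, both are first
    projected down to the smaller size (with a logged notice).  Bin ``k``
    sums ABBA mass over cells with ``i2 = k`` and BABA mass over cells with
    ``i1 = k``; ``D_k`` is their normalized difference and ``w_k`` their
    share of the total.  Bins with zero mass get ``D_k = NaN``, ``w_k = 0``.

    Raises a ValueError if the SFS is not polarized; returns NaN for
    ``d_overall`` (and all bins) when the spectrum carries no ABBA+BABA mass.
    """
    if not sfs.polarized:
        raise ValueError("D frequency spectrum requires a polarized (unfolded) joint SFS")
    n1, n2, n3 = sfs.sample_sizes
    if n1 != n2:
        n = min(n1, n2)
        logger.info("unequal P1/P2 sample sizes (%d, %d); projecting both to %d", n1, n2, n)
        sfs = project_joint_sfs(sfs, (n, n, n3))
        n1 = n2 = n
    n = n1
    if sfs.total_mass <= 0:
        raise ValueError("joint SFS carries no mass")

    c_abba, c_baba = _pattern_tensors(n1, n2, n3)
    abba_cells = sfs.counts * c_abba
    baba_cells = sfs.counts * c_baba
    # per-bin sums: ABBA stratified by the P2 count, BABA by the P1 count;
    # index 0 of these sums is structurally zero and dropped.
    abba_k = abba_cells.sum(axis=(0, 2))[1:]
    baba_k = baba_cells.sum(axis=(1, 2))[1:]
    abba_total = float(abba_cells.sum())
    baba_total = float(baba_cells.sum())
    total = abba_total + baba_total

    denom = abba_k + baba_k
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom > 0, (abba_k - baba_k) / denom, np.nan)
        w = denom / total if total > 0 else np.zeros(n)
    return DFSResult(
        n=n, d=d, w=w, abba_k=abba_k, baba_k=baba_k,
        d_overall=d_statistic(abba_total, baba_total),
        abba_total=abba_total, baba_total=baba_total,
    )


@dataclass
class DFSStandardErrors:
    """Site-resampling bootstrap standard errors for a D frequency spectrum."""

    se_d: np.ndarray        # per-bin SE of D_k (NaN where the bin was undefined)
    se_overall: float


def bootstrap_dfs_se(sfs: JointSFS, n_boot: int = 200, seed: int | None = None) -> DFSStandardErrors:
    """Bootstrap standard errors by multinomial resampling of sites.

    Treats the SFS cells as a multinomial over sites: each replicate redraws
    the (rounded) total number of sites across cells with probabilities
    proportional to the observed mass, recomputes the D frequency spectrum,
    and the SE is the standard deviation across replicates.  Intended for
    spectra whose mass is a site count (integer or near-integer).
    """
    rng = np.random.default_rng(seed)
    flat = sfs.counts.ravel()
    total = int(round(flat.sum()))
    if total <= 0:
        raise ValueError("cannot bootstrap an empty SFS")
    p = flat / flat.sum()
    base = dfs_from_joint_sfs(sfs)
    ds = np.empty((n_boot, base.n))
    d_over = np.empty(n_boot)
    for b in range(n_boot):
        resampled = rng.multinomial(total, p).astype(float).reshape(sfs.counts.shape)
        r = dfs_from_joint_sfs(JointSFS(resampled, polarized=True))
        ds[b] = r.d
        d_over[b] = r.d_overall
    with np.errstate(invalid="ignore"):
        se_d = np.nanstd(ds, axis=0, ddof=1)
    se_d[~base.defined] = np.nan
    return DFSStandardErrors(se_d=se_d, se_overall=float(np.nanstd(d_over, ddof=1)))
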