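"""Joint site frequency spectra: container, projection, polarization, text I/O.

A joint SFS over three populations is a tensor ``counts[i1, i2, i3]`` giving
the number (or fractional mass) of sites at which the derived allele was
observed ``i_j`` times out of ``n_j`` sampled haploid genomes in population
``j``.  A *polarized* spectrum is one whose axes index derived-allele counts,
i.e. the ancestral state has already been assigned (typically via an
outgroup).  Entries may be non-integer after hypergeometric projection.

The text format read and written here is the plain-array convention used by
dadi and moments: a shape line ending in ``unfolded`` or ``folded``, a line of
flattened counts in C order, and an optional mask line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

__all__ = [
    "JointSFS",
    "project_joint_sfs",
    "swap_p1_p2",
    "polarize_sfs",
    "projection_matrix",
    "read_sfs",
    "write_sfs",
    "load_joint_sfs",
]


@dataclass
class JointSFS:
    """Polarized joint site frequency spectrum for (P1, P2, P3).

    Parameters
    ----------
    counts
        Non-negative tensor of shape ``(n1 + 1, n2 + 1, n3 + 1)``; axis ``j``
        indexes the derived-allele count in population ``j``.
    polarized
        True when axis values are derived-allele counts.  Only polarized
        spectra are accepted by the D frequency spectrum computation.
    """

    counts: np.ndarray
    polarized: bool = True

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError(
                f"joint SFS must be a 3D tensor, got {self.counts.ndim} dims"
            )
        if np.any(self.counts < 0):
            raise ValueError("joint SFS entries must be non-negative")

    @property
    def sample_sizes(self) -> tuple[int, int, int]:
        """Haploid sample sizes ``(n1, n2, n3)``."""
        s = self.counts.shape
        return (s[0] - 1, s[1] - 1, s[2] - 1)

    @property
    def total_mass(self) -> float:
        return float(self.counts.sum())

    def __eq__(self, other: object) -> bool:  # value semantics, exact
        if not isinstance(other, JointSFS):
            return NotImplemented
        return (
            self.polarized == other.polarized
            and self.counts.shape == other.counts.shape
            and bool(np.array_equal(self.counts, other.counts))
        )


def projection_matrix(n: int, m: int) -> np.ndarray:
    """Exact hypergeometric downsampling matrix from ``n`` to ``m`` haploids.

    ``W[i, c] = C(i, c) C(n - i, m - c) / C(n, m)`` is the probability that a
    subsample of ``m`` of the ``n`` observed alleles contains ``c`` of the
    ``i`` derived copies.  Rows sum to 1.
    """
    if not 1 <= m <= n:
        raise ValueError(f"projection target must satisfy 1 <= m <= n, got m={m}, n={n}")
    i = np.arange(n + 1)[:, None]
    c = np.arange(m + 1)[None, :]
    return hypergeom.pmf(c, n, i, m)


def project_joint_sfs(sfs: JointSFS, target_sizes: tuple[int, int, int]) -> JointSFS:
    """Project a joint SFS down to smaller sample sizes.

    Mass at count ``i`` of ``n`` is redistributed over counts ``0..m`` with
    exact hypergeometric weights, independently along each axis.  Total mass
    is conserved.  Projecting to the current sizes is the identity.
    """
    sizes = sfs.sample_sizes
    if len(target_sizes) != 3:
        raise ValueError("target_sizes must have three entries")
    for m, n in zip(target_sizes, sizes):
        if not 1 <= m <= n:
            raise ValueError(
                f"cannot project population of size {n} to size {m}; need 1 <= m <= n"
            )
    out = sfs.counts
    for axis, (m, n) in enumerate(zip(target_sizes, sizes)):
        if m != n:
            W = projection_matrix(n, m)
            out = np.moveaxis(np.tensordot(np.moveaxis(out, axis, 0), W, axes=(0, 0)), -1, axis)
    return JointSFS(out, polarized=sfs.polarized)


def swap_p1_p2(sfs: JointSFS) -> JointSFS:
    """Exchange the roles of P1 and P2 (transpose the first two axes)."""
    return JointSFS(np.ascontiguousarray(sfs.counts.transpose(1, 0, 2)),
                    polarized=sfs.polarized)


def polarize_sfs(counts4d: np.ndarray) -> JointSFS:
    """Polarize an unpolarized 4D joint SFS using the outgroup axis.

    The fourth axis indexes the outgroup's count of the same allele that the
    first three axes count.  Under the assumption that the outgroup is fixed
    for the ancestral state:

    - outgroup count 0: the indexed allele is derived; orientation kept;
    - outgroup count ``n_o``: the indexed allele is ancestral; all three
      ingroup axes are flipped (``i_j -> n_j - i_j``);
    - outgroup polymorphic (``0 < count < n_o``): the site is discarded.
    """
    arr = np.asarray(counts4d, dtype=float)
    if arr.ndim != 4:
        raise ValueError(f"expected a 4D tensor with an outgroup axis, got {arr.ndim} dims")
    if np.any(arr < 0):
        raise ValueError("joint SFS entries must be non-negative")
    keep = arr[..., 0]
    flipped = arr[..., -1][::-1, ::-1, ::-1]
    discarded = arr[..., 1:-1].sum() if arr.shape[-1] > 2 else 0.0
    if discarded:
        logger.info("polarize_sfs: discarded %g mass at outgroup-polymorphic cells", discarded)
    return JointSFS(keep + flipped, polarized=True)


# ---------------------------------------------------------------------------
# dadi/moments-style plain-text array format
# ---------------------------------------------------------------------------

def write_sfs(path, counts: np.ndarray, folded: bool = False,
              mask: np.ndarray | None = None, comment: str | None = None) -> None:
    """Write an SFS array in the dadi-style plain-text format.

    Line 1: the shape (each entry ``n_j + 1``) followed by ``unfolded`` or
    ``folded``; line 2: the flattened entries in C order; line 3: a 0/1 mask
    (all zeros if none given).  Comment lines start with ``#``.
    """
    counts = np.asarray(counts, dtype=float)
    if mask is None:
        mask = np.zeros_like(counts, dtype=int)
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        shape = " ".join(str(s) for s in counts.shape)
        fh.write(f"{shape} {'folded' if folded else 'unfolded'}\n")
        fh.write(" ".join(repr(float(x)) for x in counts.ravel()) + "\n")
        fh.write(" ".join(str(int(x)) for x in np.asarray(mask).ravel()) + "\n")


def read_sfs(path) -> tuple[np.ndarray, bool, np.ndarray]:
    """Read a dadi-style SFS file; returns ``(array, folded, mask)``."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
    if len(lines) < 2:
        raise ValueError(f"{path}: not a valid SFS file (need shape and data lines)")
    header = lines[0].split()
    if header[-1].lower() in ("unfolded", "folded"):
        folded = header[-1].lower() == "folded"
        dims = header[:-1]
    else:
        folded = False
        dims = header
    try:
        shape = tuple(int(d) for d in dims)
    except ValueError as exc:
        raise ValueError(f"{path}: bad shape line {lines[0]!r}") from exc
    data = np.array([float(x) for x in lines[1].split()])
    if data.size != int(np.prod(shape)):
        raise ValueError(
            f"{path}: expected {int(np.prod(shape))} entries for shape {shape}, got {data.size}"
        )
    arr = data.reshape(shape)
    if len(lines) > 2:
        mask = np.array([int(float(x)) for x in lines[2].split()]).reshape(shape)
    else:
        mask = np.zeros(shape, dtype=int)
    return arr, folded, mask


def load_joint_sfs(path) -> JointSFS:
    """Load a polarized joint SFS, polarizing a 4D input via its outgroup axis.

    Folded input is rejected: the D frequency spectrum needs derived-allele
    orientation.
    """
    arr, folded, _mask = read_sfs(path)
    if folded:
        raise ValueError(f"{path}: folded SFS cannot be used; polarized input required")
    if arr.ndim == 4:
        return polarize_sfs(arr)
    if arr.ndim == 3:
        return JointSFS(arr, polarized=True)
    raise ValueError(f"{path}: expected a 3D or 4D SFS, got {arr.ndim} dims")
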