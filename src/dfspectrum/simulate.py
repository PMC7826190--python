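"""Monte Carlo joint-SFS simulation at unlinked sites.

Each site is an independent genealogy drawn from the structured coalescent
under a :class:`~dfspectrum.demography.DemographicModel` (via msprime), and
carries exactly one mutation placed uniformly at random on total branch
length — optionally restricted to branch segments inside a mutation-age
window.  The derived-allele counts of the mutated branch's descendants in
P1, P2 and P3 index a cell of the joint SFS, which is therefore polarized by
construction (no outgroup is simulated).  Because the D frequency spectrum
depends only on the distribution of allele frequencies at variant sites, one
mutation per site loses nothing relative to a mutation-rate model.

The per-tree tally is a numba kernel over the tskit edge table, exploiting
the tskit ordering guarantee that edges are sorted by parent time, so a
single forward pass accumulates descendant counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product as _iter_product

import msprime
import numpy as np
import pandas as pd
import tskit
from numba import njit

from .demography import DemographicModel, preset
from .dstat import DFSResult, dfs_from_joint_sfs
from .sfs import JointSFS

logger = logging.getLogger(__name__)

__all__ = [
    "simulate_genealogy",
    "simulate_joint_sfs",
    "SimulationResult",
    "dfs_grid",
    "run_preset",
]

_MAX_SEED = 2**31 - 2


def _msprime_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint64)[0] % _MAX_SEED) + 1


def simulate_genealogy(model: DemographicModel, samples: dict[str, int] | tuple[int, int, int],
                       seed: int | None = None, num_replicates: int | None = None):
    """Draw genealogies at a single unlinked site under ``model``.

    ``samples`` gives haploid sample counts, either ``(n1, n2, n3)`` or a
    mapping of population names.  Returns a single :class:`tskit.TreeSequence`
    (one rooted binary tree whose nodes carry times and populations), or a
    generator of them when ``num_replicates`` is given.
    """
    if not isinstance(samples, dict):
        n1, n2, n3 = samples
        samples = {"P1": n1, "P2": n2, "P3": n3}
    if sum(samples.values()) < 1:
        raise ValueError("at least one sampled lineage is required")
    return msprime.sim_ancestry(
        samples=samples, demography=model.to_msprime(), ploidy=1,
        random_seed=None if seed is None else (seed % _MAX_SEED) + 1,
        num_replicates=num_replicates,
    )


@njit(cache=True)
def _place_and_tally(child, parent, times, pop_of, n_samples, u, sfs, tmin, tmax):
    """Place one uniform mutation (within the age window) and count carriers.

    Walks the edge table once (edges sorted by parent time) accumulating per
    -population descendant sample counts, computes each branch's overlap with
    ``[tmin, tmax]``, picks the branch below which the fraction ``u`` of
    total eligible length falls, and increments the SFS cell of its carrier
    counts.  Returns 0 on success, -1 if no branch length lies in the window.
    """
    n_nodes = times.shape[0]
    c1 = np.zeros(n_nodes, np.int64)
    c2 = np.zeros(n_nodes, np.int64)
    c3 = np.zeros(n_nodes, np.int64)
    blen = np.zeros(n_nodes)
    for s in range(n_samples):
        p = pop_of[s]
        if p == 0:
            c1[s] = 1
        elif p == 1:
            c2[s] = 1
        else:
            c3[s] = 1
    total = 0.0
    n_edges = child.shape[0]
    for e in range(n_edges):
        ch = child[e]
        pa = parent[e]
        c1[pa] += c1[ch]
        c2[pa] += c2[ch]
        c3[pa] += c3[ch]
        lo = times[ch] if times[ch] > tmin else tmin
        hi = times[pa] if times[pa] < tmax else tmax
        seg = hi - lo
        if seg > 0.0:
            blen[ch] = seg
            total += seg
    if total <= 0.0:
        return -1
    target = u * total
    acc = 0.0
    for e in range(n_edges):
        ch = child[e]
        if blen[ch] > 0.0:
            acc += blen[ch]
            if acc >= target:
                sfs[c1[ch], c2[ch], c3[ch]] += 1
                return 0
    # numerical slack: attribute to the last eligible branch
    for e in range(n_edges - 1, -1, -1):
        ch = child[e]
        if blen[ch] > 0.0:
            sfs[c1[ch], c2[ch], c3[ch]] += 1
            return 0
    return -1


@dataclass
class SimulationResult:
    """A simulated polarized joint SFS plus bookkeeping.

    ``n_rejected`` counts genealogies discarded (and redrawn) because no
    branch length fell inside the mutation window.
    """

    sfs: JointSFS
    n_sites: int
    n_rejected: int
    seed: int
    model: DemographicModel


def simulate_joint_sfs(model: DemographicModel, samples: tuple[int, int, int],
                       n_sites: int, seed: int,
                       mutation_window: tuple[float, float] | None = None,
                       max_rounds: int = 60) -> SimulationResult:
    """Simulate a polarized joint SFS at ``n_sites`` unlinked sites.

    One independent genealogy per site; one mutation per genealogy, uniform
    on branch length inside ``mutation_window`` (default: the model's window,
    else the whole genealogy).  The seed fully determines the output.
    Genealogies with zero eligible branch length are resampled (counted in
    the result); if an entire resampling round yields nothing placeable the
    window is presumed unreachable and a RuntimeError is raised.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    n1, n2, n3 = samples
    window = mutation_window if mutation_window is not None else model.mutation_window
    tmin, tmax = (0.0, np.inf) if window is None else (float(window[0]), float(window[1]))
    if not (0 <= tmin < tmax):
        raise ValueError("mutation window must satisfy 0 <= t_min < t_max")

    demog = model.to_msprime()
    sample_map = {"P1": n1, "P2": n2, "P3": n3}
    n_samples = n1 + n2 + n3
    sfs = np.zeros((n1 + 1, n2 + 1, n3 + 1), dtype=np.int64)
    master = np.random.SeedSequence(seed)
    rng = np.random.default_rng(master.spawn(1)[0])

    pop_of = None
    placed = 0
    rejected = 0
    rounds = 0
    while placed < n_sites:
        if rounds >= max_rounds:
            raise RuntimeError(
                f"mutation window [{tmin}, {tmax}) unreachable: "
                f"{rejected} genealogies rejected without progress")
        todo = n_sites - placed
        reps = msprime.sim_ancestry(
            samples=sample_map, demography=demog, ploidy=1,
            num_replicates=todo,
            random_seed=_msprime_seed(master.spawn(1)[0]))
        u = rng.random(todo)
        placed_this_round = 0
        for i, ts in enumerate(reps):
            tables = ts.tables
            if pop_of is None:
                pop_of = tables.nodes.population[:n_samples].astype(np.int64)
            ok = _place_and_tally(tables.edges.child, tables.edges.parent,
                                  tables.nodes.time, pop_of, n_samples,
                                  u[i], sfs, tmin, tmax)
            if ok == 0:
                placed_this_round += 1
            else:
                rejected += 1
        placed += placed_this_round
        rounds += 1
        if placed_this_round == 0 and placed < n_sites:
            # no progress this round: likely an unreachable window
            rounds = max_rounds
    if rejected:
        logger.info("simulate_joint_sfs: resampled %d genealogies with no "
                    "branch length in the mutation window", rejected)
    return SimulationResult(sfs=JointSFS(sfs.astype(float), polarized=True),
                            n_sites=n_sites, n_rejected=rejected, seed=seed, model=model)


# ---------------------------------------------------------------------------
# Batch runner over parameter grids
# ---------------------------------------------------------------------------

def dfs_grid(preset_name: str, grid: dict[str, list], samples: tuple[int, int, int],
             n_sites: int, seed: int, fixed: dict | None = None) -> pd.DataFrame:
    """Run a scenario preset over a Cartesian parameter grid.

    ``grid`` maps preset keyword names to value lists; each combination gets
    its own deterministic child seed (a counter scheme over the master seed,
    so results are independent of execution order).  Returns one row per
    combination with the varied parameters, ``d_overall``, and flattened
    ``D_k`` / ``w_k`` columns.  Failures are recorded per row (``error``
    column) and do not abort the run.
    """
    fixed = fixed or {}
    keys = sorted(grid)
    combos = list(_iter_product(*(grid[k] for k in keys)))
    master = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1, dtype=np.uint64)[0] % _MAX_SEED)
                   for s in master.spawn(len(combos))]
    rows = []
    n_bins = min(samples[0], samples[1])
    for idx, combo in enumerate(combos):
        params = dict(zip(keys, combo))
        row: dict = {"combo": idx, **params, "seed": child_seeds[idx]}
        try:
            model = preset(preset_name, **fixed, **params)
            sim = simulate_joint_sfs(model, samples, n_sites, seed=child_seeds[idx])
            res = dfs_from_joint_sfs(sim.sfs)
            row["d_overall"] = res.d_overall
            for k in range(1, n_bins + 1):
                row[f"D_{k}"] = res.d[k - 1]
                row[f"w_{k}"] = res.w[k - 1]
            row["error"] = ""
        except Exception as exc:  # keep going; record the failure
            logger.warning("grid combination %d (%s) failed: %s", idx, params, exc)
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def run_preset(name: str, samples: tuple[int, int, int], n_sites: int, seed: int,
               **overrides) -> tuple[SimulationResult, DFSResult]:
    """Convenience: build a preset, simulate, and compute its D_FS."""
    model = preset(name, **overrides)
    sim = simulate_joint_sfs(model, samples, n_sites, seed=seed)
    return sim, dfs_from_joint_sfs(sim.sfs)
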