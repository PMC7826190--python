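"""Demographic models for the four-taxon introgression scenarios.

Time is measured backward from the present in coalescent units of 2*N_ref
generations, and population sizes are relative sizes ``nu = N / N_ref``.  In
these units a pair of lineages in a population of relative size ``nu``
coalesces at rate ``1 / nu``, and a migration epoch with population-scaled
rate ``M = 2Nm`` moves each lineage of the *recipient* population to the
donor (backward in time) at rate ``M`` per unit time: forward in time a
fraction ``m`` of the recipient is replaced by migrants each generation, so
a lineage traces back to the donor at rate ``m`` per generation, i.e.
``2Nm = M`` per 2N generations.  On this scale the D frequency spectrum is
independent of the absolute population size, generation time and mutation
rate.

The ingroup topology is fixed at (((P1, P2), P3)); the outgroup is never
simulated because simulated spectra are polarized by construction.  An
optional ancestral-structure variant subdivides the common ancestor into two
subpopulations exchanging migrants symmetrically, with P1 descending from
one and P2 and P3 from the other — the classic confounder that mimics
introgression using only ancestral variation.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import msprime

__all__ = [
    "MigrationEpoch",
    "SizeChange",
    "AncestralStructure",
    "DemographicModel",
    "preset",
    "preset_names",
    "UnknownPresetError",
]

_POPS = ("P1", "P2", "P3")


@dataclass(frozen=True)
class MigrationEpoch:
    """Continuous gene flow from ``source`` into ``dest`` (forward in time).

    Active while the time-ago ``t`` satisfies ``start <= t < end``; ``rate``
    is the population-scaled migration rate M = 2Nm.
    """

    source: str
    dest: str
    start: float
    end: float
    rate: float

    def __post_init__(self):
        if self.source == self.dest:
            raise ValueError("migration source and dest must differ")
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")
        if self.rate < 0:
            raise ValueError("migration rate must be >= 0")


@dataclass(frozen=True)
class SizeChange:
    """From time-ago ``time`` backward, ``population`` has relative size ``size``."""

    population: str
    time: float
    size: float

    def __post_init__(self):
        if self.time < 0 or self.size <= 0:
            raise ValueError("size changes need time >= 0 and size > 0")


@dataclass(frozen=True)
class AncestralStructure:
    """Two ancestral subpopulations exchanging migrants symmetrically.

    P1 merges into subpopulation A and P2 into subpopulation B at the P1/P2
    split; P3 merges into B at its split; A and B exchange migrants at
    symmetric rate ``migration`` (M = 2Nm per direction) until they fuse at
    time-ago ``end``.
    """

    migration: float
    end: float


@dataclass
class DemographicModel:
    """Piecewise-constant history of (((P1, P2), P3)).

    Parameters
    ----------
    split_p1p2, split_p3
        Time-ago of the P1/P2 split and of the deeper split of P3 from the
        P1+P2 ancestor, in units of 2*N_ref generations.
    sizes
        Relative present-epoch sizes for P1, P2, P3 and the ancestors
        ``A12`` (of P1+P2) and ``A123`` (root); unspecified populations
        default to 1.
    size_changes
        Instantaneous size changes, applied from their time backward.
    migrations
        Continuous migration epochs (forward-time direction convention).
    mutation_window
        Optional ``(t_min, t_max)``: mutations are only placed on branch
        segments whose age lies inside the window.
    ancestral_structure
        Optional structured-ancestor variant (see AncestralStructure).
    """

    split_p1p2: float = 0.5
    split_p3: float = 1.0
    sizes: dict = field(default_factory=dict)
    size_changes: tuple = ()
    migrations: tuple = ()
    mutation_window: tuple | None = None
    ancestral_structure: AncestralStructure | None = None

    def __post_init__(self):
        self.size_changes = tuple(self.size_changes)
        self.migrations = tuple(self.migrations)
        if not 0 < self.split_p1p2 < self.split_p3:
            raise ValueError("need 0 < split_p1p2 < split_p3")
        valid = set(_POPS) | {"A12", "A123"}
        for pop, nu in self.sizes.items():
            if pop not in valid:
                raise ValueError(f"unknown population {pop!r}")
            if nu <= 0:
                raise ValueError("relative sizes must be > 0")
        for sc in self.size_changes:
            if sc.population not in valid:
                raise ValueError(f"unknown population {sc.population!r} in size change")
        for mig in self.migrations:
            for pop in (mig.source, mig.dest):
                if pop not in _POPS:
                    raise ValueError(f"migration population {pop!r} must be one of {_POPS}")
        if self.mutation_window is not None:
            lo, hi = self.mutation_window
            if not (0 <= lo < hi):
                raise ValueError("mutation window must satisfy 0 <= t_min < t_max")
        if self.ancestral_structure is not None:
            st = self.ancestral_structure
            if st.end <= self.split_p3:
                raise ValueError("ancestral structure must persist beyond the P3 split")
            if st.migration < 0:
                raise ValueError("ancestral structure migration must be >= 0")

    # -- msprime bridge -----------------------------------------------------

    def to_msprime(self) -> msprime.Demography:
        """Build the equivalent msprime demography.

        Genealogies are simulated with haploid individuals (``ploidy=1``),
        where msprime's pairwise coalescence rate is ``1 / initial_size``;
        setting ``initial_size = nu`` therefore makes one msprime
        "generation" equal one unit of 2*N_ref generations with rate
        ``1 / nu``.  Migration rates pass through unchanged (backward
        per-lineage rate M per unit time, recipient to donor).
        """
        nu = {p: self.sizes.get(p, 1.0) for p in ("P1", "P2", "P3", "A12", "A123")}
        dem = msprime.Demography()
        for p in _POPS:
            dem.add_population(name=p, initial_size=nu[p])
        structured = self.ancestral_structure is not None
        if structured:
            st = self.ancestral_structure
            dem.add_population(name="SUBA", initial_size=nu["A12"])
            dem.add_population(name="SUBB", initial_size=nu["A123"])
            dem.add_population(name="ROOT", initial_size=nu["A123"])
            dem.add_population_split(time=self.split_p1p2, derived=["P1"], ancestral="SUBA")
            dem.add_population_split(time=self.split_p1p2, derived=["P2"], ancestral="SUBB")
            dem.add_population_split(time=self.split_p3, derived=["P3"], ancestral="SUBB")
            # symmetric exchange between the two ancestral demes, from the
            # P1/P2 split (when they become visible) back to their fusion
            for a, b in (("SUBA", "SUBB"), ("SUBB", "SUBA")):
                dem.add_migration_rate_change(time=self.split_p1p2, rate=st.migration,
                                              source=a, dest=b)
                dem.add_migration_rate_change(time=st.end, rate=0.0, source=a, dest=b)
            dem.add_population_split(time=st.end, derived=["SUBA", "SUBB"], ancestral="ROOT")
        else:
            dem.add_population(name="A12", initial_size=nu["A12"])
            dem.add_population(name="A123", initial_size=nu["A123"])
            dem.add_population_split(time=self.split_p1p2, derived=["P1", "P2"], ancestral="A12")
            dem.add_population_split(time=self.split_p3, derived=["A12", "P3"], ancestral="A123")
        for sc in self.size_changes:
            pop = sc.population
            if structured and pop in ("A12", "A123"):
                raise ValueError("ancestral size changes are not supported with ancestral structure")
            dem.add_population_parameters_change(time=sc.time, population=pop,
                                                 initial_size=sc.size)
        for mig in self.migrations:
            # backward in time, lineages in the forward-time recipient (dest)
            # jump to the donor (source) at rate M
            dem.add_migration_rate_change(time=mig.start, rate=mig.rate,
                                          source=mig.dest, dest=mig.source)
            dem.add_migration_rate_change(time=mig.end, rate=0.0,
                                          source=mig.dest, dest=mig.source)
        dem.sort_events()
        return dem

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "split_p1p2": self.split_p1p2,
            "split_p3": self.split_p3,
            "sizes": dict(self.sizes),
            "size_changes": [asdict(sc) for sc in self.size_changes],
            "migrations": [asdict(m) for m in self.migrations],
            "mutation_window": list(self.mutation_window) if self.mutation_window else None,
            "ancestral_structure": asdict(self.ancestral_structure)
            if self.ancestral_structure else None,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicModel":
        return cls(
            split_p1p2=d["split_p1p2"],
            split_p3=d["split_p3"],
            sizes=dict(d.get("sizes") or {}),
            size_changes=tuple(SizeChange(**sc) for sc in d.get("size_changes") or ()),
            migrations=tuple(MigrationEpoch(**m) for m in d.get("migrations") or ()),
            mutation_window=tuple(d["mutation_window"]) if d.get("mutation_window") else None,
            ancestral_structure=AncestralStructure(**d["ancestral_structure"])
            if d.get("ancestral_structure") else None,
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "DemographicModel":
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                d = json.loads(text)
            else:
                with open(text) as fh:
                    d = json.load(fh)
        return cls.from_dict(d)


class UnknownPresetError(KeyError):
    """Raised for an unknown scenario name; carries the valid names."""

    def __init__(self, name: str, valid: list[str]):
        self.valid = valid
        super().__init__(f"unknown scenario preset {name!r}; valid presets: {', '.join(valid)}")


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------
# Split times, pulse placement and bottleneck depth are round defaults chosen
# to place each scenario in the regime where its characteristic D_FS shape
# appears; every knob is overridable.  The generic history has the P1/P2
# split at t12 = 0.5 and the P3 split at t123 = 1.0; "recent" gene flow
# occupies the most recent fifth of the post-split epoch and "old" the
# middle.  Truly "ancient" gene flow must be old relative to 2N for the
# introgressed variation to have sorted to fixation or loss, so that preset
# uses deeper splits; conversely the ancestral-structure confounder needs a
# shallow P1/P2 split so that immigrant alleles still sit symmetrically at
# low frequency in both demes at present, which is what empties its
# low-frequency bins.

_T12 = 0.5
_T123 = 1.0
_RECENT = (0.0, 0.1)
_OLD = (0.2, 0.3)
_BOTTLENECK = (0.05, 0.15)   # interval during which P2 is reduced
_BOTTLENECK_SIZE = 0.05      # two coalescent units of drift over the interval


def _flow(source, dest, window, rate):
    return MigrationEpoch(source=source, dest=dest, start=window[0], end=window[1], rate=rate)


def _bottleneck(pop, window=_BOTTLENECK, size=_BOTTLENECK_SIZE):
    # piecewise-constant dip: reduced size inside the window, back to 1 before
    return (SizeChange(pop, window[0], size), SizeChange(pop, window[1], 1.0))


def _build_no_geneflow(**kw):
    return DemographicModel(**kw)


def _build_recent_geneflow(rate=2.0, window=_RECENT, **kw):
    return DemographicModel(migrations=(_flow("P3", "P2", window, rate),), **kw)


def _build_old_geneflow(rate=3.0, window=_OLD, **kw):
    return DemographicModel(migrations=(_flow("P3", "P2", window, rate),), **kw)


def _build_ancient_geneflow(rate=3.0, window=(1.6, 2.0), split_p1p2=2.0,
                            split_p3=2.5, **kw):
    return DemographicModel(split_p1p2=split_p1p2, split_p3=split_p3,
                            migrations=(_flow("P3", "P2", window, rate),), **kw)


def _build_bottleneck(window=_BOTTLENECK, size=_BOTTLENECK_SIZE, **kw):
    return DemographicModel(size_changes=_bottleneck("P2", window, size), **kw)


def _build_bottleneck_then_geneflow(rate=2.0, flow_window=(0.0, 0.04),
                                    bottleneck_window=_BOTTLENECK,
                                    size=_BOTTLENECK_SIZE, **kw):
    # forward in time: bottleneck first, gene flow after (more recent)
    return DemographicModel(
        size_changes=_bottleneck("P2", bottleneck_window, size),
        migrations=(_flow("P3", "P2", flow_window, rate),), **kw)


def _build_geneflow_then_bottleneck(rate=3.0, flow_window=(0.17, 0.27),
                                    bottleneck_window=_BOTTLENECK,
                                    size=_BOTTLENECK_SIZE, **kw):
    # forward in time: gene flow first, bottleneck after it
    return DemographicModel(
        size_changes=_bottleneck("P2", bottleneck_window, size),
        migrations=(_flow("P3", "P2", flow_window, rate),), **kw)


def _build_outward_geneflow(rate=2.0, window=_RECENT, **kw):
    return DemographicModel(migrations=(_flow("P2", "P3", window, rate),), **kw)


def _build_bidirectional_geneflow(rate_out=2.0, rate_in=1.0, window=_RECENT, **kw):
    return DemographicModel(migrations=(
        _flow("P2", "P3", window, rate_out),
        _flow("P3", "P2", window, rate_in)), **kw)


def _build_geneflow_into_both(rate_p2=3.0, rate_p1=0.5, window=_RECENT, **kw):
    return DemographicModel(migrations=(
        _flow("P3", "P2", window, rate_p2),
        _flow("P3", "P1", window, rate_p1)), **kw)


def _build_symmetric_geneflow(rate=2.0, window=_RECENT, **kw):
    return DemographicModel(migrations=(
        _flow("P3", "P2", window, rate),
        _flow("P3", "P1", window, rate)), **kw)


def _build_small_donor(rate=2.0, window=_RECENT, donor_size=0.2, **kw):
    kw.setdefault("sizes", {})
    kw["sizes"] = {**kw["sizes"], "P3": donor_size}
    return DemographicModel(migrations=(_flow("P3", "P2", window, rate),), **kw)


def _build_ancient_mutations_only(rate=2.0, window=_RECENT, split_p3=_T123, **kw):
    return DemographicModel(split_p3=split_p3,
                            migrations=(_flow("P3", "P2", window, rate),),
                            mutation_window=(split_p3, math.inf), **kw)


def _build_weak_reverse_geneflow(rate_out=2.0, rate_in=0.2, window=_RECENT, **kw):
    # outward P2->P3 dominant, inward P3->P2 ten-fold weaker
    return DemographicModel(migrations=(
        _flow("P2", "P3", window, rate_out),
        _flow("P3", "P2", window, rate_in)), **kw)


def _build_p1_p2_geneflow(rate=2.0, window=_RECENT, rate_p1p2=2.0,
                          p1p2_window=(0.0, _T12), **kw):
    return DemographicModel(migrations=(
        _flow("P3", "P2", window, rate),
        _flow("P1", "P2", p1p2_window, rate_p1p2),
        _flow("P2", "P1", p1p2_window, rate_p1p2)), **kw)


def _build_ancestral_structure(migration=0.5, end=2.0, split_p1p2=0.1,
                               split_p3=1.0, **kw):
    return DemographicModel(split_p1p2=split_p1p2, split_p3=split_p3,
                            ancestral_structure=AncestralStructure(migration=migration, end=end),
                            **kw)


_PRESETS = {
    "no_geneflow": _build_no_geneflow,
    "recent_geneflow": _build_recent_geneflow,
    "old_geneflow": _build_old_geneflow,
    "ancient_geneflow": _build_ancient_geneflow,
    "bottleneck": _build_bottleneck,
    "bottleneck_then_geneflow": _build_bottleneck_then_geneflow,
    "geneflow_then_bottleneck": _build_geneflow_then_bottleneck,
    "outward_geneflow": _build_outward_geneflow,
    "bidirectional_geneflow": _build_bidirectional_geneflow,
    "geneflow_into_both": _build_geneflow_into_both,
    "symmetric_geneflow": _build_symmetric_geneflow,
    "small_donor": _build_small_donor,
    "ancient_mutations_only": _build_ancient_mutations_only,
    "weak_reverse_geneflow": _build_weak_reverse_geneflow,
    "p1_p2_geneflow": _build_p1_p2_geneflow,
    "ancestral_structure": _build_ancestral_structure,
}


def preset_names() -> list[str]:
    """Names of all registered demographic scenario presets."""
    return sorted(_PRESETS)


def preset(name: str, **overrides) -> DemographicModel:
    """Build a named scenario's demographic model, with overridable knobs.

    Each preset is a fully parameterized model of one introgression or
    confounder scenario (timing and direction of gene flow, bottlenecks,
    donor size, mutation-age restriction, ancestral structure); numeric
    parameters such as ``rate``, ``window``, ``split_p1p2`` can be overridden
    by keyword.
    """
    try:
        builder = _PRESETS[name]
    except KeyError:
        raise UnknownPresetError(name, preset_names()) from None
    return builder(**overrides)
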