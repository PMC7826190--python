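"""VCF genotypes to polarized joint SFS, plus a synthetic-VCF fixture writer.

The pipeline mirrors standard four-taxon practice: stream biallelic SNPs
from a VCF, tally allele counts per population role (P1, P2, P3, outgroup),
polarize each site by the outgroup (fixed REF means ALT is derived; fixed
ALT means REF is derived; an outgroup segregating for both alleles cannot
polarize and the site is discarded), then bin sites into a joint SFS at a
common sample size, hypergeometrically projecting sites with missing calls.

Allele copies are counted directly from the GT field, so any ploidy works —
including tetraploid calls.  Reading goes through pysam; the fixture writer
emits deterministic plain-text VCF alongside its true joint SFS for
round-trip testing.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .sfs import JointSFS, projection_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationMap",
    "FilterConfig",
    "SiteRecord",
    "read_sites",
    "polarize_site",
    "build_joint_sfs",
    "vcf_to_joint_sfs",
    "make_fixture_vcf",
    "FixtureTruth",
]

ROLES = ("P1", "P2", "P3", "outgroup")
_INGROUP = ("P1", "P2", "P3")


@dataclass
class PopulationMap:
    """Assignment of VCF sample ids to the four roles P1, P2, P3, outgroup."""

    assignments: dict[str, str]

    def __post_init__(self):
        seen: dict[str, str] = {}
        for sample, role in self.assignments.items():
            if role not in ROLES:
                raise ValueError(f"sample {sample!r} has unknown role {role!r}; "
                                 f"expected one of {ROLES}")
            if sample in seen:
                raise ValueError(f"sample {sample!r} assigned twice")
            seen[sample] = role
        for role in ROLES:
            if role not in self.assignments.values():
                raise ValueError(f"population map assigns no sample to role {role!r}")

    @classmethod
    def from_tsv(cls, path) -> "PopulationMap":
        """Read a two-column (sample, role) TSV; '#' lines are comments."""
        assignments = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
                assignments[parts[0]] = parts[1]
        return cls(assignments)

    def samples(self, role: str) -> list[str]:
        return [s for s, r in self.assignments.items() if r == role]


@dataclass
class FilterConfig:
    """Site and genotype filters applied while streaming a VCF.

    ``min_call_fraction`` drops sites genotyped in fewer than that fraction
    of mapped individuals (default 0.8).  ``min_depth`` optionally masks
    genotypes whose FORMAT/DP falls below it (default off: upstream QC's
    job).  ``min_outgroup_alleles`` is the minimum number of called outgroup
    allele copies required to polarize.  ``missing_policy`` controls how
    partially genotyped sites enter the SFS: ``project`` redistributes them
    hypergeometrically, ``drop`` keeps only fully matching sites.
    """

    min_call_fraction: float = 0.8
    min_depth: int | None = None
    min_outgroup_alleles: int = 1
    missing_policy: str = "project"

    def __post_init__(self):
        if not 0 <= self.min_call_fraction <= 1:
            raise ValueError("min_call_fraction must lie in [0, 1]")
        if self.missing_policy not in ("drop", "project"):
            raise ValueError("missing_policy must be 'drop' or 'project'")
        if self.min_outgroup_alleles < 1:
            raise ValueError("min_outgroup_alleles must be >= 1")


@dataclass
class SiteRecord:
    """One biallelic site's per-role allele tallies.

    Before polarization ``derived`` holds ALT-allele counts; after
    :func:`polarize_site` it holds derived-allele counts for the ingroups.
    """

    chrom: str
    pos: int
    derived: dict[str, int]
    called: dict[str, int]

    def __post_init__(self):
        for role, d in self.derived.items():
            if not 0 <= d <= self.called.get(role, 0):
                raise ValueError(
                    f"{self.chrom}:{self.pos}: derived count {d} outside "
                    f"[0, {self.called.get(role, 0)}] for {role}")


_SNP_ALLELES = frozenset("ACGT")


def read_sites(vcf_source, popmap: PopulationMap, filters: FilterConfig | None = None,
               counters: Counter | None = None):
    """Stream filtered, tallied biallelic SNPs from a VCF.

    Yields a :class:`SiteRecord` per passing site with ALT-allele counts per
    role (not yet polarized).  ``counters``, if supplied, accumulates
    per-filter exclusion counts so that sites_in = sites_used + filtered.
    Raises a configuration error if a mapped sample is missing from the VCF
    header; malformed GT fields skip the site with a logged count.
    """
    filters = filters or FilterConfig()
    counters = counters if counters is not None else Counter()
    vcf = pysam.VariantFile(str(vcf_source))
    header_samples = set(vcf.header.samples)
    missing = [s for s in popmap.assignments if s not in header_samples]
    if missing:
        raise ValueError(f"samples in population map absent from VCF header: {missing}")

    role_samples = {role: popmap.samples(role) for role in ROLES}
    n_individuals = len(popmap.assignments)

    for rec in vcf:
        counters["sites_in"] += 1
        alts = rec.alts or ()
        if len(alts) != 1:
            counters["filtered_not_biallelic"] += 1
            continue
        if rec.ref not in _SNP_ALLELES or alts[0] not in _SNP_ALLELES:
            # indels, spanning deletions ('*'), symbolic alleles
            counters["filtered_not_snp"] += 1
            continue
        try:
            tallies = _tally(rec, role_samples, filters)
        except (KeyError, TypeError):
            counters["filtered_malformed_gt"] += 1
            logger.debug("skipping malformed genotypes at %s:%s", rec.chrom, rec.pos)
            continue
        derived, called, n_genotyped = tallies
        if n_genotyped < filters.min_call_fraction * n_individuals:
            counters["filtered_low_call"] += 1
            continue
        counters["sites_tallied"] += 1
        yield SiteRecord(chrom=rec.chrom, pos=rec.pos, derived=derived, called=called)


def _tally(rec, role_samples, filters):
    derived: dict[str, int] = {}
    called: dict[str, int] = {}
    n_genotyped = 0
    for role, samples in role_samples.items():
        alt = 0
        tot = 0
        for s in samples:
            sdata = rec.samples[s]
            gt = sdata.get("GT")
            if gt is None:
                continue
            if filters.min_depth is not None:
                dp = sdata.get("DP")
                if dp is None or dp < filters.min_depth:
                    continue
            any_called = False
            for allele in gt:
                if allele is None:
                    continue
                tot += 1
                any_called = True
                if allele == 1:
                    alt += 1
            if any_called:
                n_genotyped += 1
        derived[role] = alt
        called[role] = tot
    return derived, called, n_genotyped


def polarize_site(rec: SiteRecord, min_outgroup_alleles: int = 1) -> SiteRecord | None:
    """Polarize a site by its outgroup; returns None when it cannot be.

    Outgroup fixed for REF: ALT is the derived allele and ingroup counts are
    kept.  Outgroup fixed for ALT: REF is derived, so ingroup counts are
    complemented (``called - alt``).  An outgroup that is polymorphic, or has
    fewer than ``min_outgroup_alleles`` called copies, cannot polarize.
    """
    og_called = rec.called.get("outgroup", 0)
    og_alt = rec.derived.get("outgroup", 0)
    if og_called < min_outgroup_alleles:
        return None
    if og_alt == 0:
        derived = {p: rec.derived[p] for p in _INGROUP}
    elif og_alt == og_called:
        derived = {p: rec.called[p] - rec.derived[p] for p in _INGROUP}
    else:
        return None
    return SiteRecord(chrom=rec.chrom, pos=rec.pos, derived=derived,
                      called={p: rec.called[p] for p in _INGROUP})


def build_joint_sfs(records, target_n: tuple[int, int, int],
                    missing_policy: str = "project",
                    counters: Counter | None = None) -> JointSFS:
    """Bin polarized site records into a joint SFS at common sample sizes.

    Under ``project``, a site with ``called >= target`` alleles in every
    ingroup is hypergeometrically downsampled to the target sizes (its unit
    of mass spread fractionally over count cells); sites below target in any
    population are dropped and counted.  Under ``drop``, only sites whose
    called totals equal the targets exactly contribute.

    Raises a ValueError if no site contributes any mass.
    """
    if missing_policy not in ("drop", "project"):
        raise ValueError("missing_policy must be 'drop' or 'project'")
    counters = counters if counters is not None else Counter()
    n1, n2, n3 = target_n
    sfs = np.zeros((n1 + 1, n2 + 1, n3 + 1))
    proj_cache: dict[tuple[int, int], np.ndarray] = {}
    used = 0
    for rec in records:
        calls = [rec.called[p] for p in _INGROUP]
        devs = [rec.derived[p] for p in _INGROUP]
        if any(c < t for c, t in zip(calls, (n1, n2, n3))):
            counters["sfs_dropped_below_target"] += 1
            continue
        if missing_policy == "drop":
            if any(c != t for c, t in zip(calls, (n1, n2, n3))):
                counters["sfs_dropped_policy"] += 1
                continue
            sfs[devs[0], devs[1], devs[2]] += 1.0
        else:
            vecs = []
            for c, i, t in zip(calls, devs, (n1, n2, n3)):
                if c == t:
                    v = np.zeros(t + 1)
                    v[i] = 1.0
                else:
                    key = (c, t)
                    if key not in proj_cache:
                        proj_cache[key] = projection_matrix(c, t)
                    v = proj_cache[key][i]
                vecs.append(v)
            sfs += vecs[0][:, None, None] * vecs[1][None, :, None] * vecs[2][None, None, :]
        used += 1
    counters["sfs_sites_used"] = used
    if used == 0:
        raise ValueError("no sites contributed to the joint SFS")
    return JointSFS(sfs, polarized=True)


def vcf_to_joint_sfs(vcf_source, popmap: PopulationMap, target_n: tuple[int, int, int],
                     filters: FilterConfig | None = None,
                     counters: Counter | None = None) -> JointSFS:
    """Full pipeline: stream, filter, polarize and bin a VCF into a joint SFS."""
    filters = filters or FilterConfig()
    counters = counters if counters is not None else Counter()

    def polarized():
        for rec in read_sites(vcf_source, popmap, filters, counters):
            out = polarize_site(rec, filters.min_outgroup_alleles)
            if out is None:
                counters["filtered_unpolarizable"] += 1
            else:
                yield out

    return build_joint_sfs(polarized(), target_n,
                           missing_policy=filters.missing_policy, counters=counters)


# ---------------------------------------------------------------------------
# Synthetic fixture generation
# ---------------------------------------------------------------------------

@dataclass
class FixtureTruth:
    """Ground truth accompanying a synthetic VCF fixture."""

    sfs: JointSFS                 # polarized joint SFS of the polarizable sites
    n_outgroup_polymorphic: int   # injected unpolarizable sites
    sample_names: dict[str, list[str]] = field(default_factory=dict)


def make_fixture_vcf(path, n_per_pop: dict[str, int], n_sites: int, seed: int,
                     ploidy: int = 2, frac_alt_ancestral: float = 0.3,
                     frac_outgroup_polymorphic: float = 0.0,
                     missing_rate: float = 0.0) -> FixtureTruth:
    """Write a minimal synthetic VCF whose true joint SFS is known.

    Synthetic data: per site, each ingroup population draws a derived-allele
    count uniformly (rejecting the globally monomorphic-ancestral case), and
    with probability ``frac_alt_ancestral`` the REF/ALT labels are swapped so
    the outgroup is fixed for ALT — exercising the polarization complement.
    With probability ``frac_outgroup_polymorphic`` the outgroup is made
    heterozygous instead (such sites are unpolarizable and excluded from the
    truth SFS).  ``missing_rate`` masks whole genotypes at random.  Output is
    byte-identical for a fixed seed.

    The truth SFS counts derived alleles among *called* copies, so with
    missingness it is exact only for the ``drop`` policy at full size; with
    no missingness the read/polarize/bin round trip reproduces it exactly.
    """
    rng = np.random.default_rng(seed)
    names = {role: [f"{role}_{i}" for i in range(n_per_pop[role])] for role in ROLES}
    all_names = [n for role in ROLES for n in names[role]]
    n_hap = {role: n_per_pop[role] * ploidy for role in ROLES}
    truth = np.zeros((n_hap["P1"] + 1, n_hap["P2"] + 1, n_hap["P3"] + 1))
    n_og_poly = 0

    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID=chr1,length={max(n_sites * 10, 1000)}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(all_names),
    ]
    for s in range(n_sites):
        pos = (s + 1) * 10
        while True:
            der = {p: int(rng.integers(0, n_hap[p] + 1)) for p in _INGROUP}
            if any(der.values()):
                break
        og_poly = rng.random() < frac_outgroup_polymorphic
        alt_ancestral = (not og_poly) and rng.random() < frac_alt_ancestral

        # per-population derived-allele placement among haploid copies
        gt_fields = []
        called = dict(n_hap)
        der_called = dict(der)
        for role in ROLES:
            if role == "outgroup":
                if og_poly:
                    alleles = np.zeros(n_hap[role], dtype=int)
                    alleles[0] = 1  # one ALT copy: outgroup segregates
                else:
                    alleles = np.full(n_hap[role], 1 if alt_ancestral else 0, dtype=int)
            else:
                k = der[role]
                alleles = np.zeros(n_hap[role], dtype=int)
                derived_allele = 0 if alt_ancestral else 1
                anc_allele = 1 - derived_allele
                alleles[:] = anc_allele
                if k:
                    idx = rng.choice(n_hap[role], size=k, replace=False)
                    alleles[idx] = derived_allele
            for i in range(n_per_pop[role]):
                g = alleles[i * ploidy:(i + 1) * ploidy]
                if missing_rate > 0 and rng.random() < missing_rate:
                    gt_fields.append("/".join(["."] * ploidy))
                    called[role] -= ploidy
                    if role != "outgroup":
                        derived_allele = 0 if alt_ancestral else 1
                        der_called[role] -= int((g == derived_allele).sum())
                else:
                    gt_fields.append("/".join(str(a) for a in g))
        if og_poly:
            n_og_poly += 1
        elif called["outgroup"] >= 1 and all(called[p] == n_hap[p] for p in _INGROUP):
            truth[der_called["P1"], der_called["P2"], der_called["P3"]] += 1
        lines.append("\t".join(["chr1", str(pos), ".", "A", "G", ".", "PASS", ".", "GT"]
                               + gt_fields))

    Path(path).write_text("\n".join(lines) + "\n")
    return FixtureTruth(sfs=JointSFS(truth, polarized=True),
                        n_outgroup_polymorphic=n_og_poly, sample_names=names)
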