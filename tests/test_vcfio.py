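"""Tests for the VCF-to-SFS pipeline and the synthetic fixture generator."""

from collections import Counter

import numpy as np
import pytest

from dfspectrum import (FilterConfig, PopulationMap, SiteRecord, build_joint_sfs,
                        make_fixture_vcf, polarize_site, read_sites, vcf_to_joint_sfs)

POPS = {"P1": 2, "P2": 2, "P3": 2, "outgroup": 1}


def popmap(n_per_pop=POPS):
    return PopulationMap({f"{role}_{i}": role
                          for role, n in n_per_pop.items() for i in range(n)})


@pytest.fixture
def fixture_vcf(tmp_path):
    path = tmp_path / "fixture.vcf"
    truth = make_fixture_vcf(path, POPS, n_sites=80, seed=11, ploidy=2,
                             frac_alt_ancestral=0.4, frac_outgroup_polymorphic=0.1)
    return path, truth


class TestPopulationMap:
    def test_roles_required(self):
        with pytest.raises(ValueError, match="outgroup"):
            PopulationMap({"a": "P1", "b": "P2", "c": "P3"})

    def test_unknown_role(self):
        with pytest.raises(ValueError, match="unknown role"):
            PopulationMap({"a": "P1", "b": "P2", "c": "P3", "d": "OG"})

    def test_from_tsv(self, tmp_path):
        p = tmp_path / "popmap.tsv"
        p.write_text("# comment\ns1\tP1\ns2\tP2\ns3\tP3\ns4\toutgroup\n")
        pm = PopulationMap.from_tsv(p)
        assert pm.samples("P3") == ["s3"]


class TestPolarizeSite:
    def _rec(self, og_alt, og_called, p_alt=(1, 2, 3), p_called=(4, 4, 4)):
        return SiteRecord("1", 100,
                          derived={"P1": p_alt[0], "P2": p_alt[1], "P3": p_alt[2],
                                   "outgroup": og_alt},
                          called={"P1": p_called[0], "P2": p_called[1],
                                  "P3": p_called[2], "outgroup": og_called})

    def test_outgroup_fixed_ref_keeps_alt_as_derived(self):
        out = polarize_site(self._rec(og_alt=0, og_called=2))
        assert out.derived == {"P1": 1, "P2": 2, "P3": 3}

    def test_outgroup_fixed_alt_complements(self):
        out = polarize_site(self._rec(og_alt=2, og_called=2))
        assert out.derived == {"P1": 3, "P2": 2, "P3": 1}

    def test_complement_is_involution(self):
        once = polarize_site(self._rec(og_alt=2, og_called=2))
        # complementing the complement restores the original ALT counts
        assert {p: once.called[p] - once.derived[p] for p in once.derived} == \
               {"P1": 1, "P2": 2, "P3": 3}

    def test_polymorphic_outgroup_discarded(self):
        assert polarize_site(self._rec(og_alt=1, og_called=2)) is None

    def test_insufficient_outgroup_calls_discarded(self):
        assert polarize_site(self._rec(og_alt=0, og_called=1),
                             min_outgroup_alleles=2) is None


def _write_vcf(path, rows):
    samples = [f"{role}_{i}" for role, n in POPS.items() for i in range(n)]
    header = ["##fileformat=VCFv4.2", "##contig=<ID=chr1,length=10000>",
              '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
              '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
              "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)]
    path.write_text("\n".join(header + rows) + "\n")


class TestReadSitesFilters:
    def test_biallelic_snp_filters_and_call_rate(self, tmp_path):
        p = tmp_path / "filters.vcf"
        gts = "\t".join(["0/1"] * 7)
        few = "\t".join(["0/1", "./.", "./.", "./.", "./.", "./.", "./."])
        _write_vcf(p, [
            f"chr1\t100\t.\tA\tG\t.\t.\t.\tGT\t{gts}",          # passes
            f"chr1\t200\t.\tA\tG,T\t.\t.\t.\tGT\t{gts}",        # triallelic
            f"chr1\t300\t.\tA\tGT\t.\t.\t.\tGT\t{gts}",         # indel
            f"chr1\t400\t.\tA\t*\t.\t.\t.\tGT\t{gts}",          # spanning deletion
            f"chr1\t500\t.\tA\tG\t.\t.\t.\tGT\t{few}",          # 1/7 genotyped < 80%
        ])
        counters = Counter()
        recs = list(read_sites(p, popmap(), FilterConfig(), counters))
        assert [r.pos for r in recs] == [100]
        assert counters["filtered_not_biallelic"] == 1
        assert counters["filtered_not_snp"] == 2
        assert counters["filtered_low_call"] == 1
        # mass accounting: everything in is either tallied or filtered
        filtered = sum(v for k, v in counters.items() if k.startswith("filtered_"))
        assert counters["sites_in"] == counters["sites_tallied"] + filtered

    def test_allele_counting_from_gt(self, tmp_path):
        p = tmp_path / "counts.vcf"
        gts = "\t".join(["0/0", "0/1", "1/1", "0/1", "0/0", "0/1", "0/0"])
        _write_vcf(p, [f"chr1\t100\t.\tC\tT\t.\t.\t.\tGT\t{gts}"])
        rec = next(read_sites(p, popmap(), FilterConfig()))
        assert rec.called["P1"] == 4 and rec.derived["P1"] == 1
        assert rec.derived["P2"] == 3  # 1/1 + 0/1

    def test_depth_threshold_masks_genotypes(self, tmp_path):
        p = tmp_path / "depth.vcf"
        fields = "\t".join(["0/1:3"] + ["0/1:9"] * 6)
        _write_vcf(p, [f"chr1\t100\t.\tC\tT\t.\t.\t.\tGT:DP\t{fields}"])
        rec = next(read_sites(p, popmap(), FilterConfig(min_depth=5,
                                                        min_call_fraction=0.5)))
        assert rec.called["P1"] == 2  # first diploid masked by DP

    def test_missing_sample_is_configuration_error(self, tmp_path):
        p = tmp_path / "header.vcf"
        _write_vcf(p, [])
        bad = PopulationMap({"P1_0": "P1", "P2_0": "P2", "P3_0": "P3", "nope": "outgroup"})
        with pytest.raises(ValueError, match="nope"):
            list(read_sites(p, bad, FilterConfig()))


class TestBuildJointSfs:
    def test_full_calls_give_unit_mass_and_additivity(self):
        rec = SiteRecord("1", 1, derived={"P1": 1, "P2": 2, "P3": 0},
                         called={"P1": 4, "P2": 4, "P3": 4})
        sfs = build_joint_sfs([rec, rec], (4, 4, 4))
        assert sfs.counts[1, 2, 0] == pytest.approx(2.0)
        assert sfs.total_mass == pytest.approx(2.0)

    def test_partial_site_projected_hypergeometrically(self):
        rec = SiteRecord("1", 1, derived={"P1": 1, "P2": 1, "P3": 1},
                         called={"P1": 4, "P2": 3, "P3": 3})
        counters = Counter()
        sfs = build_joint_sfs([rec], (3, 3, 3), "project", counters)
        # P1: 1 of 4 -> 3 with weights C(1,c)C(3,3-c)/C(4,3) = 1/4, 3/4
        assert sfs.counts[0, 1, 1] == pytest.approx(0.25)
        assert sfs.counts[1, 1, 1] == pytest.approx(0.75)
        assert sfs.total_mass == pytest.approx(1.0)

    def test_drop_policy_requires_exact_calls(self):
        full = SiteRecord("1", 1, derived={"P1": 0, "P2": 1, "P3": 2},
                          called={"P1": 4, "P2": 4, "P3": 4})
        partial = SiteRecord("1", 2, derived={"P1": 0, "P2": 1, "P3": 2},
                             called={"P1": 4, "P2": 4, "P3": 5})
        counters = Counter()
        sfs = build_joint_sfs([full, partial], (4, 4, 4), "drop", counters)
        assert sfs.total_mass == pytest.approx(1.0)
        assert counters["sfs_dropped_policy"] == 1

    def test_below_target_sites_dropped_and_counted(self):
        rec = SiteRecord("1", 1, derived={"P1": 1, "P2": 1, "P3": 1},
                         called={"P1": 2, "P2": 4, "P3": 4})
        counters = Counter()
        with pytest.raises(ValueError, match="no sites"):
            build_joint_sfs([rec], (4, 4, 4), "project", counters)
        assert counters["sfs_dropped_below_target"] == 1


class TestFixtureRoundTrip:
    def test_truth_reproduced_exactly_without_missingness(self, fixture_vcf):
        path, truth = fixture_vcf
        counters = Counter()
        sfs = vcf_to_joint_sfs(path, popmap(), (4, 4, 4), FilterConfig(), counters)
        np.testing.assert_array_equal(sfs.counts, truth.sfs.counts)
        assert counters["filtered_unpolarizable"] == truth.n_outgroup_polymorphic

    def test_fixture_is_deterministic(self, tmp_path):
        a = tmp_path / "a.vcf"
        b = tmp_path / "b.vcf"
        make_fixture_vcf(a, POPS, 30, seed=5, frac_outgroup_polymorphic=0.2)
        make_fixture_vcf(b, POPS, 30, seed=5, frac_outgroup_polymorphic=0.2)
        assert a.read_bytes() == b.read_bytes()
        c = tmp_path / "c.vcf"
        make_fixture_vcf(c, POPS, 30, seed=6, frac_outgroup_polymorphic=0.2)
        assert a.read_bytes() != c.read_bytes()

    def test_missingness_respects_drop_policy(self, tmp_path):
        path = tmp_path / "gaps.vcf"
        truth = make_fixture_vcf(path, POPS, 120, seed=3, missing_rate=0.25)
        counters = Counter()
        filters = FilterConfig(missing_policy="drop", min_call_fraction=0.0)
        sfs = vcf_to_joint_sfs(path, popmap(), (4, 4, 4), filters, counters)
        # drop policy keeps exactly the fully called sites, which is what the
        # truth tensor records
        np.testing.assert_array_equal(sfs.counts, truth.sfs.counts)
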