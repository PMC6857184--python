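"""Phased-VCF ingestion, haplotype extraction and spectrum construction."""

from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

import founderhap as fh
from founderhap.errors import FileFormatError
from founderhap.population import (
    SUPERPOPULATIONS,
    build_spectrum,
    cross_population_table,
    extract_haplotypes,
    label_family_haplotypes,
    read_phased_vcf,
)

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=21>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
"""


def write_popmap(path, samples, pop="IBS", superpop="European"):
    lines = ["sample\tpopulation\tsuper_population"]
    lines += [f"{s}\t{pop}\t{superpop}" for s in samples]
    path.write_text("\n".join(lines) + "\n")


def small_vcf(tmp_path, pop14, drop=(), unphased_at=None):
    """3-sample phased VCF over pop14, alternating 0|1 at every marker."""
    rows = []
    for i, m in enumerate(pop14):
        if m.id in drop:
            continue
        alleles = sorted(m.alleles, key=str)
        ref, alt = (alleles[0], alleles[1]) if len(alleles) > 1 else (alleles[0], "N")
        sep = "/" if m.id == unphased_at else "|"
        gts = [f"0{sep}0", f"0{sep}1" if len(alleles) > 1 else f"0{sep}0", f"1{sep}0" if len(alleles) > 1 else f"0{sep}0"]
        rows.append(
            f"21\t{1000 * (i + 1)}\t{m.id}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    path = tmp_path / "small.vcf"
    path.write_text(VCF_HEADER + "\n".join(rows) + "\n")
    pm = tmp_path / "popmap.tsv"
    write_popmap(pm, ["S1", "S2", "S3"])
    return path, pm


class TestReadPhasedVcf:
    def test_three_sample_panel(self, tmp_path, pop14):
        vcf, pm = small_vcf(tmp_path, pop14)
        pp = read_phased_vcf(vcf, pop14, pm)
        assert pp.n_samples() == 3
        assert pp.dropped_markers == ()
        haps = extract_haplotypes(pp)
        assert len(haps) == 6
        assert all(len(h) == 14 for h in haps)

    def test_absent_marker_dropped_panelwide(self, tmp_path, pop14):
        vcf, pm = small_vcf(tmp_path, pop14, drop=("rs202445",))
        pp = read_phased_vcf(vcf, pop14, pm)
        assert pp.dropped_markers == ("rs202445",)
        assert len(pp.panel) == 13
        assert all(len(h) == 13 for pair in pp.haplotypes for h in pair)

    def test_unphased_genotype_errors_with_context(self, tmp_path, pop14):
        vcf, pm = small_vcf(tmp_path, pop14, unphased_at="rs2070422")
        with pytest.raises(FileFormatError, match="unphased.*rs2070422"):
            read_phased_vcf(vcf, pop14, pm)

    def test_sample_missing_from_popmap(self, tmp_path, pop14):
        vcf, pm = small_vcf(tmp_path, pop14)
        write_popmap(pm, ["S1", "S2"])  # S3 absent
        with pytest.raises(FileFormatError, match="S3"):
            read_phased_vcf(vcf, pop14, pm)

    def test_zero_markers_found(self, tmp_path, pop14, panel16):
        vcf, pm = small_vcf(tmp_path, pop14)
        only_ca = fh.subset_panel(panel16, keep_ids=["CA_repeat"])
        with pytest.raises(FileFormatError, match="zero panel markers"):
            read_phased_vcf(vcf, only_ca, pm)


class TestExtractHaplotypes:
    def test_two_per_sample(self, fixture_dir, pop14):
        cfg, paths = fixture_dir
        pp = read_phased_vcf(paths["vcf"], pop14, paths["popmap"])
        assert len(extract_haplotypes(pp)) == 2 * pp.n_samples()

    def test_population_filter(self, tmp_path, pop14):
        vcf, pm = small_vcf(tmp_path, pop14)
        pm.write_text(
            "sample\tpopulation\tsuper_population\n"
            "S1\tIBS\tEuropean\nS2\tTSI\tEuropean\nS3\tCHB\tEast Asian\n"
        )
        pp = read_phased_vcf(vcf, pop14, pm)
        assert len(extract_haplotypes(pp, populations=["IBS"])) == 2
        assert len(extract_haplotypes(pp, super_population="European")) == 4
        with pytest.raises(KeyError, match="valid"):
            extract_haplotypes(pp, populations=["XXX"])

    def test_superpop_definition_includes_study_codes(self):
        assert set(SUPERPOPULATIONS["European"]) == {"CEU", "FIN", "GBR", "IBS", "TSI"}
        # the source's "GWC" spelling resolves to the 1KG Gambian code
        assert "GWD" in SUPERPOPULATIONS["African"]


class TestBuildSpectrum:
    def test_counting_oracle(self):
        h1, h2, h3 = ("A", "A"), ("A", "C"), ("C", "C")
        spec = build_spectrum([h1] * 3 + [h2] * 2 + [h3])
        assert [e.count for e in spec] == [3, 2, 1]
        assert [e.frequency for e in spec] == [
            Fraction(1, 2),
            Fraction(1, 3),
            Fraction(1, 6),
        ]
        assert [e.rank_name for e in spec] == ["1", "2", "3"]

    def test_single_haplotype(self):
        spec = build_spectrum([("A", "C"), ("A", "C")])
        assert len(spec) == 1
        assert spec.entries[0].frequency == 1
        assert spec.entries[0].rank_name == "1"

    def test_errors(self):
        with pytest.raises(ValueError, match="zero"):
            build_spectrum([])
        with pytest.raises(ValueError, match="length"):
            build_spectrum([("A",), ("A", "C")])
        with pytest.raises(ValueError, match="observed"):
            build_spectrum([("A", None)])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.permutations(list(range(12))))
    def test_permutation_invariance(self, perm):
        base = [("A", "A")] * 5 + [("A", "C")] * 4 + [("C", "A")] * 2 + [("C", "C")]
        spec_a = build_spectrum(base)
        spec_b = build_spectrum([base[i] for i in perm])
        assert spec_a.entries == spec_b.entries

    def test_counts_sum_to_2n(self, fixture_dir, pop14):
        cfg, paths = fixture_dir
        pp = read_phased_vcf(paths["vcf"], pop14, paths["popmap"])
        haps = extract_haplotypes(pp, populations=["IBS"])
        spec = build_spectrum(haps, label="IBS")
        assert spec.total_haplotypes == 2 * pp.n_samples()
        assert sum(e.count for e in spec) == spec.total_haplotypes

    def test_tie_broken_lexicographically(self):
        spec = build_spectrum([("C", "C"), ("A", "A")])
        assert spec.entries[0].haplotype.alleles == ("A", "A")


class TestCrossPopulationTable:
    def _panel_with(self, assignments):
        """Tiny PopulationPanel built directly from per-pop haplotype pairs."""
        from founderhap.model import Marker, MarkerPanel, Haplotype
        from founderhap.population import PanelSample, PopulationPanel

        panel = MarkerPanel(
            (
                Marker(id="m0", kind="snp", alleles=frozenset("AC")),
                Marker(id="m1", kind="snp", alleles=frozenset("AC")),
            )
        )
        samples, haps = [], []
        for pop, pairs in assignments.items():
            for i, pair in enumerate(pairs):
                samples.append(PanelSample(f"{pop}{i}", pop, "X"))
                haps.append(tuple(Haplotype(h) for h in pair))
        return PopulationPanel(panel, tuple(samples), tuple(haps))

    def test_disjoint_groups(self):
        pp = self._panel_with(
            {
                "P1": [(("A", "A"), ("A", "A"))],
                "P2": [(("C", "C"), ("C", "C"))],
            }
        )
        t = cross_population_table(pp, {"g1": ["P1"], "g2": ["P2"]})
        assert t.n_haplotypes == 2
        f = t.frame
        assert f[("g1", "frequency")].tolist() in ([1.0, 0.0], [0.0, 1.0])
        assert f[("g2", "frequency")].tolist() in ([1.0, 0.0], [0.0, 1.0])

    def test_pooled_column_is_weighted_mean(self):
        pp = self._panel_with(
            {
                "P1": [(("A", "A"), ("A", "A"))] * 3,  # 6 haps of AA
                "P2": [(("A", "A"), ("C", "C"))] * 2,  # 2 AA + 2 CC
            }
        )
        t = cross_population_table(pp, {"g1": ["P1"], "g2": ["P2"]})
        f = t.frame
        for hap in f.index:
            pooled = f.loc[hap, ("all", "count")]
            assert pooled == f.loc[hap, ("g1", "count")] + f.loc[hap, ("g2", "count")]
        assert f[("all", "frequency")].iloc[0] == round(8 / 10, 3)

    def test_pooled_matches_build_spectrum(self, fixture_dir, pop14):
        cfg, paths = fixture_dir
        pp = read_phased_vcf(paths["vcf"], pop14, paths["popmap"])
        t = cross_population_table(pp, {"eur": ["IBS"]})
        spec = build_spectrum(extract_haplotypes(pp), label="all")
        assert t.frame[("all", "count")].tolist() == [e.count for e in spec]

    def test_empty_grouping_errors(self, fixture_dir, pop14):
        cfg, paths = fixture_dir
        pp = read_phased_vcf(paths["vcf"], pop14, paths["popmap"])
        with pytest.raises(ValueError):
            cross_population_table(pp, {})


class TestFamilyHaplotypeLabels:
    def test_rank_letter_star_convention(self, panel16, pop14):
        """Two family haplotypes sharing rank 1 (one mutant) plus a lone rank
        label reproduce the 1A / 1V / n / 1A* annotation style."""
        pool = fh.haplotype_pool(panel16, 4)
        spec = build_spectrum(
            [tuple(h[panel16.index_of(m)] for m in pop14.ids) for h in pool]
            * 1
            + [tuple(pool[0][panel16.index_of(m)] for m in pop14.ids)] * 3,
            panel=pop14,
        )
        mut_idx = panel16.index_of("rs121912442")
        h_wt = fh.Haplotype(pool[0])
        h_mut = fh.Haplotype(
            pool[0][:mut_idx] + ("T",) + pool[0][mut_idx + 1:]
        )
        ca = panel16.index_of("CA_repeat")
        h_wt2 = fh.Haplotype(
            pool[0][:ca] + (13,) + pool[0][ca + 1:]
        )
        h_other = fh.Haplotype(pool[1])
        labels = label_family_haplotypes(
            [h_wt, h_mut, h_other, h_wt2], spec, panel16, "rs121912442", "T"
        )
        other_rank = str(spec.rank_of(tuple(pool[1][panel16.index_of(m)] for m in pop14.ids)))
        assert labels[h_wt] == "1A"
        assert labels[h_mut] == "1V"
        assert labels[h_other] == other_rank
        assert labels[h_wt2] == "1A*"
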