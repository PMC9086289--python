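import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from desertscope.regions import (
    Annotation,
    GeneRecord,
    GenomicRegion,
    InfeasibleSamplingError,
    RegionParseError,
    RegionSet,
    SamplerConfig,
    genes_in_regions,
    intersect_region_sets,
    merge_regions,
    read_annotation,
    read_chrom_sizes,
    read_regions,
    region_permutation_test,
    sample_matched_regions,
    write_annotation,
    write_chrom_sizes,
    write_regions,
)


# ---------------------------------------------------------------------------
# Domain type invariants
# ---------------------------------------------------------------------------

class TestGenomicRegion:
    def test_valid(self):
        r = GenomicRegion("chr7", 0, 100, "desert")
        assert r.length == 100

    @pytest.mark.parametrize(
        "chrom,start,end", [("chr1", -1, 5), ("chr1", 5, 5), ("chr1", 10, 5), ("", 0, 5)]
    )
    def test_invalid(self, chrom, start, end):
        with pytest.raises(ValueError):
            GenomicRegion(chrom, start, end)

    def test_overlaps(self):
        a = GenomicRegion("chr1", 0, 10)
        assert a.overlaps(GenomicRegion("chr1", 9, 20))
        assert not a.overlaps(GenomicRegion("chr1", 10, 20))  # half-open
        assert not a.overlaps(GenomicRegion("chr2", 0, 10))


class TestAnnotation:
    def test_duplicate_ids_rejected(self):
        g = GeneRecord("g1", "A", "chr1", 0, 10)
        with pytest.raises(ValueError, match="duplicate"):
            Annotation([g, GeneRecord("g1", "B", "chr1", 20, 30)])

    def test_bad_gene_coords(self):
        with pytest.raises(ValueError):
            GeneRecord("g1", "A", "chr1", 10, 10)


# ---------------------------------------------------------------------------
# BED / TSV I/O
# ---------------------------------------------------------------------------

class TestReadRegions:
    def test_basic_line(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr7\t0\t100\tdesert\n")
        rs = read_regions(p)
        assert len(rs) == 1
        r = rs[0]
        assert (r.chrom, r.start, r.end, r.label) == ("chr7", 0, 100, "desert")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert len(read_regions(p)) == 0

    def test_four_desert_bed(self, tmp_path):
        # four-large-desert layout: one region per chromosome
        p = tmp_path / "deserts.bed"
        p.write_text(
            "chr1\t104000000\t114900000\tdesert1\n"
            "chr3\t76500000\t90500000\tdesert2\n"
            "chr7\t106200000\t123200000\tdesert3\n"
            "chr8\t49400000\t66500000\tdesert4\n"
        )
        rs = read_regions(p)
        assert len(rs) == 4
        assert rs.chromosomes() == ["chr1", "chr3", "chr7", "chr8"]

    def test_malformed_line_names_lineno(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t10\nchr1\t5\n")
        with pytest.raises(RegionParseError, match=":2"):
            read_regions(p)

    def test_end_before_start(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t10\t5\n")
        with pytest.raises(RegionParseError, match=":1"):
            read_regions(p)

    def test_one_based_flag(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr1\t1\t100\tx\n")
        rs = read_regions(p, one_based=True)
        assert (rs[0].start, rs[0].end) == (0, 100)

    def test_roundtrip(self, tmp_path):
        rs = RegionSet(
            "x",
            [GenomicRegion("chr1", 5, 50, "a"), GenomicRegion("chr2", 0, 9, "b")],
        )
        p = tmp_path / "x.bed"
        write_regions(rs, p)
        back = read_regions(p)
        assert [(r.chrom, r.start, r.end, r.label) for r in back] == [
            (r.chrom, r.start, r.end, r.label) for r in rs
        ]


def test_chrom_sizes_roundtrip(tmp_path):
    sizes = {"chr1": 1000, "chr2": 500}
    p = tmp_path / "chrom.sizes"
    write_chrom_sizes(sizes, p)
    assert read_chrom_sizes(p) == sizes


def test_annotation_tsv_roundtrip(tmp_path, toy_annotation):
    p = tmp_path / "genes.tsv"
    write_annotation(toy_annotation, p)
    back = read_annotation(p)
    assert [g.gene_id for g in back] == ["g1", "g2", "g3"]
    assert back.genes[2].end == 60


def test_annotation_gtf(tmp_path):
    p = tmp_path / "genes.gtf"
    p.write_text(
        'chr1\tsrc\tgene\t1\t100\t.\t+\t.\tgene_id "g1"; gene_name "A"; gene_biotype "protein_coding";\n'
        'chr1\tsrc\texon\t1\t50\t.\t+\t.\tgene_id "g1";\n'
        'chr2\tsrc\tgene\t11\t60\t.\t-\t.\tgene_id "g2"; gene_biotype "lncRNA";\n'
    )
    ann = read_annotation(p)
    assert len(ann) == 2
    g1 = ann.genes[0]
    assert (g1.start, g1.end, g1.biotype) == (0, 100, "protein_coding")


# ---------------------------------------------------------------------------
# genes_in_regions
# ---------------------------------------------------------------------------

class TestGenesInRegions:
    def test_empty_regionset(self, toy_annotation):
        assert genes_in_regions(toy_annotation, RegionSet("empty")) == []

    def test_containment_rule(self, toy_annotation):
        # brute-force oracle: g straddling the boundary must be excluded
        rs = RegionSet("r", [GenomicRegion("chr1", 15, 40)])
        expected = [
            g
            for g in toy_annotation
            if 15 <= g.start and g.end <= 40
        ]
        got = genes_in_regions(toy_annotation, rs)
        assert got == expected
        assert [g.gene_id for g in got] == ["g2"]

    def test_overlap_mode(self, toy_annotation):
        rs = RegionSet("r", [GenomicRegion("chr1", 15, 40)])
        got = genes_in_regions(toy_annotation, rs, mode="overlap")
        assert [g.gene_id for g in got] == ["g2", "g3"]

    def test_biotype_filter(self):
        ann = Annotation(
            [
                GeneRecord("g1", "A", "chr1", 0, 10, "protein_coding"),
                GeneRecord("g2", "B", "chr1", 20, 30, "lncRNA"),
            ]
        )
        rs = RegionSet("r", [GenomicRegion("chr1", 0, 100)])
        got = genes_in_regions(ann, rs, biotype="protein_coding")
        assert [g.gene_id for g in got] == ["g1"]

    def test_unknown_chrom_skipped(self, toy_annotation, caplog):
        rs = RegionSet("r", [GenomicRegion("chrZ", 0, 100)])
        with caplog.at_level("WARNING"):
            assert genes_in_regions(toy_annotation, rs) == []
        assert "unknown chromosome" in caplog.text

    def test_whole_genome_returns_all(self, planted_fixture):
        ann = planted_fixture.annotation
        whole = RegionSet(
            "genome",
            [
                GenomicRegion(c, 0, L)
                for c, L in planted_fixture.chrom_sizes.items()
            ],
        )
        got = genes_in_regions(ann, whole, biotype="protein_coding")
        assert len(got) == sum(1 for g in ann if g.biotype == "protein_coding")

    def test_empty_annotation_errors(self):
        with pytest.raises(ValueError, match="empty"):
            genes_in_regions(Annotation([]), RegionSet("r"))

    def test_stable_order(self):
        ann = Annotation(
            [
                GeneRecord("b", "B", "chr2", 0, 10),
                GeneRecord("a", "A", "chr1", 50, 60),
                GeneRecord("c", "C", "chr1", 0, 10),
            ]
        )
        rs = RegionSet(
            "r",
            [GenomicRegion("chr2", 0, 100), GenomicRegion("chr1", 0, 100)],
        )
        assert [g.gene_id for g in genes_in_regions(ann, rs)] == ["c", "a", "b"]


# ---------------------------------------------------------------------------
# intersect_region_sets
# ---------------------------------------------------------------------------

def _covered_bases(rs):
    bases = set()
    for r in rs:
        bases.update((r.chrom, b) for b in range(r.start, r.end))
    return bases


class TestIntersect:
    def test_simple(self):
        a = RegionSet("a", [GenomicRegion("chr1", 0, 10, "d")])
        b = RegionSet("b", [GenomicRegion("chr1", 5, 20, "s")])
        out = intersect_region_sets(a, b)
        assert [(r.start, r.end) for r in out] == [(5, 10)]
        assert out[0].label == "d&s"

    def test_per_base_oracle(self):
        rng = np.random.default_rng(0)
        a = RegionSet(
            "a",
            [GenomicRegion("chr1", 0, 40), GenomicRegion("chr1", 60, 90)],
        )
        for _ in range(20):
            s, l = int(rng.integers(0, 80)), int(rng.integers(1, 30))
            b = RegionSet("b", [GenomicRegion("chr1", s, s + l)])
            out = intersect_region_sets(a, b)
            assert _covered_bases(out) == _covered_bases(a) & _covered_bases(b)

    def test_disjoint(self):
        a = RegionSet("a", [GenomicRegion("chr1", 0, 10)])
        b = RegionSet("b", [GenomicRegion("chr1", 10, 20)])
        assert len(intersect_region_sets(a, b)) == 0

    def test_subset_identity(self):
        a = RegionSet("a", [GenomicRegion("chr1", 5, 10)])
        b = RegionSet("b", [GenomicRegion("chr1", 0, 100)])
        out = intersect_region_sets(a, b)
        assert [(r.chrom, r.start, r.end) for r in out] == [("chr1", 5, 10)]

    @given(
        st.lists(
            st.tuples(st.integers(0, 50), st.integers(1, 20)),
            min_size=0, max_size=4,
        ),
        st.lists(
            st.tuples(st.integers(0, 50), st.integers(1, 20)),
            min_size=0, max_size=4,
        ),
    )
    @settings(max_examples=50, deadline=None)
    def test_commutative_and_bounded(self, a_raw, b_raw):
        a = RegionSet("a", [GenomicRegion("c", s, s + l) for s, l in a_raw])
        b = RegionSet("b", [GenomicRegion("c", s, s + l) for s, l in b_raw])
        ab = intersect_region_sets(a, b)
        ba = intersect_region_sets(b, a)
        assert _covered_bases(ab) == _covered_bases(ba)
        assert len(_covered_bases(ab)) <= min(
            len(_covered_bases(a)), len(_covered_bases(b))
        )

    def test_idempotent(self):
        a = RegionSet("a", [GenomicRegion("chr1", 0, 10), GenomicRegion("chr1", 30, 45)])
        out = intersect_region_sets(a, a)
        assert _covered_bases(out) == _covered_bases(a)


def test_merge_regions():
    rs = RegionSet(
        "m",
        [
            GenomicRegion("chr1", 0, 10),
            GenomicRegion("chr1", 5, 20),
            GenomicRegion("chr1", 30, 40),
        ],
    )
    assert rs.has_self_overlap()
    merged = merge_regions(rs)
    assert [(r.start, r.end) for r in merged] == [(0, 20), (30, 40)]
    assert not merged.has_self_overlap()


# ---------------------------------------------------------------------------
# Matched sampler
# ---------------------------------------------------------------------------

@pytest.fixture
def toy_genome():
    genome = {"chrA": 2_000_000, "chrB": 1_500_000}
    rng = np.random.default_rng(3)
    genes = []
    pos = 0
    for i in range(120):
        chrom = "chrA" if i < 70 else "chrB"
        start = int(rng.integers(0, genome[chrom] - 2000))
        genes.append(
            GeneRecord(f"t{i}", f"T{i}", chrom, start, start + 1000)
        )
    # Annotation requires unique ids only; overlap is fine here
    return genome, Annotation(genes)


def brute_force_check(rep, template, cfg, annotation):
    """Independent constraint checker (plain loops, no package helpers)."""
    assert len(rep) == len(template)
    for r, t in zip(rep, template):
        assert abs(r.length - t.length) <= cfg.length_tolerance
    regs = list(rep.regions)
    for i, r in enumerate(regs):
        if cfg.excluded is not None:
            for e in cfg.excluded:
                assert not (
                    r.chrom == e.chrom and r.start < e.end and e.start < r.end
                )
        for other in regs[i + 1:]:
            assert not (
                r.chrom == other.chrom
                and r.start < other.end
                and other.start < r.end
            )
    n = 0
    for g in annotation:
        for r in regs:
            if g.chrom == r.chrom and g.start >= r.start and g.end <= r.end:
                n += 1
                break
    assert n >= cfg.min_total_genes


class TestSampler:
    def test_zero_replicates(self, toy_genome):
        genome, ann = toy_genome
        template = RegionSet("t", [GenomicRegion("chrA", 0, 100_000)])
        cfg = SamplerConfig(
            n_replicates=0, target_length=100_000, length_tolerance=10_000,
            min_total_genes=0, seed=1,
        )
        assert sample_matched_regions(genome, ann, cfg, template) == []

    def test_constraints_brute_force(self, toy_genome):
        genome, ann = toy_genome
        template = RegionSet(
            "t",
            [
                GenomicRegion("chrA", 100_000, 400_000),
                GenomicRegion("chrB", 0, 200_000),
            ],
        )
        cfg = SamplerConfig(
            n_replicates=25,
            target_length=300_000,
            length_tolerance=50_000,
            min_total_genes=5,
            excluded=template,
            seed=9,
        )
        reps = sample_matched_regions(genome, ann, cfg, template)
        assert len(reps) == 25
        for rep in reps:
            brute_force_check(rep, template, cfg, ann)

    def test_seed_reproducibility(self, toy_genome):
        genome, ann = toy_genome
        template = RegionSet("t", [GenomicRegion("chrA", 0, 200_000)])
        cfg = SamplerConfig(
            n_replicates=5, target_length=200_000, length_tolerance=20_000,
            min_total_genes=0, seed=42,
        )
        a = sample_matched_regions(genome, ann, cfg, template)
        b = sample_matched_regions(genome, ann, cfg, template)
        assert [
            (r.chrom, r.start, r.end) for rep in a for r in rep
        ] == [(r.chrom, r.start, r.end) for rep in b for r in rep]

    def test_infeasible_raises(self, toy_genome):
        genome, ann = toy_genome
        template = RegionSet("t", [GenomicRegion("chrA", 0, 100_000)])
        cfg = SamplerConfig(
            n_replicates=1, target_length=100_000, length_tolerance=1_000,
            min_total_genes=10_000, seed=1, max_attempts=50,
        )
        with pytest.raises(InfeasibleSamplingError, match="attempts"):
            sample_matched_regions(genome, ann, cfg, template)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_replicates=-1)
        with pytest.raises(ValueError):
            SamplerConfig(target_length=10, length_tolerance=10)


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def _stub_replicates(values):
    # stat_fn keyed on region length encodes the null values
    reps = [
        RegionSet(f"r{i}", [GenomicRegion("c", 0, int(v))])
        for i, v in enumerate(values)
    ]
    return reps, lambda rs: float(rs[0].length)


class TestPermutationTest:
    def test_all_equal_two_sided(self):
        reps, fn = _stub_replicates([7] * 10)
        res = region_permutation_test(7.0, fn, reps, "two-sided")
        assert res.p_value == 1.0

    def test_add_one_formula(self):
        reps, fn = _stub_replicates(range(1, 1000))  # 999 nulls, all < 1500
        res = region_permutation_test(1500.0, fn, reps, "greater")
        assert res.p_value == pytest.approx(1 / 1000)

    def test_small_null_exhaustive(self):
        null = [3, 8, 15, 20, 42]
        reps, fn = _stub_replicates(null)
        obs = 12.0
        # brute-force counts
        n_ge = sum(1 for v in null if v >= obs)
        n_le = sum(1 for v in null if v <= obs)
        res_g = region_permutation_test(obs, fn, reps, "greater")
        res_l = region_permutation_test(obs, fn, reps, "less")
        assert res_g.p_value == pytest.approx((1 + n_ge) / 6)
        assert res_l.p_value == pytest.approx((1 + n_le) / 6)
        res_t = region_permutation_test(obs, fn, reps, "two-sided")
        assert res_t.p_value == pytest.approx(
            min(1.0, 2 * min((1 + n_ge) / 6, (1 + n_le) / 6))
        )

    def test_failure_names_replicate(self):
        reps, _ = _stub_replicates([1, 2, 3])

        def bad(rs):
            if rs.name == "r1":
                raise RuntimeError("boom")
            return 0.0

        with pytest.raises(RuntimeError, match="replicate 1"):
            region_permutation_test(0.0, bad, reps)

    def test_no_replicates(self):
        with pytest.raises(ValueError):
            region_permutation_test(0.0, lambda r: 0.0, [])

    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=30),
        st.floats(-100, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_p_bounds(self, null, obs):
        reps, fn = _stub_replicates([abs(int(v)) + 1 for v in null])
        for alt in ("two-sided", "greater", "less"):
            res = region_permutation_test(obs, fn, reps, alt)
            assert 1 / (len(null) + 1) <= res.p_value <= 1.0
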