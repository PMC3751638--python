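"""Tag quantification: I/O round trips, normalization, nearest-TSS
assignment (vs brute force), metagene profiles, the Poisson site caller,
and overlap partitions."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from acetylscope import io
from acetylscope.models import GeneModel
from acetylscope.tags import (
    UNASSIGNED,
    assign_tags_to_nearest_promoter,
    call_binding_sites,
    normalize_factor,
    overlap_partition,
    sites_to_genes,
    tss_profile,
)
from conftest import brute_force_nearest, make_library


class TestTagIO:
    def test_round_trip_identity(self, tmp_path):
        lib = make_library([(("chr1"), 10), ("chr2", 999), ("chr1", 0)])
        path = tmp_path / "tags.bed"
        io.write_tags(lib, path)
        back = io.read_tags(path)
        pd.testing.assert_frame_equal(back.tags, lib.tags)
        io.write_tags(back, tmp_path / "tags2.bed")
        assert (tmp_path / "tags.bed").read_text() == (tmp_path / "tags2.bed").read_text()

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.bed"
        path.write_text("")
        assert io.read_tags(path).total_count == 0

    def test_negative_coordinate_names_line(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t5\t6\tt0\t0\t+\nchr1\t-3\t-2\tt1\t0\t+\nchr1\t9\t10\tt2\t0\t-\n")
        with pytest.raises(io.FormatError, match="line 2"):
            io.read_tags(path)

    def test_annotation_bed_and_gff3_round_trip(self, tmp_path, three_genes):
        bed = tmp_path / "ann.bed"
        io.write_annotation_bed(three_genes, bed)
        assert io.read_annotation_bed(bed) == three_genes
        gff = tmp_path / "ann.gff3"
        io.write_annotation_gff3(three_genes, gff)
        assert io.read_annotation_gff3(gff) == three_genes

    def test_minus_strand_tss_survives_gff3(self, tmp_path):
        g = GeneModel(gene_id="m", chrom="chr1", start=100, end=300, strand="-")
        gff = tmp_path / "m.gff3"
        io.write_annotation_gff3([g], gff)
        back = io.read_annotation_gff3(gff)[0]
        assert back.tss == g.tss == 299


class TestNormalizeFactor:
    def test_million_tags_gives_unity(self):
        lib = make_library(range(10))
        lib.tags = pd.concat([lib.tags] * 100_000, ignore_index=True)
        assert normalize_factor(lib) == 1.0

    def test_arithmetic(self):
        lib = make_library(range(200_000))
        assert 40 * normalize_factor(lib) == 200.0

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            normalize_factor(make_library([]))

    def test_normalized_mass_conservation(self, three_genes):
        """Normalized assigned + unassigned counts sum to exactly 1e6."""
        lib = make_library([("chr1", 1100), ("chr1", 4900), ("chrX", 5), ("chr1", 8000)])
        counts = assign_tags_to_nearest_promoter(lib, three_genes)
        factor = normalize_factor(lib)
        assert sum(counts.values()) * factor == pytest.approx(1e6)


class TestNearestPromoterAssignment:
    def test_no_tags_all_zero(self, three_genes):
        counts = assign_tags_to_nearest_promoter(make_library([]), three_genes)
        assert all(counts[g.gene_id] == 0 for g in three_genes)

    def test_documented_example(self, three_genes):
        # tag 8000: 3000 from g2's TSS vs 1000 from g3's
        lib = make_library([1100, 4900, 8000])
        counts = assign_tags_to_nearest_promoter(lib, three_genes)
        assert (counts["g1"], counts["g2"], counts["g3"]) == (1, 1, 1)

    def test_equidistant_tie_goes_to_smaller_tss(self, three_genes):
        counts = assign_tags_to_nearest_promoter(make_library([3000]), three_genes)
        assert counts["g1"] == 1 and counts["g2"] == 0

    def test_shared_tss_tie_goes_to_lexicographic_smaller(self):
        genes = [
            GeneModel(gene_id="b", chrom="chr1", start=500, end=700, strand="+"),
            GeneModel(gene_id="a", chrom="chr1", start=500, end=900, strand="+"),
        ]
        counts = assign_tags_to_nearest_promoter(make_library([510]), genes)
        assert counts["a"] == 1 and counts["b"] == 0

    def test_unknown_chrom_counted_unassigned(self, three_genes):
        counts = assign_tags_to_nearest_promoter(
            make_library([("chrUn", 100), ("chr1", 1000)]), three_genes)
        assert counts[UNASSIGNED] == 1
        assert sum(counts.values()) == 2

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            assign_tags_to_nearest_promoter(make_library([1]), [])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_instances(self, seed):
        """Vectorised assignment agrees with an O(genes x tags) argmin scan."""
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(2, 50))
        genes = []
        for i in range(n_genes):
            start = int(rng.integers(0, 100_000))
            genes.append(GeneModel(
                gene_id=f"g{i}", chrom=f"chr{rng.integers(1, 4)}", start=start,
                end=start + int(rng.integers(1, 5000)),
                strand=str(rng.choice(["+", "-"]))))
        positions = [(f"chr{rng.integers(1, 4)}", int(rng.integers(0, 105_000)))
                     for _ in range(int(rng.integers(1, 500)))]
        lib = make_library(positions)
        fast = assign_tags_to_nearest_promoter(lib, genes)
        slow = {g.gene_id: 0 for g in genes}
        slow[UNASSIGNED] = 0
        for chrom, pos in positions:
            gid = brute_force_nearest(genes, chrom, pos)
            slow[gid if gid is not None else UNASSIGNED] += 1
        assert fast == slow


class TestTssProfile:
    def test_tags_at_tss_land_in_zero_bin(self, three_genes):
        lib = make_library([1000, 5000, 9000])
        prof = tss_profile(lib, three_genes, flank=500, binwidth=100)
        zero_bin = np.where(prof.bin_left == 0)[0][0]
        assert prof.counts[zero_bin] == 3
        assert prof.counts.sum() == 3

    def test_hand_histogram(self):
        gene = [GeneModel(gene_id="g", chrom="chr1", start=1000, end=2000, strand="+")]
        lib = make_library([850, 950, 1050])  # offsets -150, -50, +50
        prof = tss_profile(lib, gene, flank=200, binwidth=100)
        assert list(prof.bin_left) == [-200, -100, 0, 100]
        assert list(prof.counts) == [1, 1, 1, 0]

    def test_minus_strand_flips_sign(self):
        gene = [GeneModel(gene_id="g", chrom="chr1", start=500, end=1001, strand="-")]
        lib = make_library([1100])  # downstream in genome = upstream of - gene
        prof = tss_profile(lib, gene, flank=200, binwidth=100)
        assert prof.counts[np.where(prof.bin_left == -100)[0][0]] == 1

    def test_mass_conservation_within_flank(self, three_genes, rng):
        pos = rng.integers(0, 12_000, size=300)
        lib = make_library(pos.tolist())
        prof = tss_profile(lib, three_genes, flank=1000, binwidth=100)
        tss = np.array([1000, 5000, 9000])
        d = np.abs(pos[:, None] - tss[None, :]).min(axis=1)
        signed_ok = 0
        for p in pos:
            nearest = tss[np.argmin(np.abs(tss - p))]
            if -1000 <= p - nearest < 1000:
                signed_ok += 1
        assert prof.counts.sum() == signed_ok

    def test_symmetric_simulation_peaks_at_center(self, rng):
        genes = [GeneModel(gene_id=f"g{i}", chrom="chr1", start=20_000 * (i + 1),
                           end=20_000 * (i + 1) + 1000, strand="+") for i in range(20)]
        tss = np.array([g.tss for g in genes])
        offsets = rng.normal(0, 150, size=5000).round().astype(int)
        pos = tss[rng.integers(0, 20, size=5000)] + offsets
        prof = tss_profile(make_library(pos.tolist()), genes, flank=1000, binwidth=100)
        peak = prof.bin_left[np.argmax(prof.counts)]
        assert peak in (-100, 0)
        upstream = prof.counts[prof.bin_left < 0].sum()
        total = prof.counts.sum()
        # binomial 99% band around half the mass
        band = 2.58 * np.sqrt(total * 0.25)
        assert abs(upstream - total / 2) < band

    def test_bad_binwidth_rejected(self, three_genes):
        with pytest.raises(ValueError):
            tss_profile(make_library([1]), three_genes, flank=100, binwidth=0)
        with pytest.raises(ValueError):
            tss_profile(make_library([1]), three_genes, flank=150, binwidth=100)


class TestCallBindingSites:
    def test_single_window_poisson_tail(self):
        """ip=50 vs expected=5 in one window: exact upper tail < 1e-12."""
        ip = make_library(list(range(100, 150)))  # 50 tags in [0, 500)
        inp = make_library([100] * 5 + [10_000] * 995)
        scale = ip.total_count / inp.total_count  # 0.05
        # expected in the first window = 5 * scale = 0.25 -> use min_fold=1
        sites = call_binding_sites(ip, inp, window=500, step=500, alpha=1e-5,
                                   min_fold=1.0)
        first = [s for s in sites if s.start == 0]
        assert first
        exact = stats.poisson.sf(49, max(5 * scale, 0.5))
        assert first[0].enrichment_p == pytest.approx(exact)
        assert exact < 1e-12

    def test_region_without_enrichment_yields_no_sites(self):
        ip = make_library([900_000])
        inp = make_library(list(range(0, 10_000, 10)))
        sites = call_binding_sites(ip, inp, window=500, step=250, alpha=1e-5)
        assert sites == []

    def test_alpha_monotonicity(self, rng):
        pos = np.concatenate([rng.integers(0, 100_000, 5000),
                              rng.normal(50_000, 200, 500).astype(int)])
        ip = make_library(np.clip(pos, 0, None).tolist())
        inp = make_library(rng.integers(0, 100_000, 5000).tolist())
        n_prev = None
        for alpha in (1e-2, 1e-4, 1e-6, 1e-8):
            n = len(call_binding_sites(ip, inp, alpha=alpha, min_fold=1.0))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_type_one_error_controlled(self):
        """IP that is a scaled copy of a uniform input: fraction of windows
        called stays <= 2 * alpha across seeded simulations."""
        # deep input: the plug-in expectation assumes the background is
        # well estimated (see methods note)
        alpha = 0.01
        called = 0
        windows = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            inp = make_library(r.integers(0, 50_000, 20_000).tolist())
            ip = make_library(r.integers(0, 50_000, 2000).tolist())
            sig = call_binding_sites(ip, inp, window=500, step=500, alpha=alpha,
                                     min_fold=1.0)
            # count merged windows back as window units
            called += sum((s.end - s.start) // 500 for s in sig)
            windows += 100  # 50_000 / 500
        assert called / windows <= 2 * alpha

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="input"):
            call_binding_sites(make_library([1]), make_library([]))


class TestSitesToGenes:
    def test_no_sites_empty(self, three_genes):
        genes, counts = sites_to_genes([], three_genes)
        assert genes == set() and counts == {}

    def test_two_sites_one_gene(self, three_genes):
        from acetylscope.models import BindingSite

        sites = [BindingSite("chr1", 900, 1100, 5, 1, 0.001),
                 BindingSite("chr1", 1200, 1400, 5, 1, 0.001)]
        genes, counts = sites_to_genes(sites, three_genes, max_distance=10_000)
        assert genes == {"g1"} and counts == {"g1": 2}

    def test_brute_force_layout(self, three_genes):
        from acetylscope.models import BindingSite

        mids = [500, 2900, 6800, 8900, 30_000]
        sites = [BindingSite("chr1", m - 50, m + 50, 1, 1, 0.01) for m in mids]
        genes, counts = sites_to_genes(sites, three_genes, max_distance=10_000)
        expected = {}
        for m in mids:
            best = min(three_genes, key=lambda g: (abs(m - g.tss), g.tss, g.gene_id))
            if abs(m - best.tss) <= 10_000:
                expected[best.gene_id] = expected.get(best.gene_id, 0) + 1
        assert counts == expected and genes == set(expected)


class TestOverlapPartition:
    def test_identical_sets_single_signature(self):
        sig, _ = overlap_partition({"A": {1, 2}, "B": {1, 2}})
        assert sig == {"A&B": 2}

    def test_documented_example(self):
        sig, _ = overlap_partition({"A": {"x", "y"}, "B": {"y", "z"}, "C": {"y"}})
        assert sig == {"A": 1, "B": 1, "A&B&C": 1}

    def test_disjoint_sets_conserve(self):
        sets = {"A": {1, 2}, "B": {3}, "C": {4, 5, 6}}
        sig, _ = overlap_partition(sets)
        assert sig == {"A": 2, "B": 1, "C": 3}
        assert sum(sig.values()) == 6

    def test_reference_percentages(self):
        sig, pct = overlap_partition({"SS": {1, 2, 3, 4}, "SM": {1, 2, 3, 4, 5}},
                                     reference="SS")
        assert pct == {"SM": 100.0}

    @settings(deadline=None, max_examples=50)
    @given(st.dictionaries(st.sampled_from(["A", "B", "C"]),
                           st.sets(st.integers(0, 20)), min_size=2, max_size=3))
    def test_signature_counts_sum_to_union(self, sets):
        sig, _ = overlap_partition(sets)
        assert sum(sig.values()) == len(set().union(*sets.values()))
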