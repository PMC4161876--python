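import numpy as np
import pytest

from ectocage import (
    GenomicInterval,
    LocusAnnotation,
    ScreenConfig,
    absolute_cutoff_filter,
    build_tss_windows,
    classify_tss_position,
    flag_artifacts,
    lift_windows_dedup,
    pool_counts,
    quartile_filter,
    run_screen,
)
from ectocage.synthetic_data import SimulationConfig, simulate_screen_inputs


class TestPoolCounts:
    def test_single_library(self):
        assert pool_counts({"a": 5}, ["a"]) == 5

    def test_two_libraries_sum(self):
        assert pool_counts({"a": 3, "b": 4}, ["a", "b"]) == 7

    def test_random_fixture_matches_independent_sum(self, rng):
        counts = {f"lib{i}": int(rng.integers(0, 100)) for i in range(20)}
        subset = [f"lib{i}" for i in range(0, 20, 2)]
        assert pool_counts(counts, subset) == sum(counts[k] for k in subset)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            pool_counts({"a": 1}, [])


class TestQuartileFilter:
    def test_all_equal_counts_pass_nothing(self):
        q3, flags = quartile_filter([7, 7, 7, 7, 7])
        assert q3 == 7 and not flags.any()

    def test_linear_interpolation_on_1_to_100(self):
        q3, flags = quartile_filter(list(range(1, 101)))
        assert q3 == pytest.approx(75.25)
        assert int(flags.sum()) == 25

    def test_order_invariance(self, rng):
        counts = rng.integers(0, 1000, size=50)
        q3a, fa = quartile_filter(counts)
        perm = rng.permutation(50)
        q3b, fb = quartile_filter(counts[perm])
        assert q3a == q3b
        assert fa[perm].tolist() == fb.tolist()

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            quartile_filter([1, 2, 3])


class TestAbsoluteCutoff:
    @pytest.mark.parametrize("pooled,cutoff,passes", [
        (100, 100, False),   # strictly more than
        (101, 100, True),
        (1, 0, True),
        (0, 0, False),
    ])
    def test_strictness(self, pooled, cutoff, passes):
        assert absolute_cutoff_filter([pooled], cutoff)[0] == passes

    def test_monotone_in_cutoff(self, rng):
        counts = rng.integers(0, 500, size=40)
        lo = absolute_cutoff_filter(counts, 50)
        hi = absolute_cutoff_filter(counts, 200)
        assert not (hi & ~lo).any()  # raising the cutoff never adds a pass


class TestArtifacts:
    ann = [
        LocusAnnotation("or1", GenomicInterval("chrT", 1000, 3000, "+"), 1000, "gene"),
        LocusAnnotation("psi", GenomicInterval("chrT", 5000, 7000, "+"), 5000, "pseudogene"),
    ]

    def test_window_in_gene_locus_not_artifact(self):
        w = GenomicInterval("chrT", 1500, 1700)
        assert flag_artifacts([w], self.ann) == [False]

    def test_window_in_unannotated_space_is_artifact(self):
        w = GenomicInterval("chrT", 90_000, 90_200)
        assert flag_artifacts([w], self.ann) == [True]

    def test_pseudogene_only_overlap_follows_flag(self):
        w = GenomicInterval("chrT", 5500, 5700)
        assert flag_artifacts([w], self.ann, pseudogene_is_artifact=True) == [True]
        assert flag_artifacts([w], self.ann, pseudogene_is_artifact=False) == [False]


class TestTssPositionClass:
    locus = LocusAnnotation("or1", GenomicInterval("chrT", 10_000, 12_000, "+"), 10_000)

    @pytest.mark.parametrize("tss,expected", [
        (10_000, "at_annotated_start"),
        (10_040, "at_annotated_start"),    # within the 50 bp tolerance
        (9_000, "upstream_proximal"),      # d = 1000
        (8_000, "upstream_proximal"),      # d = 2000, inclusive edge
        (4_000, "upstream_far_discard"),   # d = 6000
        (11_000, "intragenic"),
        (11_700, "intragenic"),
        (12_400, "three_prime_end"),
        (9_700, "unclassified"),           # d = 300: between tolerances
    ])
    def test_classes(self, tss, expected):
        assert classify_tss_position(tss, self.locus) == expected

    def test_minus_strand_orientation(self):
        locus = LocusAnnotation(
            "or2", GenomicInterval("chrT", 10_000, 12_000, "-"), 11_999
        )
        # upstream on '-' means larger coordinates
        assert classify_tss_position(12_999, locus) == "upstream_proximal"
        assert classify_tss_position(18_000, locus) == "upstream_far_discard"
        assert classify_tss_position(11_999, locus) == "at_annotated_start"
        assert classify_tss_position(10_100, locus) == "intragenic"


class TestRunScreen:
    def _run(self, seed=3):
        cfg = SimulationConfig(seed=seed)
        source_ann, target_ann, chains, entities, libraries, truth = (
            simulate_screen_inputs(cfg)
        )
        tss_list = [
            (l.locus_id, l.interval.chrom, l.annotated_tss, l.interval.strand)
            for l in source_ann
        ]
        windows = build_tss_windows(tss_list, cfg.window_width)
        results, _ = lift_windows_dedup(windows, chains)
        sc = ScreenConfig(library_subset=[l.library_id for l in libraries])
        table, meta = run_screen(results, libraries, target_ann, sc)
        return table, meta, truth

    def test_planted_expressed_receptors_become_candidates(self):
        table, _meta, truth = self._run()
        expressed = set(truth.loci.loc[truth.loci.expressed, "entity_id"])
        called = set(table.loc[table.verdict == "candidate", "receptor_id"])
        assert called == expressed

    def test_decoys_flagged_and_only_decoys(self):
        table, _meta, truth = self._run()
        decoys = set(truth.loci.loc[truth.loci.decoy, "entity_id"])
        flagged = set(table.loc[table.artifact, "receptor_id"])
        assert flagged == decoys

    def test_all_zero_libraries_yield_no_candidates(self):
        from ectocage import CtssLibrary
        cfg = SimulationConfig(seed=3)
        source_ann, target_ann, chains, *_ = simulate_screen_inputs(cfg)
        tss_list = [
            (l.locus_id, l.interval.chrom, l.annotated_tss, l.interval.strand)
            for l in source_ann
        ]
        windows = build_tss_windows(tss_list, cfg.window_width)
        results, _ = lift_windows_dedup(windows, chains)
        empty = [CtssLibrary("LIB00", [])]
        sc = ScreenConfig(library_subset=["LIB00"])
        table, meta = run_screen(results, empty, target_ann, sc)
        assert meta["n_candidates"] == 0

    def test_rerun_is_byte_identical(self, tmp_path):
        from ectocage import write_candidates
        t1, _, _ = self._run(seed=11)
        t2, _, _ = self._run(seed=11)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_candidates(t1, p1)
        write_candidates(t2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_raising_abs_cutoff_never_adds_candidates(self):
        cfg = SimulationConfig(seed=5)
        source_ann, target_ann, chains, entities, libraries, truth = (
            simulate_screen_inputs(cfg)
        )
        tss_list = [
            (l.locus_id, l.interval.chrom, l.annotated_tss, l.interval.strand)
            for l in source_ann
        ]
        windows = build_tss_windows(tss_list, cfg.window_width)
        results, _ = lift_windows_dedup(windows, chains)
        libs = [l.library_id for l in libraries]
        lo, _ = run_screen(results, libraries, target_ann,
                           ScreenConfig(library_subset=libs, abs_cutoff=100))
        hi, _ = run_screen(results, libraries, target_ann,
                           ScreenConfig(library_subset=libs, abs_cutoff=500))
        lo_c = set(lo.loc[lo.verdict == "candidate", "receptor_id"])
        hi_c = set(hi.loc[hi.verdict == "candidate", "receptor_id"])
        assert hi_c <= lo_c
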