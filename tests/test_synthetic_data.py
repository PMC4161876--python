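import numpy as np
import pytest

from ectocage import (
    GenomicInterval,
    SimulationConfig,
    promoter_profile,
    read_bed,
    read_chain,
    read_ctss,
    simulate_screen_inputs,
    write_bed,
    write_chain,
    write_ctss,
)
from ectocage.synthetic_data import simulate_genomes


class TestConfigValidation:
    def test_bad_proportion_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(sharp_fraction=1.5)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_receptors=-1)

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_genomes(SimulationConfig(n_receptors=5, collision_pairs=3))


class TestGenomes:
    def test_no_collisions_all_lifts_distinct(self):
        from ectocage import build_tss_windows, lift_windows_dedup
        cfg = SimulationConfig(seed=2, collision_pairs=0)
        src, _tgt, chains, _ents = simulate_genomes(cfg)
        tss = [(l.locus_id, l.interval.chrom, l.annotated_tss,
                l.interval.strand) for l in src]
        _kept, discarded = lift_windows_dedup(
            build_tss_windows(tss, 200), chains
        )
        assert discarded == []

    def test_exactly_three_duplicated_target_coordinates(self):
        from ectocage import build_tss_windows, lift_interval
        cfg = SimulationConfig(seed=2, collision_pairs=3)
        src, _tgt, chains, ents = simulate_genomes(cfg)
        by_id = {e.entity_id: e for e in ents}
        coords = {}
        for l in src:
            if by_id[l.locus_id].unmapped:
                continue
            w = build_tss_windows(
                [(l.locus_id, l.interval.chrom, l.annotated_tss,
                  l.interval.strand)], 200
            )[0]
            r = lift_interval(w.interval, chains)
            assert r.status == "mapped"
            key = (r.target.chrom, r.target.start, r.target.end, r.target.strand)
            coords.setdefault(key, []).append(l.locus_id)
        dup = {k: v for k, v in coords.items() if len(v) > 1}
        assert len(dup) == 3
        assert all(len(v) == 2 for v in dup.values())

    def test_unmapped_subset_has_no_chain(self):
        from ectocage import build_tss_windows, lift_interval
        cfg = SimulationConfig(seed=2, n_unmapped=2)
        src, _tgt, chains, ents = simulate_genomes(cfg)
        unmapped = [e.entity_id for e in ents if e.unmapped]
        assert len(unmapped) == 2
        for l in src:
            if l.locus_id not in unmapped:
                continue
            w = build_tss_windows(
                [(l.locus_id, l.interval.chrom, l.annotated_tss,
                  l.interval.strand)], 200
            )[0]
            assert lift_interval(w.interval, chains).status == "unmapped"

    def test_pseudogene_loci_marked_decoys(self):
        cfg = SimulationConfig(seed=2)
        _src, tgt, _chains, _ents = simulate_genomes(cfg)
        psi = [l for l in tgt if l.biotype == "pseudogene"]
        assert len(psi) == cfg.n_pseudogenes

    def test_fixed_seed_chain_file_byte_identical(self, tmp_path):
        for run in ("a", "b"):
            cfg = SimulationConfig(seed=9)
            _src, _tgt, chains, _ents = simulate_genomes(cfg)
            write_chain(chains, tmp_path / f"{run}.chain")
        assert (tmp_path / "a.chain").read_bytes() == (
            tmp_path / "b.chain").read_bytes()


class TestCtssGeneration:
    def test_depth_is_exact(self):
        cfg = SimulationConfig(seed=3, depth_per_library=200_000)
        *_rest, libs, _truth = simulate_screen_inputs(cfg)
        assert all(l.total_tags == 200_000 for l in libs)

    def test_full_determinism_across_generators(self, tmp_path):
        outs = []
        for run in range(2):
            cfg = SimulationConfig(seed=13)
            src, tgt, chains, _e, libs, truth = simulate_screen_inputs(cfg)
            d = tmp_path / f"run{run}"
            d.mkdir()
            write_bed(src, d / "src.bed")
            write_bed(tgt, d / "tgt.bed")
            write_chain(chains, d / "c.chain")
            for lib in libs:
                write_ctss(lib, d / f"{lib.library_id}.tsv")
            outs.append(d)
        for name in ["src.bed", "tgt.bed", "c.chain", "LIB00.tsv",
                     "LIB01.tsv", "LIB02.tsv"]:
            assert (outs[0] / name).read_bytes() == (outs[1] / name).read_bytes()

    def test_generated_files_parse_through_readers(self, tmp_path):
        cfg = SimulationConfig(seed=5)
        src, tgt, chains, _e, libs, _t = simulate_screen_inputs(cfg)
        write_bed(src, tmp_path / "src.bed")
        write_bed(tgt, tmp_path / "tgt.bed")
        write_chain(chains, tmp_path / "c.chain")
        write_ctss(libs[0], tmp_path / "lib.tsv")
        assert len(read_bed(tmp_path / "src.bed")) == len(src)
        assert len(read_bed(tmp_path / "tgt.bed")) == len(tgt)
        assert len(read_chain(tmp_path / "c.chain").chains) == len(chains.chains)
        assert read_ctss(tmp_path / "lib.tsv").total_tags == libs[0].total_tags

    def test_sharp_and_broad_profiles_match_request(self):
        """Sharp promoters carry >= 90% of locus tags at one position; broad
        promoters spread starts with a 10-90% width near broad_width."""
        cfg = SimulationConfig(seed=7)
        _src, tgt, _chains, ents, libs, truth = simulate_screen_inputs(cfg)
        ann = {l.locus_id: l for l in tgt}
        df = truth.loci
        lib = libs[0]
        for row in df[df.expressed].itertuples(index=False):
            locus = ann[row.entity_id]
            prof = promoter_profile(lib, row.entity_id, locus.interval)
            assert prof.total_tags >= 200
            if row.shape == "sharp":
                assert prof.dominant_fraction >= 0.9
            else:
                w = cfg.broad_width
                assert w / 2 <= prof.iq_width <= 2 * w

    def test_low_planted_tpm_recovered_within_3_binomial_sd(self):
        """A sharp receptor planted at 4.29 TPM in a million-tag library
        realises a locus TPM within 3 binomial SDs of the planted value."""
        cfg = SimulationConfig(seed=6, expression_tpm=4.29,
                               depth_per_library=10**6, background_rate=0.0,
                               expressed_fraction=1.0, sharp_fraction=1.0,
                               collision_pairs=0, n_unmapped=0)
        _src, tgt, _c, _e, libs, truth = simulate_screen_inputs(cfg)
        from ectocage import sum5end_locus, tpm
        ann = {l.locus_id: l for l in tgt}
        p = 4.29e-6
        sd_tpm = np.sqrt(cfg.depth_per_library * p * (1 - p)) / cfg.depth_per_library * 1e6
        for row in truth.loci[truth.loci.expressed].itertuples(index=False):
            cnt = sum5end_locus(libs[0], ann[row.entity_id])
            assert abs(tpm(cnt, libs[0].total_tags) - 4.29) <= 3 * sd_tpm

    def test_zero_background_no_expression_gives_only_bulk(self):
        cfg = SimulationConfig(seed=1, background_rate=0.0,
                               expressed_fraction=0.0, decoy_tpm=0.0)
        _src, tgt, _chains, _e, libs, _t = simulate_screen_inputs(cfg)
        for lib in libs:
            for l in tgt:
                from ectocage import sum5end_locus
                assert sum5end_locus(lib, l) == 0

    def test_depth_zero_with_expression_rejected(self):
        cfg = SimulationConfig(seed=1, depth_per_library=0)
        with pytest.raises(ValueError, match="depth 0"):
            simulate_screen_inputs(cfg)
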