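import numpy as np
import pytest

from chromaccess.fragments import parse_fragments
from chromaccess.motifs import scan_motif
from chromaccess.simulate import (
    SimConfig,
    generate_genome,
    simulate_accessibility_fragments,
    simulate_chip_fragments,
    simulate_mnase_fragments,
    theoretical_dyad_centers,
    write_bedpe,
)


class TestGenerateGenome:
    def test_scan_recovers_exactly_the_planted_sites(self, small_config, small_genome):
        hits = scan_motif(small_genome.sequence, small_config.motif,
                          chrom=small_config.chrom)
        planted = set(zip(small_genome.truth.motif_start,
                          small_genome.truth.motif_end))
        assert {(h.start, h.end) for h in hits} == planted
        assert len(hits) == len(small_genome.truth)

    def test_planted_strands_match_scan(self, small_genome):
        by_start = {s.start: s.strand for s in
                    scan_motif(small_genome.sequence, "WGATAR")}
        for row in small_genome.truth.itertuples():
            assert by_start[row.motif_start] == row.strand

    def test_zero_sites_gives_motif_free_genome(self):
        cfg = SimConfig(genome_length=50_000, n_sites_per_class=0, seed=5)
        sim = generate_genome(cfg)
        assert scan_motif(sim.sequence, cfg.motif) == []
        assert len(sim.truth) == 0

    def test_seed_reproducibility(self, small_config):
        a = generate_genome(small_config)
        b = generate_genome(small_config)
        assert a.sequence == b.sequence
        assert a.truth.equals(b.truth)

    def test_minimum_site_separation(self, small_config, small_genome):
        centers = np.sort(small_genome.truth.center.to_numpy())
        min_gap = 2 * small_config.n_phased_nucleosomes * \
            small_config.nucleosome_spacing
        assert np.diff(centers).min() >= min_gap

    def test_class_balance(self, small_config, small_genome):
        counts = small_genome.truth.label.value_counts()
        assert (counts == small_config.n_sites_per_class).all()

    def test_infeasible_packing_rejected(self):
        cfg = SimConfig(genome_length=10_000, n_sites_per_class=50)
        with pytest.raises(ValueError, match="infeasible"):
            generate_genome(cfg)

    def test_invalid_rate_rejected_with_field_name(self):
        cfg = SimConfig(background_rate=-1.0)
        with pytest.raises(ValueError, match="background_rate"):
            cfg.validate()


class TestMnaseSimulation:
    def test_degenerate_mixture_hits_theoretical_centers_exactly(self):
        cfg = SimConfig(
            genome_length=100_000, n_sites_per_class=1, dyad_jitter_sd=0.0,
            background_rate=0.0, mnase_depth=2000, seed=3,
        )
        sim = generate_genome(cfg)
        frags = simulate_mnase_fragments(sim.truth, "control", cfg)
        allowed = set()
        for center in sim.truth.center:
            allowed.update(theoretical_dyad_centers(int(center), cfg))
        assert frags
        assert all(f.midpoint in allowed for f in frags)

    def test_fragment_lengths_respect_truncation(self, small_config, small_genome):
        frags = simulate_mnase_fragments(small_genome.truth, "control", small_config)
        lengths = np.array([f.length for f in frags])
        lo, hi = small_config.nucleosomal_fragment_length[2:]
        assert lengths.min() >= lo and lengths.max() <= hi

    def test_kd_increases_flanking_dyads_at_inaccessible_sites(self):
        cfg = SimConfig(genome_length=600_000, n_sites_per_class=20,
                        mnase_depth=100_000, seed=9)
        sim = generate_genome(cfg)
        ctrl = simulate_mnase_fragments(sim.truth, "control", cfg)
        kd = simulate_mnase_fragments(sim.truth, "kd", cfg)
        inacc = sim.truth[sim.truth.label == "constitutively_inaccessible"]
        windows = []
        for center in inacc.center:
            for k in (1, 2, 3):
                for sign in (-1, 1):
                    c = int(center) + sign * k * cfg.nucleosome_spacing
                    windows.append((c - 40, c + 40))

        def in_windows(frags):
            return sum(
                1 for f in frags
                if any(lo <= f.midpoint < hi for lo, hi in windows)
            )

        n_ctrl, n_kd = in_windows(ctrl), in_windows(kd)
        # kd flank weight is 1.5x control; require a 3-sigma excess
        assert n_kd - n_ctrl > 3 * np.sqrt(n_kd + n_ctrl)

    def test_no_sites_no_background_rate_gives_empty_output(self):
        cfg = SimConfig(genome_length=50_000, n_sites_per_class=0,
                        background_rate=0.0, seed=2)
        sim = generate_genome(cfg)
        assert simulate_mnase_fragments(sim.truth, "control", cfg) == []

    def test_condition_streams_are_independent_and_reproducible(
        self, small_config, small_genome
    ):
        a = simulate_mnase_fragments(small_genome.truth, "control", small_config)
        b = simulate_mnase_fragments(small_genome.truth, "control", small_config)
        kd = simulate_mnase_fragments(small_genome.truth, "kd", small_config)
        assert a == b
        assert a != kd


class TestAccessibilitySimulation:
    def test_zero_depth_gives_empty_output(self):
        cfg = SimConfig(genome_length=50_000, n_sites_per_class=0,
                        background_rate=0.0, seed=4)
        sim = generate_genome(cfg)
        assert simulate_accessibility_fragments(sim.truth, "pre", cfg) == []

    def test_site_enrichment_in_post_condition(self, small_config, small_genome):
        frags = simulate_accessibility_fragments(small_genome.truth, "post",
                                                 small_config)
        newly = small_genome.truth[small_genome.truth.label == "newly_accessible"]
        in_windows = sum(
            1 for f in frags
            if any(abs(f.midpoint - c) <= 200 for c in newly.center)
        )
        # expected ~ rate*400 per site + background share
        expected = len(newly) * small_config.accessibility_rate[
            "newly_accessible"]["post"] * 400
        assert in_windows > expected * 0.7

    def test_fragment_lengths_in_configured_range(self, small_config, small_genome):
        frags = simulate_accessibility_fragments(small_genome.truth, "pre",
                                                 small_config)
        lo, hi = small_config.accessibility_fragment_length
        assert all(lo <= f.length <= hi for f in frags)


class TestChipSimulation:
    def test_zero_occupancy_gives_uniform_background(self, small_config,
                                                     small_genome):
        from scipy import stats

        frags = simulate_chip_fragments(
            small_genome.truth, {c: 0.0 for c in set(small_genome.truth.label)},
            small_config,
        )
        assert len(frags) == small_config.chip_depth
        mids = np.array([f.midpoint for f in frags])
        ks = stats.kstest(mids / small_config.genome_length, "uniform")
        assert ks.pvalue > 0.01

    def test_occupancy_doubling_doubles_site_counts(self):
        cfg = SimConfig(genome_length=600_000, n_sites_per_class=20,
                        chip_depth=60_000, seed=6)
        sim = generate_genome(cfg)

        def site_counts(scale):
            occ = {c: 0.2 * scale for c in set(sim.truth.label)}
            # keep background absolute size comparable by scaling its fraction
            frags = simulate_chip_fragments(sim.truth, occ, cfg)
            return sum(
                1 for f in frags
                if any(abs(f.midpoint - c) <= 150 for c in sim.truth.center)
            )

        # relative occupancies within one run double per-site weights
        occ_single = {c: 0.2 for c in set(sim.truth.label)}
        per_site = np.array([
            occ_single[l] for l in sim.truth.label
        ])
        doubled = per_site.copy()
        doubled[: len(doubled) // 2] *= 2
        frags = simulate_chip_fragments(sim.truth, doubled, cfg)
        first = sim.truth.center[: len(doubled) // 2]
        second = sim.truth.center[len(doubled) // 2:]
        n1 = sum(1 for f in frags if any(abs(f.midpoint - c) <= 150 for c in first))
        n2 = sum(1 for f in frags if any(abs(f.midpoint - c) <= 150 for c in second))
        assert abs(n1 - 2 * n2) < 3 * np.sqrt(n1 + 4 * n2)
        assert n1 > n2


class TestBedpeEmission:
    def test_round_trip_preserves_fragment_spans(self, small_config, small_genome,
                                                 tmp_path):
        frags = simulate_mnase_fragments(small_genome.truth, "control",
                                         small_config)[:500]
        path = tmp_path / "frags.bedpe"
        write_bedpe(frags, path)
        with open(path) as fh:
            parsed, dropped = parse_fragments(fh, format="bedpe")
        assert dropped == 0
        assert parsed == frags
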