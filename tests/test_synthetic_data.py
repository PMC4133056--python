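import hashlib
from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest

from enhancerstate.core_io import nearest_tss_distance
from enhancerstate.signal_matrix import compute_matrix, rpkm_normalize
from enhancerstate.synthetic_data import (
    SILENCED,
    ArchetypeSpec,
    SimulationConfig,
    simulate_activation,
    simulate_change_experiment,
    simulate_differentiation,
    simulate_gene_rates,
    simulate_genome,
    simulate_interactions,
    simulate_study,
    simulate_tracks,
    write_fixtures,
)
from enhancerstate.target_map import (
    chiapet_targets,
    expression_change_test,
    lineage_activation_fraction,
)


def _dir_digest(d):
    h = hashlib.sha256()
    for p in sorted(Path(d).rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def _small_config(seed=0, **kw):
    archetypes = [
        ArchetypeSpec("promoter-like", {"H3K4me3": 30, "PolII": 20},
                      erna_amplitude=6, count=8, proximal=True),
        ArchetypeSpec(SILENCED, {"5hmC": 30, "5fC": 20, "Tet1": 10}, count=12),
        ArchetypeSpec("active-enhancer",
                      {"H3K4me1": 25, "H3K27ac": 30},
                      erna_amplitude=12, count=10,
                      shapes={"H3K4me1": "bimodal", "H3K27ac": "bimodal"}),
    ]
    return SimulationConfig(
        seed=seed, chrom_size=2_000_000, n_genes=20, archetypes=archetypes, **kw
    )


class TestSimulateGenome:
    def test_counts_and_placement_constraints(self):
        cfg = _small_config()
        genes, tfbs, labels = simulate_genome(cfg)
        assert len(genes) == 20
        assert len(tfbs) == len(labels) == 30
        # genes must not overlap
        spans = sorted((g.start, g.end) for g in genes)
        assert all(spans[i][1] <= spans[i + 1][0] for i in range(len(spans) - 1))
        for r, lab in zip(tfbs, labels):
            d, _ = nearest_tss_distance(r, genes)
            if lab == "promoter-like":
                assert d <= 2_000
            else:
                assert d > 2_000

    def test_distal_filter_recovers_planted_distal_subset(self):
        cfg = _small_config()
        genes, tfbs, labels = simulate_genome(cfg)
        distal = {
            r.name for r in tfbs if nearest_tss_distance(r, genes)[0] > 2_000
        }
        planted = {
            r.name for r, lab in zip(tfbs, labels) if lab != "promoter-like"
        }
        assert distal == planted

    def test_same_seed_gives_identical_coordinates(self):
        a = simulate_genome(_small_config(seed=5))
        b = simulate_genome(_small_config(seed=5))
        assert a[0] == b[0] and a[1] == b[1] and a[2] == b[2]

    def test_genome_too_small_raises(self):
        cfg = _small_config()
        cfg = replace(cfg, chrom_size=200_000)
        with pytest.raises(ValueError, match="too small"):
            simulate_genome(cfg)


class TestSimulateTracks:
    def test_zero_amplitude_archetype_is_background_only(self):
        cfg = _small_config()
        cfg.archetypes.append(ArchetypeSpec("inert", {}, count=10))
        genes, tfbs, labels = simulate_genome(cfg)
        tracks = simulate_tracks(genes, tfbs, labels, cfg)
        vec = tracks["H3K27me3"].chrom_vectors[cfg.chrom]
        b = cfg.bin_size
        cores = np.concatenate([
            vec[r.center // b - 10 : r.center // b + 10]
            for r, lab in zip(tfbs, labels) if lab == "inert"
        ])
        se = np.sqrt(cfg.background_rate / cores.size)
        assert abs(cores.mean() - cfg.background_rate) < 3 * se

    def test_silenced_regions_have_5hmc_but_background_h3k27ac(self):
        cfg = _small_config()
        genes, tfbs, labels = simulate_genome(cfg)
        tracks = simulate_tracks(genes, tfbs, labels, cfg)
        b = cfg.bin_size
        sil = [r for r, lab in zip(tfbs, labels) if lab == SILENCED]
        for mark, expect_high in (("5hmC", True), ("H3K27ac", False)):
            vec = tracks[mark].chrom_vectors[cfg.chrom]
            cores = np.concatenate([
                vec[r.center // b - 10 : r.center // b + 10] for r in sil
            ])
            if expect_high:
                assert cores.mean() > 5 * cfg.background_rate
            else:
                se = np.sqrt(cfg.background_rate / cores.size)
                assert abs(cores.mean() - cfg.background_rate) < 4 * se

    def test_5mc_dips_at_tfbs_cores(self):
        cfg = _small_config()
        genes, tfbs, labels = simulate_genome(cfg)
        tracks = simulate_tracks(genes, tfbs, labels, cfg)
        vec = tracks["5mC"].chrom_vectors[cfg.chrom]
        b = cfg.bin_size
        core = np.concatenate(
            [vec[r.center // b - 3 : r.center // b + 3] for r in tfbs]
        )
        assert core.mean() < 0.5 * cfg.mC_base_rate

    def test_library_size_equals_total_reads(self):
        cfg = _small_config()
        genes, tfbs, labels = simulate_genome(cfg)
        tracks = simulate_tracks(genes, tfbs, labels, cfg)
        for name, t in tracks.items():
            assert t.total_mapped_reads == int(
                sum(v.sum() for v in t.chrom_vectors.values())
            )

    def test_erna_is_bidirectional_at_active_enhancers_only(self):
        cfg = _small_config()
        genes, tfbs, labels = simulate_genome(cfg)
        tracks = simulate_tracks(genes, tfbs, labels, cfg)
        plus = rpkm_normalize(tracks["GROseq_plus"])
        minus = rpkm_normalize(tracks["GROseq_minus"])
        active = [r for r, l in zip(tfbs, labels) if l == "active-enhancer"]
        silent = [r for r, l in zip(tfbs, labels) if l == SILENCED]
        for track in (plus, minus):
            m_active = compute_matrix(active, track, flank=1000, bin_size=100)
            m_silent = compute_matrix(silent, track, flank=1000, bin_size=100)
            assert m_active.values.mean() > 3 * m_silent.values.mean()


class TestInteractions:
    def test_zero_fraction_gives_no_pairs(self):
        cfg = _small_config(wired_fraction=0.0)
        genes, tfbs, labels = simulate_genome(cfg)
        rates = simulate_gene_rates(genes, cfg)
        from enhancerstate.synthetic_data import assign_target_genes
        targets = assign_target_genes(tfbs, labels, genes, rates, cfg)
        pairs, truth = simulate_interactions(tfbs, labels, genes, cfg, targets)
        assert pairs == [] and truth == {}

    def test_full_fraction_wires_every_silenced_region(self):
        cfg = _small_config(wired_fraction=1.0)
        genes, tfbs, labels = simulate_genome(cfg)
        rates = simulate_gene_rates(genes, cfg)
        from enhancerstate.synthetic_data import assign_target_genes
        targets = assign_target_genes(tfbs, labels, genes, rates, cfg)
        pairs, truth = simulate_interactions(tfbs, labels, genes, cfg, targets)
        n_sil = labels.count(SILENCED)
        assert len(pairs) == n_sil == len(truth)

    def test_chiapet_recovery_matches_ground_truth(self):
        cfg = _small_config(wired_fraction=1.0)
        genes, tfbs, labels = simulate_genome(cfg)
        rates = simulate_gene_rates(genes, cfg)
        from enhancerstate.synthetic_data import assign_target_genes
        targets = assign_target_genes(tfbs, labels, genes, rates, cfg)
        pairs, truth = simulate_interactions(tfbs, labels, genes, cfg, targets)
        sil = [r for r, l in zip(tfbs, labels) if l == SILENCED]
        got = chiapet_targets(sil, pairs, genes).targets
        assert got == truth


class TestActivationAndDifferentiation:
    def test_planted_fraction_recovered_exactly(self):
        # 100 distal regions so the planted fractions are exactly representable
        archetypes = [
            ArchetypeSpec(SILENCED, {"5hmC": 30, "5fC": 20}, count=40),
            ArchetypeSpec("active-enhancer", {"H3K27ac": 30},
                          erna_amplitude=10, count=60),
        ]
        cfg = SimulationConfig(seed=1, chrom_size=2_000_000, n_genes=10,
                               archetypes=archetypes,
                               lineage_fractions={"NPC": 0.09,
                                                  "endomesoderm": 0.20})
        genes, tfbs, labels = simulate_genome(cfg)
        calls = simulate_activation(tfbs, labels, genes, cfg)
        out = lineage_activation_fraction(tfbs, calls)
        assert out == {"NPC": 0.09, "endomesoderm": 0.20}

    def test_null_fold_is_rarely_significant(self, study):
        base = study.expr_esc
        targets = set(sorted(base.valid_genes())[:20])
        cfg = replace(study.config, activation_fold=1.0)
        hits = 0
        for tag in range(40):
            after = simulate_differentiation(base, cfg, targets, lineage_tag=tag)
            res = expression_change_test(targets, base, after)
            hits += res.p_value < 0.05
        assert hits <= 4  # >= 90% non-significant under the null

    def test_fourfold_activation_is_reliably_detected(self, study):
        base = study.expr_esc
        targets = set(sorted(base.valid_genes())[:20])
        hits = 0
        for tag in range(20):
            after = simulate_differentiation(base, study.config, targets,
                                             lineage_tag=tag)
            res = expression_change_test(targets, base, after)
            hits += res.p_value < 0.05 and res.direction == "up"
        assert hits >= 18


class TestChangeExperiment:
    def test_null_and_shift_construction(self, rng):
        targets, a, b = simulate_change_experiment(rng, target_log2_shift=2.0)
        assert len(targets) == 50 and len(a.values) == 550
        res = expression_change_test(targets, a, b)
        assert res.p_value < 1e-6 and res.direction == "up"


class TestStudyDeterminism:
    def test_fixture_files_byte_identical_across_runs(self, tmp_path):
        cfg = _small_config(seed=9)
        write_fixtures(simulate_study(cfg), tmp_path / "a")
        write_fixtures(simulate_study(_small_config(seed=9)), tmp_path / "b")
        assert _dir_digest(tmp_path / "a") == _dir_digest(tmp_path / "b")

    def test_different_seed_changes_output(self, tmp_path):
        write_fixtures(simulate_study(_small_config(seed=1)), tmp_path / "a")
        write_fixtures(simulate_study(_small_config(seed=2)), tmp_path / "b")
        assert _dir_digest(tmp_path / "a") != _dir_digest(tmp_path / "b")


class TestConfigValidation:
    def test_silenced_archetype_invariant_enforced(self):
        with pytest.raises(ValueError, match="silenced"):
            SimulationConfig(archetypes=[
                ArchetypeSpec(SILENCED, {"5hmC": 10, "5fC": 5, "H3K4me1": 3}),
            ])

    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(wired_fraction=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(lineage_fractions={"NPC": -0.1})
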