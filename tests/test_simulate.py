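"""Generative model: genome, library, selection, sequencing, orchestration."""

import numpy as np
import pytest

from tnselect.simulate import (
    MutantLibrary,
    SelectionModel,
    apply_phage_selection,
    apportion_classes,
    build_library,
    generate_genome,
    sequence_library,
    simulate_experiment,
)

SMALL_FRACTIONS = {
    "neutral": 0.85,
    "essential": 0.05,
    "resistance": 0.05,
    "costly_resistance": 0.05,
}


def small_model(**kw):
    defaults = dict(
        n_genes=100,
        class_fractions=SMALL_FRACTIONS,
        library_size=5000,
        read_depth=50_000,
        survivor_plate_capacity=5000,
        control_plate_capacity=500_000,
        seed=7,
    )
    defaults.update(kw)
    return SelectionModel(**defaults)


class TestGenerateGenome:
    def test_zero_genes_is_an_error(self):
        with pytest.raises(ValueError):
            generate_genome(0)

    def test_same_seed_is_deterministic(self):
        a, _ = generate_genome(50, class_fractions=SMALL_FRACTIONS, seed=3)
        b, _ = generate_genome(50, class_fractions=SMALL_FRACTIONS, seed=3)
        assert [(g.gene_id, g.start, g.end, g.strand) for g in a] == [
            (g.gene_id, g.start, g.end, g.strand) for g in b
        ]

    def test_largest_remainder_apportionment(self):
        counts = apportion_classes(100, SMALL_FRACTIONS)
        assert counts == {
            "neutral": 85,
            "essential": 5,
            "resistance": 5,
            "costly_resistance": 5,
        }

    def test_apportionment_always_sums_to_n(self):
        fractions = {"neutral": 1 / 3, "essential": 1 / 3, "resistance": 1 / 3}
        for n in (1, 2, 7, 100):
            assert sum(apportion_classes(n, fractions).values()) == n

    def test_genes_are_non_overlapping_and_in_bounds(self):
        ann, _ = generate_genome(80, class_fractions=SMALL_FRACTIONS, seed=1)
        prev_end = 0
        for g in ann:
            assert g.start > prev_end
            prev_end = g.end
        assert prev_end <= ann.contig_length

    def test_two_small_genes_are_planted(self):
        ann, _ = generate_genome(
            100, class_fractions=SMALL_FRACTIONS, seed=2, small_gene_len=400
        )
        small = [g for g in ann if g.length < 400]
        assert len(small) >= 2
        # the designated pair is resistance-class so the review path is realistic
        small_resistant = [g for g in small if g.sim_attrs.gene_class == "resistance"]
        assert len(small_resistant) >= 2

    def test_sequence_matches_contig_length(self):
        ann, seq = generate_genome(5, seed=0, with_sequence=True)
        assert len(seq) == ann.contig_length
        assert set(seq) <= set("ACGT")


class TestBuildLibrary:
    def test_essential_genes_are_insertion_voids(self):
        model = small_model()
        ann, _ = generate_genome(100, class_fractions=SMALL_FRACTIONS, seed=model.seed)
        lib = build_library(ann, model)
        essential = {g.gene_id for g in ann if g.sim_attrs.gene_class == "essential"}
        assert essential  # planted by construction
        assert not any(gid in essential for gid in lib.gene_ids)

    def test_fitness_scales_mean_abundance(self):
        """w=0.1 vs w=1.0 gives a ~0.1 mean abundance ratio over many draws."""
        model = small_model(library_size=40_000, seed=11)
        ann, _ = generate_genome(100, class_fractions=SMALL_FRACTIONS, seed=model.seed)
        lib = build_library(ann, model)
        cls = {g.gene_id: g.sim_attrs.gene_class for g in ann}
        costly = [
            a for a, gid in zip(lib.abundances, lib.gene_ids)
            if gid and cls[gid] == "costly_resistance"
        ]
        neutral = [
            a for a, gid in zip(lib.abundances, lib.gene_ids)
            if gid and cls[gid] == "neutral"
        ]
        ratio = np.mean(costly) / np.mean(neutral)
        assert ratio == pytest.approx(0.1, rel=0.25)  # Monte-Carlo tolerance

    def test_fixed_seed_reproduces_site_map(self):
        model = small_model()
        ann, _ = generate_genome(100, class_fractions=SMALL_FRACTIONS, seed=model.seed)
        a = build_library(ann, model, seed=5)
        b = build_library(ann, model, seed=5)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.abundances, b.abundances)

    def test_sites_lie_in_allowed_space(self):
        model = small_model()
        ann, _ = generate_genome(100, class_fractions=SMALL_FRACTIONS, seed=model.seed)
        lib = build_library(ann, model)
        spans = {g.gene_id: (g.start, g.end) for g in ann}
        for pos, gid in zip(lib.positions, lib.gene_ids):
            assert 1 <= pos <= ann.contig_length
            if gid:
                s, e = spans[gid]
                assert s <= pos <= e


class TestPhageSelection:
    def _setup(self, **kw):
        model = small_model(**kw)
        ann, _ = generate_genome(
            100,
            class_fractions=SMALL_FRACTIONS,
            seed=model.seed,
            escape_baseline=model.escape_baseline,
            resistance_survival=model.resistance_survival,
        )
        return model, ann, build_library(ann, model)

    def test_perfect_selection_limiting_case(self):
        model, ann, lib = self._setup(escape_baseline=0.0, resistance_survival=1.0)
        survivors = apply_phage_selection(lib, ann, model, seed=1)
        resistant = {
            g.gene_id
            for g in ann
            if g.sim_attrs.gene_class in ("resistance", "costly_resistance")
        }
        assert len(survivors) > 0
        assert all(gid in resistant for gid in survivors.gene_ids)

    def test_escape_rate_matches_binomial_expectation(self, rng):
        """epsilon=0.001 over 1e6 sensitive mutants -> ~1000 escapees +-4 sigma."""
        n = 1_000_000
        eps = 1e-3
        lib = MutantLibrary(
            positions=np.arange(1, n + 1),
            gene_ids=np.array([""] * n, dtype=object),  # all intergenic = sensitive
            abundances=np.ones(n),
        )
        model = small_model(escape_baseline=eps, survivor_plate_capacity=n)
        ann, _ = generate_genome(10, seed=0)
        survivors = apply_phage_selection(lib, ann, model, seed=42)
        expected = n * eps
        sigma = np.sqrt(n * eps * (1 - eps))
        assert abs(len(survivors) - expected) < 4 * sigma

    def test_capacity_at_least_survivors_is_identity(self):
        model, ann, lib = self._setup(survivor_plate_capacity=10**9)
        survivors = apply_phage_selection(lib, ann, model, seed=3)
        resurvived = apply_phage_selection(lib, ann, model, seed=3)
        np.testing.assert_array_equal(survivors.positions, resurvived.positions)
        assert len(survivors) <= len(lib)

    def test_bottleneck_caps_library_size(self):
        model, ann, lib = self._setup()
        control = apply_phage_selection(
            lib, ann, small_model(control_plate_capacity=100), seed=3, challenged=False
        )
        assert len(control) == 100

    def test_empty_library_is_an_error(self):
        model, ann, _ = self._setup()
        empty = MutantLibrary(
            np.array([], dtype=np.int64), np.array([], dtype=object), np.array([])
        )
        with pytest.raises(ValueError):
            apply_phage_selection(empty, ann, model)

    def test_survival_monotone_in_s_under_common_random_numbers(self):
        """Raising s for one gene never removes one of its survivors."""
        model, ann, lib = self._setup()
        gene = next(g for g in ann if g.sim_attrs.gene_class == "resistance")
        low = apply_phage_selection(lib, ann, small_model(resistance_survival=0.3), seed=9)
        high = apply_phage_selection(lib, ann, small_model(resistance_survival=0.9), seed=9)
        low_pos = set(low.positions[low.gene_ids == gene.gene_id].tolist())
        high_pos = set(high.positions[high.gene_ids == gene.gene_id].tolist())
        assert low_pos <= high_pos


class TestSequenceLibrary:
    def _library(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        return MutantLibrary(
            positions=np.arange(1, n + 1),
            gene_ids=np.array([""] * n, dtype=object),
            abundances=rng.gamma(1.0, size=n),
        )

    def test_zero_depth_gives_empty_table(self):
        table = sequence_library(self._library(), 0)
        assert table.counts == {}
        assert table.total_reads == 0

    def test_depth_is_conserved_exactly(self):
        for depth in (1, 1000, 123_457):
            table = sequence_library(self._library(), depth, dispersion=5.0, seed=1)
            assert table.total_reads == depth

    def test_single_site_gets_all_reads(self):
        lib = MutantLibrary(
            np.array([42]), np.array([""], dtype=object), np.array([3.0])
        )
        table = sequence_library(lib, 500, seed=0)
        assert table.counts == {42: 500}

    def test_infinite_dispersion_matches_multinomial_variance(self):
        """With dispersion=inf the per-site variance is multinomial; finite
        dispersion inflates it."""
        lib = self._library(n=50, seed=3)
        depth = 20_000
        ab = np.array([lib.site_abundances()[p] for p in sorted(lib.site_abundances())])
        q = ab / ab.sum()
        reps = 400
        draws_inf = np.zeros((reps, 50))
        draws_od = np.zeros((reps, 50))
        for i in range(reps):
            t_inf = sequence_library(lib, depth, np.inf, seed=1000 + i)
            t_od = sequence_library(lib, depth, 0.2, seed=5000 + i)
            for j, p in enumerate(sorted(lib.site_abundances())):
                draws_inf[i, j] = t_inf.counts.get(p, 0)
                draws_od[i, j] = t_od.counts.get(p, 0)
        var_multinomial = depth * q * (1 - q)
        ratio_inf = draws_inf.var(axis=0).sum() / var_multinomial.sum()
        ratio_od = draws_od.var(axis=0).sum() / var_multinomial.sum()
        assert ratio_inf == pytest.approx(1.0, rel=0.2)
        assert ratio_od > 2.0  # strong overdispersion at low concentration


class TestSimulateExperiment:
    def test_two_phage_and_two_control_samples(self, default_experiment):
        conditions = [t.condition for t in default_experiment.tables]
        assert conditions.count("phage") == 2
        assert conditions.count("control") == 2
        sheet = default_experiment.sample_sheet
        assert set(sheet.loc[sheet.condition == "phage", "paired_control_id"]) == {
            "control_1",
            "control_2",
        }

    def test_truth_table_matches_apportionment(self, default_experiment):
        counts = default_experiment.truth["gene_class"].value_counts().to_dict()
        model = SelectionModel()
        assert counts == apportion_classes(model.n_genes, model.class_fractions)
        assert default_experiment.truth["planted_hit"].sum() == 15

    def test_resistance_read_share_enriched_in_challenge(self, default_experiment):
        """Planted genes' challenged read share >> their control share."""
        from tnselect.genome import assign_sites_to_genes

        exp = default_experiment
        planted = set(exp.truth.loc[exp.truth.planted_hit, "gene_id"])
        chal, ctrl = exp.challenged[0], exp.controls[0]
        pc = assign_sites_to_genes(chal, exp.annotation)
        pk = assign_sites_to_genes(ctrl, exp.annotation)
        share_chal = sum(pc[g].gene_total for g in planted) / chal.total_reads
        share_ctrl = sum(pk[g].gene_total for g in planted) / ctrl.total_reads
        assert share_chal > 50 * share_ctrl

    def test_essential_genes_have_zero_counts_everywhere(self, default_experiment):
        from tnselect.genome import assign_sites_to_genes

        exp = default_experiment
        essential = set(
            exp.truth.loc[exp.truth.gene_class == "essential", "gene_id"]
        )
        for table in exp.tables:
            profiles = assign_sites_to_genes(table, exp.annotation)
            assert all(profiles[g].gene_total == 0 for g in essential)

    def test_same_seed_reproduces_tables(self):
        model = small_model()
        a = simulate_experiment(model)
        b = simulate_experiment(model)
        for ta, tb in zip(a.tables, b.tables):
            assert ta.counts == tb.counts

    def test_written_artifacts_round_trip(self, tmp_path):
        from tnselect import io as tio

        model = small_model()
        exp = simulate_experiment(model, out_dir=tmp_path)
        ann = tio.read_annotation(tmp_path / "genome.gff3")
        assert ann.gene_ids == exp.annotation.gene_ids
        meta = {
            r["sample_id"]: dict(condition=r["condition"])
            for _, r in exp.sample_sheet.iterrows()
        }
        tables = tio.read_counts_tsv(tmp_path / "counts.tsv", sample_meta=meta)
        by_id = {t.sample_id: t for t in tables}
        for t in exp.tables:
            assert by_id[t.sample_id].counts == t.counts
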