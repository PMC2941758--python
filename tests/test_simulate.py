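"""The synthetic cohort generator: determinism, planted signal, scoring."""

import numpy as np
import pandas as pd
import pytest

from estsplice.events import find_cassette_exons, LabeledIntron
from estsplice.model import GenomeInterval, infer_introns
from estsplice.simulate import (
    CohortConfig,
    PlantedEvent,
    generate_cohort,
    ground_truth_table,
    load_cohort_config,
    shuffle_conditions,
    truth_eval,
)


def _support(cfg):
    genes, libs, ests, truth = generate_cohort(cfg)
    introns = infer_introns(ests, {l.library_id: l for l in libs})
    return genes, libs, ests, truth, {
        (i.gene_id, i.interval.start, i.interval.end): i for i in introns}


class TestConfigValidation:
    def test_psi_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="psi"):
            PlantedEvent("G000", "cassette", 2, 1.2, 0.1, "CNS")

    def test_event_on_unknown_gene_rejected(self):
        cfg = CohortConfig(n_genes=2, planted_events=[
            PlantedEvent("G009", "cassette", 2, 0.9, 0.1, "CNS")])
        with pytest.raises(ValueError, match="unknown gene"):
            cfg.validate()

    def test_terminal_target_exon_rejected(self):
        cfg = CohortConfig(exons_per_gene=(4, 5), planted_events=[
            PlantedEvent("G000", "double_cassette", 2, 0.9, 0.1, "CNS")])
        with pytest.raises(ValueError, match="internal"):
            cfg.validate()

    def test_validation_happens_before_sampling(self):
        cfg = CohortConfig(n_genes=0)
        with pytest.raises(ValueError):
            generate_cohort(cfg)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cohort.yaml"
        path.write_text(
            "n_genes: 4\n"
            "est_count_mean: 50\n"
            "seed: 3\n"
            "planted_events:\n"
            "  - {gene_id: G001, kind: cassette, exon_index: 2,"
            " psi_normal: 0.9, psi_tumor: 0.1, tissue: CNS}\n"
        )
        cfg = load_cohort_config(str(path))
        assert cfg.n_genes == 4
        assert cfg.planted_events[0].gene_id == "G001"


class TestDeterminism:
    def test_same_seed_identical_outputs(self, small_cohort_config):
        a = generate_cohort(small_cohort_config)
        b = generate_cohort(small_cohort_config)
        assert a[0] == b[0]
        assert a[1] == b[1]
        assert a[2] == b[2]
        pd.testing.assert_frame_equal(a[3], b[3])

    def test_different_seed_different_ests(self, small_cohort_config):
        import dataclasses
        other = dataclasses.replace(small_cohort_config, seed=99)
        a = generate_cohort(small_cohort_config)[2]
        b = generate_cohort(other)[2]
        assert a != b

    def test_adding_genes_preserves_existing_gene_ests(self):
        base = CohortConfig(n_genes=3, est_count_mean=40.0,
                            planted_events=[], seed=5)
        import dataclasses
        bigger = dataclasses.replace(base, n_genes=4)
        ests_a = [e for e in generate_cohort(base)[2]]
        ests_b = [e for e in generate_cohort(bigger)[2]
                  if e.gene_id != "G003"]
        assert ests_a == ests_b


class TestEmittedCohort:
    def test_library_totals_match_emitted_records(self, small_cohort):
        _genes, libs, ests, _truth = small_cohort
        counts = {}
        for e in ests:
            counts[e.library_id] = counts.get(e.library_id, 0) + 1
        for lib in libs:
            assert lib.est_total == counts.get(lib.library_id, 0)

    def test_degenerate_psi_splits_junction_support_by_condition(self):
        cfg = CohortConfig(
            libraries_per_tissue_per_condition=1,
            est_count_mean=500.0,
            n_genes=1,
            planted_events=[
                PlantedEvent("G000", "cassette", 2, 1.0, 0.0, "CNS")],
            seed=11,
        )
        _g, _l, _e, truth, sup = _support(cfg)
        row = truth.iloc[0]
        for part in row.inclusion_introns.split(";"):
            s, e = map(int, part.split("-"))
            k_t, k_n = sup[("G000", s, e)].counts_in("CNS")
            assert k_t == 0 and k_n > 100
        s, e = map(int, row.skipping_introns.split("-"))
        k_t, k_n = sup[("G000", s, e)].counts_in("CNS")
        assert k_n == 0 and k_t > 100

    def test_balanced_psi_junction_support_is_condition_symmetric(self):
        """At PSI 0.5/0.5 no junction carries a condition signal: the
        tumor share of each planted junction's support stays within 3
        binomial SDs of one half.  (Inclusion vs skipping support is not
        compared against the raw PSI because the two isoforms differ in
        length, hence in junction-spanning probability.)"""
        cfg = CohortConfig(
            libraries_per_tissue_per_condition=1,
            est_count_mean=800.0,
            n_genes=1,
            planted_events=[
                PlantedEvent("G000", "cassette", 2, 0.5, 0.5, "CNS")],
            seed=13,
        )
        _g, libs, ests, truth, sup = _support(cfg)
        # the null tumor share is the libraries' share of gene ESTs,
        # not 1/2: library sizes are themselves random
        by_cond = {l.library_id: l.condition for l in libs}
        n_tum = sum(1 for e in ests if by_cond[e.library_id] == "tumor")
        share = n_tum / len(ests)
        row = truth.iloc[0]
        spans = row.inclusion_introns.split(";") + \
            row.skipping_introns.split(";")
        for part in spans:
            s, e = map(int, part.split("-"))
            k_t, k_n = sup[("G000", s, e)].counts_in("CNS")
            n = k_t + k_n
            assert n > 200
            assert abs(k_t / n - share) <= 3 * np.sqrt(share * (1 - share) / n)

    def test_partial_coverage_leaves_single_block_ests(self, small_cohort):
        _g, _l, ests, _t = small_cohort
        n_single = sum(1 for e in ests if len(e.blocks) == 1)
        assert 0 < n_single < len(ests)


class TestShuffleConditions:
    def test_stratified_shuffle_balances_conditions(self, small_cohort):
        _g, libs, _e, _t = small_cohort
        shuffled = shuffle_conditions(libs, seed=21)
        by_cond = {}
        original = {l.library_id: l.condition for l in libs}
        for lib in shuffled:
            by_cond.setdefault(lib.condition, []).append(
                original[lib.library_id])
        # each pseudo-condition holds one true-normal and one true-tumor
        for conds in by_cond.values():
            assert sorted(conds) == ["normal", "tumor"]

    def test_stratified_requires_even_equal_groups(self):
        from estsplice.model import Library
        libs = [Library("a", "CNS", "normal", 5),
                Library("b", "CNS", "tumor", 5),
                Library("c", "CNS", "tumor", 5)]
        with pytest.raises(ValueError, match="stratified"):
            shuffle_conditions(libs, seed=1)

    def test_naive_shuffle_preserves_label_multiset(self, small_cohort):
        _g, libs, _e, _t = small_cohort
        shuffled = shuffle_conditions(libs, seed=2, stratified=False)
        assert sorted(l.condition for l in shuffled) == \
            sorted(l.condition for l in libs)


class TestTruthEval:
    def _truth(self, genes, events):
        return ground_truth_table(genes, events)

    def test_detected_equal_truth(self, small_cohort_config, small_cohort):
        genes, _l, _e, truth = small_cohort
        from estsplice.simulate import planted_intron_sets
        from estsplice.events import SpliceEvent
        from estsplice.model import GenomeInterval

        detected = []
        by_id = {g.gene_id: g for g in genes}
        for ev in small_cohort_config.planted_events:
            incl, skip = planted_intron_sets(by_id[ev.gene_id], ev)
            chrom = by_id[ev.gene_id].interval.chrom
            detected.append(SpliceEvent(
                ev.gene_id, ev.tissue, ev.kind,
                tuple(GenomeInterval(chrom, s, e) for s, e in incl),
                tuple(GenomeInterval(chrom, s, e) for s, e in skip),
                tuple(GenomeInterval(chrom, a.end + 1, b.start - 1)
                      for (a, b) in zip(
                          [GenomeInterval(chrom, s, e) for s, e in incl],
                          [GenomeInterval(chrom, s, e) for s, e in incl][1:]))
                if ev.kind != "mutually_exclusive" else
                (GenomeInterval(chrom, incl[0][1] + 1, incl[1][0] - 1),
                 GenomeInterval(chrom, skip[0][1] + 1, skip[1][0] - 1)),
                # canonical orientation: ME inclusion is the tumor chain
                "T" if ev.kind == "mutually_exclusive"
                else ev.condition_of_inclusion,
            ))
        report = truth_eval(detected, truth)
        assert report.recall == 1.0
        assert report.precision == 1.0

    def test_empty_detection_has_undefined_precision(self, small_cohort):
        _g, _l, _e, truth = small_cohort
        report = truth_eval([], truth)
        assert report.recall == 0.0
        assert np.isnan(report.precision)

    def test_counting_with_spurious_detection(self):
        """10 planted, 8 matched plus 1 spurious: recall 0.8, precision 8/9."""
        import pandas as pd
        rows = []
        for i in range(10):
            base = 1000 * i
            rows.append({
                "gene_id": f"G{i:03d}", "anatomical_system": "CNS",
                "kind": "cassette", "condition_of_inclusion": "T",
                "inclusion_introns": f"{base+1}-{base+100};{base+201}-{base+300}",
                "skipping_introns": f"{base+1}-{base+300}",
                "psi_normal": 0.1, "psi_tumor": 0.9,
            })
        truth = pd.DataFrame(rows)
        from estsplice.events import SpliceEvent
        from estsplice.model import GenomeInterval

        def cassette(i, shift=0):
            base = 1000 * i + shift
            return SpliceEvent(
                f"G{i:03d}", "CNS", "cassette",
                (GenomeInterval("chrS", base + 1, base + 100),
                 GenomeInterval("chrS", base + 201, base + 300)),
                (GenomeInterval("chrS", base + 1, base + 300),),
                (GenomeInterval("chrS", base + 101, base + 200),),
                "T",
            )

        detected = [cassette(i) for i in range(8)] + [cassette(8, shift=7)]
        report = truth_eval(detected, truth)
        assert report.recall == pytest.approx(0.8)
        assert report.precision == pytest.approx(8 / 9)


def test_planted_introns_are_detectable_by_construction(small_cohort,
                                                        small_cohort_config):
    """Sanity: with degenerate labels assigned from truth, the cassette
    finder recovers the planted cassette exactly."""
    genes, _l, _e, truth = small_cohort
    row = truth[truth.kind == "cassette"].iloc[0]
    incl = [tuple(map(int, p.split("-")))
            for p in row.inclusion_introns.split(";")]
    skip = [tuple(map(int, p.split("-")))
            for p in row.skipping_introns.split(";")]
    side = row.condition_of_inclusion
    other = "N" if side == "T" else "T"
    labeled = [LabeledIntron(GenomeInterval("chrS", s, e), side)
               for s, e in incl]
    labeled += [LabeledIntron(GenomeInterval("chrS", s, e), other)
                for s, e in skip]
    (ev,) = find_cassette_exons(row.gene_id, "CNS", labeled)
    assert ev.condition_of_inclusion == side
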