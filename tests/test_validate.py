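"""Drug-target validation: coverage, hit fractions, O/E enrichment, Fisher tail."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from screenlink import synth, validate
from screenlink.correlate import CorrelationTable, GENE_DRUG, correlate_cross
from screenlink.errors import DataError
from screenlink.io import TargetAnnotation, expand_pairs


def hypergeom_tail_exact(O, n_ann, n_pass, n_total):
    """Right tail P(X >= O) by explicit factorial arithmetic (exact rationals)."""
    total = Fraction(0)
    for x in range(O, min(n_ann, n_pass) + 1):
        total += Fraction(
            math.comb(n_ann, x) * math.comb(n_total - n_ann, n_pass - x),
            math.comb(n_total, n_pass),
        )
    return float(total)


def _corr_from_pairs(rows):
    """rows: (gene, drug, rho, p)."""
    df = pd.DataFrame(rows, columns=["entity_a", "entity_b", "rho", "p"])
    df["edge_class"] = GENE_DRUG
    df["n"] = 100
    return CorrelationTable(df)


@pytest.fixture(scope="module")
def planted_validation():
    g, d, _, truth = synth.generate_screens(60, 40, 200, 8, seed=31)
    corr = correlate_cross(g, d, "all", min_pairs=30)
    anns = synth.planted_annotations(truth)
    return corr, anns, truth


class TestTargetCoverage:
    def test_hand_counted_fraction(self):
        # 20 annotated pairs, 3 reference absent genes -> 17/20 = 85.0%
        rows = [(f"G{i}", f"D{i % 10}", 0.1, 0.5) for i in range(17)]
        corr = _corr_from_pairs(rows)
        anns = [
            TargetAnnotation(f"D{i % 10}", frozenset({f"G{i}"}), None) for i in range(17)
        ] + [TargetAnnotation(f"DX{i}", frozenset({f"ABSENT{i}"}), None) for i in range(3)]
        cov = validate.target_coverage(anns, corr)
        assert cov.n_pairs_total == 20
        assert cov.n_pairs_with_scores == 17
        assert cov.coverage_fraction == 85.0

    def test_all_present_is_100(self, planted_validation):
        corr, anns, _ = planted_validation
        cov = validate.target_coverage(anns, corr)
        assert cov.coverage_fraction == 100.0
        assert cov.n_drugs_covered == len(anns)

    def test_empty_annotations_rejected(self, planted_validation):
        corr, *_ = planted_validation
        with pytest.raises(DataError, match="empty"):
            validate.target_coverage([], corr)


class TestTargetHitFraction:
    def test_alpha_one_hits_everything(self, planted_validation):
        corr, anns, _ = planted_validation
        res = validate.target_hit_fraction(anns, corr, alpha=1.0)
        assert res.fraction == 100.0

    def test_planted_links_hit_at_alpha_005(self):
        """Strong planted effects: >=90% of drugs hit over 20 seeds."""
        hits = evaluable = 0
        for seed in range(20):
            g, d, _, truth = synth.generate_screens(40, 25, 200, 5, seed=seed)
            corr = correlate_cross(g, d, "all", min_pairs=30)
            res = validate.target_hit_fraction(
                synth.planted_annotations(truth), corr, alpha=0.05
            )
            hits += res.n_drugs_hit
            evaluable += res.n_drugs_evaluable
        assert hits / evaluable >= 0.9

    def test_fraction_formatting_one_decimal(self):
        rows = [(f"G{i}", f"D{i}", 0.3, 0.01 if i < 774 else 0.5) for i in range(3443)]
        corr = _corr_from_pairs(rows)
        anns = [TargetAnnotation(f"D{i}", frozenset({f"G{i}"}), None) for i in range(3443)]
        res = validate.target_hit_fraction(anns, corr, alpha=0.05)
        assert res.n_drugs_hit == 774
        assert res.fraction == 22.5


class TestFisherRightTail:
    def test_matches_explicit_enumeration_small_tables(self):
        """All 2x2 margins with total <= 60 agree with exact rational arithmetic."""
        checked = 0
        for n_total in range(2, 61, 7):
            for n_ann in range(0, n_total + 1, 5):
                for n_pass in range(0, n_total + 1, 5):
                    lo = max(0, n_ann + n_pass - n_total)
                    hi = min(n_ann, n_pass)
                    for O in range(lo, hi + 1):
                        got = validate.fisher_right_tail(O, n_ann, n_pass, n_total)
                        want = hypergeom_tail_exact(O, n_ann, n_pass, n_total)
                        assert got == pytest.approx(want, abs=1e-12)
                        checked += 1
        assert checked > 500

    def test_worked_example(self):
        # O=4 of annotated=5, passing=10 of total=100: tail is the mass at 4 and 5
        want = hypergeom_tail_exact(4, 5, 10, 100)
        assert validate.fisher_right_tail(4, 5, 10, 100) == pytest.approx(want, abs=1e-15)


class TestObservedExpected:
    def test_all_pass_degenerate(self, planted_validation):
        corr, anns, _ = planted_validation
        res = validate.observed_expected(corr, expand_pairs(anns), -1.0)
        assert res.oe_ratio == pytest.approx(1.0)
        assert res.fisher_p == pytest.approx(1.0)

    def test_threshold_bounds(self, planted_validation):
        corr, anns, _ = planted_validation
        with pytest.raises(DataError, match="threshold"):
            validate.observed_expected(corr, expand_pairs(anns), 1.5)

    def test_planted_enrichment_at_network_cutoff(self):
        """O/E > 1 and Fisher p < 0.05 at the 0.27 cutoff in >=95% of 20 seeds."""
        good = 0
        for seed in range(20):
            g, d, _, truth = synth.generate_screens(60, 40, 200, 8, seed=100 + seed)
            corr = correlate_cross(g, d, "all", min_pairs=30)
            res = validate.observed_expected(
                corr, expand_pairs(synth.planted_annotations(truth)), 0.27
            )
            good += (res.oe_ratio > 1.0) and (res.fisher_p < 0.05)
        assert good >= 19

    def test_null_annotations_superuniform(self):
        """Random annotations on null screens: p<0.05 in at most 7% of 200 seeds."""
        rng = np.random.default_rng(0)
        false_pos = 0
        cells = [f"L{i}" for i in range(80)]
        from screenlink import io

        for seed in range(200):
            r = np.random.default_rng(seed)
            G = io.DependencyMatrix(
                io.GENE_EFFECT,
                pd.DataFrame(r.normal(size=(20, 80)), index=[f"G{i}" for i in range(20)], columns=cells),
            )
            D = io.DependencyMatrix(
                io.DRUG_RESPONSE,
                pd.DataFrame(r.normal(size=(15, 80)), index=[f"D{i}" for i in range(15)], columns=cells),
            )
            corr = correlate_cross(G, D, "all", min_pairs=30)
            pick = rng.choice(len(corr.records), size=10, replace=False)
            pairs = {
                (row.entity_b, row.entity_a)
                for row in corr.records.iloc[pick].itertuples(index=False)
            }
            res = validate.observed_expected(corr, pairs, 0.27)
            false_pos += res.fisher_p < 0.05
        assert false_pos / 200 <= 0.07


class TestThresholdSweep:
    def test_singleton_equals_observed_expected(self, planted_validation):
        corr, anns, _ = planted_validation
        pairs = expand_pairs(anns)
        single = validate.threshold_sweep(corr, pairs, [0.27])
        assert single == [validate.observed_expected(corr, pairs, 0.27)]

    def test_empty_threshold_list(self, planted_validation):
        corr, anns, _ = planted_validation
        assert validate.threshold_sweep(corr, expand_pairs(anns), []) == []

    def test_oe_weakly_increases_before_collapse(self, planted_validation):
        corr, anns, _ = planted_validation
        sweep = validate.threshold_sweep(corr, expand_pairs(anns), [0.0, 0.2, 0.4])
        ratios = [r.oe_ratio for r in sweep if r.n_annotated_passing > 0]
        assert ratios == sorted(ratios)

    def test_impassable_threshold_reports_zero(self, planted_validation):
        corr, anns, _ = planted_validation
        res = validate.threshold_sweep(corr, expand_pairs(anns), [1.0])[0]
        if res.n_passing_total == 0:
            assert res.n_annotated_passing == 0 and res.fisher_p == 1.0


class TestPhaseStratified:
    def test_unknown_phase_rejected(self, planted_validation):
        corr, anns, _ = planted_validation
        with pytest.raises(DataError, match="phase"):
            validate.phase_stratified(anns, corr, 0.27, "Phase 9")

    def test_single_phase_equals_unstratified(self, planted_validation):
        corr, anns, _ = planted_validation
        strat = validate.phase_stratified(anns, corr, 0.27, "Planted")
        full = validate.observed_expected(corr, expand_pairs(anns), 0.27)
        assert strat.n_annotated_passing == full.n_annotated_passing
        assert strat.oe_ratio == pytest.approx(full.oe_ratio)
        assert strat.fisher_p == pytest.approx(full.fisher_p)

    def test_stronger_phase_has_higher_oe(self):
        """Phase-3 drugs with stronger planted effects: higher O/E in >=90% of seeds."""
        from screenlink import io

        wins = 0
        for seed in range(10):
            g1, d1, _, t1 = synth.generate_screens(
                30, 20, 200, 6, effect=0.9, noise=0.4, seed=seed
            )
            anns = synth.planted_annotations(t1)
            phase3 = {a.drug_id for a in anns[:3]}
            # dilute the planted signal of non-phase-3 drugs with fresh noise
            rng = np.random.default_rng(1000 + seed)
            data = d1.data.copy()
            for a in anns:
                if a.drug_id not in phase3:
                    row = data.loc[a.drug_id]
                    data.loc[a.drug_id] = 0.2 * row + rng.normal(0, row.std(), len(row))
            d_mixed = io.DependencyMatrix(d1.kind, data)
            corr = correlate_cross(g1, d_mixed, "all", min_pairs=30)
            relabelled = [
                TargetAnnotation(
                    a.drug_id, a.target_genes,
                    "Phase 3" if a.drug_id in phase3 else "Preclinical",
                )
                for a in anns
            ]
            all_res = validate.observed_expected(corr, expand_pairs(relabelled), 0.27)
            p3 = validate.phase_stratified(relabelled, corr, 0.27, "Phase 3")
            wins += p3.oe_ratio > all_res.oe_ratio
        assert wins >= 9
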