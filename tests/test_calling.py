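import math

import numpy as np
import pandas as pd
import pytest

from slscreen import build_ratio_table
from slscreen.calling import (
    DEPLETED,
    ENRICHED,
    EXCLUDED,
    NEUTRAL,
    SYNTHETIC_LETHAL,
    SYNTHETIC_RESCUE,
    Threshold,
    call_constructs,
    call_genes,
    estimate_thresholds,
    rescue_enrichment_check,
)
from slscreen.io import LibraryDesign, ScreenConfigError, ScreenValidationError
from tests.conftest import ratio_frame


def control_rows(ratios, module=1, start=0):
    return [
        (f"luc{module}_{start + i}", "", module, True, 1000, 1000, True, r)
        for i, r in enumerate(ratios)
    ]


class TestEstimateThresholds:
    def test_two_point_closed_form(self):
        x = 0.3
        table = ratio_frame(control_rows([x, -x]))
        th = estimate_thresholds(table)
        # sample SD of {+x, -x}: sqrt(2x^2 / 1) = x*sqrt(2)
        assert th[1].sigma == pytest.approx(x * math.sqrt(2))
        assert th[1].lower == -th[1].upper
        assert th[1].n_controls_used == 2

    def test_excluded_controls_do_not_contribute(self):
        rows = control_rows([0.1, -0.1, 0.2])
        rows[2] = rows[2][:6] + (False, np.nan)  # below read floor
        th = estimate_thresholds(ratio_frame(rows))
        assert th[1].n_controls_used == 2
        assert th[1].sigma == pytest.approx(0.1 * math.sqrt(2))

    def test_too_few_controls_names_module(self):
        table = ratio_frame(control_rows([0.1], module=2))
        with pytest.raises(ScreenValidationError, match="module 2"):
            estimate_thresholds(table)

    def test_sigma_recovery_within_chi_square_band(self):
        """21 Gaussian control ratios: SD lands in the n=21 chi-square band."""
        rng = np.random.default_rng(11)
        sigma = 0.17
        lo, hi = 0.10, 0.24  # ~99% band for the sample SD at n=21
        hits = 0
        n_trials = 100
        for _ in range(n_trials):
            table = ratio_frame(control_rows(rng.normal(0, sigma, 21)))
            hits += lo <= estimate_thresholds(table)[1].sigma <= hi
        assert hits >= 95


class TestCallConstructs:
    def make_thresholds(self):
        return {1: Threshold(1, 0.1595, 21), 2: Threshold(2, 0.1863, 21)}

    @pytest.mark.parametrize(
        "module, ratio, expected",
        [
            (1, -0.20, DEPLETED),   # -0.20 < -0.1595
            (1, -0.1595, NEUTRAL),  # exactly at -sigma: strict inequality
            (2, 0.25, ENRICHED),    # 0.25 > 0.1863
            (2, 0.1863, NEUTRAL),
            (1, 0.0, NEUTRAL),
            (2, -0.17, NEUTRAL),    # below module 1's sigma but not module 2's
        ],
    )
    def test_threshold_boundaries(self, module, ratio, expected):
        rows = [("c", "G", module, False, 500, 500, True, ratio)]
        calls = call_constructs(ratio_frame(rows), self.make_thresholds())
        assert calls["call"].iloc[0] == expected

    def test_excluded_constructs_flagged(self):
        rows = [("c", "G", 1, False, 5, 500, False, np.nan)]
        calls = call_constructs(ratio_frame(rows), self.make_thresholds())
        assert calls["call"].iloc[0] == EXCLUDED

    def test_missing_module_threshold_rejected(self):
        rows = [("c", "G", 3, False, 500, 500, True, 0.0)]
        with pytest.raises(ScreenConfigError, match="module"):
            call_constructs(ratio_frame(rows), self.make_thresholds())


def make_design(genes, constructs_per_gene=5):
    rows = []
    i = 0
    for g in genes:
        for j in range(constructs_per_gene):
            rows.append((f"B{i:04d}", f"{g}_c{j}", g, 1, False))
            i += 1
    rows.append((f"B{i:04d}", "luc", "", 1, True))
    return LibraryDesign(
        pd.DataFrame(rows, columns=["barcode", "construct_id", "gene", "module", "is_control"])
    )


def calls_frame(per_gene_calls):
    """per_gene_calls: {gene: [call, ...]} -> construct_calls DataFrame."""
    rows = []
    for g, calls in per_gene_calls.items():
        for j, c in enumerate(calls):
            rows.append((f"{g}_c{j}", g, 1, np.nan, False, c))
    rows.append(("luc", "", 1, 0.0, True, NEUTRAL))
    return pd.DataFrame(
        rows, columns=["construct_id", "gene", "module", "log2_ratio", "is_control", "call"]
    )


class TestCallGenes:
    def test_two_of_five_is_not_enough(self):
        # mirrors the ADCY1 case: 2/5 depleted constructs stay below the bar
        cc = calls_frame({"G": [DEPLETED, DEPLETED, NEUTRAL, NEUTRAL, NEUTRAL]})
        out = call_genes(cc, make_design(["G"]))
        assert out["call"].iloc[0] == NEUTRAL

    def test_three_of_five_is_synthetic_lethal(self):
        cc = calls_frame({"G": [DEPLETED] * 3 + [NEUTRAL] * 2})
        out = call_genes(cc, make_design(["G"]))
        assert out["call"].iloc[0] == SYNTHETIC_LETHAL
        assert out["vote_fraction_depleted"].iloc[0] == pytest.approx(0.6)

    def test_no_votes_is_neutral(self):
        cc = calls_frame({"G": [NEUTRAL] * 5})
        assert call_genes(cc, make_design(["G"]))["call"].iloc[0] == NEUTRAL

    def test_strict_majority_moves_the_boundary(self):
        cc = calls_frame({"G": [DEPLETED, DEPLETED, NEUTRAL, NEUTRAL]})
        d = make_design(["G"], constructs_per_gene=4)
        assert call_genes(cc, d)["call"].iloc[0] == SYNTHETIC_LETHAL  # 2/4 >= 0.5
        assert call_genes(cc, d, strict_majority=True)["call"].iloc[0] == NEUTRAL

    def test_denominator_mode_passing_vs_total(self):
        cc = calls_frame({"G": [DEPLETED, DEPLETED, NEUTRAL, NEUTRAL, EXCLUDED]})
        d = make_design(["G"])
        assert call_genes(cc, d, denominator="passing")["call"].iloc[0] == SYNTHETIC_LETHAL
        assert call_genes(cc, d, denominator="total")["call"].iloc[0] == NEUTRAL

    def test_all_excluded_gene_is_neutral(self):
        cc = calls_frame({"G": [EXCLUDED] * 5})
        out = call_genes(cc, make_design(["G"]))
        assert out["call"].iloc[0] == NEUTRAL
        assert out["n_constructs_passing"].iloc[0] == 0

    def test_tie_between_directions_is_neutral(self):
        cc = calls_frame({"G": [DEPLETED, DEPLETED, ENRICHED, ENRICHED]})
        out = call_genes(cc, make_design(["G"], constructs_per_gene=4))
        assert out["call"].iloc[0] == NEUTRAL

    def test_larger_fraction_wins_when_both_pass(self):
        cc = calls_frame({"G": [DEPLETED, DEPLETED, DEPLETED, ENRICHED, ENRICHED]})
        # with vote_threshold 0.4 both directions pass; depletion is larger
        out = call_genes(cc, make_design(["G"]), vote_threshold=0.4)
        assert out["call"].iloc[0] == SYNTHETIC_LETHAL

    def test_unknown_gene_rejected(self):
        cc = calls_frame({"GHOST": [DEPLETED] * 5})
        with pytest.raises(ScreenValidationError, match="GHOST"):
            call_genes(cc, make_design(["G"]))

    def test_vote_tally_invariant(self):
        cc = calls_frame({"G": [DEPLETED, ENRICHED, NEUTRAL, EXCLUDED, DEPLETED]})
        out = call_genes(cc, make_design(["G"])).iloc[0]
        assert out["n_depleted"] + out["n_enriched"] <= out["n_constructs_passing"]
        assert out["n_constructs_passing"] <= out["n_constructs_total"] == 5


class TestSymmetryAndMonotonicity:
    def test_negating_ratios_swaps_sl_and_rescue(self, small_screen):
        _cfg, design, _truth, ctrl, treat = small_screen
        table, _ = build_ratio_table(design, ctrl, treat, min_reads=10)
        th = estimate_thresholds(table)
        gc = call_genes(call_constructs(table, th), design)

        flipped = table.copy()
        flipped["log2_ratio"] = -flipped["log2_ratio"]
        th_f = estimate_thresholds(flipped)
        gc_f = call_genes(call_constructs(flipped, th_f), design)

        assert th[1].sigma == pytest.approx(th_f[1].sigma)  # SD is sign-invariant
        sl = set(gc.loc[gc["call"] == SYNTHETIC_LETHAL, "gene"])
        rescue = set(gc.loc[gc["call"] == SYNTHETIC_RESCUE, "gene"])
        sl_f = set(gc_f.loc[gc_f["call"] == SYNTHETIC_LETHAL, "gene"])
        rescue_f = set(gc_f.loc[gc_f["call"] == SYNTHETIC_RESCUE, "gene"])
        assert sl == rescue_f and rescue == sl_f

    def test_pushing_a_ratio_down_never_loses_an_sl_call(self):
        th = {1: Threshold(1, 0.16, 21)}
        d = make_design(["G"])
        base = [-0.2, -0.2, -0.1, 0.0, 0.1]
        rows = lambda rs: ratio_frame(
            [(f"G_c{j}", "G", 1, False, 500, 500, True, r) for j, r in enumerate(rs)]
        )
        for j in range(5):
            shifted = list(base)
            shifted[j] -= 0.5
            before = call_genes(call_constructs(rows(base), th), d)["call"].iloc[0]
            after = call_genes(call_constructs(rows(shifted), th), d)["call"].iloc[0]
            if before == SYNTHETIC_LETHAL:
                assert after == SYNTHETIC_LETHAL


class TestRescueEnrichmentCheck:
    def make_calls(self, rescue_genes, all_genes):
        return pd.DataFrame(
            {
                "gene": all_genes,
                "call": [
                    SYNTHETIC_RESCUE if g in rescue_genes else NEUTRAL
                    for g in all_genes
                ],
            }
        )

    def test_disjoint_family_gives_p_one(self):
        gc = self.make_calls({"R1"}, ["R1", "A", "B", "C"])
        assert rescue_enrichment_check(gc, {"B", "C"}, 100) == 1.0

    def test_family_equal_to_rescue_set_matches_enumeration(self):
        # N=10, K=n=3, k=3: P = 1 / C(10,3) = 1/120
        genes = [f"g{i}" for i in range(10)]
        gc = self.make_calls(set(genes[:3]), genes)
        p = rescue_enrichment_check(gc, set(genes[:3]), 10)
        assert p == pytest.approx(1 / 120, rel=1e-12)

    def test_family_larger_than_universe_rejected(self):
        gc = self.make_calls(set(), ["A"])
        with pytest.raises(ScreenConfigError):
            rescue_enrichment_check(gc, {"A", "B", "C"}, 2)
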