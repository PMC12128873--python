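"""Burden scoring: purity algebra, arm calls, and a per-base counting oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aneuscope import cn, simulate
from aneuscope.cn import Thresholds
from aneuscope.genome import GenomeModel


def make_segments(rows):
    return pd.DataFrame(rows, columns=["sample", "chrom", "start_bp", "end_bp", "log2_ratio"])


class TestPurityCorrect:
    def test_pure_tumor_is_identity(self):
        assert cn.purity_correct(0.7, 1.0) == pytest.approx(0.7)

    def test_neutral_is_invariant_under_mixing(self):
        assert cn.purity_correct(0.0, 0.5) == pytest.approx(0.0)

    def test_half_purity_single_copy_gain_demixes_to_one(self):
        # observed log2(1.25) from a 50% pure single-copy gain -> tumor log2(1.5/... )
        assert cn.purity_correct(np.log2(1.5), 0.5) == pytest.approx(1.0)

    def test_uncorrectable_segment_becomes_nan(self):
        # implied tumor ratio <= 0: observed ratio below the normal contribution
        out = cn.purity_correct(np.array([-3.0, 0.0]), np.array([0.5, 0.5]))
        assert np.isnan(out[0]) and out[1] == pytest.approx(0.0)

    @given(
        r_tumor=st.floats(0.1, 4.0),
        purity=st.floats(0.05, 1.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_round_trip_through_mixture(self, r_tumor, purity):
        """De-mixing inverts the physical purity mixture exactly."""
        observed = np.log2(purity * r_tumor + (1 - purity))
        assert cn.purity_correct(observed, purity) == pytest.approx(np.log2(r_tumor), abs=1e-9)


class TestCallArmEvents:
    def test_full_arm_above_gain_cutoff_called_gain(self, two_arm_genome):
        seg = make_segments([("s", "1", 1, 50_000_000, 0.5)])
        calls = cn.call_arm_events(seg, two_arm_genome)
        assert calls.set_index("arm_id").loc["1p", "call"] == "gain"
        assert calls.set_index("arm_id").loc["1q", "call"] == "neutral"

    def test_forty_percent_of_arm_is_not_enough(self, two_arm_genome):
        seg = make_segments(
            [("s", "1", 1, 20_000_000, 0.5), ("s", "1", 20_000_001, 50_000_000, 0.0)]
        )
        calls = cn.call_arm_events(seg, two_arm_genome)
        assert calls.set_index("arm_id").loc["1p", "call"] == "neutral"

    def test_neutral_segment_stays_neutral(self, two_arm_genome):
        seg = make_segments([("s", "1", 1, 50_000_000, 0.0)])
        calls = cn.call_arm_events(seg, two_arm_genome)
        assert (calls["call"] == "neutral").all()

    def test_threshold_is_strict_inequality(self, two_arm_genome):
        seg = make_segments([("s", "1", 1, 50_000_000, 0.32)])
        calls = cn.call_arm_events(seg, two_arm_genome)
        assert calls.set_index("arm_id").loc["1p", "call"] == "neutral"

    def test_monotonicity_raising_log2_never_loses_a_gain_call(self, two_arm_genome):
        for base in (0.33, 0.5, 1.0, 2.0):
            seg = make_segments([("s", "1", 1, 50_000_000, base)])
            call = cn.call_arm_events(seg, two_arm_genome).set_index("arm_id").loc["1p", "call"]
            assert call == "gain"

    def test_segment_outside_arms_skipped_with_warning(self, two_arm_genome, caplog):
        seg = make_segments(
            [("s", "9", 1, 10_000_000, 2.0), ("s", "1", 1, 50_000_000, 0.5)]
        )
        with caplog.at_level("WARNING"):
            calls = cn.call_arm_events(seg, two_arm_genome)
        assert "outside every arm" in caplog.text
        assert calls.set_index("arm_id").loc["1p", "call"] == "gain"


class TestAneuploidyBurden:
    def test_gained_and_lost_arm_net_out_in_megabases(self, two_arm_genome):
        # 50 Mb arm gained + 30 Mb arm lost -> net +20 Mb with arm weighting
        seg = make_segments(
            [("s", "1", 1, 50_000_000, 0.5), ("s", "1", 50_000_001, 80_000_000, -0.5)]
        )
        calls = cn.call_arm_events(seg, two_arm_genome)
        score = cn.aneuploidy_burden(calls, weighting="arm").iloc[0]
        assert score["gain_mb"] == pytest.approx(50.0)
        assert score["loss_mb"] == pytest.approx(30.0)
        assert score["net_mb"] == pytest.approx(20.0)
        assert score["class"] == "net_gain"

    def test_empty_input_is_balanced_zero(self, caplog):
        with caplog.at_level("WARNING"):
            out = cn.aneuploidy_burden(pd.DataFrame())
        assert out.empty

    def test_sign_flip_swaps_gain_and_loss_with_symmetric_thresholds(self, two_arm_genome):
        th = Thresholds(arm_gain_log2=0.4, arm_loss_log2=-0.4)
        seg = make_segments(
            [("s", "1", 1, 50_000_000, 0.45), ("s", "1", 50_000_001, 80_000_000, -0.45)]
        )
        flipped = seg.assign(log2_ratio=-seg["log2_ratio"])
        a = cn.aneuploidy_burden(cn.call_arm_events(seg, two_arm_genome, th)).iloc[0]
        b = cn.aneuploidy_burden(cn.call_arm_events(flipped, two_arm_genome, th)).iloc[0]
        assert a["gain_mb"] == pytest.approx(b["loss_mb"])
        assert a["loss_mb"] == pytest.approx(b["gain_mb"])

    def test_purity_consistency_burden_matches_pure_tumor(self, genome):
        """Events mixed at purity 0.5 then de-mixed score like the pure data."""
        events = {"s": [("1p", "gain"), ("3q", "loss")]}
        pure, _ = simulate.simulate_segments(genome, events, purity=1.0, noise_sd=0.0)
        mixed, _ = simulate.simulate_segments(genome, events, purity=0.5, noise_sd=0.0)
        b_pure = cn.aneuploidy_burden(cn.call_arm_events(pure, genome)).iloc[0]
        b_mixed = cn.aneuploidy_burden(cn.call_arm_events(mixed, genome)).iloc[0]
        assert b_pure["net_mb"] == pytest.approx(b_mixed["net_mb"])
        assert b_pure["class"] == b_mixed["class"]

    def test_planted_net_gain_recovered_through_noise_and_purity(self, genome):
        events = {
            "g1": [("1p", "gain"), ("2q", "gain"), ("5p", "loss")],
            "g2": [("1q", "gain")],
        }
        seg, _ = simulate.simulate_segments(
            genome, events, purity=0.6, noise_sd=0.05, seed=11, segments_per_arm=4
        )
        burden = cn.aneuploidy_burden(cn.call_arm_events(seg, genome))
        assert (burden.set_index("sample")["class"] == "net_gain").all()


class TestPerBaseOracle:
    """Burden matches exhaustive per-base counting on tiny-coordinate toys."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_counting(self, seed):
        rng = np.random.default_rng(seed)
        # <=5 arms with coordinates small enough to enumerate every base
        toy = GenomeModel(
            pd.DataFrame(
                [
                    ("1", "p", 1, 400),
                    ("1", "q", 401, 1000),
                    ("2", "p", 1, 300),
                    ("2", "q", 301, 800),
                    ("3", "q", 1, 500),
                ],
                columns=["chrom", "arm", "start_bp", "end_bp"],
            )
        )
        # random segmentation of each arm with random levels
        rows = []
        for _, arm in toy.arms.iterrows():
            cuts = np.sort(rng.choice(
                np.arange(arm.start_bp, arm.end_bp), size=rng.integers(0, 3), replace=False
            ))
            bounds = [arm.start_bp - 1, *cuts, arm.end_bp]
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                rows.append(("s", arm.chrom, lo + 1, hi, rng.normal(0, 0.6)))
        seg = make_segments(rows)
        th = Thresholds()

        # oracle: count every base
        expected_gain = expected_loss = 0.0
        for _, arm in toy.arms.iterrows():
            gain_bases = loss_bases = 0
            for pos in range(arm.start_bp, arm.end_bp + 1):
                hit = seg[(seg.chrom == arm.chrom) & (seg.start_bp <= pos) & (pos <= seg.end_bp)]
                if hit.empty:
                    continue
                v = hit.iloc[0]["log2_ratio"]
                if v > th.arm_gain_log2:
                    gain_bases += 1
                elif v < th.arm_loss_log2:
                    loss_bases += 1
            arm_len = arm.end_bp - arm.start_bp + 1
            gain_q = gain_bases >= 0.5 * arm_len
            loss_q = loss_bases >= 0.5 * arm_len
            if gain_q and loss_q:
                if gain_bases > loss_bases:
                    expected_gain += gain_bases
                elif loss_bases > gain_bases:
                    expected_loss += loss_bases
            elif gain_q:
                expected_gain += gain_bases
            elif loss_q:
                expected_loss += loss_bases

        calls = cn.call_arm_events(seg, toy)
        score = cn.aneuploidy_burden(calls, weighting="segment").iloc[0]
        assert score["gain_mb"] * 1e6 == pytest.approx(expected_gain)
        assert score["loss_mb"] * 1e6 == pytest.approx(expected_loss)


class TestGeneLevelBurden:
    def test_published_cutoffs_classify_example_genes(self):
        mat = pd.DataFrame({"s1": [1.2, 0.7, 1.0]}, index=["gA", "gB", "gC"])
        out = cn.gene_level_burden(mat).iloc[0]
        assert out["gain_genes"] == 1 and out["loss_genes"] == 1

    def test_diploid_matrix_scores_zero(self):
        mat = pd.DataFrame(np.ones((20, 3)), columns=["a", "b", "c"])
        out = cn.gene_level_burden(mat)
        assert (out["net_genes"] == 0).all()
        assert (out["class"] == "balanced").all()

    def test_count_arithmetic(self):
        vals = np.ones(50)
        vals[:10] = 1.3
        vals[10:14] = 0.5
        mat = pd.DataFrame({"s": vals})
        assert cn.gene_level_burden(mat).iloc[0]["net_genes"] == 6

    def test_scale_mismatch_warned(self, caplog):
        mat = pd.DataFrame({"s": np.full(10, 4.0)})
        with caplog.at_level("WARNING"):
            cn.gene_level_burden(mat)
        assert "scale" in caplog.text


class TestInferCnaFromExpression:
    def test_reference_identical_tumor_has_no_calls(self, genome):
        sim = simulate.simulate_expression_cna(
            genome, {"t": []}, dosage_effect=1.0, reference_n=3, noise_sd=0.0, seed=1
        )
        _, calls, burden = cn.infer_cna_from_expression(
            sim.expr, sim.genes, ["REF00", "REF01", "REF02"], window=11
        )
        assert (calls["call"] == "neutral").all()
        assert burden.iloc[0]["net_genes"] == 0

    def test_planted_dosage_arm_called_gained(self, genome):
        sim = simulate.simulate_expression_cna(
            genome, {"t": [("1q", "gain")]}, dosage_effect=1.5,
            reference_n=3, noise_sd=0.0, seed=2,
        )
        refs = [c for c in sim.expr.columns if c.startswith("REF")]
        modified, calls, burden = cn.infer_cna_from_expression(
            sim.expr, sim.genes, refs, window=11
        )
        meta = sim.genes.set_index("gene")
        on_arm = meta[(meta["chrom"] == "1") & (meta["pos"] > 60_000_000)].index
        t_calls = calls[calls["sample"] == "t"].set_index("gene")
        # away from the smoothing boundary, the full arm is called gained
        core = on_arm[5:-5]
        assert (t_calls.loc[core, "call"] == "gain").all()
        assert burden.iloc[0]["class"] == "net_gain"

    def test_value_below_loss_cutoff_called_loss(self, genome):
        sim = simulate.simulate_expression_cna(
            genome, {"t": [("2q", "loss")]}, dosage_effect=1.5,
            reference_n=3, noise_sd=0.0, seed=3,
        )
        refs = [c for c in sim.expr.columns if c.startswith("REF")]
        modified, calls, _ = cn.infer_cna_from_expression(sim.expr, sim.genes, refs, window=11)
        meta = sim.genes.set_index("gene")
        core = meta[(meta["chrom"] == "2") & (meta["pos"] > 40_000_000)].index[5:-5]
        t_calls = calls[calls["sample"] == "t"].set_index("gene")
        assert (t_calls.loc[core, "modified_expression"] < 0.98).all()
        assert (t_calls.loc[core, "call"] == "loss").all()

    def test_empty_reference_rejected(self, genome):
        sim = simulate.simulate_expression_cna(genome, {"t": []}, reference_n=2, seed=4)
        with pytest.raises(ValueError, match="reference"):
            cn.infer_cna_from_expression(sim.expr, sim.genes, [])

    def test_oversized_window_shrinks_with_warning(self, genome, caplog):
        sim = simulate.simulate_expression_cna(genome, {"t": []}, n_genes=60, seed=5)
        refs = [c for c in sim.expr.columns if c.startswith("REF")]
        with caplog.at_level("WARNING"):
            cn.infer_cna_from_expression(sim.expr, sim.genes, refs, window=101)
        assert "window shrunk" in caplog.text
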