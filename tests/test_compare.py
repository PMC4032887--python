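import numpy as np
import pytest

from conftest import make_path_trace, make_y_trace
from neurotrace.compare import (
    all_pairs_protocol,
    compare_report,
    correspond,
    full_compare,
    mes,
    prefilter,
)
from neurotrace.image_stack import ImageStack
from neurotrace.trace_model import Trace, resample


def line_trace(x0, x1, y=0.0, z=0.0, step=1.0):
    n = int(round((x1 - x0) / step))
    return make_path_trace([(x0 + i * step, y, z) for i in range(n + 1)])


class TestPrefilter:
    def test_short_terminal_twig_removed(self):
        t = line_trace(0, 30)
        mid = 15  # node index at x=15
        twig_prev = mid
        for i in range(1, 6):  # 5-voxel twig
            n = t.add_node((15.0, i, 0.0))
            t.add_edge(twig_prev, n)
            twig_prev = n
        out = prefilter(t, min_terminal_len=12.0)
        assert len(out.branch_nodes()) == 0
        assert out.total_length() == pytest.approx(30.0)

    def test_long_bright_branches_untouched(self):
        t = make_y_trace(arm=20)
        out = prefilter(t, min_terminal_len=12.0)
        assert out.n_nodes == t.n_nodes

    def test_dim_branches_removed_with_stack(self):
        stack = ImageStack(np.full((40, 11, 5), 0.05))
        stack.voxels[:, 2, 2] = 0.9  # bright row at y=2
        bright = make_path_trace([(x, 2.0, 2.0) for x in range(0, 35, 1)])
        prev = 17  # attach mid-path so the dim chain is its own branch
        for i in range(1, 26):  # dim branch heading into the background
            n = bright.add_node((17.0, 2.0 + i * 0.5, 2.0))
            bright.add_edge(prev, n)
            prev = n
        out = prefilter(bright, stack, min_terminal_len=2.0, min_intensity=0.12)
        assert out.total_length() == pytest.approx(34.0, abs=0.5)

    def test_cascade_removal_reaches_fixed_point(self):
        # a short interior segment M between a junction and a node that
        # carries only two short twigs: the first pass removes the twigs
        # (making M terminal), the second removes M itself
        t = Trace()
        j = t.add_node((0.0, 0.0, 0.0))
        for d in ((1, 0, 0), (-1, 0, 0)):  # two long arms, length 20 each
            prev = j
            for i in range(1, 21):
                n = t.add_node(np.array(d, dtype=float) * i)
                t.add_edge(prev, n)
                prev = n
        prev = j  # segment M, length 5, to node e
        for i in range(1, 6):
            n = t.add_node((0.0, float(i), 0.0))
            t.add_edge(prev, n)
            prev = n
        e = prev
        for d in ((1, 0, 0), (-1, 0, 0)):  # two 3-length twigs at e
            prev = e
            for i in range(1, 4):
                n = t.add_node(np.array([0.0, 5.0, 0.0]) + np.array(d, dtype=float) * i)
                t.add_edge(prev, n)
                prev = n
        out = prefilter(t, min_terminal_len=12.0)
        assert out.total_length() == pytest.approx(40.0)
        assert len(out.branch_nodes()) == 0


class TestCorrespond:
    def test_identical_traces_all_correspond_at_zero(self):
        g = resample(line_trace(0, 20), 0.25)
        t = resample(line_trace(0, 20), 0.25)
        pairing = correspond(t, g, h=10.0)
        assert pairing["test_matched"].all()
        assert pairing["gold_matched"].all()
        np.testing.assert_allclose(pairing["distances"], 0.0, atol=1e-12)

    def test_perpendicular_shift_within_h(self):
        g = resample(line_trace(0, 20, y=0.0), 0.25)
        t = resample(line_trace(0, 20, y=2.0), 0.25)
        pairing = correspond(t, g, h=10.0)
        assert pairing["test_matched"].all()
        assert pairing["gold_matched"].all()
        np.testing.assert_allclose(pairing["distances"], 2.0, atol=1e-9)

    def test_shift_beyond_h_gives_no_correspondence(self):
        g = resample(line_trace(0, 20, y=0.0), 0.25)
        t = resample(line_trace(0, 20, y=11.0), 0.25)
        pairing = correspond(t, g, h=10.0)
        assert not pairing["test_matched"].any()
        assert not pairing["gold_matched"].any()


class TestMes:
    def test_identical_traces_score_one(self):
        g = resample(make_y_trace(arm=20), 0.25)
        t = resample(make_y_trace(arm=20), 0.25)
        scores = mes(t, g)
        assert scores == pytest.approx((1.0, 1.0, 1.0))

    def test_empty_test_trace_scores_zero(self):
        g = resample(line_trace(0, 20), 0.25)
        assert mes(Trace(), g)[0] == 0.0

    def test_empty_gold_rejected(self):
        with pytest.raises(ValueError):
            mes(Trace(), Trace())

    def test_printed_arithmetic_example(self):
        # gold: 80 on the shared line plus a 20-length branch far from the
        # test trace (FN = 20); test: the shared line plus a far 25-length
        # extra (FP = 25): MES = (100-20)/(100+25) = 0.64
        gold = line_trace(0, 80)
        prev = gold.add_node((0.0, 50.0, 0.0))
        for i in range(1, 21):
            n = gold.add_node((i * 1.0, 50.0, 0.0))
            gold.add_edge(prev, n)
            prev = n
        gold = resample(gold, 0.25)
        test = line_trace(0, 80)
        prev = test.add_node((0.0, 100.0, 0.0))
        for i in range(1, 26):
            n = test.add_node((i * 1.0, 100.0, 0.0))
            test.add_edge(prev, n)
            prev = n
        test = resample(test, 0.25)
        res = full_compare(test, gold, h=10.0)
        assert res.gold_length == pytest.approx(100.0)
        assert res.fn_length == pytest.approx(20.0)
        assert res.fp_length == pytest.approx(25.0)
        assert res.mes_length == pytest.approx(0.64, abs=1e-9)

    def test_swapping_test_and_gold_swaps_fp_and_fn(self):
        a = resample(line_trace(0, 50), 0.25)
        b = resample(line_trace(15, 50), 0.25)
        r_ab = full_compare(a, b, h=10.0)
        r_ba = full_compare(b, a, h=10.0)
        assert r_ab.fp_length == pytest.approx(r_ba.fn_length)
        assert r_ab.fn_length == pytest.approx(r_ba.fp_length)

    def test_perfect_score_iff_no_errors(self):
        g = resample(line_trace(0, 30), 0.25)
        t = resample(line_trace(0, 30), 0.25)
        res = full_compare(t, g)
        assert res.mes_length == 1.0 and res.fp_length == 0.0 and res.fn_length == 0.0

    def test_distances_bounded_by_h(self):
        g = resample(line_trace(0, 30, y=0.0), 0.25)
        t = resample(line_trace(0, 30, y=4.0), 0.25)
        res = full_compare(t, g, h=5.0)
        assert res.node_distances.max() <= 5.0


class TestCompareReport:
    def test_self_comparison_is_error_free(self, straight_tube):
        _, truth = straight_tube
        res = compare_report(truth, truth, do_prefilter=False)
        assert res.mes_length == 1.0
        assert res.fp_bp == res.fn_bp == 0

    def test_protocol_counts_single_stack(self):
        manuals = [resample(line_trace(0, 20, y=i * 0.1), 0.5) for i in range(3)]
        auto = resample(line_trace(0, 20, y=0.5), 0.5)
        inter, a2u = all_pairs_protocol(manuals, auto)
        assert len(inter) == 6
        assert len(a2u) == 3

    def test_protocol_counts_pool_over_nine_stacks(self):
        total_inter = total_auto = 0
        for _ in range(9):
            manuals = [line_trace(0, 5, y=i * 0.1) for i in range(3)]
            auto = line_trace(0, 5, y=0.5)
            inter, a2u = all_pairs_protocol(manuals, auto)
            total_inter += len(inter)
            total_auto += len(a2u)
        assert total_inter == 54
        assert total_auto == 27
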