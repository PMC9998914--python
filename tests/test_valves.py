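"""Lowess smoother vs an independent oracle; valve assignment rules."""

import numpy as np
import pandas as pd
import pytest

from podstar.valves import (
    DEFAULT_SPAN,
    assign_valves,
    attach_valve_columns,
    lowess,
    valve_accuracy,
)


def oracle_lowess(x, y, f, iters=3):
    """Direct per-point weighted local linear fits via np.polyfit."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    r = min(max(2, int(np.ceil(f * n))), n)
    delta = np.ones(n)
    fitted = np.empty(n)
    for it in range(iters + 1):
        for i in range(n):
            d = np.abs(x - x[i])
            h = np.sort(d)[r - 1]
            w = np.clip(1 - (d / h) ** 3, 0, None) ** 3 if h > 0 else (d == 0).astype(float)
            w = w * delta
            active = w > 0
            if active.sum() < 2 or np.ptp(x[active]) == 0:
                fitted[i] = np.average(y, weights=w) if w.sum() else y.mean()
            else:
                coeffs = np.polyfit(x, y, 1, w=np.sqrt(w))
                fitted[i] = np.polyval(coeffs, x[i])
        if it == iters:
            break
        resid = y - fitted
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        delta = np.clip(1 - (resid / (6 * s)) ** 2, 0, None) ** 2
    return fitted


def alternating_pod(n=8, x0=230.0, offset=5.0):
    z = np.linspace(50, 400, n)
    x = x0 + offset * np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    return pd.DataFrame(
        {"Seed ID Number": np.arange(1, n + 1), "Z-axis centroid": z, "X-axis centroid": x}
    )


class TestLowess:
    def test_collinear_points_reproduced_exactly(self):
        x = np.linspace(0, 10, 15)
        y = 2 * x + 1
        for f in (0.3, 2 / 3, 1.0):
            assert np.abs(lowess(x, y, f) - y).max() < 1e-9

    def test_single_point_and_two_points(self):
        assert lowess(np.array([3.0]), np.array([7.0]), 1.0)[0] == 7.0
        x2, y2 = np.array([0.0, 2.0]), np.array([1.0, 5.0])
        assert np.allclose(lowess(x2, y2, 1.0), y2)

    def test_robustness_downweights_gross_outlier(self):
        x = np.linspace(0, 2 * np.pi, 21)
        y_clean = np.sin(x)
        y = y_clean.copy()
        y[10] += 10.0  # gross outlier
        fit_clean = lowess(x, y_clean, 0.5, iters=3)
        fit_robust = lowess(x, y, 0.5, iters=3)
        assert abs(fit_robust[10] - fit_clean[10]) < 0.2

    @pytest.mark.parametrize("n,f", [(5, 1.0), (12, 0.5), (30, 2 / 3)])
    def test_agrees_with_direct_oracle(self, n, f):
        rng = np.random.default_rng(n)
        x = np.sort(rng.uniform(0, 100, n))
        y = 0.1 * x + 3 * np.sin(x / 10) + rng.normal(0, 0.5, n)
        assert np.abs(lowess(x, y, f, iters=3) - oracle_lowess(x, y, f, iters=3)).max() < 1e-8

    def test_cross_check_against_statsmodels_on_smooth_data(self):
        # Independent library implementation; window conventions differ
        # slightly so agreement is approximate on smooth data.
        sm_lowess = pytest.importorskip("statsmodels.api").nonparametric.lowess
        x = np.linspace(0, 50, 40)
        y = 0.2 * x + np.sin(x / 5)
        ours = lowess(x, y, 2 / 3, iters=3)
        theirs = sm_lowess(y, x, frac=2 / 3, it=3, return_sorted=False)
        assert np.abs(ours - theirs).max() < 0.1

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            lowess(np.arange(3.0), np.arange(4.0), 0.5)
        with pytest.raises(ValueError):
            lowess(np.arange(3.0), np.arange(3.0), 0.0)


class TestAssignValves:
    def test_alternating_seeds_split_evenly(self):
        frame = alternating_pod(8)
        out = assign_valves(frame)
        valves = [a.valve for a in out]
        assert valves == [1, 2, 1, 2, 1, 2, 1, 2]
        assert [a.sequence_in_valve for a in out] == [1, 1, 2, 2, 3, 3, 4, 4]
        for a in out:
            assert (a.spacing_to_previous is None) == (a.sequence_in_valve == 1)

    def test_single_seed_tie_break(self):
        frame = alternating_pod(1)
        (a,) = assign_valves(frame)
        assert a.valve == 1 and a.residual == 0.0 and a.sequence_in_valve == 1
        assert a.spacing_to_previous is None

    def test_small_pod_uses_full_span(self):
        # With <= 5 seeds the fit is a single global robust line (f=1):
        # 5 collinear seeds plus construction offsets split consistently.
        frame = alternating_pod(5, offset=6.0)
        out = assign_valves(frame)
        assert [a.valve for a in out] == [1, 2, 1, 2, 1]

    def test_translation_invariance_and_x_flip_swaps_valves(self):
        frame = alternating_pod(9, offset=4.0)
        base = [a.valve for a in assign_valves(frame)]
        shifted = frame.copy()
        shifted["Z-axis centroid"] += 37.0
        shifted["X-axis centroid"] += 11.0
        assert [a.valve for a in assign_valves(shifted)] == base
        flipped = frame.copy()
        flipped["X-axis centroid"] = -flipped["X-axis centroid"]
        assert [3 - a.valve for a in assign_valves(flipped)] == base

    def test_spacing_is_planar_euclidean(self):
        frame = alternating_pod(6)
        out = assign_valves(frame)
        v1 = [a for a in out if a.valve == 1]
        z = frame["Z-axis centroid"].to_numpy()
        x = frame["X-axis centroid"].to_numpy()
        expected = np.hypot(z[2] - z[0], x[2] - x[0])
        assert v1[1].spacing_to_previous == pytest.approx(expected)

    def test_valve_counts_sum_to_pod_count(self, small_pod):
        _, _, _, truth = small_pod
        frame = pd.DataFrame(
            {
                "Seed ID Number": truth.table["label"],
                "Z-axis centroid": truth.table["centroid_z"],
                "X-axis centroid": truth.table["centroid_x"],
            }
        )
        out = assign_valves(frame)
        assert len(out) == len(frame)
        n1 = sum(a.valve == 1 for a in out)
        n2 = sum(a.valve == 2 for a in out)
        assert n1 + n2 == len(frame)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            assign_valves(pd.DataFrame())


class TestValveAccuracy:
    def test_perfect_and_flipped_are_both_perfect(self):
        out = assign_valves(alternating_pod(8))
        truth = {a.seed_id: a.valve for a in out}
        assert valve_accuracy(out, truth) == 1.0
        flipped = {k: 3 - v for k, v in truth.items()}
        assert valve_accuracy(out, flipped) == 1.0

    def test_published_total_fraction(self):
        assert round(100 * 198 / 209, 2) == 94.74

    def test_id_mismatch_raises(self):
        out = assign_valves(alternating_pod(4))
        with pytest.raises(ValueError):
            valve_accuracy(out, {99: 1})


def test_attach_valve_columns_round_trip():
    frame = alternating_pod(6)
    out = assign_valves(frame)
    table = attach_valve_columns(frame, out)
    assert list(table["valve"]) == [a.valve for a in out]
    assert table["sequence_in_valve"].max() == 3
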