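import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glycoload.metrics import (
    ConsumedFood,
    compute_metrics,
    daily_metrics,
    occasion_gi,
    occasion_gl,
    occasion_profile,
)

from conftest import random_day_lines


def cf(carb, gi, order=1, amount=None, sid="S1", oid=None):
    amount = carb + 1 if amount is None else amount
    return ConsumedFood(
        student_id=sid,
        occasion_id=oid or f"{sid}-o{order}",
        occasion_order=order,
        food_id=f"f{np.random.randint(1e9)}",
        amount_g=amount,
        glycemic_carb_g=carb,
        gi=gi,
    )


class TestOccasionMetrics:
    @pytest.mark.parametrize(
        "foods,expected",
        [
            ([(50.0, 59.0)], 59.0),
            ([(50.0, 40.0), (50.0, 80.0)], 60.0),
            ([(30.0, 100.0), (70.0, 50.0)], 65.0),  # (3000+3500)/100
        ],
    )
    def test_occasion_gi_is_carb_weighted_mean(self, foods, expected):
        assert occasion_gi([cf(c, g) for c, g in foods]) == pytest.approx(expected)

    def test_occasion_gi_absent_without_carbohydrate(self):
        assert occasion_gi([cf(0.0, 0.0, amount=100)]) is None

    @pytest.mark.parametrize(
        "foods,expected",
        [
            ([(100.0, 100.0)], 100.0),  # definition of the glucose reference
            ([(50.0, 40.0), (50.0, 80.0)], 60.0),  # (2000+4000)/100
            ([(0.0, 0.0), (0.0, 0.0)], 0.0),
        ],
    )
    def test_occasion_gl(self, foods, expected):
        lines = [cf(c, g, amount=max(c, 1) + 1) for c, g in foods]
        assert occasion_gl(lines) == pytest.approx(expected)


class TestDailyMetrics:
    def test_single_food_day_collapses_all_aggregations(self):
        d = daily_metrics([cf(120.0, 59.0)])
        assert d.dgi == d.av_gi == pytest.approx(59.0)
        assert d.dgl == d.av_gl == pytest.approx(120.0 * 59 / 100)
        assert d.n_occasions == d.n_carb_occasions == 1

    def test_equal_carb_occasions_average_their_gis(self):
        d = daily_metrics([cf(80.0, 55.0, order=1), cf(80.0, 65.0, order=2)])
        assert d.av_gi == pytest.approx(60.0)
        assert d.dgi == pytest.approx(60.0)

    def test_avgl_and_dgl_in_survey_regime(self):
        # occasion GLs 40, 40, 40, 45 (gi 50 at 80/80/80/90 g of carbohydrate)
        lines = [cf(80.0, 50.0, order=o) for o in (1, 2, 3)] + [cf(90.0, 50.0, order=4)]
        d = daily_metrics(lines)
        assert d.av_gl == pytest.approx(41.25)
        assert d.dgl == pytest.approx(165.0)

    def test_zero_carb_day_flagged(self):
        d = daily_metrics([cf(0.0, 0.0, amount=350)])
        assert d.dgi is None and d.av_gi is None
        assert d.dgl == 0.0 and d.total_glycemic_carb_g == 0.0

    def test_avgl_divisor_convention_flag(self):
        lines = [cf(80.0, 50.0, order=1), cf(0.0, 0.0, order=2, amount=350)]
        over_all = daily_metrics(lines, avgl_occasions="all")
        carb_only = daily_metrics(lines, avgl_occasions="carb_only")
        assert over_all.av_gl == pytest.approx(20.0)  # 40 / 2 occasions
        assert carb_only.av_gl == pytest.approx(40.0)
        assert over_all.av_gi == carb_only.av_gi  # AvGI always excludes zero-carb occasions


def brute_force_day(df: pd.DataFrame, avgl_occasions="all"):
    """Independent re-derivation of every day metric by explicit loops."""
    total = df["glycemic_carb_g"].sum()
    dgl = float(sum(r.glycemic_carb_g * r.gi for r in df.itertuples()) / 100)
    dgi = (
        float(sum(r.glycemic_carb_g * r.gi for r in df.itertuples()) / total)
        if total > 0
        else None
    )
    occ_gi, occ_gl = [], []
    for _, sub in df.groupby("occasion_id"):
        c = sub["glycemic_carb_g"].sum()
        s = float(sum(r.glycemic_carb_g * r.gi for r in sub.itertuples()))
        occ_gl.append(s / 100)
        if c > 0:
            occ_gi.append(s / c)
    av_gi = float(np.mean(occ_gi)) if occ_gi else None
    av_gl = float(np.mean(occ_gl))
    return dgi, dgl, av_gi, av_gl, total


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_pipeline_matches_brute_force_on_random_days(seed):
    """Vectorized metrics equal an explicit-loop oracle, and the algebraic
    identities DGL = DGI × Σcarb/100 and DGL = Σ occasion GL hold."""
    rng = np.random.default_rng(seed)
    df = random_day_lines(rng)
    day, occ = compute_metrics(df)
    assert len(day) == 1
    row = day.iloc[0]
    dgi, dgl, av_gi, av_gl, total = brute_force_day(df)

    assert row["dgl"] == pytest.approx(dgl, rel=1e-12, abs=1e-12)
    assert row["total_glycemic_carb_g"] == pytest.approx(total, rel=1e-12)
    if total > 0:
        assert row["dgi"] == pytest.approx(dgi, rel=1e-12)
        assert row["av_gi"] == pytest.approx(av_gi, rel=1e-12)
        # identity: dgl = dgi × total/100, additivity over occasions
        assert row["dgl"] == pytest.approx(row["dgi"] * total / 100, rel=1e-9)
    assert row["av_gl"] == pytest.approx(av_gl, rel=1e-12)
    assert row["dgl"] == pytest.approx(occ["gl"].sum(), rel=1e-9)

    # bounds: dgi and av_gi between extreme occasion GIs
    if total > 0:
        gis = occ["gi"].dropna()
        assert gis.min() - 1e-9 <= row["dgi"] <= gis.max() + 1e-9
        assert gis.min() - 1e-9 <= row["av_gi"] <= gis.max() + 1e-9

    # scale equivariance: doubling amounts doubles loads, fixes indices
    df2 = df.assign(amount_g=df["amount_g"] * 2, glycemic_carb_g=df["glycemic_carb_g"] * 2)
    day2, _ = compute_metrics(df2)
    assert day2.iloc[0]["dgl"] == pytest.approx(2 * row["dgl"], rel=1e-9)
    assert day2.iloc[0]["av_gl"] == pytest.approx(2 * row["av_gl"], rel=1e-9)
    if total > 0:
        assert day2.iloc[0]["dgi"] == pytest.approx(row["dgi"], rel=1e-9)
        assert day2.iloc[0]["av_gi"] == pytest.approx(row["av_gi"], rel=1e-9)

    # the list-based public API agrees with the vectorized path
    foods = [
        ConsumedFood(
            student_id=r.student_id,
            occasion_id=r.occasion_id,
            occasion_order=r.occasion_order,
            food_id=r.food_id,
            amount_g=r.amount_g,
            glycemic_carb_g=r.glycemic_carb_g,
            gi=r.gi,
        )
        for r in df.itertuples()
    ]
    d = daily_metrics(foods)
    assert d.dgl == pytest.approx(row["dgl"], rel=1e-12)
    assert d.av_gl == pytest.approx(row["av_gl"], rel=1e-12)


class TestOccasionProfile:
    def _occ_df(self, gis, order=1):
        return pd.DataFrame(
            {
                "student_id": [f"S{i}" for i in range(len(gis))],
                "occasion_id": [f"S{i}-o{order}" for i in range(len(gis))],
                "occasion_order": order,
                "gi": gis,
                "gl": 10.0,
                "carb_g": 50.0,
            }
        )

    def test_degenerate_distribution_gives_flat_summary(self):
        prof = occasion_profile(self._occ_df([59.0] * 8))
        row = prof.iloc[0]
        assert all(row[q] == 59.0 for q in ["q0", "q1", "median", "q3", "q4"])

    def test_order_statistics_linear_interpolation(self):
        prof = occasion_profile(self._occ_df([40.0, 50.0, 60.0, 70.0, 80.0]))
        row = prof.iloc[0]
        assert (row["q1"], row["median"], row["q3"]) == (50.0, 60.0, 70.0)
        assert (row["q0"], row["q4"]) == (40.0, 80.0)  # Tukey whiskers = extremes here

    def test_group_with_no_occasions_is_absent_not_zero(self):
        df = self._occ_df([50.0, 60.0])
        group = pd.Series({"S0": "NW", "S1": "NW"})  # no OW students at all
        prof = occasion_profile(df, group)
        assert set(prof["group"]) == {"NW"}
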