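import numpy as np
import pandas as pd
import pytest

from saltlax import (
    IndicatorPanel,
    composite_scores,
    critic_weights,
    standardize,
)
from saltlax.core_data import InsufficientDataError, SchemaError


@pytest.fixture()
def tiny_block_panel():
    """Factory for a one-system panel carrying explicit standardized columns."""

    from saltlax import SystemSchema

    def make(columns: dict) -> IndicatorPanel:
        n = len(next(iter(columns.values())))
        schema = SystemSchema(
            system={k: "pharmacological" for k in columns},
            polarity={k: "positive" for k in columns},
        )
        df = pd.DataFrame({"treatment": ["CK"] * n, "replicate": range(1, n + 1), **columns})
        return IndicatorPanel(df, schema)

    return make


def _make_panel(base_panel, **columns):
    df = base_panel.data.copy()
    for name, values in columns.items():
        df[name] = values
    return IndicatorPanel(df, base_panel.schema)


class TestStandardize:
    def test_endpoints_map_to_unit_interval(self, small_panel):
        treat = small_panel.data["treatment"]
        col = treat.map({t: 0.0 for t in treat.unique()}).to_numpy()
        col[:5] = [2.0, 4.0, 6.0, 3.0, 5.0]  # CK block
        panel = _make_panel(small_panel, TL=col)
        std = standardize(panel, scope="per-treatment")
        ck = std.data.query("treatment == 'CK'")["TL"].to_numpy()
        assert ck == pytest.approx([0.0, 0.5, 1.0, 0.25, 0.75])

    def test_negative_polarity_reflects(self, small_panel):
        col = small_panel.data["L-MDA"].to_numpy().copy()
        col[:3] = [2.0, 4.0, 6.0]
        panel = _make_panel(small_panel, **{"L-MDA": col})
        std = standardize(panel, scope="per-treatment")
        ck = std.data.query("treatment == 'CK'")["L-MDA"].to_numpy()[:3]
        assert ck[0] > ck[1] > ck[2]  # larger MDA -> worse -> smaller score

    def test_constant_column_maps_to_zero_with_flag(self, small_panel):
        panel = _make_panel(small_panel, Tr=np.full(30, 7.0))
        with pytest.warns(UserWarning, match="constant"):
            std = standardize(panel, scope="global")
        assert (std.data["Tr"] == 0).all()
        assert "global:Tr" in std.data.attrs["constant_columns"]

    def test_insufficient_rows_rejected(self, small_panel):
        one_row = IndicatorPanel(small_panel.data.iloc[:1].copy(), small_panel.schema)
        with pytest.raises(InsufficientDataError):
            standardize(one_row, scope="per-treatment")


class TestCriticWeights:
    def test_equal_sd_uncorrelated_pair_splits_evenly(self, tiny_block_panel):
        panel = tiny_block_panel(
            {
                "a": [0.0, 0.5, 1.0, 0.5],  # orthogonal, equal SD
                "b": [0.5, 0.0, 0.5, 1.0],
            }
        )
        (weights,) = critic_weights(panel, scope="global", system="pharmacological")
        assert weights.weights["a"] == pytest.approx(0.5)
        assert weights.weights["b"] == pytest.approx(0.5)

    def test_two_identical_columns_degenerate_uniform(self, small_panel):
        df = small_panel.data.copy()
        rng = np.random.default_rng(3)
        shared = rng.random(30)
        for col in small_panel.schema.indicators_in("pharmacological"):
            df[col] = shared
        panel = IndicatorPanel(df, small_panel.schema)
        std = standardize(panel, scope="global")
        (weights,) = critic_weights(std, scope="global", system="pharmacological")
        assert weights.degenerate
        assert all(v == pytest.approx(1 / 6) for v in weights.weights.values())

    def test_matches_brute_force_on_fixed_5x3_block(self, tiny_block_panel):
        # fixed standardized 5x3 block; independent loop evaluation of
        # contrast * conflict = SD_j * sum_k (1 - r_jk)
        block = np.array(
            [
                [0.0, 1.0, 0.2],
                [0.25, 0.8, 0.0],
                [0.5, 0.1, 0.9],
                [0.75, 0.0, 0.4],
                [1.0, 0.55, 1.0],
            ]
        )
        score = np.empty(3)
        for j in range(3):
            xj = block[:, j]
            contrast = np.sqrt(((xj - xj.mean()) ** 2).sum() / (len(xj) - 1))
            conflict = 0.0
            for k in range(3):
                xk = block[:, k]
                r = ((xj - xj.mean()) @ (xk - xk.mean())) / np.sqrt(
                    ((xj - xj.mean()) ** 2).sum() * ((xk - xk.mean()) ** 2).sum()
                )
                conflict += 1.0 - r
            score[j] = contrast * conflict
        expected = score / score.sum()

        panel = tiny_block_panel(
            {"a": block[:, 0], "b": block[:, 1], "c": block[:, 2]}
        )
        (weights,) = critic_weights(panel, scope="global", system="pharmacological")
        got = np.array([weights.weights[c] for c in ("a", "b", "c")])
        assert got == pytest.approx(expected, abs=1e-12)

    def test_weights_scale_invariant_under_affine_raw_transform(self, small_panel):
        std_a = standardize(small_panel, "per-treatment")
        df = small_panel.data.copy()
        df["Gs"] = 100.0 * df["Gs"] + 3.0
        std_b = standardize(IndicatorPanel(df, small_panel.schema), "per-treatment")
        wa = critic_weights(std_a, "per-treatment", "photosynthesis")
        wb = critic_weights(std_b, "per-treatment", "photosynthesis")
        for a, b in zip(wa, wb):
            assert a.scope == b.scope
            for ind in a.weights:
                assert a.weights[ind] == pytest.approx(b.weights[ind], abs=1e-10)

    def test_high_sd_low_correlation_indicator_dominates(self, small_panel):
        rng = np.random.default_rng(5)
        df = small_panel.data.copy()
        base = np.linspace(0, 1, 30)
        cols = small_panel.schema.indicators_in("photosynthesis")
        for col in cols[:-1]:
            df[col] = base + rng.normal(0, 0.01, 30)  # tight, mutually correlated
        df[cols[-1]] = rng.permutation(base)  # independent, full spread
        std = standardize(IndicatorPanel(df, small_panel.schema), scope="global")
        (weights,) = critic_weights(std, scope="global", system="photosynthesis")
        assert max(weights.weights, key=weights.weights.get) == cols[-1]


class TestCompositeScores:
    def test_unit_weight_recovers_indicator(self, small_panel):
        std = standardize(small_panel, "per-treatment")
        weights = critic_weights(std, "per-treatment")
        for w in weights:
            if w.system == "growth":
                first = list(w.weights)[0]
                w.weights = {k: (1.0 if k == first else 0.0) for k in w.weights}
        scores = composite_scores(small_panel, weights, value_basis="raw")
        assert scores.data["growth"].to_numpy() == pytest.approx(
            small_panel.data[list(small_panel.schema.indicators_in("growth"))[0]].to_numpy()
        )

    def test_raw_basis_is_linear_in_indicators(self, small_panel):
        std = standardize(small_panel, "per-treatment")
        weights = critic_weights(std, "per-treatment")
        base = composite_scores(small_panel, weights, value_basis="raw")
        df = small_panel.data.copy()
        for col in small_panel.schema.indicators_in("antioxidant"):
            df[col] = 2.0 * df[col]
        doubled = composite_scores(IndicatorPanel(df, small_panel.schema), weights, "raw")
        assert doubled.data["antioxidant"].to_numpy() == pytest.approx(
            2.0 * base.data["antioxidant"].to_numpy()
        )
        assert doubled.data["growth"].to_numpy() == pytest.approx(
            base.data["growth"].to_numpy()
        )

    def test_uniform_weights_give_arithmetic_mean_times_k(self, small_panel):
        std = standardize(small_panel, "per-treatment")
        weights = critic_weights(std, "per-treatment")
        cols = small_panel.schema.indicators_in("photosynthesis")
        for w in weights:
            if w.system == "photosynthesis":
                w.weights = {k: 1.0 / len(cols) for k in w.weights}
        scores = composite_scores(small_panel, weights, value_basis="raw")
        expected = small_panel.data[list(cols)].mean(axis=1).to_numpy()
        assert scores.data["photosynthesis"].to_numpy() == pytest.approx(expected)

    def test_missing_weights_rejected(self, small_panel):
        std = standardize(small_panel, "per-treatment")
        weights = critic_weights(std, "per-treatment")
        with pytest.raises(SchemaError, match="no weights"):
            composite_scores(small_panel, weights[:-1])

    def test_standardized_basis_monotone_in_positive_indicator(self, small_panel):
        std = standardize(small_panel, "per-treatment")
        weights = critic_weights(std, "per-treatment")
        base = composite_scores(small_panel, weights, value_basis="standardized")
        df = small_panel.data.copy()
        idx = df.query("treatment == 'CK'").index[2]
        df.loc[idx, "Pn"] = df["Pn"].loc[df["treatment"] == "CK"].max() + 5.0
        bumped = composite_scores(
            IndicatorPanel(df, small_panel.schema), weights, "standardized"
        )
        assert (
            bumped.data.loc[idx, "photosynthesis"]
            >= base.data.loc[idx, "photosynthesis"] - 1e-12
        )
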