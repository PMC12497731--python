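"""CRITIC objective weighting and composite system scores.

CRITIC (CRiteria Importance Through Intercriteria Correlation) assigns each
indicator a weight proportional to the information it carries: its contrast
intensity (standard deviation of the min-max standardized column) times its
conflict with the other indicators of the block (sum of 1 - r_jk over
pairwise Pearson correlations). Weights are computed per system block,
either within each treatment group (the study's convention — each treatment
column of the published weight table sums to 100% per system) or globally.

Composite system scores are weighted sums of the indicators of a system,
computed on raw values by default (matching the published score magnitudes)
or on standardized values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core_data import (
    SYSTEMS,
    CompositeDataset,
    IndicatorPanel,
    InsufficientDataError,
    SchemaError,
)

__all__ = ["CriticWeights", "standardize", "critic_weights", "composite_scores"]

_SCOPES = ("per-treatment", "global")


@dataclass
class CriticWeights:
    """Weight fractions for one (scope group, system) block.

    ``scope`` is a treatment name or ``"global"``; weights are non-negative
    and sum to 1 within the block. ``degenerate`` marks blocks where every
    contrast*conflict score was zero and uniform weights were substituted.
    """

    scope: str
    system: str
    weights: Mapping[str, float]
    degenerate: bool = False
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = np.array(list(self.weights.values()), dtype=float)
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")

    def as_percent(self) -> dict[str, float]:
        return {k: 100.0 * v for k, v in self.weights.items()}


def _scope_groups(panel: IndicatorPanel, scope: str):
    if scope not in _SCOPES:
        raise ValueError(f"scope must be one of {_SCOPES}, got {scope!r}")
    if scope == "global":
        yield "global", panel.data
    else:
        for treat, grp in panel.data.groupby("treatment", sort=False):
            yield str(treat), grp


def standardize(panel: IndicatorPanel, scope: str = "per-treatment") -> IndicatorPanel:
    """Min-max standardize each indicator within each scope group.

    Positive-polarity indicators map to (x-min)/(max-min), negative-polarity
    ones (MDA) to (max-x)/(max-min), so 1 always means "best". Constant
    columns map to 0 and are flagged with a warning.
    """
    out = panel.data.copy()
    constant: list[str] = []
    for label, grp in _scope_groups(panel, scope):
        if len(grp) < 2:
            raise InsufficientDataError(
                f"scope group {label!r} has {len(grp)} row(s); need at least 2"
            )
        for ind in panel.schema.indicators:
            col = grp[ind].to_numpy(dtype=float)
            lo, hi = col.min(), col.max()
            if hi == lo:
                std = np.zeros_like(col)
                constant.append(f"{label}:{ind}")
            elif panel.schema.polarity[ind] == "positive":
                std = (col - lo) / (hi - lo)
            else:
                std = (hi - col) / (hi - lo)
            out.loc[grp.index, ind] = std
    if constant:
        warnings.warn(f"constant columns mapped to 0: {constant}", stacklevel=2)
    result = IndicatorPanel(out, panel.schema)
    result.data.attrs["constant_columns"] = tuple(constant)
    return result


def critic_weights(
    standardized: IndicatorPanel, scope: str = "per-treatment", system: str | None = None
) -> list[CriticWeights]:
    """CRITIC weights per (scope group, system) block of a standardized panel.

    For indicator j in a block: contrast C_j = sample SD of the standardized
    column; conflict R_j = sum_k (1 - r_jk); score S_j = C_j * R_j; weight
    w_j = S_j / sum(S). Undefined correlations (constant columns) enter the
    conflict sum as r = 0, with a flag; an all-zero block falls back to
    uniform weights, flagged degenerate.
    """
    systems = [system] if system is not None else list(SYSTEMS)
    results: list[CriticWeights] = []
    for label, grp in _scope_groups(standardized, scope):
        if len(grp) < 3:
            raise InsufficientDataError(
                f"scope group {label!r} has {len(grp)} rows; need at least 3 for CRITIC"
            )
        for sys_name in systems:
            cols = standardized.schema.indicators_in(sys_name)
            if len(cols) < 2:
                raise InsufficientDataError(
                    f"system {sys_name!r} has {len(cols)} indicator(s); need at least 2"
                )
            block = grp[list(cols)].to_numpy(dtype=float)
            contrast = block.std(axis=0, ddof=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                corr = np.corrcoef(block, rowvar=False)
            flags: list[str] = []
            if np.isnan(corr).any():
                flags.append("constant-column correlations treated as 0")
                corr = np.nan_to_num(corr, nan=0.0)
            np.fill_diagonal(corr, 1.0)
            conflict = (1.0 - corr).sum(axis=1)
            score = contrast * conflict
            total = score.sum()
            if total <= 0:
                weights = np.full(len(cols), 1.0 / len(cols))
                degenerate = True
            else:
                weights = score / total
                degenerate = False
            results.append(
                CriticWeights(
                    scope=label,
                    system=sys_name,
                    weights=dict(zip(cols, weights)),
                    degenerate=degenerate,
                    flags=tuple(flags),
                )
            )
    return results


def composite_scores(
    panel: IndicatorPanel,
    weights: list[CriticWeights],
    value_basis: str = "raw",
    scope: str = "per-treatment",
) -> CompositeDataset:
    """Aggregate indicators into the four composite system scores.

    score(row, system) = sum_j w_j * v_j(row), with v_j the raw indicator
    value (default; matches the published score magnitudes) or the min-max
    standardized value.
    """
    if value_basis not in ("raw", "standardized"):
        raise ValueError(f"value_basis must be 'raw' or 'standardized', got {value_basis!r}")
    basis_panel = standardize(panel, scope) if value_basis == "standardized" else panel

    by_key: dict[tuple[str, str], CriticWeights] = {}
    for w in weights:
        by_key[(w.scope, w.system)] = w
    for label, _ in _scope_groups(panel, scope):
        for sys_name in SYSTEMS:
            key = (label, sys_name)
            if key not in by_key:
                raise SchemaError(f"no weights for scope {label!r}, system {sys_name!r}")
            missing = set(panel.schema.indicators_in(sys_name)) - set(by_key[key].weights)
            if missing:
                raise SchemaError(
                    f"weights for {key} missing indicators {sorted(missing)}"
                )

    rows = []
    for label, grp in _scope_groups(basis_panel, scope):
        scores = pd.DataFrame(index=grp.index)
        for sys_name in SYSTEMS:
            w = by_key[(label, sys_name)]
            cols = list(w.weights)
            vec = np.array([w.weights[c] for c in cols])
            scores[sys_name] = grp[cols].to_numpy(dtype=float) @ vec
        scores.insert(0, "replicate", grp["replicate"].to_numpy())
        scores.insert(0, "treatment", grp["treatment"].to_numpy())
        rows.append(scores)
    data = pd.concat(rows).sort_index(kind="stable").reset_index(drop=True)
    return CompositeDataset(data)
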