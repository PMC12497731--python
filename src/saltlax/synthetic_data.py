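"""Synthetic replicate-level data with the study's design.

The trial design is 6 treatments x 5 replicate pots x 29 indicators, but the
replicate-level raw data were never published — only treatment means +/- SD
for the photosynthetic and metabolite panels, and percent changes for the
rest. This module draws correlated Gaussian replicates around configurable
treatment means so that every downstream stage (CRITIC weighting, density
weighting, LSSVM tuning) can be exercised and property-tested end to end.

Default means/SDs use the published photosynthetic and metabolite tables
verbatim; enzyme, MDA and growth defaults are documented placeholders chosen
to be consistent with the quoted percent changes (they are NOT published
values). The correlation structure follows the reported qualitative pattern:
indicators within a system are mutually positively correlated and the MDA
columns run against their system's enzymes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_data import (
    SYSTEMS,
    TREATMENTS,
    CompositeDataset,
    IndicatorPanel,
    SystemSchema,
    default_schema,
    load_fixture,
)

__all__ = [
    "SimulationConfig",
    "default_simulation_config",
    "generate_panel",
    "generate_composite_like",
    "COMPOSITE_LINKS",
]

_MDA_COLUMNS = ("L-MDA", "R-MDA")

# Placeholder CK baselines for indicators whose replicate data were only
# shown as figures (enzyme activities U/g FW, MDA nmol/g FW, biomass g,
# lengths cm, diameters mm, volume cm^3, tip counts). Synthetic values, not
# published ones.
_PLACEHOLDER_CK = {
    "root biomass": 2.5,
    "stem-leaf biomass": 4.0,
    "R-S": 0.62,
    "TL": 28.0,
    "MTD": 4.5,
    "TRL": 320.0,
    "AD": 1.2,
    "RV": 2.8,
    "Tips": 210.0,
    "L-SOD": 450.0,
    "R-SOD": 380.0,
    "L-POD": 1200.0,
    "R-POD": 900.0,
    "L-CAT": 300.0,
    "R-CAT": 220.0,
    "L-MDA": 18.0,
    "R-MDA": 15.0,
}

# Quoted percent changes: S relative to CK, and S+La0.75 relative to S.
_PCT_S_VS_CK = {
    "TL": -19, "MTD": -18, "TRL": -15, "AD": -21, "RV": -17, "Tips": -9,
    "stem-leaf biomass": -13, "root biomass": -38, "R-S": -10,
    "L-SOD": -11, "L-POD": -54, "L-CAT": -53, "L-MDA": +9,
    "R-SOD": -30, "R-POD": -49, "R-CAT": -39, "R-MDA": +9,
}
_PCT_LA075_VS_S = {
    "TL": +56, "MTD": +52, "TRL": +89, "AD": +62, "RV": +86, "Tips": +33,
    "stem-leaf biomass": +61, "root biomass": +122, "R-S": +79,
    "L-SOD": +424, "L-POD": +117, "L-CAT": +140, "L-MDA": -33,
    "R-SOD": +525, "R-POD": +133, "R-CAT": +102, "R-MDA": -29,
}

#: Dose-response interpolation between S (0) and the S+La0.75 optimum (1)
#: for the placeholder indicators; La1.0 regresses toward the S level.
_LA_FRACTION = {"S+La0.25": 1 / 3, "S+La0.5": 2 / 3, "S+La0.75": 1.0, "S+La1.0": 0.2}

_PLACEHOLDER_CV = 0.06  # relative SD for placeholder indicators


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings for a 6-treatment x n-replicate indicator panel.

    ``means``/``sds`` are treatment x indicator tables; ``rho_within`` the
    exchangeable correlation inside each system block; ``rho_mda`` the
    correlation of MDA columns against their system's enzyme columns.
    """

    means: pd.DataFrame
    sds: pd.DataFrame
    rho_within: float = 0.6
    rho_mda: float = -0.5
    replicates: int = 5
    seed: int = 0
    schema: SystemSchema = field(default_factory=default_schema)

    def __post_init__(self) -> None:
        if not -1 < self.rho_within < 1 or not -1 < self.rho_mda < 1:
            raise ValueError("correlation targets must lie in (-1, 1)")
        if (self.sds.to_numpy(dtype=float) < 0).any():
            raise ValueError("SDs must be non-negative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate per treatment")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def default_simulation_config(seed: int = 0) -> SimulationConfig:
    """Config using published means/SDs where printed, placeholders elsewhere."""
    schema = default_schema()
    means = pd.DataFrame(index=list(TREATMENTS), columns=list(schema.indicators), dtype=float)
    sds = means.copy()
    for name in ("table1", "table2"):
        tab = load_fixture(name)
        for _, row in tab.iterrows():
            means.loc[row["treatment"], row["indicator"]] = row["mean"]
            sds.loc[row["treatment"], row["indicator"]] = row["sd"]
    for ind, ck in _PLACEHOLDER_CK.items():
        s_val = ck * (1 + _PCT_S_VS_CK[ind] / 100.0)
        la075 = s_val * (1 + _PCT_LA075_VS_S[ind] / 100.0)
        means.loc["CK", ind] = ck
        means.loc["S", ind] = s_val
        for treat, frac in _LA_FRACTION.items():
            means.loc[treat, ind] = s_val + frac * (la075 - s_val)
        sds.loc[:, ind] = _PLACEHOLDER_CV * means.loc[:, ind].abs()
    return SimulationConfig(means=means, sds=sds, seed=seed, schema=schema)


def _block_correlation(config: SimulationConfig) -> np.ndarray:
    """System-block-diagonal correlation with MDA columns anti-correlated."""
    indicators = config.schema.indicators
    n = len(indicators)
    corr = np.eye(n)
    sys_of = config.schema.system
    for i, a in enumerate(indicators):
        for j, b in enumerate(indicators):
            if i == j or sys_of[a] != sys_of[b]:
                continue
            a_mda, b_mda = a in _MDA_COLUMNS, b in _MDA_COLUMNS
            corr[i, j] = config.rho_mda if a_mda != b_mda else config.rho_within
    return corr


def _nearest_psd(corr: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Eigenvalue-clipped nearest-PSD repair, rescaled to unit diagonal."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= eps:
        return corr
    repaired = (vecs * np.clip(vals, eps, None)) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    vals = np.linalg.eigvalsh(repaired)
    if vals.min() < -eps:
        raise ValueError("correlation structure not repairable to PSD")
    return repaired


def generate_panel(config: SimulationConfig) -> IndicatorPanel:
    """Draw a correlated-Gaussian replicate panel; deterministic given seed.

    Negative draws for (strictly positive) indicators are truncated at zero;
    the truncation count is flagged via a warning and stored in
    ``panel.data.attrs['truncated']``.
    """
    rng = np.random.default_rng(config.seed)
    indicators = list(config.schema.indicators)
    corr = _nearest_psd(_block_correlation(config))
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(indicators)))

    frames = []
    truncated = 0
    for treat in TREATMENTS:
        mu = config.means.loc[treat, indicators].to_numpy(dtype=float)
        sd = config.sds.loc[treat, indicators].to_numpy(dtype=float)
        z = rng.standard_normal((config.replicates, len(indicators)))
        draws = mu + (z @ chol.T) * sd
        neg = draws < 0
        truncated += int(neg.sum())
        draws[neg] = 0.0
        df = pd.DataFrame(draws, columns=indicators)
        df.insert(0, "replicate", np.arange(1, config.replicates + 1))
        df.insert(0, "treatment", treat)
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    if truncated:
        warnings.warn(f"truncated {truncated} negative draws at zero", stacklevel=2)
    panel = IndicatorPanel(data, config.schema)
    panel.data.attrs["truncated"] = truncated
    return panel


# --------------------------------------------------------------------------
# composite-shaped datasets with a known input->output link


def _link_linear(antiox: np.ndarray, photo: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    growth = 200.0 + 0.9 * antiox + 2.2 * photo
    pharm = 400.0 + 1.6 * antiox + 3.5 * photo
    return growth, pharm


def _link_smooth(antiox: np.ndarray, photo: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g_lin, p_lin = _link_linear(antiox, photo)
    growth = g_lin + 60.0 * np.sin(antiox / 90.0) + 25.0 * np.sin(photo / 20.0)
    pharm = p_lin + 90.0 * np.sin(antiox / 70.0) + 40.0 * np.sin(photo / 25.0)
    return growth, pharm


def _link_constant(antiox: np.ndarray, photo: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return np.full_like(antiox, 800.0), np.full_like(antiox, 1400.0)


COMPOSITE_LINKS = {
    "linear": _link_linear,
    "smooth-nonlinear": _link_smooth,
    "constant": _link_constant,
}


def generate_composite_like(
    config: SimulationConfig,
    link: str = "smooth-nonlinear",
    noise_sd: float | None = None,
) -> CompositeDataset:
    """Composite-score dataset with a known response surface.

    Antioxidant and photosynthesis scores are drawn per treatment as
    correlated Gaussians (means/SDs taken from the packaged composite-score
    table); growth and pharmacological scores are ``link(inputs)`` plus
    Gaussian noise. ``noise_sd=None`` defaults to 5% of each clean output's
    range; pass 0 for a noiseless surface. Deterministic given config seed.
    """
    if link not in COMPOSITE_LINKS:
        raise KeyError(f"unknown link {link!r}; valid: {sorted(COMPOSITE_LINKS)}")
    rng = np.random.default_rng(config.seed)
    ref = load_fixture("table4").data
    stats = ref.groupby("treatment", sort=False)[["antioxidant", "photosynthesis"]].agg(
        ["mean", "std"]
    )
    rho = config.rho_within
    chol = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))

    frames = []
    for treat in TREATMENTS:
        z = rng.standard_normal((config.replicates, 2)) @ chol.T
        antiox = (
            stats.loc[treat, ("antioxidant", "mean")]
            + z[:, 0] * stats.loc[treat, ("antioxidant", "std")]
        )
        photo = (
            stats.loc[treat, ("photosynthesis", "mean")]
            + z[:, 1] * stats.loc[treat, ("photosynthesis", "std")]
        )
        frames.append(
            pd.DataFrame(
                {
                    "treatment": treat,
                    "replicate": np.arange(1, config.replicates + 1),
                    "antioxidant": antiox,
                    "photosynthesis": photo,
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    growth, pharm = COMPOSITE_LINKS[link](
        data["antioxidant"].to_numpy(), data["photosynthesis"].to_numpy()
    )
    if noise_sd is None:
        noise = {
            "growth": 0.05 * (growth.max() - growth.min()),
            "pharmacological": 0.05 * (pharm.max() - pharm.min()),
        }
    else:
        noise = {"growth": float(noise_sd), "pharmacological": float(noise_sd)}
    data["growth"] = growth + rng.standard_normal(len(data)) * noise["growth"]
    data["pharmacological"] = pharm + rng.standard_normal(len(data)) * noise["pharmacological"]
    return CompositeDataset(data[["treatment", "replicate", *SYSTEMS]])
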