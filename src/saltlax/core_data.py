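"""Domain types, panel I/O and packaged reference tables.

The experimental design is a pot trial on *Glycyrrhiza uralensis* seedlings:
six treatments (unstressed control ``CK``; 160 mM NaCl stress ``S``; and NaCl
stress plus lanthanum nitrate at 0.25/0.5/0.75/1.0 mM), five replicate pots
per treatment, and a panel of 29 physiological indicators grouped into four
systems (antioxidant, photosynthesis, growth, pharmacological).

The packaged fixtures transcribe the published summary tables: photosynthetic
means +/- SD (``table1``), secondary-metabolite means +/- SD (``table2``),
per-treatment CRITIC weights in percent (``table3``), replicate-level
composite system scores (``table4``), and the HPLC / spectrophotometric
standard curves (``standard_curves``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "TREATMENTS",
    "SYSTEMS",
    "PanelParseError",
    "SchemaError",
    "InsufficientDataError",
    "SystemSchema",
    "IndicatorPanel",
    "CompositeDataset",
    "StandardCurve",
    "default_schema",
    "read_panel",
    "write_panel",
    "read_composite",
    "write_composite",
    "load_fixture",
]

#: Canonical treatment ordering (control, salt stress, salt + La(NO3)3 doses).
TREATMENTS: tuple[str, ...] = ("CK", "S", "S+La0.25", "S+La0.5", "S+La0.75", "S+La1.0")

#: The four composite indicator systems.
SYSTEMS: tuple[str, ...] = ("antioxidant", "photosynthesis", "growth", "pharmacological")

_FIXTURE_NAMES = ("table1", "table2", "table3", "table4", "standard_curves")


class PanelParseError(ValueError):
    """Raised when a panel CSV cannot be parsed (bad label, bad cell)."""


class SchemaError(ValueError):
    """Raised when data do not match the indicator schema."""


class InsufficientDataError(ValueError):
    """Raised when an operation receives too few rows/groups."""


# --------------------------------------------------------------------------
# schema

# (system, polarity) per indicator; polarity "negative" marks indicators
# where larger values mean worse condition (membrane lipid peroxidation).
_DEFAULT_SCHEMA: tuple[tuple[str, str, str], ...] = (
    # growth system: biomass, allocation and root architecture
    ("root biomass", "growth", "positive"),
    ("stem-leaf biomass", "growth", "positive"),
    ("R-S", "growth", "positive"),
    ("TL", "growth", "positive"),
    ("MTD", "growth", "positive"),
    ("TRL", "growth", "positive"),
    ("AD", "growth", "positive"),
    ("RV", "growth", "positive"),
    ("Tips", "growth", "positive"),
    # photosynthesis system
    ("SLA", "photosynthesis", "positive"),
    ("Chl", "photosynthesis", "positive"),
    ("Pn", "photosynthesis", "positive"),
    ("Gs", "photosynthesis", "positive"),
    ("Ci", "photosynthesis", "positive"),
    ("Tr", "photosynthesis", "positive"),
    # antioxidant system: leaf/root enzyme activities and MDA content
    ("L-SOD", "antioxidant", "positive"),
    ("R-SOD", "antioxidant", "positive"),
    ("L-POD", "antioxidant", "positive"),
    ("R-POD", "antioxidant", "positive"),
    ("L-CAT", "antioxidant", "positive"),
    ("R-CAT", "antioxidant", "positive"),
    ("L-MDA", "antioxidant", "negative"),
    ("R-MDA", "antioxidant", "negative"),
    # pharmacological system: medicinal secondary metabolites
    ("glycyrrhizic acid", "pharmacological", "positive"),
    ("glycyrrhetinic acid", "pharmacological", "positive"),
    ("liquiritin", "pharmacological", "positive"),
    ("liquiritigenin", "pharmacological", "positive"),
    ("isoliquiritigenin", "pharmacological", "positive"),
    ("total flavonoids", "pharmacological", "positive"),
)


@dataclass(frozen=True)
class SystemSchema:
    """Maps each indicator to its system and polarity.

    Parameters
    ----------
    system : mapping of indicator name to system name.
    polarity : mapping of indicator name to ``"positive"`` or ``"negative"``.
    """

    system: Mapping[str, str]
    polarity: Mapping[str, str]

    def __post_init__(self) -> None:
        if set(self.system) != set(self.polarity):
            raise SchemaError("system and polarity must cover the same indicators")
        bad = {s for s in self.system.values() if s not in SYSTEMS}
        if bad:
            raise SchemaError(f"unknown systems {sorted(bad)}; valid: {SYSTEMS}")
        bad = {p for p in self.polarity.values() if p not in ("positive", "negative")}
        if bad:
            raise SchemaError(f"invalid polarity values {sorted(bad)}")

    @property
    def indicators(self) -> tuple[str, ...]:
        return tuple(self.system)

    def indicators_in(self, system: str) -> tuple[str, ...]:
        if system not in SYSTEMS:
            raise SchemaError(f"unknown system {system!r}; valid: {SYSTEMS}")
        return tuple(name for name, s in self.system.items() if s == system)


def default_schema() -> SystemSchema:
    """The 29-indicator schema of the study, MDA columns negative-polarity."""
    return SystemSchema(
        system={name: sys for name, sys, _ in _DEFAULT_SCHEMA},
        polarity={name: pol for name, _, pol in _DEFAULT_SCHEMA},
    )


# --------------------------------------------------------------------------
# containers


def _check_treatments(values: Iterable[str], where: str) -> None:
    for v in values:
        if v not in TREATMENTS:
            raise PanelParseError(
                f"unknown treatment label {v!r} in {where}; valid labels: {list(TREATMENTS)}"
            )


@dataclass
class IndicatorPanel:
    """Replicate-level indicator table.

    ``data`` holds one row per pot with columns ``treatment``, ``replicate``
    and one numeric column per indicator of ``schema``.
    """

    data: pd.DataFrame
    schema: SystemSchema = field(default_factory=default_schema)

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if cols[:2] != ["treatment", "replicate"]:
            raise SchemaError("panel must start with 'treatment','replicate' columns")
        expected = set(self.schema.indicators)
        got = set(cols[2:])
        if got != expected:
            missing, extra = sorted(expected - got), sorted(got - expected)
            raise SchemaError(f"indicator mismatch: missing {missing}, unexpected {extra}")
        _check_treatments(self.data["treatment"], "panel")
        dup = self.data.duplicated(subset=["treatment", "replicate"])
        if dup.any():
            raise SchemaError("replicate ids must be unique within treatment")

    @property
    def indicators(self) -> tuple[str, ...]:
        return self.schema.indicators

    def values(self) -> pd.DataFrame:
        """Indicator columns only, in schema order."""
        return self.data[list(self.schema.indicators)]

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IndicatorPanel):
            return NotImplemented
        return self.data.equals(other.data) and self.schema == other.schema


@dataclass
class CompositeDataset:
    """Per-replicate composite scores for the four systems (Table-4 shape)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if cols != ["treatment", "replicate", *SYSTEMS]:
            raise SchemaError(
                f"composite dataset columns must be treatment,replicate,{','.join(SYSTEMS)}"
            )
        _check_treatments(self.data["treatment"], "composite dataset")
        scores = self.data[list(SYSTEMS)]
        import numpy as np

        if not np.isfinite(scores.to_numpy(dtype=float)).all():
            raise SchemaError("composite scores must be finite")

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class StandardCurve:
    """Linear calibration curve signal = slope * concentration + intercept."""

    analyte: str
    slope: float
    intercept: float
    low: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError(f"degenerate standard curve for {self.analyte}: zero slope")
        if not self.low < self.high:
            raise ValueError(f"invalid range [{self.low}, {self.high}] for {self.analyte}")


# --------------------------------------------------------------------------
# I/O

_FLOAT_FMT = "%.12g"  # 12 significant digits: lossless for table-scale reals


def read_panel(path: str | Path, schema: SystemSchema | None = None) -> IndicatorPanel:
    """Read a replicate-level panel CSV.

    Expects a header ``treatment,replicate,<indicator...>``; parsing is
    strict — an unknown treatment label or a non-numeric cell raises
    :class:`PanelParseError` naming the offending cell.
    """
    schema = schema or default_schema()
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(raw.columns)
    if cols[:2] != ["treatment", "replicate"]:
        raise SchemaError(f"{path}: header must start with 'treatment,replicate'")
    missing = [c for c in schema.indicators if c not in cols[2:]]
    if missing:
        raise SchemaError(f"{path}: missing indicator columns {missing}")
    _check_treatments(raw["treatment"], str(path))

    parsed: dict[str, object] = {"treatment": raw["treatment"].tolist()}
    for col in ["replicate", *schema.indicators]:
        out = []
        for i, cell in enumerate(raw[col]):
            try:
                out.append(int(cell) if col == "replicate" else float(cell))
            except ValueError:
                raise PanelParseError(
                    f"{path}: non-numeric value {cell!r} at row {i + 2}, column {col!r}"
                ) from None
        parsed[col] = out
    df = pd.DataFrame(parsed, columns=["treatment", "replicate", *schema.indicators])
    return IndicatorPanel(df, schema)


def write_panel(panel: IndicatorPanel, path: str | Path) -> None:
    """Write a panel CSV (comma-separated, LF endings, 12 significant digits)."""
    panel.data.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_composite(path: str | Path) -> CompositeDataset:
    """Read a composite-score CSV (``treatment,replicate,<4 systems>``)."""
    df = pd.read_csv(path)
    df["replicate"] = df["replicate"].astype(int)
    return CompositeDataset(df[["treatment", "replicate", *SYSTEMS]])


def write_composite(dataset: CompositeDataset, path: str | Path) -> None:
    dataset.data.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


# --------------------------------------------------------------------------
# fixtures


def _fixture_path(name: str):
    return resources.files("saltlax.fixtures").joinpath(name)


def load_fixture(name: str):
    """Load a packaged reference table.

    Parameters
    ----------
    name : one of ``table1`` (photosynthetic means +/- SD), ``table2``
        (metabolite means +/- SD), ``table3`` (per-treatment CRITIC weights,
        percent), ``table4`` (:class:`CompositeDataset`, 30 rows) or
        ``standard_curves`` (list of :class:`StandardCurve`).
    """
    if name not in _FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; valid names: {list(_FIXTURE_NAMES)}")
    if name == "standard_curves":
        with _fixture_path("standard_curves.json").open("r", encoding="utf-8") as fh:
            records = json.load(fh)
        return [StandardCurve(**rec) for rec in records]
    with _fixture_path(f"{name}.csv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    if name == "table4":
        df["replicate"] = df["replicate"].astype(int)
        return CompositeDataset(df)
    if name == "table3":
        return df.set_index("indicator")
    return df
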