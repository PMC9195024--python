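"""Measurement uncertainty budgets and dose-ratio evaluation.

Budgets are flat lists of named percent components with GUM type labels
(A: statistical, B: judgment/literature). All components are combined in
plain quadrature regardless of type (uncorrelated, GUM-style), scaled by
the coverage factor k. Measured dose ratios are ratios of reading-set
means; their combined relative uncertainty is the quadrature of the two
sides' combined budget percentages and standard errors of the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UncertaintyBudget",
    "ReadingSet",
    "DoseRatioResult",
    "combine_budget",
    "measured_ratio",
    "comparison_report",
    "markus_ic_budget",
    "film_budget_co60",
    "film_budget_linac",
]


@dataclass(frozen=True)
class UncertaintyBudget:
    """Named percent uncertainty components with A/B type labels."""

    components: tuple[tuple[str, float, str], ...]
    context: str = ""

    def __post_init__(self) -> None:
        labels = [c[0] for c in self.components]
        if len(set(labels)) != len(labels):
            raise ValueError("budget component labels must be unique")
        for label, pct, typ in self.components:
            if pct < 0:
                raise ValueError(f"negative percent for component {label!r}")
            if typ not in ("A", "B"):
                raise ValueError(f"component {label!r}: type must be 'A' or 'B'")

    @classmethod
    def from_pairs(cls, pairs: Iterable, context: str = "") -> "UncertaintyBudget":
        return cls(tuple((str(l), float(p), str(t)) for l, p, t in pairs), context)

    @classmethod
    def from_csv(cls, path, context: str = "") -> "UncertaintyBudget":
        """Read a `label, percent, type` CSV (header optional)."""
        df = pd.read_csv(path, header=None, names=["label", "percent", "type"], comment="#")
        if str(df.iloc[0]["label"]).strip().lower() == "label":
            df = df.iloc[1:]
        return cls.from_pairs(
            zip(df["label"].str.strip(), df["percent"].astype(float), df["type"].str.strip()),
            context,
        )

    def combined(self, k: float = 1.0) -> float:
        return combine_budget(self, k)


def combine_budget(budget: UncertaintyBudget, k: float = 1.0) -> float:
    """Combined uncertainty (percent) at coverage factor k.

    k * sqrt(sum of squared component percents); the unrounded value is
    returned — round to 2 decimals for display.
    """
    if k <= 0:
        raise ValueError("coverage factor k must be positive")
    return k * math.sqrt(sum(p * p for _, p, _ in budget.components))


@dataclass(frozen=True)
class ReadingSet:
    """Repeated dosimeter readings for one setup configuration."""

    values: tuple[float, ...]
    configuration: str = ""

    def __post_init__(self) -> None:
        if len(self.values) < 1:
            raise ValueError("need at least one reading")
        if any(v <= 0 for v in self.values):
            raise ValueError("readings must be positive")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    def sem_relative(self) -> float:
        """Relative standard error of the mean (0 for a single reading)."""
        if self.n < 2:
            return 0.0
        return float(np.std(self.values, ddof=1) / math.sqrt(self.n) / self.mean)


@dataclass(frozen=True)
class DoseRatioResult:
    """A measured dose ratio with absolute combined uncertainty at k=1."""

    ratio: float
    u_k1: float
    method: str = ""
    depth: float = float("nan")
    material: str = ""
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")
        if self.u_k1 < 0:
            raise ValueError("u_k1 must be non-negative")

    def __str__(self) -> str:  # "0.950 +- 0.028" style
        return f"{self.ratio:.3f} ± {self.u_k1:.3f}"


def measured_ratio(
    numerator: ReadingSet,
    denominator: ReadingSet,
    budget_num: UncertaintyBudget,
    budget_den: UncertaintyBudget,
    method: str = "",
    depth: float = float("nan"),
    material: str = "",
) -> DoseRatioResult:
    """Ratio of reading-set means with propagated combined uncertainty.

    Each side's combined relative uncertainty is the quadrature of its
    budget (k=1, relative) and the standard error of its mean (included
    only for n > 1); the ratio's u_k1 is the ratio times the quadrature of
    the two sides.
    """
    if denominator.mean == 0:
        raise ZeroDivisionError("denominator readings have zero mean")
    ratio = numerator.mean / denominator.mean
    c_num = math.hypot(combine_budget(budget_num) / 100.0, numerator.sem_relative())
    c_den = math.hypot(combine_budget(budget_den) / 100.0, denominator.sem_relative())
    u = ratio * math.hypot(c_num, c_den)
    return DoseRatioResult(ratio=ratio, u_k1=u, method=method, depth=depth, material=material)


def comparison_report(entries: Sequence[DoseRatioResult]) -> pd.DataFrame:
    """Tabulate dose-ratio results by (depth, method, material).

    Returns a DataFrame with one row per entry (columns: depth_cm, method,
    material, ratio, u_k1, plus any ``extra`` columns such as external
    TPS/MC values). Duplicate (depth, method, material) keys raise.
    Round-trips losslessly through CSV.
    """
    keys = [(e.depth, e.method, e.material) for e in entries]
    if len(set(keys)) != len(keys):
        dupes = {k for k in keys if keys.count(k) > 1}
        raise ValueError(f"duplicate (depth, method, material) entries: {sorted(dupes)}")
    rows = []
    for e in entries:
        row = {
            "depth_cm": e.depth,
            "method": e.method,
            "material": e.material,
            "ratio": e.ratio,
            "u_k1": e.u_k1,
        }
        row.update(e.extra)
        rows.append(row)
    return pd.DataFrame(rows)


def format_report(df: pd.DataFrame) -> str:
    """Human-readable fixed-width rendering of a comparison report."""
    out = df.copy()
    out["value"] = [
        f"{r:.3f} ± {u:.3f}" for r, u in zip(df["ratio"], df["u_k1"])
    ]
    cols = ["depth_cm", "method", "material", "value"] + [
        c for c in df.columns if c not in ("depth_cm", "method", "material", "ratio", "u_k1")
    ]
    return out[cols].to_string(index=False)


# ---------------------------------------------------------------------------
# bundled budgets (ionization chamber and radiochromic film)

_SETUP_COMPONENTS = [
    ("Front-pointer setting", 0.03, "A"),
    ("Field size setting", 0.02, "A"),
    ("Depth setting (drilling accuracy)", 0.17, "A"),
    ("Temperature and pressure variation", 0.01, "A"),
    ("Humidity change", 0.05, "A"),
    ("Silicone slab thickness variation (sag)", 0.26, "A"),
    ("Shutter error", 0.00, "A"),
]

_IC_COMPONENTS = [
    ("N_D,w calibration", 0.50, "A"),
    ("Ionization chamber stability", 0.00, "A"),
    ("Leakage current", 0.05, "A"),
    ("Solid water phantom material variability", 0.70, "B"),
]


def markus_ic_budget() -> UncertaintyBudget:
    """Parallel-plate ionization chamber reading budget (all beams).

    Quadrature combination: 0.92% at k=1, 1.84% at k=2 (2-decimal display).
    """
    return UncertaintyBudget.from_pairs(_SETUP_COMPONENTS + _IC_COMPONENTS, context="Markus IC")


_FILM_CO60 = [
    ("Scanner uniformity", 0.28, "B"),
    ("Lateral correction", 1.00, "A"),
    ("Calibration curve fitting", 0.50, "A"),
    ("Intra-batch variations", 0.28, "A"),
    ("Background", 0.50, "A"),
    ("Energy dependence", 0.50, "B"),
    ("Angular dependence", 0.50, "B"),
    ("Intrinsic film homogeneity", 1.10, "B"),
]

_FILM_LINAC = [
    ("Scanner uniformity", 0.28, "B"),
    ("Lateral correction", 0.00, "A"),
    ("Calibration curve fitting", 0.30, "A"),
    ("Intra-batch variations", 0.28, "A"),
    ("Background", 0.00, "A"),
    ("Energy dependence", 0.00, "B"),
    ("Angular dependence", 0.00, "B"),
    ("Intrinsic film homogeneity", 0.60, "B"),
]


def film_budget_co60() -> UncertaintyBudget:
    """EBT3 film net-optical-density budget for the Co-60 beam (~2.05% k=1)."""
    return UncertaintyBudget.from_pairs(
        _SETUP_COMPONENTS + _IC_COMPONENTS + _FILM_CO60, context="EBT3 film, Co-60"
    )


def film_budget_linac() -> UncertaintyBudget:
    """EBT3 film budget for 6 MV / 6 MeV linac beams (~1.09% k=1)."""
    linac_setup = [
        (l, 0.00 if l in ("Temperature and pressure variation", "Humidity change") else p, t)
        for l, p, t in _SETUP_COMPONENTS
    ]
    linac_ic = [(l, 0.00 if l == "N_D,w calibration" else p, t) for l, p, t in _IC_COMPONENTS]
    return UncertaintyBudget.from_pairs(
        linac_setup + linac_ic + _FILM_LINAC, context="EBT3 film, linac"
    )
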