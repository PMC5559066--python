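"""Fossil calibrations: lognormal prior parameterization and range extension.

A node-age calibration is a shifted lognormal prior on the age of a
clade's MRCA: ``age ~ c + LogNormal(meanlog=0, sdlog=sigma)``, where the
offset ``c`` (My) places the distribution so that a chosen low quantile
of the prior equals the hard minimum age from the fossil record. With
the anchor quantile at q = 0.05,

    c = min_age - exp(z_q * sigma),      z_q = Phi^{-1}(0.05) = -1.6449

so that 95% of the prior mass lies above the oldest secure fossil.

The module also implements the classical distribution-free stratigraphic
range extension: given H fossil horizons spanning an observed range of
R My, the one-sided confidence-C upper extension of the true range is
``alpha * R`` with ``alpha = (1 - C)^(-1/(H-1)) - 1``.
"""

from __future__ import annotations

import importlib.resources
import io
import math
import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import norm

__all__ = [
    "FossilCalibration",
    "StratRange",
    "offset_for_min_age",
    "prior_quantile",
    "marshall_extension",
    "load_calibration_table",
    "fill_offsets",
    "reference_calibrations",
    "DEFAULT_ANCHOR_QUANTILE",
]

#: anchor quantile linking the offset to the minimum age
DEFAULT_ANCHOR_QUANTILE = 0.05


class NegativeOffsetWarning(UserWarning):
    """The computed offset is below zero (nonsensical as an age)."""


@dataclass(frozen=True)
class FossilCalibration:
    """One row of a calibration table.

    Parameters are in My except ``sdlog`` (dimensionless, log-space).
    The log-mean is fixed at 0, so the prior median age is ``offset + 1``.
    """

    name: str
    min_age: float
    sdlog: float
    max_age: float | None = None
    offset: float | None = None

    def __post_init__(self):
        if self.min_age <= 0:
            raise ValueError(f"{self.name}: min_age must be positive")
        if self.sdlog is not None and self.sdlog < 0:
            raise ValueError(f"{self.name}: sdlog must be non-negative")
        if self.max_age is not None and self.max_age <= self.min_age:
            raise ValueError(f"{self.name}: max_age must exceed min_age")


@dataclass(frozen=True)
class StratRange:
    """A stratigraphic record: H horizons over an observed range R (My)."""

    horizons: int
    observed_range: float
    confidence: float = 0.95

    def __post_init__(self):
        if self.horizons < 2:
            raise ValueError("at least 2 fossil horizons are required")
        if self.observed_range <= 0:
            raise ValueError("observed range must be positive")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must lie in (0, 1)")


def offset_for_min_age(min_age: float, sdlog: float,
                       q: float = DEFAULT_ANCHOR_QUANTILE) -> float:
    """Offset c such that the q-quantile of c + LogNormal(0, sdlog) is min_age.

    With the default q = 0.05 the minimum age bounds 95% of the prior
    mass from below. A negative result (possible for large sdlog) is
    returned as-is with a :class:`NegativeOffsetWarning`.
    """
    if min_age <= 0:
        raise ValueError("min_age must be positive")
    if sdlog < 0:
        raise ValueError("sdlog must be non-negative")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    c = min_age - math.exp(norm.ppf(q) * sdlog)
    if c < 0:
        warnings.warn(
            f"computed offset {c:.4g} is negative (min_age={min_age}, sdlog={sdlog})",
            NegativeOffsetWarning,
            stacklevel=2,
        )
    return c


def prior_quantile(cal: FossilCalibration, p: float) -> float:
    """The p-quantile (in My) of the calibration's shifted lognormal prior."""
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    if cal.offset is None:
        raise ValueError(f"{cal.name}: calibration has no offset")
    return cal.offset + math.exp(norm.ppf(p) * cal.sdlog)


def marshall_extension(srange: StratRange) -> float:
    """Distribution-free confidence extension of a stratigraphic range.

    extension = alpha * R with alpha = (1-C)^(-1/(H-1)) - 1. Strictly
    decreasing in the number of horizons H and increasing in C.
    """
    h, r, c = srange.horizons, srange.observed_range, srange.confidence
    alpha = (1.0 - c) ** (-1.0 / (h - 1)) - 1.0
    return alpha * r


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

_COLUMNS = ["node_id", "taxon", "min_age", "max_age", "log_stdev", "offset"]


def load_calibration_table(source) -> pd.DataFrame:
    """Read a calibration TSV (node_id, taxon, min_age, max_age, log_stdev,
    offset); max_age and offset may be blank."""
    df = pd.read_csv(source, sep="\t")
    missing = [c for c in _COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"calibration table lacks columns: {missing}")
    for c in _COLUMNS[2:]:
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="coerce")
    return df


def fill_offsets(table: pd.DataFrame, q: float = DEFAULT_ANCHOR_QUANTILE) -> pd.DataFrame:
    """Recompute offsets for every row and report residuals.

    Returns a copy with ``offset_computed`` and, where the table already
    carried an offset, ``offset_residual = offset - offset_computed``.
    Rows without a log_stdev are left untouched.
    """
    out = table.copy()
    computed = []
    for _, row in out.iterrows():
        sd = row.get("log_stdev")
        if pd.isna(sd):
            computed.append(float("nan"))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NegativeOffsetWarning)
            computed.append(offset_for_min_age(float(row["min_age"]), float(sd), q=q))
    out["offset_computed"] = computed
    if "offset" in out.columns:
        out["offset_residual"] = out["offset"] - out["offset_computed"]
    return out


def reference_calibrations() -> pd.DataFrame:
    """The packaged 28-row muroid calibration table (My)."""
    data = importlib.resources.files("murodiv").joinpath(
        "data/muroid_calibrations.tsv").read_text()
    return load_calibration_table(io.StringIO(data))
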