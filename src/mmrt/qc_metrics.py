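"""Method-validation statistics: linearity, detection limit, reproducibility.

Also ships the 33-standard validation table of the mixed-mode LC-MS method
(LOD, CV, linear range, R², mass error per metabolite standard) as packaged
data, with summary counts recomputed from the table rather than hard-coded.
The instrument-measured values themselves are fixture data; nothing here
re-derives them from raw chromatograms.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationSeries",
    "Table1Row",
    "linearity_r2",
    "llod",
    "cv_percent",
    "coverage_percent",
    "load_table1",
    "table1_summaries",
]


def coverage_percent(n_retained: int, n_total: int) -> float:
    """Percentage of a standards library retained by the method, one decimal
    (398 of 607 -> 65.6)."""
    if n_total <= 0 or n_retained < 0 or n_retained > n_total:
        raise ValueError("need 0 <= n_retained <= n_total with n_total > 0")
    return round(100.0 * n_retained / n_total, 1)

logger = logging.getLogger(__name__)

_TABLE1_SHA256 = "af66d795eaa69e1950016d112b3129ea77f29729db31848f0f930ec310ac54a4"
_TABLE1_ROWS = 33


@dataclass(frozen=True)
class CalibrationSeries:
    """One replicate of a standard curve: injected amounts (pmole, strictly
    increasing) against detector responses (peak areas)."""

    amounts: tuple[float, ...]
    responses: tuple[float, ...]
    replicate: int = 0

    def __post_init__(self):
        if len(self.amounts) != len(self.responses) or len(self.amounts) < 3:
            raise ValueError("need >= 3 paired (amount, response) points")
        if not all(b > a for a, b in zip(self.amounts, self.amounts[1:])):
            raise ValueError("amounts must be strictly increasing")


@dataclass(frozen=True)
class Table1Row:
    metabolite: str
    lod_pmole: float
    cv_percent: float
    linear_range_pmole: str
    r_squared: float
    mass_error_ppm: float


def linearity_r2(series: CalibrationSeries) -> float:
    """R² of the ordinary least-squares fit of response against amount
    (squared Pearson correlation, as standard for calibration linearity)."""
    x = np.asarray(series.amounts, dtype=float)
    y = np.asarray(series.responses, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in calibration series")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def llod(amounts, signal_to_noise) -> float:
    """Lower limit of detection: the smallest amount whose signal-to-noise
    ratio is >= 3 in every replicate.

    ``signal_to_noise`` is (n_levels, n_replicates); returns ``math.inf`` when
    no level qualifies.
    """
    amounts = np.asarray(amounts, dtype=float)
    sn = np.atleast_2d(np.asarray(signal_to_noise, dtype=float))
    if sn.shape[0] != amounts.size:
        raise ValueError("one S:N row per amount level required")
    ok = np.all(sn >= 3.0, axis=1)
    order = np.argsort(amounts)
    for idx in order:
        if ok[idx]:
            return float(amounts[idx])
    return math.inf


def cv_percent(values) -> float:
    """Coefficient of variation: sample standard deviation over mean, in %."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(v.std(ddof=1) / mean * 100.0)


def _clean_numeric(raw: str, column: str, metabolite: str) -> float:
    """Parse a numeric cell, stripping stray non-numeric prefixes (the
    printed table contains one 'z12.4' typo)."""
    try:
        return float(raw)
    except ValueError:
        stripped = raw.lstrip("".join(c for c in raw if not (c.isdigit() or c in ".-")))
        value = float(stripped)
        logger.info(
            "cleaned %s=%r -> %s for %s at load time", column, raw, value, metabolite
        )
        return value


def load_table1(verify: bool = True) -> list[Table1Row]:
    """Load the packaged 33-row method-validation table.

    The raw CSV is checksummed; a mismatch means the fixture was altered and
    raises rather than silently summarizing different data.
    """
    raw = resources.files("mmrt").joinpath("data/table1.csv").read_bytes()
    if verify and hashlib.sha256(raw).hexdigest() != _TABLE1_SHA256:
        raise ValueError("table1.csv fixture failed its integrity check")
    df = pd.read_csv(pd.io.common.BytesIO(raw), dtype=str)
    rows = [
        Table1Row(
            metabolite=r.metabolite,
            lod_pmole=float(r.lod_pmole),
            cv_percent=_clean_numeric(r.cv_percent, "cv_percent", r.metabolite),
            linear_range_pmole=r.linear_range_pmole,
            r_squared=float(r.r_squared),
            mass_error_ppm=float(r.mass_error_ppm),
        )
        for r in df.itertuples()
    ]
    if len(rows) != _TABLE1_ROWS:
        raise ValueError(f"expected {_TABLE1_ROWS} rows, found {len(rows)}")
    return rows


def table1_summaries(
    rows: list[Table1Row] | None = None,
    r2_thresholds: tuple[float, ...] = (0.98, 0.96),
    lod_threshold_pmole: float = 1.0,
) -> dict[str, float]:
    """Summary counts and medians over the validation table.

    Medians use the midpoint element for odd n (mean of the central pair for
    even n), i.e. the ordinary sample median.
    """
    if rows is None:
        rows = load_table1()
    r2 = np.array([r.r_squared for r in rows])
    lod = np.array([r.lod_pmole for r in rows])
    cv = np.array([r.cv_percent for r in rows])
    mass = np.array([r.mass_error_ppm for r in rows])
    out: dict[str, float] = {"n_rows": len(rows)}
    for thr in r2_thresholds:
        out[f"n_r2_above_{thr}"] = int((r2 > thr).sum())
    out[f"n_lod_below_{lod_threshold_pmole}_pmole"] = int((lod < lod_threshold_pmole).sum())
    out["median_cv_percent"] = float(np.median(cv))
    out["median_abs_mass_error_ppm"] = float(np.median(np.abs(mass)))
    return out
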