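"""Derivation of strata-specific median TG:VLDL-C factor tables.

Given a cohort with directly measured LDL-C, VLDL-C follows from the
subtraction identity VLDL-C = (TC - HDL-C) - LDL-C, and the adjustable
factor for a stratum is the median TG:VLDL-C ratio of the subjects falling
in it.  Subjects with TG at or above the validity ceiling are excluded
before derivation; subjects whose computed VLDL-C is not positive cannot
contribute a ratio and are dropped from the ratio computation only (with a
logged count).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core import (
    DEFAULT_TG_MAX,
    FactorTable,
    LipidPanel,
    band_labels,
    compute_derived,
    logger,
)

#: TG band interior edges of the published 5x(1|5) tables, mg/dL.
DEFAULT_TG_EDGES = (50.0, 100.0, 150.0, 200.0)
#: non-HDL-C band interior edges of the published 25-cell table, mg/dL.
DEFAULT_NONHDL_EDGES = (100.0, 130.0, 160.0, 190.0)


def load_five_cell_table() -> FactorTable:
    """The published TG-only 5-cell median TG:VLDL-C table (2 d.p.)."""
    with resources.files("ldlkit.data").joinpath("five_cell.json").open() as fh:
        return FactorTable.from_json(fh.read())


def load_twentyfive_cell_table() -> FactorTable:
    """The published TG x non-HDL-C 25-cell median TG:VLDL-C table (1 d.p.)."""
    with resources.files("ldlkit.data").joinpath("twentyfive_cell.json").open() as fh:
        return FactorTable.from_json(fh.read())


def assign_stratum(value: float, edges: Sequence[float]) -> int:
    """Index of the half-open band [edges[i-1], edges[i]) containing ``value``.

    Band 0 is everything below the first edge; the last band is open-ended
    above.  A value equal to an edge belongs to the upper band.
    """
    if value < 0:
        raise ValueError(f"value must be >= 0, got {value}")
    return int(np.searchsorted(np.asarray(edges, dtype=float), value, side="right"))


def _ratio_arrays(
    cohort: Iterable[LipidPanel], tg_max: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(tg, non_hdl, tg:vldl ratio) for eligible subjects; drops vldl <= 0."""
    tgs: list[float] = []
    nonhdls: list[float] = []
    ratios: list[float] = []
    n_high_tg = 0
    n_nonpos_vldl = 0
    n_missing = 0
    for p in cohort:
        if p.ldl_direct is None:
            n_missing += 1
            continue
        if p.tg >= tg_max:
            n_high_tg += 1
            continue
        d = compute_derived(p)
        if d.tg_vldl_ratio is None:
            n_nonpos_vldl += 1
            continue
        tgs.append(p.tg)
        nonhdls.append(d.non_hdl)
        ratios.append(d.tg_vldl_ratio)
    if n_missing:
        raise ValueError(
            f"{n_missing} subjects lack directly measured LDL-C; table "
            "derivation requires it"
        )
    if n_high_tg:
        logger.info("excluded %d subjects with TG >= %g mg/dL", n_high_tg, tg_max)
    if n_nonpos_vldl:
        logger.info(
            "dropped %d subjects with non-positive computed VLDL-C (or TG = 0) "
            "from ratio computation",
            n_nonpos_vldl,
        )
    return np.asarray(tgs), np.asarray(nonhdls), np.asarray(ratios)


def derive_ratio_table(
    cohort: Sequence[LipidPanel],
    tg_edges: Sequence[float] = DEFAULT_TG_EDGES,
    nonhdl_edges: Sequence[float] = (),
    tg_max: float = DEFAULT_TG_MAX,
    label: str | None = None,
) -> FactorTable:
    """Derive a median TG:VLDL-C factor table from a cohort.

    Each cell holds the median ratio of its subjects; cells with no
    eligible subject hold NaN and refuse lookups.  The cohort must carry
    ``ldl_direct``; TG >= ``tg_max`` subjects are excluded first.
    """
    if len(cohort) == 0:
        raise ValueError("cannot derive a factor table from an empty cohort")
    tgs, nonhdls, ratios = _ratio_arrays(cohort, tg_max)
    n_rows = len(tg_edges) + 1
    n_cols = len(nonhdl_edges) + 1
    mat = np.full((n_rows, n_cols), math.nan)
    if ratios.size:
        row_idx = np.searchsorted(np.asarray(tg_edges, float), tgs, side="right")
        col_idx = np.searchsorted(np.asarray(nonhdl_edges, float), nonhdls, side="right")
        for i in range(n_rows):
            for j in range(n_cols):
                cell = ratios[(row_idx == i) & (col_idx == j)]
                if cell.size:
                    mat[i, j] = float(np.median(cell))
    if np.isnan(mat).all():
        raise ValueError("no stratum received any eligible subject")
    if label is None:
        label = f"{n_rows * n_cols}-cell (derived)"
    return FactorTable(
        tg_edges=tuple(float(e) for e in tg_edges),
        nonhdl_edges=tuple(float(e) for e in nonhdl_edges),
        factors=tuple(tuple(float(x) for x in row) for row in mat),
        label=label,
        tg_max=float(tg_max),
    )


@dataclass(frozen=True)
class StratumSummary:
    """Per-TG-band ratio summary mirroring the published 5-cell table rows."""

    tg_band: str
    tg_lo: float
    tg_hi: float
    n: int
    median_ratio: float | None
    median_ci: tuple[float, float] | None
    median_ci_coverage: float | None  # achieved coverage of the order-stat CI
    ratio_range: tuple[float, float] | None
    mean_vldl_tg: float | None
    sd_vldl_tg: float | None


def median_ci_order_statistic(
    values: Sequence[float], level: float = 0.95
) -> tuple[tuple[float, float], float]:
    """Distribution-free CI for the median from order statistics.

    Picks the widest symmetric pair of order statistics (x_(l), x_(n+1-l))
    whose exact binomial coverage sum_{k=l}^{n-l} C(n,k)/2^n is at least
    ``level``; returns the interval and its achieved coverage.  For n = 1
    the interval degenerates to the single observation with coverage 0.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("median CI of an empty sample")
    if n == 1:
        return (float(x[0]), float(x[0])), 0.0
    cdf = stats.binom.cdf(np.arange(n + 1), n, 0.5)
    best_l = 1
    for l in range(1, n // 2 + 1):
        coverage = cdf[n - l] - cdf[l - 1]
        if coverage >= level:
            best_l = l
        else:
            break
    coverage = float(cdf[n - best_l] - cdf[best_l - 1])
    return (float(x[best_l - 1]), float(x[n - best_l])), coverage


def stratum_summaries(
    cohort: Sequence[LipidPanel],
    tg_edges: Sequence[float] = DEFAULT_TG_EDGES,
    tg_max: float = DEFAULT_TG_MAX,
) -> list[StratumSummary]:
    """Per-TG-band n, median TG:VLDL-C with 95% CI, mean/SD of VLDL-C:TG."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    tgs, _, ratios = _ratio_arrays(cohort, tg_max)
    labels = band_labels(tg_edges, upper_cap=tg_max)
    edges_arr = np.asarray(tg_edges, dtype=float)
    row_idx = np.searchsorted(edges_arr, tgs, side="right")
    bounds = [0.0, *edges_arr, tg_max]
    out: list[StratumSummary] = []
    for i, lab in enumerate(labels):
        cell = ratios[row_idx == i]
        if cell.size == 0:
            out.append(
                StratumSummary(lab, bounds[i], bounds[i + 1], 0, None, None, None,
                               None, None, None)
            )
            continue
        ci, coverage = median_ci_order_statistic(cell)
        inv = 1.0 / cell  # VLDL-C:TG ratios of the same subjects
        out.append(
            StratumSummary(
                tg_band=lab,
                tg_lo=bounds[i],
                tg_hi=bounds[i + 1],
                n=int(cell.size),
                median_ratio=float(np.median(cell)),
                median_ci=ci,
                median_ci_coverage=coverage,
                ratio_range=(float(cell.min()), float(cell.max())),
                mean_vldl_tg=float(inv.mean()),
                sd_vldl_tg=float(inv.std(ddof=1)) if cell.size > 1 else 0.0,
            )
        )
    return out
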