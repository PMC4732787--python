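"""Domain types and LDL-C estimators.

All concentrations are in mg/dL throughout the package; no unit conversion
is performed anywhere.

The estimators all share one algebraic form

    LDL-C = non-HDL-C - TG / factor

where non-HDL-C = TC - HDL-C and the factor approximates the TG:VLDL-C
ratio.  The Friedewald equation fixes the factor at 5; the McNamara
variant switches between 4, 4.5 and 5 by triglyceride level; the
adjustable-factor (Martin-style) method looks the factor up in a table of
strata-specific median TG:VLDL-C ratios indexed by triglycerides and,
optionally, non-HDL-C.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

logger = logging.getLogger("ldlkit")

#: Validity ceiling of the TG/factor family of estimators, mg/dL.
DEFAULT_TG_MAX = 400.0

Sex = Literal["male", "female", "unknown"]


class OutOfValidityError(ValueError):
    """Raised when an input lies outside an estimator's validity domain."""


@dataclass(frozen=True)
class LipidPanel:
    """One subject's measured lipid values (mg/dL) plus demographics.

    ``ldl_direct`` is the directly (chemically) measured LDL-C; it is
    optional because estimation does not need it, only derivation and
    validation do.
    """

    subject_id: str
    age: int
    sex: Sex
    tc: float
    hdl: float
    tg: float
    ldl_direct: float | None = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be >= 0, got {self.age}")
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"sex must be male/female/unknown, got {self.sex!r}")
        if not (self.tc > 0):
            raise ValueError(f"tc must be > 0, got {self.tc}")
        if not (self.hdl > 0):
            raise ValueError(f"hdl must be > 0, got {self.hdl}")
        if not (self.tg >= 0):
            raise ValueError(f"tg must be >= 0, got {self.tg}")
        if self.tc < self.hdl:
            raise ValueError(f"tc >= hdl violated: tc={self.tc}, hdl={self.hdl}")
        if self.ldl_direct is not None and not (self.ldl_direct >= 0):
            raise ValueError(f"ldl_direct must be >= 0, got {self.ldl_direct}")

    @property
    def non_hdl(self) -> float:
        return self.tc - self.hdl


@dataclass(frozen=True)
class DerivedLipids:
    """Quantities derived from a panel by exact subtraction identities.

    ``non_hdl = tc - hdl``; ``vldl = non_hdl - ldl_direct`` (so that
    ``tc = hdl + ldl_direct + vldl`` exactly).  Ratio fields are ``None``
    (absent, never zero) whenever their denominator is not positive or
    ``ldl_direct`` is missing.
    """

    non_hdl: float
    vldl: float | None = None
    tg_vldl_ratio: float | None = None
    vldl_tg_ratio: float | None = None


def compute_derived(panel: LipidPanel) -> DerivedLipids:
    """Compute non-HDL-C, VLDL-C and the TG/VLDL-C ratios for one panel."""
    non_hdl = panel.tc - panel.hdl
    if panel.ldl_direct is None:
        return DerivedLipids(non_hdl=non_hdl)
    vldl = non_hdl - panel.ldl_direct
    tg_vldl = panel.tg / vldl if vldl > 0 else None
    vldl_tg = vldl / panel.tg if panel.tg > 0 else None
    return DerivedLipids(
        non_hdl=non_hdl, vldl=vldl, tg_vldl_ratio=tg_vldl, vldl_tg_ratio=vldl_tg
    )


@dataclass(frozen=True)
class LdlEstimate:
    """An LDL-C estimate: method tag, value (mg/dL) and the divisor used.

    ``value`` may be negative for extreme panels; it is never clipped.
    ``value == non_hdl - tg / factor_used`` holds exactly, equivalently
    ``tc == hdl + value + tg / factor_used``.
    """

    method: str
    value: float
    factor_used: float

    @property
    def is_negative(self) -> bool:
        """Flag for estimates below zero (classification treats them as '<70')."""
        return self.value < 0


def _check_tg(tg: float, tg_max: float) -> None:
    if tg >= tg_max:
        raise OutOfValidityError(
            f"triglycerides {tg:g} mg/dL are outside the estimator's validity "
            f"range (subjects with triglyceride levels of {tg_max:g} mg/dL and "
            "higher are excluded)"
        )


def ldl_friedewald(panel: LipidPanel, tg_max: float = DEFAULT_TG_MAX) -> LdlEstimate:
    """Friedewald estimate: non-HDL-C - TG/5, valid for TG < ``tg_max``."""
    _check_tg(panel.tg, tg_max)
    return LdlEstimate(
        method="friedewald", value=panel.non_hdl - panel.tg / 5.0, factor_used=5.0
    )


def ldl_fixed_factor(
    panel: LipidPanel, factor: float, tg_max: float = DEFAULT_TG_MAX
) -> LdlEstimate:
    """Fixed-factor estimate non-HDL-C - TG/``factor`` (e.g. 4, 5 or 6)."""
    if not (factor > 0) or not math.isfinite(factor):
        raise ValueError(f"factor must be a positive finite number, got {factor}")
    _check_tg(panel.tg, tg_max)
    return LdlEstimate(
        method="fixed", value=panel.non_hdl - panel.tg / factor, factor_used=factor
    )


# TG-dependent fixed factors: 4 for TG <= 50, 4.5 for (50, 200], 5 above.
_MCNAMARA_BOUNDS = ((50.0, 4.0), (200.0, 4.5), (math.inf, 5.0))


def ldl_mcnamara(panel: LipidPanel, tg_max: float = DEFAULT_TG_MAX) -> LdlEstimate:
    """McNamara-style estimate: factor 4 / 4.5 / 5 switched by TG level."""
    _check_tg(panel.tg, tg_max)
    for upper, factor in _MCNAMARA_BOUNDS:
        if panel.tg <= upper:
            break
    return LdlEstimate(
        method="mcnamara", value=panel.non_hdl - panel.tg / factor, factor_used=factor
    )


@dataclass(frozen=True)
class FactorTable:
    """Strata-specific adjustable-factor table.

    ``tg_edges`` / ``nonhdl_edges`` are the ascending *interior* boundaries
    of half-open bins over triglycerides and non-HDL-C ("50 to 99" means
    [50, 100)); an empty ``nonhdl_edges`` makes the table TG-only (one
    column).  ``factors`` has shape (len(tg_edges)+1, len(nonhdl_edges)+1);
    a NaN cell marks a stratum with no data, where lookups are refused.
    """

    tg_edges: tuple[float, ...]
    nonhdl_edges: tuple[float, ...]
    factors: tuple[tuple[float, ...], ...]
    label: str = ""
    tg_max: float = DEFAULT_TG_MAX

    def __post_init__(self) -> None:
        for name, edges in (("tg_edges", self.tg_edges), ("nonhdl_edges", self.nonhdl_edges)):
            if any(b <= a for a, b in zip(edges, edges[1:])):
                raise ValueError(f"{name} must be strictly increasing: {edges}")
        mat = np.asarray(self.factors, dtype=float)
        want = (len(self.tg_edges) + 1, len(self.nonhdl_edges) + 1)
        if mat.shape != want:
            raise ValueError(f"factors shape {mat.shape} != expected {want}")
        finite = mat[np.isfinite(mat)]
        if np.any(finite <= 0):
            raise ValueError("all factors must be positive")
        if np.isinf(mat).any():
            raise ValueError("factors must be finite or NaN (empty cell)")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.tg_edges) + 1, len(self.nonhdl_edges) + 1)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "label": self.label,
                "tg_edges": list(self.tg_edges),
                "nonhdl_edges": list(self.nonhdl_edges),
                "tg_max": self.tg_max,
                "factors": [
                    [None if math.isnan(v) else v for v in row] for row in self.factors
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FactorTable":
        d = json.loads(text)
        factors = tuple(
            tuple(math.nan if v is None else float(v) for v in row)
            for row in d["factors"]
        )
        return cls(
            tg_edges=tuple(float(x) for x in d["tg_edges"]),
            nonhdl_edges=tuple(float(x) for x in d["nonhdl_edges"]),
            factors=factors,
            label=d.get("label", ""),
            tg_max=float(d.get("tg_max", DEFAULT_TG_MAX)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "FactorTable":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))

    def band_labels(self, axis: Literal["tg", "nonhdl"]) -> list[str]:
        edges = self.tg_edges if axis == "tg" else self.nonhdl_edges
        upper_cap = self.tg_max if axis == "tg" else None
        return band_labels(edges, upper_cap)

    def to_csv(self) -> str:
        """Human-editable rendering: rows TG bands, columns non-HDL-C bands."""
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(
            ["# label", self.label, "tg_max", repr(self.tg_max)]
        )
        w.writerow(["TG band"] + (self.band_labels("nonhdl") if self.nonhdl_edges else ["factor"]))
        for lab, row in zip(self.band_labels("tg"), self.factors):
            w.writerow([lab] + ["" if math.isnan(v) else repr(v) for v in row])
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "FactorTable":
        rows = list(csv.reader(io.StringIO(text)))
        meta, header, body = rows[0], rows[1], rows[2:]
        label = meta[1]
        tg_max = float(meta[3])
        nonhdl_edges = _edges_from_labels(header[1:]) if header[1:] != ["factor"] else ()
        tg_edges = _edges_from_labels([r[0] for r in body])
        factors = tuple(
            tuple(math.nan if v == "" else float(v) for v in r[1:]) for r in body
        )
        return cls(
            tg_edges=tg_edges, nonhdl_edges=nonhdl_edges, factors=factors,
            label=label, tg_max=tg_max,
        )


def band_labels(edges: Sequence[float], upper_cap: float | None = None) -> list[str]:
    """Printed labels for half-open bands: '< 50', '50 to 99', ..., '>= 200'.

    Integer edges follow the convention that [50, 100) prints as "50 to 99";
    with an ``upper_cap`` the last band prints e.g. "200 to 399".
    """

    def fmt(x: float) -> str:
        return f"{x:g}"

    if not edges:
        return ["all"]
    labels = [f"< {fmt(edges[0])}"]
    for lo, hi in zip(edges, edges[1:]):
        labels.append(f"{fmt(lo)} to {fmt(hi - 1) if float(hi).is_integer() else fmt(hi)}")
    last = edges[-1]
    if upper_cap is not None:
        labels.append(
            f"{fmt(last)} to {fmt(upper_cap - 1) if float(upper_cap).is_integer() else fmt(upper_cap)}"
        )
    else:
        labels.append(f">= {fmt(last)}")
    return labels


def _edges_from_labels(labels: Sequence[str]) -> tuple[float, ...]:
    """Interior edges back from band labels (inverse of :func:`band_labels`)."""
    edges: list[float] = []
    for lab in labels[1:]:  # first label carries no lower edge info beyond edges[0]
        lab = lab.strip()
        if lab.startswith(">="):
            edges.append(float(lab[2:]))
        else:
            edges.append(float(lab.split(" to ")[0]))
    return tuple(edges)


def lookup_factor(table: FactorTable, tg: float, non_hdl: float = 0.0) -> float:
    """Adjustable factor for given TG and non-HDL-C levels.

    TG-only tables (no non-HDL-C edges) ignore ``non_hdl``.  Raises
    :class:`OutOfValidityError` for TG at or above the table's ceiling and
    ``ValueError`` when the addressed cell is empty.
    """
    if tg < 0:
        raise ValueError(f"tg must be >= 0, got {tg}")
    _check_tg(tg, table.tg_max)
    i = int(np.searchsorted(table.tg_edges, tg, side="right"))
    j = int(np.searchsorted(table.nonhdl_edges, non_hdl, side="right"))
    f = table.factors[i][j]
    if math.isnan(f):
        raise ValueError(
            f"factor table {table.label!r} has no data in cell "
            f"(tg band {i}, non-HDL band {j})"
        )
    return f


def ldl_adjustable(panel: LipidPanel, table: FactorTable) -> LdlEstimate:
    """Adjustable-factor estimate non-HDL-C - TG/AF with AF from ``table``."""
    non_hdl = panel.non_hdl
    f = lookup_factor(table, panel.tg, non_hdl)
    return LdlEstimate(
        method=f"adjustable:{table.label or 'table'}",
        value=non_hdl - panel.tg / f,
        factor_used=f,
    )
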