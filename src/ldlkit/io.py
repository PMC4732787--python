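"""Panel-file I/O and the end-to-end validation pipeline.

The panel file is UTF-8 delimited text (comma by default) with a header
row and columns ``subject_id, age, sex, tc, hdl, tg, ldl_direct`` (the
last optional).  Malformed rows are rejected individually with their line
number and reason rather than aborting the whole read.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import (
    FactorTable,
    LdlEstimate,
    LipidPanel,
    ldl_adjustable,
    ldl_fixed_factor,
    ldl_friedewald,
    ldl_mcnamara,
    logger,
)
from .evaluate import (
    concordance_report,
    difference_summary,
    mcnemar_exact,
    wilcoxon_signed_rank,
)

REQUIRED_COLUMNS = ("subject_id", "age", "sex", "tc", "hdl", "tg")
OPTIONAL_COLUMNS = ("ldl_direct",)


@dataclass(frozen=True)
class RejectedRow:
    line: int
    reason: str


def read_panels(
    path: str | Path, sep: str = ","
) -> tuple[list[LipidPanel], list[RejectedRow]]:
    """Read a panel file into panels plus a rejection log.

    Raises on a missing required column or when no row is valid; individual
    invalid rows (non-numeric, negative, tc < hdl, ...) are logged with
    their 1-based file line number and skipped.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel file {path} is missing required column(s): {missing}")
    has_direct = "ldl_direct" in df.columns
    panels: list[LipidPanel] = []
    rejected: list[RejectedRow] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            ldl_direct: float | None = None
            if has_direct and row["ldl_direct"].strip() != "":
                ldl_direct = float(row["ldl_direct"])
            panel = LipidPanel(
                subject_id=row["subject_id"],
                age=int(float(row["age"])),
                sex=row["sex"].strip().lower() or "unknown",
                tc=float(row["tc"]),
                hdl=float(row["hdl"]),
                tg=float(row["tg"]),
                ldl_direct=ldl_direct,
            )
            for name in ("tc", "hdl", "tg"):
                if not math.isfinite(getattr(panel, name)):
                    raise ValueError(f"{name} is not finite")
        except (ValueError, KeyError) as exc:
            rejected.append(RejectedRow(line=line, reason=str(exc)))
            continue
        panels.append(panel)
    if not panels:
        raise ValueError(f"panel file {path} contains no valid rows")
    if rejected:
        logger.info("rejected %d malformed rows while reading %s", len(rejected), path)
    return panels, rejected


def write_panels(panels: Sequence[LipidPanel], path: str | Path, sep: str = ",") -> None:
    df = pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in panels],
            "age": [p.age for p in panels],
            "sex": [p.sex for p in panels],
            "tc": [repr(p.tc) for p in panels],
            "hdl": [repr(p.hdl) for p in panels],
            "tg": [repr(p.tg) for p in panels],
            "ldl_direct": [
                "" if p.ldl_direct is None else repr(p.ldl_direct) for p in panels
            ],
        }
    )
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Estimator specs

def estimator_from_spec(
    spec: str, table_loader: Callable[[str], FactorTable] | None = None
) -> tuple[str, Callable[[LipidPanel], LdlEstimate]]:
    """(name, panel -> estimate) from a spec string.

    Specs: ``friedewald``, ``mcnamara``, ``fixed:<factor>`` or
    ``table:<path-to-factor-table-json>``.
    """
    if spec == "friedewald":
        return "friedewald", ldl_friedewald
    if spec == "mcnamara":
        return "mcnamara", ldl_mcnamara
    if spec.startswith("fixed:"):
        factor = float(spec.split(":", 1)[1])
        return f"fixed:{factor:g}", lambda p: ldl_fixed_factor(p, factor)
    if spec.startswith("table:"):
        ref = spec.split(":", 1)[1]
        table = (table_loader or FactorTable.load)(ref)
        name = table.label or Path(ref).stem
        return name, lambda p: ldl_adjustable(p, table)
    raise ValueError(
        f"unknown estimator spec {spec!r} (expected friedewald, mcnamara, "
        "fixed:<f> or table:<file>)"
    )


# ---------------------------------------------------------------------------
# Validation pipeline

def run_validate(
    panels: Sequence[LipidPanel],
    methods: dict[str, Callable[[LipidPanel], LdlEstimate]],
    tg_max: float = 400.0,
) -> dict:
    """Full method-comparison report for one cohort.

    Per method: difference summary, signed-rank test against direct LDL-C
    and a guideline-concordance report.  Per method pair: exact McNemar on
    the per-subject concordance indicators and a signed-rank test on the
    absolute deviations.  Panels with TG >= ``tg_max`` are excluded with a
    logged count; every remaining panel must carry direct LDL-C.
    """
    if not methods:
        raise ValueError("no estimation method specified")
    eligible = [p for p in panels if p.tg < tg_max]
    n_excluded = len(panels) - len(eligible)
    if n_excluded:
        logger.info(
            "excluded %d subjects with TG >= %g mg/dL from validation",
            n_excluded, tg_max,
        )
    if not eligible:
        raise ValueError("all subjects have TG >= tg_max; nothing to validate")
    if any(p.ldl_direct is None for p in eligible):
        raise ValueError("validation requires direct LDL-C on every panel")
    direct = np.array([p.ldl_direct for p in eligible])
    tg = np.array([p.tg for p in eligible])
    report: dict = {
        "n_total": len(panels),
        "n_excluded_tg": n_excluded,
        "n_validated": len(eligible),
        "methods": {},
        "pairwise": {},
    }
    estimates: dict[str, np.ndarray] = {}
    concordant: dict[str, np.ndarray] = {}
    for name, fn in methods.items():
        est = np.array([fn(p).value for p in eligible])
        estimates[name] = est
        conc = concordance_report(est, direct, tg)
        ec = np.searchsorted(np.array([70, 100, 130, 160, 190.0]), est, side="right")
        dc = np.searchsorted(np.array([70, 100, 130, 160, 190.0]), direct, side="right")
        concordant[name] = ec == dc
        if np.array_equal(est, direct):
            wilcoxon = None  # degenerate: estimates identical to direct
        else:
            w = wilcoxon_signed_rank(est, direct)
            wilcoxon = {
                "sp": w.sp, "sn": w.sn, "n_nonzero": w.n_nonzero,
                "p": w.p_two_sided, "exact": w.exact, "direction": w.direction,
            }
        report["methods"][name] = {
            "difference": difference_summary(est, direct),
            "wilcoxon_vs_direct": wilcoxon,
            "concordance": conc.to_dict(),
        }
    names = list(methods)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            key = f"{a} vs {b}"
            ca, cb = concordant[a], concordant[b]
            n01 = int((ca & ~cb).sum())
            n10 = int((~ca & cb).sum())
            if n01 == 0 and n10 == 0:
                mcnemar = {"n01": 0, "n10": 0, "p": 1.0, "note": "no discordant pairs"}
            else:
                mcnemar = {"n01": n01, "n10": n10, "p": mcnemar_exact(n01, n10)}
            wa = wilcoxon_signed_rank(
                np.abs(estimates[a] - direct), np.abs(estimates[b] - direct)
            )
            report["pairwise"][key] = {
                "mcnemar_concordance": mcnemar,
                "wilcoxon_abs_deviation": {
                    "sp": wa.sp, "sn": wa.sn, "n_nonzero": wa.n_nonzero,
                    "p": wa.p_two_sided, "direction": wa.direction,
                },
            }
    return report


# ---------------------------------------------------------------------------
# Report rendering

def report_to_markdown(report: dict) -> str:
    """Concordance section of a validation report as a markdown table.

    Columns mirror the published layout: one C/T and one "% (95% CI)"
    column per method, rows by estimate-defined LDL-C category (highest
    first), TG stratum and overall.
    """
    names = list(report["methods"])
    lines = []
    header = ["LDL-C / TG stratum"]
    for n in names:
        header += [f"{n} C/T", f"{n} % (95% CI)"]
    lines.append("| " + " | ".join(header) + " |")
    lines.append("|" + "---|" * len(header))

    def cells(block: dict) -> list[str]:
        if block.get("t", 0) == 0 or "pct_str" not in block:
            return [f"{block.get('c', 0)}/{block.get('t', 0)}", "-"]
        lo, hi = block["ci"]
        return [
            f"{block['c']}/{block['t']}",
            f"{block['pct_str']} ({lo:.1f}-{hi:.1f})",
        ]

    first = report["methods"][names[0]]["concordance"]
    cat_rows = list(first["by_estimate_category"])[::-1]
    for cat in cat_rows:
        n_direct = first["by_direct_category_n"][cat]
        row = [f"LDL-C {cat} (n = {n_direct})"]
        for n in names:
            row += cells(report["methods"][n]["concordance"]["by_estimate_category"][cat])
        lines.append("| " + " | ".join(row) + " |")
    for stratum in list(first["by_tg_stratum"])[::-1]:
        row = [f"TG {stratum}"]
        for n in names:
            row += cells(report["methods"][n]["concordance"]["by_tg_stratum"][stratum])
        lines.append("| " + " | ".join(row) + " |")
    row = ["Overall"]
    for n in names:
        row += cells(report["methods"][n]["concordance"]["overall"])
    lines.append("| " + " | ".join(row) + " |")
    return "\n".join(lines) + "\n"


def discordance_to_csv(report: dict) -> str:
    """Under/over-estimation counts and percentages per method, as CSV."""
    lines = ["method,under_count,under_pct,over_count,over_pct,total"]
    for name, block in report["methods"].items():
        c = block["concordance"]
        t = c["overall"]["t"]
        lines.append(
            f"{name},{c['under_count']},{c['under_pct_str']},"
            f"{c['over_count']},{c['over_pct_str']},{t}"
        )
    return "\n".join(lines) + "\n"


def save_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n", encoding="utf-8")
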