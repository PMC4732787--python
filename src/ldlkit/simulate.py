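"""Synthetic lipid-panel cohort generation.

The generator emulates the statistical structure the estimation pipeline
assumes in a fasting adult cohort: lognormal triglycerides, a VLDL-C:TG
ratio drawn per TG stratum from a truncated Normal whose mean falls as TG
rises (so a fixed divisor of 5 overestimates VLDL-C at high TG and
underestimates it at low TG), lognormal direct LDL-C, Normal HDL-C, and
total cholesterol assembled by the exact accounting identity

    TC = HDL-C + LDL-C + VLDL-C (+ assay noise, default none).

Default parameters reproduce the marginal summaries of a Korean adult
health-survey population: TG median ~106 mg/dL (IQR 71-157), direct LDL-C
median ~111 (IQR 91-133), HDL-C median ~48, per-stratum VLDL-C:TG means
0.398/0.255/0.197/0.180/0.167 with SDs 0.178/0.091/0.055/0.048/0.041, and
2.6% of subjects with TG >= 400 mg/dL.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .core import LipidPanel
from .derive import DEFAULT_TG_EDGES

#: Lower truncation of the VLDL-C:TG ratio draw; bounds TG:VLDL-C at <= 50.
RATIO_FLOOR = 0.02

#: Cholesterol values are snapped to this dyadic grid (2^-26 mg/dL, far below
#: assay resolution) so that TC = HDL + LDL + VLDL and its inverse
#: subtractions are exact in binary floating point.
GRID = 2.0 ** -26


def _snap(x: np.ndarray | float) -> np.ndarray | float:
    return np.round(np.asarray(x) / GRID) * GRID


def _lognormal_params(median: float, q25: float, q75: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given median and quartiles."""
    z75 = stats.norm.ppf(0.75)
    return math.log(median), math.log(q75 / q25) / (2.0 * z75)


_TG_MU, _TG_SIGMA = _lognormal_params(106.0, 71.0, 157.0)
_LDL_MU, _LDL_SIGMA = _lognormal_params(111.0, 91.0, 133.0)
# High-TG (>= 400) tail drawn separately: median 505, IQR 432-635.
_TG_HIGH_MU, _TG_HIGH_SIGMA = _lognormal_params(505.0, 432.0, 635.0)


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Distribution parameters and seed for cohort generation.

    ``stratum_ratio_means``/``stratum_ratio_sds`` parameterize the
    VLDL-C:TG Normal per TG band (bands defined by ``tg_edges``); the
    draw is truncated below at 0.02.  ``include_high_tg_fraction`` is the
    probability of a subject from the TG >= 400 mg/dL tail (mean VLDL-C:TG
    0.15 there).  ``assay_noise_sd`` adds Normal noise (mg/dL) to total
    cholesterol, breaking the accounting identity by that amount.
    """

    n: int = 5642
    seed: int = 0
    tg_log_mu: float = _TG_MU
    tg_log_sigma: float = _TG_SIGMA
    tg_edges: tuple[float, ...] = DEFAULT_TG_EDGES
    stratum_ratio_means: tuple[float, ...] = (0.398, 0.255, 0.197, 0.180, 0.167)
    stratum_ratio_sds: tuple[float, ...] = (0.178, 0.091, 0.055, 0.048, 0.041)
    ldl_log_mu: float = _LDL_MU
    ldl_log_sigma: float = _LDL_SIGMA
    hdl_mu: float = 48.0
    hdl_sigma: float = 10.4
    assay_noise_sd: float = 0.0
    include_high_tg_fraction: float = 0.026
    high_tg_ratio_mean: float = 0.15
    high_tg_ratio_sd: float = 0.04

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if len(self.stratum_ratio_means) != len(self.tg_edges) + 1:
            raise ValueError(
                "stratum_ratio_means must have len(tg_edges)+1 entries"
            )
        if len(self.stratum_ratio_sds) != len(self.stratum_ratio_means):
            raise ValueError("ratio means and sds must have equal length")
        for name in ("tg_log_sigma", "ldl_log_sigma", "hdl_sigma",
                     "high_tg_ratio_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(s <= 0 for s in self.stratum_ratio_sds):
            raise ValueError("stratum_ratio_sds must be positive")
        if any(m <= RATIO_FLOOR for m in self.stratum_ratio_means):
            raise ValueError(f"stratum_ratio_means must exceed {RATIO_FLOOR}")
        if not (0.0 <= self.include_high_tg_fraction <= 1.0):
            raise ValueError("include_high_tg_fraction must be in [0, 1]")
        if self.assay_noise_sd < 0:
            raise ValueError("assay_noise_sd must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticCohortConfig":
        d = json.loads(text)
        for key in ("tg_edges", "stratum_ratio_means", "stratum_ratio_sds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "SyntheticCohortConfig":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int, lower: float
) -> np.ndarray:
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def truncated_normal_median(mean: float, sd: float, lower: float = RATIO_FLOOR) -> float:
    """Median of a Normal(mean, sd) truncated below at ``lower``."""
    pa = stats.norm.cdf((lower - mean) / sd)
    return float(mean + sd * stats.norm.ppf((1.0 + pa) / 2.0))


def mean_for_truncated_median(
    target_median: float, sd: float, lower: float = RATIO_FLOOR
) -> float:
    """Normal mean whose ``lower``-truncated distribution has the given median."""
    if target_median <= lower:
        raise ValueError("target median must exceed the truncation point")
    lo, hi = lower, target_median + 10.0 * sd
    return float(brentq(
        lambda m: truncated_normal_median(m, sd, lower) - target_median, lo, hi
    ))


def config_for_band_medians(
    tg_vldl_medians: Sequence[float],
    sds: Sequence[float] | None = None,
    **kwargs,
) -> SyntheticCohortConfig:
    """Config whose per-band TG:VLDL-C ratio medians equal the targets.

    The generator draws VLDL-C:TG; the band median of TG:VLDL-C is the
    reciprocal of the truncated-Normal median, so the Normal mean is solved
    from each target (accounting for the truncation at 0.02).
    """
    defaults = SyntheticCohortConfig()
    sds = tuple(sds) if sds is not None else defaults.stratum_ratio_sds
    if len(tg_vldl_medians) != len(sds):
        raise ValueError("need one SD per band median")
    means = tuple(
        mean_for_truncated_median(1.0 / m, s) for m, s in zip(tg_vldl_medians, sds)
    )
    return SyntheticCohortConfig(
        stratum_ratio_means=means, stratum_ratio_sds=sds, **kwargs
    )


def _assemble(
    rng: np.random.Generator,
    tg: np.ndarray,
    vldl: np.ndarray,
    ldl: np.ndarray,
    hdl: np.ndarray,
    noise_sd: float,
    id_prefix: str = "S",
) -> list[LipidPanel]:
    n = tg.size
    noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    hdl = np.asarray(_snap(hdl), dtype=float)
    ldl = np.asarray(_snap(ldl), dtype=float)
    vldl = np.asarray(_snap(vldl), dtype=float)
    noise = np.asarray(_snap(noise), dtype=float)
    sexes = np.where(rng.random(n) < 0.5, "male", "female")
    ages = rng.integers(20, 88, n)
    panels = []
    for i in range(n):
        tc = hdl[i] + ldl[i] + vldl[i] + noise[i]
        panels.append(
            LipidPanel(
                subject_id=f"{id_prefix}{i:06d}",
                age=int(ages[i]),
                sex=str(sexes[i]),
                tc=float(tc),
                hdl=float(hdl[i]),
                tg=float(tg[i]),
                ldl_direct=float(ldl[i]),
            )
        )
    return panels


def generate_cohort(config: SyntheticCohortConfig) -> list[LipidPanel]:
    """Generate a cohort of lipid panels; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    if n == 0:
        return []
    high = rng.random(n) < config.include_high_tg_fraction
    tg = np.empty(n)
    tg[~high] = rng.lognormal(config.tg_log_mu, config.tg_log_sigma, (~high).sum())
    # regular draws straying above 400 are resampled into the valid range;
    # the >= 400 tail is governed solely by include_high_tg_fraction
    while np.any(tg[~high] >= 400.0):
        bad = (~high) & (tg >= 400.0)
        tg[bad] = rng.lognormal(config.tg_log_mu, config.tg_log_sigma, bad.sum())
    n_high = int(high.sum())
    if n_high:
        th = rng.lognormal(_TG_HIGH_MU, _TG_HIGH_SIGMA, n_high)
        while np.any(th < 400.0):
            th[th < 400.0] = rng.lognormal(
                _TG_HIGH_MU, _TG_HIGH_SIGMA, int((th < 400.0).sum())
            )
        tg[high] = th
    band = np.searchsorted(np.asarray(config.tg_edges), tg, side="right")
    ratio = np.empty(n)
    for b in range(len(config.stratum_ratio_means)):
        idx = (band == b) & ~high
        if idx.any():
            ratio[idx] = _truncated_normal(
                rng, config.stratum_ratio_means[b], config.stratum_ratio_sds[b],
                int(idx.sum()), RATIO_FLOOR,
            )
    if n_high:
        ratio[high] = _truncated_normal(
            rng, config.high_tg_ratio_mean, config.high_tg_ratio_sd,
            n_high, RATIO_FLOOR,
        )
    vldl = ratio * tg
    ldl = rng.lognormal(config.ldl_log_mu, config.ldl_log_sigma, n)
    hdl = rng.normal(config.hdl_mu, config.hdl_sigma, n)
    while np.any(hdl <= 5.0):  # resample implausible non-positive HDL draws
        bad = hdl <= 5.0
        hdl[bad] = rng.normal(config.hdl_mu, config.hdl_sigma, int(bad.sum()))
    return _assemble(rng, tg, vldl, ldl, hdl, config.assay_noise_sd)


def generate_stratified_cohort(
    config: SyntheticCohortConfig, n_per_band: int | Sequence[int]
) -> list[LipidPanel]:
    """Generate a cohort with fixed subject counts per TG band.

    TG is drawn from the configured lognormal truncated to each band (the
    last band capped at 400 mg/dL); everything else follows
    :func:`generate_cohort`.  No TG >= 400 tail is produced.
    """
    rng = np.random.default_rng(config.seed)
    n_bands = len(config.stratum_ratio_means)
    counts = (
        [int(n_per_band)] * n_bands
        if np.isscalar(n_per_band)
        else [int(c) for c in n_per_band]
    )
    if len(counts) != n_bands:
        raise ValueError("need one count per TG band")
    bounds = [0.0, *config.tg_edges, 400.0]
    tg_parts, ratio_parts = [], []
    for b, c in enumerate(counts):
        lo_q, hi_q = (
            stats.lognorm.cdf(
                [bounds[b], bounds[b + 1]],
                s=config.tg_log_sigma, scale=math.exp(config.tg_log_mu),
            )
        )
        u = rng.uniform(lo_q, hi_q, c)
        tg_parts.append(
            stats.lognorm.ppf(u, s=config.tg_log_sigma,
                              scale=math.exp(config.tg_log_mu))
        )
        ratio_parts.append(
            _truncated_normal(
                rng, config.stratum_ratio_means[b], config.stratum_ratio_sds[b],
                c, RATIO_FLOOR,
            )
        )
    tg = np.concatenate(tg_parts)
    ratio = np.concatenate(ratio_parts)
    n = tg.size
    vldl = ratio * tg
    ldl = rng.lognormal(config.ldl_log_mu, config.ldl_log_sigma, n)
    hdl = rng.normal(config.hdl_mu, config.hdl_sigma, n)
    hdl = np.clip(hdl, 10.0, None)
    return _assemble(rng, tg, vldl, ldl, hdl, config.assay_noise_sd, id_prefix="B")


def generate_noiseless_cohort(
    ratios: Sequence[float],
    n_per_band: int | Sequence[int],
    seed: int = 0,
    tg_edges: Sequence[float] = DEFAULT_TG_EDGES,
    tg_max: float = 400.0,
) -> list[LipidPanel]:
    """Cohort where VLDL-C = TG/ratio holds exactly within each TG band.

    One fixed TG:VLDL-C ratio per band; table derivation on the result
    must recover ``ratios`` exactly.  TG is uniform within each band
    (the last band capped at ``tg_max``); LDL-C and HDL-C follow the
    default marginals.
    """
    ratios = tuple(float(r) for r in ratios)
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    if len(ratios) != len(tg_edges) + 1:
        raise ValueError("need one ratio per TG band (len(tg_edges)+1)")
    counts = (
        [int(n_per_band)] * len(ratios)
        if np.isscalar(n_per_band)
        else [int(c) for c in n_per_band]
    )
    rng = np.random.default_rng(seed)
    bounds = [1.0, *tg_edges, tg_max]
    tg_all, vldl_all = [], []
    for b, (r, c) in enumerate(zip(ratios, counts)):
        # draw strictly inside the band so the exact-ratio adjustment of TG
        # (sub-1e-6 mg/dL) cannot cross a band edge
        tg_raw = rng.uniform(bounds[b] + 0.5, bounds[b + 1] - 0.5, c)
        for t in tg_raw:
            tg_exact, v_exact = _exact_ratio_pair(float(t), r)
            tg_all.append(tg_exact)
            vldl_all.append(v_exact)
    tg = np.asarray(tg_all)
    vldl = np.asarray(vldl_all)
    n = tg.size
    ldl = np.clip(np.round(rng.lognormal(_LDL_MU, _LDL_SIGMA, n)), 10.0, 250.0)
    hdl = np.clip(np.round(rng.normal(48.0, 10.4, n)), 20.0, 100.0)
    return _assemble(rng, tg, vldl, ldl, hdl, noise_sd=0.0, id_prefix="N")


def _exact_ratio_pair(tg_target: float, r: float) -> tuple[float, float]:
    """(tg, vldl) near ``tg_target`` with ``fl(tg / vldl) == r`` exactly.

    ``vldl`` is snapped to the dyadic cholesterol grid (so the TC
    subtraction chain returns it unchanged) and ``tg`` is searched within a
    few ulp of r * vldl for a value whose rounded quotient is exactly the
    requested ratio.
    """
    v = float(_snap(tg_target / r))
    for _ in range(64):
        base = r * v
        cands = [base]
        up = down = base
        for _ in range(4):
            up = math.nextafter(up, math.inf)
            down = math.nextafter(down, -math.inf)
            cands.extend((up, down))
        for cand in cands:
            if cand > 0 and cand / v == r:
                return cand, v
        v += GRID  # rare: no float maps back onto r; nudge vldl one grid step
    raise RuntimeError("could not construct an exact ratio pair")  # pragma: no cover
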