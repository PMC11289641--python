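"""Exponential mRNA decay fitting from transcription-shutoff time courses.

After cordycepin-style transcription shutoff, remaining mRNA follows
first-order kinetics y(t) = exp(-A * t), with abundance at the initial time
anchored to 1. A (min^-1) is estimated per gene by bounded nonlinear least
squares on the natural scale (a log-linear alternative is available), and
the half-life is ln(2)/A.

Spike-in correction: the chase adds a fixed amount of exogenous spike-in per
unit total RNA, so the spike-ins' *share of the library* tracks the inverse
of the decaying mRNA pool. normalize_course therefore computes spike-in size
factors on the CPM scale (spike-in CPM totals); dividing gene CPM by that
factor restores absolute decay, which plain CPM would mask as the pool
shrinks. This also makes the correction invariant to sequencing depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .intervals import TargetClassification
from .normalization import CountTable, cpm, spikein_size_factors

__all__ = [
    "DecayCurve",
    "DecayFit",
    "normalize_course",
    "fit_decay",
    "fit_decay_table",
    "half_life",
    "relative_half_life",
    "stratify_by_sites",
]

FLAT_THRESHOLD = 1e-6  # min^-1; below this the gene is reported as non-decaying
DEFAULT_RSS_MAX = 0.5  # poor-fit flag threshold over a 5-point course


@dataclass(frozen=True)
class DecayCurve:
    """One gene's normalized chase time course; y(0) = 1 by construction."""

    gene_id: str
    times: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        y = np.asarray(self.y, float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "y", y)
        if t[0] != 0 or (np.diff(t) <= 0).any():
            raise ValueError("times must strictly increase from 0")
        if not np.isclose(y[0], 1.0):
            raise ValueError("normalized curve must have y(0) = 1")
        if (y < 0).any():
            raise ValueError("relative abundance must be non-negative")


@dataclass(frozen=True)
class DecayFit:
    """Fitted decay rate A (min^-1), half-life (min), and diagnostics."""

    gene_id: str
    A: float
    halflife: float  # math.inf when A below the flat threshold
    rss: float
    status: str  # ok | flat | poor-fit

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError("decay rate must be non-negative")


def half_life(A: float) -> float:
    """t_1/2 = ln 2 / A; infinity for A = 0."""
    if A < 0:
        raise ValueError("decay rate must be non-negative")
    return math.inf if A == 0 else math.log(2) / A


def _rss(A: float, t: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum((y - np.exp(-A * t)) ** 2))


def _rss_grad(A: float, t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    e = np.exp(-A * t)
    r = e - y
    g = float(np.sum(-2.0 * r * t * e))
    h = float(np.sum(2.0 * (t * e) ** 2 + 2.0 * r * t * t * e))
    return g, h


def fit_decay(
    curve: DecayCurve,
    mode: str = "nls",
    a_max: float = 1.0,
    rss_max: float = DEFAULT_RSS_MAX,
) -> DecayFit:
    """Fit y = exp(-A * t) to one normalized curve, A >= 0.

    ``nls`` minimizes the natural-scale residual sum of squares by bounded
    scalar minimization followed by a safeguarded Newton polish; the t = 0
    anchor point participates in the loss. ``loglinear`` regresses log y on
    t through the origin, dropping non-positive y. Status is ``flat`` when
    A < 1e-6 min^-1 and ``poor-fit`` when the RSS exceeds ``rss_max``.
    """
    t, y = curve.times, curve.y
    if len(t) < 3:
        raise ValueError("need at least 3 time points to fit decay")
    if mode == "loglinear":
        keep = y > 0
        tt, yy = t[keep], y[keep]
        if len(tt) < 3:
            return DecayFit(curve.gene_id, 0.0, math.inf, _rss(0.0, t, y), "poor-fit")
        # no-intercept regression of log y on t: A = -sum(t log y)/sum(t^2)
        A = max(0.0, float(-np.sum(tt * np.log(yy)) / np.sum(tt * tt)))
    elif mode == "nls":
        res = minimize_scalar(
            _rss, bounds=(0.0, a_max), args=(t, y), method="bounded",
            options={"xatol": 1e-12},
        )
        A = float(res.x)
        # Newton polish on the gradient for machine-precision noiseless recovery
        for _ in range(8):
            g, h = _rss_grad(A, t, y)
            if h <= 0:
                break
            step = g / h
            A_new = min(max(A - step, 0.0), a_max)
            if abs(A_new - A) <= 1e-15 * max(A, 1e-12):
                A = A_new
                break
            A = A_new
    else:
        raise ValueError(f"unknown fit mode {mode!r}")

    rss = _rss(A, t, y)
    if A < FLAT_THRESHOLD:
        return DecayFit(curve.gene_id, A, math.inf, rss, "flat")
    status = "poor-fit" if rss > rss_max else "ok"
    return DecayFit(curve.gene_id, A, math.log(2) / A, rss, status)


def normalize_course(
    table: CountTable,
    factors: pd.Series | None = None,
    time_col: str = "time",
) -> list[DecayCurve]:
    """Spike-in-corrected normalized decay curves, one per gene.

    Per gene, y(t) = (CPM_t / factor_t) / (CPM_0 / factor_0) with y(0) = 1
    by construction; replicate samples at a time point are averaged on the
    normalized scale. Factors default to spike-in size factors computed on
    this table's CPM (see module docstring). Genes with zero counts at t = 0
    are dropped.
    """
    if table.samples is None or time_col not in table.samples.columns:
        raise ValueError(f"sample sheet must provide a {time_col!r} column")
    times = table.samples[time_col].astype(float)
    if not (times == 0).any():
        raise ValueError("time course must include a t = 0 sample")
    vals = cpm(table)
    if factors is None:
        factors = spikein_size_factors(vals, table.spikein)
    norm = vals.loc[~table.spikein].div(factors, axis=1)
    # average replicates per time point on the normalized scale
    by_time = norm.T.groupby(times).mean().T
    tpts = np.array(sorted(by_time.columns))
    by_time = by_time[tpts]
    y0 = by_time[0.0]
    keep = y0 > 0
    curves = []
    for gid in by_time.index[keep]:
        y = by_time.loc[gid].to_numpy() / y0[gid]
        curves.append(DecayCurve(gid, tpts, y))
    return curves


def fit_decay_table(
    curves: Sequence[DecayCurve], mode: str = "nls", rss_max: float = DEFAULT_RSS_MAX
) -> pd.DataFrame:
    """Fit every curve; tidy per-gene table of A, half-life, RSS, status."""
    fits = [fit_decay(c, mode=mode, rss_max=rss_max) for c in curves]
    return pd.DataFrame(
        {
            "gene_id": [f.gene_id for f in fits],
            "A": [f.A for f in fits],
            "halflife": [f.halflife for f in fits],
            "rss": [f.rss for f in fits],
            "status": [f.status for f in fits],
        }
    ).set_index("gene_id")


def relative_half_life(fit_mut: DecayFit, fit_wt: DecayFit) -> float:
    """log2(t_1/2 mutant / t_1/2 WT); positive = slower decay in the mutant.

    Requires both fits to have status ``ok``.
    """
    for f in (fit_mut, fit_wt):
        if f.status != "ok":
            raise ValueError(f"{f.gene_id}: cannot form ratio from status {f.status!r}")
    return float(np.log2(fit_mut.halflife / fit_wt.halflife))


def relative_half_life_table(
    fits_mut: pd.DataFrame, fits_wt: pd.DataFrame
) -> pd.Series:
    """Per-gene log2 half-life ratios over genes with ok fits in both
    genotypes; flat/poor fits are excluded."""
    common = fits_mut.index.intersection(fits_wt.index)
    ok = (fits_mut.loc[common, "status"] == "ok") & (fits_wt.loc[common, "status"] == "ok")
    genes = common[ok]
    return pd.Series(
        np.log2(fits_mut.loc[genes, "halflife"] / fits_wt.loc[genes, "halflife"]),
        index=genes,
        name="log2_halflife_ratio",
    )


def stratify_by_sites(
    ratios: Mapping[str, float] | pd.Series,
    classification: TargetClassification,
) -> dict[str, pd.Series]:
    """Split per-gene log2 half-life ratios by binding-site count.

    Strata: ``3+`` (3 or more sites), ``2``, ``1``, and ``non-targeted``;
    only genes present in ``ratios`` contribute.
    """
    ratios = pd.Series(dict(ratios) if not isinstance(ratios, pd.Series) else ratios)
    strata: dict[str, list[str]] = {"3+": [], "2": [], "1": [], "non-targeted": []}
    for g in ratios.index:
        if g in classification.reader_targets:
            c = classification.site_counts.get(g, 0)
            strata["3+" if c >= 3 else str(c)].append(g)
        elif g in classification.universe:
            strata["non-targeted"].append(g)
    return {k: ratios.loc[v] for k, v in strata.items()}
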