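"""Quantification formulas: CPM, spike-in calibration, m6A level, TE.

The m6A IP-efficiency calibration follows the methylated/unmethylated
spike-in pair convention: each IP/input sample pair yields a spike-in ratio

    r = (CPM_IP + 0.01) / (CPM_Input + 0.01)

for the methylated control, and the per-sample normalization factor

    nf = r / mean(r over the wild-type reference samples)

rescales per-feature IP/input ratios into cross-sample-comparable m6A
levels. Pseudocount 0.01 is fixed by the formula above and reused in the
relative-expression log-ratio for zero safety.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PSEUDOCOUNT",
    "CountTable",
    "SpikeCalibration",
    "cpm",
    "m6a_spike_ratio",
    "m6a_normalization_factor",
    "m6a_level",
    "translation_efficiency",
    "spikein_size_factors",
    "relative_expression",
]

PSEUDOCOUNT = 0.01
SPIKE_PREFIX = "SPIKE_"


class DegenerateSampleError(ValueError):
    """A sample with zero usable counts where positive counts are required."""


@dataclass
class CountTable:
    """Genes x samples counts with flagged spike-in rows and sample metadata.

    ``counts`` is a features-by-samples DataFrame; spike-in rows are flagged
    by ``spikein`` (defaults to ids prefixed ``SPIKE_``). ``samples`` holds
    per-sample metadata (genotype, condition, role, time, replicate) indexed
    by sample id.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame | None = None
    spikein: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            dup = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated feature ids: {dup[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.spikein is None:
            self.spikein = pd.Series(
                self.counts.index.str.startswith(SPIKE_PREFIX), index=self.counts.index
            )
        else:
            self.spikein = self.spikein.reindex(self.counts.index).fillna(False).astype(bool)
        if self.spikein.all():
            raise ValueError("need at least one non-spike-in feature")
        if self.samples is None:
            self.samples = pd.DataFrame(index=self.counts.columns)
        elif not self.counts.columns.equals(self.samples.index):
            self.samples = self.samples.reindex(self.counts.columns)

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def gene_counts(self) -> pd.DataFrame:
        return self.counts.loc[~self.spikein]

    @property
    def spike_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.spikein]

    def select_samples(self, ids: Sequence[str]) -> "CountTable":
        return CountTable(
            self.counts[list(ids)], self.samples.loc[list(ids)], self.spikein
        )


@dataclass
class SpikeCalibration:
    """Per-sample m6A spike-in ratios and normalization factors.

    The mean nf over the reference (WT) sample set is 1 by construction.
    """

    r: pd.Series
    nf: pd.Series
    reference_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.r <= 0).any() or (self.nf <= 0).any():
            raise ValueError("spike ratios and nf must be positive")
        if self.reference_samples:
            mean_nf = self.nf.loc[self.reference_samples].mean()
            if not np.isclose(mean_nf, 1.0):
                raise ValueError(f"mean nf over reference set is {mean_nf}, expected 1")


def cpm(table: CountTable) -> pd.DataFrame:
    """Counts per million over the non-spike-in library of each sample.

    CPM = count / (sum of non-spike-in counts in the sample) * 1e6, for
    every row including spike-ins; non-spike-in CPMs sum to 1e6 per sample.
    """
    lib = table.gene_counts.sum(axis=0)
    dead = lib[lib <= 0]
    if len(dead):
        raise DegenerateSampleError(
            f"zero non-spike-in library size in sample(s): {list(dead.index)}"
        )
    return table.counts.div(lib, axis=1) * 1e6


def m6a_spike_ratio(cpm_ip: float, cpm_input: float) -> float:
    """r = (CPM_IP + 0.01) / (CPM_Input + 0.01)."""
    if cpm_ip < 0 or cpm_input < 0:
        raise ValueError("CPM values must be non-negative")
    return (cpm_ip + PSEUDOCOUNT) / (cpm_input + PSEUDOCOUNT)


def m6a_normalization_factor(r_sample: float, r_reference_set: Sequence[float]) -> float:
    """nf = r_sample / arithmetic-mean of the reference-set ratios."""
    ref = np.asarray(list(r_reference_set), dtype=float)
    if ref.size == 0:
        raise ValueError("reference (WT) sample set is empty")
    if r_sample <= 0 or (ref <= 0).any():
        raise ValueError("spike ratios must be positive")
    return float(r_sample / ref.mean())


def m6a_level(cpm_ip, cpm_input, nf: float = 1.0):
    """Per-feature m6A level: (CPM_IP + 0.01)/(CPM_Input + 0.01) * nf.

    Accepts scalars or aligned arrays/Series.
    """
    if nf <= 0:
        raise ValueError("nf must be positive")
    ip = np.asarray(cpm_ip, dtype=float)
    inp = np.asarray(cpm_input, dtype=float)
    if (ip < 0).any() or (inp < 0).any():
        raise ValueError("CPM values must be non-negative")
    out = (ip + PSEUDOCOUNT) / (inp + PSEUDOCOUNT) * nf
    if np.isscalar(cpm_ip) and np.isscalar(cpm_input):
        return float(out)
    if isinstance(cpm_ip, pd.Series):
        return pd.Series(out, index=cpm_ip.index)
    return out


def calibrate_spikein(
    ip_cpm: pd.DataFrame,
    input_cpm: pd.DataFrame,
    methylated_id: str,
    pairs: dict[str, str],
    reference_samples: Sequence[str],
) -> SpikeCalibration:
    """Per-sample r and nf from the methylated m6A spike-in row.

    ``pairs`` maps each IP sample id to its matched input sample id;
    ``reference_samples`` names the WT IP samples whose mean r anchors
    nf = 1. The returned series are indexed by IP sample id.
    """
    ref = list(reference_samples)
    if not ref:
        raise ValueError("reference (WT) sample set is empty")
    r = pd.Series(
        {
            ip_s: m6a_spike_ratio(
                float(ip_cpm.loc[methylated_id, ip_s]),
                float(input_cpm.loc[methylated_id, in_s]),
            )
            for ip_s, in_s in pairs.items()
        }
    )
    nf = r / r.loc[ref].mean()
    return SpikeCalibration(r=r, nf=nf, reference_samples=ref)


def corrected_m6a_levels(
    ip_cpm: pd.DataFrame,
    input_cpm: pd.DataFrame,
    calibration: SpikeCalibration,
    pairs: dict[str, str],
) -> pd.DataFrame:
    """Per-feature m6A levels with each sample's nf applied.

    For each IP/input sample pair, level = (CPM_IP + 0.01)/(CPM_Input +
    0.01) x nf — the per-feature calibration formula applied table-wide.
    Columns of the result are the IP sample ids. Note that nf rescales a
    whole sample uniformly: it carries the sample's overall spike-in IP
    signal into the levels but cannot alter within-sample comparisons (see
    the methods note for what this does and does not correct).
    """
    out = {}
    for ip_s, in_s in pairs.items():
        out[ip_s] = m6a_level(ip_cpm[ip_s], input_cpm[in_s],
                              float(calibration.nf.loc[ip_s]))
    return pd.DataFrame(out)


def translation_efficiency(cpm_ribo, cpm_input):
    """TE = CPM_Ribo / CPM_Input; features with zero input CPM are returned
    as NaN (flagged undefined) rather than computed."""
    ribo = np.asarray(cpm_ribo, dtype=float)
    inp = np.asarray(cpm_input, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        te = np.where(inp > 0, ribo / np.where(inp > 0, inp, 1.0), np.nan)
    if np.isscalar(cpm_ribo) and np.isscalar(cpm_input):
        return float(te)
    if isinstance(cpm_ribo, pd.Series):
        return pd.Series(te, index=cpm_ribo.index)
    return te


def spikein_size_factors(table: CountTable | pd.DataFrame, spikein: pd.Series | None = None) -> pd.Series:
    """Per-sample spike-in size factors.

    factor_s = (spike-in total of sample s) / geometric mean over samples of
    the spike-in totals. Dividing each sample's values by its factor
    equalizes expected spike-in totals across samples. Accepts a CountTable
    (raw counts) or any features-by-samples frame (e.g. a CPM table) with a
    spike-in flag.
    """
    if isinstance(table, CountTable):
        totals = table.spike_counts.sum(axis=0)
    else:
        if spikein is None:
            spikein = pd.Series(
                table.index.str.startswith(SPIKE_PREFIX), index=table.index
            )
        totals = table.loc[spikein.reindex(table.index).fillna(False).astype(bool)].sum(axis=0)
    dead = totals[totals <= 0]
    if len(dead):
        raise DegenerateSampleError(
            f"zero spike-in total in sample(s): {list(dead.index)}"
        )
    geo = np.exp(np.log(totals).mean())
    return totals / geo


def relative_expression(
    table: CountTable,
    group_mut: Iterable[str],
    group_wt: Iterable[str],
    factors: pd.Series | None = None,
) -> pd.Series:
    """Per-gene log2 fold change of spike-in-normalized CPM, mutant vs WT.

    log2FC = log2((mean normalized CPM in mut + 0.01) /
                  (mean normalized CPM in wt + 0.01)).
    """
    mut = list(group_mut)
    wt = list(group_wt)
    if not mut or not wt:
        raise ValueError("both sample groups must be non-empty")
    vals = cpm(table).loc[~table.spikein]
    if factors is not None:
        vals = vals.div(factors, axis=1)
    num = vals[mut].mean(axis=1) + PSEUDOCOUNT
    den = vals[wt].mean(axis=1) + PSEUDOCOUNT
    return np.log2(num / den)
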