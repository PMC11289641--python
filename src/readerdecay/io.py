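"""File-format dialects: toy GTF, BED6, bedGraph, TSV count tables,
sample sheets, and JSON reports.

Single source of truth for coordinate conversion: GTF is 1-based closed on
disk and converted to the internal 0-based half-open frame on read; BED and
bedGraph are written natively half-open. Malformed lines are reported with
their line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, PeakSet
from .normalization import CountTable

__all__ = [
    "write_gtf", "read_gtf",
    "write_bed", "read_bed",
    "write_bedgraph", "read_bedgraph",
    "write_counts", "read_counts",
    "write_sample_sheet", "read_sample_sheet",
    "write_report",
]

_REGION_FEATURES = (("utr5", "five_prime_utr"), ("cds", "CDS"), ("utr3", "three_prime_utr"))


def write_gtf(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}";'
            rows = [("gene", m.start, m.end)]
            rows += [(feat, getattr(m, reg)[0], getattr(m, reg)[1])
                     for reg, feat in _REGION_FEATURES]
            for feat, lo, hi in rows:
                fh.write(
                    f"{m.chrom}\ttoysim\t{feat}\t{lo + 1}\t{hi}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene models written by :func:`write_gtf` back into the internal
    0-based half-open frame."""
    regions: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF fields, got {len(parts)}")
            chrom, _, feat, start, end, _, strand, _, attrs = parts
            try:
                lo, hi = int(start) - 1, int(end)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if lo < 0 or hi <= lo:
                raise ValueError(f"{path}:{lineno}: coordinate underflow after conversion")
            gid = None
            for field in attrs.split(";"):
                field = field.strip()
                if field.startswith("gene_id"):
                    gid = field.split('"')[1]
            if gid is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            rec = regions.setdefault(gid, {"chrom": chrom, "strand": strand})
            key = {"five_prime_utr": "utr5", "CDS": "cds", "three_prime_utr": "utr3"}.get(feat)
            if key:
                rec[key] = (lo, hi)
    models = []
    for gid, rec in regions.items():
        missing = [k for k in ("utr5", "cds", "utr3") if k not in rec]
        if missing:
            raise ValueError(f"{path}: gene {gid} missing features {missing}")
        models.append(GeneModel(gid, rec["chrom"], rec["strand"],
                                rec["utr5"], rec["cds"], rec["utr3"]))
    models.sort(key=lambda m: m.gene_id)
    return models


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """BED6; score = round(100 * min(enrichment, 3))."""
    with open(path, "w") as fh:
        for iv, enr in zip(peaks.intervals, peaks.enrichment):
            score = int(round(100 * min(float(enr), 3.0)))
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n")


def read_bed(path: str | Path, label: str = "") -> PeakSet:
    intervals, scores = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 BED fields")
            chrom, start, end, name, score, strand = parts[:6]
            try:
                iv = GenomicInterval(chrom, int(start), int(end), strand, name)
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from None
            intervals.append(iv)
            scores.append(float(score) / 100.0)
    return PeakSet(intervals, np.maximum(np.array(scores), 1e-6),
                   np.zeros(len(intervals)), label)


def write_bedgraph(track: Mapping[str, np.ndarray], bin_size: int, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track):
            vals = np.asarray(track[chrom], dtype=float)
            for i, v in enumerate(vals):
                if v != 0:
                    fh.write(f"{chrom}\t{i * bin_size}\t{(i + 1) * bin_size}\t{v:g}\n")


def read_bedgraph(
    path: str | Path, bin_size: int, sizes: Mapping[str, int]
) -> dict[str, np.ndarray]:
    track = {c: np.zeros(int(np.ceil(s / bin_size))) for c, s in sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph fields")
            chrom, start, end, value = parts
            if chrom not in track:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom}")
            lo, hi = int(start), int(end)
            if lo % bin_size or (hi - lo) != bin_size:
                raise ValueError(f"{path}:{lineno}: interval not aligned to {bin_size}-bp bins")
            track[chrom][lo // bin_size] = float(value)
    return track


def write_counts(table: CountTable, path: str | Path) -> None:
    out = table.counts.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_counts(path: str | Path, samples: pd.DataFrame | None = None) -> CountTable:
    """TSV count table; first column feature id, spike-ins prefixed SPIKE_.

    Duplicated feature ids are rejected with the offending line numbers.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not df.index.is_unique:
        dup = df.index[df.index.duplicated(keep=False)]
        lines = [i + 2 for i, x in enumerate(df.index) if x in set(dup)]  # header is line 1
        raise ValueError(f"{path}: duplicated feature ids {sorted(set(dup))[:5]} "
                         f"on lines {lines}")
    return CountTable(counts=df, samples=samples)


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    out = samples.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonify(v) for v in sorted(obj)] if isinstance(obj, set) else [
            _jsonify(v) for v in obj
        ]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else repr(f)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, pd.Series):
        return _jsonify(obj.to_dict())
    return obj


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonify(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
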