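"""MSF/MRF footprint calling by genome-standardized thresholding.

A footprint is a maximal run of 10-bp bins whose standardized DNS score
exceeds +cutoff (MNase hyper-sensitive footprint, MSF) or falls below
-cutoff (hyper-resistant, MRF), with cutoff = 1.5 genome-wide standard
deviations by default. Runs separated by short same-sign sub-threshold gaps
may be merged (max_gap_bins); a merged segment is kept only if its mean |z|
still clears the cutoff. Consensus footprints are the coordinate
intersection of same-kind calls from two biological replicates, rescored on
the replicate-averaged track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BinTrack, DNSTrack, TrackError, aggregate
from .genome import GenomicInterval, SEGMENT_LABELS


@dataclass(frozen=True)
class Footprint:
    interval: GenomicInterval
    kind: str  # "MSF" | "MRF"
    mean_dns: float
    mean_z: float
    replicate_support: frozenset

    def __post_init__(self):
        if self.kind not in ("MSF", "MRF"):
            raise ValueError(f"bad footprint kind {self.kind!r}")


def standardize(dns: DNSTrack) -> BinTrack:
    """z = (value - genome_mean) / genome_sd on unmasked bins; masked -> 0."""
    if dns.genome_sd <= 0:
        raise TrackError("cannot standardize a constant track")
    data = {}
    for chrom in dns.assembly:
        z = (dns.data[chrom] - dns.genome_mean) / dns.genome_sd
        z[dns.mask[chrom]] = 0.0
        data[chrom] = z
    out = dns.copy_like(data)
    return out


def _runs(flags: np.ndarray):
    """(start, end) index pairs of maximal True runs (end exclusive)."""
    if not flags.any():
        return []
    d = np.diff(flags.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if flags[0]:
        starts.insert(0, 0)
    if flags[-1]:
        ends.append(flags.size)
    return list(zip(starts, ends))


def _merge_runs(runs, sign_ok: np.ndarray, max_gap: int):
    """Merge runs whose gap is <= max_gap bins of same-sign sub-threshold z."""
    if max_gap <= 0 or len(runs) < 2:
        return runs
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        gap_lo, gap_hi = merged[-1][1], s
        if gap_hi - gap_lo <= max_gap and sign_ok[gap_lo:gap_hi].all():
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [tuple(r) for r in merged]


def call_footprints(z: BinTrack, dns: BinTrack | None = None, cutoff: float = 1.5,
                    max_gap_bins: int = 0, min_len_bins: int = 1,
                    replicate: int | None = None) -> list[Footprint]:
    """Threshold a z-score track into MSF/MRF footprints (single replicate).

    dns, when given, supplies the raw DNS values for mean_dns (otherwise
    mean_dns is reported on the z scale). Masked bins never participate.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    support = frozenset() if replicate is None else frozenset({replicate})
    kept: list[tuple[GenomicInterval, str, float]] = []
    for chrom in z.assembly:
        zc = z.data[chrom]
        ok = ~z.mask[chrom]
        for kind, sel, sign_ok in (
                ("MSF", (zc >= cutoff) & ok, (zc > 0) & ok),
                ("MRF", (zc <= -cutoff) & ok, (zc < 0) & ok)):
            runs = _merge_runs(_runs(sel), sign_ok, max_gap_bins)
            for s, e in runs:
                if e - s < min_len_bins:
                    continue
                mean_z = float(zc[s:e][ok[s:e]].mean())
                if abs(mean_z) < cutoff:
                    continue
                iv = GenomicInterval(chrom, s * z.bin_width,
                                     min(e * z.bin_width, z.assembly.length(chrom)))
                kept.append((iv, kind, mean_z))
    if dns is not None and kept:
        means = aggregate(dns, [iv for iv, _, _ in kept], "mean")
    else:
        means = [mz for _, _, mz in kept]
    return [Footprint(iv, kind, float(md), mz, support)
            for (iv, kind, mz), md in zip(kept, means)]


def consensus(rep1: list[Footprint], rep2: list[Footprint],
              averaged: DNSTrack | None = None, mode: str = "intersect") -> list[Footprint]:
    """Two-replicate consensus: same-kind coordinate intersection.

    Regions above the cutoff in both replicates are retained; mean_dns and
    mean_z of each consensus interval are recomputed on the replicate-
    averaged DNS track when supplied. mode='union' merges instead.
    """
    if mode not in ("intersect", "union"):
        raise ValueError(f"unknown consensus mode {mode!r}")
    pieces_all: list[tuple[GenomicInterval, str]] = []
    chroms = sorted({fp.interval.chrom for fp in rep1 + rep2})
    for chrom in chroms:
        for kind in ("MSF", "MRF"):
            a = sorted((fp.interval.start, fp.interval.end) for fp in rep1
                       if fp.interval.chrom == chrom and fp.kind == kind)
            b = sorted((fp.interval.start, fp.interval.end) for fp in rep2
                       if fp.interval.chrom == chrom and fp.kind == kind)
            pieces = (_intersect_sorted(a, b) if mode == "intersect"
                      else _union_sorted(a + b))
            pieces_all.extend((GenomicInterval(chrom, s, e), kind) for s, e in pieces)
    if averaged is not None and pieces_all:
        means = aggregate(averaged, [iv for iv, _ in pieces_all], "mean")
        zs = (means - averaged.genome_mean) / averaged.genome_sd
    else:
        means = zs = np.full(len(pieces_all), np.nan)
    out = [Footprint(iv, kind, float(md), float(mz), frozenset({1, 2}))
           for (iv, kind), md, mz in zip(pieces_all, means, zs)]
    out.sort(key=lambda fp: (fp.interval.chrom, fp.interval.start))
    return out


def _intersect_sorted(a, b):
    out, i, j = [], 0, 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _union_sorted(ivs):
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def footprint_summary(footprints, assembly, segments=None) -> pd.DataFrame:
    """Totals (bp, Mb, % of genome, count) per kind, subgenome and segment.

    Segment attribution is by footprint midpoint. Returns a tidy frame with
    columns stratum_type/stratum/kind/bp/mb/percent/count.
    """
    rows = []
    total = assembly.total_length

    def add(stratum_type, stratum, fps):
        for kind in ("MSF", "MRF"):
            sel = [fp for fp in fps if fp.kind == kind]
            bp = sum(len(fp.interval) for fp in sel)
            rows.append({"stratum_type": stratum_type, "stratum": stratum,
                         "kind": kind, "bp": bp, "mb": bp / 1e6,
                         "percent": 100.0 * bp / total, "count": len(sel)})

    add("genome", "all", footprints)
    for sub in assembly.subgenomes:
        add("subgenome", sub,
            [fp for fp in footprints if assembly.genome_of(fp.interval.chrom) == sub])
    if segments is not None:
        for label in SEGMENT_LABELS:
            sel = [fp for fp in footprints
                   if fp.interval.chrom in segments.chromosomes
                   and segments.label_at(fp.interval.chrom, fp.interval.midpoint) == label]
            add("segment", label, sel)
    return pd.DataFrame(rows)
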