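"""Situate footprints relative to genes, TEs, segments and chromatin states.

Each footprint receives exactly one context label, decided by its midpoint
under a precedence rule (gene body > 2-kb upstream > 2-kb downstream > TE >
unannotated intergenic by default), so that context proportions sum to one.
Upstream/downstream windows are strand-aware and anchored at the CDS
boundaries. Enrichment questions are answered with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import DNSTrack, aggregate
from .genome import GenomicInterval, SEGMENT_LABELS


class IntervalIndex:
    """Point/nearest queries over a static, possibly overlapping interval set."""

    def __init__(self, intervals_by_chrom: dict[str, list[tuple[int, int, int]]]):
        # values: (start, end, payload index)
        self._starts, self._ends, self._ids, self._prefmax = {}, {}, {}, {}
        for chrom, ivs in intervals_by_chrom.items():
            ivs = sorted(ivs)
            s = np.array([x[0] for x in ivs], dtype=np.int64)
            e = np.array([x[1] for x in ivs], dtype=np.int64)
            i = np.array([x[2] for x in ivs], dtype=np.int64)
            self._starts[chrom], self._ends[chrom], self._ids[chrom] = s, e, i
            self._prefmax[chrom] = np.maximum.accumulate(e) if e.size else e

    @classmethod
    def from_intervals(cls, intervals):
        by_chrom: dict[str, list] = {}
        for idx, iv in enumerate(intervals):
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, idx))
        return cls(by_chrom)

    def covering(self, chrom: str, pos: int) -> int:
        """Payload index of an interval containing pos, or -1."""
        if chrom not in self._starts:
            return -1
        s, e, pm = self._starts[chrom], self._ends[chrom], self._prefmax[chrom]
        hi = int(np.searchsorted(s, pos, side="right"))
        i = hi - 1
        while i >= 0 and pm[i] > pos:
            if e[i] > pos:
                return int(self._ids[chrom][i])
            i -= 1
        return -1

    def nearest_distance(self, chrom: str, pos: int):
        """(distance in bp to the nearest interval base, payload index).

        0 when pos is inside an interval; (nan, -1) when the chromosome has
        no intervals.
        """
        if chrom not in self._starts or self._starts[chrom].size == 0:
            return float("nan"), -1
        hit = self.covering(chrom, pos)
        if hit >= 0:
            return 0.0, hit
        s, e, ids = self._starts[chrom], self._ends[chrom], self._ids[chrom]
        hi = int(np.searchsorted(s, pos, side="right"))
        best, best_id = np.inf, -1
        if hi < s.size:
            best, best_id = float(s[hi] - pos), int(ids[hi])
        # nearest right edge among intervals starting before pos
        if hi > 0:
            j = int(np.argmax(e[:hi]))
            d = float(pos - (e[j] - 1))
            if d < best:
                best, best_id = d, int(ids[j])
        return best, best_id


@dataclass(frozen=True)
class ContextAssignment:
    footprint_index: int
    context: str  # gene_body | upstream_2kb | downstream_2kb | TE | unannotated_intergenic
    te_detail: tuple | None  # (class, superfamily, family)
    nearest_gene: str | None
    distance: float


CONTEXTS = ("gene_body", "upstream_2kb", "downstream_2kb", "TE",
            "unannotated_intergenic")


def _flank_windows(genes, assembly, flank, which):
    """Strand-aware CDS-anchored flank windows, clipped to the chromosome."""
    by_chrom: dict[str, list] = {}
    for idx, g in enumerate(genes):
        L = assembly.length(g.chrom)
        if (which == "upstream") == (g.strand == "+"):
            s, e = g.cds_start - flank, g.cds_start
        else:
            s, e = g.cds_end, g.cds_end + flank
        s, e = max(0, s), min(L, e)
        if s < e:
            by_chrom.setdefault(g.chrom, []).append((s, e, idx))
    return IntervalIndex(by_chrom)


def assign_context(footprints, genes, tes, assembly, flank: int = 2000,
                   precedence: str = "genic-first") -> list[ContextAssignment]:
    """One context per footprint, decided by the footprint midpoint."""
    if precedence not in ("genic-first", "te-first"):
        raise ValueError(f"unknown precedence {precedence!r}")
    body_idx = IntervalIndex.from_intervals([g.interval for g in genes])
    up_idx = _flank_windows(genes, assembly, flank, "upstream")
    down_idx = _flank_windows(genes, assembly, flank, "downstream")
    te_idx = IntervalIndex.from_intervals([t.interval for t in tes])
    gene_idx = body_idx  # nearest-gene uses gene-model edges

    out = []
    for i, fp in enumerate(footprints):
        p = fp.interval.midpoint
        chrom = fp.interval.chrom
        dist, gi = gene_idx.nearest_distance(chrom, p)
        near = genes[gi].gene_id if gi >= 0 else None

        genic = None
        for label, idx in (("gene_body", body_idx), ("upstream_2kb", up_idx),
                           ("downstream_2kb", down_idx)):
            if idx.covering(chrom, p) >= 0:
                genic = label
                break
        ti = te_idx.covering(chrom, p)
        te_detail = None
        context = "unannotated_intergenic"
        if precedence == "genic-first":
            if genic is not None:
                context = genic
            elif ti >= 0:
                context = "TE"
        else:
            if ti >= 0:
                context = "TE"
            elif genic is not None:
                context = genic
        if context == "TE":
            te = tes[ti]
            te_detail = (te.te_class, te.superfamily, te.family)
        out.append(ContextAssignment(i, context, te_detail, near, dist))
    return out


def context_proportions(assignments) -> pd.Series:
    counts = pd.Series(0, index=list(CONTEXTS), dtype=float)
    for a in assignments:
        counts[a.context] += 1
    n = counts.sum()
    return counts / n if n else counts


def kde_mode(values: np.ndarray, log_scale: bool = True) -> float:
    """Peak of a Gaussian KDE (Silverman bandwidth).

    With log_scale the density is estimated on log10(x + 1) and the mode is
    back-transformed — appropriate for the heavily right-skewed distance
    distributions. Tie-break: the smaller mode.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return float("nan")
    x = np.log10(values + 1.0) if log_scale else values
    if np.ptp(x) == 0:
        return float(values[0])
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 2048)
    dens = kde(grid)
    mode = grid[np.argmax(dens)]  # argmax takes the first (smaller) maximum
    return float(10 ** mode - 1.0) if log_scale else float(mode)


def nearest_gene_distances(footprints, genes):
    """Midpoint-to-nearest-gene-edge distances with mean and KDE mode.

    Footprints on chromosomes without genes get nan distances.
    Returns (distances array, {'mean':…, 'mode':…}).
    """
    idx = IntervalIndex.from_intervals([g.interval for g in genes])
    d = np.array([idx.nearest_distance(fp.interval.chrom, fp.interval.midpoint)[0]
                  for fp in footprints])
    finite = d[np.isfinite(d)]
    summary = {"mean": float(finite.mean()) if finite.size else float("nan"),
               "mode": kde_mode(finite)}
    return d, summary


@dataclass(frozen=True)
class EnrichmentResult:
    table: tuple
    odds_ratio: float
    p_value: float


def fisher_exact(table) -> EnrichmentResult:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Odds ratio is the sample odds ratio ad/bc (inf or nan at zero cells);
    a zero margin gives p = 1 by convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of nonnegative integers")
    orat, p = stats.fisher_exact(t, alternative="two-sided")
    return EnrichmentResult(tuple(map(tuple, t)), float(orat), float(p))


def genes_near_footprints(footprints, genes, radius: int = 2000):
    """Per-gene footprint counts within a gap radius (envelope overlap).

    A footprint is credited to every gene whose interval lies within
    `radius` bp of it (gap between the half-open intervals <= radius), so a
    footprint between two close genes counts for both. Returns
    (per-gene count Series indexed by gene_id, summary dict).
    """
    counts = pd.Series(0, index=[g.gene_id for g in genes], dtype=int)
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: g.interval.start)
        starts = np.array([g.interval.start for g in gs])
        for fp in footprints:
            if fp.interval.chrom != chrom:
                continue
            lo = fp.interval.start - radius
            hi = fp.interval.end + radius
            i0 = int(np.searchsorted(starts, hi, side="left"))
            for g in gs[:i0]:
                if g.interval.end >= lo:  # gap to footprint <= radius
                    counts[g.gene_id] += 1
    with_any = (counts > 0).mean() * 100.0 if len(counts) else float("nan")
    return counts, {"percent_genes_with_footprint": float(with_any),
                    "mean_per_gene": float(counts.mean()) if len(counts) else float("nan")}


def segment_summaries(dns: DNSTrack, footprints, segments) -> dict:
    """Per-segment mean DNS, footprint bp, and distal-vs-interior enrichment.

    Mean DNS pools all chromosomes' bins of a segment label (bin-weighted).
    The enrichment test is Fisher's exact on bp counts: footprint vs
    non-footprint bp in distal (R1+R3) vs interior (R2a+C+R2b) space,
    separately per footprint kind.
    """
    rows = []
    seg_bp = {label: 0 for label in SEGMENT_LABELS}
    fp_bp = {(label, kind): 0 for label in SEGMENT_LABELS for kind in ("MSF", "MRF")}
    for label in SEGMENT_LABELS:
        ivs = segments.intervals(label)
        seg_bp[label] = sum(len(iv) for iv in ivs)
        sums = aggregate(dns, ivs, "sum")
        # bin-weighted pooled mean over all chromosomes' segments
        nbins = []
        for iv in ivs:
            b0, b1 = iv.start // dns.bin_width, (iv.end - 1) // dns.bin_width
            nbins.append(int((~dns.mask[iv.chrom][b0:b1 + 1]).sum()))
        tot_bins = sum(nbins)
        mean = float(np.nansum(sums) / tot_bins) if tot_bins else float("nan")
        rows.append({"segment": label, "mean_dns": mean, "bp": seg_bp[label]})
    for fp in footprints:
        chrom = fp.interval.chrom
        if chrom not in segments.chromosomes:
            continue
        label = segments.label_at(chrom, fp.interval.midpoint)
        fp_bp[(label, fp.kind)] += len(fp.interval)
    table = pd.DataFrame(rows).set_index("segment")
    for kind in ("MSF", "MRF"):
        table[f"{kind.lower()}_bp"] = [fp_bp[(label, kind)] for label in table.index]
    distal = ("R1", "R3")
    interior = ("R2a", "C", "R2b")
    tests = {}
    for kind in ("MSF", "MRF"):
        fd = sum(fp_bp[(s, kind)] for s in distal)
        fi = sum(fp_bp[(s, kind)] for s in interior)
        nd = sum(seg_bp[s] for s in distal) - fd
        ni = sum(seg_bp[s] for s in interior) - fi
        tests[kind] = fisher_exact([[fd, nd], [fi, ni]])
    return {"table": table, "distal_vs_interior": tests}


def state_overlap(footprints, states: dict, dns: DNSTrack | None = None):
    """Proportion of footprints (by midpoint) in each chromatin state.

    states: label -> list of GenomicInterval; intervals of different labels
    must not overlap. Returns (proportion Series incl. 'none', per-state
    mean DNS Series when a track is given).
    """
    flat, labels = [], []
    for label, ivs in states.items():
        for iv in ivs:
            flat.append(iv)
            labels.append(label)
    order = sorted(range(len(flat)), key=lambda i: (flat[i].chrom, flat[i].start))
    for a, b in zip(order, order[1:]):
        ia, ib = flat[a], flat[b]
        if ia.chrom == ib.chrom and ib.start < ia.end and labels[a] != labels[b]:
            raise ValueError(f"overlapping states {labels[a]!r}/{labels[b]!r} "
                             f"at {ia.chrom}:{ib.start}")
    idx = IntervalIndex.from_intervals(flat)
    counts = {label: 0 for label in states}
    counts["none"] = 0
    for fp in footprints:
        hit = idx.covering(fp.interval.chrom, fp.interval.midpoint)
        counts[labels[hit] if hit >= 0 else "none"] += 1
    n = max(1, len(footprints))
    props = pd.Series({k: v / n for k, v in counts.items()})
    means = None
    if dns is not None:
        means = pd.Series({label: float(np.nanmean(aggregate(dns, ivs, "mean")))
                           if ivs else float("nan")
                           for label, ivs in states.items()})
    return props, means
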