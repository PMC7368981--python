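"""Coverage binning, normalization and DNS score tracks.

The differential nuclease sensitivity (DNS) score of a 10-bp genomic bin is
the per-million-normalized light-digest read coverage minus the normalized
heavy-digest coverage. Positive scores mark MNase hyper-sensitive (open)
chromatin, negative scores hyper-resistant (closed) chromatin. This module
provides the fixed-width BinTrack container and the operations that take
aligned read intervals to averaged DNS tracks: bin-level coverage counting
(a read increments every bin it overlaps by at least 1 bp), counts-per-million
normalization against the genome-wide mapped total, light-heavy subtraction,
replicate averaging with genome-wide moments, replicate correlation, and
interval/window aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeAssembly, GenomicInterval, GenomeError


class TrackError(ValueError):
    pass


def _n_bins(length: int, bin_width: int) -> int:
    return -(-length // bin_width)  # ceil division


def reads_to_arrays(reads) -> dict[str, np.ndarray]:
    """Coerce reads to the per-chromosome (N, 2) start/end array form.

    Accepts either a list of GenomicInterval or an already-built dict of
    chrom -> int array with columns (start, end).
    """
    if isinstance(reads, dict):
        return {c: np.asarray(a, dtype=np.int64).reshape(-1, 2) for c, a in reads.items()}
    by_chrom: dict[str, list] = {}
    for iv in reads:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {c: np.asarray(v, dtype=np.int64) for c, v in by_chrom.items()}


class BinTrack:
    """Fixed-width per-chromosome numeric signal with a no-data mask.

    data maps chromosome name -> float array of length ceil(L / bin_width);
    mask marks bins with no usable data (True = masked). The terminal bin of
    a chromosome whose length is not a bin multiple is kept with its true
    (shorter) width and treated like any other bin.
    """

    def __init__(self, assembly: GenomeAssembly, bin_width: int = 10,
                 data: dict[str, np.ndarray] | None = None,
                 mask: dict[str, np.ndarray] | None = None):
        if bin_width <= 0:
            raise TrackError("bin_width must be positive")
        self.assembly = assembly
        self.bin_width = int(bin_width)
        self.data: dict[str, np.ndarray] = {}
        self.mask: dict[str, np.ndarray] = {}
        for chrom in assembly:
            n = _n_bins(assembly.length(chrom), bin_width)
            if data is not None and chrom in data:
                arr = np.asarray(data[chrom], dtype=np.float64)
                if arr.shape != (n,):
                    raise TrackError(f"{chrom}: expected {n} bins, got {arr.shape}")
                self.data[chrom] = arr
            else:
                self.data[chrom] = np.zeros(n)
            if mask is not None and chrom in mask:
                m = np.asarray(mask[chrom], dtype=bool)
                if m.shape != (n,):
                    raise TrackError(f"{chrom}: mask shape mismatch")
                self.mask[chrom] = m
            else:
                self.mask[chrom] = np.zeros(n, dtype=bool)

    def n_bins(self, chrom: str) -> int:
        return self.data[chrom].size

    def copy_like(self, data: dict[str, np.ndarray]) -> "BinTrack":
        return BinTrack(self.assembly, self.bin_width, data=data,
                        mask={c: m.copy() for c, m in self.mask.items()})

    def congruent(self, other: "BinTrack") -> bool:
        return (self.assembly is other.assembly or
                self.assembly.names == other.assembly.names) and \
            self.bin_width == other.bin_width

    def unmasked_values(self) -> np.ndarray:
        return np.concatenate([self.data[c][~self.mask[c]] for c in self.assembly])

    def flat(self) -> np.ndarray:
        return np.concatenate([self.data[c] for c in self.assembly])

    def flat_mask(self) -> np.ndarray:
        return np.concatenate([self.mask[c] for c in self.assembly])

    def bin_interval(self, chrom: str, bin_index: int) -> GenomicInterval:
        start = bin_index * self.bin_width
        end = min(start + self.bin_width, self.assembly.length(chrom))
        return GenomicInterval(chrom, start, end)


@dataclass
class DigestSample:
    """One sequenced MNase digest: replicate id, digest level and its reads.

    Light digest corresponds to 10 U/mL MNase, heavy to 100 U/mL.
    total_mapped is the genome-wide uniquely-mapped read count used for
    per-million normalization; it may exceed the reads supplied here
    (subsetting to a region is allowed).
    """

    replicate: int
    digest: str  # "light" | "heavy"
    reads: dict[str, np.ndarray]
    total_mapped: int

    def __post_init__(self):
        if self.digest not in ("light", "heavy"):
            raise ValueError("digest must be 'light' or 'heavy'")
        self.reads = reads_to_arrays(self.reads)
        n = sum(a.shape[0] for a in self.reads.values())
        if self.total_mapped < n:
            raise ValueError("total_mapped smaller than the number of reads supplied")


class DNSTrack(BinTrack):
    """A DNS score track with provenance and genome-wide moments.

    genome_mean and genome_sd are computed over unmasked bins (population
    SD); they anchor the standardized scores used for footprint calling.
    """

    def __init__(self, assembly, bin_width=10, data=None, mask=None, provenance=()):
        super().__init__(assembly, bin_width, data=data, mask=mask)
        self.provenance = tuple(provenance)
        vals = self.unmasked_values()
        if vals.size == 0:
            raise TrackError("DNS track has no unmasked bins")
        self.genome_mean = float(vals.mean())
        self.genome_sd = float(vals.std())  # population SD


def bin_coverage(reads, assembly: GenomeAssembly, bin_width: int = 10) -> BinTrack:
    """Count, per fixed-width bin, the read intervals overlapping it >= 1 bp.

    Matches bedmap --count with the bins as reference elements: a read
    spanning k bins contributes 1 to each of the k.
    """
    arrays = reads_to_arrays(reads)
    track = BinTrack(assembly, bin_width)
    total = 0
    for chrom, arr in arrays.items():
        if chrom not in assembly:
            raise GenomeError(f"reads on unknown chromosome {chrom!r}")
        if arr.size == 0:
            continue
        L = assembly.length(chrom)
        if (arr[:, 0] < 0).any() or (arr[:, 1] > L).any() or (arr[:, 0] >= arr[:, 1]).any():
            raise GenomeError(f"read interval outside chromosome {chrom} or malformed")
        n = track.n_bins(chrom)
        first = arr[:, 0] // bin_width
        last = (arr[:, 1] - 1) // bin_width  # inclusive
        diff = np.zeros(n + 1)
        np.add.at(diff, first, 1.0)
        np.add.at(diff, last + 1, -1.0)
        track.data[chrom] = np.cumsum(diff[:-1])
        total += arr.shape[0]
    if total == 0:
        warnings.warn("no reads supplied; coverage track is all zero")
    return track


def normalize_cpm(track: BinTrack, total_mapped: int) -> BinTrack:
    """Scale coverage to counts per million mapped reads: v * 1e6 / total."""
    if total_mapped <= 0:
        raise TrackError("total_mapped must be positive")
    factor = 1e6 / float(total_mapped)
    return track.copy_like({c: track.data[c] * factor for c in track.assembly})


def dns_score(light: BinTrack, heavy: BinTrack) -> BinTrack:
    """Per-bin light minus heavy of normalized coverage tracks."""
    if not light.congruent(heavy):
        raise TrackError("light/heavy tracks are not congruent")
    out = light.copy_like({c: light.data[c] - heavy.data[c] for c in light.assembly})
    for c in out.assembly:
        out.mask[c] = light.mask[c] | heavy.mask[c]
    return out


def coverage_mask(raw_tracks: list[BinTrack]) -> dict[str, np.ndarray]:
    """Mask of bins with zero raw coverage in every supplied sample.

    Such bins (unmappable or unassembled space) are excluded from genome
    moments and correlations; their DNS value is stored as 0 but flagged.
    """
    if not raw_tracks:
        raise TrackError("need at least one track")
    first = raw_tracks[0]
    mask = {}
    for chrom in first.assembly:
        m = np.ones(first.n_bins(chrom), dtype=bool)
        for t in raw_tracks:
            m &= t.data[chrom] == 0
        mask[chrom] = m
    return mask


def average_replicates(tracks: list[BinTrack], provenance=()) -> DNSTrack:
    """Arithmetic per-bin mean of congruent DNS tracks, with genome moments."""
    if not tracks:
        raise TrackError("no tracks to average")
    first = tracks[0]
    for t in tracks[1:]:
        if not first.congruent(t):
            raise TrackError("tracks are not congruent")
    data = {c: np.mean([t.data[c] for t in tracks], axis=0) for c in first.assembly}
    mask = {c: np.logical_and.reduce([t.mask[c] for t in tracks]) for c in first.assembly}
    return DNSTrack(first.assembly, first.bin_width, data=data, mask=mask,
                    provenance=provenance)


def replicate_correlation(a: BinTrack, b: BinTrack) -> float:
    """Pearson r between two tracks over bins unmasked in both.

    Returns nan when fewer than 2 eligible bins or either side is constant.
    """
    if not a.congruent(b):
        raise TrackError("tracks are not congruent")
    xs, ys = [], []
    for chrom in a.assembly:
        ok = ~(a.mask[chrom] | b.mask[chrom])
        xs.append(a.data[chrom][ok])
        ys.append(b.data[chrom][ok])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _interval_bins(iv: GenomicInterval, bin_width: int) -> tuple[int, int]:
    """Inclusive first/last bin index overlapped by an interval."""
    return iv.start // bin_width, (iv.end - 1) // bin_width


def aggregate(track: BinTrack, intervals, stat: str = "mean") -> np.ndarray:
    """Per-interval statistic over the bins each interval overlaps (>= 1 bp).

    The mean is unweighted over overlapping unmasked bins — the convention
    that makes DNS values comparable across regions of different size. An
    interval overlapping zero unmasked bins yields nan.
    """
    if stat not in ("mean", "sum"):
        raise TrackError(f"unknown stat {stat!r}")
    # prefix sums make each interval O(1)
    val_ps: dict[str, np.ndarray] = {}
    cnt_ps: dict[str, np.ndarray] = {}
    out = np.full(len(intervals), np.nan)
    for i, iv in enumerate(intervals):
        chrom = iv.chrom
        if chrom not in track.data:
            raise GenomeError(f"interval on unknown chromosome {chrom!r}")
        if chrom not in val_ps:
            unmasked = ~track.mask[chrom]
            v = np.where(unmasked, track.data[chrom], 0.0)
            val_ps[chrom] = np.concatenate(([0.0], np.cumsum(v)))
            cnt_ps[chrom] = np.concatenate(([0], np.cumsum(unmasked)))
        track.assembly.validate(iv)
        b0, b1 = _interval_bins(iv, track.bin_width)
        s = val_ps[chrom][b1 + 1] - val_ps[chrom][b0]
        n = cnt_ps[chrom][b1 + 1] - cnt_ps[chrom][b0]
        if n == 0:
            continue
        out[i] = s if stat == "sum" else s / n
    return out


def window_summary(track: BinTrack, window: int, step: int | None = None):
    """Mean track value in tiling (step == window) or sliding windows.

    Returns (intervals, means, partial_flags); the terminal partial window
    of each chromosome is retained and flagged.
    """
    if step is None:
        step = window
    if window < track.bin_width or window % track.bin_width or step % track.bin_width:
        raise TrackError("window and step must be positive multiples of bin_width")
    ivs: list[GenomicInterval] = []
    partial: list[bool] = []
    for chrom in track.assembly:
        L = track.assembly.length(chrom)
        start = 0
        while start < L:
            end = min(start + window, L)
            ivs.append(GenomicInterval(chrom, start, end))
            partial.append(end - start < window)
            start += step
    means = aggregate(track, ivs, stat="mean")
    return ivs, means, np.asarray(partial)


def compute_dns(samples: list[DigestSample], assembly: GenomeAssembly,
                bin_width: int = 10):
    """Run the full scoring path: coverage -> CPM -> subtraction -> average.

    samples must contain one light and one heavy digest per replicate.
    Returns (per_replicate_dns: dict rep -> DNSTrack, averaged DNSTrack,
    raw coverage tracks dict (rep, digest) -> BinTrack).
    """
    by_key = {(s.replicate, s.digest): s for s in samples}
    reps = sorted({s.replicate for s in samples})
    for r in reps:
        for d in ("light", "heavy"):
            if (r, d) not in by_key:
                raise TrackError(f"missing {d} digest for replicate {r}")
    raw = {k: bin_coverage(s.reads, assembly, bin_width) for k, s in by_key.items()}
    mask = coverage_mask(list(raw.values()))
    per_rep: dict[int, DNSTrack] = {}
    for r in reps:
        norm = {d: normalize_cpm(raw[(r, d)], by_key[(r, d)].total_mapped)
                for d in ("light", "heavy")}
        diff = dns_score(norm["light"], norm["heavy"])
        per_rep[r] = DNSTrack(assembly, bin_width, data=diff.data, mask=mask,
                              provenance=(r,))
    avg = average_replicates(list(per_rep.values()), provenance=tuple(reps))
    return per_rep, avg, raw
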