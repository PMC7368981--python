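"""Centromere prediction from the joint chromatin signature.

Triticeae centromeres carry a dense block of the Gypsy-lineage Cereba
retrotransposon, show depressed read coverage under both MNase digest
levels, and — distinctively — an elevated DNS score (light exceeds heavy)
where CENH3 nucleosomes reside. The predictor works at 1-Mb window
resolution: candidate regions are maximal runs of windows whose Cereba
density clears a per-chromosome quantile, and the predicted point is the
centre of the window maximizing smoothed DNS within the candidates. The
DNS peak, not the coverage minimum, is the primary locator; when no Cereba
candidates exist the global DNS argmax is reported with a low-confidence
flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import BinTrack, TrackError, window_summary
from .genome import GenomicInterval
from .intergenic import _covered_fraction_track


@dataclass
class CentromereCall:
    chrom: str
    predicted_point: int
    candidate_regions: list = field(default_factory=list)
    low_confidence: bool = False
    in_cenh3: bool | None = None
    diagnostics: dict = field(default_factory=dict)


def cereba_density(tes, assembly, window: int = 1_000_000) -> BinTrack:
    """Per-window fraction of bp covered by Cereba-flagged TEs.

    Overlapping elements count once (coverage, not sum).
    """
    cereba = [t.interval for t in tes if t.is_cereba]
    if not cereba:
        warnings.warn("no Cereba-flagged TE annotations; density is zero")
    return _covered_fraction_track(cereba, assembly, window)


def depth_track(light: BinTrack, heavy: BinTrack, window: int = 1_000_000) -> BinTrack:
    """Window mean of summed (light + heavy) normalized coverage."""
    if not light.congruent(heavy):
        raise TrackError("light/heavy tracks are not congruent")
    total = light.copy_like({c: light.data[c] + heavy.data[c] for c in light.assembly})
    ivs, means, _ = window_summary(total, window)
    out = BinTrack(light.assembly, window)
    for iv, m in zip(ivs, means):
        out.data[iv.chrom][iv.start // window] = m
    return out


def _smooth(x: np.ndarray, k: int) -> np.ndarray:
    if k <= 1:
        return x.astype(float)
    kernel = np.ones(k) / k
    pad = k // 2
    xp = np.pad(x.astype(float), pad, mode="edge")
    s = np.convolve(xp, kernel, mode="same")
    return s[pad:pad + x.size] if pad else s


def predict_centromere(dns_windows: BinTrack, cereba: BinTrack, depth: BinTrack,
                       smoothing: int = 1_000_000,
                       density_quantile: float = 0.90,
                       cenh3: dict | None = None) -> list[CentromereCall]:
    """Call one centromere per chromosome from window-level tracks.

    dns_windows, cereba and depth must share the window resolution.
    Candidates = runs of windows with Cereba density >= the per-chromosome
    density_quantile of nonzero densities. Ties in smoothed DNS within 1%
    resolve to the lower-depth window, then to the smaller coordinate.
    cenh3 (chrom -> GenomicInterval) marks calls falling inside the known
    CENH3 interval.
    """
    w = dns_windows.bin_width
    if cereba.bin_width != w or depth.bin_width != w:
        raise TrackError("tracks must share window resolution")
    k = max(1, smoothing // w)
    calls = []
    for chrom in dns_windows.assembly:
        d = _smooth(dns_windows.data[chrom], k)
        dens = cereba.data[chrom]
        dep = depth.data[chrom]
        nz = dens[dens > 0]
        candidates = []
        if nz.size:
            # cap at half the chromosome max so a dense core split across
            # adjacent windows stays one candidate run
            thr = min(float(np.quantile(nz, density_quantile)),
                      0.5 * float(nz.max()))
            sel = dens >= thr
            # maximal runs of selected windows
            idx = np.flatnonzero(sel)
            if idx.size:
                breaks = np.flatnonzero(np.diff(idx) > 1)
                starts = np.concatenate(([0], breaks + 1))
                ends = np.concatenate((breaks, [idx.size - 1]))
                for s, e in zip(starts, ends):
                    lo = idx[s] * w
                    hi = min((idx[e] + 1) * w, dns_windows.assembly.length(chrom))
                    candidates.append(GenomicInterval(chrom, lo, hi))
        low_conf = not candidates
        if candidates:
            eligible = np.zeros(d.size, dtype=bool)
            for iv in candidates:
                eligible[iv.start // w:(iv.end - 1) // w + 1] = True
        else:
            eligible = np.ones(d.size, dtype=bool)
        scores = np.where(eligible, d, -np.inf)
        best = float(scores.max())
        # ties within 1% of the score range (shift-invariant)
        span = float(d.max() - d.min()) if d.size > 1 else 0.0
        near = np.flatnonzero(scores >= best - 0.01 * span)
        if near.size > 1:  # tie: lower depth, then smaller coordinate
            near = near[dep[near] == dep[near].min()]
        bi = int(near[0])
        centre = bi * w + min(w, dns_windows.assembly.length(chrom) - bi * w) // 2
        call = CentromereCall(chrom, centre, candidates, low_conf)
        if cenh3 is not None and chrom in cenh3:
            iv = cenh3[chrom]
            call.in_cenh3 = iv.start <= centre < iv.end
        call.diagnostics = {"smoothed_dns": d, "cereba_density": dens, "depth": dep}
        calls.append(call)
    return calls
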