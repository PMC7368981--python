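"""Synthetic allopolyploid genome with full ground truth.

Generates a miniature hexaploid-style genome (default: homoeologous groups
1 and 2 across subgenomes A, B, D; six 8-Mb chromosomes) whose statistical
structure mirrors the features the pipeline is meant to detect:

* a per-bin accessibility surface a(x) combining a telomere->centromere
  gradient, gene-proximity bumps decaying exponentially (rate kappa) to an
  intergenic background, family-specific TE effects, planted MSF/MRF
  footprints and an elevated centromeric core;
* light/heavy digest rates lambda = depth * exp(+-a(x)/2), so the expected
  DNS score tracks a(x) in sign and magnitude while total coverage is
  a-independent to first order; inside the CENH3 interval both rates are
  scaled down by a depth factor delta, producing the read-coverage dip with
  light > heavy characteristic of centromeric chromatin;
* a Cereba-family TE block dense inside the CENH3 interval (sparser across
  the surrounding pericentromere), with an optional decoy Cereba block on
  one chromosome;
* homoeologous triplets with planted balanced/dominant/suppressed
  expression-bias categories, whose focal homoeolog's promoter
  accessibility and expression are shifted jointly;
* genic SNPs and phenotypes whose genetic variance is concentrated in
  open-chromatin (or closed-chromatin) SNP sets.

Everything is deterministic under (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import DigestSample
from .genome import (ChromosomeSegments, GenomeAssembly, GenomicInterval,
                     GeneModel, TEAnnotation, SEGMENT_LABELS)


@dataclass
class TEFamilySpec:
    family: str
    effect: float  # additive accessibility effect over the element body
    weight: float  # relative placement frequency
    mean_len: int = 4000


DEFAULT_TE_FAMILIES = (
    TEFamilySpec("RLG_famc1", -0.40, 3.0, 6000),
    TEFamilySpec("RLG_famc4", -0.20, 2.0, 5000),
    TEFamilySpec("RLC_famc2", +0.15, 2.0, 5000),
    TEFamilySpec("RIX_famc5", -0.10, 1.0, 3000),
    TEFamilySpec("DTC_famc3", +0.30, 1.5, 2500),
    TEFamilySpec("DTM_famc6", +0.20, 1.0, 1500),
)

CEREBA_FAMILY = "RLG_famc8"


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults define the standard study conditions."""

    groups: tuple = (1, 2)                  # homoeologous chromosome groups
    subgenomes: tuple = ("A", "B", "D")
    chrom_length: int = 8_000_000
    bin_width: int = 10
    segment_fracs: tuple = (0.20, 0.25, 0.10, 0.25, 0.20)  # R1,R2a,C,R2b,R3
    cenh3_frac_of_c: float = 0.5
    # gene density gradient (genes per Mb): distal 6x centromeric
    genes_per_mb: dict = field(default_factory=lambda: {
        "R1": 18.0, "R2a": 8.0, "C": 3.0, "R2b": 8.0, "R3": 18.0})
    gene_len_range: tuple = (2500, 5000)
    gene_min_spacing: int = 10_000          # start-to-start in the template
    homoeolog_jitter: int = 2000
    # accessibility surface
    gene_amp: float = 0.35
    gene_amp_sd: float = 0.35               # per-gene spread of openness
    kappa: float = 3000.0                   # bp decay of the gene bump
    grad_telomere: float = 0.25
    grad_centromere: float = -0.25
    te_families: tuple = DEFAULT_TE_FAMILIES
    te_per_mb: float = 25.0
    # planted footprints
    n_footprints: int = 100
    footprint_effect: float = 1.1           # |a| units, ~3 genome SD in DNS
    footprint_len_range: tuple = (400, 1000)
    # centromere
    cen_depth_factor: float = 0.3
    cen_access: float = 0.5
    cereba_core_cov: float = 0.6
    cereba_flank_cov: float = 0.08
    cereba_len: int = 5000
    decoy_cereba_chrom: str | None = None   # extra Cereba block off-centromere
    # triplets
    triplet_fracs: dict = field(default_factory=lambda: {
        "balanced": 0.4, "A.dominant": 0.1, "B.dominant": 0.1, "D.dominant": 0.1,
        "A.suppressed": 0.1, "B.suppressed": 0.1, "D.suppressed": 0.1})
    triplet_access_shift: float = 0.5
    dominant_expr_mult: float = 12.0
    suppressed_expr_mult: float = 0.05
    # expression model
    expr_alpha: float = 0.8                 # baseline log10 tpm
    expr_gamma: float = 1.0                 # slope on promoter accessibility
    expr_noise_sd: float = 0.25             # shared per-triplet (condition) noise
    expr_indep_sd: float = 0.08             # homoeolog-independent noise
    # switches for ablation
    gradient: bool = True
    te_effects: bool = True
    plant_footprints: bool = True
    centromere_signal: bool = True

    def chrom_names(self) -> list[str]:
        return [f"{g}{s}" for g in self.groups for s in self.subgenomes]


@dataclass
class PlantedFootprint:
    interval: GenomicInterval
    kind: str   # MSF | MRF
    effect: float


class SyntheticTruth:
    """Ground truth of one generated genome."""

    def __init__(self, config: SyntheticConfig, seed: int):
        self.config = config
        self.seed = seed
        self.assembly: GenomeAssembly = None
        self.segments: ChromosomeSegments = None
        self.genes: list[GeneModel] = []
        self.tes: list[TEAnnotation] = []
        self.footprints: list[PlantedFootprint] = []
        self.triplets: pd.DataFrame = None     # gene_A/B/D + planted category
        self.gene_amps: dict[str, float] = {}  # planted per-gene openness
        self.accessibility: dict[str, np.ndarray] = {}

    def cenh3(self, chrom: str) -> GenomicInterval:
        return self.segments.cenh3(chrom)

    def to_dict(self) -> dict:
        cfg = asdict(self.config)
        cfg["te_families"] = [asdict(t) for t in self.config.te_families]
        return {
            "seed": self.seed,
            "config": cfg,
            "chromosomes": [(c, self.assembly.length(c)) for c in self.assembly],
            "genes": [(g.gene_id, g.chrom, g.interval.start, g.interval.end,
                       g.strand, g.cds_start, g.cds_end) for g in self.genes],
            "gene_amps": {k: round(v, 6) for k, v in self.gene_amps.items()},
            "tes": [(t.chrom, t.interval.start, t.interval.end, t.family,
                     t.is_cereba) for t in self.tes],
            "footprints": [(f.interval.chrom, f.interval.start, f.interval.end,
                            f.kind, f.effect) for f in self.footprints],
            "triplets": self.triplets.to_dict(orient="list") if self.triplets is not None else None,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=0, sort_keys=True)


def _segments_for(chrom: str, L: int, fracs, cenh3_frac) -> tuple[dict, GenomicInterval]:
    bounds = np.round(np.cumsum((0,) + tuple(fracs)) * L).astype(int)
    bounds[-1] = L
    segs = {label: GenomicInterval(chrom, int(bounds[i]), int(bounds[i + 1]))
            for i, label in enumerate(SEGMENT_LABELS)}
    c = segs["C"]
    half = int(len(c) * cenh3_frac / 2)
    mid = c.midpoint
    cen = GenomicInterval(chrom, max(c.start, mid - half), min(c.end, mid + half))
    return segs, cen


def _template_genes(rng, cfg: SyntheticConfig, segs: dict) -> list[tuple[int, int, str]]:
    """(start, length, strand) template positions for one homoeologous group."""
    starts = []
    for label in SEGMENT_LABELS:
        iv = segs[label]
        n = int(round(cfg.genes_per_mb[label] * len(iv) / 1e6))
        if n:
            starts.extend(rng.integers(iv.start, iv.end, n))
    starts = np.sort(np.asarray(starts, dtype=np.int64))
    keep = []
    last = -10 ** 12
    for s in starts:
        if s - last >= cfg.gene_min_spacing:
            keep.append(int(s))
            last = s
    out = []
    for s in keep:
        length = int(rng.integers(*cfg.gene_len_range))
        strand = "+" if rng.random() < 0.5 else "-"
        out.append((s, length, strand))
    return out


def _gene_blocks(genes, chrom) -> np.ndarray:
    ivs = sorted((g.interval.start, g.interval.end) for g in genes if g.chrom == chrom)
    merged = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64).reshape(-1, 2)


def _gene_blocks_with_amps(genes, chrom, amps):
    items = sorted((g.interval.start, g.interval.end, amps.get(g.gene_id, 0.0))
                   for g in genes if g.chrom == chrom)
    merged = []
    for s, e, a in items:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] = max(merged[-1][2], a)
        else:
            merged.append([s, e, a])
    blocks = np.asarray([[s, e] for s, e, _ in merged], dtype=np.int64).reshape(-1, 2)
    amps_arr = np.asarray([a for _, _, a in merged], dtype=float)
    return blocks, amps_arr


def _distance_to_blocks(mid: np.ndarray, blocks: np.ndarray) -> np.ndarray:
    """Distance from positions to the nearest block (0 inside)."""
    if blocks.size == 0:
        return np.full(mid.size, np.inf)
    starts, ends = blocks[:, 0], blocks[:, 1]
    i = np.searchsorted(starts, mid, side="right")
    d_next = np.where(i < starts.size, starts[np.minimum(i, starts.size - 1)] - mid,
                      np.iinfo(np.int64).max).astype(float)
    prev = np.maximum(i - 1, 0)
    inside = (i > 0) & (mid < ends[prev])
    d_prev = np.where(i > 0, mid - ends[prev] + 1, np.iinfo(np.int64).max).astype(float)
    d = np.minimum(d_next, d_prev)
    d[inside] = 0.0
    return d


def _distance_and_nearest(mid: np.ndarray, blocks: np.ndarray):
    """(distance, index of the nearest block) per position."""
    if blocks.size == 0:
        return np.full(mid.size, np.inf), np.full(mid.size, -1)
    starts, ends = blocks[:, 0], blocks[:, 1]
    i = np.searchsorted(starts, mid, side="right")
    nxt = np.minimum(i, starts.size - 1)
    d_next = np.where(i < starts.size, starts[nxt] - mid,
                      np.iinfo(np.int64).max).astype(float)
    prev = np.maximum(i - 1, 0)
    inside = (i > 0) & (mid < ends[prev])
    d_prev = np.where(i > 0, mid - ends[prev] + 1,
                      np.iinfo(np.int64).max).astype(float)
    take_prev = d_prev <= d_next
    d = np.where(take_prev, d_prev, d_next)
    idx = np.where(take_prev, prev, nxt)
    d[inside] = 0.0
    idx[inside] = prev[inside]
    return d, idx


def generate_truth(config: SyntheticConfig | None = None, seed: int = 0) -> SyntheticTruth:
    """Build the genome, annotations, planted features and a(x)."""
    cfg = config or SyntheticConfig()
    if abs(sum(cfg.segment_fracs) - 1.0) > 1e-9:
        raise ValueError("segment fractions must sum to 1")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(cfg, seed)
    chroms = cfg.chrom_names()
    truth.assembly = GenomeAssembly([(c, cfg.chrom_length) for c in chroms])
    truth.segments = ChromosomeSegments(truth.assembly)

    seg_map: dict[str, dict] = {}
    for chrom in chroms:
        segs, cen = _segments_for(chrom, cfg.chrom_length, cfg.segment_fracs,
                                  cfg.cenh3_frac_of_c)
        truth.segments.set_chromosome(chrom, segs, cen)
        seg_map[chrom] = segs

    # --- genes: one template per homoeologous group, jittered per subgenome
    triplet_rows = []
    for group in cfg.groups:
        template = _template_genes(rng, cfg, seg_map[f"{group}{cfg.subgenomes[0]}"])
        template_amps = np.clip(rng.normal(cfg.gene_amp, cfg.gene_amp_sd,
                                           len(template)), -0.6, 1.5)
        ids_by_sub = {}
        for sub in cfg.subgenomes:
            chrom = f"{group}{sub}"
            ids = []
            for i, (s, length, strand) in enumerate(template):
                jit = int(rng.integers(-cfg.homoeolog_jitter, cfg.homoeolog_jitter + 1))
                start = int(np.clip(s + jit, 1000, cfg.chrom_length - length - 1000))
                iv = GenomicInterval(chrom, start, start + length, strand)
                gid = f"gene_{chrom}_{i:04d}"
                truth.genes.append(GeneModel(gid, iv, start + 200,
                                             start + length - 200))
                truth.gene_amps[gid] = float(template_amps[i])
                ids.append(gid)
            ids_by_sub[sub] = ids
        cats = list(cfg.triplet_fracs)
        probs = np.array([cfg.triplet_fracs[c] for c in cats], dtype=float)
        probs /= probs.sum()
        for i in range(len(template)):
            cat = cats[int(rng.choice(len(cats), p=probs))]
            triplet_rows.append({"gene_A": ids_by_sub["A"][i] if "A" in ids_by_sub else None,
                                 "gene_B": ids_by_sub["B"][i] if "B" in ids_by_sub else None,
                                 "gene_D": ids_by_sub["D"][i] if "D" in ids_by_sub else None,
                                 "category": cat})
    truth.triplets = pd.DataFrame(triplet_rows)

    # --- TEs
    fams = list(cfg.te_families)
    weights = np.array([f.weight for f in fams], dtype=float)
    weights /= weights.sum()
    for chrom in chroms:
        blocks = _gene_blocks(truth.genes, chrom)
        n_te = int(round(cfg.te_per_mb * cfg.chrom_length / 1e6))
        for _ in range(n_te):
            fam = fams[int(rng.choice(len(fams), p=weights))]
            length = int(np.clip(rng.normal(fam.mean_len, fam.mean_len * 0.3),
                                 500, 20000))
            for _attempt in range(40):
                start = int(rng.integers(0, cfg.chrom_length - length))
                d = _distance_to_blocks(np.array([start, start + length - 1]), blocks)
                if d.min() > 500:
                    truth.tes.append(TEAnnotation(
                        GenomicInterval(chrom, start, start + length), fam.family))
                    break
        # Cereba: dense in the CENH3 core, sparse across the pericentromere
        cen = truth.segments.cenh3(chrom)
        c_seg = seg_map[chrom]["C"]
        for region, cov in ((cen, cfg.cereba_core_cov),
                            (c_seg, cfg.cereba_flank_cov)):
            n = int(cov * len(region) / cfg.cereba_len)
            for _ in range(n):
                start = int(rng.integers(region.start,
                                         max(region.start + 1, region.end - cfg.cereba_len)))
                end = min(start + cfg.cereba_len, region.end)
                truth.tes.append(TEAnnotation(GenomicInterval(chrom, start, end),
                                              CEREBA_FAMILY, is_cereba=True))
        if cfg.decoy_cereba_chrom == chrom:
            r1 = seg_map[chrom]["R2a"]
            base = (r1.start + r1.end) // 2
            n = int(cfg.cereba_core_cov * 400_000 / cfg.cereba_len)
            for j in range(n):
                start = base + j * int(cfg.cereba_len / cfg.cereba_core_cov)
                truth.tes.append(TEAnnotation(
                    GenomicInterval(chrom, start, start + cfg.cereba_len),
                    CEREBA_FAMILY, is_cereba=True))

    # --- planted footprints: intergenic, clear of genes, TEs and each other
    if cfg.plant_footprints and cfg.n_footprints:
        te_blocks = {c: _gene_blocks_from_ivs(
            [t.interval for t in truth.tes if t.chrom == c]) for c in chroms}
        gene_blk = {c: _gene_blocks(truth.genes, c) for c in chroms}
        per_chrom = np.full(len(chroms), cfg.n_footprints // len(chroms))
        per_chrom[:cfg.n_footprints % len(chroms)] += 1
        for chrom, n_fp in zip(chroms, per_chrom):
            placed = 0
            guard = 0
            occupied = []
            while placed < n_fp and guard < 5000:
                guard += 1
                length = int(rng.integers(*cfg.footprint_len_range))
                start = int(rng.integers(0, cfg.chrom_length - length))
                pts = np.array([start - 2000, start + length + 2000])
                if _distance_to_blocks(pts, gene_blk[chrom]).min() < 5000:
                    continue
                if _distance_to_blocks(pts, te_blocks[chrom]).min() < 1000:
                    continue
                cen = truth.segments.cenh3(chrom)
                if start < cen.end + 2000 and start + length > cen.start - 2000:
                    continue
                if any(abs(start - s) < 5000 for s, _ in occupied):
                    continue
                kind = "MSF" if rng.random() < 0.5 else "MRF"
                eff = cfg.footprint_effect if kind == "MSF" else -cfg.footprint_effect
                truth.footprints.append(PlantedFootprint(
                    GenomicInterval(chrom, start, start + length), kind, eff))
                occupied.append((start, length))
                placed += 1

    # --- accessibility surface
    w = cfg.bin_width
    for chrom in chroms:
        n = -(-cfg.chrom_length // w)
        mids = np.arange(n) * w + w // 2
        a = np.zeros(n)
        blocks, block_amps = _gene_blocks_with_amps(truth.genes, chrom,
                                                    truth.gene_amps)
        d, near = _distance_and_nearest(mids, blocks)
        q = np.exp(-d / cfg.kappa)
        amp_near = np.where(near >= 0, block_amps[np.maximum(near, 0)],
                            cfg.gene_amp)
        if cfg.gradient:
            cen_mid = truth.segments.cenh3(chrom).midpoint
            maxd = max(cen_mid, cfg.chrom_length - cen_mid)
            rel = np.abs(mids - cen_mid) / maxd      # 0 at centromere, 1 at telomere
            grad = cfg.grad_centromere + (cfg.grad_telomere - cfg.grad_centromere) * rel
        else:
            grad = np.zeros(n)
        a = amp_near * q + grad * (1.0 - q)
        if cfg.te_effects:
            for t in truth.tes:
                if t.chrom != chrom:
                    continue
                fam_eff = next((f.effect for f in fams if f.family == t.family), 0.0)
                if fam_eff:
                    b0, b1 = t.interval.start // w, (t.interval.end - 1) // w
                    a[b0:b1 + 1] += fam_eff
        # planted footprints are set to their target amplitude (not added),
        # so each realizes the same DNS contrast wherever it lands
        for fp in truth.footprints:
            if fp.interval.chrom != chrom:
                continue
            b0, b1 = fp.interval.start // w, (fp.interval.end - 1) // w
            a[b0:b1 + 1] = fp.effect
        # triplet promoter modifiers (regions b/c up for dominant homoeolog,
        # a/b/d down for suppressed)
        a = _apply_triplet_shifts(a, truth, chrom, cfg)
        if cfg.centromere_signal:
            cen = truth.segments.cenh3(chrom)
            b0, b1 = cen.start // w, (cen.end - 1) // w
            a[b0:b1 + 1] += cfg.cen_access
        truth.accessibility[chrom] = a
    return truth


def _gene_blocks_from_ivs(ivs) -> np.ndarray:
    pairs = sorted((iv.start, iv.end) for iv in ivs)
    merged = []
    for s, e in pairs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64).reshape(-1, 2)


def _apply_triplet_shifts(a, truth: SyntheticTruth, chrom, cfg: SyntheticConfig):
    genes = {g.gene_id: g for g in truth.genes}
    w = cfg.bin_width
    sub = truth.assembly.genome_of(chrom)
    col = f"gene_{sub}"
    if truth.triplets is None or col not in truth.triplets.columns:
        return a
    from .genic import _oriented_window
    for row in truth.triplets.itertuples(index=False):
        cat = row.category
        if cat == "balanced":
            continue
        focal_sub, mode = cat.split(".")
        gid = getattr(row, col)
        if gid is None or focal_sub != sub:
            continue
        g = genes[gid]
        if g.chrom != chrom:
            continue
        if mode == "dominant":
            windows = [(-500, 500)]
            shift = cfg.triplet_access_shift
        else:
            windows = [(-1000, 0), (500, 1000)]
            shift = -cfg.triplet_access_shift
        for u, v in windows:
            s, e = _oriented_window(g, u, v)
            s, e = max(0, s), min(cfg.chrom_length, e)
            if s < e:
                a[s // w:(e - 1) // w + 1] += shift
    return a


def coverage_to_rate(fold_coverage: float, bin_width: int = 10,
                     frag_len: float = 150.0) -> float:
    """Mean fragments per bin giving a target fold coverage."""
    return fold_coverage * bin_width / frag_len


def simulate_reads(truth: SyntheticTruth, mean_depth: float = 2.0,
                   seed: int = 0, replicates=(1, 2)) -> list[DigestSample]:
    """Draw 2 replicates x light/heavy digest fragment sets.

    mean_depth is the expected fragment count per 10-bp bin at a(x) = 0
    (2.0 ~ 30x fold coverage with 150-bp fragments). Per bin, fragment
    counts are Poisson with rate depth * exp(+-a/2) (times the centromeric
    depth factor inside CENH3); fragment midpoints are uniform within the
    bin and lengths ~ Normal(150, 20) clipped to the 100-200 bp size
    selection.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    cfg = truth.config
    rng = np.random.default_rng(seed)
    w = cfg.bin_width
    samples = []
    for rep in replicates:
        for digest, sign in (("light", +0.5), ("heavy", -0.5)):
            reads: dict[str, np.ndarray] = {}
            total = 0
            for chrom in truth.assembly:
                a = truth.accessibility[chrom]
                lam = mean_depth * np.exp(sign * a)
                if cfg.centromere_signal:
                    cen = truth.cenh3(chrom)
                    b0, b1 = cen.start // w, (cen.end - 1) // w
                    lam = lam.copy()
                    lam[b0:b1 + 1] *= cfg.cen_depth_factor
                counts = rng.poisson(lam)
                bins = np.repeat(np.arange(counts.size), counts)
                if bins.size == 0:
                    reads[chrom] = np.empty((0, 2), dtype=np.int64)
                    continue
                mid = bins * w + rng.integers(0, w, bins.size)
                lens = np.clip(rng.normal(150.0, 20.0, bins.size), 100, 200).astype(np.int64)
                start = np.maximum(mid - lens // 2, 0)
                end = np.minimum(start + lens, truth.assembly.length(chrom))
                reads[chrom] = np.stack([start, end], axis=1)
                total += bins.size
            samples.append(DigestSample(rep, digest, reads, max(total, 1)))
    return samples


def _promoter_accessibility(truth: SyntheticTruth) -> pd.Series:
    """Mean a(x) over the 500-bp region upstream of each CDS start."""
    from .genic import _oriented_window
    w = truth.config.bin_width
    vals = {}
    for g in truth.genes:
        s, e = _oriented_window(g, -500, 0)
        s, e = max(0, s), min(truth.assembly.length(g.chrom), e)
        a = truth.accessibility[g.chrom]
        vals[g.gene_id] = float(a[s // w:(e - 1) // w + 1].mean()) if s < e else 0.0
    return pd.Series(vals)


def simulate_expression(truth: SyntheticTruth, seed: int = 0):
    """(ExpressionTable Series, TripletTable DataFrame).

    log10 tpm = alpha + gamma * promoter accessibility + noise; the focal
    homoeolog of each non-balanced triplet is additionally multiplied by
    the dominant (or suppressed) expression factor, keeping accessibility
    and expression shifts aligned.
    """
    cfg = truth.config
    rng = np.random.default_rng(seed)
    prom = _promoter_accessibility(truth)
    # condition noise is shared by the three homoeologs of a triplet (the
    # table emulates replicate-averaged tpm); only a small residual is
    # homoeolog-independent
    shared = {}
    for ti, row in truth.triplets.iterrows():
        eps = rng.normal(0, cfg.expr_noise_sd)
        for col in ("gene_A", "gene_B", "gene_D"):
            gid = getattr(row, col, None) if hasattr(row, col) else row.get(col)
            if gid is not None:
                shared[gid] = eps
    noise = np.array([shared.get(g, 0.0) for g in prom.index])
    noise = noise + rng.normal(0, cfg.expr_indep_sd, prom.size)
    log_tpm = cfg.expr_alpha + cfg.expr_gamma * prom + noise
    tpm = pd.Series(10.0 ** log_tpm, index=prom.index)
    for row in truth.triplets.itertuples(index=False):
        if row.category == "balanced":
            continue
        sub, mode = row.category.split(".")
        gid = getattr(row, f"gene_{sub}")
        if gid is None:
            continue
        mult = cfg.dominant_expr_mult if mode == "dominant" else cfg.suppressed_expr_mult
        tpm[gid] *= mult
    triplets = truth.triplets[[c for c in ("gene_A", "gene_B", "gene_D")
                               if c in truth.triplets.columns]].copy()
    return tpm, triplets


def simulate_genotypes_phenotypes(truth: SyntheticTruth, n_individuals: int = 300,
                                  m_snps: int = 3000, h2_open: float = 0.5,
                                  h2_closed: float = 0.1, seed: int = 0):
    """Genic SNPs and a phenotype with chromatin-stratified genetic variance.

    SNP positions are uniform within gene bodies +- 1 kb; genotypes are iid
    Binomial(2, p), p ~ U(0.05, 0.5). Causal effects are drawn only for
    SNPs whose a(x) falls in the top (h2_open) or bottom (h2_closed)
    quintile of the genic-SNP accessibility distribution; the phenotype is
    the sum of the two scaled genetic values plus normal noise.
    Returns (positions DataFrame, genotype matrix, phenotype DataFrame,
    truth dict with the causal sets).
    """
    if not (0 <= h2_open < 1 and 0 <= h2_closed < 1 and h2_open + h2_closed < 1):
        raise ValueError("heritabilities must lie in [0,1) and sum below 1")
    cfg = truth.config
    rng = np.random.default_rng(seed)
    w = cfg.bin_width
    envelopes = []
    for g in truth.genes:
        s = max(0, g.interval.start - 1000)
        e = min(truth.assembly.length(g.chrom), g.interval.end + 1000)
        envelopes.append((g.chrom, s, e))
    lens = np.array([e - s for _, s, e in envelopes], dtype=float)
    probs = lens / lens.sum()
    rows = []
    for _ in range(m_snps):
        chrom, s, e = envelopes[int(rng.choice(len(envelopes), p=probs))]
        rows.append((chrom, int(rng.integers(s, e))))
    pos = pd.DataFrame(rows, columns=["chrom", "pos"]).drop_duplicates()
    pos = pos.sort_values(["chrom", "pos"]).reset_index(drop=True)
    m = len(pos)
    p = rng.uniform(0.05, 0.5, m)
    G = rng.binomial(2, p, size=(n_individuals, m)).astype(float)
    acc = np.array([truth.accessibility[c][bp // w]
                    for c, bp in zip(pos["chrom"], pos["pos"])])
    order = np.argsort(acc, kind="stable")
    k = max(1, m // 5)
    closed_set = np.sort(order[:k])
    open_set = np.sort(order[-k:])
    y = rng.normal(0, np.sqrt(max(1e-12, 1 - h2_open - h2_closed)), n_individuals)
    causal = {}
    for name, idx, h2 in (("open", open_set, h2_open), ("closed", closed_set, h2_closed)):
        beta = rng.normal(0, 1, idx.size)
        gval = G[:, idx] @ beta
        sd = gval.std()
        if h2 > 0 and sd > 0:
            gval = gval / sd * np.sqrt(h2)
            y = y + gval
        causal[name] = {"snps": idx, "h2": h2}
    pheno = pd.DataFrame({"trait": y}, index=[f"ind{i:04d}" for i in range(n_individuals)])
    pheno.index.name = "individual"
    return pos, G, pheno, causal


def export_all(truth: SyntheticTruth, out_dir, mean_depth: float = 2.0,
               seed: int = 0, n_individuals: int = 120, m_snps: int = 800,
               h2_open: float = 0.5, h2_closed: float = 0.1) -> dict:
    """Write every pipeline input to out_dir (text formats only)."""
    import os
    from . import io as dio
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    def p(name):
        paths[name] = os.path.join(out_dir, name)
        return paths[name]

    dio.write_assembly(truth.assembly, p("assembly.tsv"))
    dio.write_segments(truth.segments, p("segments.tsv"))
    dio.write_gene_models_gff3(truth.genes, p("genes.gff3"))
    dio.write_te_annotations(truth.tes, p("tes.bed"))
    samples = simulate_reads(truth, mean_depth=mean_depth, seed=seed)
    for s in samples:
        name = f"reads_rep{s.replicate}_{s.digest}.bed"
        with open(p(name), "w") as fh:
            for chrom in truth.assembly:
                arr = s.reads.get(chrom)
                if arr is None:
                    continue
                for st, en in arr:
                    fh.write(f"{chrom}\t{st}\t{en}\n")
    tpm, triplets = simulate_expression(truth, seed=seed)
    dio.write_expression(tpm, p("expression.tsv"))
    triplets.to_csv(p("triplets.tsv"), sep="\t", index=False)
    pos, G, pheno, _causal = simulate_genotypes_phenotypes(
        truth, n_individuals=n_individuals, m_snps=m_snps,
        h2_open=h2_open, h2_closed=h2_closed, seed=seed)
    dio.write_snps(pos, G, pheno.index.tolist(), p("snps.tsv"))
    pheno.to_csv(p("phenotypes.tsv"), sep="\t")
    truth.save(p("truth.json"))
    return paths
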