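"""Chromatin-accessibility-stratified variance partitioning (GRM + REML).

The genome's 10-bp bins are ranked by DNS score and cut into quantile
groups (quintiles by default, each holding 20% of the scored genome).
Genic SNPs are assigned to the group of their containing bin; for the most
open and most closed groups, random SNP subsets build a genomic
relationship matrix (GRM) and a single-component animal model

    y = mu + g + e,   g ~ N(0, A sigma_g^2),   e ~ N(0, I sigma_e^2)

is fitted by restricted maximum likelihood, reporting V(G)/V(p) =
sigma_g^2 / (sigma_g^2 + sigma_e^2) per trait. The REML fit profiles the
restricted likelihood over the single variance ratio lambda =
sigma_g^2/sigma_e^2 after an eigendecomposition of A, so each fit is a
1-D maximization; standard errors come from the observed information of
the restricted likelihood via the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .core import DNSTrack


# ----------------------------------------------------------- genome ranking

def rank_genome_bins(dns: DNSTrack, n_bins: int = 5) -> dict[str, np.ndarray]:
    """Partition unmasked 10-bp bins into DNS-ranked quantile groups.

    Group 0 is the most closed (lowest DNS), group n_bins-1 the most open.
    Ties are broken by genomic order (stable sort), so group sizes differ
    by at most one bin. Returns chrom -> int array with -1 on masked bins.
    """
    chroms = list(dns.assembly)
    vals = []
    keys = []
    for ci, chrom in enumerate(chroms):
        ok = ~dns.mask[chrom]
        idx = np.flatnonzero(ok)
        vals.append(dns.data[chrom][idx])
        keys.append(np.stack([np.full(idx.size, ci), idx], axis=1))
    v = np.concatenate(vals)
    k = np.concatenate(keys)
    if v.size < n_bins:
        raise ValueError("fewer unmasked bins than groups")
    order = np.argsort(v, kind="stable")  # stable: ties stay in genomic order
    groups = np.minimum((np.arange(v.size) * n_bins) // v.size, n_bins - 1)
    labels = {chrom: np.full(dns.n_bins(chrom), -1, dtype=np.int32) for chrom in chroms}
    for rank, gi in zip(order, groups):
        ci, bi = k[rank]
        labels[chroms[ci]][bi] = gi
    return labels


def select_snps(pos: pd.DataFrame, G: np.ndarray, labels: dict, genes,
                assembly, bin_width: int = 10, flank: int = 1000,
                thin: int = 10_000, maf: float = 0.002) -> dict[int, np.ndarray]:
    """Filter SNPs and assign them to DNS groups.

    Filter order: MAF > maf -> thinning (first SNP per `thin`-bp genomic
    tile) -> genic restriction (gene body +- flank) -> group of the SNP's
    containing 10-bp bin (SNPs in masked bins are dropped). Returns
    group -> array of SNP column indices.
    """
    from .context import IntervalIndex
    from .genome import GenomicInterval
    m = G.shape[1]
    with np.errstate(invalid="ignore"):
        p = np.nanmean(G, axis=0) / 2.0
    maf_arr = np.minimum(p, 1 - p)
    keep = np.flatnonzero(np.nan_to_num(maf_arr) > maf)
    # thinning: first kept SNP per tile, per chromosome, in position order
    seen: set = set()
    thinned = []
    order = sorted(keep, key=lambda i: (pos.iloc[i]["chrom"], pos.iloc[i]["pos"]))
    for i in order:
        tile = (pos.iloc[i]["chrom"], int(pos.iloc[i]["pos"]) // thin)
        if tile in seen:
            continue
        seen.add(tile)
        thinned.append(i)
    # genic restriction
    envelopes = []
    for g in genes:
        s = max(0, g.interval.start - flank)
        e = min(assembly.length(g.chrom), g.interval.end + flank)
        envelopes.append(GenomicInterval(g.chrom, s, e))
    idx = IntervalIndex.from_intervals(envelopes)
    out: dict[int, list] = {}
    for i in thinned:
        chrom, bp = pos.iloc[i]["chrom"], int(pos.iloc[i]["pos"])
        if idx.covering(chrom, bp) < 0:
            continue
        lab = int(labels[chrom][bp // bin_width])
        if lab < 0:
            continue
        out.setdefault(lab, []).append(i)
    return {k: np.asarray(v, dtype=np.int64) for k, v in sorted(out.items())}


# ------------------------------------------------------------------- GRM

def grm(G: np.ndarray) -> np.ndarray:
    """VanRaden-style genomic relationship matrix A = Z Z^T / m.

    Z standardizes each SNP column by its allele frequency (mean 2p,
    divisor sqrt(2p(1-p))); missing genotypes are mean-imputed per SNP and
    monomorphic SNPs dropped.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] < 2:
        raise ValueError("need an individuals x SNPs matrix with >= 2 individuals")
    X = G.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    p = col_mean / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic")
    X = X[:, poly]
    p = p[poly]
    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    return Z @ Z.T / Z.shape[1]


# ------------------------------------------------------------------- REML

@dataclass
class GREMLResults:
    """Variance-component estimates from a single-GRM REML fit."""
    vg: float
    ve: float
    vg_vp: float
    se: float
    loglik: float
    n: int
    converged: bool
    clipped: bool
    model: "GREML" = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            "GREML variance components (REML)",
            f"  n individuals : {self.n}",
            f"  V(G)          : {self.vg:.6g}",
            f"  V(e)          : {self.ve:.6g}",
            f"  V(G)/V(p)     : {self.vg_vp:.4f}  (SE {self.se:.4f})",
            f"  restricted LL : {self.loglik:.4f}",
            f"  converged     : {self.converged}" + ("  [boundary]" if self.clipped else ""),
        ]
        return "\n".join(lines)


class GREML:
    """Single-component GREML model for one trait and one GRM.

    Parameters
    ----------
    y : phenotype vector (non-missing, aligned to A)
    A : genomic relationship matrix (symmetric PSD)

    fit() profiles the restricted likelihood over lambda = vg/ve using the
    eigendecomposition of A; X is an intercept (upstream BLUEs are assumed
    to have absorbed design effects).
    """

    def __init__(self, y: np.ndarray, A: np.ndarray):
        y = np.asarray(y, dtype=float).ravel()
        A = np.asarray(A, dtype=float)
        if A.shape != (y.size, y.size):
            raise ValueError("A must be n x n aligned with y")
        if y.size < 3:
            raise ValueError("need at least 3 individuals")
        evals, evecs = np.linalg.eigh(A)
        if evals.min() < -1e-6 * max(1.0, evals.max()):
            raise ValueError(f"A is not PSD (min eigenvalue {evals.min():.3g})")
        self.y = y
        self.A = A
        self.d = np.maximum(evals, 0.0)
        self.ys = evecs.T @ y
        self.xs = evecs.T @ np.ones(y.size)
        self.n = y.size

    # profiled restricted log-likelihood pieces at ratio lam = vg/ve
    def _profile(self, lam: float):
        w = lam * self.d + 1.0
        xx = np.sum(self.xs ** 2 / w)
        xy = np.sum(self.xs * self.ys / w)
        yy = np.sum(self.ys ** 2 / w)
        Q = yy - xy * xy / xx
        nf = self.n - 1  # one fixed effect
        ve = Q / nf
        ll = -0.5 * (nf * np.log(ve) + np.sum(np.log(w)) + np.log(xx) + nf)
        return ll, ve

    def reml_loglik(self, vg: float, ve: float) -> float:
        """Restricted log-likelihood at explicit variance components."""
        w = vg * self.d + ve
        xx = np.sum(self.xs ** 2 / w)
        xy = np.sum(self.xs * self.ys / w)
        yy = np.sum(self.ys ** 2 / w)
        return -0.5 * (np.sum(np.log(w)) + np.log(xx) + (yy - xy * xy / xx))

    def fit(self, lam_bounds: tuple = (1e-8, 1e8)) -> GREMLResults:
        lo, hi = np.log(lam_bounds[0]), np.log(lam_bounds[1])
        res = minimize_scalar(lambda t: -self._profile(np.exp(t))[0],
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        lam = float(np.exp(res.x))
        ll, ve = self._profile(lam)
        vg = lam * ve
        h2 = vg / (vg + ve)
        clipped = res.x <= lo + 1e-6 or res.x >= hi - 1e-6
        h2 = min(max(h2, 0.0), 1.0)
        se = self._h2_se(vg, ve)
        return GREMLResults(vg=float(vg), ve=float(ve), vg_vp=float(h2),
                            se=float(se), loglik=float(ll), n=self.n,
                            converged=bool(res.success), clipped=bool(clipped),
                            model=self)

    def _h2_se(self, vg: float, ve: float) -> float:
        """Delta-method SE of vg/(vg+ve) from the numeric observed
        information of the restricted likelihood."""
        scale = max(vg + ve, 1e-12)
        h = 1e-5 * scale

        def ll(a, b):
            return self.reml_loglik(max(a, 1e-12 * scale), max(b, 1e-12 * scale))

        H = np.empty((2, 2))
        f0 = ll(vg, ve)
        H[0, 0] = (ll(vg + h, ve) - 2 * f0 + ll(vg - h, ve)) / h ** 2
        H[1, 1] = (ll(vg, ve + h) - 2 * f0 + ll(vg, ve - h)) / h ** 2
        H[0, 1] = H[1, 0] = (ll(vg + h, ve + h) - ll(vg + h, ve - h)
                             - ll(vg - h, ve + h) + ll(vg - h, ve - h)) / (4 * h ** 2)
        try:
            cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            return float("nan")
        if cov[0, 0] < 0 or cov[1, 1] < 0:
            return float("nan")
        grad = np.array([ve, -vg]) / (vg + ve) ** 2
        var = float(grad @ cov @ grad)
        return float(np.sqrt(var)) if var >= 0 else float("nan")


def reml_vg_vp(A: np.ndarray, y: np.ndarray) -> GREMLResults:
    """Convenience wrapper: fit the single-component model and return the
    V(G)/V(p) estimate."""
    return GREML(y, A).fit()


# ------------------------------------------------------------- experiment

def partition_experiment(snps_by_bin: dict, G: np.ndarray,
                         phenotypes: pd.DataFrame, bins=None,
                         n_snps: int = 10_000, reps: int = 50,
                         seed: int = 0) -> pd.DataFrame:
    """Repeated random-SNP GREML for the most closed vs most open groups.

    For each repetition and group, n_snps SNPs are sampled without
    replacement (all of them, with a warning, when fewer are available),
    a GRM is built and V(G)/V(p) estimated per trait. Returns a tidy frame
    (trait, bin, rep, vg_vp, se, clipped).
    """
    import warnings
    if bins is None:
        present = sorted(snps_by_bin)
        bins = (present[0], present[-1])
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(reps):
        for b in bins:
            pool = snps_by_bin[b]
            if pool.size < n_snps:
                warnings.warn(f"group {b}: only {pool.size} SNPs (< {n_snps}); using all")
                chosen = pool
            else:
                chosen = rng.choice(pool, n_snps, replace=False)
            A = grm(G[:, chosen])
            for trait in phenotypes.columns:
                y = phenotypes[trait].to_numpy(dtype=float)
                ok = np.isfinite(y)
                r = GREML(y[ok], A[np.ix_(ok, ok)]).fit()
                rows.append({"trait": trait, "bin": b, "rep": rep,
                             "vg_vp": r.vg_vp, "se": r.se, "clipped": r.clipped})
    return pd.DataFrame(rows)
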