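"""Pairwise r-squared, distance-binned LD decay, and the half-maximum distance.

For phased input r2 is the haplotype statistic D^2 / (pA pa pB pb); for
unphased input it is the squared Pearson correlation of dosage vectors over
samples called at both sites.  The decay curve bins all intra-chromosome
pairs by distance (pos_b - pos_a between 1-based positions); the half-decay
distance is the midpoint of the first bin, in increasing distance, whose
mean r2 drops to half the maximum bin mean.  That crossing rule — no curve
fitting — is this package's stated convention; an optional monotone
(isotonic) smoothing of the bin means is available because raw bins can be
noisy.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .variant_store import MISSING, GenotypeMatrix


class LdError(ValueError):
    pass


@dataclass(frozen=True)
class LdFilterSpec:
    """Per-population site filters applied before pairing."""

    maf_min: float = 0.05
    het_max: float = 0.88          # exclude observed heterozygosity > het_max
    missing_max: float = 0.25      # exclude sites with > 25% missing calls
    hwe_p_min: float = 0.001
    max_pair_distance: int = 500_000

    def __post_init__(self) -> None:
        for name in ("maf_min", "het_max", "missing_max", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise LdError(f"{name} must be in [0, 1]")


@dataclass
class DecayCurve:
    bin_edges: np.ndarray       # length n_bins + 1, bp
    mean_r2: np.ndarray         # NaN for empty bins
    n_pairs: np.ndarray
    r2_max: float
    half_decay_distance: Optional[float]   # bp; None if no bin crosses half max

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_start": self.bin_edges[:-1],
            "bin_end": self.bin_edges[1:],
            "mean_r2": self.mean_r2,
            "n_pairs": self.n_pairs,
        })

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Pairwise r2
# ---------------------------------------------------------------------------

def pair_r2(a: np.ndarray, b: np.ndarray, phased: bool = False) -> Optional[float]:
    """r-squared between two sites.

    ``a`` and ``b`` are per-sample dosage vectors (unphased) or per-haplotype
    allele vectors (phased), with MISSING (-1) for no-calls.  Returns None
    when either site is monomorphic over the jointly called entries.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    ok = (a != MISSING) & (b != MISSING)
    a = a[ok].astype(float)
    b = b[ok].astype(float)
    if a.size < 2:
        return None
    if phased:
        pa, pb = a.mean(), b.mean()
        if pa in (0.0, 1.0) or pb in (0.0, 1.0):
            return None
        d = (a * b).mean() - pa * pb
        return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))
    va, vb = a.var(), b.var()
    if va == 0.0 or vb == 0.0:
        return None
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


# ---------------------------------------------------------------------------
# Exact Hardy-Weinberg test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities not exceeding that of the observed
    configuration.  Monomorphic sites return 1.
    """
    n = n_het + n_hom_ref + n_hom_alt
    if n < 1:
        raise LdError("no called genotypes")
    n_alt = n_het + 2 * n_hom_alt
    n_ref = n_het + 2 * n_hom_ref
    if n_alt == 0 or n_ref == 0:
        return 1.0
    rare = min(n_alt, n_ref)

    def log_prob(h: int) -> float:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return (
            h * np.log(2.0)
            + lgamma(n + 1) - lgamma(h + 1) - lgamma(hom_rare + 1) - lgamma(hom_common + 1)
            + lgamma(n_alt + 1) + lgamma(n_ref + 1) - lgamma(2 * n + 1)
        )

    hets = range(rare % 2, rare + 1, 2)
    logs = np.array([log_prob(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = probs[list(hets).index(n_het)]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())


def hwe_site_p(gm: GenotypeMatrix, site: int, sample_index: np.ndarray) -> float:
    gt = gm.genotypes[site, sample_index]
    gt = gt[gt != MISSING]
    if gt.size < 5:
        raise LdError("need >= 5 called diploids for the exact HWE test")
    return hwe_exact_p(int((gt == 1).sum()), int((gt == 0).sum()), int((gt == 2).sum()))


# ---------------------------------------------------------------------------
# Site filters and the decay curve
# ---------------------------------------------------------------------------

def _passing_sites(gm: GenotypeMatrix, idx: np.ndarray, spec: LdFilterSpec) -> np.ndarray:
    gt = gm.genotypes[:, idx]
    called = gt != MISSING
    n = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, gt, 0).sum(axis=1) / (2.0 * n)
        het = (gt == 1).sum(axis=1) / n
        miss = 1.0 - n / len(idx)
        maf = np.minimum(p, 1.0 - p)
    keep = (
        (n >= 5)
        & (maf >= spec.maf_min - 1e-12)
        & (het <= spec.het_max + 1e-12)
        & (miss <= spec.missing_max + 1e-12)
    )
    for i in np.flatnonzero(keep):
        if hwe_site_p(gm, i, idx) < spec.hwe_p_min:
            keep[i] = False
    return keep


def _r2_matrix_phased(hap: np.ndarray) -> np.ndarray:
    """All-pairs haplotype r2 for a (sites x haplotypes) 0/1 matrix, no missing."""
    h = hap.astype(float)
    m = h.shape[1]
    p = h.mean(axis=1)
    pab = (h @ h.T) / m
    d = pab - np.outer(p, p)
    denom = np.outer(p * (1 - p), p * (1 - p))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, d * d / denom, np.nan)


def _r2_matrix_dosage(gt: np.ndarray) -> np.ndarray:
    """All-pairs squared Pearson correlation of dosage rows, no missing."""
    g = gt.astype(float)
    g = g - g.mean(axis=1, keepdims=True)
    sd = np.sqrt((g**2).mean(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (g @ g.T) / g.shape[1] / np.outer(sd, sd)
    return corr**2


def _isotonic_decreasing(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted pool-adjacent-violators fit, non-increasing."""
    vals = list(y)
    wts = list(w)
    sizes = [1] * len(y)
    i = 0
    while i < len(vals) - 1:
        if vals[i] < vals[i + 1] - 1e-15:
            tot = wts[i] + wts[i + 1]
            vals[i] = (vals[i] * wts[i] + vals[i + 1] * wts[i + 1]) / tot
            wts[i] = tot
            sizes[i] += sizes[i + 1]
            del vals[i + 1], wts[i + 1], sizes[i + 1]
            i = max(i - 1, 0)
        else:
            i += 1
    return np.repeat(vals, sizes)


def curve_from_bins(
    bin_edges: np.ndarray, mean_r2: np.ndarray, n_pairs: np.ndarray, smooth: bool = False
) -> DecayCurve:
    """Derive r2_max and the half-decay distance from binned means."""
    mean_r2 = np.asarray(mean_r2, dtype=float)
    n_pairs = np.asarray(n_pairs)
    filled = ~np.isnan(mean_r2)
    if not filled.any():
        raise LdError("no qualifying pairs")
    means = mean_r2.copy()
    if smooth:
        means[filled] = _isotonic_decreasing(means[filled], n_pairs[filled].astype(float))
    r2_max = float(np.nanmax(means))
    half = None
    for i in np.flatnonzero(filled):
        if means[i] <= r2_max / 2.0 + 1e-15:
            half = float((bin_edges[i] + bin_edges[i + 1]) / 2.0)
            break
    return DecayCurve(
        bin_edges=np.asarray(bin_edges),
        mean_r2=mean_r2,
        n_pairs=n_pairs,
        r2_max=r2_max,
        half_decay_distance=half,
    )


def decay_curve(
    gm: GenotypeMatrix,
    pop: str | Iterable[str],
    spec: LdFilterSpec = LdFilterSpec(),
    bin_width: int = 1_000,
    smooth: bool = False,
) -> DecayCurve:
    """Distance-binned mean r2 for one population.

    Uses haplotype r2 when the matrix is phased, dosage r2 otherwise.
    """
    idx = gm.samples_for(pop)
    keep = _passing_sites(gm, idx, spec)
    if keep.sum() < 2:
        raise LdError("fewer than 2 sites pass the LD filters")

    n_bins = int(np.ceil(spec.max_pair_distance / bin_width))
    edges = np.arange(n_bins + 1, dtype=np.int64) * bin_width
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    for c in gm.chroms():
        sel = np.flatnonzero((gm.chrom == c) & keep)
        if sel.size < 2:
            continue
        pos = gm.pos[sel]
        if gm.is_phased:
            hap_cols = np.stack([2 * idx, 2 * idx + 1], axis=1).ravel()
            block = gm.haplotypes[np.ix_(sel, hap_cols)]
            no_missing = not (block == MISSING).any()
            r2m = _r2_matrix_phased(block) if no_missing else None
        else:
            block = gm.genotypes[np.ix_(sel, idx)]
            no_missing = not (block == MISSING).any()
            r2m = _r2_matrix_dosage(block) if no_missing else None

        iu, ju = np.triu_indices(sel.size, k=1)
        dist = pos[ju] - pos[iu]
        in_range = (dist > 0) & (dist <= spec.max_pair_distance)
        iu, ju, dist = iu[in_range], ju[in_range], dist[in_range]
        if r2m is not None:
            r2 = r2m[iu, ju]
        else:  # missing data: per-pair complete-case computation
            r2 = np.array([
                np.nan if (v := pair_r2(block[i], block[j], phased=gm.is_phased)) is None else v
                for i, j in zip(iu, ju)
            ])
        ok = ~np.isnan(r2)
        bins = np.minimum((dist[ok] - 1) // bin_width, n_bins - 1).astype(np.int64)
        np.add.at(sums, bins, r2[ok])
        np.add.at(counts, bins, 1)

    if counts.sum() == 0:
        raise LdError("no qualifying pairs")
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / counts, np.nan)
    return curve_from_bins(edges, means, counts, smooth=smooth)


def equalize_samples(gm: GenotypeMatrix, n_per_pop: int, seed: int) -> GenotypeMatrix:
    """Uniform random subsample of ``n_per_pop`` diploids from every population."""
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for pop in ("Target", "Control", "Background"):
        idx = gm.samples_for(pop)
        if idx.size < n_per_pop:
            raise LdError(f"population {pop} has {idx.size} < {n_per_pop} samples")
        pick = rng.choice(idx, size=n_per_pop, replace=False)
        chosen.extend(sorted(int(i) for i in pick))
    return gm.take_samples(np.asarray(chosen))


def plot_decay(curve: DecayCurve, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = (curve.bin_edges[:-1] + curve.bin_edges[1:]) / 2.0 / 1000.0
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(centers, curve.mean_r2, lw=1.2)
    if curve.half_decay_distance is not None:
        ax.axvline(curve.half_decay_distance / 1000.0, ls="--", color="grey")
    ax.set_xlabel("distance (kb)")
    ax.set_ylabel("mean $r^2$")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
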