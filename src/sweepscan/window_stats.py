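"""Windowed nucleotide diversity, pairwise Weir-Cockerham FST, and LSBL.

All windowed statistics live on a sliding grid of ``size``-bp windows every
``step`` bp, anchored at position 1 on each chromosome.  Window spans are
1-based half-open: [start, start + size).

Per-site FST follows the two-population Weir & Cockerham (1984) variance
components a, b, c; a window's FST is the ratio-of-sums estimator
sum(a) / sum(a + b + c) over the polymorphic sites it contains.  LSBL for
Target/Control/Background is (FST_TC + FST_TB - FST_CB) / 2 combined from
the windowed pairwise values on the identical grid (a per-site variant is
available behind ``per_site_lsbl``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .variant_store import POPULATIONS, GenotypeMatrix

PAIRS = (("Target", "Control"), ("Target", "Background"), ("Control", "Background"))
PAIR_KEYS = ("fst_TC", "fst_TB", "fst_CB")


class WindowStatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Window grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowGrid:
    size: int = 50_000
    step: int = 25_000

    def __post_init__(self) -> None:
        if self.size < 1 or self.step < 1:
            raise WindowStatsError("window size and step must be positive")
        if self.step > self.size:
            raise WindowStatsError("step must not exceed window size")

    def starts(self, max_pos: int) -> np.ndarray:
        """Window start positions covering [1, max_pos]: 1, 1+step, ...,
        keeping every window whose start does not exceed max_pos."""
        if max_pos < 1:
            return np.empty(0, dtype=np.int64)
        n = (max_pos - 1) // self.step + 1
        return 1 + self.step * np.arange(n, dtype=np.int64)

    def window_id(self, chrom: str, start: int) -> str:
        return f"{chrom}:{start}-{start + self.size}"

    def windows_overlapping(self, chrom: str, pos: int, max_pos: int) -> list[str]:
        """IDs of grid windows containing 1-based position ``pos``."""
        out = []
        for s in self.starts(max_pos):
            if s <= pos < s + self.size:
                out.append(self.window_id(chrom, int(s)))
        return out


# ---------------------------------------------------------------------------
# Per-site building blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteCounts:
    """Per-population sample size (diploids), alt frequency, het proportion."""

    n: tuple[float, float]
    p: tuple[float, float]
    h: tuple[float, float]


@dataclass(frozen=True)
class WcComponents:
    a: float
    b: float
    c: float
    n_bar: float
    n_c: float
    p_bar: float
    s2: float
    h_bar: float

    @property
    def theta(self) -> Optional[float]:
        denom = self.a + self.b + self.c
        if denom == 0:
            return None
        return self.a / denom


def site_pi(n: int, j: int) -> Optional[float]:
    """Per-site mean pairwise difference 2 j (n - j) / (n (n - 1)).

    ``n`` is the called allele count, ``j`` the alt allele count.
    Returns None for n < 2.
    """
    if n < 2:
        return None
    return 2.0 * j * (n - j) / (n * (n - 1.0))


def wc_components(n1, p1, h1, n2, p2, h2):
    """Vectorized two-population Weir-Cockerham variance components.

    Arguments are per-site arrays: diploid sample sizes, alt-allele
    frequencies, and observed heterozygote proportions for the two
    populations.  Returns (a, b, c, valid); components are NaN where the
    preconditions (n1 >= 1, n2 >= 1, n1 + n2 >= 2, n_bar > 1) fail.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)

    r = 2.0
    n_bar = (n1 + n2) / r
    valid = (n1 >= 1) & (n2 >= 1) & (n_bar > 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        inner = p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r
        a = (n_bar / n_c) * (s2 - (inner - h_bar / 4.0) / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (
            inner - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
        )
        c = h_bar / 2.0
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c, valid


def wc_fst_site(counts: SiteCounts) -> WcComponents:
    """Two-population Weir-Cockerham components for one site."""
    (n1, n2), (p1, p2), (h1, h2) = counts.n, counts.p, counts.h
    if n1 < 1 or n2 < 1 or n1 + n2 < 2:
        raise WindowStatsError("each population needs n >= 1 and n1 + n2 >= 2")
    a, b, c, valid = wc_components([n1], [p1], [h1], [n2], [p2], [h2])
    if not valid[0]:
        raise WindowStatsError("degenerate sample configuration (n_bar <= 1)")
    r = 2.0
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    return WcComponents(
        a=float(a[0]), b=float(b[0]), c=float(c[0]),
        n_bar=n_bar, n_c=n_c, p_bar=p_bar, s2=s2, h_bar=h_bar,
    )


def lsbl(fst_tc, fst_tb, fst_cb):
    """Target-branch length (FST_TC + FST_TB - FST_CB) / 2; None/NaN in -> NaN."""
    arr = [fst_tc, fst_tb, fst_cb]
    if any(v is None for v in arr):
        return np.nan
    fst_tc, fst_tb, fst_cb = (np.asarray(v, dtype=float) for v in arr)
    return (fst_tc + fst_tb - fst_cb) / 2.0


# ---------------------------------------------------------------------------
# Windowed statistics
# ---------------------------------------------------------------------------

def _window_sums(pos: np.ndarray, per_site: np.ndarray, starts: np.ndarray, size: int):
    """Sum per-site values (NaN treated as 0) over each [start, start+size)."""
    vals = np.nan_to_num(per_site, nan=0.0)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    i0 = np.searchsorted(pos, starts, side="left")
    i1 = np.searchsorted(pos, starts + size, side="left")
    return csum[i1] - csum[i0]


def _site_pop_stats(gm: GenotypeMatrix, pops: Iterable[str] | str):
    idx = gm.samples_for(pops)
    n, alt, het = gm.allele_counts(idx)
    n = n.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def _site_pi_array(gm: GenotypeMatrix, pops: Iterable[str] | str) -> np.ndarray:
    idx = gm.samples_for(pops)
    ncall, alt, _ = gm.allele_counts(idx)
    n = 2.0 * ncall
    j = alt.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * j * (n - j) / (n * (n - 1.0))
    return np.where(n >= 2, pi, np.nan)


def window_pi(gm: GenotypeMatrix, grid: WindowGrid, pop: str | Iterable[str]) -> pd.DataFrame:
    """Per-window nucleotide diversity: sum of site pi divided by window size."""
    out = []
    pi_site = _site_pi_array(gm, pop)
    for c in gm.chroms():
        sel = gm.chrom == c
        pos = gm.pos[sel]
        starts = grid.starts(int(pos.max()))
        sums = _window_sums(pos, pi_site[sel], starts, grid.size)
        out.append(pd.DataFrame({
            "chrom": c,
            "start": starts,
            "end": starts + grid.size,
            "pi": sums / grid.size,
        }))
    return pd.concat(out, ignore_index=True)


def _pair_site_components(gm: GenotypeMatrix, pop_a, pop_b):
    na, pa, ha = _site_pop_stats(gm, pop_a)
    nb, pb, hb = _site_pop_stats(gm, pop_b)
    a, b, c, valid = wc_components(na, pa, ha, nb, pb, hb)
    # sites monomorphic for the same allele in both populations contribute
    # nothing (a = b = c = 0 there anyway); invalid sites are dropped
    a = np.where(valid, a, np.nan)
    abc = a + np.where(valid, b + c, np.nan)
    return a, abc


def window_fst(
    gm: GenotypeMatrix,
    grid: WindowGrid,
    pop_a: str | Iterable[str],
    pop_b: str | Iterable[str],
    min_snps: int = 10,
) -> pd.DataFrame:
    """Ratio-of-sums windowed Weir-Cockerham FST for one population pair.

    Windows holding fewer than ``min_snps`` polymorphic sites, or with a
    non-positive component denominator, carry NaN.
    """
    a, abc = _pair_site_components(gm, pop_a, pop_b)
    poly = _polymorphic_mask(gm, (pop_a, pop_b))
    out = []
    for c in gm.chroms():
        sel = gm.chrom == c
        pos = gm.pos[sel]
        starts = grid.starts(int(pos.max()))
        num = _window_sums(pos, np.where(poly[sel], a[sel], np.nan), starts, grid.size)
        den = _window_sums(pos, np.where(poly[sel], abc[sel], np.nan), starts, grid.size)
        nsnp = _window_sums(pos, poly[sel].astype(float), starts, grid.size)
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where((nsnp >= min_snps) & (den > 0), num / den, np.nan)
        out.append(pd.DataFrame({
            "chrom": c, "start": starts, "end": starts + grid.size,
            "n_snps": nsnp.astype(int), "fst": fst,
        }))
    return pd.concat(out, ignore_index=True)


def _polymorphic_mask(gm: GenotypeMatrix, pop_groups) -> np.ndarray:
    """Sites segregating among the samples of the given population groups."""
    labels: list[str] = []
    for g in pop_groups:
        labels.extend((g,) if isinstance(g, str) else g)
    idx = gm.samples_for(tuple(dict.fromkeys(labels)))
    n, alt, _ = gm.allele_counts(idx)
    return (alt > 0) & (alt < 2 * n)


def scan(
    gm: GenotypeMatrix,
    grid: WindowGrid = WindowGrid(),
    min_snps: int = 10,
    clamp_negative_fst: bool = False,
    per_site_lsbl: bool = False,
) -> pd.DataFrame:
    """Assemble the full per-window table: pi per population, the three
    pairwise FSTs, Target-vs-pooled FST, and LSBL.

    ``clamp_negative_fst`` clamps negative window FSTs to 0 before the LSBL
    combination (off by default: clamping biases LSBL upward).
    ``per_site_lsbl`` averages per-site LSBL over window sites instead of
    combining the three windowed FSTs.
    """
    for p in POPULATIONS:
        if len(gm.samples_for(p)) < 2:
            raise WindowStatsError(f"population {p} has fewer than 2 diploids")

    base = None
    for key, (pa, pb) in zip(PAIR_KEYS, PAIRS):
        wf = window_fst(gm, grid, pa, pb, min_snps=min_snps)
        wf = wf.rename(columns={"fst": key})
        if base is None:
            base = wf.drop(columns=["n_snps"])
            base["n_snps"] = 0
        base[key] = wf[key].to_numpy()

    # overall polymorphic-site count per window (across all three populations)
    poly = _polymorphic_mask(gm, POPULATIONS)
    nsnps = []
    for c in gm.chroms():
        sel = gm.chrom == c
        pos = gm.pos[sel]
        starts = grid.starts(int(pos.max()))
        nsnps.append(_window_sums(pos, poly[sel].astype(float), starts, grid.size))
    base["n_snps"] = np.concatenate(nsnps).astype(int)

    for short, pop in (("T", "Target"), ("C", "Control"), ("B", "Background")):
        base[f"pi_{short}"] = window_pi(gm, grid, pop)["pi"].to_numpy()

    pool = window_fst(gm, grid, "Target", ("Control", "Background"), min_snps=min_snps)
    base["fst_T_pool"] = pool["fst"].to_numpy()

    f = {k: base[k].to_numpy(copy=True) for k in PAIR_KEYS}
    if clamp_negative_fst:
        for k in PAIR_KEYS:
            f[k] = np.where(np.isnan(f[k]), np.nan, np.maximum(f[k], 0.0))
    if per_site_lsbl:
        base["lsbl"] = _per_site_window_lsbl(gm, grid, min_snps)
    else:
        base["lsbl"] = (f["fst_TC"] + f["fst_TB"] - f["fst_CB"]) / 2.0

    cols = [
        "chrom", "start", "end", "n_snps",
        "pi_T", "pi_C", "pi_B",
        "fst_TC", "fst_TB", "fst_CB", "fst_T_pool", "lsbl",
    ]
    return base[cols]


def _per_site_window_lsbl(gm: GenotypeMatrix, grid: WindowGrid, min_snps: int):
    thetas = []
    for pa, pb in PAIRS:
        a, abc = _pair_site_components(gm, pa, pb)
        with np.errstate(invalid="ignore", divide="ignore"):
            thetas.append(np.where(abc > 0, a / abc, np.nan))
    site_lsbl = (thetas[0] + thetas[1] - thetas[2]) / 2.0
    ok = ~np.isnan(site_lsbl)
    out = []
    for c in gm.chroms():
        sel = gm.chrom == c
        pos = gm.pos[sel]
        starts = grid.starts(int(pos.max()))
        s = _window_sums(pos, np.where(ok[sel], site_lsbl[sel], np.nan), starts, grid.size)
        k = _window_sums(pos, ok[sel].astype(float), starts, grid.size)
        with np.errstate(invalid="ignore", divide="ignore"):
            out.append(np.where(k >= max(min_snps, 1), s / k, np.nan))
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def windows_to_bed(table: pd.DataFrame, path: str | Path) -> None:
    """Export window spans as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for row in table.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end - 1}\n")
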