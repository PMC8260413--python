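"""Empirical outlier-window calling, region merging, gene overlap, and
haplotype-pattern extraction.

Outliers are the windows whose statistic lies strictly above the empirical
top quantile (default q = 0.99, i.e. the top 1%); ties at the threshold are
excluded.  Overlapping or book-ended outlier windows merge into regions.
A gene overlaps a region when their 1-based closed intervals share at least
one bp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .variant_store import MISSING, GeneModel, GenotypeMatrix


class SweepRegionError(ValueError):
    pass


@dataclass
class SweepRegion:
    chrom: str
    start: int        # 1-based closed span covering all member windows
    end: int
    n_windows: int
    peak_fst: float
    peak_lsbl: float
    gene_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Thresholding
# ---------------------------------------------------------------------------

def percentile_threshold(values, q: float = 0.99) -> float:
    """Empirical q-quantile (numpy linear interpolation) of the non-null values.

    Requires at least 100 non-null values.  Windows strictly above the
    returned threshold are outliers.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 100:
        raise SweepRegionError(f"need >= 100 non-null values, got {v.size}")
    if not 0.0 <= q <= 1.0:
        raise SweepRegionError("q must lie in [0, 1]")
    return float(np.quantile(v, q, method="linear"))


def _stat_column(table: pd.DataFrame, stat: str, fst_mode: str) -> pd.Series:
    if stat == "lsbl":
        return table["lsbl"]
    if stat != "fst":
        raise SweepRegionError(f"unknown statistic {stat!r}")
    if fst_mode == "pooled":
        if "fst_T_pool" in table.columns:
            return table["fst_T_pool"]
        raise SweepRegionError("table lacks fst_T_pool column")
    if fst_mode == "mean_pairs":
        return (table["fst_TC"] + table["fst_TB"]) / 2.0
    raise SweepRegionError(f"unknown fst_mode {fst_mode!r}")


def call_outlier_windows(
    table: pd.DataFrame,
    stat: str = "lsbl",
    q: float = 0.99,
    fst_mode: str = "pooled",
) -> tuple[pd.DataFrame, float]:
    """Windows whose statistic strictly exceeds the empirical q-quantile.

    ``stat`` is "fst" (Target vs pooled Control+Background by default, or
    the mean of the two Target pairs with ``fst_mode='mean_pairs'``) or
    "lsbl".  q = 0 returns every non-null window.  Returns (windows,
    threshold).
    """
    col = _stat_column(table, stat, fst_mode)
    vals = col.to_numpy(dtype=float)
    nonnull = ~np.isnan(vals)
    if q == 0.0:
        return table[nonnull].copy(), float("-inf")
    thr = percentile_threshold(vals, q)
    keep = nonnull & (vals > thr)
    return table[keep].copy(), thr


# ---------------------------------------------------------------------------
# Region merging and gene overlap
# ---------------------------------------------------------------------------

def merge_windows(windows: pd.DataFrame, fst_mode: str = "pooled") -> list[SweepRegion]:
    """Merge overlapping or book-ended windows (1-based half-open spans)
    into regions with recomputed peak statistics."""
    if windows.empty:
        return []
    w = windows.sort_values(["chrom", "start"]).reset_index(drop=True)
    regions: list[SweepRegion] = []
    cur: Optional[dict] = None
    fst_col = "fst_T_pool" if fst_mode == "pooled" else None
    for row in w.itertuples(index=False):
        fst_val = getattr(row, "fst_T_pool", np.nan) if fst_col else (
            (row.fst_TC + row.fst_TB) / 2.0
        )
        if cur is not None and row.chrom == cur["chrom"] and row.start <= cur["end"]:
            cur["end"] = max(cur["end"], int(row.end))
            cur["n"] += 1
            cur["peak_fst"] = np.nanmax([cur["peak_fst"], fst_val])
            cur["peak_lsbl"] = np.nanmax([cur["peak_lsbl"], row.lsbl])
        else:
            if cur is not None:
                regions.append(_finish(cur))
            cur = {
                "chrom": row.chrom, "start": int(row.start), "end": int(row.end),
                "n": 1, "peak_fst": fst_val, "peak_lsbl": row.lsbl,
            }
    regions.append(_finish(cur))
    return regions


def _finish(cur: dict) -> SweepRegion:
    return SweepRegion(
        chrom=cur["chrom"],
        start=cur["start"],
        end=cur["end"] - 1,        # half-open window end -> closed region end
        n_windows=cur["n"],
        peak_fst=float(cur["peak_fst"]),
        peak_lsbl=float(cur["peak_lsbl"]),
    )


def genes_in_regions(
    regions: Iterable[SweepRegion], genes: Iterable[GeneModel]
) -> tuple[list[SweepRegion], set[str]]:
    """Assign every gene overlapping a region by >= 1 bp; returns the regions
    (gene_ids filled in place) and the union gene-ID set."""
    regions = list(regions)
    genes = list(genes)
    union: set[str] = set()
    region_chroms = {r.chrom for r in regions}
    gene_chroms = {g.chrom for g in genes}
    if regions and genes and not (region_chroms & gene_chroms):
        warnings.warn(
            f"no shared chromosome names between regions {sorted(region_chroms)} "
            f"and genes {sorted(gene_chroms)}",
            stacklevel=2,
        )
    for r in regions:
        hits = [
            g.gene_id
            for g in genes
            if g.chrom == r.chrom and g.start <= r.end and g.end >= r.start
        ]
        r.gene_ids = hits
        union.update(hits)
    return regions, union


def outlier_gene_sets(
    table: pd.DataFrame,
    genes: Iterable[GeneModel],
    q: float = 0.99,
    fst_mode: str = "pooled",
) -> dict:
    """Run both the FST and the LSBL outlier scans and intersect their gene sets.

    Returns threshold, outlier-window count, merged regions and gene set per
    statistic, the union of outlier windows across the two statistics
    ("either" rule), and the shared genes (intersection of the two sets).
    """
    out: dict = {}
    window_union: Optional[pd.DataFrame] = None
    genes = list(genes)
    for stat in ("fst", "lsbl"):
        wins, thr = call_outlier_windows(table, stat=stat, q=q, fst_mode=fst_mode)
        regions = merge_windows(wins, fst_mode=fst_mode)
        regions, gene_set = genes_in_regions(regions, genes)
        out[stat] = {
            "threshold": thr,
            "n_windows": len(wins),
            "regions": regions,
            "genes": gene_set,
        }
        window_union = wins if window_union is None else (
            pd.concat([window_union, wins]).drop_duplicates(subset=["chrom", "start"])
        )
    either_regions = merge_windows(window_union, fst_mode=fst_mode)
    out["either"] = {
        "n_windows": len(window_union),
        "n_regions": len(either_regions),
        "regions": either_regions,
    }
    out["shared_genes"] = out["fst"]["genes"] & out["lsbl"]["genes"]
    return out


# ---------------------------------------------------------------------------
# Haplotype pattern
# ---------------------------------------------------------------------------

@dataclass
class HaploPattern:
    positions: np.ndarray          # selected site positions
    matrix: np.ndarray             # rows x sites; 0 = ref-oriented, 1 = alt (2 possible for dosage rows)
    row_pops: list[str]
    row_ids: list[str]
    flipped: np.ndarray            # per-site bool: orientation mirrored so Target carries the high allele

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=[str(p) for p in self.positions])
        df.insert(0, "row_id", self.row_ids)
        df.insert(1, "population", self.row_pops)
        return df

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def haplotype_pattern(
    gm: GenotypeMatrix,
    chrom: str,
    start: int,
    end: int,
    freq_high: float = 0.7,
    freq_low: float = 0.3,
) -> HaploPattern:
    """Matrix of the region's frequency-differentiated SNPs.

    Selects sites where one allele has frequency >= freq_high in Target and
    <= freq_low in pooled Control+Background; each site is oriented so the
    Target-enriched allele is coded 1.  Rows are haplotypes for phased
    input, dosage rows (0/1/2 on the oriented allele) otherwise, sorted by
    population then by decreasing mean carrier state.
    """
    in_region = (gm.chrom == chrom) & (gm.pos >= start) & (gm.pos <= end)
    if not in_region.any():
        raise SweepRegionError(f"region {chrom}:{start}-{end} contains no sites")
    t_idx = gm.samples_for("Target")
    o_idx = gm.samples_for(("Control", "Background"))
    p_t = gm.alt_freq(t_idx)
    p_o = gm.alt_freq(o_idx)

    alt_high = (p_t >= freq_high) & (p_o <= freq_low)
    ref_high = ((1 - p_t) >= freq_high) & ((1 - p_o) <= freq_low)
    selected = in_region & (alt_high | ref_high)
    flipped = ref_high & ~alt_high
    sites = np.flatnonzero(selected)
    if sites.size == 0:
        warnings.warn("no SNP satisfies the frequency-differential rule", stacklevel=2)

    order = np.concatenate([t_idx, gm.samples_for("Control"), gm.samples_for("Background")])
    if gm.is_phased:
        rows, row_pops, row_ids = [], [], []
        for j in order:
            for k in (0, 1):
                rows.append(gm.haplotypes[sites, 2 * j + k])
                row_pops.append(str(gm.pop_labels[j]))
                row_ids.append(f"{gm.sample_ids[j]}_h{k + 1}")
        mat = np.vstack(rows) if rows else np.empty((0, 0), dtype=np.int8)
    else:
        mat = gm.genotypes[np.ix_(sites, order)].T
        row_pops = [str(gm.pop_labels[j]) for j in order]
        row_ids = [gm.sample_ids[j] for j in order]
    mat = mat.astype(np.int8)

    # orient: flip sites where the reference allele is the Target-enriched one
    flip_cols = flipped[sites]
    if mat.size:
        maxval = 1 if gm.is_phased else 2
        sub = mat[:, flip_cols]
        mat[:, flip_cols] = np.where(sub == MISSING, MISSING, maxval - sub)

    # sort rows within population by decreasing mean carrier state
    pop_rank = {"Target": 0, "Control": 1, "Background": 2}
    if mat.size:
        with np.errstate(invalid="ignore"):
            means = np.where(mat != MISSING, mat, np.nan).mean(axis=1)
        means = np.nan_to_num(means)
        order_rows = sorted(
            range(mat.shape[0]), key=lambda i: (pop_rank[row_pops[i]], -means[i])
        )
        mat = mat[order_rows]
        row_pops = [row_pops[i] for i in order_rows]
        row_ids = [row_ids[i] for i in order_rows]

    return HaploPattern(
        positions=gm.pos[sites],
        matrix=mat,
        row_pops=row_pops,
        row_ids=row_ids,
        flipped=flip_cols,
    )


# ---------------------------------------------------------------------------
# Export and plotting
# ---------------------------------------------------------------------------

def regions_to_bed(regions: Iterable[SweepRegion], path: str | Path) -> None:
    """Regions as BED: 0-based half-open."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\n")


def regions_to_table(regions: Iterable[SweepRegion]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "chrom": r.chrom, "start": r.start, "end": r.end,
            "n_windows": r.n_windows, "peak_fst": r.peak_fst,
            "peak_lsbl": r.peak_lsbl, "gene_ids": ",".join(r.gene_ids),
        }
        for r in regions
    ])


def plot_manhattan(table: pd.DataFrame, path: str | Path, fst_mode: str = "pooled") -> None:
    """Two-track per-window FST and LSBL plot across chromosomes."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fst = _stat_column(table, "fst", fst_mode)
    fig, axes = plt.subplots(2, 1, figsize=(10, 5), sharex=True)
    offset = 0
    ticks, labels = [], []
    for chrom, sub in table.groupby("chrom", sort=False):
        x = sub["start"].to_numpy() + offset
        axes[0].scatter(x, fst.loc[sub.index], s=2)
        axes[1].scatter(x, sub["lsbl"], s=2)
        ticks.append(offset + sub["start"].max() / 2)
        labels.append(str(chrom))
        offset += sub["end"].max()
    axes[0].set_ylabel("window $F_{ST}$")
    axes[1].set_ylabel("window LSBL")
    axes[1].set_xticks(ticks, labels)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_haplotype_pattern(pattern: HaploPattern, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    fig, ax = plt.subplots(figsize=(8, 4))
    cmap = ListedColormap(["lightgrey", "khaki", "yellowgreen", "darkgreen"])
    shown = np.where(pattern.matrix == MISSING, -1, pattern.matrix)
    ax.imshow(shown + 1, aspect="auto", cmap=cmap, interpolation="nearest")
    ax.set_xlabel("site")
    ax.set_ylabel("haplotype / sample")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
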