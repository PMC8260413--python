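"""Three-population synthetic genotype generators with known truth.

Two simulators with different jobs:

* ``simulate_balding_nichols`` draws unlinked sites whose per-population
  allele frequencies follow a Beta distribution around an ancestral
  frequency p with variance F p (1 - p) — fast, with closed-form expected
  differentiation, for FST / LSBL / pi testing.
* ``simulate_wright_fisher`` is a forward-time diploid simulator on a
  discrete site grid with mutation, crossover recombination, a three-way
  population split, an optional bottleneck in one lineage and optional
  additive selection at a sweep site — reserved for LD and sweep-shape
  tests, emitting phased haplotypes.

A third helper, ``inject_sweep_differentiation``, pushes Target allele
frequencies toward fixation inside a region of an existing matrix: a cheap
sweep surrogate for fast outlier-calling tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .variant_store import POPULATIONS, GenotypeMatrix
from .window_stats import WindowGrid

logger = logging.getLogger(__name__)


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Specs and truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaldingNicholsSpec:
    F: tuple[float, float, float] = (0.1, 0.1, 0.1)   # Target, Control, Background
    n_diploids: tuple[int, int, int] = (25, 25, 25)
    n_sites: int = 1_000
    ancestral_low: float = 0.05        # Uniform(low, high) ancestral frequency
    ancestral_high: float = 0.95
    chrom_name: str = "chr1"
    site_spacing_bp: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.F) != 3 or len(self.n_diploids) != 3:
            raise SimulationError("exactly three populations required")
        if not all(0.0 < f < 1.0 for f in self.F):
            raise SimulationError("each F must lie in (0, 1)")
        if any(n < 2 for n in self.n_diploids):
            raise SimulationError("n_diploids must be >= 2 per population")
        if self.n_sites < 1:
            raise SimulationError("n_sites must be >= 1")
        if not 0.0 < self.ancestral_low < self.ancestral_high < 1.0:
            raise SimulationError("ancestral frequency bounds must satisfy 0 < low < high < 1")
        if self.site_spacing_bp < 1:
            raise SimulationError("site_spacing_bp must be >= 1")


@dataclass(frozen=True)
class Bottleneck:
    pop: str                   # population label
    N_e: int                   # reduced size during the bottleneck
    duration: int              # generations


@dataclass(frozen=True)
class Sweep:
    pop: str
    position: int              # bp, in [1, L]
    s: float                   # selection coefficient; fitnesses 1, 1+hs, 1+s
    h: float = 0.5


@dataclass(frozen=True)
class WrightFisherSpec:
    N_e: int = 100
    L: int = 500_000
    mu: float = 1e-7           # per bp per generation
    rho: float = 2.5e-7        # per bp per generation
    split_gens: int = 300
    n_sites: int = 500         # candidate site grid across L
    samples_per_pop: int = 20
    burnin_factor: float = 10.0   # burn-in generations = burnin_factor * N_e
    bottleneck: Optional[Bottleneck] = None
    sweep: Optional[Sweep] = None
    sweep_loss: str = "resample"   # or "fail"
    sweep_min_freq: float = 0.0    # resample until the selected allele reaches this frequency
    chrom_name: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N_e < 2 or self.n_sites < 2 or self.L < self.n_sites:
            raise SimulationError("invalid population size or site grid")
        if self.mu < 0 or self.rho < 0:
            raise SimulationError("rates must be >= 0")
        if self.samples_per_pop > self.N_e:
            raise SimulationError("cannot sample more diploids than N_e")
        if self.bottleneck is not None:
            if self.bottleneck.pop not in POPULATIONS:
                raise SimulationError(f"unknown bottleneck population {self.bottleneck.pop!r}")
            if not 1 <= self.bottleneck.N_e < self.N_e:
                raise SimulationError("bottleneck size must be in [1, N_e)")
        if self.sweep is not None:
            if self.sweep.pop not in POPULATIONS:
                raise SimulationError(f"unknown sweep population {self.sweep.pop!r}")
            if not 1 <= self.sweep.position <= self.L:
                raise SimulationError("sweep position must lie in [1, L]")
        if self.sweep_loss not in ("resample", "fail"):
            raise SimulationError("sweep_loss must be 'resample' or 'fail'")
        # discrete-site guard: the grid must accommodate expected diversity
        theta_total = 4.0 * self.N_e * self.mu * self.L
        if theta_total > 10.0 * self.n_sites:
            raise SimulationError("expected segregating sites exceed 10x the site grid")


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    spec: dict
    sweep_window_ids: list[str]
    pop_freqs: pd.DataFrame    # columns: pos, p_Target, p_Control, p_Background

    def write(self, path: str | Path) -> None:
        write_truth(self, path)


# ---------------------------------------------------------------------------
# Balding-Nichols
# ---------------------------------------------------------------------------

def simulate_balding_nichols(spec: BaldingNicholsSpec) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw unlinked genotypes under the Beta allele-frequency model.

    For each site an ancestral frequency p ~ Uniform(low, high); each
    population's frequency is Beta(p (1-F)/F, (1-p)(1-F)/F) — mean p,
    variance F p (1-p).  Diploid genotypes are two independent allele draws.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    S = spec.n_sites
    p_anc = rng.uniform(spec.ancestral_low, spec.ancestral_high, size=S)

    pop_p = np.empty((S, 3))
    geno_blocks = []
    for k, (f, nd) in enumerate(zip(spec.F, spec.n_diploids)):
        ratio = (1.0 - f) / f
        pk = rng.beta(p_anc * ratio, (1.0 - p_anc) * ratio)
        pop_p[:, k] = pk
        geno_blocks.append(
            rng.binomial(1, pk[:, None], size=(S, nd)).astype(np.int8)
            + rng.binomial(1, pk[:, None], size=(S, nd)).astype(np.int8)
        )

    pos = 1 + spec.site_spacing_bp * np.arange(S, dtype=np.int64)
    gm = GenotypeMatrix(
        chrom=np.full(S, spec.chrom_name, dtype=object),
        pos=pos,
        ref=np.full(S, "A", dtype=object),
        alt=np.full(S, "G", dtype=object),
        qual=np.full(S, 100.0),
        genotypes=np.hstack(geno_blocks),
        sample_ids=_sample_names(spec.n_diploids),
        pop_labels=_pop_label_array(spec.n_diploids),
        mean_depth=np.full(S, 30.0),
        haplotypes=None,
    )
    truth = SimTruth(
        spec={"model": "balding_nichols", **_spec_dict(spec)},
        sweep_window_ids=[],
        pop_freqs=pd.DataFrame({
            "pos": pos,
            "p_Target": pop_p[:, 0],
            "p_Control": pop_p[:, 1],
            "p_Background": pop_p[:, 2],
        }),
    )
    return gm, truth


def _sample_names(n_diploids) -> list[str]:
    names = []
    for pop, n in zip(POPULATIONS, n_diploids):
        names.extend(f"{pop[0]}{i:03d}" for i in range(n))
    return names


def _pop_label_array(n_diploids) -> np.ndarray:
    labels = []
    for pop, n in zip(POPULATIONS, n_diploids):
        labels.extend([pop] * n)
    return np.asarray(labels, dtype=object)


# ---------------------------------------------------------------------------
# Injected sweep surrogate
# ---------------------------------------------------------------------------

def inject_sweep_differentiation(
    gm: GenotypeMatrix,
    chrom: str,
    start: int,
    end: int,
    delta: float,
    seed: int = 0,
) -> GenotypeMatrix:
    """Push Target alt frequencies toward fixation inside [start, end].

    Target genotypes at every site of the region are resampled from
    min(p_Target + delta, 1), other populations untouched.  delta = 0 is the
    identity.  The region must contain at least one site.
    """
    if not 0.0 <= delta <= 1.0:
        raise SimulationError("delta must lie in [0, 1]")
    in_region = (gm.chrom == chrom) & (gm.pos >= start) & (gm.pos <= end)
    if not in_region.any():
        raise SimulationError(f"region {chrom}:{start}-{end} contains no sites")
    out = gm.take_sites(np.arange(gm.n_sites))  # copy
    if delta == 0.0:
        return out
    rng = np.random.default_rng(seed)
    t_idx = gm.samples_for("Target")
    sites = np.flatnonzero(in_region)
    p_t = gm.alt_freq(t_idx)[sites]
    p_new = np.minimum(np.nan_to_num(p_t) + delta, 1.0)
    new_gt = rng.binomial(2, p_new[:, None], size=(sites.size, t_idx.size)).astype(np.int8)
    geno = out.genotypes.copy()
    geno[np.ix_(sites, t_idx)] = new_gt
    out.genotypes = geno
    if out.haplotypes is not None:
        hap = out.haplotypes.copy()
        hap_cols = np.stack([2 * t_idx, 2 * t_idx + 1], axis=1).ravel()
        # deterministic re-phase of resampled genotypes
        h1 = (new_gt == 2).astype(np.int8)
        h2 = (new_gt >= 1).astype(np.int8)
        hap[np.ix_(sites, hap_cols[0::2])] = h1
        hap[np.ix_(sites, hap_cols[1::2])] = h2
        out.haplotypes = hap
    return out


# ---------------------------------------------------------------------------
# Forward Wright-Fisher
# ---------------------------------------------------------------------------

def _evolve(
    pop: np.ndarray,
    n_gen: int,
    N: int,
    u_site: float,
    rec_p: float,
    rng: np.random.Generator,
    sweep_col: Optional[int] = None,
    s: float = 0.0,
    h: float = 0.5,
    mut_exclude_col: Optional[int] = None,
) -> np.ndarray:
    """Evolve a (2N_in, S) haplotype array for n_gen generations at size N.

    ``mut_exclude_col`` shields one site from recurrent mutation (used for
    the de novo sweep site, which must not be re-introduced after loss).
    """
    S = pop.shape[1]
    for _ in range(n_gen):
        n_parents = pop.shape[0] // 2
        if sweep_col is not None and s != 0.0:
            g = pop[0::2, sweep_col].astype(np.int64) + pop[1::2, sweep_col]
            w = 1.0 + np.where(g == 1, h * s, 0.0) + np.where(g == 2, s, 0.0)
            probs = w / w.sum()
            parents = rng.choice(n_parents, size=2 * N, p=probs)
        else:
            parents = rng.integers(0, n_parents, size=2 * N)
        hap_a = pop[2 * parents]
        hap_b = pop[2 * parents + 1]
        # crossover lattice: random start haplotype, switch between adjacent
        # sites with probability rec_p per interval
        start = rng.integers(0, 2, size=(2 * N, 1))
        if rec_p > 0.0:
            switches = rng.random((2 * N, S - 1)) < rec_p
            chooser = (start + np.cumsum(switches, axis=1, dtype=np.int64)) % 2
            chooser = np.concatenate([start, chooser], axis=1)
        else:
            chooser = np.broadcast_to(start, (2 * N, S))
        pop = np.where(chooser == 0, hap_a, hap_b)
        # mutation: Poisson number of site flips across the population
        n_mut = rng.poisson(2 * N * S * u_site)
        if n_mut:
            rows = rng.integers(0, 2 * N, size=n_mut)
            cols = rng.integers(0, S, size=n_mut)
            if mut_exclude_col is not None:
                keep = cols != mut_exclude_col
                rows, cols = rows[keep], cols[keep]
            pop[rows, cols] ^= 1
    return pop


def simulate_wright_fisher(spec: WrightFisherSpec) -> tuple[GenotypeMatrix, SimTruth]:
    """Forward-time diploid Wright-Fisher simulation of a three-way split.

    One ancestral population is burnt in for ``burnin_factor * N_e``
    generations, split into Target/Control/Background lineages evolved for
    ``split_gens`` generations, with an optional bottleneck in one lineage
    and optional additive selection at a sweep site introduced in the swept
    lineage at the split.  Emits phased haplotypes of ``samples_per_pop``
    diploids per population.  Deterministic given the seed; if the selected
    allele is lost the run is re-seeded (logged) up to 100 times, or fails
    when ``sweep_loss='fail'``.
    """
    S = spec.n_sites
    spacing = spec.L / S
    pos = (np.round((np.arange(S) + 0.5) * spacing)).astype(np.int64)
    pos = np.maximum.accumulate(np.maximum(pos, 1))
    if len(np.unique(pos)) != S:
        pos = 1 + np.arange(S, dtype=np.int64) * max(int(spacing), 1)
    u_site = spec.mu * spacing            # each grid site absorbs its spacing's mutation rate
    rec_p = min(spec.rho * spacing, 0.5)  # per-interval crossover probability

    sweep_col = None
    if spec.sweep is not None:
        sweep_col = int(np.argmin(np.abs(pos - spec.sweep.position)))

    # evolve the swept lineage first so a lost allele aborts the attempt early
    order = list(POPULATIONS)
    if spec.sweep is not None:
        order.sort(key=lambda p: p != spec.sweep.pop)

    for attempt in range(100):
        seed = spec.seed + 7919 * attempt
        rng = np.random.default_rng(seed)
        anc = _init_equilibrium(spec, S, u_site, rng)
        anc = _evolve(anc, int(spec.burnin_factor * spec.N_e), spec.N_e, u_site, rec_p, rng)
        if spec.sweep is not None:
            # the sweep is a de novo mutation: absent everywhere at the split,
            # one copy seeded into the swept lineage
            anc[:, sweep_col] = 0

        pops: dict[str, np.ndarray] = {}
        lost = False
        for pop_name in order:
            lineage = anc.copy()
            is_swept = spec.sweep is not None and pop_name == spec.sweep.pop
            if is_swept:
                lineage[rng.integers(0, lineage.shape[0]), sweep_col] = 1
            s = spec.sweep.s if is_swept else 0.0
            h = spec.sweep.h if is_swept else 0.5
            col = sweep_col if is_swept else None
            gens_left = spec.split_gens
            if spec.bottleneck is not None and pop_name == spec.bottleneck.pop:
                dur = min(spec.bottleneck.duration, gens_left)
                lineage = _evolve(
                    lineage, dur, spec.bottleneck.N_e, u_site, rec_p, rng,
                    sweep_col=col, s=s, h=h, mut_exclude_col=sweep_col,
                )
                gens_left -= dur
            lineage = _evolve(
                lineage, gens_left, spec.N_e, u_site, rec_p, rng,
                sweep_col=col, s=s, h=h, mut_exclude_col=sweep_col,
            )
            if is_swept:
                freq = lineage[:, sweep_col].mean()
                if freq == 0.0 or freq < spec.sweep_min_freq:
                    if spec.sweep_loss == "fail":
                        raise SimulationError("selected allele lost or below sweep_min_freq")
                    logger.info(
                        "selected allele at %.3f < required; resampling (attempt %d)",
                        freq, attempt + 1,
                    )
                    lost = True
                    break
            pops[pop_name] = lineage
        if not lost:
            break
    else:
        raise SimulationError("selected allele lost in 100 consecutive attempts")

    # sample diploids per population
    hap_blocks, geno_blocks = [], []
    for pop_name in POPULATIONS:
        lineage = pops[pop_name]
        pick = rng.choice(spec.N_e, size=spec.samples_per_pop, replace=False)
        cols = np.stack([2 * pick, 2 * pick + 1], axis=1).ravel()
        hap = lineage[cols].T.astype(np.int8)   # (S, 2 * samples)
        hap_blocks.append(hap)
        geno_blocks.append((hap[:, 0::2] + hap[:, 1::2]).astype(np.int8))

    n_per = (spec.samples_per_pop,) * 3
    hap_all = np.hstack(hap_blocks)
    gm = GenotypeMatrix(
        chrom=np.full(S, spec.chrom_name, dtype=object),
        pos=pos,
        ref=np.full(S, "A", dtype=object),
        alt=np.full(S, "G", dtype=object),
        qual=np.full(S, 100.0),
        genotypes=np.hstack(geno_blocks),
        sample_ids=_sample_names(n_per),
        pop_labels=_pop_label_array(n_per),
        mean_depth=np.full(S, 30.0),
        haplotypes=hap_all,
    )

    sweep_windows: list[str] = []
    if spec.sweep is not None:
        grid = WindowGrid()
        sweep_windows = grid.windows_overlapping(
            spec.chrom_name, spec.sweep.position, int(pos.max())
        )
    freqs = {
        "pos": pos,
        **{
            f"p_{p}": gm.alt_freq(gm.samples_for(p))
            for p in POPULATIONS
        },
    }
    truth = SimTruth(
        spec={"model": "wright_fisher", **_spec_dict(spec)},
        sweep_window_ids=sweep_windows,
        pop_freqs=pd.DataFrame(freqs),
    )
    return gm, truth


def _init_equilibrium(
    spec: WrightFisherSpec, S: int, u_site: float, rng: np.random.Generator
) -> np.ndarray:
    """Linkage-free equilibrium start for the burn-in.

    Site frequencies are drawn from the symmetric two-allele stationary
    Beta(theta, theta) with theta = 4 N_e u; haplotypes start in linkage
    equilibrium and the burn-in builds up LD.
    """
    theta = max(4.0 * spec.N_e * u_site, 1e-6)
    freqs = rng.beta(theta, theta, size=S)
    return (rng.random((2 * spec.N_e, S)) < freqs).astype(np.uint8)


def _spec_dict(spec) -> dict:
    # JSON-canonical form (tuples -> lists) so truth files round-trip equal
    return json.loads(json.dumps(asdict(spec)))


# ---------------------------------------------------------------------------
# Truth round-trip
# ---------------------------------------------------------------------------

def write_truth(truth: SimTruth, path: str | Path) -> None:
    """TSV with a one-line JSON header carrying the spec and sweep windows."""
    header = json.dumps(
        {"spec": truth.spec, "sweep_window_ids": truth.sweep_window_ids},
        sort_keys=True,
    )
    with open(path, "w") as fh:
        fh.write(f"#{header}\n")
        truth.pop_freqs.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_truth(path: str | Path) -> SimTruth:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise SimulationError("missing truth header line")
        meta = json.loads(first[1:])
        table = pd.read_csv(fh, sep="\t")
    return SimTruth(
        spec=meta["spec"],
        sweep_window_ids=meta["sweep_window_ids"],
        pop_freqs=table,
    )
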