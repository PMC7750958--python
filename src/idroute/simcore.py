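"""Individual-based forward simulator of DNA-transposon invasions with
internal deletions (IDs), piRNA-cluster silencing, and 1D stepping-stone
migration.

The model
---------
A neutral (or weakly deleterious) transposable element spreads through a
diploid, randomly mating population of constant size ``N``.  Each TE copy is
either full length (FL) or carries a single internal deletion defined by an
ordered breakpoint pair on the TE consensus sequence.  Per generation the
simulator performs, in order: (1) fitness-weighted mate-pair formation,
(2) meiosis with Poisson-distributed crossovers, (3) transposition of new FL
and ID copies into the gametes of active parents, (4) zygote formation,
(5) piRNA-cluster insertion counting, (6) fitness computation, (7) optional
migration between adjacent demes, and (8) output.

A diploid is *active* — i.e. its TEs can transpose — if it carries at least
one FL copy anywhere and no copy (FL or ID) inside a piRNA cluster (the trap
model).  A transposing FL copy is converted into a brand-new ID with
probability ``c`` per transposition event (two distinct uniform breakpoints);
ID copies transpose but propagate their breakpoints unchanged and never
revert to FL.

Two equivalent interfaces are provided:

* a scalar object model (:class:`Individual`, :func:`is_active`,
  :func:`make_gamete`, :func:`transpose_into_gamete`) convenient for
  inspection and unit-level checks, and
* a vectorized population engine (:class:`Population`,
  :func:`step_generation`, :func:`run_single_invasion`,
  :func:`run_stepping_stone`) storing all insertions of a deme in flat
  NumPy arrays, which is what the long multi-deme runs use.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fingerprint import Fingerprint, FingerprintEntry

__all__ = [
    "SimConfig",
    "Genome",
    "IDVariant",
    "TEInsertion",
    "Individual",
    "VariantRegistry",
    "Population",
    "Metapopulation",
    "InvasionRecord",
    "ExtinctionError",
    "init_population",
    "is_active",
    "make_gamete",
    "transpose_into_gamete",
    "step_generation",
    "migrate",
    "run_single_invasion",
    "run_stepping_stone",
    "population_fingerprint",
]


class ExtinctionError(RuntimeError):
    """Raised when every individual has fitness zero (population extinct)."""


# ---------------------------------------------------------------------------
# configuration and genome layout
# ---------------------------------------------------------------------------


def _as_list(value, n, name) -> list:
    if np.isscalar(value):
        return [value] * n
    value = list(value)
    if len(value) != n:
        raise ValueError(f"{name} must be scalar or have one entry per chromosome")
    return value


@dataclass
class SimConfig:
    """Parameters of one invasion simulation.

    Rates are per generation; ``u`` is the transposition rate per copy,
    ``c`` the probability that a transposing FL copy is copied as a new ID,
    ``x`` the per-copy fitness cost, and ``fl_id`` the per-copy mobilization
    weight of FL copies (0.5 means every copy, FL or ID, is an equally
    likely template).
    """

    chromosome_lengths: Sequence[int] = (1_000_000,) * 5
    recombination_cm_mb: float | Sequence[float] = 4.0
    cluster_lengths: int | Sequence[int] = 100_000
    u: float = 0.1
    c: float = 0.0
    x: float = 0.0
    N: int = 1000
    fl_id: float = 0.5
    te_length: int = 2907
    n_fl_init: int = 300
    n_populations: int = 1
    migration_size: int = 100
    migration_interval: int = 300
    generations: int = 500
    record_every: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        nchrom = len(self.chromosome_lengths)
        self.chromosome_lengths = [int(l) for l in self.chromosome_lengths]
        self.recombination_cm_mb = [
            float(r) for r in _as_list(self.recombination_cm_mb, nchrom, "recombination_cm_mb")
        ]
        self.cluster_lengths = [
            int(cl) for cl in _as_list(self.cluster_lengths, nchrom, "cluster_lengths")
        ]
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.te_length < 2:
            raise ValueError("TE consensus length must be >= 2")
        if self.u < 0:
            raise ValueError("u must be >= 0")
        for nm in ("c", "x", "fl_id"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm} must be in [0, 1]")
        for length, cl in zip(self.chromosome_lengths, self.cluster_lengths):
            if cl > length:
                raise ValueError("cluster length exceeds chromosome length")
            if length < 1:
                raise ValueError("chromosome length must be positive")
        if self.n_populations < 1:
            raise ValueError("need at least one population")
        if self.migration_size > self.N:
            raise ValueError("migration size exceeds population size")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)

    def genome(self) -> "Genome":
        return Genome(self)


class Genome:
    """Precomputed genome layout: chromosome offsets, cluster windows and
    crossover intensities.

    Sites are encoded as a single integer ``offset[chrom] + (pos - 1)`` in
    ``[0, total_bp)``; positions are 1-based within chromosomes.  piRNA
    clusters occupy the *last* ``cluster_length`` bp of each chromosome.
    """

    def __init__(self, cfg: SimConfig):
        self.chrom_len = np.asarray(cfg.chromosome_lengths, dtype=np.int64)
        self.n_chrom = len(self.chrom_len)
        self.offsets = np.concatenate([[0], np.cumsum(self.chrom_len)])
        self.total_bp = int(self.offsets[-1])
        self.cluster_len = np.asarray(cfg.cluster_lengths, dtype=np.int64)
        # 1-based first position of the cluster window on each chromosome
        self.cluster_start = self.chrom_len - self.cluster_len + 1
        rr = np.asarray(cfg.recombination_cm_mb, dtype=float)
        # cM/Mb -> expected crossovers per meiosis per chromosome
        self.xover_lambda = rr * (self.chrom_len / 1e6) / 100.0
        self.max_len = int(self.chrom_len.max())

    def chrom_of_site(self, site):
        return np.searchsorted(self.offsets, site, side="right") - 1

    def pos_of_site(self, site, chrom=None):
        if chrom is None:
            chrom = self.chrom_of_site(site)
        return site - self.offsets[chrom] + 1

    def site_of(self, chrom, pos):
        return self.offsets[chrom] + pos - 1

    def in_cluster(self, chrom, pos):
        return pos >= self.cluster_start[chrom]


# ---------------------------------------------------------------------------
# scalar object model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IDVariant:
    """An internal deletion: ordered breakpoints on the TE consensus."""

    start: int
    end: int
    vid: int

    def __post_init__(self):
        if not 1 <= self.start < self.end:
            raise ValueError("require 1 <= start < end")


@dataclass(frozen=True)
class TEInsertion:
    """One TE copy at a genomic site; ``variant`` is None for FL copies."""

    chrom: int
    pos: int
    variant: Optional[IDVariant] = None

    @property
    def is_fl(self) -> bool:
        return self.variant is None


@dataclass
class Individual:
    """A diploid: two haplotypes, each a list of insertions sorted by
    (chromosome, position)."""

    hap0: list
    hap1: list

    def copy_number(self) -> int:
        return len(self.hap0) + len(self.hap1)

    def insertions(self):
        yield from self.hap0
        yield from self.hap1


class VariantRegistry:
    """Global bookkeeping of ID variants created during one simulation.

    Variant ids are 1-based (0 denotes FL in the array engine); every
    conversion event creates a new id even when breakpoints coincide by
    chance, so homoplasy is representable in the simulation truth.
    """

    def __init__(self, te_length: int):
        self.te_length = int(te_length)
        self.start = [0]  # index 0 is the FL placeholder
        self.end = [0]

    def __len__(self) -> int:
        return len(self.start) - 1

    def new_variant(self, rng: np.random.Generator) -> IDVariant:
        vid = self.new_batch(1, rng)[0]
        return self.get(vid)

    def new_batch(self, k: int, rng: np.random.Generator) -> np.ndarray:
        """Create ``k`` fresh variants with distinct ordered uniform
        breakpoints in [1, te_length]; returns their ids."""
        if k == 0:
            return np.empty(0, dtype=np.int64)
        b1 = rng.integers(1, self.te_length + 1, size=k)
        b2 = rng.integers(1, self.te_length + 1, size=k)
        bad = b1 == b2
        while bad.any():
            b2[bad] = rng.integers(1, self.te_length + 1, size=int(bad.sum()))
            bad = b1 == b2
        lo = np.minimum(b1, b2)
        hi = np.maximum(b1, b2)
        first = len(self.start)
        self.start.extend(lo.tolist())
        self.end.extend(hi.tolist())
        return np.arange(first, first + k, dtype=np.int64)

    def get(self, vid: int) -> IDVariant:
        return IDVariant(self.start[vid], self.end[vid], vid)


def is_active(individual: Individual, genome: Genome) -> bool:
    """Trap-model activity: at least one FL copy and no copy (FL or ID)
    inside any piRNA cluster."""
    has_fl = False
    for ins in individual.insertions():
        if genome.in_cluster(ins.chrom, ins.pos):
            return False
        if ins.is_fl:
            has_fl = True
    return has_fl


def make_gamete(individual: Individual, cfg: SimConfig, rng: np.random.Generator) -> list:
    """Meiosis for one diploid: per chromosome the crossover count is
    Poisson(rate_cM/Mb / 100 * length_Mb), crossover positions are uniform,
    and chromosomes assort independently.  Returns a haplotype (sorted list
    of insertions)."""
    genome = cfg.genome() if not isinstance(cfg, Genome) else cfg
    gamete = []
    for c in range(genome.n_chrom):
        k = rng.poisson(genome.xover_lambda[c])
        phase = int(rng.integers(0, 2))  # which parental haplotype starts
        if k == 0:
            src = individual.hap0 if phase == 0 else individual.hap1
            gamete.extend(i for i in src if i.chrom == c)
            continue
        xpos = np.sort(rng.integers(1, genome.chrom_len[c] + 1, size=k))
        for hap_idx, hap in enumerate((individual.hap0, individual.hap1)):
            for ins in hap:
                if ins.chrom != c:
                    continue
                # number of crossovers at or left of this insertion flips phase
                flips = int(np.searchsorted(xpos, ins.pos, side="right"))
                if (phase + flips) % 2 == hap_idx:
                    continue
                gamete.append(ins)
    gamete.sort(key=lambda i: (i.chrom, i.pos))
    return gamete


def transpose_into_gamete(
    parent: Individual,
    gamete: list,
    cfg: SimConfig,
    rng: np.random.Generator,
    registry: Optional[VariantRegistry] = None,
) -> list:
    """Transposition step for one gamete.  If the parent is inactive the
    gamete is returned unchanged.  Otherwise Poisson(u * n/2) new copies are
    inserted at uniform unoccupied sites; the template copy is drawn from the
    parent's copies with per-copy weight ``fl_id`` (FL) or ``1 - fl_id``
    (ID); an FL template yields a fresh ID with probability ``c``, an ID
    template propagates its breakpoints unchanged."""
    genome = cfg.genome()
    if registry is None:
        registry = VariantRegistry(cfg.te_length)
    if not is_active(parent, genome):
        return list(gamete)
    n = parent.copy_number()
    n_new = rng.poisson(cfg.u * n / 2.0)
    if n_new == 0:
        return list(gamete)
    copies = list(parent.insertions())
    weights = np.array([cfg.fl_id if ins.is_fl else 1.0 - cfg.fl_id for ins in copies])
    weights = weights / weights.sum()
    occupied = {(i.chrom, i.pos) for i in gamete}
    out = list(gamete)
    for _ in range(n_new):
        src = copies[rng.choice(len(copies), p=weights)]
        if src.is_fl and rng.random() < cfg.c:
            variant = registry.new_variant(rng)
        else:
            variant = src.variant
        while True:
            site = int(rng.integers(0, genome.total_bp))
            chrom = int(genome.chrom_of_site(site))
            pos = int(genome.pos_of_site(site, chrom))
            if (chrom, pos) not in occupied:
                break
        occupied.add((chrom, pos))
        out.append(TEInsertion(chrom, pos, variant))
    out.sort(key=lambda i: (i.chrom, i.pos))
    return out


# ---------------------------------------------------------------------------
# vectorized population engine
# ---------------------------------------------------------------------------


class Population:
    """All TE insertions of one deme in flat arrays.

    Columns are insertion loci: ``col_site`` (encoded genomic site),
    ``col_allele`` (0 = FL, otherwise an ID variant id), plus cached
    chromosome/position/cluster membership.  Entries are (haplotype row,
    column) pairs: ``e_hap`` (0..2N-1, sorted) and ``e_col``.
    """

    __slots__ = (
        "N", "genome", "col_site", "col_allele", "col_chrom", "col_pos",
        "col_cluster", "e_hap", "e_col", "index",
    )

    def __init__(self, N, genome, col_site, col_allele, col_chrom, col_pos,
                 col_cluster, e_hap, e_col, index=0):
        self.N = N
        self.genome = genome
        self.col_site = col_site
        self.col_allele = col_allele
        self.col_chrom = col_chrom
        self.col_pos = col_pos
        self.col_cluster = col_cluster
        self.e_hap = e_hap
        self.e_col = e_col
        self.index = index

    # -- constructors -------------------------------------------------------

    @classmethod
    def empty(cls, N: int, genome: Genome, index: int = 0) -> "Population":
        z64 = np.empty(0, dtype=np.int64)
        return cls(
            N, genome,
            z64, np.empty(0, dtype=np.int32), np.empty(0, dtype=np.int8),
            np.empty(0, dtype=np.int32), np.empty(0, dtype=bool),
            np.empty(0, dtype=np.int32), np.empty(0, dtype=np.int32), index,
        )

    @classmethod
    def from_columns(cls, N, genome, sites, alleles, e_hap, e_col, index=0):
        sites = np.asarray(sites, dtype=np.int64)
        alleles = np.asarray(alleles, dtype=np.int32)
        chrom = genome.chrom_of_site(sites).astype(np.int8)
        pos = (sites - genome.offsets[chrom] + 1).astype(np.int32)
        cluster = pos >= genome.cluster_start[chrom]
        e_hap = np.asarray(e_hap, dtype=np.int32)
        e_col = np.asarray(e_col, dtype=np.int32)
        order = np.lexsort((e_col, e_hap))
        return cls(N, genome, sites, alleles, chrom, pos, cluster,
                   e_hap[order], e_col[order], index)

    # -- summaries ----------------------------------------------------------

    @property
    def n_copies(self) -> int:
        return len(self.e_hap)

    def copy_numbers(self) -> np.ndarray:
        """Diploid copy number per individual."""
        ind = self.e_hap >> 1
        return np.bincount(ind, minlength=self.N)

    def allele_per_copy(self) -> np.ndarray:
        return self.col_allele[self.e_col]

    def fl_counts(self) -> np.ndarray:
        ind = self.e_hap >> 1
        fl = self.allele_per_copy() == 0
        return np.bincount(ind[fl], minlength=self.N)

    def cluster_counts(self) -> np.ndarray:
        ind = self.e_hap >> 1
        cl = self.col_cluster[self.e_col]
        return np.bincount(ind[cl], minlength=self.N)

    def active_mask(self) -> np.ndarray:
        """Per-individual trap-model activity (vectorized twin of
        :func:`is_active`)."""
        return (self.fl_counts() > 0) & (self.cluster_counts() == 0)

    def fraction_id(self) -> float:
        if self.n_copies == 0:
            return 0.0
        return float(np.count_nonzero(self.allele_per_copy()) / self.n_copies)

    def variant_ids(self) -> np.ndarray:
        """Distinct ID variant ids present (excluding FL)."""
        a = np.unique(self.allele_per_copy())
        return a[a > 0]

    def individual(self, i: int, registry: VariantRegistry) -> Individual:
        """Materialize individual ``i`` as the scalar object model."""
        haps = ([], [])
        lo, hi = np.searchsorted(self.e_hap, [2 * i, 2 * i + 2])
        for k in range(lo, hi):
            col = self.e_col[k]
            a = int(self.col_allele[col])
            variant = registry.get(a) if a > 0 else None
            haps[self.e_hap[k] - 2 * i].append(
                TEInsertion(int(self.col_chrom[col]), int(self.col_pos[col]), variant)
            )
        return Individual(list(haps[0]), list(haps[1]))


@dataclass
class Metapopulation:
    """Ordered 1D chain of demes sharing a variant registry."""

    populations: list
    registry: VariantRegistry
    invaded: list = field(default_factory=list)  # indices with TE copies


def init_population(
    cfg: SimConfig,
    n_fl: int,
    rng: np.random.Generator,
    genome: Optional[Genome] = None,
    index: int = 0,
) -> Population:
    """Seed a deme with ``n_fl`` FL insertions at uniformly random distinct
    sites, each on one haplotype of one random individual (population
    frequency 1/2N)."""
    genome = genome or cfg.genome()
    if n_fl > genome.total_bp:
        raise ValueError("more initial insertions than genomic sites")
    if n_fl == 0:
        return Population.empty(cfg.N, genome, index)
    sites = rng.choice(genome.total_bp, size=n_fl, replace=False, shuffle=False)
    haps = rng.integers(0, 2 * cfg.N, size=n_fl)
    return Population.from_columns(
        cfg.N, genome, np.sort(sites), np.zeros(n_fl, dtype=np.int32),
        haps, np.arange(n_fl), index,
    )


def _draw_parents(N: int, weights: Optional[np.ndarray], rng: np.random.Generator):
    """Fitness-proportional mate pairs; each offspring draws two distinct
    parents.  ``weights=None`` means neutral (uniform)."""
    if weights is None:
        pa = rng.integers(0, N, size=N)
        pb = rng.integers(0, N, size=N)
        bad = pb == pa
        while bad.any():
            pb[bad] = rng.integers(0, N, size=int(bad.sum()))
            bad = pb == pa
        return pa, pb
    total = weights.sum()
    if total <= 0:
        raise ExtinctionError("all individuals have zero fitness")
    p = weights / total
    pa = rng.choice(N, size=N, p=p)
    pb = rng.choice(N, size=N, p=p)
    bad = pb == pa
    while bad.any():
        pb[bad] = rng.choice(N, size=int(bad.sum()), p=p)
        bad = pb == pa
    return pa, pb


def _dedupe_sites(gam, sites, taken_keys_sorted, total_bp, rng):
    """Redraw new-insertion sites that collide with an occupied site of the
    same gamete (or with another new insertion on it)."""
    while True:
        keys = gam.astype(np.int64) * total_bp + sites
        bad = np.zeros(len(keys), dtype=bool)
        if len(taken_keys_sorted):
            idx = np.searchsorted(taken_keys_sorted, keys)
            idx = np.minimum(idx, len(taken_keys_sorted) - 1)
            bad |= taken_keys_sorted[idx] == keys
        order = np.argsort(keys, kind="stable")
        ks = keys[order]
        dup = np.zeros(len(ks), dtype=bool)
        dup[1:] = ks[1:] == ks[:-1]
        bad[order] |= dup
        if not bad.any():
            return sites
        sites = sites.copy()
        sites[bad] = rng.integers(0, total_bp, size=int(bad.sum()))


def step_generation(
    pop: Population,
    cfg: SimConfig,
    rng: np.random.Generator,
    registry: VariantRegistry,
) -> Population:
    """Advance one deme by one generation (steps 1-6 of the life cycle)."""
    N = pop.N
    genome = pop.genome
    e_hap, e_col = pop.e_hap, pop.e_col
    nnz = len(e_hap)

    rowcnt = np.bincount(e_hap, minlength=2 * N)
    indptr = np.concatenate([[0], np.cumsum(rowcnt)])
    n_ind = rowcnt.reshape(N, 2).sum(axis=1)
    allele_per_entry = pop.col_allele[e_col]
    is_id_entry = allele_per_entry > 0
    ind_per_entry = e_hap >> 1
    fl_ind = np.bincount(ind_per_entry[~is_id_entry], minlength=N)
    clus_ind = np.bincount(ind_per_entry[pop.col_cluster[e_col]], minlength=N)

    # 1) mate pairs from fitness w = max(0, 1 - x * n)
    weights = None
    if cfg.x > 0.0:
        weights = np.clip(1.0 - cfg.x * n_ind, 0.0, None)
    pa, pb = _draw_parents(N, weights, rng)
    P = np.empty(2 * N, dtype=np.int64)  # parent of each gamete
    P[0::2] = pa
    P[1::2] = pb

    # 2) meiosis: chromosome-level assortment + rare crossovers
    nchrom = genome.n_chrom
    bits = rng.integers(0, 2, size=(2 * N, nchrom), dtype=np.uint8)
    xnum = rng.poisson(lam=genome.xover_lambda, size=(2 * N, nchrom))

    rows = np.repeat(2 * P, 2)
    rows[1::2] += 1
    cnts = rowcnt[rows]
    tot = int(cnts.sum())
    if tot:
        cum = np.cumsum(cnts)
        gather = np.arange(tot) - np.repeat(cum - cnts, cnts) + np.repeat(indptr[rows], cnts)
        blk_g = np.repeat(np.arange(2 * N, dtype=np.int64), 2)
        g_per = np.repeat(blk_g, cnts)
        src_a = np.repeat((np.arange(4 * N) & 1) == 0, cnts)
        cols_g = e_col[gather]
        chrom_g = pop.col_chrom[cols_g].astype(np.int64)
        keep = src_a == (bits[g_per, chrom_g] == 1)
        if xnum.any():
            xg, xc = np.nonzero(xnum)
            reps = xnum[xg, xc]
            xg = np.repeat(xg, reps)
            xc = np.repeat(xc, reps)
            xpos = rng.integers(1, genome.chrom_len[xc] + 1)
            span = genome.max_len + 2
            comb = (xg * nchrom + xc) * span + xpos
            comb.sort()
            # parity only matters for entries on (gamete, chromosome) pairs
            # that actually recombined — a small minority
            hit = np.flatnonzero(xnum[g_per, chrom_g] > 0)
            if len(hit):
                ekey = (g_per[hit] * nchrom + chrom_g[hit]) * span
                lo = np.searchsorted(comb, ekey, side="left")
                hi = np.searchsorted(comb, ekey + pop.col_pos[cols_g[hit]], side="right")
                keep[hit] ^= ((hi - lo) & 1).astype(bool)
        inh_g = g_per[keep].astype(np.int32)
        inh_col = cols_g[keep]
    else:
        inh_g = np.empty(0, dtype=np.int32)
        inh_col = np.empty(0, dtype=np.int32)

    # 3) transposition into gametes of active parents
    active = (fl_ind > 0) & (clus_ind == 0)
    lam_t = np.where(active[P], cfg.u * n_ind[P] * 0.5, 0.0)
    nnew = rng.poisson(lam_t) if lam_t.any() else np.zeros(2 * N, dtype=np.int64)
    ttot = int(nnew.sum())
    S = len(pop.col_site)
    if ttot:
        gam_new = np.repeat(np.arange(2 * N, dtype=np.int64), nnew)
        par_new = P[gam_new]
        # per-individual entry ordering with FL copies first
        order = np.lexsort((is_id_entry, ind_per_entry))
        starts2 = np.concatenate([[0], np.cumsum(n_ind)])
        nFL = fl_ind[par_new]
        nID = n_ind[par_new] - nFL
        wFL = cfg.fl_id * nFL
        wID = (1.0 - cfg.fl_id) * nID
        p_fl = wFL / (wFL + wID)
        src_fl = rng.random(ttot) < p_fl
        u1 = rng.random(ttot)
        off = np.where(src_fl, (u1 * nFL).astype(np.int64),
                       nFL + (u1 * nID).astype(np.int64))
        src_entry = order[starts2[par_new] + off]
        new_allele = allele_per_entry[src_entry].astype(np.int32)
        conv = src_fl & (rng.random(ttot) < cfg.c)
        if conv.any():
            new_allele[conv] = registry.new_batch(int(conv.sum()), rng)
        taken = np.sort(inh_g.astype(np.int64) * genome.total_bp + pop.col_site[inh_col])
        sites = rng.integers(0, genome.total_bp, size=ttot)
        sites = _dedupe_sites(gam_new, sites, taken, genome.total_bp, rng)
        new_chrom = genome.chrom_of_site(sites).astype(np.int8)
        new_pos = (sites - genome.offsets[new_chrom] + 1).astype(np.int32)
        new_cluster = new_pos >= genome.cluster_start[new_chrom]
        e_hap_new = np.concatenate([inh_g, gam_new.astype(np.int32)])
        e_col_new = np.concatenate([inh_col, (S + np.arange(ttot)).astype(np.int32)])
        col_site = np.concatenate([pop.col_site, sites])
        col_allele = np.concatenate([pop.col_allele, new_allele])
        col_chrom = np.concatenate([pop.col_chrom, new_chrom])
        col_pos = np.concatenate([pop.col_pos, new_pos])
        col_cluster = np.concatenate([pop.col_cluster, new_cluster])
    else:
        e_hap_new, e_col_new = inh_g, inh_col
        col_site, col_allele = pop.col_site, pop.col_allele
        col_chrom, col_pos, col_cluster = pop.col_chrom, pop.col_pos, pop.col_cluster

    # 4) zygotes: gametes 2o and 2o+1 are the haplotypes of offspring o.
    # prune columns no longer carried by anyone
    present = np.bincount(e_col_new, minlength=len(col_site)) > 0
    remap = np.cumsum(present, dtype=np.int32) - 1
    e_col_new = remap[e_col_new]
    # entries only need to be grouped by haplotype row
    order = np.argsort(e_hap_new, kind="stable")
    return Population(
        N, genome,
        col_site[present], col_allele[present], col_chrom[present],
        col_pos[present], col_cluster[present],
        e_hap_new[order], e_col_new[order], pop.index,
    )


def migrate(
    source: Population,
    target: Population,
    m: int,
    rng: np.random.Generator,
) -> tuple:
    """Copy ``m`` individuals, sampled without replacement from the source,
    over ``m`` uniformly chosen target individuals.  The source is left
    unchanged and both demes keep census size N."""
    N = source.N
    if m > N:
        raise ValueError("cannot move more migrants than individuals")
    if m == 0:
        return source, target
    mig = rng.choice(N, size=m, replace=False, shuffle=False)
    repl = rng.choice(N, size=m, replace=False, shuffle=False)

    # entries of the migrating individuals, re-homed onto the replaced slots
    e_hap, e_col = source.e_hap, source.e_col
    lo = np.searchsorted(e_hap, 2 * mig)
    hi = np.searchsorted(e_hap, 2 * mig + 2)
    cnts = hi - lo
    tot = int(cnts.sum())
    cum = np.cumsum(cnts)
    gather = np.arange(tot) - np.repeat(cum - cnts, cnts) + np.repeat(lo, cnts)
    src_entries_col = e_col[gather]
    within = e_hap[gather] - np.repeat(2 * mig, cnts)  # 0 or 1
    new_hap = np.repeat(2 * repl, cnts) + within

    # surviving target entries
    keep = ~np.isin(target.e_hap >> 1, repl)
    t_hap = target.e_hap[keep]
    t_col = target.e_col[keep]

    # merge column spaces on (site, allele): same variant at the same site is
    # the same ancestral insertion
    vmax = int(max(source.col_allele.max(initial=0), target.col_allele.max(initial=0))) + 1
    tkey = target.col_site * vmax + target.col_allele
    skey = source.col_site * vmax + source.col_allele
    all_keys = np.concatenate([tkey[np.unique(t_col)] if len(t_col) else tkey[:0],
                               skey[np.unique(src_entries_col)] if tot else skey[:0]])
    uniq, inv = np.unique(all_keys, return_inverse=True)
    n_t = len(np.unique(t_col)) if len(t_col) else 0
    # per-column remaps
    t_remap = np.full(len(target.col_site), -1, dtype=np.int64)
    s_remap = np.full(len(source.col_site), -1, dtype=np.int64)
    if n_t:
        t_remap[np.unique(t_col)] = inv[:n_t]
    if tot:
        s_remap[np.unique(src_entries_col)] = inv[n_t:]
    sites = uniq // vmax
    alleles = (uniq % vmax).astype(np.int32)
    new_t = Population.from_columns(
        N, target.genome, sites, alleles,
        np.concatenate([t_hap, new_hap.astype(np.int32)]),
        np.concatenate([t_remap[t_col], s_remap[src_entries_col]]).astype(np.int32),
        target.index,
    )
    return source, new_t


def population_fingerprint(
    pop: Population,
    registry: VariantRegistry,
    sample_id: str = "pop",
) -> Fingerprint:
    """ID fingerprint of a deme: for every distinct ID variant its frequency
    among all TE copies (FL frequency is the complement 1 - sum f_i).  The
    support column carries the raw copy count."""
    if pop.n_copies == 0:
        raise ValueError("fingerprint undefined for a population without TE copies")
    alleles = pop.allele_per_copy()
    counts = np.bincount(alleles)
    total = pop.n_copies
    entries = []
    for vid in np.nonzero(counts)[0]:
        if vid == 0:
            continue
        entries.append(FingerprintEntry(
            start=registry.start[vid], end=registry.end[vid],
            frequency=counts[vid] / total, support=int(counts[vid]),
            label=f"v{vid}",
        ))
    entries.sort(key=lambda e: (e.start, e.end, e.label))
    return Fingerprint(sample_id=sample_id, entries=entries)


# ---------------------------------------------------------------------------
# whole-run drivers
# ---------------------------------------------------------------------------


@dataclass
class InvasionRecord:
    """Per-generation time series for one deme."""

    population: int
    generations: np.ndarray
    copy_number: np.ndarray       # mean diploid copies per individual
    fraction_id: np.ndarray
    cluster_insertions: np.ndarray  # total cluster copies in the deme
    n_variants: np.ndarray
    fingerprint: Optional[Fingerprint] = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "generation": self.generations,
            "population": self.population,
            "copy_number": self.copy_number,
            "fraction_id": self.fraction_id,
            "cluster_insertions": self.cluster_insertions,
            "n_variants": self.n_variants,
        })


def _snapshot(pop: Population) -> tuple:
    cl = int(pop.col_cluster[pop.e_col].sum()) if pop.n_copies else 0
    return (pop.n_copies / pop.N, pop.fraction_id(), cl, len(pop.variant_ids()))


def run_single_invasion(
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> InvasionRecord:
    """Run one single-deme invasion for ``cfg.generations`` generations and
    record the time series every ``cfg.record_every`` generations."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    genome = cfg.genome()
    registry = VariantRegistry(cfg.te_length)
    pop = init_population(cfg, cfg.n_fl_init, rng, genome)
    gens, rows = [], []
    gens.append(0)
    rows.append(_snapshot(pop))
    for t in range(1, cfg.generations + 1):
        pop = step_generation(pop, cfg, rng, registry)
        if t % cfg.record_every == 0:
            gens.append(t)
            rows.append(_snapshot(pop))
    arr = np.array(rows)
    fp = population_fingerprint(pop, registry, "pop1") if pop.n_copies else None
    return InvasionRecord(
        population=1,
        generations=np.array(gens),
        copy_number=arr[:, 0],
        fraction_id=arr[:, 1],
        cluster_insertions=arr[:, 2].astype(int),
        n_variants=arr[:, 3].astype(int),
        fingerprint=fp,
    )


@dataclass
class SteppingStoneResult:
    records: list                 # one InvasionRecord per deme
    fingerprints: list            # final Fingerprint (or None) per deme
    registry: VariantRegistry

    def private_id_fraction(self) -> float:
        """Fraction of distinct ID variants present in exactly one deme at
        the final generation (by simulation-truth variant id)."""
        presence = {}
        for fp in self.fingerprints:
            if fp is None:
                continue
            for e in fp.entries:
                presence[e.label] = presence.get(e.label, 0) + 1
        if not presence:
            return float("nan")
        npriv = sum(1 for v in presence.values() if v == 1)
        return npriv / len(presence)


def run_stepping_stone(
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> SteppingStoneResult:
    """1D stepping-stone invasion: the TE is seeded in deme 1; every
    ``migration_interval`` generations ``migration_size`` migrants are copied
    from the most recently invaded deme into the next naive one, triggering
    a fresh invasion there."""
    if cfg.n_populations < 2:
        raise ValueError("stepping-stone model needs at least two populations")
    n_events = cfg.n_populations - 1
    if cfg.migration_interval * n_events > cfg.generations:
        raise ValueError("migration schedule does not fit into the run length")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    genome = cfg.genome()
    registry = VariantRegistry(cfg.te_length)
    pops = [init_population(cfg, cfg.n_fl_init, rng, genome, index=0)]
    pops += [Population.empty(cfg.N, genome, index=i) for i in range(1, cfg.n_populations)]
    invaded = [True] + [False] * (cfg.n_populations - 1)
    series = [[] for _ in pops]
    gens = []

    def record(t):
        gens.append(t)
        for i, p in enumerate(pops):
            series[i].append(_snapshot(p))

    record(0)
    for t in range(1, cfg.generations + 1):
        for i in range(cfg.n_populations):
            if invaded[i]:
                pops[i] = step_generation(pops[i], cfg, rng, registry)
        if t % cfg.migration_interval == 0:
            k = t // cfg.migration_interval
            if 1 <= k <= n_events:
                src, dst = k - 1, k
                pops[src], pops[dst] = migrate(pops[src], pops[dst], cfg.migration_size, rng)
                invaded[dst] = invaded[dst] or pops[dst].n_copies > 0
        if t % cfg.record_every == 0:
            record(t)

    fps = []
    for i, p in enumerate(pops):
        fps.append(
            population_fingerprint(p, registry, f"pop{i + 1}") if p.n_copies else None
        )
    records = []
    for i in range(cfg.n_populations):
        arr = np.array(series[i])
        records.append(InvasionRecord(
            population=i + 1,
            generations=np.array(gens),
            copy_number=arr[:, 0],
            fraction_id=arr[:, 1],
            cluster_insertions=arr[:, 2].astype(int),
            n_variants=arr[:, 3].astype(int),
            fingerprint=fps[i],
        ))
    return SteppingStoneResult(records=records, fingerprints=fps, registry=registry)
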