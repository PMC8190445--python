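"""Forward-time Wright-Fisher simulation of deleterious and neutral mutation.

Simulates a single diploid chromosome under recurrent mutation (a fixed
fraction of new mutations deleterious with gamma-distributed selection
coefficients and partial dominance, the rest neutral), uniform recombination,
multiplicative soft selection and a configurable demographic history.  The
default history mirrors the Soay sheep reconstruction: a large ancestral
population, an instantaneous contraction on island colonisation, a recent
severe bottleneck and rapid exponential recovery.

Haplotypes are stored as position-sorted arrays of mutation ids (an
infinite-sites approximation: every mutation gets a unique base-pair
position).  Deleterious and neutral mutations are kept in separate arrays so
fitness evaluation touches only the deleterious set.

A population-rescaling helper divides population sizes and durations by a
factor Q while multiplying mutation and recombination rates and selection
coefficients by Q, preserving the products N*mu, N*r and N*s that govern the
dynamics; this is the standard trick for running such histories at desk scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numba
import numpy as np
import pandas as pd

__all__ = [
    "DemographyConfig",
    "DFEConfig",
    "GenomeConfig",
    "SimResult",
    "soay_demography",
    "sample_dfe",
    "fitness",
    "run_simulation",
    "rescale_config",
    "export_vcf",
]


@dataclass
class DemographyConfig:
    """Piecewise demographic history.

    ``phases`` is an ordered list of either ``("const", N, duration)`` or
    ``("exp", n_from, n_to, duration)``; an exponential phase realizes
    ``N(t) = round(n_from * (n_to / n_from)**(t / duration))`` for
    ``t = 1..duration``.
    """

    phases: list[tuple]

    def realize(self) -> np.ndarray:
        """Diploid population size for every generation (index 0 = first)."""
        sizes: list[int] = []
        for phase in self.phases:
            if phase[0] == "const":
                _, n, dur = phase
                if n < 2 or dur < 1:
                    raise ValueError(f"invalid constant phase {phase}")
                sizes.extend([int(n)] * int(dur))
            elif phase[0] == "exp":
                _, n0, n1, dur = phase
                if n0 < 2 or n1 < 2 or dur < 1:
                    raise ValueError(f"invalid exponential phase {phase}")
                for t in range(1, int(dur) + 1):
                    sizes.append(int(round(n0 * (n1 / n0) ** (t / dur))))
            else:
                raise ValueError(f"unknown phase kind {phase[0]!r}")
        return np.asarray(sizes, dtype=np.int64)

    @property
    def total_generations(self) -> int:
        return int(sum(int(p[-1]) for p in self.phases))


@dataclass
class DFEConfig:
    """Distribution of fitness effects for new mutations.

    Deleterious selection coefficients are drawn from a gamma distribution
    with mean ``|mean_s|`` and shape ``shape``, then negated; heterozygotes
    express a fraction ``h`` of the homozygous effect.  A fraction
    ``p_neutral`` of new mutations are neutral (s = 0).
    """

    mean_s: float = -0.03
    shape: float = 0.2
    h: float = 0.05
    p_deleterious: float = 0.7
    p_neutral: float = 0.3

    def __post_init__(self) -> None:
        if self.mean_s >= 0:
            raise ValueError("mean_s must be negative")
        if self.shape <= 0:
            raise ValueError("gamma shape must be positive")
        if not (0 <= self.h <= 1):
            raise ValueError("dominance coefficient h must be in [0, 1]")
        if abs(self.p_deleterious + self.p_neutral - 1.0) > 1e-9:
            raise ValueError("p_deleterious + p_neutral must equal 1")


@dataclass
class GenomeConfig:
    """Uniform single-chromosome genome; with the defaults (100 Mb, both rates
    1e-8 per bp per generation) 1 Mb corresponds to 1 cM."""

    length_bp: int = 100_000_000
    recombination_rate: float = 1e-8
    mutation_rate: float = 1e-8

    def __post_init__(self) -> None:
        if self.length_bp <= 0 or self.recombination_rate <= 0 or self.mutation_rate <= 0:
            raise ValueError("genome parameters must be positive")


@dataclass
class SimResult:
    """Final-generation sample over segregating sites.

    ``haplotypes`` is a ``(2N, n_sites)`` 0/1 array (phased); ``positions``
    are 1-based bp sorted ascending; ``mutation_table`` has one row per
    segregating site (id, position_bp, s, h, kind, origin_generation,
    frequency); ``demography_trace`` is the realized N per generation.
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    mutation_table: pd.DataFrame
    demography_trace: np.ndarray
    seed: int

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def genotypes(self) -> np.ndarray:
        """(n_individuals, n_sites) derived-allele counts in {0, 1, 2}."""
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)


def soay_demography() -> DemographyConfig:
    """The Soay sheep demographic schedule, 11,000 generations in total.

    An ancestral population of 1000 diploids for 10,000 generations, an
    instantaneous contraction to 200 on island colonisation held for 970
    generations, a one-generation crash to 10 individuals 30 generations
    before sampling, exponential recovery to 200 within 20 generations, and
    200 individuals for the remaining 9 generations.
    """
    return DemographyConfig(phases=[
        ("const", 1000, 10_000),
        ("const", 200, 970),
        ("const", 10, 1),
        ("exp", 10, 200, 20),
        ("const", 200, 9),
    ])


def sample_dfe(n: int, dfe: DFEConfig, rng) -> np.ndarray:
    """Draw ``n`` deleterious selection coefficients (all < 0) from the gamma DFE."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    scale = abs(dfe.mean_s) / dfe.shape
    return -rng.gamma(dfe.shape, scale, size=n)


def fitness(genotype_codes: np.ndarray, s: np.ndarray, h) -> float:
    """Multiplicative relative fitness of one individual.

    ``genotype_codes`` holds derived-allele counts per mutation (0/1/2) and
    ``s`` the matching selection coefficients; homozygotes contribute
    ``1 + s``, heterozygotes ``1 + h*s``.  Clamped below at 0.
    """
    g = np.asarray(genotype_codes)
    s = np.asarray(s, dtype=float)
    h = np.asarray(h, dtype=float)
    factors = np.where(g == 2, 1.0 + s, np.where(g == 1, 1.0 + h * s, 1.0))
    if np.any(factors <= 0):
        return 0.0
    return float(np.prod(factors))


def rescale_config(demography: DemographyConfig, genome: GenomeConfig,
                   dfe: DFEConfig, Q: float):
    """Rescale a (demography, genome, DFE) triple by a factor ``Q >= 1``.

    Population sizes are divided by Q (rounded, floored at 2), phase durations
    divided by Q (rounded up), and mutation rate, recombination rate and mean
    selection coefficient multiplied by Q, preserving N*mu, N*r and N*s.
    """
    if Q < 1:
        raise ValueError("Q must be >= 1")

    def scale_n(n):
        if n / Q < 1:
            raise ValueError(f"Q = {Q} reduces population size {n} below 1")
        return max(2, int(round(n / Q)))

    phases = []
    for phase in demography.phases:
        if phase[0] == "const":
            _, n, dur = phase
            phases.append(("const", scale_n(n), math.ceil(dur / Q)))
        else:
            _, n0, n1, dur = phase
            phases.append(("exp", scale_n(n0), scale_n(n1), math.ceil(dur / Q)))
    demo = DemographyConfig(phases=phases)
    gen = replace(genome, mutation_rate=genome.mutation_rate * Q,
                  recombination_rate=genome.recombination_rate * Q)
    d = replace(dfe, mean_s=dfe.mean_s * Q)
    return demo, gen, d


class _MutationRegistry:
    """Append-only store of mutation attributes, indexed by integer id."""

    def __init__(self) -> None:
        cap = 1024
        self.pos = np.empty(cap, dtype=np.int64)
        self.s = np.empty(cap, dtype=np.float64)
        self.kind_del = np.empty(cap, dtype=bool)
        self.origin = np.empty(cap, dtype=np.int32)
        self.n = 0
        self.used_positions: set[int] = set()

    def _grow(self, need: int) -> None:
        cap = self.pos.size
        if self.n + need <= cap:
            return
        new_cap = max(cap * 2, self.n + need)
        for name in ("pos", "s", "kind_del", "origin"):
            arr = getattr(self, name)
            new = np.empty(new_cap, dtype=arr.dtype)
            new[:self.n] = arr[:self.n]
            setattr(self, name, new)

    def add(self, positions, s_vals, is_del, gen) -> np.ndarray:
        k = len(positions)
        self._grow(k)
        ids = np.arange(self.n, self.n + k, dtype=np.int64)
        self.pos[self.n:self.n + k] = positions
        self.s[self.n:self.n + k] = s_vals
        self.kind_del[self.n:self.n + k] = is_del
        self.origin[self.n:self.n + k] = gen
        self.n += k
        return ids


@numba.njit(cache=True)
def _merge_gamete(reg_pos, ids_a, ids_b, breaks, start_with_a, new_pos, new_ids):
    """Build one gamete: alternate between two position-sorted id arrays at the
    crossover ``breaks`` (position >= break switches source), then merge in the
    position-sorted new mutations."""
    na, nb = ids_a.size, ids_b.size
    core = np.empty(na + nb, dtype=np.int64)
    n = 0
    i = j = 0
    use_a = start_with_a
    for t in range(breaks.size + 1):
        bnd = breaks[t] if t < breaks.size else np.int64(2**62)
        if use_a:
            while i < na and reg_pos[ids_a[i]] < bnd:
                core[n] = ids_a[i]
                n += 1
                i += 1
            while j < nb and reg_pos[ids_b[j]] < bnd:
                j += 1
        else:
            while j < nb and reg_pos[ids_b[j]] < bnd:
                core[n] = ids_b[j]
                n += 1
                j += 1
            while i < na and reg_pos[ids_a[i]] < bnd:
                i += 1
        use_a = not use_a
    if new_ids.size == 0:
        return core[:n].copy()
    out = np.empty(n + new_ids.size, dtype=np.int64)
    i = j = k = 0
    while i < n and j < new_ids.size:
        if reg_pos[core[i]] <= new_pos[j]:
            out[k] = core[i]
            i += 1
        else:
            out[k] = new_ids[j]
            j += 1
        k += 1
    while i < n:
        out[k] = core[i]
        i += 1
        k += 1
    while j < new_ids.size:
        out[k] = new_ids[j]
        j += 1
        k += 1
    return out


@numba.njit(cache=True)
def _log_fitness_kernel(d1, d2, reg_pos, reg_s, h):
    """Log multiplicative fitness from two position-sorted deleterious-id
    arrays; -inf when any factor is <= 0 (infinite sites: equal positions
    imply the same mutation)."""
    lw = 0.0
    i = j = 0
    n1, n2 = d1.size, d2.size
    while i < n1 and j < n2:
        pa, pb = reg_pos[d1[i]], reg_pos[d2[j]]
        if pa == pb:
            f = 1.0 + reg_s[d1[i]]
            i += 1
            j += 1
        elif pa < pb:
            f = 1.0 + h * reg_s[d1[i]]
            i += 1
        else:
            f = 1.0 + h * reg_s[d2[j]]
            j += 1
        if f <= 0.0:
            return -np.inf
        lw += math.log(f)
    while i < n1:
        f = 1.0 + h * reg_s[d1[i]]
        if f <= 0.0:
            return -np.inf
        lw += math.log(f)
        i += 1
    while j < n2:
        f = 1.0 + h * reg_s[d2[j]]
        if f <= 0.0:
            return -np.inf
        lw += math.log(f)
        j += 1
    return lw


def run_simulation(demography: DemographyConfig, dfe: DFEConfig,
                   genome: GenomeConfig, seed: int) -> SimResult:
    """Run the Wright-Fisher simulation and return the final population.

    Each generation, offspring draw two parents (selfing permitted) with
    probability proportional to multiplicative fitness; each transmitted
    gamete recombines with a Poisson number of crossovers at uniform positions
    and acquires Poisson(mu * L) new mutations, each deleterious with
    probability ``p_deleterious``.  Fixed mutations are removed from the
    segregating set.  Returns all individuals of the final generation over
    segregating sites only.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    rng = np.random.default_rng(seed)
    trace = demography.realize()
    if trace.size == 0 or trace[0] <= 0:
        raise ValueError("demography must have at least one generation of size > 0")
    L = genome.length_bp
    mu_count = genome.mutation_rate * L
    rec_count = genome.recombination_rate * L

    reg = _MutationRegistry()
    empty = np.empty(0, dtype=np.int64)
    # haplotypes: per hap a pair [deleterious ids, neutral ids], position-sorted
    n0 = int(trace[0])
    haps_d = [empty] * (2 * n0)
    haps_n = [empty] * (2 * n0)

    def draw_positions(k: int, buf) -> np.ndarray:
        out = np.empty(k, dtype=np.int64)
        filled = 0
        while filled < k:
            cand = buf.positions(k - filled)
            for c in cand:  # infinite sites: never reuse a position
                c = int(c)
                if c not in reg.used_positions:
                    reg.used_positions.add(c)
                    out[filled] = c
                    filled += 1
        return out

    def purge_fixed(n_cur: int) -> None:
        if reg.n == 0:
            return
        counts = np.zeros(reg.n, dtype=np.int64)
        for arr in haps_d:
            counts[arr] += 1
        for arr in haps_n:
            counts[arr] += 1
        fixed = counts == 2 * n_cur
        if not np.any(fixed):
            return
        keep = ~fixed
        for i in range(2 * n_cur):
            haps_d[i] = haps_d[i][keep[haps_d[i]]]
            haps_n[i] = haps_n[i][keep[haps_n[i]]]

    h = dfe.h
    empty_i = np.empty(0, dtype=np.int64)

    class _Buffers:
        """Chunked pre-drawn randomness for the per-gamete bookkeeping (one
        vectorized RNG call amortized over ~a generation of gametes)."""

        def __init__(self, size: int):
            self.size = max(size, 64)
            self._refill()

        def _refill(self) -> None:
            n = self.size
            self.n_x = rng.poisson(rec_count, n)
            self.n_mut = rng.poisson(mu_count, n)
            self.start = rng.integers(0, 2, n).astype(bool)
            self.unif = rng.random(2 * n)
            m = int(n * (rec_count + mu_count + 8))
            self.ints = rng.integers(1, L + 1, size=m)
            self.i = 0
            self.ui = 0
            self.ii = 0

        def gamete_draw(self):
            if self.i >= self.size:
                self._refill()
            out = (int(self.n_x[self.i]), int(self.n_mut[self.i]),
                   bool(self.start[self.i]))
            self.i += 1
            return out

        def uniform(self) -> float:
            if self.ui >= self.unif.size:
                self._refill()
            u = self.unif[self.ui]
            self.ui += 1
            return u

        def positions(self, k: int) -> np.ndarray:
            if self.ii + k > self.ints.size:
                self._refill()
            out = self.ints[self.ii:self.ii + k]
            self.ii += k
            return out

    def propose_gamete(j: int, gen: int, buf: "_Buffers"):
        """Deleterious part of one recombinant, mutated gamete from parent j.

        The neutral part is only assembled once the offspring is accepted
        (viability depends on the deleterious set alone); new mutations are
        registered immediately, rejected proposals leave harmless orphans
        with zero copies.
        """
        n_x, k, start_a = buf.gamete_draw()
        breaks = np.sort(buf.positions(n_x)) if n_x else empty_i
        dpos = dids = npos_ = nids = empty_i
        if k:
            mpos = draw_positions(k, buf)
            is_del = rng.random(k) < dfe.p_deleterious
            s_vals = np.zeros(k)
            nd = int(is_del.sum())
            if nd:
                s_vals[is_del] = sample_dfe(nd, dfe, rng)
            ids = reg.add(mpos, s_vals, is_del, gen)
            order = np.argsort(mpos, kind="stable")
            mpos, ids, is_del = mpos[order], ids[order], is_del[order]
            dpos, dids = mpos[is_del], ids[is_del]
            npos_, nids = mpos[~is_del], ids[~is_del]
        gd = _merge_gamete(reg.pos, haps_d[2 * j], haps_d[2 * j + 1],
                           breaks, start_a, dpos, dids)
        return gd, (j, breaks, start_a, npos_, nids)

    def finish_gamete(recipe) -> np.ndarray:
        j, breaks, start_a, npos_, nids = recipe
        return _merge_gamete(reg.pos, haps_n[2 * j], haps_n[2 * j + 1],
                             breaks, start_a, npos_, nids)

    n_cur = n0
    logw = np.zeros(n_cur)  # fitness of the current (parent) generation
    for gen in range(1, trace.size):
        n_next = int(trace[gen])
        finite = np.isfinite(logw)
        if not np.any(finite):
            raise RuntimeError("population fitness collapsed to zero")
        w = np.exp(logw - logw[finite].max())
        cdf = np.cumsum(w / w.sum())

        new_d: list[np.ndarray] = []
        new_n: list[np.ndarray] = []
        new_logw = np.empty(n_next)
        buf = _Buffers(5 * n_next)
        for slot in range(n_next):
            # each census slot holds a *living* individual: offspring that are
            # dead at birth (fitness exactly 0, e.g. homozygous for a lethal)
            # are re-drawn; their fitness is cached as next generation's weight
            for attempt in range(2000):
                j1 = int(np.searchsorted(cdf, buf.uniform()))
                j2 = int(np.searchsorted(cdf, buf.uniform()))
                gd1, rec1 = propose_gamete(j1, gen, buf)
                gd2, rec2 = propose_gamete(j2, gen, buf)
                lw = _log_fitness_kernel(gd1, gd2, reg.pos, reg.s, h)
                if np.isfinite(lw):
                    break
            else:
                raise RuntimeError("could not produce a viable offspring")
            new_d.extend((gd1, gd2))
            new_n.extend((finish_gamete(rec1), finish_gamete(rec2)))
            new_logw[slot] = lw
        haps_d, haps_n = new_d, new_n
        logw = new_logw
        n_cur = n_next
        if gen % 25 == 0:
            purge_fixed(n_cur)

    purge_fixed(n_cur)
    # assemble final sample over segregating sites
    counts = np.zeros(reg.n, dtype=np.int64)
    for arr in haps_d:
        counts[arr] += 1
    for arr in haps_n:
        counts[arr] += 1
    seg = np.flatnonzero((counts > 0) & (counts < 2 * n_cur))
    order = np.argsort(reg.pos[seg], kind="stable")
    seg = seg[order]
    idmap = np.full(reg.n, -1, dtype=np.int64)
    idmap[seg] = np.arange(seg.size)
    H = np.zeros((2 * n_cur, seg.size), dtype=np.int8)
    for i in range(2 * n_cur):
        for arr in (haps_d[i], haps_n[i]):
            rows = idmap[arr]
            H[i, rows[rows >= 0]] = 1
    table = pd.DataFrame({
        "id": seg,
        "position_bp": reg.pos[seg],
        "s": reg.s[seg],
        "h": np.where(reg.kind_del[seg], dfe.h, 0.0),
        "kind": np.where(reg.kind_del[seg], "deleterious", "neutral"),
        "origin_generation": reg.origin[seg],
        "frequency": counts[seg] / (2 * n_cur),
    })
    return SimResult(haplotypes=H, positions=reg.pos[seg].copy(),
                     mutation_table=table, demography_trace=trace, seed=int(seed))


def export_vcf(result: SimResult, path, mutations_path=None) -> None:
    """Write the sample as a phased VCF v4.2 with per-site INFO fields
    ``S`` (selection coefficient), ``H`` (dominance) and ``KIND``; optionally
    also write the companion mutation table TSV."""
    n = result.n_individuals
    tbl = result.mutation_table
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=1,length={max(int(result.positions.max()) + 1, 2) if result.positions.size else 2}>\n")
        fh.write('##INFO=<ID=S,Number=1,Type=Float,Description="Selection coefficient">\n')
        fh.write('##INFO=<ID=H,Number=1,Type=Float,Description="Dominance coefficient">\n')
        fh.write('##INFO=<ID=KIND,Number=1,Type=String,Description="neutral or deleterious">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        names = "\t".join(f"ind{i}" for i in range(n))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{names}\n")
        for row_i in range(len(tbl)):
            rec = tbl.iloc[row_i]
            alleles = result.haplotypes[:, row_i]
            gts = "\t".join(f"{alleles[2 * i]}|{alleles[2 * i + 1]}" for i in range(n))
            info = f"S={rec['s']:.6g};H={rec['h']:.6g};KIND={rec['kind']}"
            fh.write(f"1\t{int(rec['position_bp'])}\tm{int(rec['id'])}\tA\tT\t.\tPASS\t{info}\tGT\t{gts}\n")
    if mutations_path is not None:
        tbl.to_csv(mutations_path, sep="\t", index=False)
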