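"""Structured-coalescent simulation of multi-population SNP genealogies.

This is the engine behind expected joint site-frequency spectra, the synthetic
dataset generator, and the neutral null distribution of the outlier scan. It
implements the continuous-time approximation of the Wright-Fisher coalescent
with demes: within deme ``i`` holding ``k_i`` lineages, pairs coalesce at total
rate ``k_i (k_i - 1) / (4 N_i)`` per generation (diploid ``N_i``), and each
lineage in ``i`` traces its parent to deme ``j`` at rate ``M[i][j]`` — the
backward-in-time migration convention. Demographic events (population joins,
instantaneous resizes, migration-matrix changes) are applied at fixed times in
generations before present.

Mutations are dropped on the realized genealogy either as an infinite-sites
Poisson process or in ``one_snp`` mode (exactly one mutation, branch chosen
proportional to length), which matches SNP loci ascertained to be polymorphic.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DemographicEvent",
    "DemographicModel",
    "SampleConfig",
    "Genealogy",
    "TrappedLineagesError",
    "CalibrationError",
    "simulate_genealogy",
    "simulate_branch_batches",
    "drop_mutations",
    "simulate_hierarchical_island",
]


class TrappedLineagesError(RuntimeError):
    """Lineages cannot reach a common ancestor (disconnected demes or time guard)."""


class CalibrationError(RuntimeError):
    """Migration-rate calibration failed to bracket the target F_ST."""


@dataclass(frozen=True)
class DemographicEvent:
    """A demographic change at ``time`` generations before present.

    kind 'join': all lineages in ``source`` move to ``sink``; migration to and
    from ``source`` is shut off; ``new_size`` optionally resizes ``sink`` at the
    same instant (the usual divergence-with-ancestral-size event).
    kind 'resize': deme ``deme`` takes diploid size ``new_size``.
    kind 'set_migration': the backward migration matrix is replaced.
    """

    time: float
    kind: str
    source: int | None = None
    sink: int | None = None
    deme: int | None = None
    new_size: float | None = None
    matrix: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event time must be >= 0")
        if self.kind not in ("join", "resize", "set_migration"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class DemographicModel:
    """Deme sizes, timed events and a backward migration matrix.

    ``deme_sizes`` are diploid effective sizes at time 0. ``migration[i][j]``
    is the per-generation probability that a lineage currently in deme ``i``
    traces its parent to deme ``j``.
    """

    deme_sizes: list[float]
    events: list[DemographicEvent] = field(default_factory=list)
    migration: list[list[float]] | None = None
    mutation_rate: float = 2.5e-8

    def __post_init__(self) -> None:
        n = len(self.deme_sizes)
        if any(s <= 0 for s in self.deme_sizes):
            raise ValueError("deme sizes must be positive")
        if self.migration is None:
            self.migration = [[0.0] * n for _ in range(n)]
        m = np.asarray(self.migration, dtype=float)
        if m.shape != (n, n):
            raise ValueError("migration matrix shape must match deme count")
        if (m < 0).any():
            raise ValueError("migration rates must be >= 0")
        if np.diag(m).any():
            raise ValueError("migration matrix diagonal must be zero")
        if (m.sum(axis=1) >= 1).any():
            raise ValueError("migration row sums must be < 1 per generation")
        self.migration = m.tolist()
        self.events = sorted(self.events, key=lambda e: e.time)

    @property
    def n_pops(self) -> int:
        return len(self.deme_sizes)


@dataclass(frozen=True)
class SampleConfig:
    """Haploid sample sizes per deme and the number of independent loci."""

    sample_sizes: tuple[int, ...]
    n_loci: int = 1
    locus_length: int = 1

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sample_sizes):
            raise ValueError("sample sizes must be >= 0")
        if self.n_loci < 1 or self.locus_length < 1:
            raise ValueError("n_loci and locus_length must be >= 1")


@dataclass
class Genealogy:
    """A realized coalescent tree for one locus.

    Nodes 0..n-1 are samples at time 0 (deme order: ``sample_sizes[0]`` leaves
    of deme 0 first, and so on); internal nodes follow in coalescence order.
    ``branch_configs[b]`` counts the leaves each non-root branch subtends per
    deme; ``branch_masks`` (optional) holds the same sets as leaf bitmasks.
    """

    n_samples: int
    sample_demes: np.ndarray
    node_times: np.ndarray
    node_parents: np.ndarray
    branch_configs: np.ndarray  # (2n-2, n_pops) leaves subtended per deme
    branch_lengths: np.ndarray
    branch_masks: list[int] | None = None

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths.sum())

    @property
    def tmrca(self) -> float:
        return float(self.node_times[-1]) if self.n_samples > 1 else 0.0


def _run_coalescent(
    sizes: list[float],
    migration: list[list[float]],
    events: list[DemographicEvent],
    sample_sizes: tuple[int, ...],
    rng: random.Random,
    *,
    max_time: float = 1e12,
    max_events: int = 5_000_000,
    track_leaves: bool = False,
    record_tree: bool = False,
):
    """Core event loop. Returns (configs, lengths, masks, tree_arrays)."""
    npop = len(sizes)
    sizes = [float(s) for s in sizes]
    mig = [list(map(float, row)) for row in migration]
    rowsum = [math.fsum(row) for row in mig]
    n = sum(sample_sizes)

    # lineage record: [birth_time, cfg tuple, leaf mask, node id]
    demes: list[list[list]] = [[] for _ in range(npop)]
    sample_demes = np.empty(n, dtype=np.int32)
    node_times = [0.0] * n if record_tree else None
    node_parents = [-1] * n if record_tree else None
    nid = 0
    for d, k in enumerate(sample_sizes):
        for _ in range(k):
            cfg = [0] * npop
            cfg[d] = 1
            demes[d].append([0.0, tuple(cfg), 1 << nid if track_leaves else 0, nid])
            sample_demes[nid] = d
            nid += 1

    cfgs: list[tuple[int, ...]] = []
    lens: list[float] = []
    masks: list[int] = [] if track_leaves else None

    ev = sorted(events, key=lambda e: e.time)
    ev_i = 0
    n_ev = len(ev)
    t = 0.0
    k_total = n
    expovariate = rng.expovariate
    rnd = rng.random
    n_steps = 0

    def apply_event(e: DemographicEvent) -> None:
        nonlocal rowsum, mig, sizes
        if e.kind == "join":
            demes[e.sink].extend(demes[e.source])
            demes[e.source] = []
            for i in range(npop):
                mig[i][e.source] = 0.0
            mig[e.source] = [0.0] * npop
            rowsum = [math.fsum(row) for row in mig]
            if e.new_size is not None:
                sizes[e.sink] = float(e.new_size)
        elif e.kind == "resize":
            sizes[e.deme] = float(e.new_size)
        else:  # set_migration
            mig = [list(map(float, row)) for row in e.matrix]
            rowsum = [math.fsum(row) for row in mig]

    while k_total > 1:
        n_steps += 1
        if n_steps > max_events:
            raise TrappedLineagesError(
                f"exceeded {max_events} events with {k_total} lineages left"
            )
        coal = 0.0
        coal_d = []
        mig_total = 0.0
        for d in range(npop):
            kd = len(demes[d])
            c = kd * (kd - 1) / (4.0 * sizes[d]) if kd > 1 else 0.0
            coal += c
            coal_d.append(c)
            if kd and rowsum[d] > 0.0:
                mig_total += kd * rowsum[d]
        total = coal + mig_total
        next_ev_t = ev[ev_i].time if ev_i < n_ev else math.inf
        if total <= 0.0:
            if next_ev_t == math.inf:
                raise TrappedLineagesError(
                    "lineages in disconnected demes with no further events"
                )
            t = next_ev_t
            apply_event(ev[ev_i])
            ev_i += 1
            continue
        dt = expovariate(total)
        if t + dt >= next_ev_t:
            t = next_ev_t
            apply_event(ev[ev_i])
            ev_i += 1
            continue
        t += dt
        if t > max_time:
            raise TrappedLineagesError(f"no common ancestor by max_time={max_time}")
        u = rnd() * total
        if u < coal:
            for d in range(npop):
                u -= coal_d[d]
                if u < 0.0:
                    break
            pool = demes[d]
            kd = len(pool)
            i = rng.randrange(kd)
            j = rng.randrange(kd - 1)
            if j >= i:
                j += 1
            if i < j:
                i, j = j, i  # remove the higher index first
            a = pool[i]
            pool[i] = pool[-1]
            pool.pop()
            b = pool[j]
            pool[j] = pool[-1]
            pool.pop()
            cfgs.append(a[1])
            lens.append(t - a[0])
            cfgs.append(b[1])
            lens.append(t - b[0])
            if track_leaves:
                masks.append(a[2])
                masks.append(b[2])
            cfg = tuple(x + y for x, y in zip(a[1], b[1]))
            if record_tree:
                node_times.append(t)
                node_parents.append(-1)
                node_parents[a[3]] = nid
                node_parents[b[3]] = nid
            pool.append([t, cfg, a[2] | b[2], nid])
            nid += 1
            k_total -= 1
        else:
            u -= coal
            for d in range(npop):
                kd = len(demes[d])
                if kd and rowsum[d] > 0.0:
                    u -= kd * rowsum[d]
                    if u < 0.0:
                        break
            pool = demes[d]
            i = rng.randrange(len(pool))
            lin = pool[i]
            pool[i] = pool[-1]
            pool.pop()
            v = rnd() * rowsum[d]
            row = mig[d]
            for j in range(npop):
                v -= row[j]
                if v < 0.0:
                    break
            demes[j].append(lin)

    tree = None
    if record_tree:
        tree = (
            np.asarray(node_times),
            np.asarray(node_parents, dtype=np.int64),
            sample_demes,
        )
    return cfgs, lens, masks, tree, n_steps


def _locus_seeds(master: random.Random, n: int) -> list[int]:
    """Deterministic per-locus substream seeds; earlier loci are unaffected by n."""
    return [master.getrandbits(63) for _ in range(n)]


def simulate_genealogy(
    model: DemographicModel,
    config: SampleConfig,
    seed: int | random.Random = 0,
    *,
    max_time: float = 1e12,
    max_events: int = 5_000_000,
    track_leaves: bool = True,
) -> Genealogy:
    """Simulate one structured-coalescent genealogy; node times in generations."""
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    n = sum(config.sample_sizes)
    if len(config.sample_sizes) != model.n_pops:
        raise ValueError("sample_sizes length must match model.n_pops")
    if n < 1:
        raise ValueError("need at least one sample")
    if n == 1:
        d = int(np.nonzero(config.sample_sizes)[0][0])
        return Genealogy(
            n_samples=1,
            sample_demes=np.asarray([d], dtype=np.int32),
            node_times=np.zeros(1),
            node_parents=np.asarray([-1]),
            branch_configs=np.zeros((0, model.n_pops), dtype=np.int32),
            branch_lengths=np.zeros(0),
            branch_masks=[] if track_leaves else None,
        )
    cfgs, lens, masks, tree, _ = _run_coalescent(
        model.deme_sizes,
        model.migration,
        model.events,
        config.sample_sizes,
        rng,
        max_time=max_time,
        max_events=max_events,
        track_leaves=track_leaves,
        record_tree=True,
    )
    node_times, node_parents, sample_demes = tree
    return Genealogy(
        n_samples=n,
        sample_demes=sample_demes,
        node_times=node_times,
        node_parents=node_parents,
        branch_configs=np.asarray(cfgs, dtype=np.int32),
        branch_lengths=np.asarray(lens),
        branch_masks=masks,
    )


def simulate_branch_batches(
    model: DemographicModel,
    config: SampleConfig,
    n_loci: int,
    seed: int = 0,
    *,
    max_events: int = 5_000_000,
    max_events_total: int | None = None,
):
    """Yield (configs, lengths) branch tables for ``n_loci`` independent loci.

    Lean path used by the expected-JSFS estimator: no tree or leaf sets are
    recorded, only each branch's subtended leaf counts per deme and its length.
    ``max_events_total`` bounds the summed event count over the whole batch,
    so pathological parameter regions (very high migration) fail fast instead
    of stalling.
    """
    master = random.Random(seed)
    remaining = max_events_total if max_events_total is not None else None
    for s in _locus_seeds(master, n_loci):
        cap = max_events if remaining is None else min(max_events, remaining)
        cfgs, lens, _, _, steps = _run_coalescent(
            model.deme_sizes,
            model.migration,
            model.events,
            config.sample_sizes,
            random.Random(s),
            max_events=cap,
        )
        if remaining is not None:
            remaining -= steps
            if remaining <= 0:
                raise TrappedLineagesError("batch event budget exhausted")
        yield np.asarray(cfgs, dtype=np.int32), np.asarray(lens)


def drop_mutations(
    gen: Genealogy,
    mu: float,
    mode: str = "infinite_sites",
    locus_length: int = 1,
    seed: int | random.Random = 0,
    *,
    min_minor_freq: float | None = None,
) -> np.ndarray:
    """Place mutations on a genealogy; returns a (variants x samples) 0/1 array.

    ``infinite_sites``: Poisson(mu * L * total length) mutations, uniform on
    branches. ``one_snp``: exactly one mutation on a branch chosen proportional
    to length — the conditioned-on-polymorphism model for ascertained SNP loci.
    With ``min_minor_freq`` set, only branches whose folded sample frequency
    exceeds it are eligible (emulating a MAF-filtered SNP panel); if no branch
    qualifies the locus yields zero variants.
    """
    if gen.branch_masks is None:
        raise ValueError("genealogy was simulated without leaf tracking")
    if mode not in ("infinite_sites", "one_snp"):
        raise ValueError("mode must be 'infinite_sites' or 'one_snp'")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    n = gen.n_samples
    lengths = gen.branch_lengths
    total = float(lengths.sum())
    if total <= 0.0 or len(lengths) == 0:
        return np.zeros((0, n), dtype=np.int8)

    if mode == "infinite_sites":
        k = np.random.default_rng(rng.getrandbits(63)).poisson(
            mu * locus_length * total
        )
        if k == 0:
            return np.zeros((0, n), dtype=np.int8)
        probs = lengths / total
        idx = np.random.default_rng(rng.getrandbits(63)).choice(
            len(lengths), size=k, p=probs
        )
    else:
        if min_minor_freq is not None:
            counts = gen.branch_configs.sum(axis=1)
            minor = np.minimum(counts, n - counts) / n
            eligible = np.nonzero(minor > min_minor_freq)[0]
            if len(eligible) == 0:
                return np.zeros((0, n), dtype=np.int8)
            w = lengths[eligible]
            idx = [int(eligible[_weighted_index(w, rng.random())])]
        else:
            idx = [int(_weighted_index(lengths, rng.random()))]

    out = np.zeros((len(idx), n), dtype=np.int8)
    for row, b in enumerate(idx):
        mask = gen.branch_masks[b]
        for i in range(n):
            if mask >> i & 1:
                out[row, i] = 1
    return out


def _weighted_index(weights: np.ndarray, u: float) -> int:
    c = np.cumsum(weights)
    return int(np.searchsorted(c, u * c[-1], side="right").clip(0, len(weights) - 1))


# ---------------------------------------------------------------------------
# Hierarchical island model (outlier-scan null)
# ---------------------------------------------------------------------------


def _island_locus(
    groups: int,
    demes_per_group: int,
    deme_size: float,
    m_within: float,
    m_between: float,
    sample_sizes: tuple[int, ...],
    rng: random.Random,
    max_events: int = 2_000_000,
):
    """One hierarchical-island genealogy; returns (configs, lengths, masks).

    Sampled demes are placed in distinct demes spread round-robin over groups.
    A migrating lineage stays in its group with probability proportional to
    ``m_within`` (moving to one of the other demes of the group) and jumps to a
    uniform deme of a uniform other group otherwise.
    """
    npop = len(sample_sizes)
    n = sum(sample_sizes)
    cfg: list[tuple[int, ...]] = []
    mask: list[int] = []
    birth: list[float] = []
    cell_of: list[tuple[int, int] | None] = []
    pos_in_cell: list[int] = []
    occupancy: dict[tuple[int, int], list[int]] = {}
    alive: list[int] = []
    alive_pos: dict[int, int] = {}

    def place(lin: int, cell: tuple[int, int]) -> float:
        """Add lineage to a cell; returns the coalescence-rate increment."""
        members = occupancy.setdefault(cell, [])
        cell_of[lin] = cell
        pos_in_cell[lin] = len(members)
        members.append(lin)
        return 2.0 * (len(members) - 1) * coal_c

    def remove(lin: int) -> float:
        cell = cell_of[lin]
        members = occupancy[cell]
        i = pos_in_cell[lin]
        last = members[-1]
        members[i] = last
        pos_in_cell[last] = i
        members.pop()
        if not members:
            del occupancy[cell]
        cell_of[lin] = None
        return -2.0 * len(members) * coal_c

    coal_c = 1.0 / (4.0 * deme_size)
    r_coal = 0.0
    nid = 0
    for s in range(npop):
        g = s % groups
        d = s // groups  # sampled demes occupy distinct demes, spread over groups
        if d >= demes_per_group:
            raise ValueError("more sampled demes than available demes")
        for _ in range(sample_sizes[s]):
            c = [0] * npop
            c[s] = 1
            cfg.append(tuple(c))
            mask.append(1 << nid)
            birth.append(0.0)
            cell_of.append(None)
            pos_in_cell.append(0)
            r_coal += place(nid, (g, d))
            alive_pos[nid] = len(alive)
            alive.append(nid)
            nid += 1

    cfgs_out: list[tuple[int, ...]] = []
    lens_out: list[float] = []
    masks_out: list[int] = []
    t = 0.0
    m_tot = m_within + m_between
    expovariate = rng.expovariate
    rnd = rng.random
    steps = 0
    k_total = n

    def drop_alive(lin: int) -> None:
        i = alive_pos.pop(lin)
        last = alive[-1]
        alive[i] = last
        alive_pos[last] = i
        alive.pop()

    while k_total > 1:
        steps += 1
        if steps > max_events:
            raise TrappedLineagesError("island model exceeded max_events")
        total = r_coal + k_total * m_tot
        t += expovariate(total)
        u = rnd() * total
        if u < r_coal:
            for cell, members in occupancy.items():
                c = len(members)
                if c > 1:
                    u -= c * (c - 1) * coal_c
                    if u < 0.0:
                        break
            i = rng.randrange(len(members))
            j = rng.randrange(len(members) - 1)
            if j >= i:
                j += 1
            a, b = members[i], members[j]
            r_coal += remove(a)
            r_coal += remove(b)
            drop_alive(a)
            drop_alive(b)
            cfgs_out.append(cfg[a])
            lens_out.append(t - birth[a])
            masks_out.append(mask[a])
            cfgs_out.append(cfg[b])
            lens_out.append(t - birth[b])
            masks_out.append(mask[b])
            cfg.append(tuple(x + y for x, y in zip(cfg[a], cfg[b])))
            mask.append(mask[a] | mask[b])
            birth.append(t)
            cell_of.append(None)
            pos_in_cell.append(0)
            r_coal += place(nid, cell)
            alive_pos[nid] = len(alive)
            alive.append(nid)
            nid += 1
            k_total -= 1
        else:
            lin = alive[rng.randrange(k_total)]
            g, d = cell_of[lin]
            r_coal += remove(lin)
            if rnd() * m_tot < m_within:
                nd = rng.randrange(demes_per_group - 1)
                if nd >= d:
                    nd += 1
                new_cell = (g, nd)
            else:
                ng = rng.randrange(groups - 1)
                if ng >= g:
                    ng += 1
                new_cell = (ng, rng.randrange(demes_per_group))
            r_coal += place(lin, new_cell)
    return cfgs_out, lens_out, masks_out


def _island_batch_stats(
    groups: int,
    demes_per_group: int,
    deme_size: float,
    m_within: float,
    m_between: float,
    sample_sizes: tuple[int, ...],
    n_loci: int,
    rng: random.Random,
) -> np.ndarray:
    """Simulate loci and return per-locus (het, fst, a, a+b+c) rows.

    ``a`` and ``a+b+c`` are the Weir-Cockerham variance components so callers
    can form both per-locus and multi-locus (ratio-of-sums) F_ST. Haplotypes
    are paired into diploids within each sampled deme.
    """
    from .popgen_stats import wc_components_from_dosage

    rows = []
    npop = len(sample_sizes)
    dip = [s // 2 for s in sample_sizes]
    for _ in range(n_loci):
        cfgs, lens, masks = _island_locus(
            groups, demes_per_group, deme_size, m_within, m_between, sample_sizes, rng
        )
        w = np.asarray(lens)
        b = _weighted_index(w, rng.random())
        mask = masks[b]
        # haploid derived indicators, in sample order
        n = sum(sample_sizes)
        hap = np.fromiter(((mask >> i) & 1 for i in range(n)), dtype=np.int8, count=n)
        # pair consecutive haplotypes into diploids per deme
        dosages = []
        off = 0
        for s in range(npop):
            h = hap[off : off + sample_sizes[s]]
            off += sample_sizes[s]
            dosages.append(h[: 2 * dip[s] : 2] + h[1 : 2 * dip[s] : 2])
        p = hap.mean()
        het = 2.0 * p * (1.0 - p)
        a, abc = wc_components_from_dosage(dosages)
        fst = a / abc if abc > 0 else 0.0
        rows.append((het, fst, a, abc))
    return np.asarray(rows)


def simulate_hierarchical_island(
    groups: int,
    demes_per_group: int,
    target_fst: float,
    config: SampleConfig,
    n_sims: int = 20_000,
    seed: int = 0,
    *,
    deme_size: float = 500.0,
    between_within_ratio: float = 0.1,
    n_calibration: int = 400,
    tol: float = 0.005,
) -> tuple[np.ndarray, dict]:
    """Neutral (heterozygosity, F_ST) null sample under a hierarchical island model.

    The within-group migration rate (with between-group rate held at
    ``between_within_ratio`` times it) is calibrated by bisection so the
    realized multi-locus Weir-Cockerham F_ST across simulated loci matches
    ``target_fst`` within ``tol``. Returns an (n_sims, 2) array of per-locus
    (expected heterozygosity, single-locus F_ST) pairs and a calibration record.
    """
    if groups < 2 or demes_per_group < 2:
        raise ValueError("need >= 2 groups and >= 2 demes per group")
    if not (0.0 < target_fst < 1.0):
        raise ValueError("target_fst must be in (0, 1)")
    rng = random.Random(seed)
    ss = config.sample_sizes

    def realized(m_w: float, n_loci: int, r: random.Random) -> float:
        st = _island_batch_stats(
            groups, demes_per_group, deme_size, m_w,
            m_w * between_within_ratio, ss, n_loci, r,
        )
        denom = st[:, 3].sum()
        return float(st[:, 2].sum() / denom) if denom > 0 else 0.0

    # F_ST decreases with migration; start the bracket around the two-deme
    # analytic guess F = 1/(1 + 8 N m_tot) and bisect on log10(m_within)
    guess = (1.0 / target_fst - 1.0) / (8.0 * deme_size * (1 + between_within_ratio))
    hi_cap = math.log10(0.2 / (1 + between_within_ratio))
    lo = max(math.log10(guess) - 1.0, -7.0)
    hi = min(math.log10(guess) + 1.0, hi_cap)
    probe = max(80, n_calibration // 3)
    f_lo = realized(10.0**lo, probe, random.Random(rng.getrandbits(63)))
    f_hi = realized(10.0**hi, probe, random.Random(rng.getrandbits(63)))
    for _ in range(3):  # widen if the guess bracket misses
        if f_lo < target_fst and lo > -7.0:
            lo = max(lo - 1.5, -7.0)
            f_lo = realized(10.0**lo, probe, random.Random(rng.getrandbits(63)))
        elif f_hi > target_fst and hi < hi_cap:
            hi = min(hi + 1.5, hi_cap)
            f_hi = realized(10.0**hi, probe, random.Random(rng.getrandbits(63)))
        else:
            break
    if not (f_hi <= target_fst <= f_lo):
        raise CalibrationError(
            f"target F_ST {target_fst} outside achievable range "
            f"[{f_hi:.4f}, {f_lo:.4f}]; widen rate bounds"
        )
    mid, f_mid = lo, f_lo
    for _ in range(7):
        mid = 0.5 * (lo + hi)
        f_mid = realized(10.0**mid, n_calibration, random.Random(rng.getrandbits(63)))
        if abs(f_mid - target_fst) <= tol:
            break
        if f_mid > target_fst:
            lo = mid
        else:
            hi = mid
    m_w = 10.0**mid
    stats = _island_batch_stats(
        groups, demes_per_group, deme_size, m_w,
        m_w * between_within_ratio, ss, n_sims,
        random.Random(rng.getrandbits(63)),
    )
    denom = stats[:, 3].sum()
    info = {
        "m_within": m_w,
        "m_between": m_w * between_within_ratio,
        "deme_size": deme_size,
        "realized_fst": float(stats[:, 2].sum() / denom) if denom > 0 else 0.0,
        "calibration_fst": f_mid,
    }
    return stats[:, :2], info
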