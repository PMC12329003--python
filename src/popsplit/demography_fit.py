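"""Four-population demographic model fitting on joint site-frequency spectra.

Six competing divergence histories for the four genetic populations (0
southern, 1 northern, 2 Japanese, 3 Yalu River Estuary) are fitted to the six
pairwise folded JSFS by composite multinomial likelihood and compared by AIC:

* M1-M3 - strict isolation (SI) with the three possible divergence orders for
  pops 0/1/2 after the initial Yalu split;
* M4-M6 - the best SI topology (M3: Japanese subdivides from northern) plus
  gene flow between the adjacent southern and northern populations under
  isolation-with-migration (IM), ancient-migration (AM) or secondary-contact
  (SC) scenarios, with steady bidirectional northern<->Japanese and
  northern<->Yalu flow;
* M6+resize - the SC model with additional founding-size parameters allowing
  each terminal population's size to change along its branch.

Likelihoods are reported in log10 (so the lack-of-fit statistic
``delta_L = MaxObsLhood - MaxEstLhood`` is on the customary scale) and
``AIC = 2k - 2 ln(10) MaxEstLhood``. The optimizer is a multi-start cyclic
per-parameter golden-section search on log-scaled parameters with common
random numbers per run, standing in for the ECM cycles of likelihood-based
SFS fitters. Migration parameters are stated forward in time (``M01`` =
fraction of pop 1 made of pop-0 migrants per generation); the model builder
performs the forward-to-backward index swap.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coalescent_sim import (
    DemographicEvent,
    DemographicModel,
    SampleConfig,
    simulate_branch_batches,
)
from .sfs import JointSFS, expected_pairwise_jsfs

__all__ = [
    "ParameterSet",
    "ModelSpec",
    "FitSettings",
    "DemographicInference",
    "DemographyResults",
    "model_registry",
    "get_model_spec",
    "build_model",
    "composite_log_likelihood",
    "max_obs_lhood",
    "fit_model",
    "staged_fit",
    "compare_models",
    "parametric_bootstrap_ci",
    "simulate_counts_jsfs",
    "generations_to_years",
    "SECONDARY_CONTACT_BEST_FIT",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class ParameterSet:
    """Point parameters of a four-population divergence/migration history.

    Sizes are diploid effective sizes; times are generations before present
    (``T0 > T1 > T2``, with ``T3`` the start/stop of southern<->northern flow
    in the SC/AM scenarios). ``N_stem`` is the ancestor of pops 0/1/2 after
    the Yalu split; ``N_pair`` the ancestor of the most recently diverged
    pair. Migration rates ``Mxy`` are forward per-generation fractions x->y.
    """

    N_anc: float
    N_stem: float
    N_pair: float
    N0: float
    N1: float
    N2: float
    N3: float
    T0: float
    T1: float
    T2: float
    T3: float | None = None
    M01: float = 0.0
    M10: float = 0.0
    M12: float = 0.0
    M21: float = 0.0
    M13: float = 0.0
    M31: float = 0.0
    mu: float = 2.5e-8
    generation_time: float = 2.5

    def __post_init__(self) -> None:
        for name in ("N_anc", "N_stem", "N_pair", "N0", "N1", "N2", "N3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (self.T0 > self.T1 > self.T2 >= 0):
            raise ValueError("need T0 > T1 > T2 >= 0")
        for name in ("M01", "M10", "M12", "M21", "M13", "M31"):
            if not (0 <= getattr(self, name) < 1):
                raise ValueError(f"{name} must be in [0, 1)")

    def scaled(self, factor: float) -> "ParameterSet":
        """Shrink sizes and times by ``factor`` and boost migration to match.

        Preserves the drift (T/N) and gene-flow (N*M) scales so summary
        statistics are approximately invariant while runtimes drop.
        """
        return replace(
            self,
            N_anc=self.N_anc / factor,
            N_stem=self.N_stem / factor,
            N_pair=self.N_pair / factor,
            N0=self.N0 / factor,
            N1=self.N1 / factor,
            N2=self.N2 / factor,
            N3=self.N3 / factor,
            T0=self.T0 / factor,
            T1=self.T1 / factor,
            T2=self.T2 / factor,
            T3=None if self.T3 is None else self.T3 / factor,
            M01=self.M01 * factor,
            M10=self.M10 * factor,
            M12=self.M12 * factor,
            M21=self.M21 * factor,
            M13=self.M13 * factor,
            M31=self.M31 * factor,
        )


#: Best-fit secondary-contact history of the emulated survey (times in
#: generations; forward migration fractions). Northern<->Yalu flow was part of
#: the model space but no point values are reported for it, so it is zero here.
SECONDARY_CONTACT_BEST_FIT = ParameterSet(
    N_anc=160_175,
    N_stem=193_217,
    N_pair=1_874,
    N0=18_806,
    N1=190_642,
    N2=147_197,
    N3=50_348,
    T0=23_802,
    T1=9_120,
    T2=4_213,
    T3=3_214,
    M01=6.37e-4,
    M10=5.19e-5,
    M12=1.27e-3,
    M21=3.22e-5,
)

# free-parameter definitions: (transformed lower, upper, scale)
_SIZE_B = (2.0, 7.0, "log10")
_TIME_B = (1.0, 5.0, "log10")  # time increments, generations
_MIG_B = (-8.0, -1.0, "log10")
_FRAC_B = (0.02, 0.98, "linear")

_SIZES = ("N_anc", "N_stem", "N_pair", "N0", "N1", "N2", "N3")
_TIMES = ("dT2", "dT21", "dT10")
_MIGS = ("M01", "M10", "M12", "M21", "M13", "M31")
_FOUNDING = ("NF0", "NF1", "NF2", "NF3")


@dataclass(frozen=True)
class ModelSpec:
    """A divergence topology plus migration scenario, with its free parameters.

    ``joins`` lists (source, sink) backward merges at times (T2, T1, T0);
    sinks keep their deme index, so the last join always folds pop 3 into 0.
    """

    id: str
    description: str
    joins: tuple[tuple[int, int], ...]
    scenario: str  # SI | IM | AM | SC
    resize: bool = False

    @property
    def free_params(self) -> list[tuple[str, float, float, str]]:
        out = [(n, *_SIZE_B) for n in _SIZES]
        out += [(n, *_TIME_B) for n in _TIMES]
        if self.scenario != "SI":
            out += [(n, *_MIG_B) for n in _MIGS]
        if self.scenario in ("AM", "SC"):
            out += [("frac3", *_FRAC_B)]
        if self.resize:
            out += [(n, *_SIZE_B) for n in _FOUNDING]
        return out

    @property
    def k(self) -> int:
        return len(self.free_params)

    def params_from_vector(self, x: np.ndarray):
        """Transformed vector -> (ParameterSet, founding sizes or None)."""
        defs = self.free_params
        if len(x) != len(defs):
            raise ValueError("parameter vector length mismatch")
        raw = {}
        for (name, _, _, scale), v in zip(defs, x):
            raw[name] = 10.0**v if scale == "log10" else float(v)
        t2 = raw["dT2"]
        t1 = t2 + raw["dT21"]
        t0 = t1 + raw["dT10"]
        t3 = raw["frac3"] * t1 if "frac3" in raw else None
        pset = ParameterSet(
            N_anc=raw["N_anc"],
            N_stem=raw["N_stem"],
            N_pair=raw["N_pair"],
            N0=raw["N0"],
            N1=raw["N1"],
            N2=raw["N2"],
            N3=raw["N3"],
            T0=t0,
            T1=t1,
            T2=t2,
            T3=t3,
            M01=raw.get("M01", 0.0),
            M10=raw.get("M10", 0.0),
            M12=raw.get("M12", 0.0),
            M21=raw.get("M21", 0.0),
            M13=raw.get("M13", 0.0),
            M31=raw.get("M31", 0.0),
        )
        founding = (
            tuple(raw[n] for n in _FOUNDING) if self.resize else None
        )
        return pset, founding

    def vector_from(
        self,
        pset: ParameterSet,
        founding: tuple | None = None,
        frac3_default: float = 0.5,
    ) -> np.ndarray:
        """Transformed start vector for these free parameters from a point.

        Used to warm-start a model from a nested fit: absent migration rates
        start at the lower bound (effectively no flow); a missing contact-time
        fraction starts at ``frac3_default`` (near 1 reproduces an IM fit
        under the SC window, near 0 under the AM window). Values are clipped
        into the search box.
        """
        natural = {
            "N_anc": pset.N_anc, "N_stem": pset.N_stem, "N_pair": pset.N_pair,
            "N0": pset.N0, "N1": pset.N1, "N2": pset.N2, "N3": pset.N3,
            "dT2": pset.T2, "dT21": pset.T1 - pset.T2, "dT10": pset.T0 - pset.T1,
            "M01": pset.M01, "M10": pset.M10, "M12": pset.M12,
            "M21": pset.M21, "M13": pset.M13, "M31": pset.M31,
            "frac3": (pset.T3 / pset.T1) if pset.T3 else frac3_default,
        }
        if founding is not None:
            natural.update(dict(zip(_FOUNDING, founding)))
        x = []
        for name, lo, hi, scale in self.free_params:
            v = natural.get(name)
            if v is None or (scale == "log10" and v <= 0):
                z = lo if name in _MIGS else (lo + hi) / 2.0
            else:
                z = math.log10(v) if scale == "log10" else v
            x.append(min(max(z, lo), hi))
        return np.asarray(x)


def model_registry() -> list[ModelSpec]:
    """The six competing histories plus the SC-with-resize variant."""
    return [
        ModelSpec(
            "M1",
            "SI; Japanese splits from southern stem before northern does",
            joins=((1, 0), (2, 0), (3, 0)),
            scenario="SI",
        ),
        ModelSpec(
            "M2",
            "SI; northern splits before Japanese does",
            joins=((2, 0), (1, 0), (3, 0)),
            scenario="SI",
        ),
        ModelSpec(
            "M3",
            "SI; Japanese subdivides from northern after the southern split",
            joins=((2, 1), (1, 0), (3, 0)),
            scenario="SI",
        ),
        ModelSpec(
            "M4",
            "M3 topology with continuous southern<->northern migration (IM)",
            joins=((2, 1), (1, 0), (3, 0)),
            scenario="IM",
        ),
        ModelSpec(
            "M5",
            "M3 topology with ancient-only southern<->northern migration (AM)",
            joins=((2, 1), (1, 0), (3, 0)),
            scenario="AM",
        ),
        ModelSpec(
            "M6",
            "M3 topology with secondary contact southern<->northern (SC)",
            joins=((2, 1), (1, 0), (3, 0)),
            scenario="SC",
        ),
        ModelSpec(
            "M6r",
            "SC model with per-population founding-size change",
            joins=((2, 1), (1, 0), (3, 0)),
            scenario="SC",
            resize=True,
        ),
    ]


def get_model_spec(model_id: str) -> ModelSpec:
    for spec in model_registry():
        if spec.id == model_id:
            return spec
    raise KeyError(f"unknown model id {model_id!r}")


def _backward_matrix(
    pset: ParameterSet, scenario: str, allow01: bool, extinct: set[int]
) -> list[list[float]]:
    """Backward migration matrix for an epoch (forward rates index-swapped)."""
    m = [[0.0] * 4 for _ in range(4)]
    if scenario == "SI":
        return m

    def setflow(src: int, dst: int, rate: float) -> None:
        # forward src->dst: backward, lineages in dst find parents in src
        if rate > 0 and src not in extinct and dst not in extinct:
            m[dst][src] = rate

    if allow01:
        setflow(0, 1, pset.M01)
        setflow(1, 0, pset.M10)
    setflow(1, 2, pset.M12)
    setflow(2, 1, pset.M21)
    setflow(1, 3, pset.M13)
    setflow(3, 1, pset.M31)
    return m


def build_model(
    spec: ModelSpec,
    pset: ParameterSet,
    founding: tuple[float, float, float, float] | None = None,
) -> DemographicModel:
    """Assemble the simulable demographic model for a spec and parameter point."""
    join_times = (pset.T2, pset.T1, pset.T0)
    anc_sizes = (pset.N_pair, pset.N_stem, pset.N_anc)
    events: list[DemographicEvent] = [
        DemographicEvent(time=t, kind="join", source=s, sink=k, new_size=nsz)
        for t, (s, k), nsz in zip(join_times, spec.joins, anc_sizes)
    ]
    allow01_now = spec.scenario in ("IM", "SC")
    if spec.scenario in ("AM", "SC"):
        if pset.T3 is None:
            raise ValueError(f"scenario {spec.scenario} requires T3")
        t3 = min(pset.T3, 0.999 * pset.T1)
        extinct = {s for t, (s, _) in zip(join_times, spec.joins) if t <= t3}
        events.append(
            DemographicEvent(
                time=t3,
                kind="set_migration",
                matrix=tuple(
                    tuple(row)
                    for row in _backward_matrix(
                        pset, spec.scenario, allow01=(spec.scenario == "AM"), extinct=extinct
                    )
                ),
            )
        )
    if spec.resize:
        if founding is None:
            raise ValueError("resize model needs founding sizes")
        origin = {0: pset.T1, 1: pset.T1, 2: pset.T2, 3: pset.T0}
        for deme, nf in enumerate(founding):
            events.append(
                DemographicEvent(
                    time=0.5 * origin[deme], kind="resize", deme=deme, new_size=nf
                )
            )
    return DemographicModel(
        deme_sizes=[pset.N0, pset.N1, pset.N2, pset.N3],
        events=events,
        migration=_backward_matrix(pset, spec.scenario, allow01_now, set()),
        mutation_rate=pset.mu,
    )


# ---------------------------------------------------------------------------
# Composite likelihood
# ---------------------------------------------------------------------------


def _as_items(obs) -> list[tuple[object, JointSFS]]:
    if isinstance(obs, dict):
        return sorted(obs.items(), key=lambda kv: str(kv[0]))
    return list(enumerate(obs))


def composite_log_likelihood(obs, expected) -> float:
    """Sum over pairs and unmasked cells of ``m_i log10 p_i``."""
    obs_items = _as_items(obs)
    exp_items = _as_items(expected)
    if len(obs_items) != len(exp_items):
        raise ValueError("observed/expected pair lists differ in length")
    ll = 0.0
    for (ko, o), (ke, e) in zip(obs_items, exp_items):
        if o.cells.shape != e.cells.shape:
            raise ValueError(f"dimension mismatch for pair {ko}/{ke}")
        m = o.mask
        mm = m & (o.cells > 0)
        ll += float(np.sum(o.cells[mm] * np.log10(e.cells[mm])))
    return ll


def max_obs_lhood(obs) -> float:
    """Saturated-fit upper bound: plug-in cell probabilities m_i / sum(m)."""
    items = _as_items(obs)
    if not items:
        raise ValueError("empty observation list")
    ll = 0.0
    for _, o in items:
        m = o.cells[o.mask]
        total = m.sum()
        if total <= 0:
            raise ValueError("empty spectrum (no unmasked mass)")
        pos = m > 0
        ll += float(np.sum(m[pos] * np.log10(m[pos] / total)))
    return ll


@dataclass
class FitSettings:
    """Optimizer budget. Paper-scale would be n_runs=100, sims_per_eval=100000,
    ecm_cycles=30; the defaults are the scaled-down desk configuration."""

    n_runs: int = 20
    sims_per_eval: int = 10_000
    ecm_cycles: int = 10
    line_evals: int = 6
    final_sims: int | None = None  # default: 2x sims_per_eval
    #: mean coalescent-event budget per simulated locus; parameter points
    #: whose batch exceeds n_sims x this (pathological high-migration
    #: corners) score -inf instead of stalling the search
    events_budget_per_locus: int = 1_000
    #: optional refinement stage: narrow-width cycles at a higher simulation
    #: count, cutting the Monte-Carlo noise the coarse search chases
    refine_cycles: int = 0
    refine_sims: int | None = None  # default: 5x sims_per_eval
    refine_width: float = 0.4  # half-width in transformed (log10) units


@dataclass
class DemographyResults:
    """Fit output: point estimates, likelihoods, AIC and (optionally) CIs."""

    spec: ModelSpec
    params: ParameterSet
    founding: tuple | None
    free_values: dict[str, float]
    max_est_lhood: float
    max_obs_lhood: float
    n_runs: int
    best_run_seed: int
    runs: list[dict]
    settings: FitSettings
    model: "DemographicInference"
    conf_int_: pd.DataFrame | None = None

    @property
    def k(self) -> int:
        return self.spec.k

    @property
    def delta_l(self) -> float:
        return self.max_obs_lhood - self.max_est_lhood

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * LN10 * self.max_est_lhood

    def bootstrap_ci(
        self,
        n_boot: int = 20,
        runs_per_boot: int = 10,
        seed: int = 0,
        settings: FitSettings | None = None,
        n_snps: int | None = None,
    ) -> pd.DataFrame:
        ci = parametric_bootstrap_ci(
            self.spec,
            self.params,
            founding=self.founding,
            sample_sizes=self.model.sample_sizes,
            n_snps=n_snps or int(round(self.model.total_mass)),
            n_boot=n_boot,
            runs_per_boot=runs_per_boot,
            seed=seed,
            settings=settings or self.settings,
            folded=self.model.folded,
        )
        self.conf_int_ = ci
        return ci

    def summary(self) -> str:
        rows = []
        for name, value in self.free_values.items():
            lo = hi = float("nan")
            if self.conf_int_ is not None and name in self.conf_int_.index:
                lo = self.conf_int_.loc[name, "2.5%"]
                hi = self.conf_int_.loc[name, "97.5%"]
            rows.append((name, value, lo, hi))
        frame = pd.DataFrame(rows, columns=["param", "estimate", "2.5%", "97.5%"])
        head = (
            f"Demographic fit: {self.spec.id} ({self.spec.scenario}) — "
            f"{self.spec.description}\n"
            f"k = {self.k}, runs = {self.n_runs}\n"
            f"MaxEstLhood = {self.max_est_lhood:.4f}  "
            f"MaxObsLhood = {self.max_obs_lhood:.4f}  "
            f"delta_L = {self.delta_l:.4f}  AIC = {self.aic:.2f}\n"
        )
        return head + frame.to_string(index=False, float_format=lambda v: f"{v:.6g}")


class DemographicInference:
    """Composite-likelihood JSFS model, statsmodels-style.

    Parameters
    ----------
    observed : dict[(str, str) -> JointSFS]
        Observed pairwise count spectra, keyed by population-name pairs.
    spec : ModelSpec
        The candidate history to fit.
    sample_sizes : tuple[int, ...]
        Haploid projection size per deme (must match the observed spectra).
    """

    def __init__(
        self,
        observed: dict[tuple[str, str], JointSFS],
        spec: ModelSpec,
        sample_sizes: tuple[int, ...],
        pop_names: list[str] | None = None,
    ):
        self.observed = dict(observed)
        self.spec = spec
        self.sample_sizes = tuple(sample_sizes)
        self.pop_names = pop_names or [f"pop{i}" for i in range(len(sample_sizes))]
        folded = {o.folded for o in observed.values()}
        if len(folded) != 1:
            raise ValueError("observed spectra mix folded and unfolded")
        self.folded = folded.pop()
        name_to_idx = {n: i for i, n in enumerate(self.pop_names)}
        self.pairs = []
        for (a, b), o in self.observed.items():
            ia, ib = name_to_idx[a], name_to_idx[b]
            if (o.n_a, o.n_b) != (self.sample_sizes[ia], self.sample_sizes[ib]):
                raise ValueError(
                    f"projection of pair ({a},{b}) does not match sample_sizes"
                )
            self.pairs.append((ia, ib))
        self.total_mass = sum(
            float(o.cells[o.mask].sum()) for o in self.observed.values()
        )
        self._max_obs = max_obs_lhood(self.observed)

    def expected(
        self, pset: ParameterSet, founding=None, n_sims=1000, seed=0,
        max_events_total: int | None = None,
    ):
        model = build_model(self.spec, pset, founding)
        return expected_pairwise_jsfs(
            model,
            SampleConfig(self.sample_sizes, n_loci=1),
            n_sims=n_sims,
            seed=seed,
            pop_names=self.pop_names,
            folded=self.folded,
            pairs=self.pairs,
            max_events_total=max_events_total,
        )

    def loglike(
        self, pset: ParameterSet, founding=None, n_sims=1000, seed=0,
        max_events_total: int | None = None,
    ) -> float:
        exp = self.expected(pset, founding, n_sims, seed, max_events_total)
        return composite_log_likelihood(self.observed, exp)

    def loglike_vector(
        self, x: np.ndarray, n_sims: int, seed: int,
        max_events_total: int | None = None,
    ) -> float:
        from .coalescent_sim import TrappedLineagesError

        pset, founding = self.spec.params_from_vector(x)
        try:
            return self.loglike(pset, founding, n_sims, seed, max_events_total)
        except TrappedLineagesError:
            return -math.inf

    def fit(
        self,
        seed: int = 0,
        settings: FitSettings | None = None,
        start: np.ndarray | None = None,
        cycle_params: list[str] | None = None,
    ) -> DemographyResults:
        """Multi-start cyclic golden-section maximization of the composite
        log-likelihood; Monte-Carlo noise is held fixed within a run by a
        common simulation seed so the coordinate search sees a deterministic
        surface. Run 0 starts from ``start`` when given (e.g. a nested fit),
        else from the center of the search box; later runs start at random.
        ``cycle_params`` restricts the coordinate search to the named free
        parameters (profile-style refinement of a warm start)."""
        settings = settings or FitSettings()
        defs = self.spec.free_params
        active = (
            [i for i, (n, *_) in enumerate(defs) if n in cycle_params]
            if cycle_params is not None
            else list(range(len(defs)))
        )
        master = np.random.default_rng(seed)
        runs = []
        for run_idx in range(settings.n_runs):
            run_seed = int(master.integers(2**31))
            rng = np.random.default_rng(run_seed)
            sim_seed = int(rng.integers(2**31))
            if run_idx == 0:
                if start is not None:
                    x = np.asarray(start, dtype=float).copy()
                else:
                    # deterministic start at the center of the search box
                    x = np.array([(lo + hi) / 2.0 for _, lo, hi, _ in defs])
            else:
                x = np.array([rng.uniform(lo, hi) for _, lo, hi, _ in defs])

            budget = settings.sims_per_eval * settings.events_budget_per_locus

            def f(xv):
                return self.loglike_vector(
                    xv, settings.sims_per_eval, sim_seed, budget
                )

            def cycle_pass(x, ll, f, width):
                for pi in active:
                    name, lo, hi, _ = defs[pi]
                    a = max(lo, x[pi] - width[pi])
                    b = min(hi, x[pi] + width[pi])
                    best_v, best_ll = _golden_max(
                        lambda v: f(_with(x, pi, v)), a, b, settings.line_evals
                    )
                    if best_ll > ll:
                        x = _with(x, pi, best_v)
                        ll = best_ll
                return x, ll

            ll = f(x)
            for cycle in range(settings.ecm_cycles):
                width = max(0.25, 0.5 ** cycle) * np.array(
                    [(hi - lo) / 2.0 for _, lo, hi, _ in defs]
                )
                x, ll = cycle_pass(x, ll, f, width)
            if settings.refine_cycles:
                refine_sims = settings.refine_sims or 5 * settings.sims_per_eval
                refine_seed = int(rng.integers(2**31))
                refine_budget = refine_sims * settings.events_budget_per_locus

                def f_fine(xv):
                    return self.loglike_vector(
                        xv, refine_sims, refine_seed, refine_budget
                    )

                ll = f_fine(x)
                width = np.full(len(defs), settings.refine_width)
                for _ in range(settings.refine_cycles):
                    x, ll = cycle_pass(x, ll, f_fine, width)
            runs.append({"seed": run_seed, "x": x, "loglike": ll, "sim_seed": sim_seed})
        best = max(runs, key=lambda r: r["loglike"])
        final_sims = settings.final_sims or 2 * settings.sims_per_eval
        final_seed = int(master.integers(2**31))
        final_ll = self.loglike_vector(
            best["x"], final_sims, final_seed,
            final_sims * settings.events_budget_per_locus,
        )
        pset, founding = self.spec.params_from_vector(best["x"])
        free_values = {}
        for (name, _, _, scale), v in zip(defs, best["x"]):
            free_values[name] = 10.0**v if scale == "log10" else float(v)
        # report natural-scale derived times too
        free_values.update({"T0": pset.T0, "T1": pset.T1, "T2": pset.T2})
        if pset.T3 is not None:
            free_values["T3"] = pset.T3
        return DemographyResults(
            spec=self.spec,
            params=pset,
            founding=founding,
            free_values=free_values,
            max_est_lhood=final_ll,
            max_obs_lhood=self._max_obs,
            n_runs=settings.n_runs,
            best_run_seed=best["seed"],
            runs=runs,
            settings=settings,
            model=self,
        )


def _with(x: np.ndarray, i: int, v: float) -> np.ndarray:
    y = x.copy()
    y[i] = v
    return y


def _golden_max(f, a: float, b: float, n_evals: int) -> tuple[float, float]:
    """Golden-section search returning the best *evaluated* point (noise-safe)."""
    g = (math.sqrt(5.0) - 1.0) / 2.0
    c = b - g * (b - a)
    d = a + g * (b - a)
    fc, fd = f(c), f(d)
    pts = [(c, fc), (d, fd)]
    for _ in range(max(0, n_evals - 2)):
        if fc < fd:
            a, c, fc = c, d, fd
            d = a + g * (b - a)
            fd = f(d)
            pts.append((d, fd))
        else:
            b, d, fd = d, c, fc
            c = b - g * (b - a)
            fc = f(c)
            pts.append((c, fc))
    return max(pts, key=lambda p: p[1])


def fit_model(
    obs: dict[tuple[str, str], JointSFS],
    spec: ModelSpec,
    sample_sizes: tuple[int, ...],
    settings: FitSettings | None = None,
    seed: int = 0,
    pop_names: list[str] | None = None,
    start: np.ndarray | None = None,
    cycle_params: list[str] | None = None,
) -> DemographyResults:
    """Functional wrapper over :class:`DemographicInference`."""
    return DemographicInference(obs, spec, sample_sizes, pop_names).fit(
        seed=seed, settings=settings, start=start, cycle_params=cycle_params
    )


def staged_fit(
    obs: dict[tuple[str, str], JointSFS],
    model_ids: list[str],
    sample_sizes: tuple[int, ...],
    settings: FitSettings | None = None,
    seed: int = 0,
    pop_names: list[str] | None = None,
    rescore_sims: int | None = None,
) -> list[DemographyResults]:
    """Fit a candidate set with nested warm starts.

    Migration models start from the strict-isolation fit of the same
    topology; the windowed-migration scenarios (AM/SC) additionally prefer
    the continuous-migration (IM) fit, entering at the boundary contact
    fraction that reproduces it. This mirrors the usual practice of building
    gene-flow scenarios on the best isolation model and keeps the fitted
    likelihoods of nested models monotone up to search noise.

    All fits are finally re-scored with a common simulation seed and
    ``rescore_sims`` genealogies (default 4x the per-eval count), so that the
    AIC comparison between models shares its Monte-Carlo error instead of
    compounding it.
    """
    results: list[DemographyResults] = []
    si_by_joins: dict[tuple, DemographyResults] = {}
    im_by_joins: dict[tuple, DemographyResults] = {}
    for i, mid in enumerate(model_ids):
        spec = get_model_spec(mid)
        start = None
        cycle_params = None
        if spec.scenario != "SI":
            im = im_by_joins.get(spec.joins)
            si = si_by_joins.get(spec.joins)
            if spec.scenario in ("AM", "SC") and im is not None:
                frac3 = 0.95 if spec.scenario == "SC" else 0.05
                start = spec.vector_from(
                    im.params, im.founding, frac3_default=frac3
                )
                # profile the migration window on the shared base point, so
                # base-parameter search error cancels between models
                cycle_params = list(_MIGS) + ["frac3"]
            elif si is not None:
                start = spec.vector_from(si.params, si.founding)
        fit_settings = settings
        if cycle_params is not None and settings is not None:
            # refine-only profiling: narrow widths at the high simulation
            # count, no coarse wandering of the warm-started point
            fit_settings = replace(
                settings,
                ecm_cycles=0,
                refine_cycles=max(2, settings.refine_cycles),
                refine_width=0.75,
            )
        # every model shares one fit seed: the searches chase the same
        # Monte-Carlo noise realization, which common-seed rescoring then
        # largely cancels from the between-model comparison
        res = fit_model(
            obs, spec, sample_sizes, settings=fit_settings, seed=seed,
            pop_names=pop_names, start=start, cycle_params=cycle_params,
        )
        book = si_by_joins if spec.scenario == "SI" else (
            im_by_joins if spec.scenario == "IM" else None
        )
        if book is not None:
            prev = book.get(spec.joins)
            if prev is None or res.max_est_lhood > prev.max_est_lhood:
                book[spec.joins] = res
        results.append(res)
    settings = settings or FitSettings()
    n_rescore = rescore_sims or 4 * settings.sims_per_eval
    rescore_seed = int(np.random.default_rng(seed ^ 0xA5A5A5).integers(2**31))
    for res in results:
        res.max_est_lhood = res.model.loglike(
            res.params,
            res.founding,
            n_sims=n_rescore,
            seed=rescore_seed,
            max_events_total=n_rescore * settings.events_budget_per_locus,
        )
    return results


def compare_models(fits: list[DemographyResults]) -> pd.DataFrame:
    """Rank fits of the same observations by AIC (ties to fewer parameters)."""
    if len(fits) < 1:
        raise ValueError("need at least one fit")
    obs_ids = {round(f.max_obs_lhood, 6) for f in fits}
    if len(obs_ids) > 1:
        raise ValueError("fits compare different observations (MaxObsLhood differs)")
    rows = [
        {
            "model": f.spec.id,
            "scenario": f.spec.scenario,
            "k": f.k,
            "MaxEstLhood": f.max_est_lhood,
            "MaxObsLhood": f.max_obs_lhood,
            "delta_L": f.delta_l,
            "AIC": f.aic,
        }
        for f in fits
    ]
    frame = pd.DataFrame(rows).sort_values(["AIC", "k"]).reset_index(drop=True)
    frame["delta_AIC"] = frame["AIC"] - frame["AIC"].iloc[0]
    return frame


def simulate_counts_jsfs(
    spec: ModelSpec,
    pset: ParameterSet,
    sample_sizes: tuple[int, ...],
    n_snps: int,
    seed: int = 0,
    founding=None,
    pop_names: list[str] | None = None,
    folded: bool = True,
) -> dict[tuple[str, str], JointSFS]:
    """Simulate a pairwise count JSFS: one SNP per locus, branch ~ length."""
    model = build_model(spec, pset, founding)
    names = pop_names or [f"pop{i}" for i in range(len(sample_sizes))]
    from itertools import combinations

    pairs = [
        (i, j)
        for i, j in combinations(range(len(sample_sizes)), 2)
        if sample_sizes[i] > 0 and sample_sizes[j] > 0
    ]
    grids = {
        (i, j): np.zeros((sample_sizes[i] + 1, sample_sizes[j] + 1))
        for i, j in pairs
    }
    rng = random.Random(seed ^ 0x5F5E1)
    for cfgs, lens in simulate_branch_batches(
        model, SampleConfig(sample_sizes), n_snps, seed
    ):
        c = np.cumsum(lens)
        b = int(np.searchsorted(c, rng.random() * c[-1], side="right"))
        b = min(b, len(lens) - 1)
        for (i, j) in pairs:
            grids[(i, j)][cfgs[b, i], cfgs[b, j]] += 1
    out = {}
    for (i, j), grid in grids.items():
        s = JointSFS(grid, pop_pair=(names[i], names[j]), folded=False, kind="counts")
        out[(names[i], names[j])] = s.fold() if folded else s
    return out


def parametric_bootstrap_ci(
    spec: ModelSpec,
    pset: ParameterSet,
    sample_sizes: tuple[int, ...],
    n_snps: int,
    n_boot: int = 20,
    runs_per_boot: int = 10,
    seed: int = 0,
    settings: FitSettings | None = None,
    founding=None,
    folded: bool = True,
) -> pd.DataFrame:
    """Percentile CIs from refits of spectra simulated at the point estimate.

    Each bootstrap refit warm-starts at the point estimate (the usual
    parametric-bootstrap practice: the refit measures data resampling
    variability around the optimum, not global search scatter). Returns a
    frame indexed by free-parameter name with 2.5%/97.5% columns. Percentile
    intervals need not bracket the point estimate; asymmetry is reported,
    not corrected.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    settings = settings or FitSettings()
    boot_settings = replace(settings, n_runs=runs_per_boot)
    start = spec.vector_from(pset, founding)
    master = np.random.default_rng(seed)
    estimates: list[dict[str, float]] = []
    for _ in range(n_boot):
        s1 = int(master.integers(2**31))
        s2 = int(master.integers(2**31))
        obs = simulate_counts_jsfs(
            spec, pset, sample_sizes, n_snps, seed=s1, founding=founding, folded=folded
        )
        res = fit_model(
            obs, spec, sample_sizes, settings=boot_settings, seed=s2, start=start
        )
        estimates.append(res.free_values)
    frame = pd.DataFrame(estimates)
    lo = frame.quantile(0.025)
    hi = frame.quantile(0.975)
    return pd.DataFrame({"2.5%": lo, "97.5%": hi})


def generations_to_years(
    gens: float, generation_time: float = 2.5
) -> tuple[float, float]:
    """Convert generations before present to (years, Kyr rounded to 1 decimal)."""
    if gens < 0:
        raise ValueError("generations must be >= 0")
    years = gens * generation_time
    return years, round(years / 1000.0, 1)
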