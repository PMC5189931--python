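"""Pareto-ensemble parameter estimation by multiobjective simulated annealing.

Candidates are scored on the full objective vector and compared by
Pareto dominance; a candidate's rank is the number of candidates that
dominate it (rank 0 = the non-dominated front).  Moves are accepted when
they do not worsen the rank, or with Boltzmann probability
exp(-(rank_new - rank_old)/T) under a geometric cooling schedule.
Leave-one-out cross-validation over the objectives yields one ensemble
per partition together with independent training and prediction errors.
A randomized-parameter family (no fitting) serves as the negative
control, compared by a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dynamics import CORRECTION_FACTOR_BOUNDS, ParameterSet
from .objectives import Objective, evaluate_objectives

__all__ = [
    "ParameterSpace",
    "perturb",
    "pareto_rank",
    "anneal_accept",
    "POETsConfig",
    "Candidate",
    "Archive",
    "CVPartition",
    "CVResult",
    "run_poets",
    "crossvalidate",
    "select_ensemble",
    "random_control",
    "compare_to_control",
]

# searched parameter categories; characteristic expression constants and
# Hill orders stay fixed at their literature/configured values
_SEARCH_DICTS = (
    "k", "ksat", "control_half", "alpha", "beta", "delta", "gamma",
    "lambda_const",
)
_CORRECTION_DICTS = ("alpha", "beta", "delta", "gamma")
# per-step move blocks: signaling kinetics vs gene-expression parameters
_SIGNALING_DICTS = ("k", "ksat", "control_half")


class ParameterSpace:
    """Flat log-space view of the searched entries of a ParameterSet."""

    def __init__(self, nominal: ParameterSet, neighborhood: float = 0.3):
        self.nominal = nominal
        self.keys: list[tuple[str, str]] = []
        for d in _SEARCH_DICTS:
            for key in getattr(nominal, d):
                self.keys.append((d, key))
        self.n = len(self.keys)
        nom = self.to_vector(nominal)
        # +/-30% neighborhood of the nominal set, intersected with the
        # admissible correction-factor box
        lo = nom * (1.0 - neighborhood)
        hi = nom * (1.0 + neighborhood)
        for i, (d, _) in enumerate(self.keys):
            if d in _CORRECTION_DICTS:
                lo[i] = max(lo[i], CORRECTION_FACTOR_BOUNDS[0])
                hi[i] = min(hi[i], CORRECTION_FACTOR_BOUNDS[1])
        self.lower = lo
        self.upper = hi
        self.signaling_mask = np.array(
            [d in _SIGNALING_DICTS for d, _ in self.keys]
        )

    def to_vector(self, params: ParameterSet) -> np.ndarray:
        return np.array([getattr(params, d)[k] for d, k in self.keys])

    def from_vector(self, vec: np.ndarray) -> ParameterSet:
        p = self.nominal.copy()
        for (d, k), v in zip(self.keys, vec):
            getattr(p, d)[k] = float(v)
        return p


def perturb(
    params: ParameterSet,
    fraction: float,
    rng: np.random.Generator,
    mask: np.ndarray | None = None,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    space: ParameterSpace | None = None,
) -> ParameterSet:
    """Multiply each searched parameter by an independent U[1-f, 1+f] factor.

    Correction factors are clipped to their admissible range; optional
    ``bounds`` clip to a search neighborhood.  fraction = 0 is the
    identity; a fixed rng state gives bitwise-reproducible output.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    space = space or ParameterSpace(params)
    vec = space.to_vector(params)
    factors = rng.uniform(1.0 - fraction, 1.0 + fraction, size=space.n)
    if mask is not None:
        factors = np.where(mask, factors, 1.0)
    vec = vec * factors
    lo_cf, hi_cf = CORRECTION_FACTOR_BOUNDS
    for i, (d, _) in enumerate(space.keys):
        if d in _CORRECTION_DICTS:
            vec[i] = min(max(vec[i], lo_cf), hi_cf)
    if bounds is not None:
        vec = np.clip(vec, bounds[0], bounds[1])
    return space.from_vector(vec)


def pareto_rank(error_vectors) -> np.ndarray:
    """Rank = number of strict dominators (rank 0 = Pareto front).

    Candidate i dominates j when err_i <= err_j componentwise with at
    least one strict inequality.
    """
    E = np.asarray(error_vectors, dtype=float)
    if E.ndim != 2:
        raise ValueError("expected a 2-D array of error vectors")
    n = E.shape[0]
    ranks = np.zeros(n, dtype=int)
    block = 256
    for j0 in range(0, n, block):
        Ej = E[j0 : j0 + block]
        le = np.all(E[:, None, :] <= Ej[None, :, :], axis=2)
        lt = np.any(E[:, None, :] < Ej[None, :, :], axis=2)
        ranks[j0 : j0 + block] = (le & lt).sum(axis=0)
    return ranks


def anneal_accept(
    rank_new: int, rank_old: int, temperature: float, rng: np.random.Generator
) -> bool:
    """Accept non-worsening ranks; otherwise Boltzmann on the rank gap."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if rank_new <= rank_old:
        return True
    return rng.uniform() < np.exp(-(rank_new - rank_old) / temperature)


@dataclass(eq=False)
class Candidate:
    params: ParameterSet
    errors: np.ndarray
    rank: int = 0
    step: int = -1  # insertion step (age)

    @property
    def training_error(self) -> float:
        return float(np.sum(self.errors))


@dataclass
class Archive:
    candidates: list[Candidate] = field(default_factory=list)
    capacity: int = 2000

    def error_matrix(self) -> np.ndarray:
        return np.array([c.errors for c in self.candidates])

    def rerank(self) -> None:
        if not self.candidates:
            return
        for c, r in zip(self.candidates, pareto_rank(self.error_matrix())):
            c.rank = int(r)

    def insert(self, cand: Candidate) -> None:
        self.candidates.append(cand)
        self.rerank()
        while len(self.candidates) > self.capacity:
            # evict worst rank first, then highest total error, then age;
            # dominated members always leave before the current front
            worst = max(
                (c for c in self.candidates),
                key=lambda c: (c.rank, c.training_error, -c.step),
            )
            self.candidates.remove(worst)
            self.rerank()

    def front(self) -> list[Candidate]:
        return [c for c in self.candidates if c.rank == 0]


@dataclass
class POETsConfig:
    seed: int = 0
    steps: int = 500
    fraction: float = 0.3  # move size (and search neighborhood half-width)
    move_subset: float = 0.05  # fraction of the active block moved per step
    cooling: float = 0.9  # geometric temperature decay
    t0: float = 1.44  # ~50% initial acceptance for a unit rank gap
    cooling_interval: int = 25  # steps between cooling events
    capacity: int = 2000


@dataclass
class CVPartition:
    train_ids: list[int]
    validation_id: int


@dataclass
class CVResult:
    partition: CVPartition
    archive: Archive
    training_errors: np.ndarray  # per rank-0 candidate, summed over trained
    prediction_errors: np.ndarray  # per rank-0 candidate, held-out objective
    log: list[dict] = field(default_factory=list)

    @property
    def training_error(self) -> float:
        return float(np.median(self.training_errors))

    @property
    def prediction_error(self) -> float:
        return float(np.median(self.prediction_errors))


def run_poets(
    model,
    objectives: list[Objective],
    conditions,
    config: POETsConfig,
    nominal: ParameterSet,
) -> tuple[Archive, list[dict]]:
    """Multiobjective simulated-annealing search around a nominal set.

    Returns the rank-annotated archive and an audit log (one record per
    step: move block, acceptance, ranks, temperature).  Deterministic
    for a fixed config seed.
    """
    rng = np.random.default_rng(config.seed)
    space = ParameterSpace(nominal, neighborhood=config.fraction)
    bounds = (space.lower, space.upper)

    errors0 = evaluate_objectives(nominal, objectives, model, conditions)
    if not np.any(np.isfinite(errors0)):
        raise RuntimeError("nominal parameter set failed on every objective")
    archive = Archive(capacity=config.capacity)
    archive.insert(Candidate(nominal, errors0, step=0))

    current = Candidate(nominal, errors0)
    temperature = config.t0
    log: list[dict] = []
    for step in range(1, config.steps + 1):
        block = (
            space.signaling_mask if step % 2 == 1 else ~space.signaling_mask
        )
        # move a random subset of the active block (finer SA steps)
        subset = block & (rng.uniform(size=space.n) < config.move_subset)
        if not subset.any():
            subset = block
        trial_params = perturb(
            current.params, config.fraction, rng,
            mask=subset, bounds=bounds, space=space,
        )
        trial_errors = evaluate_objectives(
            trial_params, objectives, model, conditions
        )
        # rank the trial against the archive plus the current point
        E = np.vstack([archive.error_matrix(), current.errors, trial_errors])
        ranks = pareto_rank(E)
        rank_old, rank_new = int(ranks[-2]), int(ranks[-1])
        if rank_new == rank_old:
            # rank ties are common with many objectives; break them with a
            # Metropolis criterion on the relative total error
            old_sum = float(np.sum(current.errors))
            new_sum = float(np.sum(trial_errors))
            d_rel = (new_sum - old_sum) / max(old_sum, 1e-12)
            accept = rng.uniform() < np.exp(
                -max(d_rel, 0.0) / (0.1 * temperature)
            )
        else:
            accept = anneal_accept(rank_new, rank_old, temperature, rng)
        if accept:
            current = Candidate(trial_params, trial_errors)
        if np.all(np.isfinite(trial_errors)):
            archive.insert(Candidate(trial_params, trial_errors, step=step))
        log.append(
            {
                "step": step,
                "block": "signaling" if step % 2 == 1 else "expression",
                "rank_old": rank_old,
                "rank_new": rank_new,
                "accepted": bool(accept),
                "temperature": temperature,
            }
        )
        if step % config.cooling_interval == 0:
            temperature *= config.cooling
    return archive, log


def make_partitions(objective_ids: list[int]) -> list[CVPartition]:
    """Leave-one-out partitions: each objective is held out exactly once."""
    return [
        CVPartition([j for j in objective_ids if j != held_out], held_out)
        for held_out in objective_ids
    ]


def crossvalidate(
    model,
    objectives: list[Objective],
    conditions,
    config: POETsConfig,
    nominal: ParameterSet,
    partitions: list[CVPartition] | None = None,
) -> list[CVResult]:
    """Leave-one-out cross-validation: one ensemble per partition.

    Each partition trains on its objectives and evaluates the held-out
    objective on the partition's rank-0 front (the prediction error).
    """
    by_id = {o.id: o for o in objectives}
    partitions = partitions or make_partitions(sorted(by_id))
    results = []
    for i, part in enumerate(partitions):
        sub = [by_id[j] for j in part.train_ids]
        sub_config = POETsConfig(**{**config.__dict__, "seed": config.seed + i})
        archive, log = run_poets(model, sub, conditions, sub_config, nominal)
        front = archive.front()
        train_err = np.array([c.training_error for c in front])
        held = by_id[part.validation_id]
        pred_err = np.array(
            [
                evaluate_objectives(c.params, [held], model, conditions)[0]
                for c in front
            ]
        )
        results.append(CVResult(part, archive, train_err, pred_err, log))
    return results


def select_ensemble(
    results: list[CVResult],
    max_rank: int = 0,
    error_quantile: float = 1.0,
) -> list[ParameterSet]:
    """Union of candidates with rank <= max_rank and both errors below the
    stated quantile of their partition's distribution, deduplicated."""
    selected: list[ParameterSet] = []
    seen: set[bytes] = set()
    for res in results:
        front = [c for c in res.archive.candidates if c.rank <= max_rank]
        if not front:
            continue
        tr = np.array([c.training_error for c in front])
        space = ParameterSpace(front[0].params)
        if res.prediction_errors.size and len(res.prediction_errors) == len(
            res.archive.front()
        ):
            pred_by_id = {
                id(c): e
                for c, e in zip(res.archive.front(), res.prediction_errors)
            }
        else:
            pred_by_id = {}
        tr_cut = np.quantile(tr, error_quantile)
        pred_vals = np.array(
            [pred_by_id.get(id(c), 0.0) for c in front]
        )
        pred_cut = (
            np.quantile(pred_vals, error_quantile) if pred_vals.size else np.inf
        )
        for c, pv in zip(front, pred_vals):
            if c.training_error <= tr_cut and pv <= pred_cut:
                key = space.to_vector(c.params).tobytes()
                if key not in seen:
                    seen.add(key)
                    selected.append(c.params)
    if not selected:
        raise RuntimeError("ensemble selection produced no candidates")
    return selected


def random_control(
    nominal: ParameterSet,
    n: int,
    rng: np.random.Generator,
    scale: float = 10.0,
) -> list[ParameterSet]:
    """Randomized parameter family: log-uniform factors in [1/scale, scale]
    applied to every searched parameter, with no fitting."""
    if n < 1:
        raise ValueError("n must be >= 1")
    space = ParameterSpace(nominal)
    nom = space.to_vector(nominal)
    out = []
    lo_cf, hi_cf = CORRECTION_FACTOR_BOUNDS
    for _ in range(n):
        factors = np.exp(rng.uniform(-np.log(scale), np.log(scale), size=space.n))
        vec = nom * factors
        for i, (d, _) in enumerate(space.keys):
            if d in _CORRECTION_DICTS:
                vec[i] = min(max(vec[i], lo_cf), hi_cf)
        out.append(space.from_vector(vec))
    return out


def compare_to_control(trained_errors, control_errors):
    """Two-sided Wilcoxon rank-sum test (Mann-Whitney U form).

    Returns (statistic, p, significant at alpha = 0.05).  The exact null
    distribution is used for small samples without ties, so p-values
    match direct enumeration of rank assignments.
    """
    trained = np.asarray(trained_errors, dtype=float)
    control = np.asarray(control_errors, dtype=float)
    if trained.size == 0 or control.size == 0:
        raise ValueError("both samples must be nonempty")
    if (
        trained.size == control.size
        and np.array_equal(np.sort(trained), np.sort(control))
    ):
        warnings.warn("identical samples; rank-sum test is degenerate")
        return 0.0, 1.0, False
    res = stats.mannwhitneyu(trained, control, alternative="two-sided")
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < 0.05)
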