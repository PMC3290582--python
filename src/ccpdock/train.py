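"""Weight learning for the CCP scoring function.

Three pieces cooperate:

* a rank-based *native-recovery objective*: for each training complex the
  decoys are scored, the best ``top_k`` (default 50) by score are selected,
  and the complex contributes -100 if at least one selected decoy has a CCD
  rank below 100, plus -1 for every such decoy.  Lower totals mean the
  scoring weights push chemically native-like decoys to the top;

* *forward sequential feature selection* (FSFS) over the 60-key
  nucleotide-independent feature space: features are activated greedily one
  at a time, keeping at each round the activation with the best objective;

* a *particle swarm optimizer* (PSO, N = 50 particles) with a local
  stochastic refinement step — whenever a particle improves its personal
  best, random single-dimension two-sided steps are tried and kept while
  they improve, giving up after 10 consecutive failures — and early
  stopping after a step count drawn uniformly from 1-100.

Evaluation helpers (isoelectric point, binder/non-binder separation report)
support splitting control protein sets at pI = 7.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy import optimize as sp_optimize
from scipy import stats as sp_stats

from .constants import (
    AA_THREE_TO_ONE,
    DEFAULT_PKA,
    NEGATIVE_PKA_GROUPS,
    POSITIVE_PKA_GROUPS,
    REDUCED_KEYS,
)
from .scoring import WeightVector

__all__ = [
    "TrainingInstance",
    "ObjectiveSpec",
    "PSOConfig",
    "PSOResult",
    "FSFSResult",
    "ccd_rank",
    "score_instance",
    "objective_native_recovery",
    "pool_top_decoys",
    "pso_optimize",
    "fsfs",
    "fsfs_repeated",
    "make_native_recovery_evaluator",
    "train_weights",
    "isoelectric_point",
    "separation_report",
]


@dataclass(eq=False)
class TrainingInstance:
    """Per-complex decoy features: 60-dim reduced CCP + Coulomb + |CCP|,
    plus the CCD rank of every decoy (1-based, ascending CCD)."""

    complex_id: str
    features: np.ndarray      # (n_decoys, 60) in canonical reduced-key order
    coulomb: np.ndarray       # (n_decoys,)
    ccp_norm: np.ndarray      # (n_decoys,)
    ccd_rank: np.ndarray      # (n_decoys,) permutation of 1..n
    pose_ids: Optional[list] = None

    def __post_init__(self) -> None:
        n = self.features.shape[0]
        if self.features.shape[1] != len(REDUCED_KEYS):
            raise ValueError(f"feature matrix must have {len(REDUCED_KEYS)} columns")
        for name in ("coulomb", "ccp_norm", "ccd_rank"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have one entry per decoy")
        if sorted(self.ccd_rank.tolist()) != list(range(1, n + 1)):
            raise ValueError("ccd_rank must be a permutation of 1..n_decoys")

    @property
    def n_decoys(self) -> int:
        return self.features.shape[0]


@dataclass(eq=False)
class ObjectiveSpec:
    """Parameters of the rank-based native-recovery objective."""

    top_k_by_score: int = 50
    ccd_rank_threshold: int = 100
    hit_bonus: float = -100.0
    per_decoy_bonus: float = -1.0

    def __post_init__(self) -> None:
        if self.top_k_by_score < 1 or self.ccd_rank_threshold < 1:
            raise ValueError("top_k and ccd rank threshold must be >= 1")


@dataclass(eq=False)
class PSOConfig:
    n_particles: int = 50
    early_stop_steps: Optional[int] = None  # default: drawn uniformly in [1, 100]
    local_refine_failure_limit: int = 10
    rng_seed: int = 0
    inertia: float = 0.7298
    cognitive: float = 1.49618
    social: float = 1.49618
    max_evals: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.local_refine_failure_limit < 1:
            raise ValueError("particle count and failure limit must be positive")
        if self.early_stop_steps is not None and self.early_stop_steps < 1:
            raise ValueError("early_stop_steps must be >= 1")


@dataclass(eq=False)
class PSOResult:
    x: np.ndarray
    fun: float
    n_evals: int
    n_steps: int


@dataclass(eq=False)
class FSFSResult:
    selection_order: list
    appearance_counts: dict
    selected: list


def ccd_rank(ccds: Sequence[float], pose_ids: Optional[Sequence] = None) -> np.ndarray:
    """1-based ranks ascending by CCD; ties broken stably by pose id order."""
    ccds = np.asarray(ccds, dtype=float)
    n = len(ccds)
    if pose_ids is None:
        order = np.argsort(ccds, kind="stable")
    else:
        order = np.lexsort((np.asarray(pose_ids), ccds))
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    return ranks


def _weight_arrays(weights: WeightVector | np.ndarray,
                   area_weight: Optional[float] = None,
                   coulomb_weight: float = 1.0) -> tuple[np.ndarray, float, float]:
    if isinstance(weights, WeightVector):
        return weights.pair_weight_array(), weights.area_weight, weights.coulomb_weight
    w = np.asarray(weights, dtype=float)
    return w, (0.0 if area_weight is None else area_weight), coulomb_weight


def score_instance(instance: TrainingInstance,
                   weights: WeightVector | np.ndarray,
                   area_weight: Optional[float] = None,
                   coulomb_weight: float = 1.0) -> np.ndarray:
    """Scores S of every decoy of one complex under the given weights."""
    w, wa, wc = _weight_arrays(weights, area_weight, coulomb_weight)
    return instance.features @ w + wa * instance.ccp_norm + wc * instance.coulomb


def _top_k_indices(scores: np.ndarray, k: int) -> np.ndarray:
    # stable top-k by ascending score; ties resolve by decoy (pose id) order
    return np.argsort(scores, kind="stable")[:k]


def objective_native_recovery(
    weights: WeightVector | np.ndarray,
    instances: Sequence[TrainingInstance],
    spec: Optional[ObjectiveSpec] = None,
    area_weight: Optional[float] = None,
) -> float:
    """Sum over complexes of hit_bonus*[any selected decoy has CCD rank <
    threshold] + per_decoy_bonus*(count of such decoys); lower is better."""
    spec = spec or ObjectiveSpec()
    total = 0.0
    for inst in instances:
        if inst.n_decoys < spec.top_k_by_score:
            raise ValueError(
                f"complex {inst.complex_id}: {inst.n_decoys} decoys < "
                f"top_k {spec.top_k_by_score}"
            )
        scores = score_instance(inst, weights, area_weight=area_weight)
        sel = _top_k_indices(scores, spec.top_k_by_score)
        hits = int(np.sum(inst.ccd_rank[sel] < spec.ccd_rank_threshold))
        if hits:
            total += spec.hit_bonus + spec.per_decoy_bonus * hits
    return total


def make_fast_objective(
    instances: Sequence[TrainingInstance],
    spec: Optional[ObjectiveSpec] = None,
    cols: Optional[Sequence[int]] = None,
    fit_area_weight: bool = False,
) -> Callable[[np.ndarray], float]:
    """Vectorized native-recovery objective over stacked instance arrays.

    Equivalent to :func:`objective_native_recovery` restricted to the given
    feature columns (scores differing only in tie handling, which is
    measure-zero for continuous features); used inside FSFS/PSO loops where
    the per-call cost matters.  Requires equal decoy counts per complex.
    """
    spec = spec or ObjectiveSpec()
    n = instances[0].n_decoys
    if any(i.n_decoys != n for i in instances):
        raise ValueError("fast objective requires equal decoy counts per complex")
    if n < spec.top_k_by_score:
        raise ValueError("fewer decoys than top_k")
    cols = list(range(len(REDUCED_KEYS))) if cols is None else list(cols)
    F = np.stack([i.features[:, cols] for i in instances])   # (m, n, d)
    C = np.stack([i.coulomb for i in instances])             # (m, n)
    N = np.stack([i.ccp_norm for i in instances])
    hit = np.stack([i.ccd_rank < spec.ccd_rank_threshold for i in instances])
    k = spec.top_k_by_score

    def objective(x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if fit_area_weight:
            scores = F @ x[:-1] + x[-1] * N + C
        else:
            scores = F @ x + C
        sel = np.argpartition(scores, k - 1, axis=1)[:, :k]
        hits = np.take_along_axis(hit, sel, axis=1).sum(axis=1)
        return float(np.sum(np.where(hits > 0,
                                     spec.hit_bonus + spec.per_decoy_bonus * hits,
                                     0.0)))

    return objective


def pool_top_decoys(
    instances: Sequence[TrainingInstance],
    weights: WeightVector | np.ndarray,
    top_k: int = 50,
    area_weight: Optional[float] = None,
) -> list[tuple[str, int]]:
    """The pooled training set: the best ``top_k`` decoys by score from every
    complex, as (complex_id, decoy index) pairs (50 x 34 = 1700 at the
    canonical training scale)."""
    pooled = []
    for inst in instances:
        if inst.n_decoys < top_k:
            raise ValueError(f"complex {inst.complex_id} has fewer than {top_k} decoys")
        scores = score_instance(inst, weights, area_weight=area_weight)
        pooled.extend((inst.complex_id, int(i)) for i in _top_k_indices(scores, top_k))
    return pooled


def pso_optimize(
    objective: Callable[[np.ndarray], float],
    config: PSOConfig,
    bounds: tuple[np.ndarray, np.ndarray],
) -> PSOResult:
    """Particle swarm minimization with local stochastic refinement and
    randomized early stopping; fully reproducible for a given rng_seed."""
    lo = np.asarray(bounds[0], dtype=float)
    hi = np.asarray(bounds[1], dtype=float)
    if lo.size == 0 or lo.shape != hi.shape or np.any(~np.isfinite(lo)) or np.any(~np.isfinite(hi)):
        raise ValueError("bounds must be two equal-length finite arrays")
    if np.any(hi <= lo):
        raise ValueError("upper bounds must exceed lower bounds")
    dim = lo.size
    rng = np.random.default_rng(config.rng_seed)
    n_steps = (config.early_stop_steps if config.early_stop_steps is not None
               else int(rng.integers(1, 101)))
    span = hi - lo

    evals = 0

    def f(x: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        return float(objective(x))

    x = lo + span * rng.random((config.n_particles, dim))
    v = 0.1 * span * (rng.random((config.n_particles, dim)) - 0.5)
    pbest = x.copy()
    pbest_f = np.array([f(xi) for xi in x])
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])

    def refine(xi: np.ndarray, fi: float) -> tuple[np.ndarray, float]:
        """Two-sided random-dimension steps, kept while they improve;
        stops after `local_refine_failure_limit` consecutive failures."""
        failures = 0
        while failures < config.local_refine_failure_limit:
            if config.max_evals is not None and evals >= config.max_evals:
                break
            d = int(rng.integers(dim))
            step = 0.1 * span[d] * abs(rng.standard_normal())
            best_x, best_f = xi, fi
            for sign in (+1.0, -1.0):
                cand = xi.copy()
                cand[d] = np.clip(cand[d] + sign * step, lo[d], hi[d])
                fc = f(cand)
                if fc < best_f:
                    best_x, best_f = cand, fc
            if best_f < fi:
                xi, fi = best_x, best_f
                failures = 0
            else:
                failures += 1
        return xi, fi

    for _ in range(n_steps):
        if config.max_evals is not None and evals >= config.max_evals:
            break
        r1 = rng.random((config.n_particles, dim))
        r2 = rng.random((config.n_particles, dim))
        v = (config.inertia * v
             + config.cognitive * r1 * (pbest - x)
             + config.social * r2 * (gbest - x))
        x = np.clip(x + v, lo, hi)
        for i in range(config.n_particles):
            fi = f(x[i])
            if fi < pbest_f[i]:
                xi, fi = refine(x[i].copy(), fi)
                pbest[i], pbest_f[i] = xi, fi
                if fi < gbest_f:
                    gbest, gbest_f = xi.copy(), float(fi)
            if config.max_evals is not None and evals >= config.max_evals:
                break
    return PSOResult(x=gbest, fun=gbest_f, n_evals=evals, n_steps=n_steps)


def fsfs(
    features: Sequence,
    evaluate: Callable[[tuple], float],
    max_features: int,
) -> FSFSResult:
    """Greedy forward selection: each round, activate the single inactive
    feature whose activation yields the best (lowest) objective; stop at
    ``max_features``.  Ties keep the earliest feature in the given order."""
    features = list(features)
    if max_features > len(features):
        raise ValueError("max_features exceeds the feature space size")
    active: list = []
    for _ in range(max_features):
        best_feat, best_val = None, np.inf
        for feat in features:
            if feat in active:
                continue
            val = float(evaluate(tuple(active) + (feat,)))
            if val < best_val:
                best_feat, best_val = feat, val
        active.append(best_feat)
    counts = {feat: 1 for feat in active}
    return FSFSResult(selection_order=list(active), appearance_counts=counts,
                      selected=list(active))


def fsfs_repeated(
    features: Sequence,
    evaluators: Iterable[Callable[[tuple], float]],
    max_features: int,
) -> FSFSResult:
    """Run FSFS once per evaluator (e.g. per training split) and aggregate
    how often each feature is selected; features chosen early and often are
    the important ones."""
    counts: dict = {}
    orders = []
    for ev in evaluators:
        res = fsfs(features, ev, max_features)
        orders.append(res.selection_order)
        for feat in res.selected:
            counts[feat] = counts.get(feat, 0) + 1
    ranked = sorted(counts, key=lambda k: (-counts[k], orders[0].index(k)
                                           if k in orders[0] else len(features)))
    return FSFSResult(selection_order=orders[0], appearance_counts=counts,
                      selected=ranked[:max_features])


def make_native_recovery_evaluator(
    instances: Sequence[TrainingInstance],
    spec: Optional[ObjectiveSpec] = None,
    include_area: bool = False,
) -> Callable[[tuple], float]:
    """Cheap subset evaluator for FSFS: weight each active feature by the
    (sign-carrying) correlation of that feature with the CCD rank across all
    decoys, then measure the native-recovery objective.

    Features positively correlated with CCD rank (present in bad poses) get
    positive = repulsive weights and vice versa, so the evaluator rewards
    informative features without running a full weight optimization per
    candidate subset.
    """
    spec = spec or ObjectiveSpec()
    feats = np.concatenate([inst.features for inst in instances], axis=0)
    ranks = np.concatenate([inst.ccd_rank for inst in instances])
    ranks_c = ranks - ranks.mean()
    denom_r = np.sqrt(np.sum(ranks_c**2))
    corr = np.zeros(feats.shape[1])
    for j in range(feats.shape[1]):
        col = feats[:, j] - feats[:, j].mean()
        s = np.sqrt(np.sum(col**2))
        if s > 0:
            corr[j] = float(np.sum(col * ranks_c)) / (s * denom_r)
    area = 0.0
    if include_area:
        norms = np.concatenate([inst.ccp_norm for inst in instances])
        nc = norms - norms.mean()
        s = np.sqrt(np.sum(nc**2))
        area = float(np.sum(nc * ranks_c)) / (s * denom_r) if s > 0 else 0.0

    index = {feat: i for i, feat in enumerate(REDUCED_KEYS)}
    same_n = len({inst.n_decoys for inst in instances}) == 1
    fast = (make_fast_objective(instances, spec, fit_area_weight=include_area)
            if same_n else None)

    def evaluate(active: tuple) -> float:
        w = np.zeros(len(REDUCED_KEYS))
        for feat in active:
            w[index[feat]] = corr[index[feat]]
        if fast is not None:
            x = np.append(w, area) if include_area else w
            return fast(x)
        return objective_native_recovery(
            w, instances, spec, area_weight=area if include_area else None)

    return evaluate


def train_weights(
    instances: Sequence[TrainingInstance],
    active_features: Sequence[tuple],
    config: Optional[PSOConfig] = None,
    spec: Optional[ObjectiveSpec] = None,
    bound: float = 3.0,
    fit_area_weight: bool = True,
) -> WeightVector:
    """Optimize the weights of the given active features (plus, optionally,
    the |CCP| weight) with PSO against the native-recovery objective and
    return the resulting scoring model."""
    config = config or PSOConfig()
    spec = spec or ObjectiveSpec()
    active = list(active_features)
    index = {feat: i for i, feat in enumerate(REDUCED_KEYS)}
    cols = [index[feat] for feat in active]
    dim = len(cols) + (1 if fit_area_weight else 0)
    objective = make_fast_objective(instances, spec, cols=cols,
                                    fit_area_weight=fit_area_weight)
    res = pso_optimize(objective, config,
                       (np.full(dim, -bound), np.full(dim, bound)))
    pair = {feat: float(res.x[i]) for i, feat in enumerate(active)}
    return WeightVector(
        pair_weights=pair,
        area_weight=float(res.x[-1]) if fit_area_weight else 0.0,
        coulomb_weight=1.0,
    )


def _net_charge(ph: float, counts: dict, pka: dict) -> float:
    pos = sum(counts.get(g, 0) / (1.0 + 10.0 ** (ph - pka[g]))
              for g in POSITIVE_PKA_GROUPS + ("Nterm",))
    neg = sum(counts.get(g, 0) / (1.0 + 10.0 ** (pka[g] - ph))
              for g in NEGATIVE_PKA_GROUPS + ("Cterm",))
    return pos - neg


def isoelectric_point(protein_sequence: str, pka_table: Optional[dict] = None) -> float:
    """pH of zero net charge, solved by bisection of the Henderson-Hasselbalch
    charge equation with an EMBOSS-style pKa table.

    Accepts a one-letter sequence string or an iterable of three-letter codes.
    """
    if not protein_sequence:
        raise ValueError("empty protein sequence")
    if isinstance(protein_sequence, str):
        letters = list(protein_sequence.upper())
    else:
        letters = [AA_THREE_TO_ONE.get(str(x).upper(), str(x).upper())
                   for x in protein_sequence]
    unknown = [x for x in letters if x not in AA_THREE_TO_ONE.values()]
    if unknown:
        raise ValueError(f"unknown residues in sequence: {sorted(set(unknown))}")
    pka = dict(DEFAULT_PKA)
    if pka_table:
        pka.update(pka_table)
    counts = {g: letters.count(g) for g in POSITIVE_PKA_GROUPS + NEGATIVE_PKA_GROUPS}
    counts["Nterm"] = 1
    counts["Cterm"] = 1
    return float(sp_optimize.brentq(lambda ph: _net_charge(ph, counts, pka),
                                    -2.0, 16.0, xtol=1e-6))


def separation_report(
    binder_scores: Sequence[float],
    nonbinder_scores: Sequence[float],
    method: str = "hist",
) -> tuple[float, float]:
    """Z-score and normalized overlap of binder vs non-binder score
    distributions.

    Z = (chi - mu)/sigma with mu and the population sigma taken from the
    binder set and chi the *median* of the non-binder set: positive Z means
    non-binders score worse (higher) than binders on average.  The overlap
    is the integral of the pointwise minimum of the two normalized score
    densities (1 = indistinguishable, 0 = disjoint), estimated from shared
    Freedman-Diaconis histogram bins or, with ``method='kde'``, Gaussian
    kernel density estimates.
    """
    b = np.asarray(binder_scores, dtype=float)
    nb = np.asarray(nonbinder_scores, dtype=float)
    if b.size == 0 or nb.size == 0:
        raise ValueError("both score sets must be nonempty")
    mu, sigma = float(b.mean()), float(b.std(ddof=0))
    if sigma == 0.0:
        raise ValueError("binder scores have zero spread; Z-score undefined")
    z = (float(np.median(nb)) - mu) / sigma
    if method == "hist":
        both = np.concatenate([b, nb])
        edges = np.histogram_bin_edges(both, bins="fd")
        db, _ = np.histogram(b, bins=edges, density=True)
        dn, _ = np.histogram(nb, bins=edges, density=True)
        widths = np.diff(edges)
        overlap = float(np.sum(np.minimum(db, dn) * widths))
    elif method == "kde":
        kb = sp_stats.gaussian_kde(b)
        kn = sp_stats.gaussian_kde(nb)
        lo = min(b.min(), nb.min()) - 3 * max(b.std(), nb.std())
        hi = max(b.max(), nb.max()) + 3 * max(b.std(), nb.std())
        xs = np.linspace(lo, hi, 2048)
        overlap = float(np.trapezoid(np.minimum(kb(xs), kn(xs)), xs))
    else:
        raise ValueError("method must be 'hist' or 'kde'")
    return z, min(overlap, 1.0)
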