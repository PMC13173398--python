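"""NSGA-II search for Pareto-optimal matrix compositions and ASF selection.

The decision variables are the three peptide molarities, box-constrained to
the design region. Each objective is the predicted expression of one target
gene under its fitted response surface: genes to be upregulated enter
negated (so every objective is minimized), genes to be downregulated enter
as-is. The final non-dominated set is normalized between its ideal and nadir
points, and a single composition is picked by an augmented achievement
scalarizing function (ASF) whose weights encode per-gene model reliability
(adjusted R^2). A "control" composition — nearly Pareto-optimal but far from
the ASF pick in normalized Chebyshev distance — can be selected for
falsification experiments.

NSGA-II follows Deb's canonical formulation: fast non-dominated sorting,
crowding-distance diversity, binary tournament mating selection and elitist
(mu + lambda) environmental selection, with simulated binary crossover (SBX)
and polynomial mutation as variation operators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .design import Composition, FactorBounds
from .errors import ConfigError, EmptySelectionError, SpecError
from .surface import GeneResponseModel, quadratic_basis

#: defaults from the study's optimizer configuration
SBX_ETA = 15.0
SBX_PROB = 0.9
MUTATION_ETA = 20.0
MUTATION_PROB = 0.5
ASF_RHO = 1e-6
DEGENERATE_EPS = 1e-6


@dataclass
class ObjectiveSpec:
    """Target gene set with directions, reliability weights and fitted models.

    ``directions[i]`` is ``'up'`` (maximize predicted expression) or
    ``'down'`` (minimize). ``weights`` are per-gene reliabilities (adjusted
    R^2 clipped to (0, 1]); ``bounds`` are the factor bounds the models were
    coded against.
    """

    genes: list[str]
    directions: list[str]
    weights: np.ndarray
    models: list[GeneResponseModel]
    bounds: list[FactorBounds]

    def __post_init__(self):
        m = len(self.genes)
        if m < 1:
            raise SpecError("need at least one objective gene")
        if not (len(self.directions) == m and len(self.models) == m):
            raise SpecError("genes/directions/models length mismatch")
        if any(d not in ("up", "down") for d in self.directions):
            raise SpecError("directions must be 'up' or 'down'")
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != m:
            raise SpecError("weights length mismatch")
        if np.any(self.weights <= 0):
            raise SpecError("weights must be positive")
        for g, mod in zip(self.genes, self.models):
            if mod is None or mod.status != "ok":
                raise SpecError(f"gene {g} has no fitted model")

    @property
    def n_objectives(self) -> int:
        return len(self.genes)

    def signs(self) -> np.ndarray:
        return np.array([-1.0 if d == "up" else 1.0 for d in self.directions])

    def evaluate(self, X_raw: np.ndarray) -> np.ndarray:
        """Minimization objective matrix at raw-molarity points (n, 3) -> (n, m)."""
        X_raw = np.atleast_2d(np.asarray(X_raw, dtype=float))
        coded = np.column_stack(
            [fb.code(X_raw[:, i]) for i, fb in enumerate(self.bounds)]
        )
        B = quadratic_basis(coded)
        preds = np.column_stack([mod.predict_basis(B) for mod in self.models])
        return preds * self.signs()[None, :]


def objective_vector(x, spec: ObjectiveSpec) -> np.ndarray:
    """Minimization objective vector for one composition."""
    if isinstance(x, Composition):
        x = x.as_array()
    return spec.evaluate(np.asarray(x, dtype=float)[None, :])[0]


@dataclass
class ParetoResult:
    """Final non-dominated set and the ASF decision made on it."""

    X: np.ndarray  # solutions x 3, raw molarities
    F: np.ndarray  # solutions x objectives (minimization)
    ideal: np.ndarray
    nadir: np.ndarray
    asf_index: int
    asf_weights: np.ndarray
    seed: int
    n_gen: int
    pop_size: int
    b_mm: float = 0.2625

    def solutions(self) -> list[Composition]:
        return [Composition(*row, b=self.b_mm) for row in self.X]

    @property
    def asf_solution(self) -> Composition:
        return Composition(*self.X[self.asf_index], b=self.b_mm)


# ---------------------------------------------------------------------------
# NSGA-II building blocks


def fast_nondominated_sort(F: np.ndarray) -> list[np.ndarray]:
    """Deb's non-dominated fronts under minimization.

    Returns index arrays; front 0 is the non-dominated set. Vectorized over
    the pairwise dominance matrix (fine for population-scale inputs).
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    n = F.shape[0]
    le = (F[:, None, :] <= F[None, :, :]).all(axis=2)
    lt = (F[:, None, :] < F[None, :, :]).any(axis=2)
    dominates = le & lt  # dominates[i, j]: i dominates j
    n_dom = dominates.sum(axis=0).astype(int)
    fronts = []
    remaining = np.ones(n, dtype=bool)
    while remaining.any():
        current = remaining & (n_dom == 0)
        if not current.any():  # numerical safety; cannot happen with strict dominance
            current = remaining.copy()
        idx = np.flatnonzero(current)
        fronts.append(idx)
        remaining[idx] = False
        n_dom = n_dom - dominates[idx].sum(axis=0)
    return fronts


def crowding_distance(F: np.ndarray) -> np.ndarray:
    """Crowding distance of each point of one front (Deb's formula).

    Boundary points in any objective get +inf; interior points sum the
    neighbour gaps normalized by the front's per-objective range.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    n, m = F.shape
    d = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        fj = F[order, j]
        span = fj[-1] - fj[0]
        d[order[0]] = d[order[-1]] = np.inf
        if span <= 0:
            continue
        d[order[1:-1]] += (fj[2:] - fj[:-2]) / span
    return d


def sbx_crossover(
    p1: np.ndarray,
    p2: np.ndarray,
    eta: float = SBX_ETA,
    prob: float = SBX_PROB,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
    var_prob: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated binary crossover on one parent pair.

    With probability ``prob`` the pair is crossed; each variable is then
    crossed with probability ``var_prob`` using spread factor
    beta(u) = (2u)^(1/(eta+1)) or (1/(2(1-u)))^(1/(eta+1)), which conserves
    the per-variable parent sum before boundary clipping.
    """
    rng = np.random.default_rng() if rng is None else rng
    p1 = np.asarray(p1, dtype=float).copy()
    p2 = np.asarray(p2, dtype=float).copy()
    c1, c2 = p1.copy(), p2.copy()
    if rng.uniform() < prob:
        for i in range(len(p1)):
            if rng.uniform() >= var_prob or abs(p1[i] - p2[i]) < 1e-14:
                continue
            u = rng.uniform()
            if u <= 0.5:
                beta = (2.0 * u) ** (1.0 / (eta + 1.0))
            else:
                beta = (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta + 1.0))
            c1[i] = 0.5 * ((1 + beta) * p1[i] + (1 - beta) * p2[i])
            c2[i] = 0.5 * ((1 - beta) * p1[i] + (1 + beta) * p2[i])
    if bounds is not None:
        xl, xu = bounds
        c1 = np.clip(c1, xl, xu)
        c2 = np.clip(c2, xl, xu)
    return c1, c2


def polynomial_mutation(
    x: np.ndarray,
    eta: float = MUTATION_ETA,
    prob: float = MUTATION_PROB,
    bounds: tuple[np.ndarray, np.ndarray] = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Bounded polynomial mutation; each variable mutates with probability ``prob``."""
    rng = np.random.default_rng() if rng is None else rng
    x = np.asarray(x, dtype=float).copy()
    xl, xu = bounds
    for i in range(len(x)):
        if rng.uniform() >= prob:
            continue
        span = xu[i] - xl[i]
        if span <= 0:
            continue
        d1 = (x[i] - xl[i]) / span
        d2 = (xu[i] - x[i]) / span
        u = rng.uniform()
        mut_pow = 1.0 / (eta + 1.0)
        if u < 0.5:
            val = 2.0 * u + (1.0 - 2.0 * u) * (1.0 - d1) ** (eta + 1.0)
            delta = val**mut_pow - 1.0
        else:
            val = 2.0 * (1.0 - u) + (2.0 * u - 1.0) * (1.0 - d2) ** (eta + 1.0)
            delta = 1.0 - val**mut_pow
        x[i] = np.clip(x[i] + delta * span, xl[i], xu[i])
    return x


def _rank_and_crowding(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    fronts = fast_nondominated_sort(F)
    rank = np.empty(F.shape[0], dtype=int)
    crowd = np.empty(F.shape[0])
    for r, idx in enumerate(fronts):
        rank[idx] = r
        crowd[idx] = crowding_distance(F[idx])
    return rank, crowd


def _tournament(rank, crowd, rng):
    a, b = rng.integers(0, len(rank), size=2)
    if rank[a] < rank[b]:
        return a
    if rank[b] < rank[a]:
        return b
    if crowd[a] > crowd[b]:
        return a
    if crowd[b] > crowd[a]:
        return b
    return a if rng.uniform() < 0.5 else b


def _environmental_selection(F, pop_size):
    """Elitist truncation: fill by front, split the last front by crowding."""
    fronts = fast_nondominated_sort(F)
    chosen: list[int] = []
    for idx in fronts:
        if len(chosen) + len(idx) <= pop_size:
            chosen.extend(idx.tolist())
        else:
            crowd = crowding_distance(F[idx])
            order = np.argsort(-crowd, kind="stable")
            chosen.extend(idx[order][: pop_size - len(chosen)].tolist())
            break
    return np.array(chosen, dtype=int)


def nsga2(
    evaluate,
    xl,
    xu,
    pop_size: int = 100,
    n_gen: int = 200,
    seed: int = 0,
    eta_cx: float = SBX_ETA,
    p_cx: float = SBX_PROB,
    eta_mut: float = MUTATION_ETA,
    p_mut: float = MUTATION_PROB,
) -> tuple[np.ndarray, np.ndarray]:
    """Generational NSGA-II over a box; returns the final population (X, F).

    ``evaluate`` maps an (n, d) array to an (n, m) minimization matrix.
    Deterministic per seed: initialization, tournament, crossover and
    mutation each draw from an independent stream spawned from the root seed,
    so reordering one operator's internals cannot silently shift another's
    draws.
    """
    if pop_size < 4 or pop_size % 2:
        raise ConfigError("pop_size must be even and >= 4")
    if n_gen < 1:
        raise ConfigError("n_gen must be >= 1")
    xl = np.asarray(xl, dtype=float)
    xu = np.asarray(xu, dtype=float)
    streams = np.random.SeedSequence(seed).spawn(4)
    rng_init, rng_tour, rng_cx, rng_mut = (np.random.default_rng(s) for s in streams)

    X = rng_init.uniform(xl, xu, size=(pop_size, len(xl)))
    F = np.atleast_2d(evaluate(X))
    for _ in range(n_gen):
        rank, crowd = _rank_and_crowding(F)
        children = []
        while len(children) < pop_size:
            i1 = _tournament(rank, crowd, rng_tour)
            i2 = _tournament(rank, crowd, rng_tour)
            c1, c2 = sbx_crossover(
                X[i1], X[i2], eta=eta_cx, prob=p_cx, bounds=(xl, xu), rng=rng_cx
            )
            children.append(polynomial_mutation(c1, eta=eta_mut, prob=p_mut,
                                                bounds=(xl, xu), rng=rng_mut))
            children.append(polynomial_mutation(c2, eta=eta_mut, prob=p_mut,
                                                bounds=(xl, xu), rng=rng_mut))
        Xc = np.array(children[:pop_size])
        Fc = np.atleast_2d(evaluate(Xc))
        X_all = np.vstack([X, Xc])
        F_all = np.vstack([F, Fc])
        keep = _environmental_selection(F_all, pop_size)
        X, F = X_all[keep], F_all[keep]
    return X, F


# ---------------------------------------------------------------------------
# Decision making on the front


def estimate_ideal_nadir(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ideal (column min) and nadir (column max) over the non-dominated set.

    Degenerate objectives (nadir - ideal < eps) are widened by eps with a
    warning so downstream normalization stays finite.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    ideal = F.min(axis=0)
    nadir = F.max(axis=0)
    degenerate = nadir - ideal < DEGENERATE_EPS
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} degenerate objective(s); widening by eps",
            RuntimeWarning,
            stacklevel=2,
        )
        nadir = nadir + np.where(degenerate, DEGENERATE_EPS, 0.0)
    return ideal, nadir


def asf_values(
    F: np.ndarray,
    ideal: np.ndarray,
    nadir: np.ndarray,
    weights: np.ndarray,
    convention: str = "multiply",
    rho: float = ASF_RHO,
) -> np.ndarray:
    """Augmented achievement scalarizing function of each objective row.

    Deviations are normalized to (f - ideal)/(nadir - ideal); weights are
    normalized to sum to one. ``convention='multiply'`` (default) multiplies
    the normalized deviation by the weight, so a high-reliability objective
    constrains the solution more; ``'divide'`` uses the reference-point
    convention common in optimization libraries (deviation / weight).
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != F.shape[1]:
        raise SpecError("one weight per objective required")
    if np.any(weights <= 0):
        raise SpecError("weights must be positive")
    wt = weights / weights.sum()
    denom = nadir - ideal
    D = (F - ideal) / denom
    if convention == "multiply":
        term = D * wt
    elif convention == "divide":
        term = D / wt
    else:
        raise SpecError(f"unknown ASF convention {convention!r}")
    return term.max(axis=1) + rho * D.sum(axis=1)


def asf_select(
    F: np.ndarray,
    ideal: np.ndarray,
    nadir: np.ndarray,
    weights: np.ndarray,
    convention: str = "multiply",
    rho: float = ASF_RHO,
) -> int:
    """Index of the front member minimizing the augmented ASF (ties: lowest index)."""
    return int(np.argmin(asf_values(F, ideal, nadir, weights, convention, rho)))


def chebyshev_distance(f, f_ref, ideal, nadir) -> float:
    """Chebyshev (max-abs) distance between two objective vectors in normalized space."""
    f = np.asarray(f, dtype=float)
    f_ref = np.asarray(f_ref, dtype=float)
    denom = np.asarray(nadir, dtype=float) - np.asarray(ideal, dtype=float)
    if np.any(denom <= 0):
        raise SpecError("degenerate normalization; widen nadir first")
    return float(np.max(np.abs((f - f_ref) / denom)))


def optimize_composition(
    spec: ObjectiveSpec,
    pop_size: int | None = None,
    n_gen: int = 200,
    seed: int = 0,
    asf_convention: str = "multiply",
) -> ParetoResult:
    """Run NSGA-II on an objective spec and select the ASF-optimal composition.

    Population size defaults to max(100, 20 x n_objectives), rounded up to a
    multiple of 4. The returned set is the non-dominated subset of the final
    population (duplicates removed), with ideal/nadir estimated from it.
    """
    if pop_size is None:
        pop_size = max(100, 20 * spec.n_objectives)
        pop_size += (-pop_size) % 4
    xl = np.array([fb.low for fb in spec.bounds])
    xu = np.array([fb.high for fb in spec.bounds])
    X, F = nsga2(spec.evaluate, xl, xu, pop_size=pop_size, n_gen=n_gen, seed=seed)
    front = fast_nondominated_sort(F)[0]
    Xf, Ff = X[front], F[front]
    _, unique_idx = np.unique(np.round(Xf, 12), axis=0, return_index=True)
    keep = np.sort(unique_idx)
    Xf, Ff = Xf[keep], Ff[keep]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ideal, nadir = estimate_ideal_nadir(Ff)
    idx = asf_select(Ff, ideal, nadir, spec.weights, convention=asf_convention)
    return ParetoResult(
        X=Xf, F=Ff, ideal=ideal, nadir=nadir, asf_index=idx,
        asf_weights=np.asarray(spec.weights, dtype=float), seed=seed,
        n_gen=n_gen, pop_size=pop_size,
        b_mm=getattr(spec.bounds[0], "b_mm", 0.2625),
    )


def select_control(
    result: ParetoResult,
    spec: ObjectiveSpec,
    front_gap_max: float = 0.12,
    cheb_range: tuple[float, float] = (0.2, 0.6),
    candidates: np.ndarray | None = None,
    n_lhs: int = 512,
    seed: int = 0,
    asf_convention: str = "multiply",
) -> tuple[Composition, dict]:
    """Pick a near-Pareto control composition far from the ASF solution.

    Candidates (default: the final front plus Latin-hypercube samples of the
    box) are kept if their ASF value exceeds the front's best by at most
    ``front_gap_max`` (differences on the ideal/nadir-normalized objective
    scale, so 0.12 means within 12% of objective space of the optimum).
    Among those whose normalized Chebyshev distance to the ASF solution lies
    inside ``cheb_range``, the most distant is returned, re-verified against
    both constraints. Raises :class:`EmptySelectionError` (reporting the
    achievable ranges) if no candidate qualifies.
    """
    xl = np.array([fb.low for fb in spec.bounds])
    xu = np.array([fb.high for fb in spec.bounds])
    if candidates is None:
        sampler = qmc.LatinHypercube(d=len(xl), seed=seed)
        lhs = qmc.scale(sampler.random(n_lhs), xl, xu)
        candidates = np.vstack([result.X, lhs])
    candidates = np.atleast_2d(np.asarray(candidates, dtype=float))
    Fc = spec.evaluate(candidates)
    asf_c = asf_values(Fc, result.ideal, result.nadir, result.asf_weights,
                       convention=asf_convention)
    asf_best = float(
        asf_values(result.F, result.ideal, result.nadir, result.asf_weights,
                   convention=asf_convention).min()
    )
    gaps = asf_c - asf_best
    f_star = result.F[result.asf_index]
    cheb = np.array(
        [chebyshev_distance(f, f_star, result.ideal, result.nadir) for f in Fc]
    )
    near = gaps <= front_gap_max
    in_band = near & (cheb >= cheb_range[0]) & (cheb <= cheb_range[1])
    if not in_band.any():
        raise EmptySelectionError(
            "no candidate satisfies both constraints; "
            f"achievable gap range [{gaps.min():.4g}, {gaps.max():.4g}], "
            f"Chebyshev range among near-front candidates "
            f"[{cheb[near].min() if near.any() else float('nan'):.4g}, "
            f"{cheb[near].max() if near.any() else float('nan'):.4g}]",
            gap_range=(float(gaps.min()), float(gaps.max())),
            cheb_range=(
                (float(cheb[near].min()), float(cheb[near].max()))
                if near.any()
                else None
            ),
        )
    pool = np.flatnonzero(in_band)
    best = pool[np.argmax(cheb[pool])]
    # re-verify the returned candidate against both constraints
    assert gaps[best] <= front_gap_max + 1e-12
    assert cheb_range[0] - 1e-12 <= cheb[best] <= cheb_range[1] + 1e-12
    info = {
        "asf_gap": float(gaps[best]),
        "chebyshev": float(cheb[best]),
        "objectives": Fc[best].tolist(),
    }
    return Composition(*candidates[best], b=result.b_mm), info
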