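"""Atom search optimisation (ASO) and its coupling to the ANFIS.

Candidate solutions are atoms in a d-dimensional box.  Atoms interact
through a Lennard-Jones-style pair force whose repulsion and attraction
components cancel at r = 2**(1/6) * sigma (about 1.12 sigma); better
solutions receive larger masses, so they accelerate less and anchor the
population while poor atoms are flung around the search space.

Two dynamics are provided:

``mode="adaptive"`` (default)
    The practical optimiser: interaction restricted to a shrinking set of
    best neighbours, reduced distances clipped into the near-equilibrium
    band, a depth weight that decays over iterations, and a drift force
    pulling every atom toward the global best.  This is the variant that
    actually converges and is used for model fitting.

``mode="literal"``
    The bare equation set — full pairwise force at fixed sigma/epsilon and
    a = F/m — useful for tracing the primitive dynamics by hand.

The pair-force primitives are shared by both modes and are exact
implementations of the printed force expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .anfis import (
    AnfisConfig,
    AnfisParameters,
    init_from_clustering,
    pack,
    predict_batch,
    rmse,
    unpack,
)

__all__ = [
    "AsoConfig",
    "AsoState",
    "pair_force",
    "total_force",
    "compute_masses",
    "step",
    "optimize",
    "fit_asoanfis_arrays",
    "fit_asoanfis",
    "anfis_search_bounds",
]

_DIST_FLOOR_FACTOR = 1e-9


@dataclass(frozen=True)
class AsoConfig:
    n_atoms: int
    n_dims: int
    n_iterations: int = 200
    lower: np.ndarray | float = 0.0
    upper: np.ndarray | float = 1.0
    sigma: float = 1.0
    epsilon: float = 1.0
    stop_threshold: float | None = None
    seed: int | None = None
    mode: str = "adaptive"  # "adaptive" | "literal"
    depth_weight: float = 50.0  # alpha: scales the interaction force
    drift_weight: float = 0.2  # beta: scales the pull toward the best atom

    def __post_init__(self) -> None:
        if self.n_atoms < 2 or self.n_dims < 1 or self.n_iterations < 1:
            raise ValueError("need n_atoms >= 2, n_dims >= 1, n_iterations >= 1")
        if self.mode not in ("adaptive", "literal"):
            raise ValueError("mode must be 'adaptive' or 'literal'")

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.broadcast_to(np.asarray(self.lower, float), (self.n_dims,)).copy()
        hi = np.broadcast_to(np.asarray(self.upper, float), (self.n_dims,)).copy()
        if np.any(hi <= lo):
            raise ValueError("upper bounds must exceed lower bounds")
        return lo, hi


@dataclass
class AsoState:
    iteration: int
    positions: np.ndarray  # (n, d)
    velocities: np.ndarray  # (n, d)
    fitnesses: np.ndarray  # (n,)
    best_position: np.ndarray  # (d,)
    best_fitness: float
    history: list = field(default_factory=list)  # best-so-far per executed step
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    n_evaluations: int = 0


# ---------------------------------------------------------------------------
# Force primitives (printed expressions, shared by both modes)


def _force_bracket(r: np.ndarray, sigma: float) -> np.ndarray:
    """2*(sigma/r)**14 - (sigma/r)**8 — positive in the repulsion regime."""
    s = sigma / r
    return 2.0 * s**14 - s**8


def pair_force(
    xi: np.ndarray, xj: np.ndarray, sigma: float = 1.0, epsilon: float = 1.0
) -> np.ndarray:
    """Lennard-Jones pair force acting on atom i due to atom j.

    F_i = 24*eps/sigma**2 * [2*(sigma/r)**14 - (sigma/r)**8] * (x_i - x_j),
    which repels below the equilibrium distance r = 2**(1/6)*sigma (~1.12
    sigma) and attracts beyond it.  The distance is floored to avoid the
    singularity at coincident atoms.
    """
    xi = np.asarray(xi, float)
    xj = np.asarray(xj, float)
    diff = xi - xj
    r = max(float(np.linalg.norm(diff)), _DIST_FLOOR_FACTOR * sigma)
    return 24.0 * epsilon / sigma**2 * _force_bracket(r, sigma) * diff


def total_force(
    i: int, positions: np.ndarray, sigma: float = 1.0, epsilon: float = 1.0
) -> np.ndarray:
    """Sum of pair forces on atom i from every other atom."""
    positions = np.asarray(positions, float)
    if positions.shape[0] < 2:
        raise ValueError("need at least two atoms")
    out = np.zeros(positions.shape[1])
    for j in range(positions.shape[0]):
        if j != i:
            out += pair_force(positions[i], positions[j], sigma, epsilon)
    return out


def equilibrium_distance(sigma: float = 1.0) -> float:
    """Numeric root of the force bracket: the distance of zero net pair force."""
    from scipy.optimize import brentq

    return float(brentq(lambda r: _force_bracket(r, sigma), 0.5 * sigma, 2.0 * sigma))


def compute_masses(fitnesses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fitness-derived masses: (unnormalised M, normalised m summing to 1).

    M_i = exp(-(Fit_i - Fit_best) / (Fit_worst - Fit_best)); the best atom
    gets M = 1 and the worst M = 1/e.  All-equal fitnesses degenerate to
    uniform masses.
    """
    fit = np.asarray(fitnesses, float)
    best, worst = fit.min(), fit.max()
    if worst - best < 1e-300:
        M = np.ones_like(fit)
    else:
        M = np.exp(-(fit - best) / (worst - best))
    return M, M / M.sum()


# ---------------------------------------------------------------------------
# Population dynamics


def _evaluate(objective, positions, lo, hi, rng, counter):
    fits = np.empty(positions.shape[0])
    for idx in range(positions.shape[0]):
        val = float(objective(positions[idx]))
        counter[0] += 1
        tries = 0
        while not np.isfinite(val):
            warnings.warn("non-finite objective value; atom resampled in bounds")
            positions[idx] = lo + rng.random(lo.size) * (hi - lo)
            val = float(objective(positions[idx]))
            counter[0] += 1
            tries += 1
            if tries > 20:
                raise RuntimeError("objective keeps returning non-finite values")
        fits[idx] = val
    return fits


def _literal_forces(positions: np.ndarray, sigma: float, epsilon: float) -> np.ndarray:
    n, d = positions.shape
    diff = positions[:, None, :] - positions[None, :, :]  # x_i - x_j
    r = np.linalg.norm(diff, axis=2)
    np.fill_diagonal(r, np.inf)
    r = np.maximum(r, _DIST_FLOOR_FACTOR * sigma)
    coef = 24.0 * epsilon / sigma**2 * _force_bracket(r, sigma)
    np.fill_diagonal(coef, 0.0)
    return (coef[:, :, None] * diff).sum(axis=1)


def _adaptive_forces(state: AsoState, cfg: AsoConfig) -> np.ndarray:
    """Interaction + drift forces of the adaptive dynamics."""
    X = state.positions
    n, d = X.shape
    t, T = state.iteration + 1, cfg.n_iterations
    order = np.argsort(state.fitnesses)
    K = max(2, int(round(n - (n - 2) * np.sqrt(t / T))))
    kbest = order[:K]
    xbar = X[kbest].mean(axis=0)

    eta = cfg.depth_weight * (1.0 - (t - 1) / T) ** 3 * np.exp(-20.0 * t / T)
    g = 0.1 * np.sin(np.pi / 2.0 * t / T)
    h_min, h_max = 1.1 + g, 1.24

    forces = np.zeros((n, d))
    scale = np.linalg.norm(X - xbar[None, :], axis=1) + 1e-12  # per-atom sigma(t)
    for j in kbest:
        diff = X[j][None, :] - X  # toward neighbour j
        r = np.linalg.norm(diff, axis=1)
        h = np.clip(r / scale, h_min, h_max)
        mag = -_force_bracket(1.0, 1.0 / h)  # -(2 h^-14 - h^-8): attract when h > 1.12
        randj = state.rng.random(n)
        contrib = (eta * randj * mag / np.maximum(r, 1e-12))[:, None] * diff
        contrib[j] = 0.0
        forces += contrib

    lam = cfg.drift_weight * np.exp(-20.0 * t / T)
    forces += lam * (state.best_position[None, :] - X)
    return forces


def step(state: AsoState, objective, cfg: AsoConfig) -> AsoState:
    """Advance the population one iteration (in place) and return the state.

    Velocities update as v <- rand * v + a with a = F/m and per-atom,
    per-dimension uniform rand in [0, 1]; positions move by the new velocity
    and are clamped to the bounds; fitnesses, masses and the global best are
    refreshed.  The recorded best is best-so-far, hence non-increasing.
    """
    lo, hi = cfg.bounds_arrays()
    n, d = state.positions.shape

    if cfg.mode == "literal":
        forces = _literal_forces(state.positions, cfg.sigma, cfg.epsilon)
    else:
        forces = _adaptive_forces(state, cfg)

    _, m = compute_masses(state.fitnesses)
    accel = forces / m[:, None]

    rand = state.rng.random((n, d))
    state.velocities = rand * state.velocities + accel
    state.positions = np.clip(state.positions + state.velocities, lo, hi)

    counter = [state.n_evaluations]
    state.fitnesses = _evaluate(objective, state.positions, lo, hi, state.rng, counter)
    state.n_evaluations = counter[0]

    ibest = int(np.argmin(state.fitnesses))
    if state.fitnesses[ibest] < state.best_fitness:
        state.best_fitness = float(state.fitnesses[ibest])
        state.best_position = state.positions[ibest].copy()
    state.iteration += 1
    state.history.append(state.best_fitness)
    return state


def optimize(
    objective,
    cfg: AsoConfig,
    initial_positions: np.ndarray | None = None,
) -> tuple[np.ndarray, float, list[float]]:
    """Run the ASO on a scalar objective; returns (best x, best f, history).

    ``initial_positions`` may seed any leading subset of the population
    (e.g. one atom from a clustering-based warm start); the rest is drawn
    uniformly in the bounds.  The history holds the best-so-far objective
    after each executed iteration and is therefore monotone non-increasing.
    Terminates early once the best objective falls at or below
    ``cfg.stop_threshold``.
    """
    lo, hi = cfg.bounds_arrays()
    rng = np.random.default_rng(cfg.seed)
    positions = lo + rng.random((cfg.n_atoms, cfg.n_dims)) * (hi - lo)
    if initial_positions is not None:
        seeded = np.atleast_2d(np.asarray(initial_positions, float))
        positions[: seeded.shape[0]] = np.clip(seeded, lo, hi)

    counter = [0]
    fits = _evaluate(objective, positions, lo, hi, rng, counter)
    ibest = int(np.argmin(fits))
    state = AsoState(
        iteration=0,
        positions=positions,
        velocities=np.zeros_like(positions),
        fitnesses=fits,
        best_position=positions[ibest].copy(),
        best_fitness=float(fits[ibest]),
        rng=rng,
        n_evaluations=counter[0],
    )
    if cfg.stop_threshold is not None and state.best_fitness <= cfg.stop_threshold:
        return state.best_position, state.best_fitness, state.history

    for _ in range(cfg.n_iterations):
        step(state, objective, cfg)
        if cfg.stop_threshold is not None and state.best_fitness <= cfg.stop_threshold:
            break
    return state.best_position, state.best_fitness, state.history


# ---------------------------------------------------------------------------
# ANFIS coupling


def anfis_search_bounds(
    X: np.ndarray, y: np.ndarray, cfg: AnfisConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Physical box constraints for the packed ANFIS parameter vector.

    Per feature with observed range R: bell widths a in (0, 2R], shapes b in
    [0.5, 5] (avoids flat or needle memberships), centres c padded 10%
    outside the data range; consequents bounded by +-10 times the target
    range.  Degenerate (constant) columns fall back to unit ranges.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    m, k = cfg.n_features, cfg.n_rules
    fmin, fmax = X.min(axis=0), X.max(axis=0)
    frange = np.maximum(fmax - fmin, 1e-6)
    yrange = max(y.max() - y.min(), 1e-6)
    yscale = max(np.abs(y).max(), yrange)

    a_lo = np.tile(1e-3 * frange, k)
    a_hi = np.tile(2.0 * frange, k)
    b_lo = np.full(k * m, 0.5)
    b_hi = np.full(k * m, 5.0)
    c_lo = np.tile(fmin - 0.1 * frange, k)
    c_hi = np.tile(fmax + 0.1 * frange, k)
    cons_lo = np.full((m + 1) * k, -10.0 * yscale)
    cons_hi = np.full((m + 1) * k, 10.0 * yscale)
    lo = np.concatenate([a_lo, b_lo, c_lo, cons_lo])
    hi = np.concatenate([a_hi, b_hi, c_hi, cons_hi])
    return lo, hi


def conditional_consequents(
    X: np.ndarray, y: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-rule weighted least-squares consequents for given memberships.

    With the bell parameters frozen, each rule's linear consequent enters
    the prediction linearly, so the training-RMSE-optimal consequents given
    a rule placement are a weighted least-squares solve per rule.  Used to
    seed atoms at sensible consequents; the joint search over everything
    stays with the optimiser.
    """
    n, m = X.shape
    k = a.shape[0]
    z = np.abs((X[:, None, :] - c[None]) / a[None])
    mu = 1.0 / (1.0 + z ** (2.0 * b[None]))
    w = mu.prod(axis=2)
    wbar = w / np.maximum(w.sum(axis=1, keepdims=True), 1e-12)
    design = np.column_stack([np.ones(n), X])
    p0 = np.zeros(k)
    p = np.zeros((k, m))
    for j in range(k):
        sw = np.sqrt(wbar[:, j] + 1e-9)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
        p0[j] = coef[0]
        p[j] = coef[1:]
    return p0, p


def _rule_placement(X, y, cfg, rng, lo, hi) -> np.ndarray:
    """One random rule placement with conditionally optimal consequents."""
    m, k = cfg.n_features, cfg.n_rules
    fmin, fmax = X.min(axis=0), X.max(axis=0)
    frange = np.maximum(fmax - fmin, 1e-6)
    a = rng.uniform(0.1, 0.8, (k, m)) * frange[None, :]
    b = np.full((k, m), 2.0)
    c = fmin[None, :] + rng.random((k, m)) * frange[None, :]
    p0, p = conditional_consequents(X, y, a, b, c)
    vec = pack(AnfisParameters(a=a, b=b, c=c, p0=p0, p=p))
    return np.clip(vec, lo, hi)


def _polish(objective, u, d, maxfun):
    from scipy.optimize import minimize

    res = minimize(
        objective,
        u,
        method="L-BFGS-B",
        bounds=[(0.0, 1.0)] * d,
        options=dict(maxfun=int(maxfun), ftol=1e-14, gtol=1e-12),
    )
    return np.clip(np.asarray(res.x, float), 0.0, 1.0), float(res.fun)


def fit_asoanfis_arrays(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    anfis_cfg: AnfisConfig | None = None,
    n_atoms: int = 30,
    n_iterations: int = 200,
    seed: int | None = None,
    mode: str = "adaptive",
    stop_threshold: float | None = None,
    polish: str = "deep",
    n_hops: int = 20,
    polish_maxfun: int = 4000,
    objective: str = "val",
) -> tuple[AnfisParameters, list[float]]:
    """Tune every ANFIS parameter by minimising the validation RMSE.

    The search runs in the unit box, mapped affinely onto the physical
    bounds from :func:`anfis_search_bounds`.  The atom population is seeded
    with the fuzzy-clustering warm start plus random rule placements whose
    consequents are conditionally optimal (weighted least squares on the
    training rows); the atom search then explores the joint space.

    The validation-RMSE landscape has narrow, curved valleys that
    population moves alone cannot descend, so the search is memetic:

    * ``polish="deep"`` (default) — every initial atom is refined with a
      bounded quasi-Newton descent, the incumbent is re-polished
      periodically during the search (Lamarckian reinjection), and a final
      iterated-local-search phase hops around the incumbent;
    * ``polish="light"`` — a single final polish of the incumbent;
    * ``polish="none"`` — the bare population search (cheapest; used by
      budgeted wrapper fitnesses).

    Returns the best parameters and the per-iteration best-RMSE curve
    (monotone non-increasing; polish improvements fold into it).
    """
    X_train = np.asarray(X_train, float)
    y_train = np.asarray(y_train, float)
    X_val = np.asarray(X_val, float)
    y_val = np.asarray(y_val, float)
    if X_train.size == 0 or X_val.size == 0:
        raise ValueError("train and validation parts must both be nonempty")
    if anfis_cfg is None:
        anfis_cfg = AnfisConfig(n_features=X_train.shape[1])
    if X_train.shape[1] != anfis_cfg.n_features:
        raise ValueError("X has wrong number of features for the ANFIS config")
    if polish not in ("deep", "light", "none"):
        raise ValueError("polish must be 'deep', 'light' or 'none'")
    if objective not in ("val", "train"):
        raise ValueError("objective must be 'val' or 'train'")

    lo, hi = anfis_search_bounds(X_train, y_train, anfis_cfg)
    span = hi - lo
    m, k = anfis_cfg.n_features, anfis_cfg.n_rules
    d = anfis_cfg.n_params

    X_obj, y_obj = (X_val, y_val) if objective == "val" else (X_train, y_train)

    def _loss(u: np.ndarray) -> float:
        params = unpack(lo + u * span, m, k)
        return rmse(predict_batch(X_obj, params, anfis_cfg), y_obj)

    rng = np.random.default_rng(seed)
    warm = init_from_clustering(X_train, y_train, anfis_cfg, seed=seed)
    seeds = [(np.clip(pack(warm), lo, hi) - lo) / span]
    for _ in range(n_atoms - 1):
        seeds.append((_rule_placement(X_train, y_train, anfis_cfg, rng, lo, hi) - lo) / span)
    init = np.array(seeds)

    if polish == "deep":
        for i in range(init.shape[0]):
            init[i], _ = _polish(_loss, init[i], d, maxfun=3000)

    cfg = AsoConfig(
        n_atoms=n_atoms,
        n_dims=d,
        n_iterations=n_iterations,
        seed=seed,
        mode=mode,
        stop_threshold=stop_threshold,
    )
    polish_every = max(1, n_iterations // 12) if polish == "deep" else None
    best_u, best_f, history = _memetic_optimize(
        _loss, cfg, init, polish_every=polish_every
    )

    if polish == "light":
        u, f = _polish(_loss, best_u, d, maxfun=polish_maxfun)
        if f < best_f:
            best_u, best_f = u, f
            history[-1] = best_f
    elif polish == "deep" and (stop_threshold is None or best_f > stop_threshold):
        for _ in range(n_hops):
            sig = 10.0 ** rng.uniform(-1.7, -0.4)
            cand = np.clip(best_u + sig * rng.standard_normal(d), 0.0, 1.0)
            u, f = _polish(_loss, cand, d, maxfun=8000)
            if f < best_f:
                best_u, best_f = u, f
        history[-1] = min(history[-1], best_f)

    return unpack(lo + best_u * span, m, k), history


def _memetic_optimize(objective, cfg: AsoConfig, init, polish_every=None):
    """ASO run with optional periodic polish of the incumbent."""
    lo, hi = cfg.bounds_arrays()
    rng = np.random.default_rng(cfg.seed)
    positions = lo + rng.random((cfg.n_atoms, cfg.n_dims)) * (hi - lo)
    seeded = np.atleast_2d(np.asarray(init, float))
    positions[: seeded.shape[0]] = np.clip(seeded, lo, hi)

    counter = [0]
    fits = _evaluate(objective, positions, lo, hi, rng, counter)
    ibest = int(np.argmin(fits))
    state = AsoState(
        iteration=0,
        positions=positions,
        velocities=np.zeros_like(positions),
        fitnesses=fits,
        best_position=positions[ibest].copy(),
        best_fitness=float(fits[ibest]),
        rng=rng,
        n_evaluations=counter[0],
    )
    for t in range(cfg.n_iterations):
        if cfg.stop_threshold is not None and state.best_fitness <= cfg.stop_threshold:
            break
        step(state, objective, cfg)
        if polish_every and (t + 1) % polish_every == 0:
            u, f = _polish(objective, state.best_position, cfg.n_dims, maxfun=2500)
            if f < state.best_fitness:
                state.best_fitness = f
                state.best_position = u
                worst = int(np.argmax(state.fitnesses))
                state.positions[worst] = u  # Lamarckian reinjection
                state.fitnesses[worst] = f
                state.history[-1] = f
    return state.best_position, state.best_fitness, state.history


def fit_asoanfis(
    table,
    split,
    anfis_cfg: AnfisConfig | None = None,
    target_column: str = "agb",
    feature_columns: list[str] | None = None,
    **kwargs,
) -> tuple[AnfisParameters, list[float]]:
    """Table-level wrapper: fit on a feature table and a hold-out split."""
    feats = feature_columns or [c for c in table.columns if c != target_column]
    X = table[feats].to_numpy(float)
    y = table[target_column].to_numpy(float)
    if anfis_cfg is None:
        anfis_cfg = AnfisConfig(n_features=len(feats))
    tr, va = np.asarray(split.train_idx), np.asarray(split.val_idx)
    if tr.size == 0 or va.size == 0:
        raise ValueError("split has an empty train or validation part")
    return fit_asoanfis_arrays(
        X[tr], y[tr], X[va], y[va], anfis_cfg=anfis_cfg, **kwargs
    )
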