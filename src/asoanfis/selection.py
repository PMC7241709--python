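"""Feature selection: ReliefF ranking, correlation ranking, CFS, GA wrapper.

Four strategies over a table of predictor columns and a continuous target:

* ``relief_rank`` — regression ReliefF (RReliefF) weights from k-nearest
  neighbour contrasts; higher weight = more relevant.
* ``correlation_rank`` — ranking by absolute Pearson correlation with the
  target.
* ``cfs_select`` — correlation-based feature subset selection: best-first
  search maximising the merit  k r_cf / sqrt(k + k (k-1) r_ff).
* ``ga_select`` — a binary genetic algorithm over feature masks whose
  fitness is the validation RMSE of a budgeted ASO-ANFIS fitted on the
  training rows (fitting on the scoring rows would reward spurious
  capacity); fitness values are memoised per mask so no mask is ever
  evaluated twice.

``incremental_screen`` implements the stopping rule used with the rankers:
add features in rank order until validation performance stops improving.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anfis import AnfisConfig, param_count, predict_batch, rmse
from .aso import fit_asoanfis_arrays
from .evaluation import HoldoutSplit, split_holdout

__all__ = [
    "FeatureMask",
    "SelectionResult",
    "relief_rank",
    "correlation_rank",
    "cfs_merit",
    "cfs_select",
    "ga_select",
    "incremental_screen",
    "make_budgeted_fitness",
]


@dataclass
class SelectionResult:
    method: str
    selected: list[str]  # ordered selected feature names
    mask: np.ndarray  # binary vector over the full feature list
    score_trace: list  # method-specific trace (e.g. best RMSE per generation)
    n_rules: int = 5
    budget_exhausted: bool = False

    def __post_init__(self) -> None:
        if len(self.selected) == 0:
            raise ValueError("a selection result must keep at least one feature")

    @property
    def anfis_dimensionality(self) -> int:
        """Search-space dimension of an ANFIS built on the selected subset."""
        return param_count(len(self.selected), self.n_rules)


FeatureMask = np.ndarray  # binary vector, 1 = selected


def _xy(table: pd.DataFrame, target_column: str, feature_columns=None):
    feats = list(feature_columns) if feature_columns else [
        c for c in table.columns if c != target_column
    ]
    X = table[feats].to_numpy(float)
    y = table[target_column].to_numpy(float)
    return X, y, feats


# ---------------------------------------------------------------------------
# ReliefF (regression variant)


def relief_rank(
    table: pd.DataFrame,
    target_column: str = "agb",
    feature_columns: list[str] | None = None,
    n_neighbors: int = 10,
    n_samples: int | None = None,
    seed: int | None = 0,
) -> pd.Series:
    """RReliefF attribute weights for a continuous target, sorted descending.

    For each probed instance and its k nearest neighbours (normalised
    feature space, Manhattan distance) the algorithm accumulates how often a
    feature's value differs together with the target.  The weight of
    attribute A is

        W[A] = P(dA | dy) - P(dA | same y)
             = NdCdA / NdC - (NdA - NdCdA) / (m - NdC)

    with all "probabilities" replaced by accumulated normalised differences.
    By default every row is probed (deterministic exhaustive variant);
    ``n_samples`` subsamples probes reproducibly under ``seed``.
    """
    X, y, feats = _xy(table, target_column, feature_columns)
    n, p = X.shape
    if n < 2:
        raise ValueError("ReliefF needs at least two rows")
    frange = np.maximum(X.max(axis=0) - X.min(axis=0), 1e-12)
    yrange = max(y.max() - y.min(), 1e-12)
    Xn = (X - X.min(axis=0)) / frange

    if n_samples is None or n_samples >= n:
        probes = np.arange(n)
    else:
        probes = np.sort(np.random.default_rng(seed).choice(n, n_samples, replace=False))
    k = min(n_neighbors, n - 1)

    ndc = 0.0
    nda = np.zeros(p)
    ndcda = np.zeros(p)
    total = 0.0
    for i in probes:
        dist = np.abs(Xn - Xn[i]).sum(axis=1)
        dist[i] = np.inf
        nbrs = np.argpartition(dist, k - 1)[:k]
        # rank-exponential neighbour weights, nearer neighbours count more
        order = nbrs[np.argsort(dist[nbrs], kind="stable")]
        w = np.exp(-np.arange(k) / max(k / 3.0, 1.0))
        w /= w.sum()
        dy = np.abs(y[order] - y[i]) / yrange
        da = np.abs(Xn[order] - Xn[i])  # (k, p)
        ndc += float(w @ dy)
        nda += w @ da
        ndcda += (w * dy) @ da
        total += 1.0
    ndc = max(ndc, 1e-12)
    weights = ndcda / ndc - (nda - ndcda) / max(total - ndc, 1e-12)
    return pd.Series(weights, index=feats).sort_values(ascending=False)


def correlation_rank(
    table: pd.DataFrame,
    target_column: str = "agb",
    feature_columns: list[str] | None = None,
) -> pd.Series:
    """Features ranked by |Pearson r| with the target (zero-variance -> 0)."""
    X, y, feats = _xy(table, target_column, feature_columns)
    out = np.zeros(len(feats))
    ys = y - y.mean()
    ynorm = np.sqrt((ys**2).sum())
    for i in range(X.shape[1]):
        xs = X[:, i] - X[:, i].mean()
        xnorm = np.sqrt((xs**2).sum())
        if xnorm < 1e-12 or ynorm < 1e-12:
            out[i] = 0.0
        else:
            out[i] = abs(float(xs @ ys) / (xnorm * ynorm))
    return pd.Series(out, index=feats).sort_values(ascending=False)


# ---------------------------------------------------------------------------
# CFS


def cfs_merit(subset: list[int], rcf: np.ndarray, rff: np.ndarray) -> float:
    """CFS merit of a subset: k r_cf / sqrt(k + k (k-1) r_ff)."""
    k = len(subset)
    if k == 0:
        return 0.0
    mean_cf = rcf[subset].mean()
    if k == 1:
        mean_ff = 0.0
    else:
        idx = np.array(subset)
        sub = rff[np.ix_(idx, idx)]
        mean_ff = sub[np.triu_indices(k, 1)].mean()
    return k * mean_cf / np.sqrt(k + k * (k - 1) * mean_ff)


def cfs_select(
    table: pd.DataFrame,
    target_column: str = "agb",
    feature_columns: list[str] | None = None,
    patience: int = 5,
) -> SelectionResult:
    """Correlation-based feature subset selection via forward best-first search.

    Expands the best open subset by one feature at a time, keeping the
    overall best merit; stops after ``patience`` consecutive expansions with
    no improvement.  Guarded to return at least the single best-correlated
    feature on all-noise tables.
    """
    X, y, feats = _xy(table, target_column, feature_columns)
    p = X.shape[1]
    corr = np.corrcoef(np.column_stack([X, y]), rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    rcf = np.abs(corr[:p, p])
    rff = np.abs(corr[:p, :p])

    best_subset: list[int] = [int(np.argmax(rcf))]
    best_merit = cfs_merit(best_subset, rcf, rff)
    frontier = [(best_merit, best_subset)]
    trace = [best_merit]
    stale = 0
    visited = {tuple(best_subset)}
    while frontier and stale <= patience:
        frontier.sort(key=lambda t: t[0])
        merit, subset = frontier.pop()
        improved = False
        for j in range(p):
            if j in subset:
                continue
            cand = sorted(subset + [j])
            key = tuple(cand)
            if key in visited:
                continue
            visited.add(key)
            m = cfs_merit(cand, rcf, rff)
            frontier.append((m, cand))
            if m > best_merit + 1e-12:
                best_merit, best_subset = m, cand
                improved = True
        trace.append(best_merit)
        stale = 0 if improved else stale + 1
    mask = np.zeros(p, dtype=int)
    mask[best_subset] = 1
    return SelectionResult(
        method="cfs",
        selected=[feats[j] for j in best_subset],
        mask=mask,
        score_trace=trace,
    )


# ---------------------------------------------------------------------------
# GA wrapper


def make_budgeted_fitness(
    table: pd.DataFrame,
    target_column: str = "agb",
    feature_columns: list[str] | None = None,
    anfis_rules: int = 2,
    n_atoms: int = 8,
    n_iterations: int = 10,
    polish: str = "light",
    polish_maxfun: int = 800,
    split: HoldoutSplit | None = None,
    seed: int = 0,
):
    """Budgeted wrapper fitness: mask -> validation RMSE of an ASO-ANFIS.

    The budgeted model is tuned against the training rows and scored on the
    held-out validation rows, so masks carrying uninformative features pay
    their overfitting cost.  Deterministic per mask: the fit seed is derived
    from the base seed and the mask bits, so repeated queries — by the GA or
    by an exhaustive enumeration — score identically.  Results are memoised;
    the returned callable exposes ``cache`` and ``n_evaluations``.
    """
    X, y, feats = _xy(table, target_column, feature_columns)
    if split is None:
        split = split_holdout(len(y), 0.7, seed)
    tr, va = split.train_idx, split.val_idx
    cache: dict[tuple, float] = {}

    def fitness(mask) -> float:
        key = tuple(int(b) for b in mask)
        if sum(key) == 0:
            return float("inf")
        if key not in cache:
            cols = [i for i, b in enumerate(key) if b]
            mask_seed = (seed * 1_000_003 + int("".join(map(str, key)), 2)) % (2**31 - 1)
            params, _ = fit_asoanfis_arrays(
                X[np.ix_(tr, cols)],
                y[tr],
                X[np.ix_(va, cols)],
                y[va],
                anfis_cfg=AnfisConfig(n_features=len(cols), n_rules=anfis_rules),
                n_atoms=n_atoms,
                n_iterations=n_iterations,
                polish=polish,
                polish_maxfun=polish_maxfun,
                objective="train",
                seed=mask_seed,
            )
            cache[key] = rmse(predict_batch(X[np.ix_(va, cols)], params), y[va])
            fitness.n_evaluations += 1
        return cache[key]

    fitness.cache = cache
    fitness.n_evaluations = 0
    fitness.feature_names = feats
    return fitness


@dataclass
class GaConfig:
    population: int = 20
    generations: int = 30
    crossover_rate: float = 0.8
    mutation_rate: float | None = None  # default 1/n_features
    tournament: int = 3
    elitism: int = 2
    local_search: bool = True  # single-bit-flip descent from the GA best
    max_evaluations: int | None = None


def ga_select(
    table: pd.DataFrame,
    target_column: str = "agb",
    feature_columns: list[str] | None = None,
    ga_cfg: GaConfig | None = None,
    fitness=None,
    seed: int = 0,
    **fitness_kwargs,
) -> SelectionResult:
    """Binary GA over feature masks minimising the wrapper fitness.

    Tournament selection, single-point crossover, bit-flip mutation and
    elitism over 0/1 chromosomes of length n_features.  A custom ``fitness``
    callable (e.g. from :func:`make_budgeted_fitness`) may be supplied;
    otherwise one is built from ``fitness_kwargs``.  After the GA, an
    optional steepest-descent pass over single bit flips polishes the best
    mask (memoised, so it costs at most n_features extra evaluations per
    step).  If ``max_evaluations`` is exhausted the best-so-far mask is
    returned with ``budget_exhausted=True``.
    """
    cfg = ga_cfg or GaConfig()
    if fitness is None:
        fitness = make_budgeted_fitness(
            table, target_column, feature_columns, seed=seed, **fitness_kwargs
        )
    feats = fitness.feature_names
    L = len(feats)
    pmut = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / L
    rng = np.random.default_rng(seed)

    def budget_left() -> bool:
        return cfg.max_evaluations is None or fitness.n_evaluations < cfg.max_evaluations

    pop = (rng.random((cfg.population, L)) < 0.5).astype(int)
    for row in pop:  # guard: no empty chromosomes
        if row.sum() == 0:
            row[rng.integers(L)] = 1
    fits = np.array([fitness(ind) for ind in pop])
    best_idx = int(np.argmin(fits))
    best_mask, best_fit = pop[best_idx].copy(), float(fits[best_idx])
    trace = [best_fit]
    exhausted = False

    for _ in range(cfg.generations):
        if not budget_left():
            exhausted = True
            break
        order = np.argsort(fits)
        nxt = [pop[i].copy() for i in order[: cfg.elitism]]
        while len(nxt) < cfg.population:
            duel = rng.integers(0, cfg.population, cfg.tournament)
            p1 = pop[duel[np.argmin(fits[duel])]].copy()
            duel = rng.integers(0, cfg.population, cfg.tournament)
            p2 = pop[duel[np.argmin(fits[duel])]].copy()
            if rng.random() < cfg.crossover_rate and L > 1:
                cut = int(rng.integers(1, L))
                c1 = np.concatenate([p1[:cut], p2[cut:]])
                c2 = np.concatenate([p2[:cut], p1[cut:]])
            else:
                c1, c2 = p1, p2
            for child in (c1, c2):
                flip = rng.random(L) < pmut
                child[flip] = 1 - child[flip]
                if child.sum() == 0:
                    child[rng.integers(L)] = 1
                nxt.append(child)
        pop = np.array(nxt[: cfg.population])
        fits = np.array([fitness(ind) for ind in pop])
        gi = int(np.argmin(fits))
        if fits[gi] < best_fit:
            best_fit, best_mask = float(fits[gi]), pop[gi].copy()
        trace.append(best_fit)

    if cfg.local_search and budget_left():
        improved = True
        while improved and budget_left():
            improved = False
            flips = [(j,) for j in range(L)]
            if L <= 16:  # pair flips are affordable only for short chromosomes
                flips += [(i, j) for i in range(L) for j in range(i + 1, L)]
            for idx in flips:
                cand = best_mask.copy()
                for j in idx:
                    cand[j] = 1 - cand[j]
                if cand.sum() == 0:
                    continue
                f = fitness(cand)
                if f < best_fit - 1e-15:
                    best_fit, best_mask = f, cand
                    improved = True
            trace.append(best_fit)

    if cfg.max_evaluations is not None and fitness.n_evaluations >= cfg.max_evaluations:
        exhausted = True
        warnings.warn("GA wrapper budget exhausted; returning best-so-far mask")

    return SelectionResult(
        method="ga",
        selected=[feats[j] for j in range(L) if best_mask[j]],
        mask=best_mask,
        score_trace=trace,
        budget_exhausted=exhausted,
    )


# ---------------------------------------------------------------------------
# Incremental screen


def incremental_screen(
    ranked_features: list[str],
    fit_score,
    patience: int = 2,
) -> list[str]:
    """Grow a prefix of the ranking until validation performance stops improving.

    ``fit_score(features)`` must return a validation loss (lower = better).
    Stops after ``patience`` consecutive non-improving additions and returns
    the best prefix seen.
    """
    best_prefix = ranked_features[:1]
    best_score = fit_score(best_prefix)
    stale = 0
    for stop in range(2, len(ranked_features) + 1):
        prefix = ranked_features[:stop]
        score = fit_score(prefix)
        if score < best_score - 1e-15:
            best_score, best_prefix = score, prefix
            stale = 0
        else:
            stale += 1
            if stale > patience:
                break
    return list(best_prefix)
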