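"""Takagi-Sugeno adaptive neuro-fuzzy inference system (forward model).

The model carries ``k`` fuzzy rules over ``m`` inputs.  Rule ``j`` holds one
generalized-bell membership function per input,

    mu_ji(x_i) = 1 / (1 + |(x_i - c_ji) / a_ji| ** (2 * b_ji)),

a firing strength ``w_j = prod_i mu_ji(x_i)``, and a first-order linear
consequent ``g_j(x) = p0_j + sum_i p_ji x_i``.  The prediction is the
normalised-weight combination ``P(x) = sum_j wbar_j g_j(x)`` with
``wbar_j = w_j / sum_j w_j``.  All tunable parameters — the bell triples
(a, b, c) and the consequents — live in one flat vector of length
``m*k*3 + (m+1)*k`` so a population optimiser can move them together.

Packing order (documented contract): all widths ``a`` rule-major
(a[0,0..m-1], a[1,0..m-1], ...), then all shapes ``b``, then all centres
``c``, then per rule the consequent block ``[p0_j, p_j1 .. p_jm]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AnfisConfig",
    "AnfisParameters",
    "param_count",
    "membership",
    "rule_strengths",
    "normalize_weights",
    "predict",
    "predict_batch",
    "rmse",
    "pack",
    "unpack",
    "init_from_clustering",
    "fuzzy_c_means",
]


@dataclass(frozen=True)
class AnfisConfig:
    n_features: int  # m
    n_rules: int = 5  # k, number of clusters = rules
    weight_eps: float = 1e-12  # guard for vanishing rule-strength sums

    def __post_init__(self) -> None:
        if self.n_features < 1 or self.n_rules < 1:
            raise ValueError("need n_features >= 1 and n_rules >= 1")

    @property
    def n_params(self) -> int:
        return param_count(self.n_features, self.n_rules)


def param_count(m: int, k: int) -> int:
    """Number of tunable parameters: m*k*3 bell parameters + (m+1)*k consequents."""
    if m < 1 or k < 1:
        raise ValueError("m and k must be positive")
    return m * k * 3 + (m + 1) * k


@dataclass
class AnfisParameters:
    """Structured view of the flat parameter vector."""

    a: np.ndarray  # (k, m) bell widths, > 0
    b: np.ndarray  # (k, m) bell shapes, > 0
    c: np.ndarray  # (k, m) bell centres
    p0: np.ndarray  # (k,) consequent intercepts
    p: np.ndarray  # (k, m) consequent slopes

    def __post_init__(self) -> None:
        k, m = self.a.shape
        for name in ("b", "c", "p"):
            if getattr(self, name).shape != (k, m):
                raise ValueError(f"parameter block {name} has wrong shape")
        if self.p0.shape != (k,):
            raise ValueError("p0 has wrong shape")
        if np.any(self.a <= 0) or np.any(self.b <= 0):
            raise ValueError("bell widths a and shapes b must be strictly positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.a.shape  # (k, m)

    def to_vector(self) -> np.ndarray:
        return pack(self)

    def to_json(self) -> str:
        k, m = self.shape
        return json.dumps(
            {
                "config": {"n_features": m, "n_rules": k},
                "packing_order": "a(rule-major), b, c, consequents [p0_j, p_j*]",
                "parameter_vector": pack(self).tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "AnfisParameters":
        payload = json.loads(text)
        cfg = payload["config"]
        return unpack(
            np.asarray(payload["parameter_vector"], dtype=float),
            cfg["n_features"],
            cfg["n_rules"],
        )


def pack(params: AnfisParameters) -> np.ndarray:
    k, m = params.shape
    cons = np.concatenate([params.p0[:, None], params.p], axis=1)  # (k, m+1)
    return np.concatenate(
        [params.a.ravel(), params.b.ravel(), params.c.ravel(), cons.ravel()]
    )


def unpack(vector: np.ndarray, m: int, k: int) -> AnfisParameters:
    vector = np.asarray(vector, dtype=float)
    expected = param_count(m, k)
    if vector.shape != (expected,):
        raise ValueError(
            f"parameter vector has length {vector.size}, expected {expected} "
            f"(= m*k*3 + (m+1)*k with m={m}, k={k})"
        )
    km = k * m
    a = vector[:km].reshape(k, m)
    b = vector[km : 2 * km].reshape(k, m)
    c = vector[2 * km : 3 * km].reshape(k, m)
    cons = vector[3 * km :].reshape(k, m + 1)
    return AnfisParameters(a=a, b=b, c=c, p0=cons[:, 0], p=cons[:, 1:])


# ---------------------------------------------------------------------------
# Forward model


def membership(x, a, b, c):
    """Generalized bell membership value in (0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("bell parameters a and b must be strictly positive")
    z = np.abs((np.asarray(x, dtype=float) - c) / a)
    return 1.0 / (1.0 + z ** (2.0 * b))


def rule_strengths(x: np.ndarray, params: AnfisParameters) -> np.ndarray:
    """Firing strength of each rule: product of memberships across features."""
    x = np.asarray(x, dtype=float)
    mu = membership(x[None, :], params.a, params.b, params.c)  # (k, m)
    return mu.prod(axis=1)


def normalize_weights(w: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Normalise firing strengths to sum 1; uniform fallback if all vanish."""
    w = np.asarray(w, dtype=float)
    total = w.sum()
    if total < eps:
        return np.full(w.shape, 1.0 / w.size)
    return w / total


def predict(x: np.ndarray, params: AnfisParameters, cfg: AnfisConfig | None = None) -> float:
    """Model output for one input vector (convex combination of rule outputs)."""
    return float(predict_batch(np.asarray(x, dtype=float)[None, :], params, cfg)[0])


def predict_batch(
    X: np.ndarray, params: AnfisParameters, cfg: AnfisConfig | None = None
) -> np.ndarray:
    """Vectorised forward pass over the rows of ``X`` (n, m)."""
    X = np.asarray(X, dtype=float)
    k, m = params.shape
    if X.ndim != 2 or X.shape[1] != m:
        raise ValueError(f"X must be (n, {m})")
    eps = cfg.weight_eps if cfg is not None else 1e-12
    z = np.abs((X[:, None, :] - params.c[None]) / params.a[None])
    mu = 1.0 / (1.0 + z ** (2.0 * params.b[None]))  # (n, k, m)
    w = mu.prod(axis=2)  # (n, k)
    total = w.sum(axis=1, keepdims=True)
    wbar = np.where(total < eps, 1.0 / k, w / np.maximum(total, eps))
    g = params.p0[None, :] + X @ params.p.T  # (n, k)
    return (wbar * g).sum(axis=1)


def rmse(pred: np.ndarray, obs: np.ndarray) -> float:
    """Root mean square error (radical applied)."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError("pred and obs must be nonempty and the same length")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


# ---------------------------------------------------------------------------
# Clustering-based initialisation


def fuzzy_c_means(
    X: np.ndarray,
    k: int,
    fuzzifier: float = 2.0,
    max_iter: int = 150,
    tol: float = 1e-6,
    seed: int | None = 0,
):
    """Plain fuzzy c-means; returns (centres (k, m), memberships (n, k))."""
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if k > n:
        raise ValueError(f"cannot form {k} clusters from {n} rows")
    rng = np.random.default_rng(seed)
    U = rng.dirichlet(np.ones(k), size=n)  # (n, k)
    centres = np.zeros((k, m))
    power = 2.0 / (fuzzifier - 1.0)
    for _ in range(max_iter):
        Um = U**fuzzifier
        centres = (Um.T @ X) / np.maximum(Um.sum(axis=0)[:, None], 1e-12)
        d2 = ((X[:, None, :] - centres[None]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-power / 2.0)
        U_new = inv / inv.sum(axis=1, keepdims=True)
        if np.max(np.abs(U_new - U)) < tol:
            U = U_new
            break
        U = U_new
    return centres, U


def init_from_clustering(
    X: np.ndarray,
    y: np.ndarray,
    cfg: AnfisConfig,
    seed: int | None = 0,
    width_floor: float = 1e-3,
    init_shape: float = 2.0,
) -> AnfisParameters:
    """Seed ANFIS parameters from a fuzzy clustering of the training rows.

    Bell centres come from the cluster centres, widths from the
    membership-weighted per-cluster dispersion (floored), shapes start at
    ``init_shape``, and each rule's consequent is a membership-weighted least
    squares fit on the rows it claims (global least squares as fallback for
    starved clusters).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    k = cfg.n_rules
    if n < k:
        raise ValueError(f"need at least k={k} training rows, got {n}")

    centres, U = fuzzy_c_means(X, k, seed=seed)
    Um = U**2.0
    var = np.einsum("nk,nkm->km", Um, (X[:, None, :] - centres[None]) ** 2)
    var /= np.maximum(Um.sum(axis=0)[:, None], 1e-12)
    a = np.maximum(np.sqrt(var), width_floor)
    b = np.full((k, m), float(init_shape))

    design = np.column_stack([np.ones(n), X])
    global_coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    p0 = np.zeros(k)
    p = np.zeros((k, m))
    for j in range(k):
        wj = U[:, j]
        sw = np.sqrt(wj)
        if wj.sum() < 1e-8 or np.count_nonzero(wj > 1e-3) <= m:
            coef = global_coef
        else:
            coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
        p0[j] = coef[0]
        p[j] = coef[1:]
    return AnfisParameters(a=a, b=b, c=centres, p0=p0, p=p)
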