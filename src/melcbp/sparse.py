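"""Multi-region joint sparse learning for grid-feature selection.

Each facial grid cell i contributes a design matrix ``X_i`` (s samples x d
per-cell feature values) and learns its own coefficient block ``W_i``
(d x c, one column per class) against a shared one-hot label matrix ``Y``.
Stacking the blocks side by side gives ``W`` (d x beta*c), and the fit
minimizes

    sum_i ||X_i W_i - Y||_F^2  +  theta1 ||W||_F^2
        +  delta * sum_{u<v} (||m_u - m_v||^2 + eps)^(-1)
        +  theta2 ||W||_{2,1}

where ``m_u`` is the class-u mean of the weighted features (the per-sample
concatenation over grids of ``X_i W_i`` rows) and ``||W||_{2,1}`` is the
sum of row norms.  The l2,1 penalty zeroes whole rows of W, i.e. discards
the same per-cell feature across *all* grids; the inverse-distance penalty
pushes class centers apart in the weighted feature space.

The composite objective (smooth + row-separable nonsmooth) is solved by an
accelerated proximal gradient method with backtracking line search and a
monotone safeguard, so the recorded objective trace never increases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MultiGridDesign",
    "SparseModel",
    "SolverError",
    "encode_labels",
    "class_means",
    "objective",
    "smooth_objective",
    "smooth_gradient",
    "prox_l21",
    "l21_norm",
    "ridge_solution",
    "apg_solve",
    "select_and_weight",
    "save_model",
    "load_model",
]

DEFAULT_EPS = 1e-8


class SolverError(RuntimeError):
    """The optimizer produced a non-finite objective."""


def encode_labels(labels: np.ndarray, c: int) -> np.ndarray:
    """One-hot encode integer labels in {1..c} into an (s, c) matrix."""
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 1 or labels.max() > c:
        raise ValueError(f"labels must lie in 1..{c}, got range [{labels.min()}, {labels.max()}]")
    y = np.zeros((labels.size, c))
    y[np.arange(labels.size), labels - 1] = 1.0
    return y


@dataclass
class MultiGridDesign:
    """Training design: per-grid feature matrices plus labels.

    ``X`` is a list of beta matrices, all (s, d); ``labels`` are 1-based
    class indices.
    """

    X: list[np.ndarray]
    labels: np.ndarray
    n_classes: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.X) < 1:
            raise ValueError("need at least one grid")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        shapes = {x.shape for x in self.X}
        if len(shapes) != 1:
            raise ValueError(f"all grids must share (s, d), got {sorted(shapes)}")
        s, _ = self.X[0].shape
        if self.labels.shape != (s,):
            raise ValueError("labels length must match sample count")
        self.Y = encode_labels(self.labels, self.n_classes)
        # (beta, s, d) stack used by the vectorized objective/gradient
        self._stack = np.ascontiguousarray(np.stack(self.X))

    @property
    def n_grids(self) -> int:
        return len(self.X)

    @property
    def n_samples(self) -> int:
        return self.X[0].shape[0]

    @property
    def dim(self) -> int:
        return self.X[0].shape[1]


def _as_blocks(W: np.ndarray, design: MultiGridDesign) -> np.ndarray:
    """View W (d, beta*c) as (d, beta, c) so W[:, i, :] is grid block i."""
    return W.reshape(design.dim, design.n_grids, design.n_classes)


def _predictions(W: np.ndarray, design: MultiGridDesign) -> np.ndarray:
    """Per-grid fitted values X_i W_i, shape (beta, s, c)."""
    return np.einsum("isd,dic->isc", design._stack, _as_blocks(W, design))


def weighted_features(W: np.ndarray, design: MultiGridDesign) -> np.ndarray:
    """Per-sample weighted feature: concat over grids of X_i W_i rows, (s, beta*c)."""
    preds = _predictions(W, design)  # (beta, s, c)
    return preds.transpose(1, 0, 2).reshape(design.n_samples, -1)


def class_means(W: np.ndarray, design: MultiGridDesign) -> np.ndarray:
    """Class centers m_u of the weighted features, shape (c, beta*c)."""
    feats = weighted_features(W, design)
    means = np.empty((design.n_classes, feats.shape[1]))
    for u in range(1, design.n_classes + 1):
        mask = design.labels == u
        if not mask.any():
            raise ValueError(f"class {u} has no samples")
        means[u - 1] = feats[mask].mean(axis=0)
    return means


def l21_norm(W: np.ndarray) -> float:
    """Sum of row-wise l2 norms."""
    return float(np.linalg.norm(W, axis=1).sum())


def _interclass_penalty(means: np.ndarray, eps: float) -> float:
    c = means.shape[0]
    total = 0.0
    for u in range(c):
        for v in range(u + 1, c):
            d2 = float(np.sum((means[u] - means[v]) ** 2))
            total += 1.0 / (d2 + eps)
    return total


def smooth_objective(
    W: np.ndarray,
    design: MultiGridDesign,
    theta1: float,
    delta: float,
    eps: float = DEFAULT_EPS,
) -> float:
    """The differentiable part: data fit + ridge + interclass penalty."""
    preds = _predictions(W, design)
    fit = float(np.sum((preds - design.Y[None]) ** 2))
    ridge = theta1 * float(np.sum(W**2))
    inter = 0.0
    if delta != 0.0:
        inter = delta * _interclass_penalty(class_means(W, design), eps)
    return fit + ridge + inter


def objective(
    W: np.ndarray,
    design: MultiGridDesign,
    theta1: float,
    theta2: float,
    delta: float,
    eps: float = DEFAULT_EPS,
) -> float:
    """Full objective value at W."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    return smooth_objective(W, design, theta1, delta, eps) + theta2 * l21_norm(W)


def smooth_gradient(
    W: np.ndarray,
    design: MultiGridDesign,
    theta1: float,
    delta: float,
    eps: float = DEFAULT_EPS,
) -> np.ndarray:
    """Analytic gradient of the smooth part, shape (d, beta*c)."""
    Wb = _as_blocks(W, design)
    preds = np.einsum("isd,dic->isc", design._stack, Wb)
    resid = preds - design.Y[None]  # (beta, s, c)
    grad = 2.0 * np.einsum("isd,isc->dic", design._stack, resid)
    grad += 2.0 * theta1 * Wb

    if delta != 0.0:
        means = class_means(W, design)  # (c, beta*c)
        c = design.n_classes
        # dh/dm_u for h = delta * sum_{u<v} 1/(||m_u-m_v||^2 + eps)
        A = np.zeros_like(means)
        for u in range(c):
            for v in range(u + 1, c):
                diff = means[u] - means[v]
                coef = -2.0 * delta / (float(diff @ diff) + eps) ** 2
                A[u] += coef * diff
                A[v] -= coef * diff
        # route through m_u = mean of weighted features of class u
        M = np.zeros((design.n_samples, design.n_grids * c))
        for u in range(1, c + 1):
            mask = design.labels == u
            M[mask] = A[u - 1] / mask.sum()
        Mb = M.reshape(design.n_samples, design.n_grids, c)
        grad += np.einsum("isd,sic->dic", design._stack, Mb)

    return grad.reshape(W.shape)


def prox_l21(E: np.ndarray, lam: float) -> np.ndarray:
    """Row-wise shrinkage: argmin_W ||W - E||_F^2 + lam * ||W||_{2,1}.

    Each row e_r is scaled by max(0, 1 - lam / (2 ||e_r||)); rows with norm
    at most lam/2 (and all-zero rows) become zero.
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    if lam == 0:
        return E.copy()
    norms = np.linalg.norm(E, axis=1)
    scale = np.zeros_like(norms)
    nz = norms > 0
    scale[nz] = np.maximum(0.0, 1.0 - lam / (2.0 * norms[nz]))
    return E * scale[:, None]


def ridge_solution(design: MultiGridDesign, theta1: float) -> np.ndarray:
    """Closed-form per-grid minimizer of ||X_i W_i - Y||^2 + theta1 ||W_i||^2."""
    d = design.dim
    blocks = []
    eye = np.eye(d)
    for X in design.X:
        blocks.append(np.linalg.solve(X.T @ X + theta1 * eye, X.T @ design.Y))
    return np.concatenate(blocks, axis=1)


@dataclass
class SparseModel:
    """Fitted multi-region sparse model."""

    W: np.ndarray = field(repr=False)
    theta1: float
    theta2: float
    delta: float
    eps: float
    n_grids: int
    n_classes: int
    row_weights: np.ndarray = field(repr=False)
    selected_rows: np.ndarray = field(repr=False)
    objective_trace: list[float] = field(repr=False)
    n_iter: int = 0
    converged: bool = False

    def grid_block(self, i: int) -> np.ndarray:
        """Coefficient block W_i of grid i, shape (d, c)."""
        c = self.n_classes
        return self.W[:, i * c : (i + 1) * c]

    def grid_norms(self) -> np.ndarray:
        """Frobenius norm of each grid's block — its importance score."""
        return np.array([np.linalg.norm(self.grid_block(i)) for i in range(self.n_grids)])


def _spectral_step_estimate(design: MultiGridDesign, theta1: float) -> float:
    # curvature of the least-squares + ridge part; backtracking covers the rest
    top = 0.0
    for X in design.X:
        s = np.linalg.svd(X, compute_uv=False)[0]
        top = max(top, float(s) ** 2)
    return 2.0 * top + 2.0 * theta1


def apg_solve(
    design: MultiGridDesign,
    theta1: float = 0.1,
    theta2: float = 0.1,
    delta: float = 0.1,
    eps: float = DEFAULT_EPS,
    max_iter: int = 200,
    tol: float = 1e-5,
    init: str = "ridge",
    tau: float = 1e-6,
    seed: int | None = None,
) -> SparseModel:
    """Fit the model by accelerated proximal gradient.

    Iterates gradient steps on the smooth terms at the momentum search
    point, row-wise shrinkage for the l2,1 penalty, and FISTA momentum
    phi_k = 2/(k+2).  The step 1/rho is found by halving (doubling rho)
    until the quadratic majorization of the smooth part holds.  A monotone
    safeguard keeps the best iterate so the objective trace is
    non-increasing.  Stops when the relative objective change drops below
    ``tol`` or after ``max_iter`` iterations.

    ``init`` is "ridge" (per-grid closed form, avoids the degenerate
    all-equal-means point at W = 0), "zeros", or "random" (seeded).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    shape = (design.dim, design.n_grids * design.n_classes)
    if init == "ridge":
        W = ridge_solution(design, theta1)
    elif init == "zeros":
        W = np.zeros(shape)
    elif init == "random":
        W = np.random.default_rng(seed).standard_normal(shape) * 0.01
    else:
        raise ValueError(f"unknown init {init!r}")

    def f(M: np.ndarray) -> float:
        return smooth_objective(M, design, theta1, delta, eps)

    def full(M: np.ndarray) -> float:
        return f(M) + theta2 * l21_norm(M)

    rho = _spectral_step_estimate(design, theta1)
    Q = W.copy()
    W_prev = W.copy()
    trace = [full(W)]
    converged = False

    for k in range(max_iter):
        gQ = smooth_gradient(Q, design, theta1, delta, eps)
        fQ = f(Q)
        if not np.isfinite(fQ):
            raise SolverError(f"non-finite objective at iteration {k}")
        for _ in range(60):
            E = Q - gQ / rho
            cand = prox_l21(E, theta2 / rho)
            diff = cand - Q
            quad = fQ + float(np.vdot(gQ, diff)) + 0.5 * rho * float(np.sum(diff**2))
            if f(cand) <= quad + 1e-10 * max(1.0, abs(quad)):
                break
            rho *= 2.0
        obj_cand = full(cand)
        if not np.isfinite(obj_cand):
            raise SolverError(f"non-finite objective at iteration {k}")

        # monotone safeguard: keep the better of candidate and current W
        accepted = obj_cand <= trace[-1]
        if accepted:
            W_new, obj_new = cand, obj_cand
        else:
            W_new, obj_new = W, trace[-1]

        phi_k = 2.0 / (k + 2)
        phi_k1 = 2.0 / (k + 3)
        Q = cand + ((1.0 - phi_k) / phi_k) * phi_k1 * (cand - W_prev)
        W_prev = cand
        W = W_new
        trace.append(obj_new)
        # convergence is only judged on accepted (descending) steps
        if tol > 0 and accepted and abs(trace[-2] - trace[-1]) <= tol * max(1.0, abs(trace[-2])):
            converged = True
            break

    row_weights = np.linalg.norm(W, axis=1)
    selected = np.flatnonzero(row_weights > tau)
    return SparseModel(
        W=W,
        theta1=theta1,
        theta2=theta2,
        delta=delta,
        eps=eps,
        n_grids=design.n_grids,
        n_classes=design.n_classes,
        row_weights=row_weights,
        selected_rows=selected,
        objective_trace=trace,
        n_iter=len(trace) - 1,
        converged=converged,
    )


def select_and_weight(
    model: SparseModel, X: list[np.ndarray], tau: float = 1e-6
) -> np.ndarray:
    """Weight features by row norms and keep selected rows, concatenated
    over grids: output is (s, n_grids * n_selected).

    Raises if no row survives the threshold (lower theta2 to keep more).
    """
    if len(X) != model.n_grids:
        raise ValueError(f"expected {model.n_grids} grids, got {len(X)}")
    d = model.row_weights.size
    for x in X:
        if x.shape[1] != d:
            raise ValueError(f"grid matrices must have {d} columns, got {x.shape[1]}")
    selected = np.flatnonzero(model.row_weights > tau)
    if selected.size == 0:
        raise ValueError(
            "no features selected (all row weights below tau); lower theta2 or tau"
        )
    w = model.row_weights[selected]
    return np.concatenate([x[:, selected] * w[None, :] for x in X], axis=1)


def save_model(model: SparseModel, prefix: str) -> None:
    """Serialize a model to ``<prefix>.json`` + ``<prefix>.npz``."""
    import json
    from pathlib import Path

    meta = {
        "theta1": model.theta1,
        "theta2": model.theta2,
        "delta": model.delta,
        "eps": model.eps,
        "n_grids": model.n_grids,
        "n_classes": model.n_classes,
        "n_iter": model.n_iter,
        "converged": model.converged,
        "objective_trace": list(map(float, model.objective_trace)),
    }
    Path(prefix + ".json").write_text(json.dumps(meta, indent=2))
    np.savez(
        prefix + ".npz",
        W=model.W,
        row_weights=model.row_weights,
        selected_rows=model.selected_rows,
    )


def load_model(prefix: str) -> SparseModel:
    import json
    from pathlib import Path

    meta = json.loads(Path(prefix + ".json").read_text())
    arrays = np.load(prefix + ".npz")
    return SparseModel(
        W=arrays["W"],
        row_weights=arrays["row_weights"],
        selected_rows=arrays["selected_rows"],
        theta1=meta["theta1"],
        theta2=meta["theta2"],
        delta=meta["delta"],
        eps=meta["eps"],
        n_grids=meta["n_grids"],
        n_classes=meta["n_classes"],
        objective_trace=meta["objective_trace"],
        n_iter=meta["n_iter"],
        converged=meta["converged"],
    )
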