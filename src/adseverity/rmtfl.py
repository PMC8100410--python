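"""Robust multitask feature learning (rMTFL).

Given m regression tasks {(X_i, y_i)} sharing d features, the weight
matrix W = [w_1 ... w_m] is decomposed as W = P + Q and estimated by

    min_{P,Q}  sum_i (1 / (m n_i)) || X_i^T (p_i + q_i) - y_i ||^2
               + lambda1 * ||P||_{1,2}  +  lambda2 * ||Q^T||_{1,2}

where ||M||_{1,2} sums the Euclidean norms of rows.  The row-group
penalty on P makes P row-sparse — its nonzero rows are the features
shared across tasks — while the row-group penalty on Q^T (i.e. columns
of Q) makes Q column-sparse, absorbing whole outlier tasks whose
weights deviate from the shared pattern.

The problem is solved by monotone proximal gradient descent (ISTA with
backtracking): a joint gradient step on the smooth loss in (P, Q)
followed by group soft-thresholding of P's rows and Q's columns.  The
objective trace is non-increasing by construction.

Feature relevance is scored by the row norms of P; outlier tasks are
the columns of Q with non-negligible norm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "TaskDataset",
    "RmtflModel",
    "SolverConfig",
    "normalize_features",
    "objective",
    "prox_group",
    "fit",
    "tune_lambdas",
    "feature_scores",
    "outlier_tasks",
    "select_features",
    "save_task_dataset",
    "load_task_dataset",
]


@dataclass(frozen=True)
class TaskDataset:
    """m regression tasks: X_i is d x n_i (features by samples), y_i length n_i."""

    tasks: tuple[tuple[np.ndarray, np.ndarray], ...]

    def __init__(self, tasks: Sequence[tuple[np.ndarray, np.ndarray]]):
        if not tasks:
            raise ValueError("TaskDataset needs at least one task")
        checked = []
        d = None
        for i, (X, y) in enumerate(tasks):
            X = np.asarray(X, dtype=float)
            y = np.asarray(y, dtype=float).ravel()
            if X.ndim != 2:
                raise ValueError(f"task {i}: X must be 2-D (features x samples)")
            if d is None:
                d = X.shape[0]
            elif X.shape[0] != d:
                raise ValueError(f"task {i}: feature count {X.shape[0]} != {d}")
            if X.shape[1] != y.size or y.size < 1:
                raise ValueError(f"task {i}: X has {X.shape[1]} samples, y has {y.size}")
            if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
                raise ValueError(f"task {i}: non-finite entries")
            checked.append((X, y))
        object.__setattr__(self, "tasks", tuple(checked))

    @property
    def d(self) -> int:
        return self.tasks[0][0].shape[0]

    @property
    def m(self) -> int:
        return len(self.tasks)

    @property
    def n_per_task(self) -> tuple[int, ...]:
        return tuple(X.shape[1] for X, _ in self.tasks)


@dataclass(frozen=True)
class RmtflModel:
    """Fitted decomposition W = P + Q with its regularization weights."""

    P: np.ndarray
    Q: np.ndarray
    lambda1: float
    lambda2: float
    objective_trace: np.ndarray

    @property
    def W(self) -> np.ndarray:
        return self.P + self.Q


@dataclass(frozen=True)
class SolverConfig:
    max_iters: int = 1000
    tolerance: float = 1e-9
    step_shrink: float = 0.5
    init_step: float = 1.0
    init: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if not 0 < self.step_shrink < 1:
            raise ValueError("step_shrink must lie in (0, 1)")


def normalize_features(data: TaskDataset, return_zero_rows: bool = False):
    """Scale each feature row of each X_i to unit Euclidean norm.

    All-zero rows are left untouched; their (task, feature) indices are
    returned when ``return_zero_rows`` is set.
    """
    new_tasks = []
    zero_rows: list[tuple[int, int]] = []
    for i, (X, y) in enumerate(data.tasks):
        norms = np.linalg.norm(X, axis=1)
        zeros = np.flatnonzero(norms == 0)
        zero_rows.extend((i, int(j)) for j in zeros)
        safe = np.where(norms == 0, 1.0, norms)
        new_tasks.append((X / safe[:, None], y))
    out = TaskDataset(new_tasks)
    return (out, zero_rows) if return_zero_rows else out


def _loss(P: np.ndarray, Q: np.ndarray, data: TaskDataset) -> float:
    W = P + Q
    m = data.m
    total = 0.0
    for i, (X, y) in enumerate(data.tasks):
        r = X.T @ W[:, i] - y
        total += float(r @ r) / (m * y.size)
    return total


def _loss_gradient(P: np.ndarray, Q: np.ndarray, data: TaskDataset) -> np.ndarray:
    """Gradient of the smooth loss w.r.t. W (identical for P and Q)."""
    W = P + Q
    m = data.m
    G = np.empty_like(W)
    for i, (X, y) in enumerate(data.tasks):
        G[:, i] = (2.0 / (m * y.size)) * (X @ (X.T @ W[:, i] - y))
    return G


def objective(model: RmtflModel, data: TaskDataset) -> float:
    """Penalized objective: scaled squared loss + lambda1 ||P||_{1,2} + lambda2 ||Q^T||_{1,2}."""
    P, Q = model.P, model.Q
    if P.shape != (data.d, data.m) or Q.shape != (data.d, data.m):
        raise ValueError(
            f"model shape {P.shape} does not match data (d={data.d}, m={data.m})")
    return _loss(P, Q, data) \
        + model.lambda1 * float(np.linalg.norm(P, axis=1).sum()) \
        + model.lambda2 * float(np.linalg.norm(Q, axis=0).sum())


def prox_group(M: np.ndarray, t: float, axis: Literal["rows", "columns"]) -> np.ndarray:
    """Group soft-thresholding: each group g -> g * max(0, 1 - t/||g||_2).

    This is the proximal operator of t * (sum of group Euclidean norms);
    groups are rows or columns of M.  Zero groups stay zero.
    """
    if t < 0:
        raise ValueError("threshold must be nonnegative")
    if axis not in ("rows", "columns"):
        raise ValueError(f"axis must be 'rows' or 'columns', got {axis!r}")
    M = np.asarray(M, dtype=float)
    ax = 1 if axis == "rows" else 0
    norms = np.linalg.norm(M, axis=ax)
    scale = np.where(norms > 0, np.maximum(0.0, 1.0 - t / np.where(norms == 0, 1.0, norms)), 0.0)
    return M * (scale[:, None] if axis == "rows" else scale[None, :])


def fit(data: TaskDataset, lambda1: float, lambda2: float,
        config: SolverConfig | None = None) -> RmtflModel:
    """Monotone proximal gradient (backtracking ISTA) on the rMTFL objective.

    Both blocks share the smooth-loss gradient; after the gradient step,
    P's rows and Q's columns are group-soft-thresholded with step*lambda.
    Backtracking enforces the standard sufficient-decrease condition, so
    the returned ``objective_trace`` is non-increasing.  Iteration stops
    when the relative objective change drops below the tolerance.
    """
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("lambda1 and lambda2 must be nonnegative")
    if config is None:
        config = SolverConfig()
    d, m = data.d, data.m
    if config.init is not None:
        P, Q = (np.array(config.init[0], float), np.array(config.init[1], float))
    else:
        P, Q = np.zeros((d, m)), np.zeros((d, m))

    def penalty(P_, Q_):
        return lambda1 * np.linalg.norm(P_, axis=1).sum() \
            + lambda2 * np.linalg.norm(Q_, axis=0).sum()

    f_cur = _loss(P, Q, data)
    obj_cur = f_cur + penalty(P, Q)
    trace = [obj_cur]
    step = config.init_step
    for _ in range(config.max_iters):
        G = _loss_gradient(P, Q, data)
        while True:
            P_new = prox_group(P - step * G, step * lambda1, "rows")
            Q_new = prox_group(Q - step * G, step * lambda2, "columns")
            dP, dQ = P_new - P, Q_new - Q
            f_new = _loss(P_new, Q_new, data)
            quad = f_cur + float(np.sum(G * dP)) + float(np.sum(G * dQ)) \
                + (float(np.sum(dP * dP)) + float(np.sum(dQ * dQ))) / (2.0 * step)
            if f_new <= quad + 1e-12:
                break
            step *= config.step_shrink
            if step < 1e-18:
                raise RuntimeError(
                    "rMTFL solver failure: backtracking exhausted; trace="
                    + np.array2string(np.asarray(trace[-5:])))
        P, Q, f_cur = P_new, Q_new, f_new
        obj_new = f_new + penalty(P, Q)
        rel_change = abs(obj_cur - obj_new) / max(abs(obj_cur), 1.0)
        obj_cur = obj_new
        trace.append(obj_cur)
        step /= config.step_shrink  # try a larger step next iteration
        if rel_change < config.tolerance:
            break
    return RmtflModel(P, Q, float(lambda1), float(lambda2), np.asarray(trace))


def tune_lambdas(data: TaskDataset, lambda1_grid: Sequence[float],
                 lambda2_grid: Sequence[float], val_fraction: float = 0.2,
                 seed: int = 0, config: SolverConfig | None = None,
                 parsimony_tol: float = 0.0) -> tuple[float, float, dict]:
    """Grid search (lambda1, lambda2) by task-wise hold-out validation MSE.

    Within each task a ``val_fraction`` of samples is held out and the
    mean held-out squared error is scored for every grid point.  The
    best-MSE point wins; a positive ``parsimony_tol`` instead prefers,
    among points within that relative MSE slack of the best, the
    largest (lambda2, lambda1) in that priority (a one-standard-error
    style rule).  Returns the chosen pair and a log of all grid scores.
    """
    rng = np.random.default_rng(seed)
    train_tasks, val_sets = [], []
    for X, y in data.tasks:
        n = y.size
        n_val = max(1, int(round(val_fraction * n)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if tr_idx.size == 0:
            raise ValueError("val_fraction leaves no training samples")
        train_tasks.append((X[:, tr_idx], y[tr_idx]))
        val_sets.append((X[:, val_idx], y[val_idx]))
    train_data = TaskDataset(train_tasks)
    log: dict[tuple[float, float], float] = {}
    for l1 in lambda1_grid:
        for l2 in lambda2_grid:
            model = fit(train_data, l1, l2, config)
            W = model.W
            mse = float(np.mean([np.mean((Xv.T @ W[:, i] - yv) ** 2)
                                 for i, (Xv, yv) in enumerate(val_sets)]))
            log[(float(l1), float(l2))] = mse
    best_mse = min(log.values())
    admissible = [k for k, v in log.items() if v <= best_mse * (1.0 + parsimony_tol)]
    l1, l2 = max(admissible, key=lambda k: (k[1], k[0]))
    return l1, l2, {"scores": log, "chosen": (l1, l2), "val_mse": log[(l1, l2)],
                    "best_mse": best_mse}


def feature_scores(model: RmtflModel) -> np.ndarray:
    """Per-feature relevance: Euclidean norm of each row of P."""
    return np.linalg.norm(model.P, axis=1)


def outlier_tasks(model: RmtflModel, tol: float = 1e-8,
                  relative: bool = False) -> set[int]:
    """Task indices whose Q column norm exceeds ``tol``.

    With ``relative=True`` the threshold is a fraction of each task's
    total weight norm: task i is flagged when ||q_i|| > tol * ||w_i||.
    This is the robust reading when the penalties were chosen by
    held-out prediction error, which leaves small nonzero Q columns on
    every task; an outlier task is one whose weights are *dominated* by
    the outlier component (tol around 0.8 works well in practice).
    """
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    norms = np.linalg.norm(model.Q, axis=0)
    if relative:
        wnorms = np.linalg.norm(model.W, axis=0)
        return {int(i) for i in np.flatnonzero(norms > tol * np.where(wnorms == 0, 1.0, wnorms))}
    return {int(i) for i in np.flatnonzero(norms > tol)}


def select_features(scores: np.ndarray, k: int) -> list[int]:
    """Indices of the k largest scores, descending; ties -> smaller index first."""
    scores = np.asarray(scores, dtype=float)
    if not 1 <= k <= scores.size:
        raise ValueError(f"k must lie in [1, {scores.size}], got {k}")
    order = np.argsort(-scores, kind="stable")
    return [int(j) for j in order[:k]]


def save_task_dataset(data: TaskDataset, directory) -> None:
    """One CSV per task (rows = features, final row = response) plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, (X, y) in enumerate(data.tasks):
        name = f"task_{i:02d}.csv"
        np.savetxt(directory / name, np.vstack([X, y[None, :]]), delimiter=",")
        names.append(name)
    (directory / "manifest.json").write_text(
        json.dumps({"d": data.d, "m": data.m, "tasks": names}, indent=2))


def load_task_dataset(directory) -> TaskDataset:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    tasks = []
    for name in manifest["tasks"]:
        arr = np.loadtxt(directory / name, delimiter=",", ndmin=2)
        tasks.append((arr[:-1, :], arr[-1, :]))
    return TaskDataset(tasks)
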