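"""Supervised two-class genotype classifiers.

Two classifiers, sharing the per-SNP normalized input convention of the
unsupervised arm:

* a three-layer feed-forward neural network — tanh hidden layer (the
  activation must be bounded, smooth and monotonic), linear output layer,
  softmax class probabilities — trained by full-batch gradient descent on the
  mean cross-entropy with a backtracking line search.  Repeated trainings from
  random starting weights form an ensemble, whose spread yields a sigma
  confidence band on the hold-out accuracy and whose averaged outputs give a
  per-individual membership probability.  ``hidden_nodes = 0`` degenerates to
  a direct linear softmax map (convex), which is the relevant comparison when
  asking whether the signal a network finds is purely linear.

* a linear soft-margin SVM, ``min 1/2 ||w||^2 + C sum hinge``, solved by
  deterministic dual coordinate descent with a fixed sample ordering (the
  bias is an augmented, regularised feature).  The solver is exact enough to
  match a brute-force QP on small problems and, being deterministic, always
  returns the same model for the same input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkParams",
    "TrainConfig",
    "EnsembleResult",
    "LinearSVMModel",
    "ann_forward",
    "ann_predict_proba",
    "ann_train",
    "ann_ensemble",
    "svm_train",
    "svm_predict",
    "svm_decision",
]


# ---------------------------------------------------------------------------
# Neural network
# ---------------------------------------------------------------------------

@dataclass
class NetworkParams:
    """Weights and biases of the three-layer network.

    With ``hidden > 0``: ``w1`` (n_inputs x hidden), ``b1`` (hidden,),
    ``w2`` (hidden x 2), ``b2`` (2,).  With ``hidden == 0`` the map is direct:
    ``w2`` (n_inputs x 2), ``b2`` (2,); ``w1``/``b1`` are None.
    """

    n_inputs: int
    hidden: int
    w1: np.ndarray | None
    b1: np.ndarray | None
    w2: np.ndarray
    b2: np.ndarray

    def check(self) -> None:
        if self.hidden > 0:
            assert self.w1 is not None and self.b1 is not None
            if self.w1.shape != (self.n_inputs, self.hidden):
                raise ValueError("w1 shape mismatch")
            if self.b1.shape != (self.hidden,):
                raise ValueError("b1 shape mismatch")
            if self.w2.shape != (self.hidden, 2):
                raise ValueError("w2 shape mismatch")
        else:
            if self.w2.shape != (self.n_inputs, 2):
                raise ValueError("w2 shape mismatch for a direct linear map")
        if self.b2.shape != (2,):
            raise ValueError("b2 shape mismatch")
        for arr in (self.w1, self.b1, self.w2, self.b2):
            if arr is not None and not np.isfinite(arr).all():
                raise ValueError("non-finite network parameter")


@dataclass
class TrainConfig:
    """Knobs of the gradient trainer and the restart ensemble.

    ``l2`` is a small ridge penalty on weights (not biases) for numerical
    stability of the optimum; ``init_scale`` scales the
    ``Normal(0, init_scale/sqrt(fan_in))`` starting weights.
    """

    hidden_nodes: int = 8
    repetitions: int = 10
    max_iterations: int = 300
    tolerance: float = 1e-7
    init_scale: float = 1.0
    l2: float = 1e-4
    seed: int = 0

    def validate(self) -> None:
        if self.hidden_nodes < 0:
            raise ValueError("hidden_nodes must be >= 0")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.max_iterations < 1 or self.tolerance <= 0 or self.init_scale <= 0:
            raise ValueError("invalid trainer configuration")


def _softmax(o: np.ndarray) -> np.ndarray:
    z = o - o.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def ann_predict_proba(params: NetworkParams, x: np.ndarray) -> np.ndarray:
    """Class-probability matrix (M x 2) for a batch of input rows."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != params.n_inputs:
        raise ValueError(
            f"input dimension {x.shape[1]} != network inputs {params.n_inputs}"
        )
    if params.hidden > 0:
        h = np.tanh(x @ params.w1 + params.b1)
        o = h @ params.w2 + params.b2
    else:
        o = x @ params.w2 + params.b2
    return _softmax(o)


def ann_forward(params: NetworkParams, x: np.ndarray) -> tuple[float, float]:
    """Forward pass for one individual: hidden ``h = tanh(W1 x + b1)``,
    output ``o = W2 h + b2``, probabilities ``softmax(o)``."""
    p = ann_predict_proba(params, np.asarray(x, dtype=float).reshape(1, -1))[0]
    return float(p[0]), float(p[1])


def _init_params(n_inputs: int, hidden: int, scale: float, rng: np.random.Generator) -> NetworkParams:
    if hidden > 0:
        w1 = rng.normal(0.0, scale / np.sqrt(max(n_inputs, 1)), size=(n_inputs, hidden))
        b1 = rng.normal(0.0, 0.1 * scale, size=hidden)
        w2 = rng.normal(0.0, scale / np.sqrt(hidden), size=(hidden, 2))
    else:
        w1 = b1 = None
        w2 = rng.normal(0.0, scale / np.sqrt(max(n_inputs, 1)), size=(n_inputs, 2))
    b2 = rng.normal(0.0, 0.1 * scale, size=2)
    return NetworkParams(n_inputs, hidden, w1, b1, w2, b2)


def _pack(p: NetworkParams) -> np.ndarray:
    parts = [p.w2.ravel(), p.b2]
    if p.hidden > 0:
        parts = [p.w1.ravel(), p.b1] + parts
    return np.concatenate(parts)


def _unpack(theta: np.ndarray, template: NetworkParams) -> NetworkParams:
    n, h = template.n_inputs, template.hidden
    i = 0
    if h > 0:
        w1 = theta[i : i + n * h].reshape(n, h); i += n * h
        b1 = theta[i : i + h]; i += h
        w2 = theta[i : i + h * 2].reshape(h, 2); i += h * 2
    else:
        w1 = b1 = None
        w2 = theta[i : i + n * 2].reshape(n, 2); i += n * 2
    b2 = theta[i : i + 2]
    return NetworkParams(n, h, w1, b1, w2, b2)


def ann_loss_and_grad(
    params: NetworkParams, x: np.ndarray, y: np.ndarray, l2: float = 0.0
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy (+ ridge on weights) and its flat gradient.

    The analytic gradient is standard backpropagation through the linear
    output and tanh hidden layer; it is checked against central finite
    differences in the test suite.
    """
    m = x.shape[0]
    onehot = np.zeros((m, 2))
    onehot[np.arange(m), y] = 1.0
    if params.hidden > 0:
        a1 = x @ params.w1 + params.b1
        h = np.tanh(a1)
        o = h @ params.w2 + params.b2
    else:
        h = x
        o = x @ params.w2 + params.b2
    p = _softmax(o)
    eps = 1e-12
    loss = float(-(onehot * np.log(p + eps)).sum() / m)
    do = (p - onehot) / m
    gw2 = h.T @ do
    gb2 = do.sum(axis=0)
    if params.hidden > 0:
        dh = do @ params.w2.T
        da1 = dh * (1.0 - h**2)
        gw1 = x.T @ da1
        gb1 = da1.sum(axis=0)
        if l2 > 0:
            loss += 0.5 * l2 * (float((params.w1**2).sum()) + float((params.w2**2).sum()))
            gw1 = gw1 + l2 * params.w1
            gw2 = gw2 + l2 * params.w2
        grad = np.concatenate([gw1.ravel(), gb1, gw2.ravel(), gb2])
    else:
        if l2 > 0:
            loss += 0.5 * l2 * float((params.w2**2).sum())
            gw2 = gw2 + l2 * params.w2
        grad = np.concatenate([gw2.ravel(), gb2])
    return loss, grad


class TrainingError(RuntimeError):
    pass


def ann_train(
    train_x: np.ndarray,
    train_labels: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator,
) -> NetworkParams:
    """Train one network by full-batch gradient descent.

    Backtracking (Armijo) line search with a gently growing step keeps the
    loss monotone; iteration stops at ``config.tolerance`` relative loss
    change, a vanishing gradient, or ``config.max_iterations``.  Deterministic
    given the generator state.
    """
    config.validate()
    x = np.asarray(train_x, dtype=float)
    y = np.asarray(train_labels, dtype=int)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("training inputs and labels misaligned")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least one sample of each class")
    params = _init_params(x.shape[1], config.hidden_nodes, config.init_scale, rng)
    theta = _pack(params)
    loss, grad = ann_loss_and_grad(params, x, y, config.l2)
    step = 0.5
    for it in range(config.max_iterations):
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite loss at iteration {it}")
        gnorm2 = float(grad @ grad)
        if gnorm2 < 1e-18:
            break
        accepted = False
        for _ in range(40):
            cand = theta - step * grad
            cand_params = _unpack(cand, params)
            cand_loss, cand_grad = ann_loss_and_grad(cand_params, x, y, config.l2)
            if cand_loss <= loss - 1e-4 * step * gnorm2:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        rel_change = (loss - cand_loss) / max(abs(loss), 1e-12)
        theta, loss, grad, params = cand, cand_loss, cand_grad, cand_params
        step = min(step * 1.25, 1e3)
        if rel_change < config.tolerance:
            break
    final = _unpack(theta, params)
    final.check()
    return final


@dataclass
class EnsembleResult:
    """Hold-out performance of a restart ensemble.

    Accuracies are percentages; ``sigma`` is the sample standard deviation
    over repetitions; ``per_sample_mean_probability`` is each hold-out
    individual's class-1 membership probability averaged over the ensemble.
    """

    per_repetition_accuracy: np.ndarray
    mean_accuracy: float
    sigma: float
    per_sample_mean_probability: np.ndarray
    members: list[NetworkParams] = field(default_factory=list)


def ann_ensemble(
    train_x: np.ndarray,
    train_labels: np.ndarray,
    holdout_x: np.ndarray,
    holdout_labels: np.ndarray,
    config: TrainConfig,
) -> EnsembleResult:
    """Train ``config.repetitions`` networks from distinct random starting
    points and score each on the hold-out set."""
    config.validate()
    seeds = np.random.SeedSequence(config.seed).spawn(config.repetitions)
    accs = np.empty(config.repetitions)
    probs = np.zeros(np.atleast_2d(holdout_x).shape[0])
    members: list[NetworkParams] = []
    y_hold = np.asarray(holdout_labels, dtype=int)
    for r in range(config.repetitions):
        rng = np.random.default_rng(seeds[r])
        params = ann_train(train_x, train_labels, config, rng)
        p1 = ann_predict_proba(params, holdout_x)[:, 1]
        pred = (p1 >= 0.5).astype(int)
        accs[r] = 100.0 * float((pred == y_hold).mean())
        probs += p1
        members.append(params)
    probs /= config.repetitions
    if config.repetitions < 2:
        warnings.warn("single repetition: sigma reported as 0", stacklevel=2)
        sigma = 0.0
    else:
        sigma = float(accs.std(ddof=1))
    return EnsembleResult(
        per_repetition_accuracy=accs,
        mean_accuracy=float(accs.mean()),
        sigma=sigma,
        per_sample_mean_probability=probs,
        members=members,
    )


# ---------------------------------------------------------------------------
# Linear soft-margin SVM
# ---------------------------------------------------------------------------

@dataclass
class LinearSVMModel:
    """Separating hyperplane ``w . x + b`` with soft-margin cost ``C``.

    ``objective_path`` records the dual objective (minimisation form,
    ``1/2 ||w~||^2 - sum alpha``) after each coordinate sweep; it is
    monotonically non-increasing.
    """

    weights: np.ndarray
    bias: float
    cost: float
    n_sweeps: int
    objective_path: np.ndarray

    @property
    def margin_width(self) -> float:
        nrm = float(np.linalg.norm(self.weights))
        return np.inf if nrm == 0 else 2.0 / nrm


class SVMConvergenceError(RuntimeError):
    pass


def svm_train(
    train_x: np.ndarray,
    train_labels: np.ndarray,
    C: float = 1.0,
    tol: float = 1e-3,
    max_sweeps: int = 50000,
) -> LinearSVMModel:
    """Deterministic dual coordinate descent for the linear soft-margin SVM.

    The bias is an augmented constant feature (regularised like the weights),
    which removes the dual equality constraint; each sweep visits samples in
    their fixed input order, so retraining on identical input is bit-identical.
    Convergence is declared when the largest projected-gradient violation in a
    sweep falls below ``tol``.
    """
    if C <= 0:
        raise ValueError("C must be positive")
    x = np.asarray(train_x, dtype=float)
    yy = np.asarray(train_labels, dtype=int)
    if len(np.unique(yy)) < 2:
        raise ValueError("need at least one sample of each class")
    y = np.where(yy == 1, 1.0, -1.0)
    m, d = x.shape
    xa = np.hstack([x, np.ones((m, 1))])
    qii = (xa**2).sum(axis=1)
    alpha = np.zeros(m)
    w = np.zeros(d + 1)
    objectives = []
    last_max_pg = np.inf
    for sweep in range(max_sweeps):
        max_pg = 0.0
        for i in range(m):
            g = y[i] * float(xa[i] @ w) - 1.0
            a = alpha[i]
            if a <= 0.0:
                pg = min(g, 0.0)
            elif a >= C:
                pg = max(g, 0.0)
            else:
                pg = g
            if pg != 0.0:
                max_pg = max(max_pg, abs(pg))
                a_new = min(max(a - g / qii[i], 0.0), C)
                if a_new != a:
                    w += (a_new - a) * y[i] * xa[i]
                    alpha[i] = a_new
        objectives.append(0.5 * float(w @ w) - float(alpha.sum()))
        last_max_pg = max_pg
        if max_pg < tol:
            break
    else:
        raise SVMConvergenceError(
            f"no convergence in {max_sweeps} sweeps; final violation {last_max_pg:.3e}"
        )
    return LinearSVMModel(
        weights=w[:d].copy(),
        bias=float(w[d]),
        cost=C,
        n_sweeps=len(objectives),
        objective_path=np.array(objectives),
    )


def svm_decision(model: LinearSVMModel, x: np.ndarray) -> np.ndarray:
    """Signed decision values ``w . x + b`` for a batch of rows."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.weights.shape[0]:
        raise ValueError(
            f"input dimension {x.shape[1]} != model dimension {model.weights.shape[0]}"
        )
    return x @ model.weights + model.bias


def svm_predict(model: LinearSVMModel, x: np.ndarray) -> tuple[int, float]:
    """Class and signed score for one individual; a point exactly on the
    hyperplane (score 0) is assigned class 1 by convention."""
    score = float(svm_decision(model, np.asarray(x, dtype=float).reshape(1, -1))[0])
    return (1 if score >= 0.0 else 0), score
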