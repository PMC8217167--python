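"""The diagnosis model: a small MLP trained by Levenberg-Marquardt.

The network has one hidden layer of ``n_hidden`` logistic-sigmoid units and
a single linear output unit:

    y = W2 . sigma(W1 x + b1) + b2

Weights are fitted by damped Gauss-Newton (Levenberg-Marquardt) on the
sum-of-squares residual: at each iteration the analytic Jacobian J of the
residual vector is formed by backpropagation and the step solves

    (J^T J + mu I) delta = J^T r .

A step is accepted (and mu shrunk) only if it lowers the loss; otherwise mu
grows and the step is retried, so the recorded loss history is
nonincreasing.  Inputs and the target are min-max scaled onto [-1, 1] by
default so that sigmoid dynamics are not swamped by raw units
(yields are of order 10^3 kg ha^-1).

A network with ~10^2 weights interpolates 60 noisy samples exactly if LM
runs to convergence, and its predictions between training points then
degrade without bound.  Generalization is therefore controlled the way
the classic LM fitting tools do it: a fraction of the training samples is
held out as an early-stopping subset, training halts after ``max_fail``
consecutive iterations without improvement on that subset, and the
weights from the best-stopping iteration are restored.  Set
``early_stop_frac=0`` for pure LM (used for realizable, noiseless fits).

Because the sum-of-squares surface of an MLP is nonconvex, fitting uses a
small multi-start: ``n_restarts`` seeded initializations are trained and
the one with the lowest final training loss is kept.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class MLPConfig:
    n_hidden: int = 10
    max_iter: int = 200
    mu0: float = 1e-3          # initial LM damping
    mu_inc: float = 10.0       # damping growth on a rejected step
    mu_dec: float = 0.1        # damping shrink on an accepted step
    mu_max: float = 1e10       # damping overflow -> stop
    grad_tol: float = 1e-7     # inf-norm of J^T r
    loss_tol: float = 1e-12    # stop when the scaled SSE falls below this
    seed: int = 0
    input_scaling: str = "minmax"    # minmax | zscore | none
    output_scaling: str = "minmax"
    n_restarts: int = 5
    early_stop_frac: float = 0.25    # held-out fraction of training data; 0 = off
    max_fail: int = 6                # consecutive stop-subset failures tolerated
    early_stop_min_n: int = 10       # below this many samples, early stop is off

    def __post_init__(self) -> None:
        if not self.mu_inc > 1:
            raise ValueError("mu_inc must be > 1")
        if not 0 < self.mu_dec < 1:
            raise ValueError("mu_dec must lie in (0, 1)")
        if self.n_hidden < 1 or self.max_iter < 0 or self.n_restarts < 1:
            raise ValueError("n_hidden, max_iter and n_restarts must be positive")
        if self.input_scaling not in ("minmax", "zscore", "none"):
            raise ValueError(f"unknown input_scaling {self.input_scaling!r}")
        if self.output_scaling not in ("minmax", "zscore", "none"):
            raise ValueError(f"unknown output_scaling {self.output_scaling!r}")
        if not 0.0 <= self.early_stop_frac < 1.0:
            raise ValueError("early_stop_frac must lie in [0, 1)")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclasses.dataclass
class _AffineScale:
    """x_scaled = (x - offset) / scale, elementwise."""

    offset: np.ndarray
    scale: np.ndarray

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (x - self.offset) / self.scale

    def invert(self, x: np.ndarray) -> np.ndarray:
        return x * self.scale + self.offset

    @classmethod
    def fit(cls, x: np.ndarray, kind: str) -> "_AffineScale":
        x = np.atleast_2d(x)
        if kind == "none":
            return cls(np.zeros(x.shape[1]), np.ones(x.shape[1]))
        if kind == "zscore":
            sd = x.std(axis=0, ddof=0)
            sd[sd == 0.0] = 1.0
            return cls(x.mean(axis=0), sd)
        # minmax onto [-1, 1]
        lo, hi = x.min(axis=0), x.max(axis=0)
        half = (hi - lo) / 2.0
        half[half == 0.0] = 1.0
        return cls((hi + lo) / 2.0, half)


@dataclasses.dataclass
class DiagnosisModel:
    """Trained (or freshly initialized) MLP plus its scaling and feature recipe."""

    W1: np.ndarray                     # n_hidden x n_inputs
    b1: np.ndarray                     # n_hidden
    W2: np.ndarray                     # n_hidden
    b2: float
    config: MLPConfig
    x_scale: _AffineScale
    y_scale: _AffineScale
    history: list[float] = dataclasses.field(default_factory=list)
    feature_names: Optional[list[str]] = None
    target_name: Optional[str] = None
    recipe: Optional[dict] = None      # feature-extraction recipe (IIMV/IIH)
    chosen_seed: Optional[int] = None
    stop_error: Optional[float] = None  # early-stopping subset SSE at the kept weights

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[1]

    # ---- parameter vector packing (order: W1, b1, W2, b2) ----
    def _get_theta(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(), self.b1, self.W2, [self.b2]])

    def _set_theta(self, theta: np.ndarray) -> None:
        h, d = self.W1.shape
        self.W1 = theta[: h * d].reshape(h, d)
        self.b1 = theta[h * d: h * d + h]
        self.W2 = theta[h * d + h: h * d + 2 * h]
        self.b2 = float(theta[-1])

    def to_json(self, path) -> None:
        payload = {
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "W2": self.W2.tolist(), "b2": self.b2,
            "config": dataclasses.asdict(self.config),
            "x_offset": self.x_scale.offset.tolist(),
            "x_scale": self.x_scale.scale.tolist(),
            "y_offset": self.y_scale.offset.tolist(),
            "y_scale": self.y_scale.scale.tolist(),
            "history": self.history,
            "feature_names": self.feature_names,
            "target_name": self.target_name,
            "recipe": self.recipe,
            "chosen_seed": self.chosen_seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "DiagnosisModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            W1=np.asarray(p["W1"]), b1=np.asarray(p["b1"]),
            W2=np.asarray(p["W2"]), b2=float(p["b2"]),
            config=MLPConfig(**p["config"]),
            x_scale=_AffineScale(np.asarray(p["x_offset"]), np.asarray(p["x_scale"])),
            y_scale=_AffineScale(np.asarray(p["y_offset"]), np.asarray(p["y_scale"])),
            history=list(p["history"]),
            feature_names=p["feature_names"],
            target_name=p["target_name"],
            recipe=p["recipe"],
            chosen_seed=p["chosen_seed"],
        )


def init_weights(
    config: MLPConfig, n_inputs: int, seed: Optional[int] = None
) -> DiagnosisModel:
    """Seeded Nguyen-Widrow-style initialization (scaled uniform weights).

    Hidden rows are drawn uniform on [-1, 1] and rescaled to magnitude
    0.7 * n_hidden^(1/n_inputs); hidden biases spread the active regions
    across the input range.  Deterministic for a given seed.
    """
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    h = config.n_hidden
    W1 = rng.uniform(-1.0, 1.0, size=(h, n_inputs))
    norms = np.linalg.norm(W1, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    beta = 0.7 * h ** (1.0 / n_inputs)
    W1 = beta * W1 / norms
    signs = rng.choice([-1.0, 1.0], size=h)
    b1 = beta * np.linspace(-1.0, 1.0, h) * signs
    W2 = rng.uniform(-0.5, 0.5, size=h)
    b2 = 0.0
    ident = _AffineScale(np.zeros(n_inputs), np.ones(n_inputs))
    return DiagnosisModel(
        W1=W1, b1=b1, W2=W2, b2=b2, config=config,
        x_scale=ident, y_scale=_AffineScale(np.zeros(1), np.ones(1)),
    )


def _net_forward_scaled(model: DiagnosisModel, Xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hidden activations and scaled output for pre-scaled inputs."""
    A = _sigmoid(Xs @ model.W1.T + model.b1)
    return A, A @ model.W2 + model.b2


def forward(model: DiagnosisModel, X: np.ndarray) -> np.ndarray:
    """Network predictions in original target units for raw features X."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if not np.all(np.isfinite(X)):
        raise ValueError("inputs must be finite")
    if X.shape[1] != model.n_inputs:
        raise ValueError(
            f"input has {X.shape[1]} columns but the model expects {model.n_inputs}"
        )
    _, ys = _net_forward_scaled(model, model.x_scale.apply(X))
    return model.y_scale.invert(ys[:, None]).ravel()


def predict(
    model: DiagnosisModel, X: np.ndarray, feature_names: Optional[Sequence[str]] = None
) -> np.ndarray:
    """Alias of :func:`forward` that enforces the stored feature recipe."""
    if feature_names is not None and model.feature_names is not None:
        if list(feature_names) != list(model.feature_names):
            raise ValueError(
                "feature columns do not match the model's recipe:\n"
                f"  expected {model.feature_names}\n  got      {list(feature_names)}"
            )
    return forward(model, X)


def _jacobian_scaled(model: DiagnosisModel, Xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Analytic Jacobian of scaled predictions w.r.t. theta, plus predictions."""
    n, d = Xs.shape
    h = model.config.n_hidden
    A, ys = _net_forward_scaled(model, Xs)
    D = A * (1.0 - A) * model.W2          # n x h : dy/dz_j
    J = np.empty((n, h * d + 2 * h + 1))
    J[:, : h * d] = (D[:, :, None] * Xs[:, None, :]).reshape(n, h * d)
    J[:, h * d: h * d + h] = D
    J[:, h * d + h: h * d + 2 * h] = A
    J[:, -1] = 1.0
    return J, ys


def lm_step(J: np.ndarray, r: np.ndarray, mu: float) -> np.ndarray:
    """Solve (J^T J + mu I) delta = J^T r for one damped Gauss-Newton step."""
    JtJ = J.T @ J
    g = J.T @ r
    A = JtJ + mu * np.eye(JtJ.shape[0])
    c, low = scipy.linalg.cho_factor(A)
    return scipy.linalg.cho_solve((c, low), g)


def train_lm(
    model: DiagnosisModel,
    X: np.ndarray,
    y: np.ndarray,
    config: Optional[MLPConfig] = None,
) -> DiagnosisModel:
    """Fit the network to (X, y) by Levenberg-Marquardt from its current weights.

    Scaling parameters are (re)computed from the training data per the
    config.  The returned model's ``history`` holds the scaled
    sum-of-squares loss at initialization and after every accepted step;
    the sequence is nonincreasing by construction.
    """
    config = config or model.config
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y must have the same number of samples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("training data must be finite")
    if y.std() == 0.0:
        raise ValueError("target has zero variance")
    if X.shape[0] < X.shape[1] + 2:
        logger.warning(
            "training with %d samples for %d inputs; fewer than n_inputs+2",
            X.shape[0], X.shape[1],
        )
    model = dataclasses.replace(model, history=[])
    model.x_scale = _AffineScale.fit(X, config.input_scaling)
    model.y_scale = _AffineScale.fit(y[:, None], config.output_scaling)
    Xs_all = model.x_scale.apply(X)
    ys_all = model.y_scale.apply(y[:, None]).ravel()

    n = Xs_all.shape[0]
    use_stop = config.early_stop_frac > 0.0 and n >= config.early_stop_min_n
    if use_stop:
        rng = np.random.default_rng(config.seed)
        n_stop = max(1, int(round(config.early_stop_frac * n)))
        perm = rng.permutation(n)
        stop_idx, fit_idx = perm[:n_stop], perm[n_stop:]
        Xs, ys_target = Xs_all[fit_idx], ys_all[fit_idx]
        Xstop, ystop = Xs_all[stop_idx], ys_all[stop_idx]
    else:
        Xs, ys_target = Xs_all, ys_all
        Xstop = ystop = None

    def sse(theta: np.ndarray, Xm: np.ndarray, ym: np.ndarray) -> float:
        model._set_theta(theta)
        _, pred = _net_forward_scaled(model, Xm)
        r = pred - ym
        return float(r @ r)

    theta = model._get_theta()
    loss = sse(theta, Xs, ys_target)
    model.history = [loss]
    best_theta, best_stop, n_fail = theta, np.inf, 0
    if use_stop:
        best_stop = sse(theta, Xstop, ystop)
    mu = config.mu0
    for _ in range(config.max_iter):
        if loss < config.loss_tol:
            break
        model._set_theta(theta)
        J, pred = _jacobian_scaled(model, Xs)
        r = pred - ys_target
        if not np.isfinite(r).all():
            raise FloatingPointError("non-finite residuals during LM training")
        if np.max(np.abs(J.T @ r)) < config.grad_tol:
            break
        accepted = False
        while mu <= config.mu_max:
            try:
                delta = lm_step(J, r, mu)
            except np.linalg.LinAlgError:
                mu *= config.mu_inc
                continue
            new_theta = theta - delta
            new_loss = sse(new_theta, Xs, ys_target)
            if np.isfinite(new_loss) and new_loss < loss:
                theta, loss = new_theta, new_loss
                model.history.append(loss)
                mu = max(mu * config.mu_dec, 1e-20)
                accepted = True
                break
            mu *= config.mu_inc
        if not accepted:
            break  # damping overflow: no descent direction left
        if use_stop:
            stop_loss = sse(theta, Xstop, ystop)
            if stop_loss < best_stop:
                best_stop, best_theta, n_fail = stop_loss, theta, 0
            else:
                n_fail += 1
                if n_fail > config.max_fail:
                    break
    if use_stop:
        theta = best_theta
        model.stop_error = float(best_stop)
    model._set_theta(theta)
    return model


def fit(
    X: np.ndarray,
    y: np.ndarray,
    config: Optional[MLPConfig] = None,
    feature_names: Optional[Sequence[str]] = None,
    target_name: Optional[str] = None,
    recipe: Optional[dict] = None,
) -> DiagnosisModel:
    """Multi-start LM fit: best of ``n_restarts`` seeded runs by training loss."""
    config = config or MLPConfig()
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    def score(m: DiagnosisModel) -> float:
        # with early stopping active, restarts compete on stop-subset error
        return m.stop_error if m.stop_error is not None else m.history[-1]

    best = None
    for k in range(config.n_restarts):
        seed = config.seed + k
        m = init_weights(config, X.shape[1], seed=seed)
        # config.seed (not the restart seed) fixes the stop subset, so all
        # restarts are scored on the same held-out samples
        m = train_lm(m, X, y, config)
        m.chosen_seed = seed
        if best is None or score(m) < score(best):
            best = m
    best.feature_names = list(feature_names) if feature_names is not None else None
    best.target_name = target_name
    best.recipe = recipe
    logger.debug(
        "multi-start LM: kept seed %s with loss %.3e", best.chosen_seed, best.history[-1]
    )
    return best
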