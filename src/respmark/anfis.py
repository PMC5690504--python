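"""Sugeno-type adaptive neuro-fuzzy inference system (ANFIS).

The correlation model mapping external-marker displacements to the internal
reference trajectory is a first-order Sugeno fuzzy system:

* one rule per fuzzy cluster, with Gaussian premise membership functions in
  every input dimension (product t-norm across dimensions),
* a linear consequent per rule,
* weighted-average defuzzification:

      w_j(x)   = prod_k exp(-(x_k - c_jk)^2 / (2 sigma_jk^2))
      yhat(x)  = sum_j w_j (a_j^T x + b_j) / sum_j w_j

Premise parameters are initialized from fuzzy c-means (FCM) clusters of the
training inputs and refined by gradient descent; consequents are re-solved
each epoch by linear least squares on the firing-strength-weighted
regressors (the classic hybrid learning scheme).  Everything here is
implemented directly — no fuzzy-logic toolbox is involved.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import DegenerateInputError, InvalidParameterError, SchemaError
from .motion_sim import MotionTrace, SyntheticSession

_SIGMA_FLOOR = 1e-6
_FIRING_FLOOR = 1e-300
MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of FCM initialization and hybrid training."""

    n_rules: int = 3
    fcm_fuzzifier: float = 2.0
    fcm_tol: float = 1e-5
    fcm_max_iter: int = 200
    epochs: int = 50
    premise_learning_rate: float = 0.01
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rules < 1:
            raise InvalidParameterError("n_rules must be >= 1")
        if not (0 < self.train_fraction < 1):
            raise InvalidParameterError("train_fraction must be in (0, 1)")
        if self.fcm_fuzzifier <= 1:
            raise InvalidParameterError("FCM fuzzifier must be > 1")


@dataclass(frozen=True)
class FcmResult:
    """Fitted fuzzy c-means clustering."""

    centers: np.ndarray  # (c, d)
    memberships: np.ndarray  # (n, c), rows sum to 1
    fuzzifier: float
    objective_history: tuple[float, ...]


@dataclass(frozen=True)
class GaussianMF:
    center: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise InvalidParameterError("sigma must be > 0")


@dataclass(frozen=True)
class SugenoRule:
    premise: tuple[GaussianMF, ...]
    consequent: np.ndarray  # (d + 1,): d weights then intercept


@dataclass
class AnfisModel:
    """Rule-base parameters of one ANFIS (one output axis).

    ``centers``/``sigmas`` are (n_rules, d) premise parameters,
    ``consequents`` is (n_rules, d + 1) with the intercept last.
    """

    centers: np.ndarray
    sigmas: np.ndarray
    consequents: np.ndarray
    output_axis: str | None = None
    marker_labels: tuple[str, ...] | None = None
    training_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.sigmas = np.atleast_2d(np.asarray(self.sigmas, dtype=float))
        self.consequents = np.atleast_2d(np.asarray(self.consequents, dtype=float))
        c, d = self.centers.shape
        if self.sigmas.shape != (c, d) or self.consequents.shape != (c, d + 1):
            raise InvalidParameterError("inconsistent rule parameter shapes")
        if c < 1:
            raise InvalidParameterError("model needs >= 1 rule")
        if np.any(self.sigmas <= 0):
            raise InvalidParameterError("all sigmas must be > 0")

    @property
    def n_rules(self) -> int:
        return self.centers.shape[0]

    @property
    def input_dim(self) -> int:
        return self.centers.shape[1]

    @property
    def rules(self) -> list[SugenoRule]:
        return [
            SugenoRule(
                tuple(
                    GaussianMF(float(c), float(s))
                    for c, s in zip(self.centers[j], self.sigmas[j])
                ),
                self.consequents[j].copy(),
            )
            for j in range(self.n_rules)
        ]

    def copy(self) -> "AnfisModel":
        return AnfisModel(
            self.centers.copy(),
            self.sigmas.copy(),
            self.consequents.copy(),
            self.output_axis,
            self.marker_labels,
            list(self.training_history),
        )


# ---------------------------------------------------------------------------
# Fuzzy c-means


def _fcm_objective(x: np.ndarray, u: np.ndarray, v: np.ndarray, m: float) -> float:
    d2 = ((x[:, None, :] - v[None, :, :]) ** 2).sum(axis=2)
    return float(((u**m) * d2).sum())


def fcm_cluster(
    data,
    c: int,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 200,
    seed: int = 0,
) -> FcmResult:
    """Fuzzy c-means clustering with the standard alternating updates.

    Memberships are initialized at random (seeded), then centers and
    memberships are updated alternately until the objective

        J = sum_i sum_j u_ij^m ||x_i - v_j||^2

    changes by less than ``tol`` or ``max_iter`` is reached.  A collapsed
    clustering (coincident centers) triggers a seeded restart, at most 5
    times.
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    if x.ndim != 2:
        raise InvalidParameterError("data must be (n, d)")
    n, d = x.shape
    if c < 1:
        raise InvalidParameterError("c must be >= 1")
    if n <= c:
        raise InvalidParameterError(f"need n > c, got n={n}, c={c}")
    if m <= 1:
        raise InvalidParameterError("fuzzifier m must be > 1")

    scale = float(np.max(np.ptp(x, axis=0), initial=0.0))
    for attempt in range(6):
        rng = np.random.default_rng(seed + attempt)
        u = rng.random((n, c))
        u /= u.sum(axis=1, keepdims=True)
        history: list[float] = []
        prev = np.inf
        for _ in range(max_iter):
            um = u**m
            v = (um.T @ x) / um.sum(axis=0)[:, None]
            d2 = ((x[:, None, :] - v[None, :, :]) ** 2).sum(axis=2)
            # points coinciding with a center get full membership there
            zero = d2 <= 0
            if np.any(zero):
                u = zero.astype(float)
                u /= u.sum(axis=1, keepdims=True)
            else:
                ratio = d2 ** (-1.0 / (m - 1))
                u = ratio / ratio.sum(axis=1, keepdims=True)
            obj = _fcm_objective(x, u, v, m)
            history.append(obj)
            if abs(prev - obj) < tol:
                break
            prev = obj
        collapsed = False
        if c > 1:
            dv = np.sqrt(((v[:, None, :] - v[None, :, :]) ** 2).sum(axis=2))
            np.fill_diagonal(dv, np.inf)
            collapsed = bool(dv.min() < 1e-9 * max(scale, 1.0))
        if not (collapsed or np.any(~np.isfinite(v))):
            return FcmResult(v, u, m, tuple(history))
        warnings.warn(
            f"FCM cluster collapse, restarting (attempt {attempt + 1})",
            RuntimeWarning,
        )
    raise DegenerateInputError("FCM failed to separate clusters after 5 restarts")


# ---------------------------------------------------------------------------
# Model construction and evaluation


def init_from_fcm(fcm: FcmResult, data, targets) -> AnfisModel:
    """Build an initial ANFIS from FCM clusters of the training inputs.

    Rule j's Gaussian premise in dimension k is centred at the cluster
    centre, with sigma equal to the membership-weighted standard deviation
    of that dimension around the centre (floored at 1e-6 with a warning
    for zero-spread dimensions).  Consequents start from one global linear
    least-squares fit shared by all rules.
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    y = np.asarray(targets, dtype=float).ravel()
    if x.shape[0] != y.size:
        raise InvalidParameterError("data and targets lengths differ")
    centers = fcm.centers
    c, d = centers.shape
    um = fcm.memberships**fcm.fuzzifier
    sigmas = np.empty((c, d))
    for j in range(c):
        w = um[:, j]
        var = (w[:, None] * (x - centers[j]) ** 2).sum(axis=0) / w.sum()
        sigmas[j] = np.sqrt(var)
    if np.any(sigmas < _SIGMA_FLOOR):
        warnings.warn(
            "zero-spread premise dimension; sigma floored at 1e-6", RuntimeWarning
        )
        sigmas = np.maximum(sigmas, _SIGMA_FLOOR)
    xa = np.column_stack([x, np.ones(x.shape[0])])
    theta, *_ = np.linalg.lstsq(xa, y, rcond=None)
    consequents = np.tile(theta, (c, 1))
    return AnfisModel(centers, sigmas, consequents)


def _firing(model: AnfisModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalized firing strengths (n, c) and an underflow-fallback mask."""
    z = (x[:, None, :] - model.centers[None, :, :]) / model.sigmas[None, :, :]
    logw = -0.5 * (z**2).sum(axis=2)  # (n, c)
    w = np.exp(logw)
    tot = w.sum(axis=1)
    fallback = tot < _FIRING_FLOOR
    wbar = np.zeros_like(w)
    ok = ~fallback
    wbar[ok] = w[ok] / tot[ok, None]
    if np.any(fallback):
        # far outside every premise: fall back to the nearest rule
        nearest = np.argmax(logw[fallback], axis=1)
        wbar[np.nonzero(fallback)[0], nearest] = 1.0
    return wbar, fallback


def _rule_outputs(model: AnfisModel, x: np.ndarray) -> np.ndarray:
    xa = np.column_stack([x, np.ones(x.shape[0])])
    return xa @ model.consequents.T  # (n, c)


def anfis_predict(model: AnfisModel, X) -> np.ndarray:
    """Vectorized forward pass over an (n, d) input matrix."""
    x = np.atleast_2d(np.asarray(X, dtype=float))
    if x.shape[1] != model.input_dim:
        raise InvalidParameterError(
            f"input dim {x.shape[1]} != model dim {model.input_dim}"
        )
    wbar, fallback = _firing(model, x)
    if np.any(fallback):
        warnings.warn(
            f"{int(fallback.sum())} sample(s) under all premises; "
            "nearest-rule fallback applied",
            RuntimeWarning,
        )
    return (wbar * _rule_outputs(model, x)).sum(axis=1)


def anfis_forward(model: AnfisModel, x) -> float:
    """Forward pass for a single input vector (product firing, weighted average)."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != model.input_dim:
        raise InvalidParameterError(
            f"input length {x.size} != model dim {model.input_dim}"
        )
    return float(anfis_predict(model, x[None, :])[0])


# ---------------------------------------------------------------------------
# Hybrid training


def _rmse_of(model: AnfisModel, x: np.ndarray, y: np.ndarray) -> float:
    r = anfis_predict(model, x) - y
    return float(np.sqrt(np.mean(r**2)))


def _lse_consequents(model: AnfisModel, x: np.ndarray, y: np.ndarray) -> None:
    """Solve all consequents jointly by (possibly ridge-regularized) LSE."""
    n, d = x.shape
    c = model.n_rules
    wbar, _ = _firing(model, x)
    xa = np.column_stack([x, np.ones(n)])
    phi = (wbar[:, :, None] * xa[:, None, :]).reshape(n, c * (d + 1))
    theta, _, rank, _ = np.linalg.lstsq(phi, y, rcond=None)
    if rank < c * (d + 1):
        warnings.warn("singular LSE system; ridge-regularized", RuntimeWarning)
        lam = 1e-8 * float(np.trace(phi.T @ phi)) / (c * (d + 1))
        theta = np.linalg.solve(
            phi.T @ phi + lam * np.eye(c * (d + 1)), phi.T @ y
        )
    model.consequents = theta.reshape(c, d + 1)


def _premise_gradients(
    model: AnfisModel, x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    n = x.shape[0]
    wbar, _ = _firing(model, x)
    f = _rule_outputs(model, x)
    yhat = (wbar * f).sum(axis=1)
    r = yhat - y
    # dE/dparam through w_j: (2/n) sum_i r_i (f_ij - yhat_i) wbar_ij dlogw/dparam
    common = (2.0 / n) * r[:, None] * (f - yhat[:, None]) * wbar  # (n, c)
    diff = x[:, None, :] - model.centers[None, :, :]  # (n, c, d)
    g_c = (common[:, :, None] * diff / model.sigmas[None, :, :] ** 2).sum(axis=0)
    g_s = (common[:, :, None] * diff**2 / model.sigmas[None, :, :] ** 3).sum(axis=0)
    return g_c, g_s


def train_hybrid(
    model: AnfisModel, X, y, config: TrainConfig | None = None
) -> AnfisModel:
    """Hybrid training: LSE consequents + gradient-descent premises.

    Each epoch first re-solves the consequents by least squares on the
    firing-strength-weighted regressors (this step can only lower the
    training RMSE), then takes one gradient step on premise centers and
    sigmas.  A step that raises the RMSE by more than 10% is retried with
    a halved learning rate; the halving persists.  Per-epoch training RMSE
    is appended to ``model.training_history``.
    """
    config = config or TrainConfig()
    x = np.atleast_2d(np.asarray(X, dtype=float))
    yv = np.asarray(y, dtype=float).ravel()
    if x.shape[0] != yv.size:
        raise InvalidParameterError("X and y lengths differ")
    if x.shape[0] < 10 * model.n_rules:
        raise InvalidParameterError("need n >= 10 x n_rules samples")
    model = model.copy()
    lr = config.premise_learning_rate
    for _ in range(config.epochs):
        _lse_consequents(model, x, yv)
        rmse_lse = _rmse_of(model, x, yv)
        if model.n_rules > 1 and lr > 0:
            g_c, g_s = _premise_gradients(model, x, yv)
            saved = (model.centers.copy(), model.sigmas.copy())
            step_lr = lr
            for _retry in range(8):
                model.centers = saved[0] - step_lr * g_c
                model.sigmas = np.maximum(saved[1] - step_lr * g_s, _SIGMA_FLOOR)
                if _rmse_of(model, x, yv) <= 1.1 * rmse_lse:
                    lr = step_lr
                    break
                step_lr *= 0.5
            else:
                model.centers, model.sigmas = saved
                lr = step_lr
        model.training_history.append(_rmse_of(model, x, yv))
    return model


def fit_anfis(
    X,
    y,
    config: TrainConfig | None = None,
    output_axis: str | None = None,
    marker_labels: Sequence[str] | None = None,
) -> AnfisModel:
    """FCM-initialize and hybrid-train one ANFIS on (X, y)."""
    config = config or TrainConfig()
    x = np.atleast_2d(np.asarray(X, dtype=float))
    fcm = fcm_cluster(
        x,
        config.n_rules,
        m=config.fcm_fuzzifier,
        tol=config.fcm_tol,
        max_iter=config.fcm_max_iter,
        seed=config.seed,
    )
    model = init_from_fcm(fcm, x, y)
    model = train_hybrid(model, x, y, config)
    model.output_axis = output_axis
    model.marker_labels = tuple(marker_labels) if marker_labels is not None else None
    return model


def block_split(n: int, train_fraction: float = 0.7) -> tuple[np.ndarray, np.ndarray]:
    """Contiguous train/test index split (first block trains).

    Block-wise rather than random, so serially-correlated breathing samples
    do not leak between the splits.  Deterministic; the two blocks are
    disjoint and cover range(n).
    """
    if not (0 < train_fraction < 1):
        raise InvalidParameterError("train_fraction must be in (0, 1)")
    if n < 2:
        raise InvalidParameterError("need n >= 2 to split")
    k = min(max(int(round(n * train_fraction)), 1), n - 1)
    idx = np.arange(n)
    return idx[:k], idx[k:]


# ---------------------------------------------------------------------------
# Session-level prediction


def session_design_matrix(
    session: SyntheticSession, labels: Sequence[str]
) -> np.ndarray:
    """Stack the (AP, SI) channels of the given markers into an (n, 2m) matrix."""
    labels = list(labels)
    if not labels:
        raise InvalidParameterError("empty marker subset")
    missing = [lb for lb in labels if lb not in session.marker_traces]
    if missing:
        raise SchemaError(f"markers {missing} absent from session")
    cols = []
    for lb in labels:
        tr = session.marker_traces[lb]
        cols.extend([tr.ap, tr.si])
    return np.column_stack(cols)


def predict_setup(
    models: Mapping[str, AnfisModel],
    session: SyntheticSession,
    labels: Sequence[str] | None = None,
) -> MotionTrace:
    """Predict the internal reference trajectory of a session.

    ``models`` maps output axis ('ap', 'si') to a trained ANFIS; all models
    must have been trained on the same marker subset, which must be present
    in the session.  Timestamps are copied from the input session.
    """
    if set(models) != {"ap", "si"}:
        raise InvalidParameterError("models must provide exactly the ap and si axes")
    trained = {m.marker_labels for m in models.values()}
    if len(trained) != 1:
        raise SchemaError("axis models were trained on different marker subsets")
    trained_labels = trained.pop()
    if labels is None:
        labels = trained_labels
    if labels is None or len(list(labels)) == 0:
        raise InvalidParameterError("empty marker subset")
    if trained_labels is not None and tuple(labels) != tuple(trained_labels):
        raise SchemaError(
            f"marker subset {tuple(labels)} != training subset {tuple(trained_labels)}"
        )
    x = session_design_matrix(session, labels)
    ap = anfis_predict(models["ap"], x)
    si = anfis_predict(models["si"], x)
    return MotionTrace(session.timestamps.copy(), ap, si)


# ---------------------------------------------------------------------------
# Serialization


def model_to_dict(model: AnfisModel) -> dict:
    return {
        "format_version": MODEL_FORMAT_VERSION,
        "centers": model.centers.tolist(),
        "sigmas": model.sigmas.tolist(),
        "consequents": model.consequents.tolist(),
        "output_axis": model.output_axis,
        "marker_labels": list(model.marker_labels) if model.marker_labels else None,
        "training_history": list(model.training_history),
    }


def model_from_dict(d: Mapping) -> AnfisModel:
    if d.get("format_version") != MODEL_FORMAT_VERSION:
        raise SchemaError(f"unsupported model format {d.get('format_version')!r}")
    return AnfisModel(
        np.asarray(d["centers"], dtype=float),
        np.asarray(d["sigmas"], dtype=float),
        np.asarray(d["consequents"], dtype=float),
        d.get("output_axis"),
        tuple(d["marker_labels"]) if d.get("marker_labels") else None,
        list(d.get("training_history", [])),
    )


def save_model(model: AnfisModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def load_model(path) -> AnfisModel:
    return model_from_dict(json.loads(Path(path).read_text()))
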