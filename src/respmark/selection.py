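"""Marker scoring and selection via canonical correlation and PCA.

Each candidate marker is scored against the internal reference point once
per breathing session:

* **CCA score** — the first canonical correlation between the marker's
  (AP, SI) channel pair and the reference's (AP, SI) pair, i.e. the
  maximum Pearson correlation achievable between linear combinations of
  the two channel sets.
* **PCA score** — the absolute Pearson correlation between the first
  principal component of the marker's channels and that of the
  reference's channels.

Scores are aggregated across sessions to a mean +/- SD per marker, and
markers are selected by the conjunction *high mean correlation AND low
cross-session variability* (mean >= tau_corr and SD <= tau_sd).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.decomposition import PCA

from .errors import AlignmentError, DegenerateInputError, InvalidParameterError
from .motion_sim import MARKER_LABELS, MotionTrace, SyntheticSession

METHODS = ("cca", "pca")


@dataclass(frozen=True)
class MarkerScore:
    """One marker's score against the reference in one session."""

    label: str
    session_id: str
    method: str
    score: float
    pc1_var_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise InvalidParameterError(f"unknown method {self.method!r}")
        if not (-1e-9 <= self.score <= 1 + 1e-9):
            raise InvalidParameterError(f"score {self.score} outside [0, 1]")
        if (self.pc1_var_fraction is not None) != (self.method == "pca"):
            raise InvalidParameterError("pc1_var_fraction present iff method is pca")


@dataclass(frozen=True)
class AggregatedScore:
    label: str
    method: str
    mean_score: float
    sd_score: float
    n_sessions: int

    def __post_init__(self) -> None:
        if self.sd_score < 0 or self.n_sessions < 1:
            raise InvalidParameterError("sd_score >= 0 and n_sessions >= 1 required")


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds of the selection rule.

    ``tau_corr``: minimum acceptable cross-session mean score (inclusive).
    ``tau_sd``: maximum acceptable cross-session score SD (inclusive).
    ``coverage_threshold``: variance/correlation coverage gate (strict >).
    """

    tau_corr: float = 0.95
    tau_sd: float = 0.25
    coverage_threshold: float = 0.90

    def __post_init__(self) -> None:
        for v in (self.tau_corr, self.tau_sd, self.coverage_threshold):
            if not (0 < v <= 1):
                raise InvalidParameterError("criteria thresholds must be in (0, 1]")


@dataclass(frozen=True)
class SelectionResult:
    method: str
    selected: frozenset[str]
    scores: tuple[AggregatedScore, ...]
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)


def _as_channels(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise InvalidParameterError("series must be 1-D or (n, channels)")
    return x


def cca_first_correlation(x, y, ridge: float = 0.0) -> float:
    """First (largest) canonical correlation between channel sets x and y.

    Computed as the largest singular value of the whitened cross-covariance
    Cxx^{-1/2} Cxy Cyy^{-1/2}; invariant under invertible affine
    transformations of either channel set.  A rank-deficient within-set
    covariance is ridge-regularized (with a warning) rather than failing.

    Parameters
    ----------
    x, y : array-like, shape (n,) or (n, channels)
        The two variable sets, observed on the same n samples.
    ridge : float
        Optional explicit ridge added to both within-set covariances,
        as a fraction of their mean diagonal.
    """
    x, y = _as_channels(x), _as_channels(y)
    if x.shape[0] != y.shape[0]:
        raise AlignmentError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    n = x.shape[0]
    if n < 10 * max(x.shape[1], y.shape[1]):
        raise InvalidParameterError("need n >= 10 x max(channel counts)")
    for name, arr in (("x", x), ("y", y)):
        if np.any(np.ptp(arr, axis=0) == 0):
            raise DegenerateInputError(f"constant channel in {name}")

    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    cxx = xc.T @ xc / (n - 1)
    cyy = yc.T @ yc / (n - 1)
    cxy = xc.T @ yc / (n - 1)

    def _inv_sqrt(c: np.ndarray, name: str) -> np.ndarray:
        lam = ridge * float(np.mean(np.diag(c)))
        w, v = linalg.eigh(c + lam * np.eye(c.shape[0]))
        tiny = 1e-10 * w.max()
        if w.min() < tiny:
            warnings.warn(
                f"rank-deficient covariance of {name}; ridge-regularizing",
                RuntimeWarning,
                stacklevel=3,
            )
            w = np.maximum(w, tiny)
        return v @ np.diag(1.0 / np.sqrt(w)) @ v.T

    m = _inv_sqrt(cxx, "x") @ cxy @ _inv_sqrt(cyy, "y")
    rho = float(linalg.svdvals(m)[0])
    return min(rho, 1.0)


def pca_reduce(series) -> tuple[np.ndarray, float]:
    """Collapse a multichannel series to its first principal component.

    Returns ``(pc1_signal, pc1_var_fraction)`` where the variance fraction
    is lambda_1 / sum(lambda_i).  Channels are mean-centred internally but
    not rescaled (all channels share units of mm).  Sign convention: the
    PC1 signal correlates positively with the channel of largest variance.
    """
    x = _as_channels(series)
    if x.shape[1] < 2:
        raise InvalidParameterError("pca_reduce needs >= 2 channels")
    if x.shape[0] < 10:
        raise InvalidParameterError("pca_reduce needs n >= 10")
    variances = np.var(x, axis=0)
    if np.all(variances == 0):
        raise DegenerateInputError("constant input")
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(x)
    pc1 = scores[:, 0]
    frac = float(pca.explained_variance_ratio_[0])
    dominant = x[:, int(np.argmax(variances))]
    r = np.corrcoef(pc1, dominant)[0, 1] if np.std(pc1) > 0 else 0.0
    if r < 0:
        pc1 = -pc1
    return pc1, frac


def _pearson_abs(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        raise DegenerateInputError("constant signal in correlation")
    return float(abs(np.corrcoef(a, b)[0, 1]))


def pca_score(
    marker: MotionTrace, reference: MotionTrace, label: str = "", session_id: str = ""
) -> MarkerScore:
    """|Pearson r| between the PC1 signals of marker and reference."""
    if marker.n != reference.n or not np.array_equal(
        marker.timestamps, reference.timestamps
    ):
        raise AlignmentError("marker and reference must share timestamps")
    pc1_m, frac = pca_reduce(marker.channels())
    pc1_r, _ = pca_reduce(reference.channels())
    score = min(_pearson_abs(pc1_m, pc1_r), 1.0)
    return MarkerScore(label, session_id, "pca", score, pc1_var_fraction=frac)


def cca_score(
    marker: MotionTrace, reference: MotionTrace, label: str = "", session_id: str = ""
) -> MarkerScore:
    """First canonical correlation between marker and reference channels."""
    if marker.n != reference.n or not np.array_equal(
        marker.timestamps, reference.timestamps
    ):
        raise AlignmentError("marker and reference must share timestamps")
    rho = cca_first_correlation(marker.channels(), reference.channels())
    return MarkerScore(label, session_id, "cca", rho)


def score_all(
    sessions: Sequence[SyntheticSession], method: str
) -> list[MarkerScore]:
    """Score every marker of every session against its reference.

    Returns one MarkerScore per (marker, session), ordered by
    (session, label).
    """
    if method not in METHODS:
        raise InvalidParameterError(f"unknown method {method!r}")
    if len(sessions) < 1:
        raise InvalidParameterError("need >= 1 session")
    scorer = cca_score if method == "cca" else pca_score
    out: list[MarkerScore] = []
    for i, sess in enumerate(sessions):
        if set(sess.marker_traces) != set(MARKER_LABELS):
            raise AlignmentError(f"session {i} has an inconsistent marker set")
        for label in MARKER_LABELS:
            out.append(
                scorer(
                    sess.marker_traces[label],
                    sess.reference_trace,
                    label=label,
                    session_id=str(i),
                )
            )
    return out


def aggregate(scores: Iterable[MarkerScore]) -> list[AggregatedScore]:
    """Cross-session mean and population SD per (label, method)."""
    scores = list(scores)
    if not scores:
        raise InvalidParameterError("no scores to aggregate")
    by_key: dict[tuple[str, str], list[float]] = {}
    for s in scores:
        by_key.setdefault((s.label, s.method), []).append(s.score)
    out = []
    for (label, method), vals in sorted(by_key.items()):
        # summing in sorted order makes the result independent of session order
        arr = np.sort(np.asarray(vals))
        out.append(
            AggregatedScore(label, method, float(arr.mean()), float(arr.std()), arr.size)
        )
    return out


def select_markers(
    agg: Sequence[AggregatedScore], criteria: SelectionCriteria | None = None
) -> SelectionResult:
    """Select markers with mean score >= tau_corr and score SD <= tau_sd.

    Both thresholds are inclusive.  An empty selection is allowed but
    emits a warning.  All aggregated scores must come from one method.
    """
    criteria = criteria or SelectionCriteria()
    methods = {a.method for a in agg}
    if len(methods) != 1:
        raise InvalidParameterError(f"mixed methods in input: {sorted(methods)}")
    selected = frozenset(
        a.label
        for a in agg
        if a.mean_score >= criteria.tau_corr and a.sd_score <= criteria.tau_sd
    )
    if not selected:
        warnings.warn("no marker satisfies the selection criteria", RuntimeWarning)
    return SelectionResult(methods.pop(), selected, tuple(agg), criteria)


def coverage_check(values, threshold: float = 0.90) -> np.ndarray:
    """Data-quality gate: strictly-greater-than comparison per value.

    Used on PC1 variance fractions (PCA) or first canonical correlations
    (CCA): each value must cover *more than* the threshold for the
    mono-dimensional reduction to lose only a small amount of data.
    """
    values = np.asarray(values, dtype=float)
    if np.any((values < 0) | (values > 1)):
        raise InvalidParameterError("coverage values must be in [0, 1]")
    ok = values > threshold
    for v, passed in zip(np.atleast_1d(values), np.atleast_1d(ok)):
        if not passed:
            warnings.warn(
                f"coverage {v:.3f} does not exceed {threshold:.2f}", RuntimeWarning
            )
    return ok


def selection_to_frame(results: Sequence[SelectionResult]) -> pd.DataFrame:
    """Flatten selection results to the scores-CSV schema."""
    rows = []
    for res in results:
        for a in res.scores:
            rows.append(
                {
                    "label": a.label,
                    "method": a.method,
                    "mean_score": a.mean_score,
                    "sd_score": a.sd_score,
                    "n_sessions": a.n_sessions,
                    "selected": int(a.label in res.selected),
                }
            )
    return pd.DataFrame(rows)
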