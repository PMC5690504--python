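"""Setup-accuracy evaluation: RMSE, region importance, mode comparison.

The figure of merit throughout is the root mean square error between the
benchmark internal-reference positions A_i and the model predictions P_i,

    RMSE = sqrt( (1/N) * sum_i (A_i - P_i)^2 )   [mm],

computed on held-out sessions so that a marker subset is judged by how
well a correlation model trained on *other* sessions transfers to it.
A thoracic subregion whose markers yield a low prediction RMSE — and whose
markers are frequently picked by the input-selection algorithms — is an
important (good) marker placement site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .anfis import TrainConfig, fit_anfis, predict_setup, session_design_matrix
from .errors import InvalidParameterError
from .motion_sim import MARKER_LABELS, REGIONS, SyntheticSession
from .selection import (
    SelectionCriteria,
    SelectionResult,
    aggregate,
    score_all,
    select_markers,
)

AXES = ("ap", "si")

#: Canonical evaluation modes; the selected_* subsets are filled at run time.
MODE_NAMES = ("selected_cca", "selected_pca", "all_markers", "upper", "middle", "lower")


@dataclass(frozen=True)
class EvalMode:
    name: str
    marker_subset: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.marker_subset:
            raise InvalidParameterError(f"mode {self.name!r} has no markers")
        unknown = set(self.marker_subset) - set(MARKER_LABELS)
        if unknown:
            raise InvalidParameterError(f"unknown markers {sorted(unknown)}")
        if self.name in REGIONS and set(self.marker_subset) != set(REGIONS[self.name]):
            raise InvalidParameterError(
                f"region mode {self.name} must use markers {REGIONS[self.name]}"
            )
        if self.name == "all_markers" and set(self.marker_subset) != set(MARKER_LABELS):
            raise InvalidParameterError("all_markers mode must use all nine markers")


@dataclass
class EvaluationReport:
    """Per-(mode, axis) RMSE table plus run metadata."""

    rows: pd.DataFrame  # columns: mode, axis, rmse_mm, n_markers, rank
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "EvaluationReport":
        return cls(pd.read_csv(path))


def rmse(actual, predicted) -> float:
    """Root mean square deviation between two equal-length arrays (mm)."""
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if a.size != p.size:
        raise InvalidParameterError(f"length mismatch: {a.size} vs {p.size}")
    if a.size < 1:
        raise InvalidParameterError("need N >= 1")
    return float(np.sqrt(np.mean((a - p) ** 2)))


def _split_sessions(
    sessions: Sequence[SyntheticSession], train_fraction: float
) -> tuple[list[SyntheticSession], list[SyntheticSession]]:
    n = len(sessions)
    if n < 2:
        raise InvalidParameterError("need >= 2 sessions for train/test separation")
    k = min(max(int(np.floor(n * train_fraction)), 1), n - 1)
    return list(sessions[:k]), list(sessions[k:])


def _stack(
    sessions: Sequence[SyntheticSession], labels: Sequence[str]
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    xs, targets = [], {ax: [] for ax in AXES}
    for sess in sessions:
        xs.append(session_design_matrix(sess, labels))
        targets["ap"].append(sess.reference_trace.ap)
        targets["si"].append(sess.reference_trace.si)
    return np.vstack(xs), {ax: np.concatenate(v) for ax, v in targets.items()}


def fit_axis_models(
    sessions: Sequence[SyntheticSession],
    labels: Sequence[str],
    config: TrainConfig | None = None,
):
    """Train one ANFIS per output axis on the pooled sessions."""
    config = config or TrainConfig()
    labels = tuple(labels)
    x, targets = _stack(sessions, labels)
    return {
        ax: fit_anfis(x, targets[ax], config, output_axis=ax, marker_labels=labels)
        for ax in AXES
    }


def evaluate_subset(
    train_sessions: Sequence[SyntheticSession],
    test_sessions: Sequence[SyntheticSession],
    labels: Sequence[str],
    config: TrainConfig | None = None,
) -> dict[str, float]:
    """Train on one set of sessions, report per-axis test RMSE on another.

    Returns {'ap': ..., 'si': ..., 'combined': ...} in mm, where combined is
    the root of the mean of the two per-axis mean squared errors.
    """
    models = fit_axis_models(train_sessions, labels, config)
    sq = {ax: [] for ax in AXES}
    for sess in test_sessions:
        pred = predict_setup(models, sess)
        sq["ap"].append((pred.ap - sess.reference_trace.ap) ** 2)
        sq["si"].append((pred.si - sess.reference_trace.si) ** 2)
    out = {ax: float(np.sqrt(np.mean(np.concatenate(sq[ax])))) for ax in AXES}
    out["combined"] = float(np.sqrt(np.mean([out[ax] ** 2 for ax in AXES])))
    return out


def importance_degree(
    sessions: Sequence[SyntheticSession],
    subsets: Mapping[str, Sequence[str]] | None = None,
    train_config: TrainConfig | None = None,
) -> pd.DataFrame:
    """Rank marker subsets (by default the three thoracic regions) by RMSE.

    Trains one correlation model per subset on the training sessions and
    ranks subsets ascending by held-out combined RMSE: rank 1 (lowest
    RMSE) marks the most important placement region.  Ties break
    lexicographically by subset name, so the ranking is deterministic.
    """
    subsets = dict(subsets) if subsets is not None else {r: list(v) for r, v in REGIONS.items()}
    for name, labels in subsets.items():
        if not list(labels):
            raise InvalidParameterError(f"subset {name!r} has no markers")
    train_config = train_config or TrainConfig()
    train, test = _split_sessions(sessions, train_config.train_fraction)
    rows = []
    for name in sorted(subsets):
        res = evaluate_subset(train, test, subsets[name], train_config)
        rows.append(
            {
                "subset": name,
                "markers": ",".join(subsets[name]),
                "n_markers": len(list(subsets[name])),
                "rmse_ap_mm": res["ap"],
                "rmse_si_mm": res["si"],
                "rmse_mm": res["combined"],
            }
        )
    df = pd.DataFrame(rows).sort_values(["rmse_mm", "subset"], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def compare_modes(
    sessions: Sequence[SyntheticSession],
    criteria: SelectionCriteria | None = None,
    train_config: TrainConfig | None = None,
) -> EvaluationReport:
    """Full pipeline comparison across the six evaluation modes.

    Scores and selects markers with both CCA and PCA on the training
    sessions, then trains and evaluates a correlation model for each mode
    (selected-by-CCA, selected-by-PCA, all nine markers, and the upper /
    middle / lower regions) on the held-out sessions.  A selection that
    comes back empty falls back to the best-mean marker so the mode stays
    comparable.
    """
    criteria = criteria or SelectionCriteria()
    train_config = train_config or TrainConfig()
    train, test = _split_sessions(sessions, train_config.train_fraction)

    selections: dict[str, SelectionResult] = {}
    for method in ("cca", "pca"):
        agg = aggregate(score_all(train, method))
        selections[method] = select_markers(agg, criteria)

    modes = []
    for method in ("cca", "pca"):
        sel = selections[method]
        labels = tuple(sorted(sel.selected))
        if not labels:  # degenerate criteria: keep the single best marker
            labels = (max(sel.scores, key=lambda a: a.mean_score).label,)
        modes.append(EvalMode(f"selected_{method}", labels))
    modes.append(EvalMode("all_markers", MARKER_LABELS))
    for region in ("upper", "middle", "lower"):
        modes.append(EvalMode(region, REGIONS[region]))

    rows = []
    combined = {}
    for mode in modes:
        res = evaluate_subset(train, test, mode.marker_subset, train_config)
        combined[mode.name] = res["combined"]
        for ax in AXES:
            rows.append(
                {
                    "mode": mode.name,
                    "axis": ax,
                    "rmse_mm": res[ax],
                    "n_markers": len(mode.marker_subset),
                }
            )
    order = sorted(combined, key=lambda name: (combined[name], name))
    ranks = {name: i + 1 for i, name in enumerate(order)}
    df = pd.DataFrame(rows)
    df["rank"] = df["mode"].map(ranks)
    meta = {
        "n_sessions": len(sessions),
        "n_train_sessions": len(train),
        "selected_cca": sorted(selections["cca"].selected),
        "selected_pca": sorted(selections["pca"].selected),
        "train_seed": train_config.seed,
    }
    return EvaluationReport(df, meta)
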