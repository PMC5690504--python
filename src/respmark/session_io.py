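"""Session CSV and configuration file I/O.

One session is one CSV with a mandatory header row::

    time_s, M1_ap, M1_si, ..., M9_ap, M9_si, ref_ap, ref_si

UTF-8, '.' decimal, one row per time sample, displacements in mm.  The
generating configuration is serialized alongside as YAML.  All floats are
written with locale-independent formatting at 10 significant digits, so a
write/read round trip is lossless to well below 1e-9 mm.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, SchemaError
from .motion_sim import MARKER_LABELS, MotionTrace, SimulationConfig, SyntheticSession

SESSION_COLUMNS = (
    ["time_s"]
    + [f"{m}_{ax}" for m in MARKER_LABELS for ax in ("ap", "si")]
    + ["ref_ap", "ref_si"]
)


def session_to_frame(session: SyntheticSession) -> pd.DataFrame:
    data = {"time_s": session.timestamps}
    for m in MARKER_LABELS:
        tr = session.marker_traces[m]
        data[f"{m}_ap"] = tr.ap
        data[f"{m}_si"] = tr.si
    data["ref_ap"] = session.reference_trace.ap
    data["ref_si"] = session.reference_trace.si
    return pd.DataFrame(data, columns=SESSION_COLUMNS)


def write_session_csv(session: SyntheticSession, path, with_config: bool = True) -> None:
    """Write one session CSV (and, by default, its config YAML sidecar)."""
    path = Path(path)
    session_to_frame(session).to_csv(path, index=False, float_format="%.10g")
    if with_config:
        save_sim_config(session.config, path.with_suffix(".yaml"))


def read_session_csv(path, config: SimulationConfig | None = None) -> SyntheticSession:
    """Load a session CSV, validating schema and time-grid uniformity.

    If no explicit ``config`` is given, a config YAML sidecar next to the
    CSV is used when present; otherwise a minimal placeholder config is
    reconstructed from the time grid.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path} is empty") from exc
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} is missing column(s): {', '.join(missing)}")
    bad = df.index[df[SESSION_COLUMNS].isna().any(axis=1)]
    if len(bad):
        # +2: header line plus 1-based numbering
        lines = ", ".join(str(i + 2) for i in bad[:5])
        raise FormatError(f"{path}: malformed/missing values at line(s) {lines}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: need >= 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
        raise FormatError(f"{path}: non-uniform timestamps")

    if config is None:
        sidecar = path.with_suffix(".yaml")
        if sidecar.exists():
            config = load_sim_config(sidecar)
        else:
            from .motion_sim import BreathingCycleSpec

            period = max(2.0, min(10.0, t[-1] / 4))
            config = SimulationConfig(
                cycle=BreathingCycleSpec(1.0, 1.8, period),
                duration_s=float(t.size * dt[0]),
                dt_s=float(dt[0]),
            )
    traces = {
        m: MotionTrace(t, df[f"{m}_ap"].to_numpy(float), df[f"{m}_si"].to_numpy(float))
        for m in MARKER_LABELS
    }
    ref = MotionTrace(t, df["ref_ap"].to_numpy(float), df["ref_si"].to_numpy(float))
    return SyntheticSession(traces, ref, config)


def save_sim_config(config: SimulationConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_sim_config(path) -> SimulationConfig:
    d = yaml.safe_load(Path(path).read_text())
    if not isinstance(d, dict):
        raise SchemaError(f"{path}: not a mapping")
    return SimulationConfig.from_dict(d)
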