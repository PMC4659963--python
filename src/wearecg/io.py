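"""Plain-text I/O: ECG CSV, beat annotation CSV, pattern/DFA JSON files."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DomainError, EcgSignal
from .rfsm import (
    DfaTable,
    dfa_from_json,
    dfa_to_json,
    patterns_from_json,
    patterns_to_json,
)

__all__ = [
    "read_ecg_csv",
    "write_ecg_csv",
    "write_beats_csv",
    "read_beats_csv",
    "save_patterns",
    "load_patterns",
    "save_dfa",
    "load_dfa",
    "save_record_truth",
    "load_record_truth",
]


def read_ecg_csv(path, fs: float | None = None) -> EcgSignal:
    """Read an ECG from a two-column CSV (``time_s``, ``mv``).

    When ``fs`` is omitted it is inferred from the median time step; the
    series must be (close to) uniformly sampled.
    """
    df = pd.read_csv(path)
    if not {"time_s", "mv"} <= set(df.columns):
        raise DomainError("ECG CSV needs columns time_s and mv")
    t = df["time_s"].to_numpy(dtype=float)
    if fs is None:
        dt = np.diff(t)
        if len(dt) == 0:
            raise DomainError("cannot infer fs from a single sample")
        med = float(np.median(dt))
        if med <= 0 or np.max(np.abs(dt - med)) > 0.01 * med:
            raise DomainError("non-uniform sampling; pass fs explicitly")
        fs = 1.0 / med
    return EcgSignal(samples=df["mv"].to_numpy(dtype=float), fs=fs, t0=float(t[0]) if len(t) else 0.0)


def write_ecg_csv(signal: EcgSignal, path) -> None:
    pd.DataFrame({"time_s": signal.times, "mv": signal.samples}).to_csv(path, index=False)


def write_beats_csv(beats, fs: float, path) -> None:
    """Beats as CSV: r_index, r_time_s, valid, semicolon-joined reasons."""
    pd.DataFrame(
        {
            "r_index": [b.r_index for b in beats],
            "r_time_s": [b.r_index / fs for b in beats],
            "valid": [b.valid for b in beats],
            "reasons": [";".join(b.rejection_reasons) for b in beats],
        }
    ).to_csv(path, index=False)


def read_beats_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_patterns(patterns, path) -> None:
    Path(path).write_text(patterns_to_json(patterns))


def load_patterns(path) -> list:
    return patterns_from_json(Path(path).read_text())


def save_dfa(dfa: DfaTable, path) -> None:
    Path(path).write_text(dfa_to_json(dfa))


def load_dfa(path) -> DfaTable:
    return dfa_from_json(Path(path).read_text())


def save_record_truth(record, path) -> None:
    """Ground-truth sidecar (JSON) for a generated record."""
    truth = {
        "fs": record.fs,
        "true_r_indices": [int(i) for i in record.true_r_indices],
        "injected_artifacts": [[int(i), kind] for i, kind in record.injected_artifacts],
    }
    Path(path).write_text(json.dumps(truth, indent=2))


def load_record_truth(path) -> dict:
    return json.loads(Path(path).read_text())
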