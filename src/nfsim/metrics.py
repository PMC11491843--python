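"""Derived behavioural statistics for the self-evaluation analysis.

From the trial records this module computes, per non-catch trial:

* the running-average prior — the mean of the last five feedback values
  of the same target level that the participant had seen (catch-trial
  feedback included: it was displayed too); missing before any same-level
  history exists;
* the distances of the performance prediction to the real achieved value
  and to that prior;
* the self-regulation outcome centred on the target's scale position
  (6 or 9).

History runs across runs and sessions within a participant by default
(the protocol never resets it); ``reset_per_session`` covers the
alternative reading.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import TARGET_SCALE_POSITIONS

__all__ = [
    "running_prior",
    "build_analysis_table",
    "long_format_distances",
    "session_summary",
]

_KEYS = ["participant", "session", "run", "trial"]


def _check_sorted(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    missing = [c for c in _KEYS + ["target_level", "catch", "nf_value"] if c not in df]
    if missing:
        raise ValueError(f"records missing columns: {missing}")
    if df.duplicated(subset=_KEYS).any():
        raise ValueError("duplicated trial keys in records")
    return df.sort_values(_KEYS, kind="stable").reset_index(drop=True)


def running_prior(
    records: pd.DataFrame,
    window: int = 5,
    *,
    include_catch_history: bool = True,
    reset_per_session: bool = False,
) -> pd.Series:
    """Per-trial running-average prior, aligned to the sorted records.

    For each trial: the mean of up to ``window`` most recent preceding
    feedback values of the same target level within the participant
    (NaN when there is no history yet).
    """
    df = _check_sorted(records)
    priors = np.full(len(df), np.nan)
    for _, group in df.groupby(
        ["participant", "session"] if reset_per_session else "participant", sort=False
    ):
        history: dict[int, list[float]] = {}
        for i, row in group.iterrows():
            tl = row["target_level"]
            past = history.setdefault(tl, [])
            if past:
                priors[i] = float(np.mean(past[-window:]))
            if include_catch_history or not row["catch"]:
                past.append(float(row["nf_value"]))
    return pd.Series(priors, index=df.index, name="prior")


def build_analysis_table(
    records: pd.DataFrame,
    window: int = 5,
    *,
    reset_per_session: bool = False,
) -> pd.DataFrame:
    """Wide per-trial analysis table (catch trials excluded as rows).

    Columns added: ``prior``, ``dist_real`` = |prediction - feedback|,
    ``dist_prior`` = |prediction - prior|, ``centred_selfreg`` =
    feedback - target scale position, ``pred_accuracy`` (= dist_real).
    """
    df = _check_sorted(records)
    df["prior"] = running_prior(df, window, reset_per_session=reset_per_session)
    df = df[~df["catch"].astype(bool)].reset_index(drop=True)
    df["dist_real"] = (df["prediction"] - df["nf_value"]).abs()
    df["dist_prior"] = (df["prediction"] - df["prior"]).abs()
    df["centred_selfreg"] = df["nf_value"] - df["target_level"].map(
        TARGET_SCALE_POSITIONS
    )
    df["pred_accuracy"] = df["dist_real"]
    return df


def long_format_distances(rows: pd.DataFrame) -> pd.DataFrame:
    """Two rows per trial: distance to the real value and to the prior.

    Trials without a prior (each target level's first trial) are dropped;
    ``reference`` is 'real' or 'prior'.
    """
    base = rows.dropna(subset=["prior"])
    parts = []
    for ref in ("real", "prior"):
        part = base[_KEYS + ["target_level"]].copy()
        part["reference"] = ref
        part["distance"] = base[f"dist_{ref}"].to_numpy()
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def session_summary(rows: pd.DataFrame) -> pd.DataFrame:
    """Participant x session x target-level means with trial counts."""
    if rows.empty:
        raise ValueError("no rows to summarise")
    cols = [c for c in ("nf_value", "dist_real", "dist_prior", "confidence") if c in rows]
    g = rows.groupby(["participant", "session", "target_level"])
    out = g[cols].mean()
    out["n_trials"] = g.size()
    return out.reset_index()
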