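"""Standardization of weight reports and aggregate/difference scores.

Raw reports live on participant-chosen scales, so every analysis first
converts them to per-participant z-scores (grand mean and sample SD over
that participant's included trials).  Cell means then aggregate any
dependent variable per participant x order pair x stimulation condition,
and two difference transforms feed the regression analyses: previous-weight
differences (previous-heavy minus previous-light) and stimulation
differences (stimulated minus baseline).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FORCE_DVS = (
    "peak_LFR",
    "peak_GFR",
    "peak1_LFR",
    "peak1_GFR",
    "tp_LFR",
    "tp_GFR",
    "gf_static",
)
PERCEPTUAL_DVS = ("z_estimate",)

#: order pairs keyed by (current weight, previous weight)
_PAIRS_BY_CURRENT = {"light": ("LL", "HL"), "heavy": ("LH", "HH")}


def zscore_estimates(raw: pd.Series, participant: pd.Series) -> pd.Series:
    """Convert raw weight reports to within-participant z-scores.

    Uses each participant's grand mean and sample standard deviation
    (ddof=1) over the supplied (already included) trials.  Raises when a
    participant has fewer than two distinct values.
    """
    raw = pd.Series(np.asarray(raw, dtype=float), index=raw.index)
    out = pd.Series(np.nan, index=raw.index, dtype=float)
    for pid, grp in raw.groupby(participant):
        if len(grp) < 2:
            raise ValueError(f"participant {pid}: need >= 2 estimates to z-score")
        sd = grp.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"participant {pid}: zero variance in estimates")
        out.loc[grp.index] = (grp - grp.mean()) / sd
    return out


def build_cell_means(
    trials: pd.DataFrame,
    dv: str,
    include: pd.Series | None = None,
) -> pd.DataFrame:
    """Participant x order pair x condition means of one dependent variable.

    ``trials`` is a tidy per-trial table with columns ``participant``,
    ``group``, ``order_pair``, ``tms_condition`` and the dv column.
    ``include`` restricts to the appropriate exclusion set; by default all
    rows with a defined order pair enter.
    """
    df = trials if include is None else trials[include]
    df = df[df["order_pair"] != "undefined"]
    cells = (
        df.groupby(["participant", "group", "order_pair", "tms_condition"],
                   observed=True)[dv]
        .mean()
        .reset_index()
        .rename(columns={dv: "value"})
    )
    cells.insert(len(cells.columns) - 1, "dv", dv)
    return cells


def previous_weight_differences(cells: pd.DataFrame) -> pd.DataFrame:
    """Previous-heavy minus previous-light cell means.

    For current light objects the difference is HL - LL; for current heavy
    objects HH - LH, per participant, stimulation condition and dv.
    Records with a missing cell are skipped with a log entry.
    """
    wide = cells.pivot_table(
        index=["participant", "group", "dv", "tms_condition"],
        columns="order_pair",
        values="value",
        observed=True,
    )
    rows = []
    for key, row in wide.iterrows():
        pid, group, dv, cond = key
        for current, (pair_light, pair_heavy) in _PAIRS_BY_CURRENT.items():
            lo, hi = row.get(pair_light), row.get(pair_heavy)
            if pd.isna(lo) or pd.isna(hi):
                logger.warning(
                    "missing cell for participant=%s dv=%s condition=%s "
                    "current=%s; record skipped", pid, dv, cond, current,
                )
                continue
            rows.append(
                {
                    "participant": pid,
                    "group": group,
                    "dv": dv,
                    "tms_condition": cond,
                    "current": current,
                    "diff": hi - lo,
                }
            )
    return pd.DataFrame(rows)


def tms_differences(cells: pd.DataFrame) -> pd.DataFrame:
    """Stimulated-minus-baseline differences, pooled over previous weight.

    Cell means are first averaged to current-weight level (pooling the two
    order pairs sharing a current weight), then the no-stimulation value is
    subtracted from each stimulation condition.
    """
    df = cells.copy()
    df["current"] = df["order_pair"].map(
        {"LL": "light", "HL": "light", "LH": "heavy", "HH": "heavy"}
    )
    pooled = (
        df.groupby(["participant", "group", "dv", "current", "tms_condition"],
                   observed=True)["value"]
        .mean()
        .unstack("tms_condition")
    )
    rows = []
    for key, row in pooled.iterrows():
        pid, group, dv, current = key
        base = row.get("none")
        if pd.isna(base):
            logger.warning(
                "missing baseline cell for participant=%s dv=%s current=%s; "
                "record skipped", pid, dv, current,
            )
            continue
        for cond in ("dynamic", "static"):
            val = row.get(cond)
            if pd.isna(val):
                logger.warning(
                    "missing %s cell for participant=%s dv=%s current=%s; "
                    "record skipped", cond, pid, dv, current,
                )
                continue
            rows.append(
                {
                    "participant": pid,
                    "group": group,
                    "dv": dv,
                    "tms_condition": cond,
                    "current": current,
                    "diff": val - base,
                }
            )
    return pd.DataFrame(rows)


def percent_bias(trials: pd.DataFrame, estimate_col: str = "raw_estimate") -> pd.DataFrame:
    """Previous-weight perceptual bias as a percentage, per participant.

    For current light objects: ``100 * (mean_after_light - mean_after_heavy)
    / mean_after_light`` -- positive values mean the light object felt
    lighter after a heavy lift.  For current heavy objects the same formula
    reads as "felt heavier after a light lift".
    """
    df = trials[trials["order_pair"].isin(["LL", "HL", "LH", "HH"])]
    means = (
        df.groupby(["participant", "order_pair"], observed=True)[estimate_col]
        .mean()
        .unstack("order_pair")
    )
    rows = []
    for pid, row in means.iterrows():
        for current, (pair_after_light, pair_after_heavy) in _PAIRS_BY_CURRENT.items():
            after_light = row.get(pair_after_light)
            after_heavy = row.get(pair_after_heavy)
            if pd.isna(after_light) or pd.isna(after_heavy):
                continue
            if after_light == 0:
                raise ZeroDivisionError(
                    f"participant {pid}: zero mean estimate for current={current}"
                )
            rows.append(
                {
                    "participant": pid,
                    "current": current,
                    "percent_bias": 100.0 * (after_light - after_heavy) / after_light,
                }
            )
    return pd.DataFrame(rows)
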