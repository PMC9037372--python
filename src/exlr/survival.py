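"""Kaplan-Meier estimation, log-rank testing and median-split score screening.

The screen dichotomizes CRC samples at the median of each per-sample score
(cell-type or pathway enrichment, ties to the low group) and tests the two
arms' overall or disease-free survival with the two-group log-rank test —
the standard way to ask whether an inferred cell-type abundance carries
prognostic information.  Only CRC samples enter: controls have no tumor
outcome to model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from exlr.core_data import DataError

logger = logging.getLogger(__name__)


def _coerce_records(records) -> tuple[np.ndarray, np.ndarray]:
    """Accept a DataFrame with time/event columns or a sequence of pairs."""
    if isinstance(records, pd.DataFrame):
        time = records["time"].to_numpy(dtype=float)
        event = records["event"].to_numpy(dtype=bool)
    else:
        arr = list(records)
        time = np.array([t for t, _ in arr], dtype=float)
        event = np.array([e for _, e in arr], dtype=bool)
    if time.size == 0:
        raise DataError("no survival records")
    if (time < 0).any():
        raise DataError("negative survival time")
    return time, event


@dataclass(frozen=True)
class KMCurve:
    """Product-limit curve: steps only at event times, S(0) = 1."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def at(self, t: float) -> float:
        """S(t): survival probability at time t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(records) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times t_i
    with d_i events and n_i at risk.  A sample censored at an event time is
    counted as still at risk there (censoring after events at equal times).
    """
    time, event = _coerce_records(records)
    event_times = np.unique(time[event])
    if event_times.size == 0:
        return KMCurve(np.array([]), np.array([]), np.array([]))
    surv = []
    at_risk = []
    s = 1.0
    for t in event_times:
        n_i = int((time >= t).sum())
        d_i = int(((time == t) & event).sum())
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
    return KMCurve(event_times, np.array(surv), np.array(at_risk, dtype=int))


def logrank_test(group_a, group_b) -> tuple[float, float]:
    """Two-group log-rank test: chi-square statistic and p from chi2(1).

    chi2 = (O_a - E_a)^2 / V summed over distinct event times, with the
    hypergeometric variance V at each event time.  Returns (nan, nan) with
    a warning when no events are observed.
    """
    ta, ea = _coerce_records(group_a)
    tb, eb = _coerce_records(group_b)
    time = np.concatenate([ta, tb])
    event = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    event_times = np.unique(time[event])
    if event_times.size == 0:
        logger.warning("log-rank with zero events; p undefined")
        return float("nan"), float("nan")
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = time >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        d = int(((time == t) & event).sum())
        d_a = int(((time == t) & event & in_a).sum())
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi_sq = o_minus_e**2 / var
    return float(chi_sq), float(stats.chi2.sf(chi_sq, df=1))


def screen_scores(
    scores: pd.DataFrame,
    design: pd.DataFrame,
    endpoint: str = "OS",
) -> pd.DataFrame:
    """Median-split survival screen of every score set over CRC samples.

    For each set: CRC samples with endpoint data are split at the median
    score (ties to the low group); the arms are compared by log-rank.
    ``direction`` is +1 when the high-score arm survives longer (KM curves
    compared at their medians, falling back to the last event time) and -1
    otherwise.  Sets with identical scores on all samples are skipped.
    """
    if endpoint not in ("OS", "DFS"):
        raise DataError(f"unknown endpoint {endpoint!r}")
    tcol, ecol = ("os_time", "os_event") if endpoint == "OS" else ("dfs_time", "dfs_event")
    design = design.set_index("sample_id") if "sample_id" in design.columns else design
    crc = design[design["cohort"] == "CRC"]
    crc = crc[crc[tcol].notna() & crc[ecol].notna()]
    samples = [s for s in scores.columns if s in crc.index]
    if len(samples) < 4:
        raise DataError(f"need >=4 CRC samples with {endpoint} data, got {len(samples)}")
    time = crc.loc[samples, tcol].to_numpy(dtype=float)
    event = crc.loc[samples, ecol].to_numpy(dtype=bool)
    rows = []
    for set_name in scores.index:
        vals = scores.loc[set_name, samples].to_numpy(dtype=float)
        if np.unique(vals).size == 1:
            logger.warning("set %r constant over CRC samples; skipped", set_name)
            continue
        med = np.median(vals)
        high = vals > med  # ties go low
        if high.sum() < 2 or (~high).sum() < 2:
            logger.warning("set %r: degenerate median split; skipped", set_name)
            continue
        rec_high = pd.DataFrame({"time": time[high], "event": event[high]})
        rec_low = pd.DataFrame({"time": time[~high], "event": event[~high]})
        chi_sq, p = logrank_test(rec_high, rec_low)
        rows.append(
            {
                "set": set_name,
                "direction": _direction(rec_high, rec_low),
                "chi_sq": chi_sq,
                "p": p,
                "n_high": int(high.sum()),
                "n_low": int((~high).sum()),
            }
        )
    return pd.DataFrame(rows)


def _median_survival(curve: KMCurve) -> float:
    below = curve.survival <= 0.5
    return float(curve.event_times[below][0]) if below.any() else np.inf


def _direction(rec_high: pd.DataFrame, rec_low: pd.DataFrame) -> int:
    """+1 when the high-score arm fares better, -1 when worse, 0 when tied."""
    km_high = km_estimate(rec_high)
    km_low = km_estimate(rec_low)
    mh, ml = _median_survival(km_high), _median_survival(km_low)
    if mh != ml and not (np.isinf(mh) and np.isinf(ml)):
        return 1 if mh > ml else -1
    times = np.concatenate([km_high.event_times, km_low.event_times])
    if times.size == 0:
        return 0
    t_last = times.max()
    sh, sl = km_high.at(t_last), km_low.at(t_last)
    return 0 if sh == sl else (1 if sh > sl else -1)
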