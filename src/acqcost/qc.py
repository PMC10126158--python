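"""Quality control of raw colony growth curves.

Scanner-derived curves carry characteristic artifacts: transient spikes from
shadowing or pixelation, merged colonies or shadows that inflate the final
size, and curves that never plateau (unreliable logistic fits).  The filter
applies, in order:

1. within each (population, plate) group, drop curves whose final density
   lies outside mean +/- ``sd_multiplier`` * SD of the group's final values;
2. close spikes of <= ``max_spike_close`` consecutive points by replacing
   them with the average of the flanking samples;
3. drop curves containing wider spikes (cannot be reliably closed);
4. drop curves whose terminal derivative (mean slope over the last
   ``plateau_window_h`` hours) exceeds ``plateau_tol_frac`` of the curve's
   maximum derivative — i.e. curves still rising at the end of the run.

Every rejection carries a reason code: ``final_density_outlier``,
``spike_too_wide`` or ``no_plateau``.
"""
from __future__ import annotations

import logging
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.ndimage import median_filter

from .growth import smooth
from .types import GrowthCurve, QCReport

logger = logging.getLogger(__name__)

__all__ = ["qc_filter", "find_spike_runs", "close_spikes"]

REASON_OUTLIER = "final_density_outlier"
REASON_SPIKE = "spike_too_wide"
REASON_NO_PLATEAU = "no_plateau"


def find_spike_runs(values: np.ndarray, spike_tol: float = 0.15,
                    ref_window: int = 11) -> list[tuple[int, int]]:
    """Maximal runs of consecutive points deviating from a median-filtered
    reference by more than ``spike_tol`` (start, stop) half-open index pairs.

    The reference window must exceed twice the widest spike to be detected;
    the default (11 points) resolves runs up to 5 points at 15-min sampling.
    """
    values = np.asarray(values, dtype=float)
    ref = median_filter(values, size=ref_window, mode="nearest")
    flag = np.abs(values - ref) > spike_tol
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(values)
    while i < n:
        if flag[i]:
            j = i
            while j < n and flag[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def close_spikes(values: np.ndarray, runs: Sequence[tuple[int, int]]) -> np.ndarray:
    """Replace each spike run with the average of the flanking samples."""
    out = np.asarray(values, dtype=float).copy()
    n = len(out)
    for start, stop in runs:
        flanks = []
        if start - 1 >= 0:
            flanks.append(out[start - 1])
        if stop < n:
            flanks.append(out[stop])
        if flanks:
            out[start:stop] = np.mean(flanks)
    return out


def _plateau_failed(times: np.ndarray, values: np.ndarray,
                    plateau_tol_frac: float, plateau_window_h: float) -> bool:
    ys = smooth(values)
    deriv = np.gradient(ys, times)
    max_deriv = float(deriv.max())
    if max_deriv <= 0:
        return False  # flat/decreasing curves carry no plateau information
    tail = times >= times[-1] - plateau_window_h
    if tail.sum() < 2:
        return False
    tail_slope = float((ys[tail][-1] - ys[tail][0]) / (times[tail][-1] - times[tail][0]))
    return tail_slope > plateau_tol_frac * max_deriv


def qc_filter(curves: Iterable[GrowthCurve],
              group_key: Callable[[GrowthCurve], tuple] | None = None,
              sd_multiplier: float = 2.0,
              max_spike_close: int = 2,
              spike_tol: float = 0.15,
              plateau_tol_frac: float = 0.10,
              plateau_window_h: float = 2.0,
              min_group_for_sd: int = 3) -> tuple[list[GrowthCurve], QCReport]:
    """Filter raw curves, returning (passed curves, rejection report).

    ``group_key`` defaults to (population, replicate_id) — i.e. the colony
    type on a single plate, mirroring how scanner experiments batch their
    colonies.  The final-density SD rule only applies within groups of at
    least ``min_group_for_sd`` curves.  Passed curves have their narrow
    spikes closed; the report records closures and rejection reasons.
    """
    curves = list(curves)
    if group_key is None:
        group_key = lambda c: (c.population, c.replicate_id)

    report = QCReport()
    if not curves:
        logger.warning("qc_filter called with no curves")
        return [], report

    # --- step 1: final-density outliers within each group -----------------
    groups: dict[tuple, list[GrowthCurve]] = {}
    for c in curves:
        groups.setdefault(group_key(c), []).append(c)

    survivors: list[GrowthCurve] = []
    for key, members in groups.items():
        finals = np.array([m.values[-1] for m in members])
        if len(members) >= min_group_for_sd and finals.std() > 0:
            lo = finals.mean() - sd_multiplier * finals.std()
            hi = finals.mean() + sd_multiplier * finals.std()
            for m, f in zip(members, finals):
                if lo <= f <= hi:
                    survivors.append(m)
                else:
                    report.rejected[m.colony_id] = REASON_OUTLIER
        else:
            survivors.extend(members)

    # --- steps 2-4: spikes and plateau, per curve --------------------------
    passed: list[GrowthCurve] = []
    for c in survivors:
        runs = find_spike_runs(c.values, spike_tol=spike_tol)
        wide = [r for r in runs if (r[1] - r[0]) > max_spike_close]
        if wide:
            report.rejected[c.colony_id] = REASON_SPIKE
            continue
        if runs:
            closed = np.clip(close_spikes(c.values, runs), 0.0, None)
            c = c.with_values(closed)
            report.spikes_closed[c.colony_id] = int(sum(r[1] - r[0] for r in runs))
        if _plateau_failed(c.times, c.values, plateau_tol_frac, plateau_window_h):
            report.rejected[c.colony_id] = REASON_NO_PLATEAU
            continue
        passed.append(c)

    report.passed_ids = [c.colony_id for c in passed]
    return passed, report
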