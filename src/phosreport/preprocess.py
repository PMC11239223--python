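"""Median normalization across runs and class-I confidence filtering.

Normalization equalizes per-run median intensities: every intensity in
run *r* is multiplied by ``f_r = exp(m - m_r)``, where ``m_r`` is the
median of the natural-log intensities of run *r* and ``m`` is the mean
of the ``m_r`` — i.e. all runs are brought to the geometric mean of the
per-run medians.  Within-run intensity ratios are untouched, so the
operation only removes differences in loaded material.

Filtering keeps class-I evidence: peptide q-value strictly below the
cut-off and, in site mode, localization confidence at or above the
dialect's threshold (0.75 for the Spectronaut score, 0.01 for DIA-NN's).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_Q_MAX = 0.01


def normalize_median(rows: pd.DataFrame) -> pd.DataFrame:
    """Scale intensities so that per-run medians of log intensity agree.

    Zero or missing intensities are excluded from the median computation
    and left untouched.  Rows without a fragment id (MS1 evidence) are
    scaled by the factor computed from the fragment-level rows of their
    run when fragment rows exist.

    Raises
    ------
    ValueError
        If some run has no positive intensity at all.
    """
    if len(rows) == 0:
        return rows.copy()
    intensity = rows["intensity"].to_numpy(dtype=float)
    positive = np.isfinite(intensity) & (intensity > 0)
    is_fragment = rows["fragment_id"].astype(str).str.len() > 0
    # median over fragment rows (the quantified unit); fall back to all
    # positive rows when the report carries no fragment ids
    basis = positive & is_fragment.to_numpy()
    if not basis.any():
        basis = positive

    runs = rows["run_id"]
    log_medians: dict[str, float] = {}
    for run in runs.unique():
        mask = (runs == run).to_numpy()
        if not (mask & positive).any():
            raise ValueError(f"run {run!r} has no positive intensities")
        sel = mask & basis
        if not sel.any():
            sel = mask & positive
        log_medians[run] = float(np.median(np.log(intensity[sel])))

    target = float(np.mean(list(log_medians.values())))
    factors = {run: np.exp(target - m) for run, m in log_medians.items()}
    out = rows.copy()
    scaled = intensity * runs.map(factors).to_numpy(dtype=float)
    out["intensity"] = np.where(positive, scaled, intensity)
    log.info(
        "median normalization over %d runs; factors in [%.4g, %.4g]",
        len(factors),
        min(factors.values()),
        max(factors.values()),
    )
    return out


@dataclass
class FilterLog:
    rows_in: int = 0
    removed_q: int = 0
    removed_loc: int = 0
    rows_out: int = 0


def filter_confident(
    rows: pd.DataFrame,
    q_max: float = DEFAULT_Q_MAX,
    loc_min: float = 0.75,
    require_loc: bool = True,
) -> tuple[pd.DataFrame, FilterLog]:
    """Keep rows with ``q_value < q_max`` and, when ``require_loc``,
    ``localization >= loc_min``.

    ``require_loc`` is on for site-level reporting and off for
    peptide-level reporting, where localization confidence is optional.
    Rows with a missing score fail the corresponding criterion.
    """
    if not (0 <= q_max <= 1 and 0 <= loc_min <= 1):
        raise ValueError("q_max and loc_min must lie in [0, 1]")
    q = rows["q_value"].to_numpy(dtype=float)
    pass_q = np.isfinite(q) & (q < q_max)
    if require_loc:
        loc = rows["localization"].to_numpy(dtype=float)
        pass_loc = np.isfinite(loc) & (loc >= loc_min)
    else:
        pass_loc = np.ones(len(rows), dtype=bool)
    keep = pass_q & pass_loc
    flog = FilterLog(
        rows_in=len(rows),
        removed_q=int((~pass_q).sum()),
        removed_loc=int((pass_q & ~pass_loc).sum()),
        rows_out=int(keep.sum()),
    )
    log.info(
        "confidence filter: %d -> %d rows (%d failed q<%g, %d further failed loc>=%g)",
        flog.rows_in,
        flog.rows_out,
        flog.removed_q,
        q_max,
        flog.removed_loc,
        loc_min,
    )
    return rows.loc[keep].copy(), flog
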