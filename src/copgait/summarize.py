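"""Per-subject, per-trial summaries of stride- and cycle-level metrics.

The analysis unit of the trial statistics is the subject: every gait
metric is reduced to a per-subject, per-trial mean and sample standard
deviation (n - 1 denominator).  Both moments are analyzed downstream —
the SD captures the within-subject variability that perturbation
training is expected to change.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: fewer valid units than this in a cell gets a low-n flag (a 5-minute
#: walk yields far more strides than this; low counts signal data loss)
MIN_UNITS = 10


def summarize_subject_trial(units: pd.DataFrame, min_units: int = MIN_UNITS) -> pd.DataFrame:
    """Reduce a tidy unit-level metric table to per-cell summaries.

    ``units`` must have columns subject_id, group, trial, metric, value
    and optionally flag; rows with a non-empty flag (or NaN value) are
    excluded, with exclusion counts logged.  Returns one row per
    (subject, trial, metric): mean, sd (ddof=1, NaN when n < 2), n_units,
    and a flag column marking low-n cells.
    """
    required = {"subject_id", "group", "trial", "metric", "value"}
    missing = required - set(units.columns)
    if missing:
        raise ValidationError(f"units table missing columns: {sorted(missing)}")
    df = units.copy()
    if "flag" in df.columns:
        flagged = df["flag"].fillna("").astype(str) != ""
    else:
        flagged = pd.Series(False, index=df.index)
    flagged |= df["value"].isna()
    n_excluded = int(flagged.sum())
    if n_excluded:
        logger.info("summarize: excluding %d flagged/missing units", n_excluded)
    df = df[~flagged]
    if df.empty:
        logger.warning("summarize: no valid units remain")
        return pd.DataFrame(columns=["subject_id", "group", "trial", "metric",
                                     "mean", "sd", "n_units", "flag"])
    g = df.groupby(["subject_id", "group", "trial", "metric"], sort=True)["value"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n_units="count")
    out = out.reset_index()
    out["flag"] = np.where(out["n_units"] < min_units, "low_n", "")
    return out


def pool_moments(parts: list[tuple[float, float, int]]) -> tuple[float, float, int]:
    """Pool (mean, sd, n) triples into the moments of the concatenation.

    Standard pooled-moments identity: the combined variance is the
    n-1-weighted within-part variance plus the between-part dispersion of
    means.  Parts with n = 1 contribute their mean only (sd may be NaN).
    """
    parts = [(m, s, n) for m, s, n in parts if n > 0]
    if not parts:
        raise ValidationError("cannot pool zero parts")
    n_tot = sum(n for _, _, n in parts)
    mean = sum(m * n for m, _, n in parts) / n_tot
    if n_tot < 2:
        return mean, float("nan"), n_tot
    ssq = 0.0
    for m, s, n in parts:
        if n > 1:
            if not math.isfinite(s):
                raise ValidationError("part with n > 1 has undefined sd")
            ssq += (n - 1) * s * s
        ssq += n * (m - mean) ** 2
    return mean, math.sqrt(ssq / (n_tot - 1)), n_tot
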