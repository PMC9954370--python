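"""FPKM quantification, feature ranking, correlation, and lncRNA/mRNA summaries.

FPKM[i, j] = counts[i, j] * 1e9 / (length[i] * total[j]), with total[j] the
within-matrix column sum (no external mapped-read count exists in this
pipeline; callers may substitute their own totals). All-zero libraries yield
all-zero FPKM columns rather than a division error.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats import ExpressionMatrix, TranscriptModel


class ConstantVectorError(ValueError):
    """Correlation of a constant vector is undefined; never silently zero."""


def fpkm(
    counts: ExpressionMatrix,
    lengths: Mapping[str, int],
    library_sizes: Mapping[str, float] | None = None,
) -> ExpressionMatrix:
    """Convert a counts matrix to FPKM using spliced feature lengths in nt."""
    if counts.unit != "counts":
        raise ValueError(f"expected a counts matrix, got unit {counts.unit!r}")
    missing = [f for f in counts.feature_ids if f not in lengths]
    if missing:
        raise KeyError(f"no length for feature {missing[0]!r}")
    lens = np.array([lengths[f] for f in counts.feature_ids], dtype=float)
    if (lens < 1).any():
        raise ValueError("feature lengths must be >= 1 nt")
    if library_sizes is None:
        totals = counts.values.sum(axis=0).to_numpy(dtype=float)
    else:
        totals = np.array([library_sizes[s] for s in counts.sample_ids], dtype=float)
    safe_totals = np.where(totals > 0, totals, 1.0)
    values = counts.values.to_numpy(dtype=float) * 1e9 / (lens[:, None] * safe_totals[None, :])
    values[:, totals == 0] = 0.0
    df = pd.DataFrame(values, index=counts.feature_ids, columns=counts.sample_ids)
    return ExpressionMatrix(values=df, unit="FPKM")


def rank_top_features(m: ExpressionMatrix, n: int, by: str = "mean") -> list[str]:
    """Top-n feature ids by descending cross-sample mean; ties lexicographic."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if by != "mean":
        raise ValueError(f"unsupported ranking criterion {by!r}")
    means = m.values.mean(axis=1)
    order = sorted(means.index, key=lambda f: (-means[f], f))
    return order[: min(n, len(order))]


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError("correlation of a constant vector is undefined")
    return float(stats.pearsonr(x, y).statistic)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("correlation needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError("correlation of a constant vector is undefined")
    return float(stats.spearmanr(x, y).statistic)


def compare_lnc_mrna(
    lnc: Iterable[TranscriptModel],
    mrna: Iterable[TranscriptModel],
    m: ExpressionMatrix,
) -> pd.DataFrame:
    """Median and quartiles of mean FPKM, spliced length and exon count per group.

    Empty groups are reported with n = 0 and NaN summaries (the explicit
    empty-summary marker) rather than dropped.
    """
    rows = []
    for group, transcripts in (("lncRNA", list(lnc)), ("mRNA", list(mrna))):
        if not transcripts:
            rows.append({"group": group, "n": 0})
            continue
        for t in transcripts:
            if t.transcript_id not in m.values.index:
                raise KeyError(f"transcript {t.transcript_id!r} not in matrix")
        expr = m.values.loc[[t.transcript_id for t in transcripts]].mean(axis=1)
        lengths = pd.Series([t.spliced_length for t in transcripts], dtype=float)
        exons = pd.Series([t.n_exons for t in transcripts], dtype=float)
        row = {"group": group, "n": len(transcripts)}
        for name, series in (("fpkm", expr), ("length", lengths), ("exons", exons)):
            row[f"{name}_q1"] = float(series.quantile(0.25))
            row[f"{name}_median"] = float(series.quantile(0.5))
            row[f"{name}_q3"] = float(series.quantile(0.75))
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
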