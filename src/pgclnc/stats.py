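"""qPCR relative quantification (2^-ddCt) and PGC-mislocalization statistics.

The ddCt method normalizes each replicate's target Ct to the arithmetic mean
of the two reference-gene Cts (ef1a, rpl13a) — equivalent to the geometric
mean of reference expression — then centers on the control group's mean dCt,
so the control group's mean fold change is 1 by construction.

The phenotype summary reports, per group, the percentage of embryos with at
least one mislocalized PGC and the mean mislocalized-PGC count. The mean is
taken among affected embryos by default (`among_affected=False` averages over
all embryos instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats

REFERENCE_GENES = ("ef1a", "rpl13a")

CT_COLUMNS = ("group", "replicate", "gene", "ct")
PHENOTYPE_COLUMNS = ("group", "embryo", "mislocalized_count")


def validate_ct_table(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table lacks column {missing[0]!r}")
    if ((ct["ct"] <= 0) | (ct["ct"] >= 45)).any():
        raise ValueError("Ct values must lie in (0, 45) cycles")
    for (group, rep), sub in ct.groupby(["group", "replicate"]):
        genes = set(sub["gene"])
        for ref in REFERENCE_GENES:
            if ref not in genes:
                raise ValueError(
                    f"reference gene {ref} missing in group {group!r} replicate {rep!r}"
                )
    return ct


def ddct_fold_change(
    ct: pd.DataFrame, target_gene: str, control_group: str
) -> pd.DataFrame:
    """Per-group mean fold change (2^-ddCt) and SD over replicates.

    dCt = Ct_target - mean(Ct_ef1a, Ct_rpl13a) per replicate; ddCt subtracts
    the control group's mean dCt; fold = 2^-ddCt.
    """
    validate_ct_table(ct)
    groups = ct["group"].unique()
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} not in Ct table")
    dct: dict[str, list[float]] = {g: [] for g in groups}
    for (group, _rep), sub in ct.groupby(["group", "replicate"], sort=False):
        by_gene = sub.set_index("gene")["ct"]
        if target_gene not in by_gene.index:
            raise ValueError(f"target gene {target_gene!r} missing in group {group!r}")
        ref = float(np.mean([by_gene[r] for r in REFERENCE_GENES]))
        dct[group].append(float(by_gene[target_gene]) - ref)
    control_mean = float(np.mean(dct[control_group]))
    rows = []
    for group in groups:
        folds = np.array([2.0 ** -(d - control_mean) for d in dct[group]])
        rows.append(
            {
                "group": group,
                "n_replicates": folds.size,
                "fold": float(folds.mean()),
                "sd": float(folds.std(ddof=1)) if folds.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("group")


@dataclass
class GroupPhenotype:
    group: str
    n_embryos: int
    percent_mislocalized: float
    mean_mislocalized: float
    no_affected: bool  # flag: no affected embryo, mean reported as 0


def phenotype_summary(
    table: pd.DataFrame, among_affected: bool = True
) -> pd.DataFrame:
    """Per-group % embryos with mislocalized PGC and mean mislocalized count."""
    missing = [c for c in PHENOTYPE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype table lacks column {missing[0]!r}")
    counts = table["mislocalized_count"]
    if (counts < 0).any() or (counts != counts.astype(int)).any():
        raise ValueError("mislocalized counts must be non-negative integers")
    rows = []
    for group, sub in table.groupby("group", sort=False):
        c = sub["mislocalized_count"].to_numpy(dtype=float)
        affected = c[c >= 1]
        percent = 100.0 * affected.size / c.size
        if among_affected:
            no_affected = affected.size == 0
            mean = float(affected.mean()) if affected.size else 0.0
        else:
            no_affected = False
            mean = float(c.mean())
        rows.append(
            {
                "group": group,
                "n_embryos": int(c.size),
                "percent_mislocalized": percent,
                "mean_mislocalized": mean,
                "no_affected": no_affected,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def two_sample_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Student's t with pooled variance, df = n1 + n2 - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    res = scipy_stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F = MS_between / MS_within with (k-1, N-k) df."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    res = scipy_stats.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)
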