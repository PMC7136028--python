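"""Resting-vs-induced expression and promoter-methylation analysis.

Given a genes × samples count matrix with resting/induced condition labels,
this module computes per-gene fold changes on CPM-normalised values, bins
genes by fold-change magnitude (<2, 2–5, 5–15, >15), aggregates promoter
methylation from per-CpG coverage tables, stratifies expression and
methylation changes by promoter CpG-ratio quartile, and compares the
extreme quartiles with the two-sample Kolmogorov–Smirnov test.  A
time-course summary scores how tightly expression and promoter methylation
move in opposite directions during induction and washout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

FOLD_CHANGE_BINS = ("<2", "2-5", "5-15", ">15")
_BIN_EDGES = (1.0, 2.0, 5.0, 15.0, np.inf)

QUARTILE_ORDER = ("Q1", "Q2", "Q3", "Q4")


@dataclass
class CountMatrix:
    """Genes × samples counts with per-sample condition labels.

    ``condition`` maps sample id -> "resting" / "induced"; ``timepoint``
    (optional) carries hours for time-course designs.
    """

    counts: pd.DataFrame
    condition: pd.Series
    timepoint: pd.Series | None = None

    def __post_init__(self):
        missing = set(self.counts.columns) - set(self.condition.index)
        if missing:
            raise InputError(f"samples without condition labels: {sorted(missing)}")
        labels = set(self.condition.loc[list(self.counts.columns)])
        if not labels <= {"resting", "induced"}:
            raise InputError(f"unknown condition labels: {labels - {'resting', 'induced'}}")
        arr = self.counts.to_numpy()
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise InputError("counts must be finite and non-negative")


def normalize_counts(matrix: CountMatrix) -> pd.DataFrame:
    """Counts-per-million per sample, plus a pseudocount of 1 after scaling.

    The pseudocount makes downstream ratios well defined for all-zero genes
    (their normalised value is exactly 1 in every sample).
    """
    lib = matrix.counts.sum(axis=0)
    zero = lib.index[lib == 0]
    if len(zero):
        raise InputError(f"zero library size for sample(s): {list(zero)}")
    return matrix.counts.div(lib, axis=1) * 1e6 + 1.0


def fold_change(normalized: pd.DataFrame, condition: pd.Series) -> pd.DataFrame:
    """Per-gene fold change between condition means, with magnitude bins.

    fc = mean(induced) / mean(resting); the bin is by the magnitude
    m = max(fc, 1/fc), half-open intervals [1,2), [2,5), [5,15), [15,inf),
    so 2-fold repression lands in the same bin as 2-fold induction.
    """
    cond = condition.loc[list(normalized.columns)]
    for label in ("resting", "induced"):
        if not (cond == label).any():
            raise InputError(f"no {label!r} samples present")
    mean_rest = normalized.loc[:, cond[cond == "resting"].index].mean(axis=1)
    mean_ind = normalized.loc[:, cond[cond == "induced"].index].mean(axis=1)
    fc = mean_ind / mean_rest
    magnitude = np.maximum(fc, 1.0 / fc)
    bins = pd.cut(
        magnitude,
        bins=list(_BIN_EDGES),
        labels=list(FOLD_CHANGE_BINS),
        right=False,
        include_lowest=True,
    )
    return pd.DataFrame(
        {
            "fc": fc,
            "log2fc": np.log2(fc),
            "magnitude": magnitude,
            "bin": bins.astype(object),
        },
        index=normalized.index,
    )


@dataclass(frozen=True)
class MethLevel:
    """Coverage-weighted promoter methylation for one gene/window."""

    mean: float
    n_cpgs: int
    mean_coverage: float


def promoter_methylation_level(
    per_cpg: pd.DataFrame,
    start: int,
    end: int,
    chrom: str | None = None,
    min_coverage: int = 5,
) -> MethLevel | None:
    """Coverage-weighted mean methylation over CpGs in [start, end).

    ``per_cpg`` needs columns ``position`` (or ``start``), ``methylated``,
    ``total``; with a ``chrom`` column rows are restricted to ``chrom``.
    CpGs under ``min_coverage`` are excluded.  Returns None when no CpG
    qualifies — the gene is then missing, not 0.
    """
    if min_coverage < 1:
        raise InputError("min_coverage must be >= 1")
    table = per_cpg
    if chrom is not None and "chrom" in table.columns:
        table = table[table["chrom"] == chrom]
    pos_col = "position" if "position" in table.columns else "start"
    mask = (
        (table[pos_col] >= start)
        & (table[pos_col] < end)
        & (table["total"] >= min_coverage)
    )
    hits = table[mask]
    if len(hits) == 0:
        return None
    total = hits["total"].sum()
    return MethLevel(
        mean=float(hits["methylated"].sum() / total),
        n_cpgs=int(len(hits)),
        mean_coverage=float(hits["total"].mean()),
    )


@dataclass(frozen=True)
class KSResult:
    """Two-sample Kolmogorov–Smirnov comparison."""

    d: float
    pvalue: float
    n1: int
    n2: int


def ks_test(
    sample_x: Sequence[float], sample_y: Sequence[float], exact: bool = False
) -> KSResult:
    """Two-sided two-sample K-S test.

    D is the supremum over breakpoints of the ECDF difference; the p-value is
    asymptotic (Kolmogorov distribution at effective n = n1 n2/(n1+n2)) by
    default, exact behind the flag for small samples.
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("K-S test needs non-empty samples")
    res = stats.ks_2samp(x, y, method="exact" if exact else "asymp")
    return KSResult(d=float(res.statistic), pvalue=float(res.pvalue),
                    n1=x.size, n2=y.size)


@dataclass
class StratifiedSummary:
    """Per-quartile effect sizes and the Q1-vs-Q4 K-S comparisons.

    ``per_quartile`` rows are ordered Q1..Q4 with columns ``n``,
    ``median_abs_log2fc`` and (when a methylation delta is supplied)
    ``median_abs_delta``.  The monotonic flags are true iff the medians are
    non-increasing from Q1 (most CpG-poor) to Q4.
    """

    per_quartile: pd.DataFrame
    ks_log2fc: KSResult
    ks_delta: KSResult | None
    monotonic_log2fc: bool
    monotonic_delta: bool | None


def stratified_comparison(
    table: pd.DataFrame, exact_ks: bool = False
) -> StratifiedSummary:
    """Stratify |log2fc| (and |delta| if present) by CpG-ratio quartile.

    ``table`` needs columns ``quartile`` and ``log2fc``; a ``delta`` column
    (induced − resting promoter methylation) adds the methylation arm.
    Every quartile must be non-empty.
    """
    for col in ("quartile", "log2fc"):
        if col not in table.columns:
            raise InputError(f"missing column {col!r}")
    has_delta = "delta" in table.columns
    rows = {}
    for q in QUARTILE_ORDER:
        sub = table[table["quartile"] == q]
        if len(sub) == 0:
            raise InputError(f"empty quartile {q}")
        row = {"n": len(sub), "median_abs_log2fc": sub["log2fc"].abs().median()}
        if has_delta:
            row["median_abs_delta"] = sub["delta"].abs().median()
        rows[q] = row
    per_q = pd.DataFrame.from_dict(rows, orient="index").loc[list(QUARTILE_ORDER)]

    q1 = table[table["quartile"] == "Q1"]
    q4 = table[table["quartile"] == "Q4"]
    ks_fc = ks_test(q1["log2fc"].abs(), q4["log2fc"].abs(), exact=exact_ks)
    mono_fc = bool(np.all(np.diff(per_q["median_abs_log2fc"]) <= 0))
    ks_d = mono_d = None
    if has_delta:
        ks_d = ks_test(q1["delta"].abs(), q4["delta"].abs(), exact=exact_ks)
        mono_d = bool(np.all(np.diff(per_q["median_abs_delta"]) <= 0))
    return StratifiedSummary(
        per_quartile=per_q,
        ks_log2fc=ks_fc,
        ks_delta=ks_d,
        monotonic_log2fc=mono_fc,
        monotonic_delta=mono_d,
    )


@dataclass
class TimecourseSummary:
    """Paired expression/methylation trajectory and inverse-coupling score.

    The score is the fraction of consecutive-timepoint intervals in which
    expression and methylation moved in opposite directions, among intervals
    where both changed; NaN when no interval is usable.
    """

    table: pd.DataFrame
    inverse_coupling: float
    n_intervals: int
    n_zero_change: int


def timecourse_summary(
    expression: pd.Series, methylation: pd.Series
) -> TimecourseSummary:
    """Pair expression and methylation series over shared timepoints."""
    shared = expression.index.intersection(methylation.index).sort_values()
    if len(shared) < 3:
        raise InputError("need at least 3 shared timepoints")
    expr = expression.loc[shared].astype(float)
    meth = methylation.loc[shared].astype(float)
    de = np.diff(expr.to_numpy())
    dm = np.diff(meth.to_numpy())
    usable = (de != 0) & (dm != 0)
    n_zero = int(np.count_nonzero(~usable))
    if usable.any():
        score = float(np.mean(np.sign(de[usable]) == -np.sign(dm[usable])))
    else:
        score = float("nan")
    table = pd.DataFrame(
        {"time": shared, "expression": expr.to_numpy(),
         "methylation": meth.to_numpy()}
    ).set_index("time")
    return TimecourseSummary(
        table=table,
        inverse_coupling=score,
        n_intervals=int(len(de)),
        n_zero_change=n_zero,
    )
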