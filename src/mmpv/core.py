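"""Detection of miRNA-mRNA pairs whose regulatory pattern differs between
the two statuses of a binary biopathological feature.

For each validated targeting pair the Pearson correlation coefficient (PCC)
of miRNA and mRNA expression is computed separately within each status
stratum; a PCC > 0 is read as positive regulation in that stratum and
PCC < 0 as negative. Per-stratum significance is a two-sided t-test on the
correlation (n - 2 degrees of freedom) with Benjamini-Hochberg FDR control
across all pairs of the stratum. A pair whose two stratum correlations are
both insignificant (q >= alpha in both) is removed. The remaining pairs are
classified as

* ``sign_change`` when the two PCCs have opposite algebraic signs, or
* ``fold_change`` when they share a sign but their ratio is >= ``fold``
  (default 2) or <= 1/``fold``,

and each detected pair is summarised by a pattern string such as
``D_U_U*``: the healthy-population sign, then the status1 and status2 signs,
with ``*`` marking FDR-significant strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)
from .io_model import ExpressionMatrix, SampleAnnotation, TargetPair

logger = logging.getLogger(__name__)

MIN_STRATUM_N = 3  # smallest n with a defined correlation p-value (df = n-2 >= 1)

MMPV_TABLE_COLUMNS = [
    "mirna_id",
    "mrna_id",
    "healthy_sign",
    "r_status1",
    "n_status1",
    "p_status1",
    "q_status1",
    "r_status2",
    "n_status2",
    "p_status2",
    "q_status2",
    "mmpv_class",
    "pattern",
    "feature",
]


@dataclass(frozen=True)
class StratumCorrelation:
    """PCC of one pair within one status stratum, with its raw and adjusted p."""

    r: float
    n: int
    p: float
    q: float


@dataclass(frozen=True)
class MMPVRecord:
    """A detected pair: per-stratum correlations, class, and pattern string."""

    pair: TargetPair
    corr_status1: StratumCorrelation
    corr_status2: StratumCorrelation
    mmpv_class: str  # sign_change | fold_change
    pattern: str
    feature_name: str


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation, clamped to [-1, 1].

    Raises :class:`InsufficientDataError` for fewer than two observations and
    :class:`DegenerateDataError` when either vector is constant.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    if xa.size < 2:
        raise InsufficientDataError(f"need >= 2 observations, got {xa.size}")
    xd = xa - xa.mean()
    yd = ya - ya.mean()
    sxx = float(xd @ xd)
    syy = float(yd @ yd)
    if sxx == 0.0 or syy == 0.0:
        raise DegenerateDataError("constant input: correlation undefined")
    r = float(xd @ yd) / np.sqrt(sxx * syy)
    return float(np.clip(r, -1.0, 1.0))


def correlation_p_value(r: float, n: int) -> float:
    """Two-sided p for a sample correlation under bivariate normality.

    Uses t = r * sqrt(n-2) / sqrt(1-r^2) on n-2 degrees of freedom; the
    degenerate r = +/-1 limit is defined as p = 0.
    """
    if n < 3:
        raise InsufficientDataError(f"need n >= 3 for a correlation p, got {n}")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"r must lie in [-1, 1], got {r}")
    if abs(r) == 1.0:
        return 0.0
    df = n - 2
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    q(i) = min over j >= i (ascending order) of p(j) * m / j, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify_pair(
    r1: float,
    r2: float,
    q1: float,
    q2: float,
    alpha: float = 0.05,
    fold: float = 2.0,
) -> str:
    """Assign exactly one of {sign_change, fold_change, none} to a pair.

    Pairs insignificant in both strata (q >= alpha twice) are ``none``
    regardless of their correlations. Otherwise opposite signs give
    ``sign_change``; a shared nonzero sign with ratio r1/r2 outside
    (1/fold, fold) gives ``fold_change``; exactly one zero correlation is
    treated as an infinite ratio (``fold_change``); everything else is
    ``none``.
    """
    if fold <= 1.0:
        raise ValueError(f"fold must exceed 1, got {fold}")
    if q1 >= alpha and q2 >= alpha:
        return "none"
    s1, s2 = np.sign(r1), np.sign(r2)
    if s1 * s2 < 0:
        return "sign_change"
    if s1 != 0 and s2 != 0:
        ratio = r1 / r2
        if ratio >= fold or ratio <= 1.0 / fold:
            return "fold_change"
        return "none"
    if (s1 == 0) != (s2 == 0):
        return "fold_change"
    return "none"


def encode_pattern(
    healthy_sign: str,
    r1: float,
    q1: float,
    r2: float,
    q2: float,
    alpha: float = 0.05,
) -> str:
    """Render the H_S1_S2 pattern string (e.g. ``D_U_U*``).

    H is the healthy-population sign; S1/S2 are 'U' or 'D' by the sign of
    the status1/status2 correlation, each suffixed with '*' when that
    stratum's q is below ``alpha``. Status1 always occupies the middle token.
    """
    if healthy_sign not in ("U", "D"):
        raise ValueError(f"healthy_sign must be U or D, got {healthy_sign!r}")

    def token(r: float, q: float) -> str:
        if r == 0:
            # measure-zero tie: rendered as 'U' so the function stays total
            logger.warning("zero correlation encountered in encode_pattern")
        letter = "U" if r >= 0 else "D"
        return letter + ("*" if q < alpha else "")

    return f"{healthy_sign}_{token(r1, q1)}_{token(r2, q2)}"


def stratified_pair_correlations(
    mirna_matrix: ExpressionMatrix,
    mrna_matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    feature_name: str,
    pairs: Iterable[TargetPair],
    min_n: int = MIN_STRATUM_N,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-pair, per-stratum PCCs with p and BH-q for one feature.

    Samples are split by the feature's two statuses; within each stratum the
    correlation uses pairwise-complete observations (a sample is dropped for
    a pair only where either member is missing). Pairs whose ids are absent
    from the matrices, that retain fewer than ``min_n`` samples in a stratum,
    or that are constant within a stratum are dropped and counted in the
    returned counters (``unresolved_pairs``, ``insufficient_pairs``,
    ``degenerate_pairs``). q-values are BH-adjusted per stratum across all
    retained pairs.
    """
    if feature_name not in annotation.registry:
        raise ConfigurationError(f"feature {feature_name!r} not in annotation")
    s1_samples, s2_samples = annotation.strata(feature_name)
    counters = {"unresolved_pairs": 0, "insufficient_pairs": 0, "degenerate_pairs": 0}

    mirna_cols = {c: i for i, c in enumerate(mirna_matrix.col_ids)}
    mrna_cols = {c: i for i, c in enumerate(mrna_matrix.col_ids)}
    idx1 = [
        (mirna_cols[s], mrna_cols[s])
        for s in s1_samples
        if s in mirna_cols and s in mrna_cols
    ]
    idx2 = [
        (mirna_cols[s], mrna_cols[s])
        for s in s2_samples
        if s in mirna_cols and s in mrna_cols
    ]
    mi1 = np.array([i for i, _ in idx1], dtype=int)
    mr1 = np.array([j for _, j in idx1], dtype=int)
    mi2 = np.array([i for i, _ in idx2], dtype=int)
    mr2 = np.array([j for _, j in idx2], dtype=int)

    mirna_values = mirna_matrix.values
    mrna_values = mrna_matrix.values
    mirna_rows = {r: i for i, r in enumerate(mirna_matrix.row_ids)}
    mrna_rows = {r: i for i, r in enumerate(mrna_matrix.row_ids)}

    rows: list[dict] = []
    for pair in pairs:
        if pair.mirna_id not in mirna_rows or pair.mrna_id not in mrna_rows:
            counters["unresolved_pairs"] += 1
            continue
        x_full = mirna_values[mirna_rows[pair.mirna_id]]
        y_full = mrna_values[mrna_rows[pair.mrna_id]]
        stats_per_stratum = []
        for mi, mr in ((mi1, mr1), (mi2, mr2)):
            x = x_full[mi]
            y = y_full[mr]
            keep = ~(np.isnan(x) | np.isnan(y))
            x, y = x[keep], y[keep]
            if x.size < min_n:
                stats_per_stratum.append(None)
                continue
            try:
                r = pearson_r(x, y)
            except DegenerateDataError:
                stats_per_stratum.append("degenerate")
                continue
            stats_per_stratum.append((r, int(x.size), correlation_p_value(r, x.size)))
        if any(s == "degenerate" for s in stats_per_stratum):
            counters["degenerate_pairs"] += 1
            logger.warning("pair %s dropped: constant expression in a stratum", pair)
            continue
        if any(s is None for s in stats_per_stratum):
            counters["insufficient_pairs"] += 1
            continue
        (r1, n1, p1), (r2, n2, p2) = stats_per_stratum
        rows.append(
            {
                "mirna_id": pair.mirna_id,
                "mrna_id": pair.mrna_id,
                "healthy_sign": pair.healthy_sign,
                "r_status1": r1,
                "n_status1": n1,
                "p_status1": p1,
                "r_status2": r2,
                "n_status2": n2,
                "p_status2": p2,
            }
        )

    table = pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "mrna_id",
            "healthy_sign",
            "r_status1",
            "n_status1",
            "p_status1",
            "r_status2",
            "n_status2",
            "p_status2",
        ],
    )
    if len(table):
        table["q_status1"] = bh_adjust(table["p_status1"].to_numpy())
        table["q_status2"] = bh_adjust(table["p_status2"].to_numpy())
    else:
        table["q_status1"] = pd.Series(dtype=float)
        table["q_status2"] = pd.Series(dtype=float)
    return table, counters


def detect_mmpvs(
    mirna_matrix: ExpressionMatrix,
    mrna_matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    feature_name: str,
    pairs: Iterable[TargetPair],
    alpha: float = 0.05,
    fold: float = 2.0,
) -> tuple[list[MMPVRecord], dict[str, int]]:
    """Full detection for one feature: correlations, classification, patterns.

    Returns the detected records (classes ``sign_change``/``fold_change``
    only) and a summary with ``n_fold_change``, ``n_sign_change``,
    ``n_total`` plus the drop counters of
    :func:`stratified_pair_correlations`.
    """
    table, counters = stratified_pair_correlations(
        mirna_matrix, mrna_matrix, annotation, feature_name, pairs
    )
    records: list[MMPVRecord] = []
    for row in table.itertuples(index=False):
        label = classify_pair(
            row.r_status1, row.r_status2, row.q_status1, row.q_status2, alpha, fold
        )
        if label == "none":
            continue
        pattern = encode_pattern(
            row.healthy_sign,
            row.r_status1,
            row.q_status1,
            row.r_status2,
            row.q_status2,
            alpha,
        )
        records.append(
            MMPVRecord(
                pair=TargetPair(row.mirna_id, row.mrna_id, row.healthy_sign),
                corr_status1=StratumCorrelation(
                    row.r_status1, row.n_status1, row.p_status1, row.q_status1
                ),
                corr_status2=StratumCorrelation(
                    row.r_status2, row.n_status2, row.p_status2, row.q_status2
                ),
                mmpv_class=label,
                pattern=pattern,
                feature_name=feature_name,
            )
        )
    n_fold = sum(1 for r in records if r.mmpv_class == "fold_change")
    n_sign = sum(1 for r in records if r.mmpv_class == "sign_change")
    summary = {
        "feature": feature_name,
        "n_fold_change": n_fold,
        "n_sign_change": n_sign,
        "n_total": n_fold + n_sign,
        **counters,
    }
    return records, summary


def mmpv_table(records: Sequence[MMPVRecord]) -> pd.DataFrame:
    """Flatten MMPV records into the standard output table layout."""
    rows = [
        {
            "mirna_id": rec.pair.mirna_id,
            "mrna_id": rec.pair.mrna_id,
            "healthy_sign": rec.pair.healthy_sign,
            "r_status1": rec.corr_status1.r,
            "n_status1": rec.corr_status1.n,
            "p_status1": rec.corr_status1.p,
            "q_status1": rec.corr_status1.q,
            "r_status2": rec.corr_status2.r,
            "n_status2": rec.corr_status2.n,
            "p_status2": rec.corr_status2.p,
            "q_status2": rec.corr_status2.q,
            "mmpv_class": rec.mmpv_class,
            "pattern": rec.pattern,
            "feature": rec.feature_name,
        }
        for rec in records
    ]
    return pd.DataFrame(rows, columns=MMPV_TABLE_COLUMNS)


def read_mmpv_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(MMPV_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"MMPV table missing columns {sorted(missing)}")
    return table


def records_from_table(table: pd.DataFrame) -> list[MMPVRecord]:
    """Rebuild MMPV records from a table written by :func:`mmpv_table`."""
    return [
        MMPVRecord(
            pair=TargetPair(row.mirna_id, row.mrna_id, row.healthy_sign),
            corr_status1=StratumCorrelation(
                row.r_status1, int(row.n_status1), row.p_status1, row.q_status1
            ),
            corr_status2=StratumCorrelation(
                row.r_status2, int(row.n_status2), row.p_status2, row.q_status2
            ),
            mmpv_class=row.mmpv_class,
            pattern=row.pattern,
            feature_name=row.feature,
        )
        for row in table.itertuples(index=False)
    ]
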