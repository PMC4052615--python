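"""Permutation differential expression (SAM-style) and DE-MMPV selection.

Each entity (miRNA or mRNA) receives a moderated two-class statistic

    d = (mean(status1) - mean(status2)) / (s + s0)

where s is the unpaired pooled standard error of the mean difference and s0
is an exchangeability constant (the median of per-entity pooled standard
errors) that damps the inflation of d for entities with tiny variance. The
null distribution comes from random permutations of the status labels; the
empirical p-value uses the add-one correction

    p = (1 + #{b : |d_b| >= |d_obs|}) / (n_perm + 1)

so p is never zero and never below 1/(n_perm + 1). q-values are
Benjamini-Hochberg adjusted across all rows of a matrix. A DE-MMPV is a
detected pair whose miRNA and mRNA are both significant at q < alpha.

Direction convention: 'U' when mean(status1) > mean(status2), else 'D',
with status1 fixed by the feature registry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import MMPVRecord, bh_adjust
from .errors import (
    ConfigurationError,
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)
from .io_model import ExpressionMatrix, SampleAnnotation

DE_TABLE_COLUMNS = ["entity_id", "d", "p_perm", "q", "direction"]


@dataclass(frozen=True)
class DifferentialRecord:
    entity_id: str
    d: float
    p_perm: float
    q: float
    direction: str  # U | D


@dataclass(frozen=True)
class DEMMPVRecord:
    """An MMPV whose miRNA and mRNA are both differentially expressed."""

    mmpv: MMPVRecord
    mirna_diff: DifferentialRecord
    mrna_diff: DifferentialRecord

    def render(self) -> str:
        """Row in the `miRNA(dir) mRNA(dir) pattern` layout."""
        return (
            f"{self.mirna_diff.entity_id}({self.mirna_diff.direction})\t"
            f"{self.mrna_diff.entity_id}({self.mrna_diff.direction})\t"
            f"{self.mmpv.pattern}"
        )


def _pooled_se(group1: np.ndarray, group2: np.ndarray) -> float:
    n1, n2 = group1.size, group2.size
    ss1 = float(np.sum((group1 - group1.mean()) ** 2))
    ss2 = float(np.sum((group2 - group2.mean()) ** 2))
    pooled_var = (ss1 + ss2) / (n1 + n2 - 2)
    return float(np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2)))


def sam_d_statistic(
    group1: Sequence[float], group2: Sequence[float], s0: float
) -> float:
    """Moderated difference-of-means statistic d = (m1 - m2) / (s + s0)."""
    if s0 <= 0:
        raise ValueError(f"s0 must be positive, got {s0}")
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise InsufficientDataError("each group needs >= 2 observations")
    s = _pooled_se(g1, g2)
    return float((g1.mean() - g2.mean()) / (s + s0))


def choose_s0(standard_errors: Sequence[float]) -> float:
    """Exchangeability constant: median per-entity SE, forced positive.

    Falls back to the smallest strictly positive SE when the median is 0;
    all-zero input is degenerate.
    """
    se = np.asarray(standard_errors, dtype=float)
    if se.size == 0:
        raise ValueError("empty standard-error vector")
    med = float(np.median(se))
    if med > 0:
        return med
    positive = se[se > 0]
    if positive.size == 0:
        raise DegenerateDataError("all standard errors are zero")
    return float(positive.min())


def _matrix_d(
    values: np.ndarray, mask1: np.ndarray, mask2: np.ndarray, s0: float
) -> np.ndarray:
    """Vectorised d over matrix rows for one labelling, NaN-aware."""
    with np.errstate(invalid="ignore"):
        x1, x2 = values[:, mask1], values[:, mask2]
        n1 = np.sum(~np.isnan(x1), axis=1)
        n2 = np.sum(~np.isnan(x2), axis=1)
        m1 = np.nanmean(x1, axis=1)
        m2 = np.nanmean(x2, axis=1)
        ss1 = np.nansum((x1 - m1[:, None]) ** 2, axis=1)
        ss2 = np.nansum((x2 - m2[:, None]) ** 2, axis=1)
        pooled_var = (ss1 + ss2) / (n1 + n2 - 2)
        s = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
        d = (m1 - m2) / (s + s0)
        d[(n1 < 2) | (n2 < 2)] = np.nan
    return d


def permutation_p_values(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    feature_name: str,
    n_perm: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Observed d and permutation p for every row of the matrix.

    Status labels are permuted uniformly at random ``n_perm`` times; d is
    recomputed with the same s0 as observed. Deterministic given ``rng``.
    Returns columns entity_id, d, p_perm, direction (q left to
    :func:`differential_table`).
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    if feature_name not in annotation.registry:
        raise ConfigurationError(f"feature {feature_name!r} not in annotation")
    s1, s2 = annotation.strata(feature_name)
    cols = {c: i for i, c in enumerate(matrix.col_ids)}
    idx1 = np.array([cols[s] for s in s1 if s in cols], dtype=int)
    idx2 = np.array([cols[s] for s in s2 if s in cols], dtype=int)
    if idx1.size < 2 or idx2.size < 2:
        raise ConfigurationError(
            f"each stratum of {feature_name!r} needs >= 2 samples present in "
            f"the matrix (got {idx1.size} and {idx2.size})"
        )
    values = matrix.values[:, np.concatenate([idx1, idx2])]
    n1, n_all = idx1.size, idx1.size + idx2.size
    mask1 = np.zeros(n_all, dtype=bool)
    mask1[:n1] = True

    # per-row pooled SEs under the observed labels fix s0 for all permutations
    with np.errstate(invalid="ignore"):
        x1, x2 = values[:, mask1], values[:, ~mask1]
        c1 = np.sum(~np.isnan(x1), axis=1)
        c2 = np.sum(~np.isnan(x2), axis=1)
        ss1 = np.nansum((x1 - np.nanmean(x1, axis=1)[:, None]) ** 2, axis=1)
        ss2 = np.nansum((x2 - np.nanmean(x2, axis=1)[:, None]) ** 2, axis=1)
        ses = np.sqrt((ss1 + ss2) / (c1 + c2 - 2) * (1.0 / c1 + 1.0 / c2))
    s0 = choose_s0(ses[np.isfinite(ses)])

    d_obs = _matrix_d(values, mask1, ~mask1, s0)
    exceed = np.zeros(values.shape[0], dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(n_all)
        pm1 = np.zeros(n_all, dtype=bool)
        pm1[perm[:n1]] = True
        d_b = _matrix_d(values, pm1, ~pm1, s0)
        with np.errstate(invalid="ignore"):
            exceed += (np.abs(d_b) >= np.abs(d_obs)).astype(int)
    p_perm = (1.0 + exceed) / (n_perm + 1.0)
    p_perm[~np.isfinite(d_obs)] = np.nan

    with np.errstate(invalid="ignore"):
        m1 = np.nanmean(values[:, mask1], axis=1)
        m2 = np.nanmean(values[:, ~mask1], axis=1)
    direction = np.where(m1 > m2, "U", "D")
    return pd.DataFrame(
        {
            "entity_id": matrix.row_ids,
            "d": d_obs,
            "p_perm": p_perm,
            "direction": direction,
        }
    )


def differential_table(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    feature_name: str,
    n_perm: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Permutation p-values plus BH q across all rows of the matrix."""
    table = permutation_p_values(matrix, annotation, feature_name, n_perm, rng)
    valid = table["p_perm"].notna()
    q = np.full(len(table), np.nan)
    if valid.any():
        q[valid.to_numpy()] = bh_adjust(table.loc[valid, "p_perm"].to_numpy())
    table["q"] = q
    return table[DE_TABLE_COLUMNS[:2] + ["p_perm", "q", "direction"]]


def select_de_mmpvs(
    mmpvs: Sequence[MMPVRecord],
    mirna_table: pd.DataFrame,
    mrna_table: pd.DataFrame,
    alpha: float = 0.05,
) -> list[DEMMPVRecord]:
    """Keep MMPVs whose miRNA AND mRNA reach q < alpha, attaching both records."""
    mirna_idx = mirna_table.set_index("entity_id")
    mrna_idx = mrna_table.set_index("entity_id")
    out: list[DEMMPVRecord] = []
    for rec in mmpvs:
        for entity, idx in ((rec.pair.mirna_id, mirna_idx), (rec.pair.mrna_id, mrna_idx)):
            if entity not in idx.index:
                raise ValidationError(
                    f"entity {entity!r} of an MMPV is missing from its "
                    "differential table"
                )
        mi = mirna_idx.loc[rec.pair.mirna_id]
        mr = mrna_idx.loc[rec.pair.mrna_id]
        if mi["q"] < alpha and mr["q"] < alpha:
            out.append(
                DEMMPVRecord(
                    mmpv=rec,
                    mirna_diff=DifferentialRecord(
                        rec.pair.mirna_id,
                        float(mi["d"]),
                        float(mi["p_perm"]),
                        float(mi["q"]),
                        str(mi["direction"]),
                    ),
                    mrna_diff=DifferentialRecord(
                        rec.pair.mrna_id,
                        float(mr["d"]),
                        float(mr["p_perm"]),
                        float(mr["q"]),
                        str(mr["direction"]),
                    ),
                )
            )
    return out


def de_mmpv_table(records: Sequence[DEMMPVRecord]) -> pd.DataFrame:
    """DE-MMPV rows in the `feature, miRNA(dir), mRNA(dir), pattern` layout."""
    rows = [
        {
            "feature": rec.mmpv.feature_name,
            "mirna": f"{rec.mirna_diff.entity_id}({rec.mirna_diff.direction})",
            "mrna": f"{rec.mrna_diff.entity_id}({rec.mrna_diff.direction})",
            "pattern": rec.mmpv.pattern,
        }
        for rec in records
    ]
    return pd.DataFrame(rows, columns=["feature", "mirna", "mrna", "pattern"])
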