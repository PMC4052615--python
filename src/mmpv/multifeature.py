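"""Cross-feature MMPV overlap counting and two-feature shared-gene extraction.

Pairs detected for several biopathological features point at regulation that
is not specific to one stratifier; the overlap matrix counts, for every
feature pair, how many detected (miRNA, mRNA) pairs they share.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Set, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError

Pair = Tuple[str, str]


@dataclass(frozen=True)
class OverlapMatrix:
    """Symmetric pairwise overlap counts; diagonal = per-feature MMPV counts."""

    features: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        assert self.counts.shape == (len(self.features),) * 2
        assert np.array_equal(self.counts, self.counts.T), "overlap must be symmetric"

    def overlap(self, feature_a: str, feature_b: str) -> int:
        i = self.features.index(feature_a)
        j = self.features.index(feature_b)
        return int(self.counts[i, j])

    def to_long(self) -> pd.DataFrame:
        """Long-form `feature_1, feature_2, overlap` layout (off-diagonal)."""
        rows = [
            {
                "feature_1": self.features[i],
                "feature_2": self.features[j],
                "overlap": int(self.counts[i, j]),
            }
            for i in range(len(self.features))
            for j in range(i + 1, len(self.features))
        ]
        return pd.DataFrame(rows, columns=["feature_1", "feature_2", "overlap"])


def overlap_counts(
    mmpvs_by_feature: Mapping[str, Set[Pair]], on: str = "pair"
) -> OverlapMatrix:
    """Pairwise intersection sizes between per-feature MMPV sets.

    ``on='pair'`` counts (miRNA, mRNA) pair identity; ``on='mrna'`` counts
    distinct target mRNAs instead.
    """
    if not mmpvs_by_feature:
        raise ConfigurationError("need at least one feature")
    if on not in ("pair", "mrna"):
        raise ValueError(f"unknown overlap unit {on!r}")
    features = tuple(mmpvs_by_feature)
    sets = [
        set(mmpvs_by_feature[f])
        if on == "pair"
        else {mrna for _, mrna in mmpvs_by_feature[f]}
        for f in features
    ]
    k = len(features)
    counts = np.zeros((k, k), dtype=int)
    for i in range(k):
        counts[i, i] = len(sets[i])
        for j in range(i + 1, k):
            counts[i, j] = counts[j, i] = len(sets[i] & sets[j])
    return OverlapMatrix(features=features, counts=counts)


def two_feature_genes(
    mmpvs_by_feature: Mapping[str, Set[Pair]],
    feature_a: str,
    feature_b: str,
    exclude_others: bool = False,
) -> set[str]:
    """mRNAs of pairs detected under both features.

    With ``exclude_others`` the result keeps only mRNAs none of whose
    miRNA partners (within the shared pairs) appear in any third feature's
    MMPVs — an exclusivity reading of "closely associated with exactly these
    two features". The permissive reading (``False``) returns all shared
    mRNAs.
    """
    for f in (feature_a, feature_b):
        if f not in mmpvs_by_feature:
            raise ConfigurationError(f"feature {f!r} not present")
    shared = set(mmpvs_by_feature[feature_a]) & set(mmpvs_by_feature[feature_b])
    if not exclude_others:
        return {mrna for _, mrna in shared}
    other_mirnas = {
        mirna
        for feat, pairs in mmpvs_by_feature.items()
        if feat not in (feature_a, feature_b)
        for mirna, _ in pairs
    }
    return {mrna for mirna, mrna in shared if mirna not in other_mirnas}
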