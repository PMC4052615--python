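"""Hypergeometric term enrichment of MMPV target-gene sets.

The background universe is the set of all mRNAs appearing in the supplied
validated targeting-pair list, not the whole genome: enrichment is asked
relative to what could have been detected at all. Each term's p is the
upper-tail hypergeometric probability P(X >= k) of drawing k or more term
genes when n target genes are sampled without replacement from the N
background genes of which K belong to the term. Terms are reported below a
raw-p threshold (default 1e-3) with a BH-adjusted column included for
information only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Set

from scipy import stats

from .core import bh_adjust
from .errors import ValidationError
from .io_model import TermMap


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # target genes in the term
    K: int  # term size within the background
    n: int  # target size
    N: int  # background size
    p: float
    q_info: float  # BH across all tested terms; informational only


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Delegates to the log-space survival function of
    :data:`scipy.stats.hypergeom` for numerical stability.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def enrich_terms(
    target_genes: Set[str],
    background_genes: Set[str],
    term_map: TermMap,
    p_threshold: float = 1e-3,
) -> list[EnrichmentResult]:
    """Terms over-represented in the target set at p < ``p_threshold``.

    Term gene sets are intersected with the background before counting;
    the target must be a subset of the background. Results are sorted by
    ascending p (ties by term_id).
    """
    stray = set(target_genes) - set(background_genes)
    if stray:
        raise ValidationError(
            f"target genes outside the background: {sorted(stray)[:5]}"
        )
    N = len(background_genes)
    n = len(target_genes)
    tested: list[EnrichmentResult] = []
    for term_id, (term_name, genes) in sorted(term_map.items()):
        in_background = genes & set(background_genes)
        if not in_background:
            continue
        K = len(in_background)
        k = len(in_background & set(target_genes))
        p = hypergeometric_p(k, K, n, N)
        tested.append(EnrichmentResult(term_id, term_name, k, K, n, N, p, q_info=1.0))
    if not tested:
        return []
    qs = bh_adjust([t.p for t in tested])
    tested = [
        EnrichmentResult(t.term_id, t.term_name, t.k, t.K, t.n, t.N, t.p, float(q))
        for t, q in zip(tested, qs)
    ]
    hits = [t for t in tested if t.p < p_threshold]
    return sorted(hits, key=lambda t: (t.p, t.term_id))


def enrichment_table(results: Sequence[EnrichmentResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p": r.p,
                "q_info": r.q_info,
            }
            for r in results
        ],
        columns=["term_id", "term_name", "k", "K", "n", "N", "p", "q_info"],
    )
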