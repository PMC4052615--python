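"""Synthetic paired miRNA/mRNA expression with known correlation structure.

Each targeting pair is simulated from a bivariate normal on the log scale:
within each status stratum the (miRNA, mRNA) values share a specified
population correlation, a common standard deviation, and stratum means that
may differ (differential expression). The generator records the
ground-truth class of every pair — the label the detection stage should
assign given the population correlations, significance aside — so that
sensitivity and false-discovery behaviour can be measured exactly.

Seeding uses one master seed; each pair draws from a substream derived from
(seed, pair index), so adding pairs to a spec never perturbs earlier pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .core import classify_pair
from .errors import ValidationError
from .io_model import ExpressionMatrix, SampleAnnotation, TargetPair

BASE_MEAN = 8.0  # typical log2 array intensity; status2 sits at this baseline

TRUTH_COLUMNS = ["mirna_id", "mrna_id", "rho_status1", "rho_status2", "expected_class"]
TRUTH_CLASSES = {"sign_change", "fold_change", "none"}


@dataclass(frozen=True)
class PairSpec:
    """Generative parameters for one targeting pair.

    ``rho_status1``/``rho_status2``: population correlations per stratum,
    in (-1, 1). ``delta_mirna``/``delta_mrna``: mean shift of status1 minus
    status2 (log-scale units). ``noise_sd``: common within-stratum standard
    deviation.
    """

    pair: TargetPair
    rho_status1: float
    rho_status2: float
    delta_mirna: float = 0.0
    delta_mrna: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        for rho in (self.rho_status1, self.rho_status2):
            if not -1.0 < rho < 1.0:
                raise ValidationError(f"|rho| must be < 1, got {rho}")
        if self.noise_sd <= 0:
            raise ValidationError(f"noise_sd must be positive, got {self.noise_sd}")


@dataclass(frozen=True)
class DatasetSpec:
    """A full simulated study: stratum sizes, pairs, feature name, seed."""

    n_status1: int
    n_status2: int
    pair_specs: tuple[PairSpec, ...]
    feature_name: str = "ER"
    seed: int = 0
    share_entities: bool = False  # allow one miRNA to target several mRNAs

    def __post_init__(self) -> None:
        if self.n_status1 < 3 or self.n_status2 < 3:
            raise ValidationError("each stratum needs >= 3 samples")
        if not self.share_entities:
            mirnas = [ps.pair.mirna_id for ps in self.pair_specs]
            mrnas = [ps.pair.mrna_id for ps in self.pair_specs]
            ids = mirnas + mrnas
            if len(set(ids)) != len(ids):
                raise ValidationError(
                    "entity ids must be distinct across pair_specs "
                    "(set share_entities=True for pleiotropic designs)"
                )

    @classmethod
    def from_yaml(cls, path) -> "DatasetSpec":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        specs = tuple(
            PairSpec(
                pair=TargetPair(p["mirna"], p["mrna"], p["healthy_sign"]),
                rho_status1=float(p["rho_status1"]),
                rho_status2=float(p["rho_status2"]),
                delta_mirna=float(p.get("delta_mirna", 0.0)),
                delta_mrna=float(p.get("delta_mrna", 0.0)),
                noise_sd=float(p.get("noise_sd", 1.0)),
            )
            for p in doc["pairs"]
        )
        return cls(
            n_status1=int(doc["n_status1"]),
            n_status2=int(doc["n_status2"]),
            pair_specs=specs,
            feature_name=str(doc.get("feature", "ER")),
            seed=int(doc.get("seed", 0)),
            share_entities=bool(doc.get("share_entities", False)),
        )


def sample_bivariate_pair(
    rho: float,
    n: int,
    mean_x: float,
    mean_y: float,
    sd: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n observations from a bivariate normal with correlation rho.

    Both marginals share ``sd``. The draw is deterministic given the
    generator state (Cholesky construction from two standard-normal vectors).
    """
    if not -1.0 < rho < 1.0:
        raise ValidationError(f"|rho| must be < 1, got {rho}")
    if n < 2:
        raise ValidationError(f"n must be >= 2, got {n}")
    if sd <= 0:
        raise ValidationError(f"sd must be positive, got {sd}")
    z = rng.standard_normal((2, n))
    x = mean_x + sd * z[0]
    y = mean_y + sd * (rho * z[0] + np.sqrt(1.0 - rho * rho) * z[1])
    return x, y


def expected_class(rho1: float, rho2: float, fold: float = 2.0) -> str:
    """Ground-truth label from population correlations, significance ignored.

    Shares the decision rule with :func:`mmpv.core.classify_pair` by passing
    q = 0 for both strata (every population correlation counts as
    significant), so truth labels and the detector can never drift apart.
    """
    return classify_pair(rho1, rho2, 0.0, 0.0, alpha=0.05, fold=fold)


def simulate_dataset(
    spec: DatasetSpec,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SampleAnnotation, pd.DataFrame]:
    """Generate (miRNA matrix, mRNA matrix, annotation, truth table).

    Samples s1..s(n1) receive status1 of the feature, the remainder status2.
    Per pair, each stratum is drawn with its own population correlation;
    status1 means are shifted by the deltas relative to the status2 baseline.
    The truth table carries the population correlations and expected class
    per pair.
    """
    n1, n2 = spec.n_status1, spec.n_status2
    samples = [f"s{i}" for i in range(1, n1 + n2 + 1)]

    mirna_rows: dict[str, np.ndarray] = {}
    mirna_drivers: dict[str, np.ndarray] = {}  # standard-normal driver per miRNA
    mrna_rows: dict[str, np.ndarray] = {}
    truth_rows = []
    for index, ps in enumerate(spec.pair_specs):
        rng = np.random.default_rng([spec.seed, index])
        zx = rng.standard_normal(n1 + n2)
        zy = rng.standard_normal(n1 + n2)
        mirna_id = ps.pair.mirna_id
        if mirna_id in mirna_rows:
            if not spec.share_entities:
                raise ValidationError(f"duplicate miRNA id {mirna_id!r}")
            # pleiotropic miRNA: reuse its driver so this pair's correlation
            # with the already-emitted expression row is still rho
            zx = mirna_drivers[mirna_id]
        else:
            x = BASE_MEAN + ps.noise_sd * zx
            x[:n1] += ps.delta_mirna
            mirna_rows[mirna_id] = x
            mirna_drivers[mirna_id] = zx
        if ps.pair.mrna_id in mrna_rows:
            raise ValidationError(f"duplicate mRNA id {ps.pair.mrna_id!r}")
        y = np.empty(n1 + n2)
        for sl, rho in ((slice(0, n1), ps.rho_status1), (slice(n1, None), ps.rho_status2)):
            y[sl] = ps.noise_sd * (
                rho * zx[sl] + np.sqrt(1.0 - rho * rho) * zy[sl]
            )
        y += BASE_MEAN
        y[:n1] += ps.delta_mrna
        mrna_rows[ps.pair.mrna_id] = y
        truth_rows.append(
            {
                "mirna_id": ps.pair.mirna_id,
                "mrna_id": ps.pair.mrna_id,
                "rho_status1": ps.rho_status1,
                "rho_status2": ps.rho_status2,
                "expected_class": expected_class(ps.rho_status1, ps.rho_status2),
            }
        )

    mirna_matrix = ExpressionMatrix(
        pd.DataFrame(mirna_rows, index=samples).T.astype(float)
    )
    mrna_matrix = ExpressionMatrix(
        pd.DataFrame(mrna_rows, index=samples).T.astype(float)
    )
    s1_name = f"{spec.feature_name}+"
    s2_name = f"{spec.feature_name}-"
    annotation = SampleAnnotation(
        registry={spec.feature_name: (s1_name, s2_name)},
        assignments={
            s: {spec.feature_name: s1_name if i < n1 else s2_name}
            for i, s in enumerate(samples)
        },
    )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return mirna_matrix, mrna_matrix, annotation, truth


def write_truth_table(truth: pd.DataFrame, path) -> None:
    """Write the truth table as TSV; class strings are validated first."""
    if list(truth.columns) != TRUTH_COLUMNS:
        raise ValidationError(f"truth table must have columns {TRUTH_COLUMNS}")
    bad = set(truth["expected_class"]) - TRUTH_CLASSES
    if bad:
        raise ValidationError(f"invalid expected_class values: {sorted(bad)}")
    truth.to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t")
    if list(truth.columns) != TRUTH_COLUMNS:
        raise ValidationError(f"truth table must have columns {TRUTH_COLUMNS}")
    return truth


# --- convenience generators for the downstream stages -----------------------


def simulate_ppi_graph(
    genes: Sequence[str], n_extra: int = 200, m: int = 2, seed: int = 0
) -> nx.Graph:
    """Scale-free interaction network over ``genes`` plus background nodes.

    A Barabasi-Albert graph gives the heavy-tailed degree distribution
    typical of curated PPI databases; the supplied genes are mapped onto the
    highest-degree nodes last-to-first so hub enrichment can be planted by
    ordering ``genes``.
    """
    total = len(genes) + n_extra
    graph = nx.barabasi_albert_graph(total, m, seed=seed)
    by_degree = sorted(graph.nodes, key=lambda v: (-graph.degree(v), v))
    mapping = {}
    for rank, gene in enumerate(genes):
        mapping[by_degree[rank]] = gene
    for i, node in enumerate(v for v in by_degree if v not in mapping):
        mapping[node] = f"BG{i + 1}"
    return nx.relabel_nodes(graph, mapping)


def simulate_term_map(
    background: Sequence[str],
    enriched_genes: Sequence[str],
    n_null_terms: int = 10,
    term_size: int = 15,
    seed: int = 0,
):
    """Term map with one term equal to ``enriched_genes`` plus random terms."""
    from .io_model import TermMap

    rng = np.random.default_rng(seed)
    terms = {"T0001": ("planted_process", frozenset(enriched_genes))}
    pool = list(background)
    for k in range(n_null_terms):
        size = min(term_size, len(pool))
        members = rng.choice(pool, size=size, replace=False)
        terms[f"T{k + 2:04d}"] = (f"random_process_{k + 1}", frozenset(members))
    return TermMap(terms=terms)
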