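"""Domain types and TSV readers/writers for the pipeline's tabular inputs.

The pipeline operates on four kinds of input:

* paired expression matrices (miRNAs x samples and mRNAs x samples,
  log-scale intensities, missing cells allowed),
* a sample annotation assigning each sample one of two statuses per binary
  biopathological feature (e.g. ER+/ER-),
* a list of experimentally validated miRNA-mRNA targeting pairs, each
  carrying the sign of its regulatory pattern in the healthy population
  (U = positive, D = negative),
* optionally a protein-protein-interaction edge list and a term -> gene
  annotation map for the downstream network and enrichment stages.

All files are UTF-8 TSV with a header row. Expression matrices use "." or
the empty string for missing cells.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Literal, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DuplicateIdError, ParseError, ValidationError

_MISSING = ["", "."]

# The literature mixes "hsa-miR-375", "has-mir-375" etc.; identifier
# matching is exact afterwards, so spelling is unified once at read time.
_MIR_PREFIX = re.compile(r"^(?:hsa|has)[-_]mi[rR]", re.IGNORECASE)


def normalize_id(identifier: str) -> str:
    """Trim whitespace and unify the 'hsa-miR' prefix spelling."""
    s = identifier.strip()
    return _MIR_PREFIX.sub("hsa-miR", s)


class TargetPair(NamedTuple):
    """A validated miRNA->mRNA targeting pair with its healthy-population sign.

    ``healthy_sign`` is 'U' when the pair shows positive regulation in the
    healthy population and 'D' when negative.
    """

    mirna_id: str
    mrna_id: str
    healthy_sign: str


@dataclass(frozen=True)
class ExpressionMatrix:
    """Named entities x named samples of log-scale expression, NaN = missing."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate row ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate sample ids: {dups[:5]}")

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def row(self, row_id: str) -> np.ndarray:
        return self.data.loc[row_id].to_numpy(dtype=float)

    def __contains__(self, row_id: str) -> bool:
        return row_id in self.data.index

    def write(self, path) -> None:
        out = self.data.copy()
        out.index.name = "id"
        out.to_csv(path, sep="\t", na_rep="")


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample binary status per feature plus the feature registry.

    ``registry`` maps each feature name to the display names of its two
    statuses; the first entry is "status1" and fixes the ordering used in
    pattern strings (the middle token is always status1).
    """

    registry: dict[str, tuple[str, str]]
    assignments: dict[str, dict[str, str]]  # sample -> feature -> status name

    def features(self) -> list[str]:
        return list(self.registry)

    def strata(self, feature: str) -> tuple[list[str], list[str]]:
        """Samples annotated with status1 and status2 of ``feature``, in order."""
        if feature not in self.registry:
            raise ValidationError(f"unknown feature {feature!r}")
        s1_name, s2_name = self.registry[feature]
        s1, s2 = [], []
        for sample, fmap in self.assignments.items():
            status = fmap.get(feature)
            if status == s1_name:
                s1.append(sample)
            elif status == s2_name:
                s2.append(sample)
        return s1, s2

    def with_swapped_statuses(self, feature: str) -> "SampleAnnotation":
        """Registry with status1/status2 of ``feature`` exchanged (assignments kept)."""
        reg = dict(self.registry)
        s1, s2 = reg[feature]
        reg[feature] = (s2, s1)
        return SampleAnnotation(registry=reg, assignments=self.assignments)

    def write(self, path) -> None:
        rows = [
            (sample, feat, status)
            for sample, fmap in self.assignments.items()
            for feat, status in fmap.items()
        ]
        pd.DataFrame(rows, columns=["sample_id", "feature", "status"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class TermMap:
    """Flat term_id -> (term_name, gene set) annotation map (no hierarchy)."""

    terms: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for term_id, (_, genes) in self.terms.items():
            if not genes:
                raise ValidationError(f"term {term_id!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.terms)

    def items(self):
        return self.terms.items()


PPIGraph = nx.Graph


def read_expression_matrix(
    path, collapse: Literal["none", "mean", "max_variance"] = "none"
) -> ExpressionMatrix:
    """Read an entities x samples TSV; optionally collapse duplicate row ids.

    ``collapse='mean'`` averages duplicate rows element-wise (ignoring
    missing cells); ``'max_variance'`` keeps the duplicate row with the
    largest variance across samples, which preserves the most correlation
    signal when several probes map to one gene symbol. With ``'none'``,
    duplicate ids raise :class:`DuplicateIdError`.
    """
    if collapse not in ("none", "mean", "max_variance"):
        raise ValueError(f"unknown collapse mode {collapse!r}")
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    raw.index = [normalize_id(str(i)) for i in raw.index]
    raw.columns = [str(c).strip() for c in raw.columns]

    body = raw.replace(dict.fromkeys(_MISSING, np.nan))
    try:
        data = body.astype(float)
    except ValueError:
        for j, col in enumerate(body.columns):
            for i, cell in enumerate(body[col]):
                if isinstance(cell, str):
                    try:
                        float(cell)
                    except ValueError:
                        raise ParseError(
                            f"non-numeric cell {cell!r} at row {body.index[i]!r} "
                            f"(line {i + 2}), column {col!r} (field {j + 2})"
                        ) from None
        raise  # pragma: no cover - unreachable: some cell must have failed

    if data.index.has_duplicates:
        if collapse == "none":
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise DuplicateIdError(
                f"duplicate row ids with collapse='none': {dups[:5]}"
            )
        order = list(dict.fromkeys(data.index))
        if collapse == "mean":
            data = data.groupby(level=0, sort=False).mean().loc[order]
        else:  # max_variance; ties keep the first occurrence
            keep = []
            for rid in order:
                block = data.loc[[rid]]
                variances = block.var(axis=1, ddof=1).fillna(-np.inf).to_numpy()
                keep.append(block.iloc[[int(np.argmax(variances))]])
            data = pd.concat(keep)
    return ExpressionMatrix(data=data)


def read_sample_annotations(
    path, registry: dict[str, tuple[str, str]] | None = None
) -> SampleAnnotation:
    """Read a sample_id/feature/status TSV.

    When ``registry`` is given, every status string must match one of the two
    registered names for its feature. Without a registry, one is inferred:
    per feature, the first status string encountered becomes status1.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["sample_id", "feature", "status"]
    if list(table.columns) != expected:
        raise ParseError(
            f"annotation header must be {expected}, got {list(table.columns)}"
        )
    inferred: dict[str, list[str]] = {}
    assignments: dict[str, dict[str, str]] = {}
    for line_no, row in enumerate(table.itertuples(index=False), start=2):
        sample, feature, status = (
            str(row.sample_id).strip(),
            str(row.feature).strip(),
            str(row.status).strip(),
        )
        if registry is not None:
            if feature not in registry:
                raise ValidationError(
                    f"line {line_no}: feature {feature!r} not in registry"
                )
            if status not in registry[feature]:
                raise ValidationError(
                    f"line {line_no}: status {status!r} not in "
                    f"{registry[feature]} for feature {feature!r}"
                )
        else:
            seen = inferred.setdefault(feature, [])
            if status not in seen:
                if len(seen) == 2:
                    raise ValidationError(
                        f"line {line_no}: third status {status!r} for binary "
                        f"feature {feature!r} (already {seen})"
                    )
                seen.append(status)
        prev = assignments.setdefault(sample, {})
        if feature in prev and prev[feature] != status:
            raise ValidationError(
                f"line {line_no}: sample {sample!r} annotated with two "
                f"statuses for feature {feature!r}"
            )
        prev[feature] = status
    if registry is None:
        registry = {
            feat: (names[0], names[1] if len(names) > 1 else names[0] + "_other")
            for feat, names in inferred.items()
        }
    return SampleAnnotation(registry=registry, assignments=assignments)


def read_pair_list(path) -> list[TargetPair]:
    """Read a mirna_id/mrna_id/healthy_sign TSV into unique pairs, file order."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["mirna_id", "mrna_id", "healthy_sign"]
    if list(table.columns) != expected:
        raise ParseError(
            f"pair-list header must be {expected}, got {list(table.columns)}"
        )
    pairs: list[TargetPair] = []
    seen: set[tuple[str, str]] = set()
    for line_no, row in enumerate(table.itertuples(index=False), start=2):
        mirna = normalize_id(str(row.mirna_id))
        mrna = str(row.mrna_id).strip()
        sign = str(row.healthy_sign).strip()
        if sign not in ("U", "D"):
            raise ValidationError(
                f"line {line_no}: healthy_sign must be U or D, got {sign!r}"
            )
        key = (mirna, mrna)
        if key in seen:
            raise DuplicateIdError(f"line {line_no}: duplicate pair {key}")
        seen.add(key)
        pairs.append(TargetPair(mirna, mrna, sign))
    return pairs


def write_pair_list(pairs: Iterable[TargetPair], path) -> None:
    pd.DataFrame(pairs, columns=["mirna_id", "mrna_id", "healthy_sign"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path) -> PPIGraph:
    """Read a two-column gene_a/gene_b TSV into an undirected graph.

    Repeated edges (in either orientation) are deduplicated; self-loops are
    permitted and contribute 1 to a node's degree under the distinct-neighbour
    convention used by :func:`mmpv.network.degree_map`.
    """
    graph = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header and len(header.rstrip("\n").split("\t")) != 2:
            raise ParseError("edge-list header must have exactly 2 fields")
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"line {line_no}: expected 2 fields, got {len(fields)}"
                )
            graph.add_edge(fields[0].strip(), fields[1].strip())
    return graph


def write_edge_list(graph: PPIGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in graph.edges():
            fh.write(f"{a}\t{b}\n")


def read_term_map(path) -> TermMap:
    """Read a term_id/term_name/gene TSV (one gene per line) into gene sets."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["term_id", "term_name", "gene"]
    if list(table.columns) != expected:
        raise ParseError(
            f"term-map header must be {expected}, got {list(table.columns)}"
        )
    names: dict[str, str] = {}
    genes: dict[str, set[str]] = {}
    for line_no, row in enumerate(table.itertuples(index=False), start=2):
        term_id = str(row.term_id).strip()
        gene = str(row.gene).strip()
        if not gene or gene.lower() == "nan":
            raise ValidationError(f"line {line_no}: blank gene symbol")
        names[term_id] = str(row.term_name).strip()
        genes.setdefault(term_id, set()).add(gene)
    return TermMap(
        terms={tid: (names[tid], frozenset(genes[tid])) for tid in genes}
    )


def write_term_map(term_map: TermMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_id\tterm_name\tgene\n")
        for term_id, (name, genes) in term_map.items():
            for gene in sorted(genes):
                fh.write(f"{term_id}\t{name}\t{gene}\n")
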