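"""Stage orchestration: shared config, deterministic seeding, run manifest.

Stages run in the fixed order simulate -> detect -> de -> overlap -> enrich
-> network. Each stage writes TSV/JSON artifacts into the output directory
and registers them (with a content hash and row count) in ``manifest.json``.
A stage that needs an upstream artifact accepts it either from the same run
or from a previous run's files in the output directory; otherwise a
:class:`MissingDependencyError` names the stage to run first.

All randomness flows from the single config seed: each (stage, feature)
combination draws from its own deterministic substream, so runs with the
same config and seed produce byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import core, differential, enrichment, multifeature, network, synth
from .errors import ConfigurationError, MissingDependencyError
from .io_model import (
    read_edge_list,
    read_expression_matrix,
    read_pair_list,
    read_sample_annotations,
    read_term_map,
)

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "detect", "de", "overlap", "enrich", "network"]


@dataclass
class PipelineConfig:
    """All knobs of a run; thresholds default to the standard settings
    (alpha 0.05, PCC fold ratio 2, 200 permutations, enrichment p 1e-3)."""

    out_dir: Path
    seed: int = 0
    alpha: float = 0.05
    fold: float = 2.0
    n_perm: int = 200
    p_threshold: float = 1e-3
    features: list[str] = field(default_factory=list)
    dataset_spec: Path | None = None  # for the simulate stage
    mirna_path: Path | None = None
    mrna_path: Path | None = None
    annotation_path: Path | None = None
    pairs_path: Path | None = None
    edges_path: Path | None = None
    terms_path: Path | None = None
    collapse: str = "max_variance"
    exclude_others: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0,1), got {self.alpha}")
        if self.fold <= 1:
            raise ConfigurationError(f"fold must exceed 1, got {self.fold}")
        if self.n_perm < 1:
            raise ConfigurationError(f"n_perm must be >= 1, got {self.n_perm}")
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        base = Path(path).parent
        kwargs = {}
        for key in (
            "seed",
            "alpha",
            "fold",
            "n_perm",
            "p_threshold",
            "features",
            "collapse",
            "exclude_others",
        ):
            if key in doc:
                kwargs[key] = doc[key]
        for key in (
            "out_dir",
            "dataset_spec",
            "mirna_path",
            "mrna_path",
            "annotation_path",
            "pairs_path",
            "edges_path",
            "terms_path",
        ):
            if key in doc and doc[key] is not None:
                kwargs[key] = base / doc[key]
        if "out_dir" not in kwargs:
            raise ConfigurationError("config must set out_dir")
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Run:
    """Mutable state threaded through the stages of one run_pipeline call."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.files: dict[str, dict] = {}
        self.mirna = None
        self.mrna = None
        self.annotation = None
        self.pairs = None
        self.mmpvs: dict[str, list[core.MMPVRecord]] = {}
        self.summaries: dict[str, dict] = {}

    def register(self, path: Path, n_rows: int | None = None) -> None:
        self.files[path.name] = {"sha256": _sha256(path), "rows": n_rows}

    # --- lazy input resolution ------------------------------------------

    def _resolve(self, attr: str, config_path, out_name: str, reader, stage: str):
        value = getattr(self, attr)
        if value is not None:
            return value
        candidate = Path(config_path) if config_path else self.out / out_name
        if not candidate.exists():
            raise MissingDependencyError(
                f"stage {stage!r} needs {out_name} — run 'simulate' first or "
                f"point the config at an existing file"
            )
        value = reader(candidate)
        setattr(self, attr, value)
        return value

    def expression(self, stage: str):
        c = self.config
        mirna = self._resolve(
            "mirna",
            c.mirna_path,
            "mirna.tsv",
            lambda p: read_expression_matrix(p, collapse=c.collapse),
            stage,
        )
        mrna = self._resolve(
            "mrna",
            c.mrna_path,
            "mrna.tsv",
            lambda p: read_expression_matrix(p, collapse=c.collapse),
            stage,
        )
        annotation = self._resolve(
            "annotation", c.annotation_path, "annotation.tsv",
            read_sample_annotations, stage,
        )
        pairs = self._resolve(
            "pairs", c.pairs_path, "pairs.tsv", read_pair_list, stage
        )
        return mirna, mrna, annotation, pairs

    def feature_list(self, annotation) -> list[str]:
        return list(self.config.features) or annotation.features()

    def mmpvs_for(self, feature: str, stage: str) -> list[core.MMPVRecord]:
        if feature in self.mmpvs:
            return self.mmpvs[feature]
        path = self.out / f"mmpv_{feature}.tsv"
        if not path.exists():
            raise MissingDependencyError(
                f"stage {stage!r} needs MMPVs for feature {feature!r} — run "
                "'detect' first"
            )
        records = core.records_from_table(core.read_mmpv_table(path))
        self.mmpvs[feature] = records
        return records


def _stage_simulate(run: _Run) -> None:
    c = run.config
    if c.dataset_spec is None:
        raise ConfigurationError("simulate stage needs dataset_spec in the config")
    spec = synth.DatasetSpec.from_yaml(c.dataset_spec)
    spec = synth.DatasetSpec(
        n_status1=spec.n_status1,
        n_status2=spec.n_status2,
        pair_specs=spec.pair_specs,
        feature_name=spec.feature_name,
        seed=c.seed,
        share_entities=spec.share_entities,
    )
    mirna, mrna, annotation, truth = synth.simulate_dataset(spec)
    mirna.write(run.out / "mirna.tsv")
    mrna.write(run.out / "mrna.tsv")
    annotation.write(run.out / "annotation.tsv")
    pairs = [ps.pair for ps in spec.pair_specs]
    from .io_model import write_pair_list

    write_pair_list(pairs, run.out / "pairs.tsv")
    synth.write_truth_table(truth, run.out / "truth.tsv")
    for name, n in [
        ("mirna.tsv", len(mirna.row_ids)),
        ("mrna.tsv", len(mrna.row_ids)),
        ("annotation.tsv", len(annotation.assignments)),
        ("pairs.tsv", len(pairs)),
        ("truth.tsv", len(truth)),
    ]:
        run.register(run.out / name, n)
    run.mirna, run.mrna, run.annotation, run.pairs = mirna, mrna, annotation, pairs
    logger.info("[simulate] wrote %d pairs, %d samples", len(pairs),
                len(annotation.assignments))


def _stage_detect(run: _Run) -> None:
    c = run.config
    mirna, mrna, annotation, pairs = run.expression("detect")
    for feature in run.feature_list(annotation):
        records, summary = core.detect_mmpvs(
            mirna, mrna, annotation, feature, pairs, alpha=c.alpha, fold=c.fold
        )
        run.mmpvs[feature] = records
        run.summaries[feature] = summary
        table = core.mmpv_table(records)
        path = run.out / f"mmpv_{feature}.tsv"
        table.to_csv(path, sep="\t", index=False)
        run.register(path, len(table))
        logger.info(
            "[detect] %s: %d MMPVs (%d sign, %d fold)",
            feature,
            summary["n_total"],
            summary["n_sign_change"],
            summary["n_fold_change"],
        )
    summary_path = run.out / "mmpv_summary.json"
    summary_path.write_text(
        json.dumps(run.summaries, indent=2, sort_keys=True) + "\n"
    )
    run.register(summary_path, len(run.summaries))


def _stage_de(run: _Run) -> None:
    c = run.config
    mirna, mrna, annotation, _ = run.expression("de")
    for fi, feature in enumerate(run.feature_list(annotation)):
        records = run.mmpvs_for(feature, "de")
        tables = {}
        for mi, (label, matrix) in enumerate(
            (("mirna", mirna), ("mrna", mrna))
        ):
            rng = np.random.default_rng([c.seed, 100 + fi, mi])
            tables[label] = differential.differential_table(
                matrix, annotation, feature, c.n_perm, rng
            )
            path = run.out / f"de_{label}_{feature}.tsv"
            tables[label].to_csv(path, sep="\t", index=False)
            run.register(path, len(tables[label]))
        de_records = differential.select_de_mmpvs(
            records, tables["mirna"], tables["mrna"], alpha=c.alpha
        )
        table = differential.de_mmpv_table(de_records)
        path = run.out / f"de_mmpv_{feature}.tsv"
        table.to_csv(path, sep="\t", index=False)
        run.register(path, len(table))
        logger.info("[de] %s: %d DE-MMPVs", feature, len(table))


def _feature_pair_sets(run: _Run, annotation, stage: str):
    return {
        feature: {
            (r.pair.mirna_id, r.pair.mrna_id)
            for r in run.mmpvs_for(feature, stage)
        }
        for feature in run.feature_list(annotation)
    }


def _stage_overlap(run: _Run) -> None:
    _, _, annotation, _ = run.expression("overlap")
    by_feature = _feature_pair_sets(run, annotation, "overlap")
    matrix = multifeature.overlap_counts(by_feature)
    table = matrix.to_long()
    path = run.out / "overlap.tsv"
    table.to_csv(path, sep="\t", index=False)
    run.register(path, len(table))
    if len(matrix.features) >= 2:
        a, b = matrix.features[:2]
        genes = multifeature.two_feature_genes(
            by_feature, a, b, exclude_others=run.config.exclude_others
        )
        gpath = run.out / f"shared_genes_{a}_{b}.txt"
        gpath.write_text("".join(f"{g}\n" for g in sorted(genes)))
        run.register(gpath, len(genes))
    logger.info("[overlap] %d feature pairs", len(table))


def _stage_enrich(run: _Run) -> None:
    c = run.config
    if c.terms_path is None:
        raise ConfigurationError("enrich stage needs terms_path in the config")
    _, _, annotation, pairs = run.expression("enrich")
    term_map = read_term_map(c.terms_path)
    background = {p.mrna_id for p in pairs}
    for feature in run.feature_list(annotation):
        records = run.mmpvs_for(feature, "enrich")
        target = {r.pair.mrna_id for r in records} & background
        results = enrichment.enrich_terms(
            target, background, term_map, p_threshold=c.p_threshold
        )
        table = enrichment.enrichment_table(results)
        path = run.out / f"enrich_{feature}.tsv"
        table.to_csv(path, sep="\t", index=False)
        run.register(path, len(table))
        logger.info("[enrich] %s: %d terms < %g", feature, len(table), c.p_threshold)


def _stage_network(run: _Run) -> None:
    c = run.config
    if c.edges_path is None:
        raise ConfigurationError("network stage needs edges_path in the config")
    _, _, annotation, _ = run.expression("network")
    graph = read_edge_list(c.edges_path)
    net_mean = network.network_mean_degree(graph)
    rows = []
    for feature in run.feature_list(annotation):
        records = run.mmpvs_for(feature, "network")
        genes = {r.pair.mrna_id for r in records}
        mapped, unmapped = network.degree_map(genes, graph)
        if len(mapped) >= 2 and len(set(mapped.values())) > 1:
            res = network.mean_degree_test(
                list(mapped.values()), net_mean, n_unmapped=len(unmapped)
            )
            rows.append(
                {
                    "feature": feature,
                    "mean_degree": res.mean_degree,
                    "p_value": res.p_one_tailed,
                    "n_mapped": res.n_mapped,
                    "n_unmapped": res.n_unmapped,
                }
            )
        else:
            rows.append(
                {
                    "feature": feature,
                    "mean_degree": float("nan"),
                    "p_value": float("nan"),
                    "n_mapped": len(mapped),
                    "n_unmapped": len(unmapped),
                }
            )
    rows.append(
        {
            "feature": "network",
            "mean_degree": net_mean,
            "p_value": float("nan"),
            "n_mapped": graph.number_of_nodes(),
            "n_unmapped": 0,
        }
    )
    table = pd.DataFrame(
        rows, columns=["feature", "mean_degree", "p_value", "n_mapped", "n_unmapped"]
    )
    path = run.out / "network_degree.tsv"
    table.to_csv(path, sep="\t", index=False)
    run.register(path, len(table))
    logger.info("[network] mean network degree %.2f", net_mean)


_STAGES = {
    "simulate": _stage_simulate,
    "detect": _stage_detect,
    "de": _stage_de,
    "overlap": _stage_overlap,
    "enrich": _stage_enrich,
    "network": _stage_network,
}


def run_pipeline(config: PipelineConfig, stages: Sequence[str]) -> dict:
    """Run the requested stages in canonical order; returns the manifest."""
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
    run = _Run(config)
    ordered = [s for s in STAGE_ORDER if s in set(stages)]
    for stage in ordered:
        _STAGES[stage](run)
    manifest = {
        "seed": config.seed,
        "stages": ordered,
        "parameters": {
            "alpha": config.alpha,
            "fold": config.fold,
            "n_perm": config.n_perm,
            "p_threshold": config.p_threshold,
            "collapse": config.collapse,
        },
        "files": run.files,
    }
    (run.out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
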