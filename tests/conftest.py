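import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")

from mmpv.io_model import SampleAnnotation, TargetPair
from mmpv.synth import DatasetSpec, PairSpec, simulate_dataset


def make_pair_specs(configs, start=0):
    """configs: list of dicts with rho1/rho2 and optional extras."""
    specs = []
    for i, cfg in enumerate(configs, start=start):
        specs.append(
            PairSpec(
                pair=TargetPair(
                    cfg.get("mirna", f"hsa-miR-{i}"),
                    cfg.get("mrna", f"G{i}"),
                    cfg.get("sign", "D"),
                ),
                rho_status1=cfg["rho1"],
                rho_status2=cfg["rho2"],
                delta_mirna=cfg.get("delta_mirna", 0.0),
                delta_mrna=cfg.get("delta_mrna", 0.0),
                noise_sd=cfg.get("noise_sd", 1.0),
            )
        )
    return tuple(specs)


@pytest.fixture
def small_dataset():
    """10 pairs (5 sign-change, 5 uncoupled nulls), 60/stratum, seeded."""
    specs = make_pair_specs(
        [{"rho1": 0.8, "rho2": -0.8} for _ in range(5)]
        + [{"rho1": 0.0, "rho2": 0.0} for _ in range(5)]
    )
    spec = DatasetSpec(n_status1=60, n_status2=60, pair_specs=specs, seed=7)
    mirna, mrna, annotation, truth = simulate_dataset(spec)
    return spec, mirna, mrna, annotation, truth


@pytest.fixture
def toy_annotation():
    return SampleAnnotation(
        registry={"ER": ("ER+", "ER-")},
        assignments={
            f"s{i}": {"ER": "ER+" if i <= 3 else "ER-"} for i in range(1, 7)
        },
    )
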