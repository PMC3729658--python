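import numpy as np
import pandas as pd
import pytest

from avmeth.data_model import (
    AnalysisConfig,
    ArrayDataset,
    Manifest,
    MethylationMatrices,
    ProbeAnnotation,
    SampleSheet,
)
from avmeth.simulate import TruthSpec, simulate_dataset, simulate_manifest


def make_sheet(n_pairs: int = 3) -> SampleSheet:
    rows = []
    for i in range(1, n_pairs + 1):
        rows.append({"sample_id": f"A{i}", "group": "arterial", "pair_id": f"P{i}"})
        rows.append({"sample_id": f"V{i}", "group": "venous", "pair_id": f"P{i}"})
    return SampleSheet(pd.DataFrame(rows))


def make_manifest(specs) -> Manifest:
    """specs: iterable of dicts with ProbeAnnotation fields (probe_id required)."""
    probes = []
    for i, spec in enumerate(specs):
        defaults = {
            "probe_id": f"cg{i:06d}",
            "chromosome": "1",
            "position": 1000 + 100 * i,
            "design_type": "II",
        }
        defaults.update(spec)
        probes.append(ProbeAnnotation(**defaults))
    return Manifest(probes)


def matrices_from_beta(beta: pd.DataFrame) -> MethylationMatrices:
    eps = 1e-12
    clipped = beta.clip(eps, 1 - eps)
    mval = np.log2(clipped / (1 - clipped))
    return MethylationMatrices(
        beta=beta, mvalue=mval, kept_probe_ids=list(beta.index), qc_log={}
    )


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig(seed=0)


@pytest.fixture
def small_sheet() -> SampleSheet:
    return make_sheet(3)


@pytest.fixture(scope="session")
def sim_bundle():
    """A moderately sized seeded simulation shared across tests."""
    manifest = simulate_manifest(300, (5, 5), sex_chrom_fraction=0.05, seed=11)
    dataset, expression, truth = simulate_dataset(
        manifest,
        n_pairs=9,
        truth_spec=TruthSpec(
            n_dmr_genes=40, delta_beta=0.3, n_reciprocal=20, logfc=1.0, global_offset=0.0
        ),
        seed=12,
    )
    return manifest, dataset, expression, truth
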