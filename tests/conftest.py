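import dataclasses

import numpy as np
import pandas as pd
import pytest

import nmomics as nm
from nmomics.simulate import TraitSpec


def make_replicate_table(
    values_by_treatment: dict, analytes=None, control="control", layer="layer", is_log2=True
) -> nm.ReplicateIntensityTable:
    """Build a ReplicateIntensityTable from {treatment: 2-D array} blocks."""
    blocks = []
    cols = []
    for treatment, block in values_by_treatment.items():
        block = np.atleast_2d(np.asarray(block, dtype=float))
        blocks.append(block)
        cols += [(treatment, r + 1) for r in range(block.shape[1])]
    data = np.hstack(blocks)
    if analytes is None:
        analytes = [f"A{i + 1}" for i in range(data.shape[0])]
    frame = pd.DataFrame(
        data, index=pd.Index(analytes, name="analyte"),
        columns=pd.MultiIndex.from_tuples(cols, names=["treatment", "replicate"]),
    )
    return nm.ReplicateIntensityTable(
        layer_name=layer, values=frame, control_label=control, is_log2=is_log2
    )


def fold_changes_from_dataset(ds: nm.SimulatedDataset, min_present: int = 3) -> dict:
    """Plain-log2 preprocessing of a simulated dataset into FC matrices."""
    from nmomics.preprocess import fold_change_test, log2_transform, replicate_filter

    fcs = {}
    for name, table in ds.tables.items():
        table = log2_transform(table)
        kept = replicate_filter(table, min_present)
        table = dataclasses.replace(table, values=table.values.loc[kept])
        fcs[name] = fold_change_test(table)
    return fcs


@pytest.fixture(scope="session")
def small_config() -> nm.GeneratorConfig:
    """Two-layer screen with 5 planted modules of 45 analytes + grey."""
    return nm.GeneratorConfig(
        layers=(("proteomics", 200), ("metabolomics", 50)),
        n_modules=5,
        traits=(
            TraitSpec("agglomerate_size", 0, 0.9, False, "physchem", 500.0, 900.0),
            TraitSpec("cell_viability", 1, -0.9, False, "toxicity", 20.0, 75.0),
            TraitSpec("active_in_vitro", 2, 0.9, True, "activity_class"),
        ),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config) -> nm.SimulatedDataset:
    return nm.generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_fold_changes(small_dataset) -> dict:
    return fold_changes_from_dataset(small_dataset)


@pytest.fixture(scope="session")
def fitted_results(small_dataset, small_fold_changes) -> nm.WGCNAResults:
    model = nm.IntegrativeWGCNA.from_fold_changes(small_fold_changes, small_dataset.traits)
    return model.fit()


@pytest.fixture(scope="session")
def zero_noise_dataset() -> nm.SimulatedDataset:
    """Noise-free screen: 3 modules of 30 analytes, no grey, no missingness."""
    cfg = nm.GeneratorConfig(
        n_treatments=6,
        layers=(("proteomics", 90),),
        n_modules=3,
        module_sizes=(30, 30, 30),
        background_fraction=0.0,
        noise_sd=0.0,
        missing_rate=0.0,
        differential_rate=0.0,
        traits=(TraitSpec("activity", 0, 1.0, False),),
        seed=11,
    )
    return nm.generate_dataset(cfg)
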