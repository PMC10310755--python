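import numpy as np
import pytest
import trimesh

from spinemorph import synthetic
from spinemorph.features import feature_table


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def icosphere():
    return trimesh.creation.icosphere(subdivisions=3, radius=1.0)


@pytest.fixture(scope="session")
def unit_cube():
    return trimesh.creation.box(extents=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def hemisphere_spine():
    spine, analytic = synthetic.make_spine_mesh(
        synthetic.SpineSpec("stubby", head_radius=0.5, neck_radius=0.5,
                            neck_length=0.0)
    )
    return spine, analytic


@pytest.fixture(scope="session")
def capsule_spine():
    spine, analytic = synthetic.make_spine_mesh(
        synthetic.SpineSpec("filopodia", head_radius=0.1, neck_radius=0.1,
                            neck_length=2.0)
    )
    return spine, analytic


@pytest.fixture(scope="session")
def mushroom_spine():
    spine, analytic = synthetic.make_spine_mesh(
        synthetic.SpineSpec("mushroom", head_radius=0.4, neck_radius=0.1,
                            neck_length=0.8)
    )
    return spine, analytic


def archetype_features(n_per_class, classes=("mushroom", "thin", "stubby"),
                       seed=0, resolution=32):
    """Feature table + true labels for generated archetype spines."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    spines, labels = [], []
    for cls in classes:
        for _ in range(n_per_class):
            spec = synthetic.sample_spec(cls, rng)
            spec = synthetic.SpineSpec(
                spec.archetype, head_radius=spec.head_radius,
                neck_radius=spec.neck_radius, neck_length=spec.neck_length,
                resolution=resolution, jitter=spec.jitter,
            )
            spine, _ = synthetic.make_spine_mesh(spec, rng)
            spines.append(spine)
            labels.append(cls)
    table = feature_table(spines)
    return table, pd.Series(labels, index=table.index, name="true_label")


@pytest.fixture(scope="session")
def archetype_dataset():
    return archetype_features(40, seed=11)
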