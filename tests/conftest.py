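import pytest

from shapealign.alignment import AlignmentConfig, align_class
from shapealign.shapes import extract_shape_window, toy_pentamer_table
from shapealign.simulate import SimulationSpec, simulate_dataset


@pytest.fixture(scope="session")
def toy_table():
    return toy_pentamer_table()


@pytest.fixture(scope="session")
def small_spec():
    """A fast-to-generate dataset for unit tests."""
    return SimulationSpec(genome_size=150_000, n_sites=25, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return simulate_dataset(small_spec)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions (200 sites per class, 1 Mb genome)."""
    return simulate_dataset(SimulationSpec(seed=0))


@pytest.fixture(scope="session")
def default_alignments(default_dataset):
    """Per-class alignment of the default dataset under one shared config."""
    config = AlignmentConfig()
    results = {}
    for class_label, sites in default_dataset.sites_by_class().items():
        windows = [extract_shape_window(s, default_dataset.track, 201) for s in sites]
        results[class_label] = align_class(windows, config)
    return config, results


def random_window(rng, width=141, n_features=4):
    from shapealign.shapes import ShapeWindow
    return ShapeWindow(
        site_id=f"w{rng.integers(1e9)}",
        features=rng.normal(size=(n_features, width)),
        center_index=width // 2,
    )
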