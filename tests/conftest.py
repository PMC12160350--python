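import numpy as np
import pandas as pd
import pytest

from cslv.genome import GenomeBuild
from cslv.io import MarkerManifest


@pytest.fixture
def toy_build():
    """Three small chromosomes; enough to exercise segmentation."""
    return GenomeBuild({"1": 100, "2": 60, "3": 40})


@pytest.fixture
def toy_manifest(toy_build):
    table = pd.DataFrame(
        {
            "marker_id": ["m1", "m2", "m3", "m4", "m5", "m6", "m7"],
            "chromosome": ["1", "1", "1", "1", "2", "2", "3"],
            "position": [10, 40, 60, 90, 15, 45, 20],
        }
    )
    return MarkerManifest(table=table, build=toy_build)


@pytest.fixture
def toy_lrr(toy_manifest):
    rng = np.random.default_rng(7)
    values = rng.normal(0, 0.1, size=(4, len(toy_manifest)))
    return pd.DataFrame(
        values,
        index=[f"s{i}" for i in range(1, 5)],
        columns=toy_manifest.marker_ids,
    )


def random_manifest(build: GenomeBuild, markers_per_chrom: int, seed: int) -> MarkerManifest:
    """Uniform random marker panel over a build, manifest-sorted."""
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in build.names:
        length = build.length(chrom)
        n = min(markers_per_chrom, length)
        positions = np.unique(rng.integers(1, length + 1, size=n))
        while positions.size < n:
            extra = rng.integers(1, length + 1, size=n - positions.size)
            positions = np.unique(np.concatenate([positions, extra]))
        for j, pos in enumerate(positions):
            rows.append((f"{chrom}_m{j}", chrom, int(pos)))
    return MarkerManifest(
        table=pd.DataFrame(rows, columns=["marker_id", "chromosome", "position"]),
        build=build,
    )


def make_cohort(n_cases, n_controls, seed=0, groups=("unknown",)):
    """Plain cohort table with Gaussian ages."""
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    labels = np.r_[np.ones(n_cases, int), np.zeros(n_controls, int)]
    return pd.DataFrame(
        {
            "sample_id": [f"s{i:05d}" for i in range(n)],
            "label": labels,
            "age": np.round(rng.normal(60, 10, n), 1),
            "group": rng.choice(list(groups), size=n),
        }
    )
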