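import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from rnaiquant.network import PathContributions, Thresholds
from rnaiquant.synthetic import GroundTruth, make_variant_fixtures


@pytest.fixture(scope="session")
def accepted_example():
    """A hand-checked parameter set that satisfies every constraint."""
    return PathContributions(1.2, 1.1, 0.8, 0.7), Thresholds(1.0, 3.5)


@pytest.fixture(scope="session")
def planted_vcf_dir(tmp_path_factory):
    """Per-strain VCF fixtures with one 5-strain planted group and one pair."""
    out = tmp_path_factory.mktemp("vcfs")
    planted = {
        "mut-16": ["strain01", "strain02", "strain03", "strain04", "strain05"],
        "rde-10": ["strain02", "strain06"],
    }
    paths = make_variant_fixtures(
        out, n_strains=6, n_shared=10, planted=planted, n_decoys=4, seed=11
    )
    return paths, planted


@pytest.fixture(scope="session")
def ground_truth():
    return GroundTruth(seed=5)
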