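import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from pepmap import align6, synthgen


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic bundle shared across the suite."""
    return synthgen.generate(synthgen.SynthConfig(seed=1))


@pytest.fixture(scope="session")
def hits(bundle):
    """Strict-mode (default parameter) search results on the bundle."""
    return align6.tblastn_search(bundle.peptides, bundle.genome)


@pytest.fixture(scope="session")
def fs_bundle():
    """Frameshift-heavy bundle for stitching tests."""
    cfg = synthgen.SynthConfig(seed=7, frameshift_intron_fraction=0.6, n_genes=10)
    return synthgen.generate(cfg)


@pytest.fixture(scope="session")
def fs_hits_relaxed(fs_bundle):
    """Multi-HSP relaxed-coverage search on the frameshift bundle, as used
    by the stitching pipeline."""
    params = align6.AlignmentParams(
        max_hsps_per_target=3, min_query_coverage_pct=10.0
    )
    return align6.tblastn_search(fs_bundle.peptides, fs_bundle.genome, params)


@pytest.fixture(scope="session")
def genome_by_id(bundle):
    return {c.id: c for c in bundle.genome}
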