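"""Shared fixtures: the toy organism bundle and its reconstructed pc-model.

Session-scoped because reconstruction is deterministic and read-only in
all tests; anything that mutates builds its own copy.
"""

import pytest

from pcforge.reconstruction import build_pc_model
from pcforge.toy import ToyOrganismSpec, generate_toy_organism


@pytest.fixture(scope="session")
def bundle():
    return generate_toy_organism(ToyOrganismSpec(seed=1))


@pytest.fixture(scope="session")
def pc(bundle):
    return build_pc_model(bundle.gem, bundle.records, bundle.kcat_entries,
                          bundle.complex_defs, bundle.expr_config)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("toy_bundle")
    generate_toy_organism(ToyOrganismSpec(seed=1), outdir=outdir)
    return outdir
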