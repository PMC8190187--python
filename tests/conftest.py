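import numpy as np
import pytest

from xistruct.contact_matrix import RAW, BinTable, ContactMatrix


def make_matrix(values, resolution=100_000, chrom="chrT", state=RAW, mappability=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    bins = BinTable.from_resolution(chrom, n * resolution, resolution,
                                    mappability=mappability)
    return ContactMatrix(bins, values, state)


@pytest.fixture(scope="session")
def worked_fixture():
    from xistruct.simulate import make_worked_fixture

    return make_worked_fixture()


@pytest.fixture(scope="session")
def worked_manifest():
    import json
    import pathlib

    path = pathlib.Path(__file__).parent / "fixtures" / "worked_manifest.json"
    return json.loads(path.read_text())
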