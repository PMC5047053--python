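import warnings

import pytest

from osteowave import orchestration_cli as oc
from osteowave import tissue_materials as tm


@pytest.fixture(scope="session")
def paper_model():
    """One reduced-resolution run of the full fracture model (shared)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return oc.run_paper_model()


@pytest.fixture(scope="session")
def materials():
    return tm.material_map("reconciled")
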