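import pytest

from cardiophen import synth


@pytest.fixture(scope="session")
def wt_imaging():
    """Noiseless calcium stack from the WT 12D Glc+FA preset (shared)."""
    return synth.gen_imaging("WT_12D_GlcFA")


@pytest.fixture(scope="session")
def mut_imaging():
    return synth.gen_imaging("Mut_12D_GlcFA")


@pytest.fixture(scope="session")
def wt_ocr():
    """Noiseless mitostress assay from the WT 12D Glc+FA preset."""
    return synth.gen_ocr("WT_12D_GlcFA")
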