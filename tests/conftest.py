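import numpy as np
import pytest

from znet3d import PhantomSpec, generate_phantom, stack_case


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_case():
    """One deterministic tumor-bearing phantom at 32 cubed."""
    return generate_phantom(PhantomSpec(shape=(32, 32, 32), seed=7))


@pytest.fixture(scope="session")
def phantom_pair(phantom_case):
    """Preprocessed (ModalityStack, MaskStack) pair at native resolution."""
    return stack_case(phantom_case, (32, 32, 32))


@pytest.fixture
def case_dir(tmp_path, phantom_case):
    """The phantom written to disk in BraTS layout."""
    from znet3d.brats_io import MODALITIES, save_volume

    d = tmp_path / phantom_case.case_id
    d.mkdir()
    for name, vol in zip(MODALITIES, phantom_case.modalities()):
        save_volume(vol, d / f"{phantom_case.case_id}_{name}.nii.gz")
    save_volume(phantom_case.seg, d / f"{phantom_case.case_id}_seg.nii.gz")
    return d
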