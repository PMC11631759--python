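import numpy as np
import pytest

from pequant import EmbryoSimConfig, ReadRecord, make_synthetic_target


@pytest.fixture(scope="session")
def spec():
    """Synthetic target locus with secondary nick and three barcoded samples."""
    return make_synthetic_target(n_samples=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_read(bases, quals=None, read_id="r0", barcode=None, masked=False):
    if quals is None:
        quals = np.full(len(bases), 37, dtype=np.int16)
    return ReadRecord(
        read_id=read_id, bases=bases, quals=np.asarray(quals), barcode=barcode,
        masked=masked,
    )


def noise_free_config(spec, mix, depth=300, seed=0):
    return EmbryoSimConfig(
        spec=spec,
        depth=depth,
        mix=mix,
        subst_error_rate=0.0,
        quality_model=(37, 11, 0.0),
        seed=seed,
    )
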