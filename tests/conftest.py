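import pytest

from ampedit import locus as demo_locus
from ampedit.splice import synthetic_donor_training_set, train_pwm


@pytest.fixture(scope="session")
def demo():
    """The synthetic diploid demonstration locus (guides A and B)."""
    return demo_locus.synthetic_lztr1_locus()


@pytest.fixture(scope="session")
def donor_model():
    """Donor-site PWM trained on the synthetic donor training set."""
    return train_pwm(synthetic_donor_training_set(500, seed=7))


@pytest.fixture(scope="session")
def spectrum_b(demo):
    """Canonical default simulation spectrum (guide B)."""
    return demo.spectrum_keys("B", demo_locus.DEFAULT_SPECTRUM_B)


@pytest.fixture(scope="session")
def spectrum_a(demo):
    """Canonical paper-like spectrum at the cryptic donor site (guide A)."""
    return demo.spectrum_keys("A", demo_locus.SPLICE_DEMO_SPECTRUM_A)
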