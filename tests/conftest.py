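import numpy as np
import pytest

from dwmkit.matrix_model import BackgroundModel, Pwm, SiteAlignment, build_dwm, build_pwm


@pytest.fixture
def aa_tt_alignment() -> SiteAlignment:
    """The two-site AA/TT alignment behind the worked closed-form example."""
    return SiteAlignment(["AA", "TT"])


@pytest.fixture
def aa_tt_pwm(aa_tt_alignment) -> Pwm:
    return build_pwm(aa_tt_alignment, 1.0)


@pytest.fixture
def aa_tt_dwm(aa_tt_alignment):
    return build_dwm(aa_tt_alignment, 1.0)


@pytest.fixture
def uniform_background() -> BackgroundModel:
    return BackgroundModel.uniform()


def random_pwm(rng: np.random.Generator, length: int, concentration: float = 1.0) -> Pwm:
    """A random strictly positive Pwm via Dirichlet column draws."""
    probs = rng.dirichlet(np.full(4, concentration), size=length)
    probs = np.clip(probs, 1e-9, None)
    probs /= probs.sum(axis=1, keepdims=True)
    return Pwm(probs)


def random_window(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
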