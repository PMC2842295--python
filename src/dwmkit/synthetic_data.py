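"""Generators for synthetic fixtures: motif samples, correlated sites,
background sequence, and embedded-site benchmark sequences.

Correlated sites are generated from a mixture of Pwms rather than a pairwise
random field: the mixture's pair joints have an exact closed form (the
weighted sum of component outer products), which provides an analytic oracle
for correlation-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix_model import BackgroundModel, Pwm, SiteAlignment, decode


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class MixtureMotifModel:
    """A mixture of equal-length Pwms with analytically known pair joints."""

    components: list[tuple[float, Pwm]]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("mixture requires at least one component")
        weights = np.array([w for w, _ in self.components], dtype=float)
        if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("component weights must be non-negative and sum to 1")
        lengths = {p.length for _, p in self.components}
        if len(lengths) != 1:
            raise ValueError("all mixture components must share one motif length")

    @property
    def length(self) -> int:
        return self.components[0][1].length

    def marginal(self) -> Pwm:
        """The mixture's per-position marginal as a Pwm."""
        probs = sum(w * p.probs for w, p in self.components)
        return Pwm(probs, pseudocount=self.components[0][1].pseudocount)

    def pair_joint(self, i: int, j: int) -> np.ndarray:
        """Closed-form joint P(a at i, b at j): weighted sum of outer products."""
        return sum(w * np.outer(p.probs[i], p.probs[j]) for w, p in self.components)


@dataclass
class GroundTruthInterval:
    """A labelled interval in benchmark-sequence coordinates."""

    start: int
    end: int
    label: str  # 'real' or 'fake'

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class EmbeddingLayout:
    """Geometry of the embedded-site benchmark sequence."""

    spacer_length: int = 100
    flank: int = 10

    def __post_init__(self) -> None:
        if self.spacer_length < 0 or self.flank < 0:
            raise ValueError("spacer_length and flank must be non-negative")


def _sample_codes(probs: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n rows with each column sampled from its probability row."""
    L = probs.shape[0]
    out = np.empty((n, L), dtype=np.int8)
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0  # guard roundoff
    u = rng.random((n, L))
    for i in range(L):
        out[:, i] = np.searchsorted(cum[i], u[:, i], side="right")
    return out


def sample_pwm_sites(
    pwm: Pwm, n: int, seed: int | np.random.Generator | None = None
) -> SiteAlignment:
    """n independent site draws with each position sampled from its column."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = _rng(seed)
    if n == 0:
        return SiteAlignment([], length=pwm.length)
    codes = _sample_codes(pwm.probs, n, rng)
    return SiteAlignment([decode(row) for row in codes])


def sample_mixture_sites(
    model: MixtureMotifModel, n: int, seed: int | np.random.Generator | None = None
) -> SiteAlignment:
    """Sites drawn by picking a component per site, then sampling its Pwm."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if len(model.components) == 1:
        return sample_pwm_sites(model.components[0][1], n, seed)
    rng = _rng(seed)
    if n == 0:
        return SiteAlignment([], length=model.length)
    weights = np.array([w for w, _ in model.components])
    picks = rng.choice(len(model.components), size=n, p=weights)
    sequences = [""] * n
    for c, (_, pwm) in enumerate(model.components):
        rows = np.flatnonzero(picks == c)
        if rows.size == 0:
            continue
        codes = _sample_codes(pwm.probs, rows.size, rng)
        for k, row in enumerate(rows):
            sequences[row] = decode(codes[k])
    return SiteAlignment(sequences)


def sample_background(
    background: BackgroundModel, length: int, seed: int | np.random.Generator | None = None
) -> str:
    """An i.i.d. background nucleotide string of the requested length."""
    if length < 0:
        raise ValueError("length must be non-negative")
    if length == 0:
        return ""
    rng = _rng(seed)
    probs = background.probs.reshape(1, 4)
    codes = _sample_codes(np.repeat(probs, length, axis=0), 1, rng)[0]
    return decode(codes)


def build_embedded_benchmark(
    real_sites: list[str],
    fake_model: Pwm,
    layout: EmbeddingLayout,
    background: BackgroundModel,
    seed: int | np.random.Generator | None = None,
) -> tuple[str, list[GroundTruthInterval]]:
    """A benchmark sequence embedding real sites and an equal number of decoys.

    Each embedded block is ``flank + site + flank`` with flanks drawn from the
    background; blocks appear in randomised order and are separated (and
    bracketed) by background spacers of ``spacer_length`` bp.  The returned
    ground-truth intervals cover the core sites (flanks excluded), labelled
    'real' or 'fake'.
    """
    if not real_sites:
        raise ValueError("at least one real site is required")
    rng = _rng(seed)
    fakes = sample_pwm_sites(fake_model, len(real_sites), rng).sequences
    blocks = [("real", s) for s in real_sites] + [("fake", s) for s in fakes]
    order = rng.permutation(len(blocks))
    pieces: list[str] = []
    truth: list[GroundTruthInterval] = []
    pos = 0

    def _spacer() -> None:
        nonlocal pos
        pieces.append(sample_background(background, layout.spacer_length, rng))
        pos += layout.spacer_length

    _spacer()
    for idx in order:
        label, site = blocks[idx]
        left = sample_background(background, layout.flank, rng)
        right = sample_background(background, layout.flank, rng)
        pieces.append(left + site + right)
        site_start = pos + layout.flank
        truth.append(GroundTruthInterval(site_start, site_start + len(site), label))
        pos += 2 * layout.flank + len(site)
        _spacer()
    return "".join(pieces), truth


def correlated_mixture_motif(
    core: str = "ACG",
    tail: str = "TCA",
    middle: int = 4,
    core_weight: float = 0.91,
    middle_weight: float = 0.94,
) -> MixtureMotifModel:
    """A two-component mixture with strong pairwise but weak marginal signal.

    Both components share conserved core and tail consensus blocks; between
    them, ``middle`` positions are jointly A-rich in one component and T-rich
    in the other.  The mixture marginal at those positions is a 50/50 A/T
    blend, so a Pwm sees almost no information there while the pair joints
    carry a strong correlated block.
    """
    length = len(core) + middle + len(tail)

    def component(middle_base: str) -> Pwm:
        probs = np.full((length, 4), (1.0 - core_weight) / 3.0)
        for k, ch in enumerate(core + "." * middle + tail):
            if ch != ".":
                probs[k, "ACGT".index(ch)] = core_weight
        for k in range(len(core), len(core) + middle):
            probs[k] = (1.0 - middle_weight) / 3.0
            probs[k, "ACGT".index(middle_base)] = middle_weight
        probs /= probs.sum(axis=1, keepdims=True)
        return Pwm(probs)

    return MixtureMotifModel([(0.5, component("A")), (0.5, component("T"))])


def embed_sites_in_probes(
    sites: list[str],
    probe_length: int,
    background: BackgroundModel,
    seed: int | np.random.Generator | None = None,
    prefix: str = "probe",
) -> tuple[dict[str, str], dict[str, GroundTruthInterval]]:
    """One probe per site: background sequence with the site at a random offset."""
    rng = _rng(seed)
    probes: dict[str, str] = {}
    positions: dict[str, GroundTruthInterval] = {}
    for k, site in enumerate(sites):
        if len(site) > probe_length:
            raise ValueError("probe_length shorter than a site")
        offset = int(rng.integers(0, probe_length - len(site) + 1))
        bg = sample_background(background, probe_length - len(site), rng)
        probe_id = f"{prefix}_{k:04d}"
        probes[probe_id] = bg[:offset] + site + bg[offset:]
        positions[probe_id] = GroundTruthInterval(offset, offset + len(site), "real")
    return probes, positions


def make_benchmark_probes(
    real_sites: list[str],
    decoy_sites: list[str],
    probe_length: int,
    background: BackgroundModel,
    seed: int | np.random.Generator | None = None,
) -> tuple[dict[str, str], set[str]]:
    """Target probes embedding real sites plus decoy probes embedding decoys.

    Returns the probe collection and the set of annotated (target) probe ids.
    """
    rng = _rng(seed)
    targets, _ = embed_sites_in_probes(real_sites, probe_length, background, rng, "target")
    decoys, _ = embed_sites_in_probes(decoy_sites, probe_length, background, rng, "decoy")
    probes = {**targets, **decoys}
    return probes, set(targets)
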