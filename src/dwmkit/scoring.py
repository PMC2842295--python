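"""Likelihood and log-odds scoring of sequence windows under motif models.

The dinucleotide likelihood of a window is the product over positions of the
posterior probability of the observed nucleotide given all other nucleotides
in the window: at each position the unnormalised weight of nucleotide ``a`` is

    u_i(a) = w_ai * prod_{j != i} pair(i, j)[a, s_j] / w_ai

and the per-position factor is ``u_i(s_i) / Z_i`` with ``Z_i = sum_a u_i(a)``.
When every pair table is the outer product of its marginal columns this
reduces exactly to the Pwm likelihood.  All arithmetic is carried out in
natural-log space; with motif lengths around 30 the products underflow in
linear space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import logsumexp

from .matrix_model import (
    BackgroundModel,
    Dwm,
    Pwm,
    encode,
    reverse_complement,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoredSite:
    """A candidate binding site with its best-orientation log-odds."""

    sequence_id: str
    start: int  # 0-based
    end: int  # half-open
    strand: str  # '+' or '-'
    logodds: float  # natural-log units

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not np.isfinite(self.logodds):
            raise ValueError("log-odds must be finite")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class PosteriorProfile:
    """Per-position posterior weights for one scored window."""

    weights: np.ndarray  # u_i(a), (L, 4), positive
    normalisers: np.ndarray  # Z_i, (L,)
    posterior: np.ndarray  # p_i(a) = u_i(a) / Z_i, (L, 4)


def _window_codes(model_length: int, window: str) -> np.ndarray:
    codes = encode(window)
    if codes.shape[0] != model_length:
        raise ValueError(
            f"window length {codes.shape[0]} does not match model length {model_length}"
        )
    if (codes > 3).any():
        raise ValueError(f"window contains non-ACGT characters: {window!r}")
    return codes


def pwm_log_likelihood(pwm: Pwm, window: str) -> float:
    """ln P(window | Pwm): the sum of per-position log weights."""
    codes = _window_codes(pwm.length, window)
    return float(pwm.log_probs[np.arange(pwm.length), codes].sum())


def dwm_log_likelihood(dwm: Dwm, window: str) -> tuple[float, PosteriorProfile]:
    """ln P(window | Dwm) under the posterior-product approximation."""
    L = dwm.length
    codes = _window_codes(L, window)
    lw = dwm.marginal.log_probs
    lp = dwm.log_pair_tensor
    log_u = np.empty((L, 4))
    for i in range(L):
        if L == 1:
            log_u[i] = lw[i]
            continue
        # sum over j != i of log pair(i,j)[a, s_j]; the diagonal block is zero
        s = lp[i, np.arange(L), :, codes].sum(axis=0)
        base = np.where(np.isfinite(lw[i]), (2.0 - L) * lw[i], -np.inf)
        log_u[i] = base + s
    log_z = logsumexp(log_u, axis=1)
    loglik = float((log_u[np.arange(L), codes] - log_z).sum())
    profile = PosteriorProfile(
        weights=np.exp(log_u),
        normalisers=np.exp(log_z),
        posterior=np.exp(log_u - log_z[:, None]),
    )
    return loglik, profile


def background_log_likelihood(background: BackgroundModel, window: str) -> float:
    codes = encode(window)
    if (codes > 3).any():
        raise ValueError(f"window contains non-ACGT characters: {window!r}")
    return float(background.log_probs[codes].sum())


def log_odds(model_loglik: float, window: str, background: BackgroundModel) -> float:
    """Natural-log odds of the model against the background for one window."""
    return model_loglik - background_log_likelihood(background, window)


def _pwm_window_scores(pwm: Pwm, codes: np.ndarray) -> np.ndarray:
    L = pwm.length
    windows = sliding_window_view(codes, L)
    safe = np.where(windows <= 3, windows, 0)
    scores = pwm.log_probs[np.arange(L)[None, :], safe].sum(axis=1)
    scores[(windows > 3).any(axis=1)] = np.nan
    return scores


def _dwm_window_scores(dwm: Dwm, codes: np.ndarray) -> np.ndarray:
    L = dwm.length
    windows = sliding_window_view(codes, L)
    safe = np.where(windows <= 3, windows, 0)
    n_win = safe.shape[0]
    lw = dwm.marginal.log_probs
    lp = dwm.log_pair_tensor
    jidx = np.arange(L)
    total = np.zeros(n_win)
    rows = np.arange(n_win)
    for i in range(L):
        if L == 1:
            log_u = np.broadcast_to(lw[i], (n_win, 4))
        else:
            # (j, beta, alpha) layout so fancy-indexing by window codes works
            lpi = lp[i].transpose(0, 2, 1)
            gathered = lpi[jidx[None, :], safe]  # (n_win, L, 4); j == i adds 0
            s = gathered.sum(axis=1)
            base = np.where(np.isfinite(lw[i]), (2.0 - L) * lw[i], -np.inf)
            log_u = base[None, :] + s
        log_z = logsumexp(log_u, axis=1)
        total += log_u[rows, safe[:, i]] - log_z
    total[(windows > 3).any(axis=1)] = np.nan
    return total


def _window_log_likelihoods(model: Pwm | Dwm, codes: np.ndarray) -> np.ndarray:
    if isinstance(model, Pwm):
        return _pwm_window_scores(model, codes)
    if isinstance(model, Dwm):
        return _dwm_window_scores(model, codes)
    raise TypeError(f"cannot score with {type(model).__name__}")


def scan_sequence(
    model: Pwm | Dwm,
    seq: str,
    background: BackgroundModel,
    sequence_id: str = "seq",
) -> list[ScoredSite]:
    """Score every window on both strands, keeping the better orientation.

    Returns one :class:`ScoredSite` per start position; windows containing
    non-ACGT characters are skipped.  Ties between strands go to '+'.
    """
    L = model.length
    codes = encode(seq)
    if codes.shape[0] < L:
        logger.warning(
            "sequence %s shorter than model (%d < %d); no windows scored",
            sequence_id,
            codes.shape[0],
            L,
        )
        return []
    fwd = _window_log_likelihoods(model, codes)
    rev = _window_log_likelihoods(reverse_complement(model), codes)
    bg_terms = np.where(codes <= 3, background.log_probs[np.where(codes <= 3, codes, 0)], 0.0)
    bg = sliding_window_view(bg_terms, L).sum(axis=1)
    with np.errstate(invalid="ignore"):
        lo_fwd = fwd - bg
        lo_rev = rev - bg
    sites: list[ScoredSite] = []
    for t in range(fwd.shape[0]):
        if np.isnan(lo_fwd[t]) or np.isnan(lo_rev[t]):
            continue
        if lo_fwd[t] >= lo_rev[t]:
            sites.append(ScoredSite(sequence_id, t, t + L, "+", float(lo_fwd[t])))
        else:
            sites.append(ScoredSite(sequence_id, t, t + L, "-", float(lo_rev[t])))
    return sites


def total_log_odds(sites: list[ScoredSite], positive_only: bool = False) -> float:
    """Sum of per-position best-orientation log-odds over all scored sites."""
    values = [s.logodds for s in sites]
    if positive_only:
        values = [v for v in values if v > 0]
    return float(sum(values))
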