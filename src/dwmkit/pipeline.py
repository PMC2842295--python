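"""Site selection, the two-step bootstrap matrix construction with
leave-one-out variants, and benchmark metrics.

The bootstrap takes a prior Pwm and a collection of target sequences: sites
selected with the prior (optionally widened by a flank) yield interim
matrices, which re-predict sites on all targets to yield the final posterior
Pwm and Dwm.  For every contributing target a leave-one-out matrix is also
built, omitting all of that target's sites, so predictions on a target never
rest on its own sequence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix_model import (
    BackgroundModel,
    Dwm,
    Pwm,
    SiteAlignment,
    dinucleotide_counts,
    dwm_from_counts,
    extend_alignment_with_flank,
    nucleotide_counts,
    pwm_from_counts,
)
from .scoring import ScoredSite, scan_sequence, total_log_odds

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionCriteria:
    """The three-branch site-selection rule (natural-log log-odds units):
    keep every site above ``primary_cutoff``; failing that, keep the single
    best site if it reaches ``fallback_cutoff``; otherwise reject the
    sequence."""

    primary_cutoff: float = 3.0
    fallback_cutoff: float = 1.5

    def __post_init__(self) -> None:
        if self.primary_cutoff < self.fallback_cutoff:
            raise ValueError("primary_cutoff must be >= fallback_cutoff")


def select_sites(
    scored: Sequence[ScoredSite], criteria: SelectionCriteria
) -> list[ScoredSite]:
    """Apply the selection rule to the scored windows of one sequence."""
    strong = [s for s in scored if s.logodds > criteria.primary_cutoff]
    if strong:
        return strong
    if scored:
        best = max(scored, key=lambda s: s.logodds)
        if best.logodds >= criteria.fallback_cutoff:
            return [best]
    return []


@dataclass
class PredictionRecord:
    """Per-probe aggregate of scored sites."""

    probe_id: str
    sites: list[ScoredSite]
    total_logodds: float
    best_logodds: float

    @classmethod
    def from_scan(
        cls, probe_id: str, scored: Sequence[ScoredSite], positive_only: bool = False
    ) -> "PredictionRecord":
        best = max((s.logodds for s in scored), default=-math.inf)
        return cls(
            probe_id=probe_id,
            sites=list(scored),
            total_logodds=total_log_odds(list(scored), positive_only=positive_only),
            best_logodds=best,
        )


@dataclass
class BootstrapResult:
    """Posterior matrices from the two-step bootstrap."""

    pwm: Pwm
    dwm: Dwm
    loo_pwm: dict[str, Pwm]
    loo_dwm: dict[str, Dwm]
    interim_pwm: Pwm
    interim_dwm: Dwm
    sites_pwm: dict[str, list[ScoredSite]]
    sites_dwm: dict[str, list[ScoredSite]]
    background: BackgroundModel

    def pwm_for(self, target_id: str) -> Pwm:
        return self.loo_pwm.get(target_id, self.pwm)

    def dwm_for(self, target_id: str) -> Dwm:
        return self.loo_dwm.get(target_id, self.dwm)


def _selected_sites(
    model: Pwm | Dwm,
    targets: Mapping[str, str],
    criteria: SelectionCriteria,
    background: BackgroundModel,
) -> dict[str, list[ScoredSite]]:
    out: dict[str, list[ScoredSite]] = {}
    for target_id, seq in targets.items():
        selected = select_sites(
            scan_sequence(model, seq, background, sequence_id=target_id), criteria
        )
        if selected:
            out[target_id] = selected
    return out


def _grouped_counts(
    alignment: SiteAlignment,
) -> tuple[np.ndarray, np.ndarray, dict[str, tuple[np.ndarray, np.ndarray, int]]]:
    """Total and per-source nucleotide/dinucleotide counts for an alignment."""
    codes = alignment.codes()
    L = alignment.length
    total_mono = nucleotide_counts(codes, L)
    total_di = dinucleotide_counts(codes, L)
    per_source: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
    sources = np.array(alignment.source_ids)
    for sid in dict.fromkeys(alignment.source_ids):
        sub = codes[sources == sid]
        per_source[sid] = (
            nucleotide_counts(sub, L),
            dinucleotide_counts(sub, L),
            sub.shape[0],
        )
    return total_mono, total_di, per_source


def _second_pass(
    model: Pwm | Dwm,
    targets: Mapping[str, str],
    criteria: SelectionCriteria,
    background: BackgroundModel,
    pseudocount: float,
    factor: str,
    kind: str,
) -> tuple[Pwm | Dwm, dict[str, Pwm | Dwm], dict[str, list[ScoredSite]]]:
    selected = _selected_sites(model, targets, criteria, background)
    if len(selected) < 2:
        raise ValueError(
            f"factor {factor!r}: only {len(selected)} target(s) contributed sites "
            f"in the {kind} re-prediction step"
        )
    coords = [
        (tid, s.start, s.end, s.strand) for tid, sel in selected.items() for s in sel
    ]
    alignment = extend_alignment_with_flank(coords, targets, flank=0)
    total_mono, total_di, per_source = _grouped_counts(alignment)
    n = alignment.count

    def _make(mono: np.ndarray, di: np.ndarray, count: int) -> Pwm | Dwm:
        if kind == "pwm":
            return pwm_from_counts(mono, count, pseudocount)
        return dwm_from_counts(di, mono, count, pseudocount)

    final = _make(total_mono, total_di, n)
    loo: dict[str, Pwm | Dwm] = {}
    for sid, (mono, di, count) in per_source.items():
        loo[sid] = _make(total_mono - mono, total_di - di, n - count)
    return final, loo, selected


def bootstrap_build(
    prior_pwm: Pwm,
    targets: Mapping[str, str],
    flank: int = 10,
    criteria: SelectionCriteria | None = None,
    pseudocount: float = 1.0,
    background: BackgroundModel | None = None,
    factor: str = "motif",
) -> BootstrapResult:
    """Two-step posterior matrix construction with leave-one-out variants.

    Step 1 selects sites on every target with the prior Pwm, widens them by
    ``flank`` bp, and builds interim matrices.  Step 2 re-predicts sites with
    the interim matrices (same criteria, no additional flank) and builds the
    final matrices, plus one leave-one-out Pwm/Dwm per contributing target.
    The whole procedure is deterministic.
    """
    criteria = criteria or SelectionCriteria()
    if background is None:
        background = BackgroundModel.from_sequences(targets.values())
    step1 = _selected_sites(prior_pwm, targets, criteria, background)
    coords = [
        (tid, s.start, s.end, s.strand) for tid, sel in step1.items() for s in sel
    ]
    if not coords:
        raise ValueError(f"factor {factor!r}: the prior Pwm selected no sites")
    alignment = extend_alignment_with_flank(coords, targets, flank=flank)
    contributing = set(alignment.source_ids)
    if len(contributing) < 2:
        raise ValueError(
            f"factor {factor!r}: only {len(contributing)} target(s) contributed sites"
        )
    codes_mono = nucleotide_counts(alignment.codes(), alignment.length)
    interim_pwm = pwm_from_counts(codes_mono, alignment.count, pseudocount)
    interim_dwm = dwm_from_counts(
        dinucleotide_counts(alignment.codes(), alignment.length),
        codes_mono,
        alignment.count,
        pseudocount,
    )
    final_pwm, loo_pwm, sites_pwm = _second_pass(
        interim_pwm, targets, criteria, background, pseudocount, factor, "pwm"
    )
    final_dwm, loo_dwm, sites_dwm = _second_pass(
        interim_dwm, targets, criteria, background, pseudocount, factor, "dwm"
    )
    return BootstrapResult(
        pwm=final_pwm,
        dwm=final_dwm,
        loo_pwm=loo_pwm,
        loo_dwm=loo_dwm,
        interim_pwm=interim_pwm,
        interim_dwm=interim_dwm,
        sites_pwm=sites_pwm,
        sites_dwm=sites_dwm,
        background=background,
    )


class CurvePoint(NamedTuple):
    cutoff: float
    precision: float
    sensitivity: float
    n_predicted: int


def precision_sensitivity_at(
    predictions: Sequence[PredictionRecord],
    annotated_targets: set[str],
    cutoff: float,
) -> CurvePoint:
    """Probe-level precision and sensitivity at one log-odds cutoff.

    A probe counts as predicted when its best site reaches the cutoff.  With
    zero predictions the precision is 1 by convention (flagged by
    ``n_predicted == 0``).
    """
    if not annotated_targets:
        raise ValueError("the annotated target set is empty")
    predicted = {p.probe_id for p in predictions if p.best_logodds >= cutoff}
    tp = len(predicted & annotated_targets)
    precision = tp / len(predicted) if predicted else 1.0
    sensitivity = tp / len(annotated_targets)
    return CurvePoint(cutoff, precision, sensitivity, len(predicted))


def precision_sensitivity_curve(
    predictions: Sequence[PredictionRecord], annotated_targets: set[str]
) -> list[CurvePoint]:
    """Sweep the cutoff over the observed best log-odds (descending)."""
    if not annotated_targets:
        raise ValueError("the annotated target set is empty")
    cutoffs = sorted(
        {p.best_logodds for p in predictions if math.isfinite(p.best_logodds)},
        reverse=True,
    )
    return [precision_sensitivity_at(predictions, annotated_targets, c) for c in cutoffs]


def precision_at_sensitivity(curve: Sequence[CurvePoint], sensitivity: float) -> float:
    """Precision at the highest cutoff whose sensitivity reaches the target."""
    for point in curve:  # descending cutoff, non-decreasing sensitivity
        if point.sensitivity >= sensitivity:
            return point.precision
    return curve[-1].precision if curve else 0.0


def _interval(annotation) -> tuple[float, float]:
    if hasattr(annotation, "start"):
        return float(annotation.start), float(annotation.end)
    start, end = annotation[0], annotation[1]
    return float(start), float(end)


def site_hit(
    prediction: ScoredSite,
    annotation,
    mode: str = "midpoint-midpoint",
    tolerance: float = 10.0,
) -> bool:
    """Whether a predicted site hits an annotated interval.

    ``midpoint-midpoint``: the midpoints lie within ``tolerance`` bp of each
    other.  ``midpoint-region``: the prediction midpoint falls inside the
    annotated region widened by ``tolerance`` bp on each side (half-open on
    the right).
    """
    a_start, a_end = _interval(annotation)
    mid_pred = prediction.midpoint
    if mode == "midpoint-midpoint":
        return abs(mid_pred - (a_start + a_end) / 2.0) <= tolerance
    if mode == "midpoint-region":
        return a_start - tolerance <= mid_pred < a_end + tolerance
    raise ValueError(f"unknown hit mode {mode!r}")


@dataclass
class DiscriminationResult:
    precision: float
    disc_precision: float
    sensitivity: float
    n_predictions: int
    defined: bool = True


def discriminative_precision(
    predictions: Sequence[ScoredSite],
    real_sites: Sequence,
    fake_sites: Sequence,
    cutoff: float,
    mode: str = "midpoint-region",
    tolerance: float = 10.0,
) -> DiscriminationResult:
    """Precision, discriminative precision and site sensitivity at a cutoff.

    Over predictions at or above the cutoff: precision is the fraction
    hitting real sites, discriminative precision subtracts the fraction
    hitting decoy sites, and sensitivity is the fraction of real sites hit.
    """
    kept = [p for p in predictions if p.logodds >= cutoff]
    n_tot = len(kept)
    if n_tot == 0:
        return DiscriminationResult(0.0, 0.0, 0.0, 0, defined=False)
    n_real = sum(any(site_hit(p, r, mode, tolerance) for r in real_sites) for p in kept)
    n_fake = sum(any(site_hit(p, f, mode, tolerance) for f in fake_sites) for p in kept)
    hit_real = sum(any(site_hit(p, r, mode, tolerance) for p in kept) for r in real_sites)
    sensitivity = hit_real / len(real_sites) if real_sites else 0.0
    return DiscriminationResult(
        precision=n_real / n_tot,
        disc_precision=(n_real - n_fake) / n_tot,
        sensitivity=sensitivity,
        n_predictions=n_tot,
    )


@dataclass
class BindingTable:
    """Per-probe ChIP binding p-values across experimental conditions."""

    pvalues: pd.DataFrame  # index: probe id; columns: condition names
    rich_condition: str

    def __post_init__(self) -> None:
        if self.rich_condition not in self.pvalues.columns:
            raise ValueError(f"missing rich-medium column {self.rich_condition!r}")
        values = self.pvalues.to_numpy(dtype=float)
        finite = values[~np.isnan(values)]
        if np.any(finite <= 0) or np.any(finite > 1):
            raise ValueError("p-values must lie in (0, 1]")

    def combined_pvalues(
        self, max_other_conditions: int = 2, reported_threshold: float = 1e-3
    ) -> pd.Series:
        """Geometric mean of the rich-medium p-value and up to the
        ``max_other_conditions`` smallest other-condition p-values, counting a
        condition only when binding is reported there (p <= threshold)."""
        out = {}
        others = self.pvalues.drop(columns=[self.rich_condition])
        for probe, row in self.pvalues.iterrows():
            rich = row[self.rich_condition]
            if np.isnan(rich):
                continue
            reported = others.loc[probe].dropna()
            reported = reported[reported <= reported_threshold]
            chosen = reported.nsmallest(max_other_conditions)
            values = np.array([rich, *chosen.to_numpy()])
            out[probe] = float(np.exp(np.mean(np.log(values))))
        return pd.Series(out, name="combined_p")


@dataclass
class BindingCorrelation:
    r: float
    n_probes: int
    degenerate: bool = False


def correlate_with_binding(
    predictions: Sequence[PredictionRecord],
    binding: BindingTable,
    max_other_conditions: int = 2,
    transform: str = "neglog",
    reported_threshold: float = 1e-3,
) -> BindingCorrelation:
    """Pearson correlation of per-probe total log-odds with combined binding.

    The default transform correlates against ``-log(combined p)`` so that
    stronger binding (smaller p) should give a positive coefficient; pass
    ``transform='raw'`` for the untransformed p-value.
    """
    combined = binding.combined_pvalues(max_other_conditions, reported_threshold)
    totals = {p.probe_id: p.total_logodds for p in predictions}
    common = [probe for probe in combined.index if probe in totals]
    if not common:
        raise ValueError("no overlapping probes between predictions and binding table")
    x = np.array([totals[p] for p in common])
    p_vals = combined.loc[common].to_numpy()
    if transform == "neglog":
        y = -np.log(p_vals)
    elif transform == "raw":
        y = p_vals
    else:
        raise ValueError(f"unknown transform {transform!r}")
    if len(common) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return BindingCorrelation(r=0.0, n_probes=len(common), degenerate=True)
    r, _ = stats.pearsonr(x, y)
    return BindingCorrelation(r=float(r), n_probes=len(common))


def yeast_correlation_census(
    tamo_path,
    targets_path,
    probes_fasta_path,
    min_targets: int = 32,
    criteria: SelectionCriteria | None = None,
    pseudocount: float = 1.0,
):
    """Recompute the 40-factor yeast gapped-dinucleotide census from the
    published supplementary files (prior log-odds matrices, per-factor target
    lists, and the microarray probe FASTA).

    For every factor with at least ``min_targets`` targets that map to probe
    sequences, sites are selected in those probes with the converted prior
    Pwm under the standard selection rule, aligned without flank, and fed to
    the deviation analysis; the per-factor results are aggregated by
    :func:`dwmkit.correlation.correlation_census`.
    """
    import re

    from . import io as io_mod
    from .correlation import correlation_census

    criteria = criteria or SelectionCriteria()
    matrices = io_mod.read_tamo(tamo_path)
    probes = io_mod.read_fasta(probes_fasta_path)
    background = BackgroundModel.from_sequences(probes.values())

    orf_pattern = re.compile(r"Y[A-P][LR]\d{3}[WC](?:-[A-Z])?")
    orf_to_probes: dict[str, list[str]] = {}
    for probe_id in probes:
        for orf in orf_pattern.findall(probe_id.upper()):
            orf_to_probes.setdefault(orf, []).append(probe_id)

    matrix_by_name = {name.upper(): m for name, m in matrices.items()}
    alignments: dict[str, SiteAlignment] = {}
    with open(targets_path) as handle:
        for line in handle:
            fields = line.split()
            if len(fields) < 2:
                continue
            factor = fields[0].split(";")[0].upper()
            if factor not in matrix_by_name:
                continue
            target_probes: list[str] = []
            for orf in fields[1:]:
                target_probes.extend(orf_to_probes.get(orf.upper(), []))
            target_probes = list(dict.fromkeys(target_probes))
            if len(target_probes) < min_targets:
                continue
            prior = io_mod.convert_logodds_to_pwm(
                matrix_by_name[factor], background, pseudocount
            )
            targets = {p: probes[p] for p in target_probes}
            selected = _selected_sites(prior, targets, criteria, background)
            coords = [
                (tid, s.start, s.end, s.strand)
                for tid, sel in selected.items()
                for s in sel
            ]
            if not coords:
                logger.warning("factor %s: no sites selected; skipped", factor)
                continue
            alignments[factor] = extend_alignment_with_flank(coords, targets, flank=0)
    logger.info("census over %d factors", len(alignments))
    return correlation_census(alignments, pseudocount)


@dataclass
class ModelComparison:
    """Probe-level benchmark of leave-one-out Pwm vs Dwm predictions."""

    pwm_predictions: list[PredictionRecord]
    dwm_predictions: list[PredictionRecord]
    pwm_curve: list[CurvePoint]
    dwm_curve: list[CurvePoint]
    pwm_precision: float
    dwm_precision: float
    sensitivity: float


def compare_models_loo(
    prior_pwm: Pwm,
    probes: Mapping[str, str],
    annotated_targets: set[str],
    flank: int = 2,
    criteria: SelectionCriteria | None = None,
    pseudocount: float = 1.0,
    background: BackgroundModel | None = None,
    sensitivity: float = 0.5,
    factor: str = "motif",
) -> ModelComparison:
    """Bootstrap matrices on the annotated probes, predict every probe with
    leave-one-out matrices where applicable, and compare the precision of the
    Pwm and Dwm tracks at a fixed sensitivity."""
    if background is None:
        background = BackgroundModel.from_sequences(probes.values())
    training = {t: probes[t] for t in annotated_targets if t in probes}
    result = bootstrap_build(
        prior_pwm,
        training,
        flank=flank,
        criteria=criteria,
        pseudocount=pseudocount,
        background=background,
        factor=factor,
    )
    pwm_records: list[PredictionRecord] = []
    dwm_records: list[PredictionRecord] = []
    for probe_id, seq in probes.items():
        pwm_scan = scan_sequence(result.pwm_for(probe_id), seq, background, probe_id)
        dwm_scan = scan_sequence(result.dwm_for(probe_id), seq, background, probe_id)
        pwm_records.append(PredictionRecord.from_scan(probe_id, pwm_scan))
        dwm_records.append(PredictionRecord.from_scan(probe_id, dwm_scan))
    pwm_curve = precision_sensitivity_curve(pwm_records, annotated_targets)
    dwm_curve = precision_sensitivity_curve(dwm_records, annotated_targets)
    return ModelComparison(
        pwm_predictions=pwm_records,
        dwm_predictions=dwm_records,
        pwm_curve=pwm_curve,
        dwm_curve=dwm_curve,
        pwm_precision=precision_at_sensitivity(pwm_curve, sensitivity),
        dwm_precision=precision_at_sensitivity(dwm_curve, sensitivity),
        sensitivity=sensitivity,
    )
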