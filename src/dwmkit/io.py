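"""Readers and writers for the plain-text formats the toolkit touches.

Coordinates are 0-based half-open throughout; strands are '+'/'-'.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .correlation import GapHistogram, PairDeviation
from .matrix_model import BackgroundModel, Dwm, Pwm, SiteAlignment
from .scoring import ScoredSite

logger = logging.getLogger(__name__)

_NON_ACGT = re.compile(r"[^ACGT]")


def _clean_sequence(raw: str) -> str:
    """Uppercase, map U to T, and replace any other non-ACGT character by N."""
    seq = raw.upper().replace("U", "T")
    return _NON_ACGT.sub("N", seq)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Parse a FASTA file into an id -> sequence mapping."""
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}:{lineno}: malformed FASTA (expected '>' header, "
                        f"got {line.strip()[:30]!r})"
                    )
                break
        else:
            logger.warning("empty FASTA file: %s", path)
            return {}
    records: dict[str, str] = {}
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            name = header.split()[0] if header.split() else header
            if name in records:
                raise ValueError(f"{path}: duplicate sequence id {name!r}")
            records[name] = _clean_sequence(seq)
    return records


def write_fasta(path: str | Path, records: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in records.items():
            handle.write(f">{name}\n")
            for k in range(0, len(seq), width):
                handle.write(seq[k : k + width] + "\n")


def read_alignment(path: str | Path) -> SiteAlignment:
    """Site alignment from FASTA or one-sequence-per-line text."""
    path = Path(path)
    with open(path) as handle:
        first = handle.read(1)
    if first == ">":
        records = read_fasta(path)
        return SiteAlignment(list(records.values()), source_ids=list(records))
    sequences = [
        line.strip().upper() for line in path.read_text().splitlines() if line.strip()
    ]
    return SiteAlignment(sequences)


# --- matrix serialisation ---------------------------------------------------

_FLOAT = "%.17g"


def _format_row(row: Iterable[float]) -> str:
    return " ".join(_FLOAT % v for v in row)


def write_pwm(path: str | Path, pwm: Pwm) -> None:
    """Header line (PWM, length, pseudocount) then L rows in A C G T order."""
    with open(path, "w") as handle:
        handle.write(_pwm_block(pwm))


def _pwm_block(pwm: Pwm) -> str:
    lines = [f"PWM {pwm.length} {_FLOAT % pwm.pseudocount}"]
    lines += [_format_row(row) for row in pwm.probs]
    return "\n".join(lines) + "\n"


def _parse_pwm_block(lines: list[str], start: int) -> tuple[Pwm, int]:
    header = lines[start].split()
    if header[0] != "PWM" or len(header) != 3:
        raise ValueError(f"malformed PWM header: {lines[start]!r}")
    length = int(header[1])
    pseudocount = float(header[2])
    rows = [
        [float(v) for v in lines[start + 1 + i].split()] for i in range(length)
    ]
    return Pwm(np.array(rows), pseudocount=pseudocount), start + 1 + length


def read_pwm(path: str | Path) -> Pwm:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    pwm, _ = _parse_pwm_block(lines, 0)
    return pwm


def write_dwm(path: str | Path, dwm: Dwm) -> None:
    """Header, marginal PWM block, then one 'PAIR i j' block per pair i < j.

    Pair rows correspond to the nucleotide at position i, columns to the
    nucleotide at position j, both in A C G T order.
    """
    with open(path, "w") as handle:
        handle.write(f"DWM {dwm.length} {_FLOAT % dwm.prior_mass}\n")
        handle.write(_pwm_block(dwm.marginal))
        for (i, j), table in sorted(dwm.pairs.items()):
            handle.write(f"PAIR {i} {j}\n")
            for row in table:
                handle.write(_format_row(row) + "\n")


def read_dwm(path: str | Path) -> Dwm:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = lines[0].split()
    if header[0] != "DWM" or len(header) != 3:
        raise ValueError(f"malformed DWM header: {lines[0]!r}")
    length = int(header[1])
    prior_mass = float(header[2])
    marginal, pos = _parse_pwm_block(lines, 1)
    pairs: dict[tuple[int, int], np.ndarray] = {}
    while pos < len(lines):
        tag, i, j = lines[pos].split()
        if tag != "PAIR":
            raise ValueError(f"malformed pair header: {lines[pos]!r}")
        table = np.array(
            [[float(v) for v in lines[pos + 1 + r].split()] for r in range(4)]
        )
        pairs[(int(i), int(j))] = table
        pos += 5
    dwm = Dwm(marginal=marginal, pairs=pairs, prior_mass=prior_mass)
    if dwm.length != length:
        raise ValueError("DWM header length does not match its marginal")
    return dwm


def detect_matrix(path: str | Path) -> Pwm | Dwm:
    """Load a serialised matrix, dispatching on the header tag."""
    with open(path) as handle:
        tag = handle.readline().split()[0]
    if tag == "PWM":
        return read_pwm(path)
    if tag == "DWM":
        return read_dwm(path)
    raise ValueError(f"{path}: unrecognised matrix header {tag!r}")


# --- scored sites (BED6-like) ----------------------------------------------


def write_sites_bed(path: str | Path, sites: Sequence[ScoredSite]) -> None:
    """BED6-like text: sequence_id, start, end, name, logodds, strand."""
    with open(path, "w") as handle:
        for k, s in enumerate(sites):
            handle.write(
                f"{s.sequence_id}\t{s.start}\t{s.end}\tsite{k}\t"
                f"{_FLOAT % s.logodds}\t{s.strand}\n"
            )


def read_sites_bed(path: str | Path) -> list[ScoredSite]:
    sites = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        chrom, start, end, _name, score, strand = line.split("\t")[:6]
        sites.append(ScoredSite(chrom, int(start), int(end), strand, float(score)))
    return sites


def read_intervals_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """BED-like intervals with an optional label column (chrom start end [label])."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        label = fields[3] if len(fields) > 3 else ""
        out.append((fields[0], int(fields[1]), int(fields[2]), label))
    return out


# --- deviation tables -------------------------------------------------------

_DEV_COLUMNS = [
    "factor", "i", "j", "gap", "alpha", "beta",
    "n_obs", "expected", "sigma", "z", "significant", "abundant",
]


def deviations_to_frame(devs: Sequence[PairDeviation], factor: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "factor": factor,
                "i": d.i,
                "j": d.j,
                "gap": d.gap,
                "alpha": d.alpha,
                "beta": d.beta,
                "n_obs": d.n_obs,
                "expected": d.expected,
                "sigma": d.sigma,
                "z": d.z,
                "significant": d.significant,
                "abundant": d.abundant,
            }
            for d in devs
        ],
        columns=_DEV_COLUMNS,
    )


def write_deviation_table(
    path: str | Path, devs: Sequence[PairDeviation], factor: str = ""
) -> None:
    deviations_to_frame(devs, factor).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_deviation_table(path: str | Path) -> list[PairDeviation]:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        PairDeviation(
            i=int(row.i),
            j=int(row.j),
            alpha=row.alpha,
            beta=row.beta,
            expected=float(row.expected),
            sigma=float(row.sigma),
            n_obs=int(row.n_obs),
            z=float(row.z),
            significant=bool(row.significant),
            abundant=bool(row.abundant),
        )
        for row in frame.itertuples()
    ]


def write_gap_histogram(path: str | Path, histogram: GapHistogram) -> None:
    gaps = sorted(histogram.availability)
    pd.DataFrame(
        {
            "gap": gaps,
            "count": [histogram.counts.get(g, 0) for g in gaps],
            "availability": [histogram.availability[g] for g in gaps],
            "rate": [histogram.rates.get(g, float("nan")) for g in gaps],
        }
    ).to_csv(path, sep="\t", index=False)


# --- log-odds matrix dialect ------------------------------------------------


@dataclass
class LogOddsMatrix:
    """A motif matrix in log-odds units relative to a stated background."""

    values: np.ndarray  # (L, 4) in A C G T order

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 4:
            raise ValueError("log-odds matrix must be an (L, 4) table")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("log-odds entries must be finite")

    @property
    def length(self) -> int:
        return self.values.shape[0]


def convert_logodds_to_pwm(
    matrix: LogOddsMatrix, background: BackgroundModel, pseudocount: float = 1.0
) -> Pwm:
    """Probability matrix with w = b * exp(lambda), renormalised per column."""
    shifted = matrix.values - matrix.values.max(axis=1, keepdims=True)
    unnorm = background.probs[None, :] * np.exp(shifted)
    probs = unnorm / unnorm.sum(axis=1, keepdims=True)
    return Pwm(probs, pseudocount=pseudocount)


def pwm_to_logodds(pwm: Pwm, background: BackgroundModel) -> LogOddsMatrix:
    if np.any(pwm.probs <= 0):
        raise ValueError("log-odds conversion requires strictly positive weights")
    return LogOddsMatrix(np.log(pwm.probs / background.probs[None, :]))


_TAMO_ROW = re.compile(r"^#([ACGT])\s+(.*)$")


def read_tamo(path: str | Path) -> dict[str, LogOddsMatrix]:
    """Best-effort parser for TAMO-style log-odds matrix dumps.

    Recognises blocks introduced by a 'Log-odds matrix' line followed by
    '#A'/'#C'/'#G'/'#T' rows; motifs are keyed by the nearest 'Source:' line
    when present, else by block index.
    """
    matrices: dict[str, LogOddsMatrix] = {}
    rows: dict[str, list[float]] = {}
    block = 0
    pending: LogOddsMatrix | None = None

    def _finish() -> LogOddsMatrix | None:
        nonlocal rows
        if set(rows) == set("ACGT"):
            values = np.array([rows[c] for c in "ACGT"]).T
            rows = {}
            return LogOddsMatrix(values)
        rows = {}
        return None

    for line in Path(path).read_text().splitlines():
        m = _TAMO_ROW.match(line.strip())
        if m:
            values = [float(v) for v in m.group(2).split()]
            if values:
                rows[m.group(1)] = values
            continue
        if rows:
            matrix = _finish()
            if matrix is not None:
                pending = matrix
                block += 1
                matrices[f"motif_{block}"] = matrix
        if line.startswith("Source:") and pending is not None:
            name = line.split(":", 1)[1].strip().split()[0]
            if name:
                matrices[name] = pending
                matrices.pop(f"motif_{block}", None)
            pending = None
    if rows:
        matrix = _finish()
        if matrix is not None:
            block += 1
            matrices[f"motif_{block}"] = matrix
    return matrices


def read_binding_table(
    path: str | Path,
    rich_condition: str,
    probe_column: str | int = 0,
    sep: str | None = None,
) -> "pd.DataFrame":
    """Delimited per-probe p-value table, indexed by probe id."""
    frame = pd.read_csv(path, sep=sep, engine="python")
    if isinstance(probe_column, int):
        probe_column = frame.columns[probe_column]
    frame = frame.set_index(probe_column)
    if rich_condition not in frame.columns:
        raise ValueError(f"binding table lacks condition column {rich_condition!r}")
    return frame
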