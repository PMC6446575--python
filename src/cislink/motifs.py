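"""PWM scanning and target-versus-background motif enrichment.

Motifs are position probability matrices scored as log2-odds against a
background base composition (uniform by default).  A sequence "hits" a
motif when any window on either strand scores at least a fixed fraction
of the motif's maximum achievable score (default 0.8).  Set-level
enrichment compares hit rates between a target enhancer set and a
background enhancer set with a one-sided Fisher exact test, BH-adjusted
across motifs.

The bundled motif file covers the nuclear-receptor geometry relevant to
LXR biology — a DR4 response element (AGGTCAnnnnAGGTCA), the AGGTCA
half-site — plus NF-kB and AP-1 as inflammation-pathway references; all
are consensus-built matrices, not database-fitted models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .intervals import GenomicInterval

__all__ = [
    "PWM",
    "ScanResult",
    "consensus_pwm",
    "read_pwms",
    "write_pwms",
    "load_builtin_pwms",
    "scan_sequence",
    "set_enrichment",
    "fetch_sequences",
]

_PSEUDO = 1e-3
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "N": "ACGT",
}


@dataclass
class PWM:
    motif_id: str
    matrix: np.ndarray  # L x 4 base probabilities, A C G T order
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold_frac: float = 0.8

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: matrix must be L x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: matrix rows must sum to 1")
        if not (0.0 < self.threshold_frac <= 1.0):
            raise ValueError("threshold_frac must be in (0, 1]")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        p = (self.matrix + _PSEUDO) / (1.0 + 4.0 * _PSEUDO)
        return np.log2(p / self.background[None, :])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def threshold(self) -> float:
        return self.threshold_frac * self.max_score


def consensus_pwm(
    motif_id: str, consensus: str, strong: float = 0.91, threshold_frac: float = 0.8
) -> PWM:
    """Build a PWM from an IUPAC consensus string.

    Allowed bases split ``strong`` probability evenly; disallowed bases
    share the remainder.  ``N``/``n`` positions are uniform.
    """
    rows = []
    for ch in consensus.upper():
        allowed = _IUPAC.get(ch)
        if allowed is None:
            raise ValueError(f"unsupported consensus symbol {ch!r}")
        row = np.empty(4)
        if len(allowed) == 4:
            row[:] = 0.25
        else:
            weak = (1.0 - strong) / (4 - len(allowed))
            row[:] = weak
            for b in allowed:
                row[_BASE_INDEX[b]] = strong / len(allowed)
        rows.append(row)
    return PWM(motif_id, np.array(rows), threshold_frac=threshold_frac)


# ---------------------------------------------------------------------------
# PWM text format: one block per motif, ">id" header, L rows "A C G T"
# ---------------------------------------------------------------------------


def read_pwms(path: str | Path, threshold_frac: float = 0.8) -> list[PWM]:
    pwms: list[PWM] = []
    name, rows = None, []
    def flush() -> None:
        if name is not None:
            if not rows:
                raise ValueError(f"motif {name!r} has no matrix rows")
            pwms.append(PWM(name, np.array(rows), threshold_frac=threshold_frac))
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                name, rows = line[1:].split()[0], []
            else:
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise ValueError(f"{path}: expected 4 probabilities per row")
                rows.append(vals)
    flush()
    return pwms


def write_pwms(pwms: Sequence[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            for row in pwm.matrix:
                fh.write("\t".join(format(v, ".6g") for v in row) + "\n")


def load_builtin_pwms(threshold_frac: float = 0.8) -> list[PWM]:
    """The bundled DR4/LXRE, NR half-site, NF-kB and AP-1 matrices."""
    ref = resources.files("cislink").joinpath("data/motifs.pwm")
    with resources.as_file(ref) as path:
        return read_pwms(path, threshold_frac=threshold_frac)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

_CODE = np.full(256, -1, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score of every window; windows containing N score -inf."""
    L = log_odds.shape[0]
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    bad = np.zeros(n_win, dtype=bool)
    for i in range(L):
        c = codes[i : i + n_win]
        bad |= c < 0
        scores += log_odds[i, np.clip(c, 0, 3)]
    scores[bad] = -np.inf
    return scores


@dataclass
class ScanResult:
    motif_id: str
    positions: list[tuple[int, str]]  # (window start on forward strand, strand)
    best_score: float

    @property
    def n_hits(self) -> int:
        return len(self.positions)


def scan_sequence(seq: str, pwm: PWM) -> ScanResult:
    """Scan both strands; a hit is a window scoring >= threshold_frac of
    the maximum achievable log-odds score."""
    lom = pwm.log_odds
    L = pwm.length
    codes = _encode(seq)
    fwd = _window_scores(codes, lom)
    # reverse strand: score the reverse complement matrix on the forward
    # sequence, so positions stay in forward coordinates
    rc_lom = lom[::-1, ::-1]
    rev = _window_scores(codes, rc_lom)
    hits: list[tuple[int, str]] = []
    best = -math.inf
    for scores, strand in ((fwd, "+"), (rev, "-")):
        if scores.size:
            best = max(best, float(scores.max()))
            for i in np.flatnonzero(scores >= pwm.threshold):
                hits.append((int(i), strand))
    hits.sort()
    return ScanResult(pwm.motif_id, hits, best)


# ---------------------------------------------------------------------------
# set enrichment
# ---------------------------------------------------------------------------


def fetch_sequences(
    intervals: Sequence[GenomicInterval], fasta: str | Path | dict[str, str]
) -> list[str]:
    """Sequences for intervals from a FASTA path (via pyfaidx) or an
    in-memory {chrom: sequence} dict."""
    if isinstance(fasta, dict):
        return [fasta[iv.chrom][iv.start : iv.end] for iv in intervals]
    from pyfaidx import Fasta

    fa = Fasta(str(fasta))
    return [fa[iv.chrom][iv.start : iv.end].seq for iv in intervals]


def set_enrichment(
    target: Sequence[GenomicInterval],
    background: Sequence[GenomicInterval],
    fasta: str | Path | dict[str, str],
    pwms: Sequence[PWM],
) -> pd.DataFrame:
    """Per-motif hit-rate enrichment of target versus background enhancers.

    Returns a DataFrame indexed by motif id with columns target_rate,
    background_rate, fold_enrichment, p (one-sided Fisher exact), q (BH).
    A motif absent from both sets has undefined (NaN) fold and p = 1.
    """
    if not target or not background:
        raise ValueError("target and background sets must be non-empty")
    tgt_seqs = fetch_sequences(target, fasta)
    bg_seqs = fetch_sequences(background, fasta)
    rows = []
    for pwm in pwms:
        t_hit = sum(1 for s in tgt_seqs if scan_sequence(s, pwm).n_hits > 0)
        b_hit = sum(1 for s in bg_seqs if scan_sequence(s, pwm).n_hits > 0)
        t_rate = t_hit / len(tgt_seqs)
        b_rate = b_hit / len(bg_seqs)
        if t_hit == 0 and b_hit == 0:
            fold = math.nan
        elif b_rate == 0:
            fold = math.inf
        else:
            fold = t_rate / b_rate
        table = [[t_hit, len(tgt_seqs) - t_hit], [b_hit, len(bg_seqs) - b_hit]]
        _, p = stats.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "motif_id": pwm.motif_id,
                "target_rate": t_rate,
                "background_rate": b_rate,
                "fold_enrichment": fold,
                "p": float(p),
            }
        )
    df = pd.DataFrame(rows).set_index("motif_id")
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df
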