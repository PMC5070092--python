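"""PWM scanning of allele-specific flanks, JASPAR-style relative scores.

A position frequency matrix is turned into a log2 likelihood-ratio PWM
with a background-distributed pseudocount (JASPAR-tool convention:
cell = log2(((count + pc*bg_b) / (col_total + pc)) / bg_b)).  Hits are
reported when the *relative* score — (raw - min)/(max - min) over all
possible words — reaches the threshold (0.80 by default).  For an X/Y
variant, both alleles are substituted into the flank and only scan windows
overlapping the variant base are compared, so a gained or lost site is
attributable to the SNP itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import BASES, Pfm

log = logging.getLogger(__name__)

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

LOST_ON_Y = "LOST_ON_Y"
GAINED_ON_Y = "GAINED_ON_Y"
UNCHANGED = "UNCHANGED"


@dataclass(frozen=True)
class Pwm:
    matrix_id: str
    name: str
    matrix: np.ndarray  # (4, L) log2 likelihood ratios, rows A,C,G,T
    score_min: float
    score_max: float

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def relative(self, raw: float) -> float:
        if self.score_max == self.score_min:
            return 1.0  # constant matrix: every word is the best word
        return (raw - self.score_min) / (self.score_max - self.score_min)


@dataclass(frozen=True)
class BindingHit:
    motif_id: str
    offset: int  # 0-based position of the match start on the forward sequence
    strand: str  # '+' or '-'
    raw_score: float
    relative_score: float


@dataclass(frozen=True)
class AlleleDiff:
    motif_id: str
    status: str  # LOST_ON_Y | GAINED_ON_Y | UNCHANGED
    best_hit_x: BindingHit | None
    best_hit_y: BindingHit | None


def pfm_to_pwm(
    pfm: Pfm, pseudocount: float = 0.8, background: Sequence[float] | None = None
) -> Pwm:
    """Log2 likelihood-ratio PWM with background-distributed pseudocount."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any() or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be a positive 4-vector summing to 1")
    counts = pfm.counts
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError(f"PFM {pfm.matrix_id}: zero column total")
    probs = (counts + pseudocount * bg[:, None]) / (totals + pseudocount)
    matrix = np.log2(probs / bg[:, None])
    return Pwm(
        matrix_id=pfm.matrix_id,
        name=pfm.name,
        matrix=matrix,
        score_min=float(matrix.min(axis=0).sum()),
        score_max=float(matrix.max(axis=0).sum()),
    )


def _encode(seq: str) -> np.ndarray:
    """Base indices; non-ACGT encoded as -1."""
    return np.array([_BASE_INDEX.get(b, -1) for b in seq.upper()], dtype=np.int64)


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


def score_word(word: str, pwm: Pwm) -> float:
    """Raw score of one exact-length word (forward strand)."""
    idx = _encode(word)
    if len(idx) != pwm.length or (idx < 0).any():
        raise ValueError("word must be ACGT-only and match the motif length")
    return float(pwm.matrix[idx, np.arange(pwm.length)].sum())


def scan_sequence(
    seq: str,
    pwm: Pwm,
    threshold: float = 0.80,
    both_strands: bool = True,
    offsets: Sequence[int] | None = None,
) -> list[BindingHit]:
    """All hits with relative score >= threshold.

    Reverse-strand matches are scored on the reverse complement and
    reported at their forward-sequence offset.  Windows containing
    non-ACGT characters are skipped with a warning.  ``offsets`` restricts
    the scan to the given forward start positions.
    """
    L = pwm.length
    if len(seq) < L:
        raise ValueError(f"sequence shorter than motif ({len(seq)} < {L})")
    idx = _encode(seq)
    if (idx < 0).any():
        log.warning("scan_sequence: skipping windows with non-ACGT characters")
    all_offsets = range(len(seq) - L + 1) if offsets is None else offsets
    cols = np.arange(L)
    rc_matrix = pwm.matrix[::-1, ::-1]  # scoring the reverse complement in place
    hits: list[BindingHit] = []
    for o in all_offsets:
        if o < 0 or o + L > len(seq):
            continue
        window = idx[o : o + L]
        if (window < 0).any():
            continue
        raw = float(pwm.matrix[window, cols].sum())
        rel = pwm.relative(raw)
        if rel >= threshold:
            hits.append(BindingHit(pwm.matrix_id, o, "+", raw, rel))
        if both_strands:
            raw_rc = float(rc_matrix[window, cols].sum())
            rel_rc = pwm.relative(raw_rc)
            if rel_rc >= threshold:
                hits.append(BindingHit(pwm.matrix_id, o, "-", raw_rc, rel_rc))
    return hits


def allele_diff(
    flank: str,
    variant_offset: int,
    x_allele: str,
    y_allele: str,
    pwms: Sequence[Pwm],
    threshold: float = 0.80,
    flank_radius: int = 20,
) -> list[AlleleDiff]:
    """Binding-site gains/losses between the X and the Y allele of one SNP.

    Each allele is substituted at ``variant_offset`` and, per motif, only
    scan windows overlapping the variant base (and within ``flank_radius``
    of it) are compared.  A motif is LOST_ON_Y when the X-allele sequence
    has a hit at/above threshold and the Y-allele sequence has none in the
    overlapping windows; GAINED_ON_Y is symmetric; otherwise UNCHANGED.
    """
    if not (0 <= variant_offset < len(flank)):
        raise ValueError("variant offset outside the flank")
    x_allele, y_allele = x_allele.upper(), y_allele.upper()
    if x_allele == y_allele:
        raise ValueError("X and Y alleles are identical: no variant to compare")
    for allele in (x_allele, y_allele):
        if allele not in BASES:
            raise ValueError(f"allele must be one of {BASES}: {allele}")
    seq_x = flank[:variant_offset] + x_allele + flank[variant_offset + 1 :]
    seq_y = flank[:variant_offset] + y_allele + flank[variant_offset + 1 :]

    out: list[AlleleDiff] = []
    for pwm in pwms:
        L = pwm.length
        lo = max(variant_offset - L + 1, variant_offset - flank_radius, 0)
        hi = min(variant_offset, len(flank) - L)
        offsets = list(range(lo, hi + 1))
        hits_x = scan_sequence(seq_x, pwm, threshold, offsets=offsets)
        hits_y = scan_sequence(seq_y, pwm, threshold, offsets=offsets)
        best_x = max(hits_x, key=lambda h: h.relative_score, default=None)
        best_y = max(hits_y, key=lambda h: h.relative_score, default=None)
        if hits_x and not hits_y:
            status = LOST_ON_Y
        elif hits_y and not hits_x:
            status = GAINED_ON_Y
        else:
            status = UNCHANGED
        out.append(AlleleDiff(pwm.matrix_id, status, best_x, best_y))
    return out
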