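"""Allele-aware PWM scoring.

Scores are information-content-weighted log-odds: position i, base b
contributes ic_i * log2(p_i(b) / bg_b). A sequence's raw score is min-max
rescaled against the motif's minimum and maximum attainable scores, so the
consensus scores exactly 1 and the anti-consensus exactly 0. The best match
for an allele is the maximum over both strands and all motif placements
covering the variant.

Match p-values are exact for a quantized score: per-position scores are
rounded to a fixed granularity (1e-4 of the score range) and the full score
distribution under the background base model is obtained by dynamic
programming (convolution over positions). For motifs of length <= 8 this
distribution can be checked against exhaustive enumeration of all k-mers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

_BASE_IX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
QUANT_BINS = 10_000  # score-range granularity for the exact p-value DP


class SequenceError(ValueError):
    """Bad base or window geometry."""


@dataclass
class Pwm:
    """A probability PWM with background frequencies and per-position IC."""

    name: str
    probs: np.ndarray  # L x 4, rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be L x 4")
        if len(self.probs) < 4:
            raise ValueError("PWM length must be >= 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        p = np.clip(self.probs, 1e-6, None)
        p = p / p.sum(axis=1, keepdims=True)
        self.ic = np.log2(4) + (p * np.log2(p)).sum(axis=1)  # bits per position
        self.score_matrix = self.ic[:, None] * np.log2(p / self.background[None, :])
        self.smin = float(self.score_matrix.min(axis=1).sum())
        self.smax = float(self.score_matrix.max(axis=1).sum())
        # integer-quantized scores defining the exact match-p distribution
        self._delta = (self.smax - self.smin) / QUANT_BINS
        self.qscore_matrix = np.round(self.score_matrix / self._delta).astype(np.int64)

    def __len__(self) -> int:
        return len(self.probs)

    # -- scoring -----------------------------------------------------------
    def raw_score(self, seq: str) -> float:
        """Raw IC-weighted log-odds of one placement; N averages over bg."""
        if len(seq) != len(self):
            raise SequenceError("sequence length != motif length")
        total = 0.0
        for i, b in enumerate(seq.upper()):
            if b == "N":
                total += float(self.background @ self.score_matrix[i])
            elif b in _BASE_IX:
                total += float(self.score_matrix[i, _BASE_IX[b]])
            else:
                raise SequenceError(f"bad base {b!r}")
        return total

    def relative_score(self, seq: str) -> float:
        return (self.raw_score(seq) - self.smin) / (self.smax - self.smin)

    def quantized_score(self, seq: str) -> int:
        """The integer score whose exact null distribution the DP computes."""
        if len(seq) != len(self):
            raise SequenceError("sequence length != motif length")
        total = 0
        for i, b in enumerate(seq.upper()):
            if b == "N":
                total += int(round(self.background @ self.qscore_matrix[i]))
            elif b in _BASE_IX:
                total += int(self.qscore_matrix[i, _BASE_IX[b]])
            else:
                raise SequenceError(f"bad base {b!r}")
        return total

    def score_distribution(self) -> Tuple[np.ndarray, np.ndarray]:
        """Exact (values, probabilities) of the quantized score under bg.

        Dynamic programming: convolve the per-position 4-outcome score
        distributions into the full-length sum distribution.
        """
        lo = int(self.qscore_matrix.min(axis=1).sum())
        hi = int(self.qscore_matrix.max(axis=1).sum())
        dist = np.zeros(hi - lo + 1)
        dist[-lo if lo < 0 else 0] = 0.0
        # start: degenerate at 0, expressed on the [lo, hi] lattice
        cur = {0: 1.0}
        for i in range(len(self)):
            nxt: Dict[int, float] = {}
            for s, pr in cur.items():
                for b in range(4):
                    key = s + int(self.qscore_matrix[i, b])
                    nxt[key] = nxt.get(key, 0.0) + pr * float(self.background[b])
            cur = nxt
        values = np.array(sorted(cur))
        probs = np.array([cur[v] for v in values])
        return values, probs

    def match_pvalue(self, qscore: int) -> float:
        """P(quantized score >= qscore) under the background model."""
        values, probs = self._cached_distribution()
        return float(probs[values >= qscore].sum())

    def _cached_distribution(self) -> Tuple[np.ndarray, np.ndarray]:
        if not hasattr(self, "_dist"):
            self._dist = self.score_distribution()
        return self._dist

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.name, self.probs[::-1, ::-1], self.background[::-1])


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


@dataclass
class AllelicPrediction:
    variant_id: str
    tf_name: str
    score_ref: float
    score_alt: float
    delta: float
    strand: str
    offset: int  # variant offset within the best motif placement
    match_p: float
    allelic: bool


def score_allele(
    pwm: Pwm, window: str, allele_base: str, variant_offset: int
) -> Tuple[float, str, int, int]:
    """Best relative score over strands x placements covering the variant.

    Returns (relative score, strand, variant offset within motif, quantized
    raw score of the best placement).
    """
    window = window.upper()
    if allele_base.upper() not in _BASE_IX:
        raise SequenceError(f"allele base must be A/C/G/T, got {allele_base!r}")
    seq = window[:variant_offset] + allele_base.upper() + window[variant_offset + 1 :]
    L = len(pwm)
    if variant_offset - L + 1 < 0 or variant_offset + L > len(seq):
        raise SequenceError("window too short for every placement covering the variant")
    best = (-np.inf, "+", 0, 0)
    rc_pwm = pwm.reverse_complement()
    for start in range(variant_offset - L + 1, variant_offset + 1):
        sub = seq[start : start + L]
        off = variant_offset - start
        for strand, mat in (("+", pwm), ("-", rc_pwm)):
            s = mat.relative_score(sub)
            if s > best[0]:
                best = (s, strand, off, mat.quantized_score(sub))
    return best


def predict_allelic_tfs(
    variant_id: str,
    window: str,
    ref: str,
    alt: str,
    variant_offset: int,
    pwms: Dict[str, "Pwm | np.ndarray"],
    match_p_max: float = 1e-4,
    delta_cutoff: float = 0.7,
) -> List[AllelicPrediction]:
    """One prediction per PWM whose best match (either allele) passes the
    match p-value threshold; the allelic flag requires |delta| > 0.7.

    Both alleles are scored at the same placement — the strand/offset whose
    better allele attains the overall best match — so the delta measures how
    the substitution changes that binding site, not a shift to an unrelated
    placement elsewhere in the window.
    """
    if not pwms:
        raise ValueError("empty PWM set")
    window = window.upper()
    out: List[AllelicPrediction] = []
    for name, p in pwms.items():
        pwm = p if isinstance(p, Pwm) else Pwm(name, p)
        L = len(pwm)
        if variant_offset - L + 1 < 0 or variant_offset + L > len(window):
            continue
        seq_ref = window[:variant_offset] + ref.upper() + window[variant_offset + 1 :]
        seq_alt = window[:variant_offset] + alt.upper() + window[variant_offset + 1 :]
        rc_pwm = pwm.reverse_complement()
        best = None  # (max score, s_ref, s_alt, strand, offset, best q)
        for start in range(variant_offset - L + 1, variant_offset + 1):
            off = variant_offset - start
            for strand, mat in (("+", pwm), ("-", rc_pwm)):
                sub_ref = seq_ref[start : start + L]
                sub_alt = seq_alt[start : start + L]
                try:
                    s_ref = mat.relative_score(sub_ref)
                    s_alt = mat.relative_score(sub_alt)
                except SequenceError:
                    continue
                top = max(s_ref, s_alt)
                if best is None or top > best[0]:
                    q = mat.quantized_score(sub_ref if s_ref >= s_alt else sub_alt)
                    best = (top, s_ref, s_alt, strand, off, q)
        if best is None:
            continue
        _, s_ref, s_alt, strand, off, q = best
        match_p = pwm.match_pvalue(q)
        if match_p > match_p_max:
            continue
        delta = s_alt - s_ref
        out.append(
            AllelicPrediction(
                variant_id=variant_id,
                tf_name=pwm.name,
                score_ref=s_ref,
                score_alt=s_alt,
                delta=delta,
                strand=strand,
                offset=off,
                match_p=match_p,
                allelic=abs(delta) > delta_cutoff,
            )
        )
    return out
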