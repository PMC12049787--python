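"""Allelic transcription-factor motif disruption scoring.

A regulatory SNP can change chromatin accessibility by strengthening or
weakening a transcription-factor binding site.  Given a JASPAR-style position
frequency matrix and the two allelic versions of a SNP-centred sequence
window, this module scores every motif placement (both strands) that covers
the SNP with the standard log2-odds score against a background base
composition, and reports the best score per allele together with their
difference (delta > 0: the alternative allele is the stronger binder).

Only placements covering the SNP are scored — the question asked is allelic
disruption at the SNP, not genome-wide scanning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PWM", "AlleleMotifScore", "pfm_to_pwm", "score_window", "score_alleles"]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N

#: epsilon added inside the log to keep zero-probability columns finite
_EPS = 1e-9


@dataclass
class PWM:
    """Position weight matrix: per-position base probabilities (A, C, G, T)."""

    name: str
    probs: np.ndarray          # (L, 4), rows sum to 1
    background: np.ndarray     # (4,), sums to 1

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError("probs must be an L x 4 matrix with L >= 1")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each PWM row must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(L, 5) log2-odds; the 5th column (N) contributes 0."""
        lo = np.log2((self.probs + _EPS) / self.background)
        return np.hstack([lo, np.zeros((len(self), 1))])


def pfm_to_pwm(
    pfm_counts,
    pseudocount: float = 0.01,
    background=None,
    name: str = "",
) -> PWM:
    """Normalise an L x 4 position frequency (count) matrix into a PWM.

    Each position's counts receive a pseudocount proportional to that
    position's column total (``pseudocount * total`` added per base), then
    the row is normalised to sum to 1.  An all-zero position cannot be
    normalised and raises ``ValueError``.
    """
    counts = np.asarray(pfm_counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("pfm_counts must be an L x 4 matrix")
    if np.any(counts < 0):
        raise ValueError("pfm_counts must be non-negative")
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("PFM contains an all-zero position")
    probs = (counts + pseudocount * totals) / (totals * (1.0 + 4.0 * pseudocount))
    if background is None:
        background = np.full(4, 0.25)
    return PWM(name=name, probs=probs, background=np.asarray(background, float))


def _encode(window: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in window.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in window") from None


def _best_covering(lo: np.ndarray, codes: np.ndarray, snp_index: int):
    """Best score/offset of motif placements covering ``snp_index`` (one strand)."""
    L, W = lo.shape[0], codes.size
    first = max(0, snp_index - L + 1)
    last = min(snp_index, W - L)
    best, best_off = None, None
    for off in range(first, last + 1):
        s = float(lo[np.arange(L), codes[off:off + L]].sum())
        if best is None or s > best + 1e-12:
            best, best_off = s, off
    return best, best_off


def score_window(pwm: PWM, window: str, snp_index: int):
    """Best log2-odds of the motif over all SNP-covering placements/strands.

    Returns ``(best_score, offset, strand)`` with the offset expressed in
    0-based coordinates of the *forward* window regardless of strand.  The
    reverse strand scores the reverse complement; an ``N`` base contributes
    the background (zero log-odds) term.  Ties prefer the forward strand,
    then the leftmost offset.
    """
    codes = _encode(window)
    W = codes.size
    if not (0 <= snp_index < W):
        raise ValueError(f"snp_index {snp_index} outside window of length {W}")
    L = len(pwm)
    if L > W or max(0, snp_index - L + 1) > min(snp_index, W - L):
        raise ValueError("window too short: no motif placement covers the SNP")
    lo = pwm.log_odds

    fwd_score, fwd_off = _best_covering(lo, codes, snp_index)
    rc_codes = _COMPLEMENT[codes[::-1]]
    rev_score, rev_off_rc = _best_covering(lo, rc_codes, W - 1 - snp_index)

    if rev_score is not None and (fwd_score is None or rev_score > fwd_score + 1e-12):
        return rev_score, W - L - rev_off_rc, "-"
    return fwd_score, fwd_off, "+"


@dataclass
class AlleleMotifScore:
    """Best per-allele motif scores for one SNP and one TF."""

    snp_id: str
    tf_name: str
    score_ref: float
    score_alt: float
    delta: float                 # score_alt - score_ref; > 0: alt binds stronger
    best_offset_ref: int
    best_offset_alt: int
    strand_ref: str
    strand_alt: str


def score_alleles(
    pwm: PWM,
    window_ref: str,
    window_alt: str,
    snp_index: int,
    snp_id: str = "",
) -> AlleleMotifScore:
    """Score both allelic windows and report the binding difference.

    The windows must be identical except (possibly) at ``snp_index``.
    """
    if len(window_ref) != len(window_alt):
        raise ValueError("allelic windows differ in length")
    diffs = [
        i for i, (a, b) in enumerate(zip(window_ref.upper(), window_alt.upper()))
        if a != b
    ]
    if any(i != snp_index for i in diffs):
        raise ValueError(
            f"allelic windows differ away from snp_index {snp_index}: {diffs}"
        )
    s_ref, off_ref, strand_ref = score_window(pwm, window_ref, snp_index)
    s_alt, off_alt, strand_alt = score_window(pwm, window_alt, snp_index)
    return AlleleMotifScore(
        snp_id=snp_id,
        tf_name=pwm.name,
        score_ref=s_ref,
        score_alt=s_alt,
        delta=s_alt - s_ref,
        best_offset_ref=off_ref,
        best_offset_alt=off_alt,
        strand_ref=strand_ref,
        strand_alt=strand_alt,
    )
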