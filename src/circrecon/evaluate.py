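"""Benchmark reconstructed circRNA sequences against a long-read reference set.

A short-read prediction A is *verified* by a long-read sequence B when
(1) A and B have more than 95% identity, identity being 100·M divided by
the mean of the two lengths, and (2) the mean length and the match count
M differ by fewer than 10 bases.  M is the number of matched columns in
an optimal global alignment (match +1, mismatch −1, gap −1; among
equal-scoring alignments the one with the most matches is taken).

Verified predictions are true positives, unverified ones false
positives; a circRNA verified for a *competing* method but not assembled
by the current one is a false negative of the current method.  From TP /
FP / FN follow precision, sensitivity and F1, and from
assembled-over-candidate counts the reconstruction rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np


def match_count(a: str, b: str) -> int:
    """Number of matched columns M in an optimal global alignment of ``a`` and ``b``.

    Scoring is match +1, mismatch −1, gap −1; ties in score are broken
    in favour of more matched columns.  Implemented as a single additive
    dynamic programme over the composite objective score·K + matches
    (K larger than any match count), which makes the tie-break exact.
    """
    if not a or not b:
        raise ValueError("match_count requires two non-empty sequences")
    n, m = len(a), len(b)
    big = n + m + 1
    b_arr = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    prev = -big * np.arange(m + 1, dtype=np.int64)
    offsets = big * np.arange(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        match = b_arr == ord(a[i - 1])
        diag = np.where(match, big + 1, -big)
        cand = np.maximum(prev[:-1] + diag, prev[1:] - big)
        # left-to-right gap relaxation row[j] = max(cand[j], row[j-1] - big)
        # via a running max of row[j] + j*big
        t = np.empty(m + 1, dtype=np.int64)
        t[0] = -i * big
        t[1:] = cand + offsets[1:]
        prev = np.maximum.accumulate(t) - offsets
    return int(prev[m] % big)


@dataclass
class SimilarityResult:
    """Outcome of the two-criteria similarity test between one sequence pair."""

    match_count: int
    len_a: int
    len_b: int
    identity_pct: float
    criteria1: bool
    criteria2: bool
    similar: bool


def is_similar(
    a: str,
    b: str,
    identity_threshold_pct: float = 95.0,
    length_window: float = 10.0,
    combine: str = "and",
    literal_criteria2: bool = False,
) -> SimilarityResult:
    """Apply the two similarity criteria to a prediction/reference pair.

    Criterion 1: identity (100·M / mean length) above
    ``identity_threshold_pct``.  Criterion 2: |mean length − M| below
    ``length_window``; ``literal_criteria2=True`` instead tests the
    signed difference M − mean < window, which is vacuously true
    whenever the identity is below 100% (M never exceeds the shorter
    length).  ``combine`` is ``"and"`` (default) or ``"or"``.
    """
    if combine not in ("and", "or"):
        raise ValueError("combine must be 'and' or 'or'")
    m = match_count(a, b)
    avg = (len(a) + len(b)) / 2.0
    identity = 100.0 * m / avg
    crit1 = identity > identity_threshold_pct
    crit2 = (m - avg < length_window) if literal_criteria2 else (abs(avg - m) < length_window)
    similar = (crit1 and crit2) if combine == "and" else (crit1 or crit2)
    return SimilarityResult(m, len(a), len(b), identity, crit1, crit2, similar)


@dataclass
class EvalCounts:
    """TP/FP/FN tallies for one method on one sample.

    ``fn`` is ``None`` when no competing method was supplied, in which
    case sensitivity is undefined.
    """

    n_reconstructed: int
    tp: int
    fp: int
    fn: int | None = None

    def __post_init__(self) -> None:
        if self.tp + self.fp != self.n_reconstructed:
            raise ValueError("tp + fp must equal the number of reconstructed sequences")
        if min(self.tp, self.fp) < 0 or (self.fn is not None and self.fn < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class MetricsReport:
    """Derived metrics; percentages on 0-100, F1 on 0-1; None where undefined."""

    precision_pct: float | None
    sensitivity_pct: float | None
    f1: float | None
    reconstruction_rate_pct: float | None = None

    def rounded(self) -> dict:
        """Percentages to 2 decimals, F1 to 4 — the conventional reporting precision."""
        r2 = lambda x: None if x is None else round(x, 2)
        return {
            "precision_pct": r2(self.precision_pct),
            "sensitivity_pct": r2(self.sensitivity_pct),
            "f1": None if self.f1 is None else round(self.f1, 4),
            "reconstruction_rate_pct": r2(self.reconstruction_rate_pct),
        }


def _verified_ids(
    predictions: Mapping[str, str],
    reference: Mapping[str, str],
    match_mode: str,
    sim_kwargs: dict,
) -> set[str]:
    """Identifiers of predictions similar to at least one reference sequence."""
    verified: set[str] = set()
    for pred_id, seq in predictions.items():
        if match_mode == "id" and pred_id in reference:
            candidates: Sequence[str] = [reference[pred_id]]
        else:
            candidates = list(reference.values())
        if any(is_similar(seq, ref_seq, **sim_kwargs).similar for ref_seq in candidates):
            verified.add(pred_id)
    return verified


def classify(
    current: Mapping[str, str],
    reference: Mapping[str, str],
    other: Mapping[str, str] | None = None,
    match_mode: str = "id",
    **sim_kwargs,
) -> EvalCounts:
    """Classify the current method's predictions against the long-read reference.

    TP: current predictions verified by (similar to) a reference
    sequence.  FP: current predictions verified by none.  FN: circRNAs
    the competing method ``other`` got verified but the current method
    did not assemble at all.  With no competitor, FN is undefined.

    ``match_mode='id'`` compares a prediction to the reference sequence
    sharing its ``chrom:start|end`` identifier when present, falling
    back to scanning all references; ``match_mode='all'`` always scans.
    """
    if match_mode not in ("id", "all"):
        raise ValueError("match_mode must be 'id' or 'all'")
    verified = _verified_ids(current, reference, match_mode, sim_kwargs)
    tp = len(verified)
    fp = len(current) - tp
    fn: int | None = None
    if other is not None:
        other_verified = _verified_ids(other, reference, match_mode, sim_kwargs)
        fn = len(other_verified - set(current))
    return EvalCounts(n_reconstructed=len(current), tp=tp, fp=fp, fn=fn)


def metrics(counts: EvalCounts, n_candidates: int | None = None) -> MetricsReport:
    """Precision, sensitivity, F1 and reconstruction rate from raw counts.

    Precision = 100·TP/(TP+FP); sensitivity = 100·TP/(TP+FN); F1 is the
    harmonic mean computed on the fractional (0-1) precision and
    sensitivity.  ``n_candidates`` is the number of circRNA candidates
    offered to the method; with it the reconstruction rate
    100·NRS/NSC is reported.  Undefined quantities (zero denominators,
    missing FN) are returned as ``None``, never as 0.
    """
    precision = None
    if counts.tp + counts.fp > 0:
        precision = 100.0 * counts.tp / (counts.tp + counts.fp)
    sensitivity = None
    if counts.fn is not None and counts.tp + counts.fn > 0:
        sensitivity = 100.0 * counts.tp / (counts.tp + counts.fn)
    f1 = None
    if precision is not None and sensitivity is not None:
        p, s = precision / 100.0, sensitivity / 100.0
        f1 = 0.0 if p + s == 0 else 2.0 * p * s / (p + s)
    rate = None
    if n_candidates:
        rate = 100.0 * counts.n_reconstructed / n_candidates
    return MetricsReport(precision, sensitivity, f1, rate)
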