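"""Guide-peptide prioritization from predicted interface probabilities.

Fixed-length candidate peptides are "cut" from an interacting partner's
per-position probability curve: every length-L window is scored by its
mean probability, windows that are local maxima of that score profile
are kept, ranked by score, and (by default) pruned greedily so no two
returned peptides overlap.  When a target protein has several partners,
candidates are pooled across partners and re-ranked globally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .interactome import PartnerTable
from .model import InterfaceModel, PredictionTrack
from .seqio import ProteinSequence, format_value

logger = logging.getLogger("pepprior")

DEFAULT_PEPTIDE_LENGTH = 15


@dataclass(frozen=True)
class PeptideCandidate:
    """A ranked candidate guide peptide cut from a partner sequence."""

    partner_id: str
    start: int  # 1-based, inclusive
    length: int
    residues: str
    score: float
    rank: int

    def __post_init__(self) -> None:
        if len(self.residues) != self.length:
            raise ValueError("residues length must equal window length")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("candidate score must lie in [0, 1]")
        if self.start < 1 or self.rank < 1:
            raise ValueError("start and rank are 1-based positive integers")

    @property
    def end(self) -> int:
        return self.start + self.length - 1


def window_scores(track: PredictionTrack, L: int) -> np.ndarray:
    """Mean probability of every length-L window, indexed by start.

    Returns an array of length n-L+1; entry i-1 is the mean of p over
    positions i..i+L-1 (1-based).  Masked positions are excluded from
    the mean; a window that is entirely masked scores NaN.
    """
    n = len(track.p)
    if L < 1:
        raise ValueError("window length must be positive")
    if L > n:
        raise ValueError(f"window length {L} exceeds sequence length {n}")
    valid = track.mask.astype(float)
    p_masked = np.where(track.mask, track.p, 0.0)
    kernel = np.ones(L)
    sums = np.convolve(p_masked, kernel, mode="valid")
    counts = np.convolve(valid, kernel, mode="valid")
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return scores


def local_maxima(scores: Sequence[float]) -> list[int]:
    """1-based start indices of the local maxima of a window-score profile.

    An index is a maximum iff its value strictly exceeds both
    neighbours.  A plateau of equal values strictly above both flanks
    contributes its leftmost index; a boundary index qualifies when it
    exceeds its single neighbour.  Missing (NaN) scores are never maxima
    and count as minus-infinity flanks.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty score profile")
    vals = np.where(np.isnan(s), -np.inf, s)
    maxima: list[int] = []
    i = 0
    n = len(vals)
    while i < n:
        j = i
        while j + 1 < n and vals[j + 1] == vals[i]:
            j += 1
        left = vals[i - 1] if i > 0 else -np.inf
        right = vals[j + 1] if j + 1 < n else -np.inf
        if not np.isnan(s[i]) and vals[i] > left and vals[i] > right:
            maxima.append(i + 1)
        i = j + 1
    return maxima


def select_candidates(
    track: PredictionTrack,
    sequence: ProteinSequence,
    L: int = DEFAULT_PEPTIDE_LENGTH,
    top_n: int = 6,
    allow_overlap: bool = False,
) -> list[PeptideCandidate]:
    """Rank local-maximum windows and cut the top peptides.

    Maxima are ordered by score descending, ties broken by smaller
    start.  Unless ``allow_overlap``, a greedy pass keeps a window only
    if it shares no position with an already-kept one.  At most
    ``top_n`` candidates are returned, re-ranked 1..k.
    """
    if top_n < 1:
        raise ValueError("top_n must be at least 1")
    if len(sequence) != len(track.p):
        raise ValueError(
            f"track length {len(track.p)} does not match sequence "
            f"{sequence.id!r} length {len(sequence)}"
        )
    scores = window_scores(track, L)
    starts = local_maxima(scores)
    ordered = sorted(starts, key=lambda i: (-scores[i - 1], i))
    chosen: list[tuple[int, float]] = []
    occupied = np.zeros(len(sequence), dtype=bool)
    for start in ordered:
        if len(chosen) == top_n:
            break
        lo, hi = start - 1, start - 1 + L
        if not allow_overlap and occupied[lo:hi].any():
            continue
        chosen.append((start, float(scores[start - 1])))
        occupied[lo:hi] = True
    if len(chosen) < top_n:
        logger.info(
            "%s: only %d candidate(s) available for top_n=%d",
            sequence.id, len(chosen), top_n,
        )
    return [
        PeptideCandidate(
            partner_id=sequence.id,
            start=start,
            length=L,
            residues=sequence.residues[start - 1 : start - 1 + L],
            score=score,
            rank=rank,
        )
        for rank, (start, score) in enumerate(chosen, start=1)
    ]


def prioritize_for_target(
    target_id: str,
    partner_table: PartnerTable,
    model: InterfaceModel,
    partner_sequences: Sequence[ProteinSequence],
    L: int = DEFAULT_PEPTIDE_LENGTH,
    top_n: int = 6,
    allow_overlap: bool = False,
    pool: bool = True,
) -> list[PeptideCandidate]:
    """Predict interfaces on every partner of a target and pool candidates.

    Each partner of ``target_id`` is scored by the model and mined with
    :func:`select_candidates`; candidates are pooled and re-ranked
    globally by score (``pool=True``) or kept per partner with their
    local ranks (``pool=False``).  An unknown target or one with no
    partners yields an empty list with a logged warning.
    """
    partners = partner_table.partners(target_id)
    if not partners:
        logger.warning("target %r has no interaction partners", target_id)
        return []
    by_id = {s.id: s for s in partner_sequences}
    missing = sorted(partners - set(by_id))
    if missing:
        raise ValueError(f"partner sequences missing for {target_id!r}: {missing}")
    pooled: list[PeptideCandidate] = []
    for pid in sorted(partners):
        seq = by_id[pid]
        track = model.predict(seq)
        pooled.extend(select_candidates(track, seq, L, top_n, allow_overlap))
    if not pool:
        return pooled
    pooled.sort(key=lambda c: (-c.score, c.partner_id, c.start))
    return [
        PeptideCandidate(c.partner_id, c.start, c.length, c.residues, c.score, rank)
        for rank, c in enumerate(pooled[:top_n], start=1)
    ]


def write_candidates(candidates: Sequence[PeptideCandidate], path: str | Path) -> None:
    """Candidate TSV: rank, partner, coordinates, score and peptide."""
    with open(path, "w") as fh:
        fh.write("rank\tpartner_id\tstart\tend\tlength\tscore\tpeptide\n")
        for c in candidates:
            fh.write(
                f"{c.rank}\t{c.partner_id}\t{c.start}\t{c.end}\t{c.length}\t"
                f"{format_value(c.score)}\t{c.residues}\n"
            )
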