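"""Sequence and score-track I/O.

Protein sequences are read from FASTA; per-position score tracks
(interface probabilities or mean binding energies) are exchanged as
three-column TSV files.  All positions are 1-based and inclusive
throughout the package, matching residue-numbering conventions used
when comparing predictions to structures.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("pepprior")

#: The 20 standard amino acids plus 'X' for anything nonstandard.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"

#: Nonstandard one-letter codes collapsed onto 'X'.
NONSTANDARD = set("BJOUZ*")


@dataclass(frozen=True)
class ProteinSequence:
    """A named protein sequence over the 20-letter alphabet plus 'X'."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id: {self.id!r}")
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.residues != self.residues.upper():
            raise ValueError(f"sequence {self.id!r} must be uppercase")
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains symbols outside the "
                f"amino-acid alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ScoreTrack:
    """Per-position real values for one sequence.

    ``kind`` distinguishes interface probabilities (constrained to
    [0, 1]) from mean Rosetta energies (unconstrained, lower = more
    favourable).  NaN marks positions with no defined value.
    """

    sequence_id: str
    values: np.ndarray
    kind: str = "probability"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("track values must be a nonempty 1-D array")
        if self.kind not in ("probability", "energy"):
            raise ValueError(f"unknown track kind: {self.kind!r}")
        if self.kind == "probability":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
                raise ValueError("probability track values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.values)


def _clean_residues(seq_id: str, raw: str) -> str:
    residues = raw.upper()
    if any(c in NONSTANDARD for c in residues):
        mapped = sorted({c for c in residues if c in NONSTANDARD})
        logger.warning(
            "sequence %s: nonstandard residues %s mapped to 'X'",
            seq_id,
            ",".join(mapped),
        )
        residues = "".join("X" if c in NONSTANDARD else c for c in residues)
    return residues


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a multi-record FASTA file.

    Residues are uppercased and the nonstandard codes B, J, O, U, Z
    and '*' are mapped to 'X' (with a logged warning) rather than
    rejected, since structure-derived sequences routinely contain them.
    Record order is preserved.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    out: list[ProteinSequence] = []
    for rec in records:
        if len(rec.seq) == 0:
            line_no = _header_line(path, rec.id)
            raise ValueError(
                f"malformed FASTA record {rec.id!r} at line {line_no}: "
                "header with no sequence"
            )
        out.append(ProteinSequence(rec.id, _clean_residues(rec.id, str(rec.seq))))
    return out


def _header_line(path: Path, rec_id: str) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">") and line[1:].split()[:1] == [rec_id]:
                return i
    return -1


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def format_value(v: float) -> str:
    """Render a score with 6 significant digits (the track precision)."""
    if isinstance(v, float) and math.isnan(v):
        return "nan"
    return format(float(v), ".6g")


def write_track(track: ScoreTrack, path: str | Path, sequence: ProteinSequence | None = None) -> None:
    """Write a score track as TSV (``sequence_id  position  value``).

    Positions are 1-based; values carry 6 significant digits, which
    round-trips bit-identically through :func:`read_track`.
    """
    if sequence is not None and len(sequence) != len(track):
        raise ValueError(
            f"track length {len(track)} does not match sequence "
            f"{sequence.id!r} length {len(sequence)}"
        )
    with open(path, "w") as fh:
        fh.write("sequence_id\tposition\tvalue\n")
        for pos, v in enumerate(track.values, start=1):
            fh.write(f"{track.sequence_id}\t{pos}\t{format_value(v)}\n")


def read_track(path: str | Path, kind: str = "probability") -> ScoreTrack:
    """Read a single-sequence score track written by :func:`write_track`."""
    seq_id: str | None = None
    values: list[float] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["sequence_id", "position", "value"]:
            raise ValueError(f"unexpected track header in {path}: {header}")
        for line in fh:
            sid, pos, val = line.rstrip("\n").split("\t")
            if seq_id is None:
                seq_id = sid
            elif sid != seq_id:
                raise ValueError(f"multiple sequence ids in {path}")
            if int(pos) != len(values) + 1:
                raise ValueError(f"non-contiguous positions in {path}")
            values.append(float(val))
    if seq_id is None:
        raise ValueError(f"no data rows in {path}")
    return ScoreTrack(seq_id, np.array(values), kind=kind)


def read_tracks(path: str | Path, kind: str = "probability") -> dict[str, ScoreTrack]:
    """Read a multi-sequence track TSV into a dict keyed by sequence id."""
    per_seq: dict[str, list[float]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["sequence_id", "position", "value"]:
            raise ValueError(f"unexpected track header in {path}: {header}")
        for line in fh:
            sid, pos, val = line.rstrip("\n").split("\t")
            rows = per_seq.setdefault(sid, [])
            if int(pos) != len(rows) + 1:
                raise ValueError(f"non-contiguous positions for {sid} in {path}")
            rows.append(float(val))
    if not per_seq:
        raise ValueError(f"no data rows in {path}")
    return {sid: ScoreTrack(sid, np.array(vals), kind=kind) for sid, vals in per_seq.items()}


def write_tracks(tracks: Sequence[ScoreTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\tposition\tvalue\n")
        for track in tracks:
            for pos, v in enumerate(track.values, start=1):
                fh.write(f"{track.sequence_id}\t{pos}\t{format_value(v)}\n")
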