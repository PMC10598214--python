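"""Dataset construction: window energies -> per-position labels -> splits.

The training labels come from linear-peptide energy scans: every
fixed-length window of a chain carries a Rosetta energy (REU, lower =
more favourable binding contribution).  This module turns those window
scores into per-residue mean energies, binarizes them into interface
labels, merges duplicate chains, and produces homology-aware
train/validation/test splits via connected-component clustering on a
sequence-identity graph.

Positions with no covering window are *missing*: they receive label 0
but are masked out of both the training loss and every metric.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .seqio import ProteinSequence, format_value

logger = logging.getLogger("pepprior")

#: Records with REU below this are treated as numerical artifacts and dropped.
REU_ARTIFACT_FLOOR = -1000.0
#: Sequences must be strictly longer than this to enter the dataset.
MIN_SEQ_LENGTH = 50
#: ... and strictly shorter than this.
MAX_SEQ_LENGTH = 1023
#: Default per-position energy threshold separating binding (< -1) from not.
DEFAULT_LABEL_THRESHOLD = -1.0
#: Same-pair interactions within this buried-surface-area delta are duplicates.
BSA_DUPLICATE_DELTA = 100.0

SPLITS = ("train", "val", "test")
#: Split proportions approximating the reference 26423/3487/3817 partition.
DEFAULT_FRACTIONS = (0.77, 0.10, 0.13)


@dataclass(frozen=True)
class DerivedPeptideRecord:
    """One scored peptide window: a slice of a chain with its REU."""

    sequence_id: str
    window_start: int  # 1-based
    window_length: int = 10
    reu: float = 0.0

    def __post_init__(self) -> None:
        if self.window_start < 1:
            raise ValueError(f"window_start must be >= 1, got {self.window_start}")
        if self.window_length < 1:
            raise ValueError(f"window_length must be >= 1, got {self.window_length}")


@dataclass(frozen=True)
class InteractionRecord:
    """A chain pair from a co-complex with its buried surface area (A^2)."""

    partner_a: str
    partner_b: str
    buried_surface_area: float
    entry_id: str = ""

    def __post_init__(self) -> None:
        if self.buried_surface_area < 0:
            raise ValueError(
                f"negative buried surface area for ({self.partner_a}, "
                f"{self.partner_b}): {self.buried_surface_area}"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.partner_a, self.partner_b)))  # type: ignore[return-value]


@dataclass
class PositionEnergyProfile:
    """Per-position mean REU and window coverage for one sequence.

    ``energy`` holds NaN at positions covered by no window; ``coverage``
    counts the windows averaged at each position.
    """

    sequence_id: str
    residues: str
    energy: np.ndarray
    coverage: np.ndarray
    merged_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.energy = np.asarray(self.energy, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=int)
        n = len(self.residues)
        if self.energy.shape != (n,) or self.coverage.shape != (n,):
            raise ValueError(
                f"profile {self.sequence_id!r}: energy/coverage shape must "
                f"match sequence length {n}"
            )
        if np.any((self.coverage == 0) & ~np.isnan(self.energy)):
            raise ValueError(
                f"profile {self.sequence_id!r}: zero-coverage positions must "
                "carry NaN energy, never a silent value"
            )
        if np.any(self.coverage < 0):
            raise ValueError("coverage must be nonnegative")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.energy)


@dataclass
class LabeledSequence:
    """A sequence with binary interface labels, a validity mask and a weight.

    ``mask[i]`` is False where the energy was missing; such positions are
    excluded from the loss and from all metrics.  ``weight`` scales the
    whole sequence's loss (the per-protein weighting used for dataset
    rebalancing).
    """

    sequence_id: str
    residues: str
    labels: np.ndarray
    mask: np.ndarray | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.mask is None:
            self.mask = np.ones(len(self.residues), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = len(self.residues)
        if self.labels.shape != (n,) or self.mask.shape != (n,):
            raise ValueError(
                f"labels/mask length must equal sequence length for "
                f"{self.sequence_id!r}"
            )
        if not np.all(np.isin(self.labels, (0, 1))):
            raise ValueError("labels must be binary")
        if not self.weight > 0:
            raise ValueError(f"weight must be positive, got {self.weight}")


@dataclass(frozen=True)
class SplitAssignment:
    sequence_id: str
    cluster_id: int
    split: str

    def __post_init__(self) -> None:
        if self.split not in SPLITS:
            raise ValueError(f"unknown split {self.split!r}")


# ---------------------------------------------------------------------------
# interaction dedup and record filtering
# ---------------------------------------------------------------------------

def dedupe_interactions(records: Sequence[InteractionRecord]) -> list[InteractionRecord]:
    """Drop same-pair interactions that are not meaningfully distinct.

    Records are kept greedily in input order; within one unordered
    partner pair a record is dropped iff some already-kept record of
    that pair has a buried-surface-area difference of at most 100 A^2.
    Distinct pairs never collide.
    """
    kept: list[InteractionRecord] = []
    kept_bsa: dict[tuple[str, str], list[float]] = defaultdict(list)
    for rec in records:
        seen = kept_bsa[rec.pair]
        if any(abs(rec.buried_surface_area - b) <= BSA_DUPLICATE_DELTA for b in seen):
            continue
        kept.append(rec)
        seen.append(rec.buried_surface_area)
    return kept


def filter_records(
    records: Sequence[DerivedPeptideRecord],
    seq_lengths: Mapping[str, int],
) -> list[DerivedPeptideRecord]:
    """Apply the REU-artifact and sequence-length filters.

    Individual windows with REU below -1000 are discarded as numerical
    artifacts.  All windows of sequences with length <= 50 or >= 1023
    are discarded (kept range is 51..1022, both strict in the original
    phrasing "greater than 50 and less than 1023").
    """
    n_reu = n_len = 0
    out: list[DerivedPeptideRecord] = []
    for rec in records:
        length = seq_lengths.get(rec.sequence_id)
        if length is None:
            raise ValueError(f"unknown sequence id in record: {rec.sequence_id!r}")
        if rec.window_start + rec.window_length - 1 > length:
            raise ValueError(
                f"window out of bounds for {rec.sequence_id!r}: start "
                f"{rec.window_start}, length {rec.window_length}, "
                f"sequence length {length}"
            )
        if rec.reu < REU_ARTIFACT_FLOOR:
            n_reu += 1
            continue
        if not (MIN_SEQ_LENGTH < length < MAX_SEQ_LENGTH):
            n_len += 1
            continue
        out.append(rec)
    logger.info(
        "filter_records: dropped %d windows below %.0f REU, %d windows on "
        "out-of-range-length sequences; kept %d",
        n_reu, REU_ARTIFACT_FLOOR, n_len, len(out),
    )
    return out


# ---------------------------------------------------------------------------
# window -> position aggregation
# ---------------------------------------------------------------------------

def windows_to_positions(
    records: Sequence[DerivedPeptideRecord],
    sequence: ProteinSequence,
) -> PositionEnergyProfile:
    """Average window REUs onto the positions each window covers.

    ``energy[i]`` is the arithmetic mean of the REU of every window
    containing position ``i``; ``coverage[i]`` counts those windows.
    Uncovered positions are NaN/0.  Zero records is a legal input and
    yields an all-missing profile.
    """
    n = len(sequence)
    total = np.zeros(n)
    coverage = np.zeros(n, dtype=int)
    for rec in records:
        if rec.sequence_id != sequence.id:
            raise ValueError(
                f"record for {rec.sequence_id!r} passed with sequence "
                f"{sequence.id!r}"
            )
        lo = rec.window_start - 1
        hi = lo + rec.window_length
        if hi > n:
            raise ValueError(
                f"window out of bounds for {sequence.id!r}: start "
                f"{rec.window_start}, length {rec.window_length}"
            )
        total[lo:hi] += rec.reu
        coverage[lo:hi] += 1
    energy = np.full(n, np.nan)
    covered = coverage > 0
    energy[covered] = total[covered] / coverage[covered]
    return PositionEnergyProfile(sequence.id, sequence.residues, energy, coverage)


def merge_duplicates(
    profiles: Sequence[PositionEnergyProfile],
) -> list[PositionEnergyProfile]:
    """Collapse profiles with identical residue strings into one.

    At each position the merged energy is the plain (coverage-unweighted)
    mean over the member profiles that have a value there.  The merged
    profile takes the lexicographically smallest member id and records
    all member ids in ``merged_ids``.
    """
    groups: dict[str, list[PositionEnergyProfile]] = defaultdict(list)
    order: list[str] = []
    for prof in profiles:
        if prof.residues not in groups:
            order.append(prof.residues)
        groups[prof.residues].append(prof)
    out: list[PositionEnergyProfile] = []
    for residues in order:
        members = groups[residues]
        if len(members) == 1:
            out.append(members[0])
            continue
        stack = np.stack([m.energy for m in members])
        has_value = ~np.isnan(stack)
        n_values = has_value.sum(axis=0)
        total = np.where(has_value, stack, 0.0).sum(axis=0)
        energy = np.full(len(residues), np.nan)
        nonzero = n_values > 0
        energy[nonzero] = total[nonzero] / n_values[nonzero]
        coverage = np.stack([m.coverage for m in members]).sum(axis=0)
        # coverage>0 but all-NaN cannot happen: members carry NaN iff coverage 0
        ids = tuple(sorted(m.sequence_id for m in members))
        out.append(
            PositionEnergyProfile(ids[0], residues, energy, coverage, merged_ids=ids)
        )
    return out


def binarize(
    profile: PositionEnergyProfile,
    threshold: float = DEFAULT_LABEL_THRESHOLD,
) -> LabeledSequence:
    """Threshold mean energies into binary interface labels.

    A position is an interface residue iff its mean energy is strictly
    below the threshold (default -1 REU).  Missing positions get label 0
    and are flagged in the mask so downstream losses and metrics skip
    them.
    """
    with np.errstate(invalid="ignore"):
        labels = (profile.energy < threshold).astype(np.int8)
    mask = ~profile.missing
    labels[~mask] = 0
    return LabeledSequence(profile.sequence_id, profile.residues, labels, mask, weight=1.0)


# ---------------------------------------------------------------------------
# homology-aware splitting
# ---------------------------------------------------------------------------

def kmer_identity(a: str, b: str, k: int = 5) -> float:
    """Shared-k-mer containment: an alignment-free identity estimate.

    |k-mers(a) & k-mers(b)| divided by the smaller k-mer set.  Sequences
    shorter than k fall back to exact-match (1.0 or 0.0).  This is the
    built-in stand-in for an external clustering tool; real cluster
    assignments can be injected via ``precomputed_clusters``.
    """
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0 if a == b else 0.0
    return len(ka & kb) / min(len(ka), len(kb))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def identity_graph_edges(
    sequences: Sequence[ProteinSequence],
    min_identity: float,
    identity_fn: Callable[[str, str], float],
) -> list[tuple[int, int]]:
    edges = []
    for i in range(len(sequences)):
        for j in range(i + 1, len(sequences)):
            if identity_fn(sequences[i].residues, sequences[j].residues) >= min_identity:
                edges.append((i, j))
    return edges


def cluster_split(
    sequences: Sequence[ProteinSequence],
    min_identity: float = 0.25,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    forced_test_ids: Iterable[str] = (),
    seed: int = 0,
    identity_fn: Callable[[str, str], float] | None = None,
    precomputed_clusters: Mapping[str, int] | None = None,
) -> list[SplitAssignment]:
    """Cluster sequences and assign whole clusters to train/val/test.

    Sequences joined (directly or transitively) by pairwise identity at
    or above ``min_identity`` share a cluster, so no homologous pair can
    straddle a split boundary.  Any cluster containing a forced-test id
    goes to test in full (the in-vitro-partner rule).  Remaining
    clusters are assigned largest-first to whichever split is furthest
    below its target fraction, ties broken by a seeded cluster order.
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if not sequences:
        return []
    ids = [s.id for s in sequences]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")

    if precomputed_clusters is not None:
        missing = [i for i in ids if i not in precomputed_clusters]
        if missing:
            raise ValueError(f"sequences missing from precomputed clusters: {missing}")
        raw = [precomputed_clusters[i] for i in ids]
    else:
        fn = identity_fn or kmer_identity
        uf = _UnionFind(len(sequences))
        for i, j in identity_graph_edges(sequences, min_identity, fn):
            uf.union(i, j)
        raw = [uf.find(i) for i in range(len(sequences))]

    # renumber clusters 0..k-1 in first-appearance order
    remap: dict[int, int] = {}
    cluster_of: list[int] = []
    for r in raw:
        if r not in remap:
            remap[r] = len(remap)
        cluster_of.append(remap[r])

    members: dict[int, list[int]] = defaultdict(list)
    for idx, c in enumerate(cluster_of):
        members[c].append(idx)

    forced = set(forced_test_ids)
    unknown_forced = forced - set(ids)
    if unknown_forced:
        logger.warning("forced-test ids not in corpus: %s", sorted(unknown_forced))
    forced_clusters = {cluster_of[i] for i, sid in enumerate(ids) if sid in forced}

    total = len(sequences)
    counts = {"train": 0, "val": 0, "test": 0}
    assignment: dict[int, str] = {}
    for c in forced_clusters:
        assignment[c] = "test"
        counts["test"] += len(members[c])
    if counts["test"] / total > fractions[2]:
        logger.warning(
            "forced-test sequences occupy %.1f%% of the corpus, above the "
            "test fraction %.1f%%",
            100 * counts["test"] / total, 100 * fractions[2],
        )

    rng = np.random.default_rng(seed)
    free = [c for c in members if c not in forced_clusters]
    perm = rng.permutation(len(free))
    free = [free[p] for p in perm]
    free.sort(key=lambda c: -len(members[c]))  # stable: seeded order breaks ties

    targets = dict(zip(SPLITS, fractions))
    for c in free:
        deficits = {s: targets[s] - counts[s] / total for s in SPLITS}
        best = max(SPLITS, key=lambda s: deficits[s])
        assignment[c] = best
        counts[best] += len(members[c])

    return [
        SplitAssignment(ids[i], cluster_of[i], assignment[cluster_of[i]])
        for i in range(len(sequences))
    ]


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def read_derived_peptides(path: str | Path) -> list[DerivedPeptideRecord]:
    """Read a derived-peptide TSV (sequence_id, window_start, window_length, reu)."""
    out: list[DerivedPeptideRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["sequence_id", "window_start", "window_length", "reu"]
        if header != expected:
            raise ValueError(f"unexpected header in {path}: {header}")
        for line in fh:
            sid, start, length, reu = line.rstrip("\n").split("\t")
            out.append(DerivedPeptideRecord(sid, int(start), int(length), float(reu)))
    return out


def write_derived_peptides(records: Sequence[DerivedPeptideRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\twindow_start\twindow_length\treu\n")
        for r in records:
            fh.write(f"{r.sequence_id}\t{r.window_start}\t{r.window_length}\t{format_value(r.reu)}\n")


def read_interactions(path: str | Path) -> list[InteractionRecord]:
    out: list[InteractionRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["partner_a", "partner_b", "bsa", "entry_id"]:
            raise ValueError(f"unexpected header in {path}: {header}")
        for line in fh:
            a, b, bsa, entry = line.rstrip("\n").split("\t")
            out.append(InteractionRecord(a, b, float(bsa), entry))
    return out


def write_labeled_dataset(
    labeled: Sequence[LabeledSequence],
    path: str | Path,
    energies: Mapping[str, np.ndarray] | None = None,
) -> None:
    """Write per-position labels (and optionally energies) as one TSV."""
    with open(path, "w") as fh:
        fh.write("sequence_id\tposition\tresidue\tenergy\tlabel\tmask\n")
        for ls in labeled:
            energy = energies.get(ls.sequence_id) if energies else None
            for i in range(len(ls.residues)):
                e = format_value(float(energy[i])) if energy is not None else "nan"
                fh.write(
                    f"{ls.sequence_id}\t{i + 1}\t{ls.residues[i]}\t{e}\t"
                    f"{int(ls.labels[i])}\t{int(ls.mask[i])}\n"
                )


def read_labeled_dataset(
    path: str | Path,
) -> tuple[list[LabeledSequence], dict[str, np.ndarray]]:
    rows: dict[str, list[tuple[str, float, int, bool]]] = {}
    order: list[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["sequence_id", "position", "residue", "energy", "label", "mask"]
        if header != expected:
            raise ValueError(f"unexpected header in {path}: {header}")
        for line in fh:
            sid, pos, res, energy, label, mask = line.rstrip("\n").split("\t")
            if sid not in rows:
                rows[sid] = []
                order.append(sid)
            if int(pos) != len(rows[sid]) + 1:
                raise ValueError(f"non-contiguous positions for {sid} in {path}")
            rows[sid].append((res, float(energy), int(label), bool(int(mask))))
    labeled = []
    energies = {}
    for sid in order:
        res, energy, label, mask = zip(*rows[sid])
        labeled.append(
            LabeledSequence(sid, "".join(res), np.array(label), np.array(mask))
        )
        energies[sid] = np.array(energy)
    return labeled, energies


def write_splits(assignments: Sequence[SplitAssignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\tcluster_id\tsplit\n")
        for a in assignments:
            fh.write(f"{a.sequence_id}\t{a.cluster_id}\t{a.split}\n")


def read_splits(path: str | Path) -> list[SplitAssignment]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["sequence_id", "cluster_id", "split"]:
            raise ValueError(f"unexpected header in {path}: {header}")
        for line in fh:
            sid, cid, split = line.rstrip("\n").split("\t")
            out.append(SplitAssignment(sid, int(cid), split))
    return out
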