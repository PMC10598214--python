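"""Seeded synthetic fixtures with the statistical structure the pipeline assumes.

The generator emulates the label source of the real pipeline: proteins
carry short planted binding motifs; every position has a true binding
energy equal to a motif effect (default -2 REU at motif positions, 0
elsewhere) plus Gaussian noise; 10-mer window scores are the means of
the position energies they cover, i.e. exactly the quantity the dataset
builder averages back onto positions.  The binding signal is
*compositional* — motif residues are drawn from a distribution biased
toward a hydrophobic subset — so a sequence-only model can learn it.
Labels are produced by the dataset builder's own binarization, so the
generator and the builder cannot drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import dataset
from .dataset import DerivedPeptideRecord, LabeledSequence, PositionEnergyProfile
from .interactome import PPIRecord
from .seqio import AMINO_ACIDS, ProteinSequence

#: Residues over-represented inside planted motifs.  The strongly
#: hydrophobic core (Phe/Ile/Leu/Val) keeps the background rate of
#: motif-like residues low (4/20), so a planted run is compositionally
#: unambiguous and a sequence-only model can localize its boundaries.
MOTIF_RESIDUES = "FILV"


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    ``motif_alphabet_bias`` is the probability mass moved onto the
    hydrophobic subset inside motifs (0 = background composition,
    1 = motifs drawn purely from the subset).  ``energy_effect`` is the
    mean REU shift at motif positions and ``noise_sigma`` the standard
    deviation of the per-position Gaussian noise, in REU.
    """

    n_sequences: int = 200
    length_range: tuple[int, int] = (60, 120)
    motif_length_range: tuple[int, int] = (8, 12)
    motifs_per_sequence: int = 1
    motif_alphabet_bias: float = 0.9
    energy_effect: float = -2.0
    noise_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be positive")
        for name in ("length_range", "motif_length_range"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} must satisfy 1 <= min <= max")
        if self.motifs_per_sequence < 0:
            raise ValueError("motifs_per_sequence must be nonnegative")
        if not (0.0 <= self.motif_alphabet_bias <= 1.0):
            raise ValueError("motif_alphabet_bias must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.motif_length_range[1] > self.length_range[0]:
            raise ValueError("motifs may not be longer than the shortest sequence")


@dataclass
class SyntheticCorpus:
    """Sequences, labels, ground-truth motif coordinates and true energies."""

    config: GeneratorConfig
    sequences: list[ProteinSequence]
    labeled: list[LabeledSequence]
    #: sequence id -> list of (start, end) 1-based inclusive motif spans
    motifs: dict[str, list[tuple[int, int]]]
    #: sequence id -> true per-position energy (REU)
    energies: dict[str, np.ndarray]


def _motif_distribution(bias: float) -> np.ndarray:
    """Background-uniform distribution with ``bias`` mass moved onto the subset."""
    p = np.full(len(AMINO_ACIDS), (1.0 - bias) / len(AMINO_ACIDS))
    subset = [AMINO_ACIDS.index(a) for a in MOTIF_RESIDUES]
    p[subset] += bias / len(subset)
    return p / p.sum()


def generate_labeled_corpus(cfg: GeneratorConfig) -> SyntheticCorpus:
    """Draw a seeded corpus of sequences with planted binding motifs.

    Background residues are uniform over the 20 amino acids; motif
    residues come from the biased distribution.  The true per-position
    energy is ``energy_effect`` inside motifs plus N(0, noise_sigma)
    everywhere, and labels are obtained by thresholding that energy
    with :func:`pepprior.dataset.binarize`.
    """
    rng = np.random.default_rng(cfg.seed)
    aa = np.array(list(AMINO_ACIDS))
    motif_p = _motif_distribution(cfg.motif_alphabet_bias)

    sequences, labeled = [], []
    motifs: dict[str, list[tuple[int, int]]] = {}
    energies: dict[str, np.ndarray] = {}
    for idx in range(cfg.n_sequences):
        sid = f"SYN{idx:04d}"
        n = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        residues = rng.choice(aa, size=n)
        is_motif = np.zeros(n, dtype=bool)
        spans: list[tuple[int, int]] = []
        for _ in range(cfg.motifs_per_sequence):
            m = int(rng.integers(cfg.motif_length_range[0], cfg.motif_length_range[1] + 1))
            # place without overlapping an existing motif; give up after a few tries
            for _attempt in range(20):
                start = int(rng.integers(0, n - m + 1))
                if not is_motif[start : start + m].any():
                    break
            else:
                continue
            is_motif[start : start + m] = True
            residues[start : start + m] = rng.choice(aa, size=m, p=motif_p)
            spans.append((start + 1, start + m))
        spans.sort()
        energy = cfg.energy_effect * is_motif + rng.normal(0.0, cfg.noise_sigma, n) \
            if cfg.noise_sigma > 0 else cfg.energy_effect * is_motif.astype(float)
        seq = ProteinSequence(sid, "".join(residues))
        profile = PositionEnergyProfile(sid, seq.residues, energy, np.ones(n, dtype=int))
        sequences.append(seq)
        labeled.append(dataset.binarize(profile))
        motifs[sid] = spans
        energies[sid] = energy
    return SyntheticCorpus(cfg, sequences, labeled, motifs, energies)


def generate_window_records(
    corpus: SyntheticCorpus, window_length: int = 10
) -> list[DerivedPeptideRecord]:
    """Emit the window energy scan the true position energies induce.

    Each window's REU is the mean of the true per-position energies it
    covers — the exact inverse of the builder's aggregation, so feeding
    these records through ``windows_to_positions`` recovers a smoothed
    version of the truth (exactly, in the noiseless interior).
    """
    records = []
    for seq in corpus.sequences:
        energy = corpus.energies[seq.id]
        n = len(seq)
        for start in range(1, n - window_length + 2):
            reu = float(energy[start - 1 : start - 1 + window_length].mean())
            records.append(DerivedPeptideRecord(seq.id, start, window_length, reu))
    return records


def generate_ppi_table(
    n_targets: int,
    partners_per_target: int,
    seed: int = 0,
    partner_config: GeneratorConfig | None = None,
) -> tuple[list[PPIRecord], SyntheticCorpus]:
    """A synthetic interactome whose partners carry one planted interface.

    Each target symbol gets ``partners_per_target`` partner proteins.
    The first partner of each target is backed by an always-trusted
    IMEX record; further partners cycle through BioGRID LTP/HTP and
    PROPER records with p-values straddling both policy cutoffs, so the
    stringent and lenient filters genuinely differ on the table.  The
    returned corpus holds the partner sequences with their true motif
    (interface) coordinates; partner sequences are noiseless by default
    so the planted interface is unambiguous.
    """
    if n_targets < 1 or partners_per_target < 1:
        raise ValueError("n_targets and partners_per_target must be positive")
    cfg = partner_config or GeneratorConfig(
        n_sequences=n_targets * partners_per_target,
        noise_sigma=0.0,
        seed=seed,
    )
    if cfg.n_sequences != n_targets * partners_per_target:
        raise ValueError("partner_config.n_sequences must equal n_targets * partners_per_target")
    corpus = generate_labeled_corpus(replace(cfg, seed=seed))
    rng = np.random.default_rng(seed + 1)
    evidence_cycle = [
        ("IMEX", "NA", None),
        ("BIOGRID", "LTP", None),
        ("BIOGRID", "HTP", None),
        ("PROPER", "NA", 0.005),
        ("PROPER", "NA", 0.03),
        ("PROPER", "NA", 0.2),
    ]
    records = []
    k = 0
    for t in range(n_targets):
        target = f"TGT{t:03d}"
        for j in range(partners_per_target):
            partner = corpus.sequences[k].id
            if j == 0:
                source, evidence, p = evidence_cycle[0]
            else:
                source, evidence, p = evidence_cycle[int(rng.integers(len(evidence_cycle)))]
            records.append(PPIRecord(target, partner, source, evidence, p))
            k += 1
    return records, corpus
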