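"""Evaluation metrics for per-position interface prediction.

Two computational metrics — AUROC (Mann-Whitney pair-counting
formulation, half credit for ties) and Spearman rank correlation
against the per-position binding energies — plus two laboratory-proxy
summaries of the top-scoring residues: their mean energy and the
percentage falling below a binding-energy threshold.  All metrics are
computed only over unmasked positions.  The energy axis is negated for
the correlation so that better binding (lower REU) aligns with higher
predicted probability; a positive Spearman therefore means agreement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass
class MetricsReport:
    auroc: float
    spearman: float | None
    top_n_mean_energy: float | None
    pct_top_below_threshold: float | None
    n_positions: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def auroc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Probability a random positive outscores a random negative.

    Rank (Mann-Whitney) formulation with 0.5 credit for score ties;
    requires both classes present.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be 1-D and equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: both classes must be present")
    ranks = stats.rankdata(s)  # average ranks handle ties -> 0.5 credit
    pos_rank_sum = ranks[y == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson on average ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman undefined for constant input")
    return float(stats.spearmanr(x, y).statistic)


def spearman_vs_energy(probabilities: Sequence[float], energies: Sequence[float]) -> float:
    """Correlation between predicted probability and binding favourability.

    Energies are negated so lower (more favourable) REU maps to larger
    values; perfect agreement gives +1.
    """
    return spearman(probabilities, -np.asarray(energies, dtype=float))


def top_n_energy(
    scores: Sequence[float],
    energies: Sequence[float],
    n: int,
    tau: float = -1.0,
) -> tuple[float, float]:
    """Energy summary of the n highest-scoring positions.

    Ties in score are broken by position order.  Returns the mean
    energy of the selected positions and 100x the fraction with energy
    strictly below ``tau``.
    """
    s = np.asarray(scores, dtype=float)
    e = np.asarray(energies, dtype=float)
    if s.shape != e.shape or s.ndim != 1:
        raise ValueError("scores and energies must be 1-D and equal length")
    if n < 1 or n > len(s):
        raise ValueError(f"n must be in 1..{len(s)}, got {n}")
    top = np.argsort(-s, kind="stable")[:n]
    sel = e[top]
    return float(sel.mean()), float(100.0 * np.mean(sel < tau))


def evaluate_tracks(
    predictions: dict[str, np.ndarray],
    labels: dict[str, np.ndarray],
    masks: dict[str, np.ndarray] | None = None,
    energies: dict[str, np.ndarray] | None = None,
    n_top: int = 10,
    tau: float = -1.0,
    average: str = "macro",
) -> MetricsReport:
    """Pool per-sequence tracks into one metrics report.

    ``macro`` computes each metric per sequence and averages across
    sequences (sequences where a metric is undefined — single-class
    labels, constant scores — are skipped for that metric); ``micro``
    pools all unmasked positions globally first.
    """
    if average not in ("macro", "micro"):
        raise ValueError(f"average must be 'macro' or 'micro', got {average!r}")
    ids = sorted(predictions)
    if set(ids) != set(labels):
        raise ValueError("prediction and label ids differ")

    def seq_arrays(sid):
        p = np.asarray(predictions[sid], dtype=float)
        y = np.asarray(labels[sid])
        m = (
            np.asarray(masks[sid], dtype=bool)
            if masks is not None
            else np.ones(len(p), dtype=bool)
        )
        e = np.asarray(energies[sid], dtype=float) if energies is not None else None
        return p[m], y[m], (e[m] if e is not None else None)

    n_positions = 0
    if average == "micro":
        ps, ys, es = [], [], []
        for sid in ids:
            p, y, e = seq_arrays(sid)
            ps.append(p)
            ys.append(y)
            if e is not None:
                es.append(e)
        p = np.concatenate(ps)
        y = np.concatenate(ys)
        n_positions = len(p)
        a = auroc(y, p)
        if es:
            e = np.concatenate(es)
            rho = spearman_vs_energy(p, e)
            n_eff = min(n_top, len(p))
            mean_e, pct = top_n_energy(p, e, n_eff, tau)
        else:
            rho = mean_e = pct = None
        return MetricsReport(a, rho, mean_e, pct, n_positions)

    aurocs, rhos, mean_es, pcts = [], [], [], []
    for sid in ids:
        p, y, e = seq_arrays(sid)
        n_positions += len(p)
        try:
            aurocs.append(auroc(y, p))
        except ValueError:
            pass
        if e is not None and len(p) >= 3:
            try:
                rhos.append(spearman_vs_energy(p, e))
            except ValueError:
                pass
            n_eff = min(n_top, len(p))
            if n_eff >= 1:
                me, pc = top_n_energy(p, e, n_eff, tau)
                mean_es.append(me)
                pcts.append(pc)
    if not aurocs:
        raise ValueError("AUROC undefined on every sequence")
    return MetricsReport(
        float(np.mean(aurocs)),
        float(np.mean(rhos)) if rhos else None,
        float(np.mean(mean_es)) if mean_es else None,
        float(np.mean(pcts)) if pcts else None,
        n_positions,
    )
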