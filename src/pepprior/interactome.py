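"""PPI evidence filtering, partner lookup and proteome coverage.

Interaction evidence comes from three database families: IMEx-style
curated sets (always trusted), BioGRID-style sets whose records carry a
low-throughput (LTP) or high-throughput (HTP) physical-evidence class,
and PROPER-style screening sets whose records carry a p-value.  Two
filter policies are supported:

stringent : all IMEX; BioGRID LTP only; PROPER p < 0.01
lenient   : all IMEX; BioGRID LTP or HTP; PROPER p < 0.05

Self-interactions (homogeneous) are tracked separately from
heterogeneous partners throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

SOURCES = ("IMEX", "BIOGRID", "PROPER")
EVIDENCE = ("LTP", "HTP", "NA")
POLICIES = ("stringent", "lenient")

#: PROPER p-value cutoffs (strict inequality) per policy.
PROPER_P_CUTOFF = {"stringent": 0.01, "lenient": 0.05}


@dataclass(frozen=True)
class PPIRecord:
    protein_a: str
    protein_b: str
    source: str
    evidence: str = "NA"
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.evidence not in EVIDENCE:
            raise ValueError(f"unknown evidence class {self.evidence!r}")
        if self.source == "PROPER":
            if self.p_value is None:
                raise ValueError(
                    f"PROPER record ({self.protein_a}, {self.protein_b}) "
                    "lacks a p-value"
                )
            if not (0.0 <= self.p_value <= 1.0):
                raise ValueError(f"p-value out of range: {self.p_value}")
        if self.source == "BIOGRID" and self.evidence not in ("LTP", "HTP"):
            raise ValueError(
                f"BIOGRID record ({self.protein_a}, {self.protein_b}) must "
                "carry LTP or HTP evidence"
            )


def apply_policy(records: Sequence[PPIRecord], policy: str) -> list[PPIRecord]:
    """Filter evidence records under the stringent or lenient policy."""
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    kept = []
    for rec in records:
        if rec.source == "IMEX":
            kept.append(rec)
        elif rec.source == "BIOGRID":
            if rec.evidence == "LTP" or (policy == "lenient" and rec.evidence == "HTP"):
                kept.append(rec)
        else:  # PROPER
            if rec.p_value < PROPER_P_CUTOFF[policy]:  # type: ignore[operator]
                kept.append(rec)
    return kept


class PartnerTable:
    """Symmetric protein -> partner-set mapping.

    Heterogeneous partners are symmetric by construction; proteins with
    a self-interaction are tracked in a separate homogeneous set.
    Symbols are matched exactly after uppercasing.
    """

    def __init__(self) -> None:
        self._partners: dict[str, set[str]] = {}
        self._homogeneous: set[str] = set()

    def add(self, a: str, b: str) -> None:
        a, b = a.upper(), b.upper()
        if a == b:
            self._homogeneous.add(a)
            self._partners.setdefault(a, set())
            return
        self._partners.setdefault(a, set()).add(b)
        self._partners.setdefault(b, set()).add(a)

    def partners(self, symbol: str) -> set[str]:
        return set(self._partners.get(symbol.upper(), set()))

    def is_homogeneous(self, symbol: str) -> bool:
        return symbol.upper() in self._homogeneous

    def proteins(self) -> set[str]:
        return set(self._partners)

    def __len__(self) -> int:
        return len(self._partners)


def build_partner_table(records: Sequence[PPIRecord]) -> PartnerTable:
    """Collapse (already policy-filtered) records into a partner table."""
    table = PartnerTable()
    for rec in records:
        table.add(rec.protein_a, rec.protein_b)
    return table


def coverage(table: PartnerTable, proteome: Sequence[str]) -> float:
    """Percent of a proteome with at least one heterogeneous partner."""
    if not proteome:
        raise ValueError("proteome must be nonempty")
    proteome_upper = [p.upper() for p in proteome]
    covered = sum(1 for p in proteome_upper if table.partners(p))
    return 100.0 * covered / len(proteome_upper)


def read_ppi_table(path: str | Path) -> list[PPIRecord]:
    """Read a PPI TSV (protein_a, protein_b, source, evidence, p_value)."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["protein_a", "protein_b", "source", "evidence", "p_value"]
        if header != expected:
            raise ValueError(f"unexpected header in {path}: {header}")
        for line in fh:
            a, b, source, evidence, p = line.rstrip("\n").split("\t")
            p_value = None if p in ("", "NA", "nan") else float(p)
            out.append(PPIRecord(a, b, source, evidence, p_value))
    return out


def write_ppi_table(records: Sequence[PPIRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\tsource\tevidence\tp_value\n")
        for r in records:
            p = "NA" if r.p_value is None else format(r.p_value, "g")
            fh.write(f"{r.protein_a}\t{r.protein_b}\t{r.source}\t{r.evidence}\t{p}\n")


def read_proteome(path: str | Path) -> list[str]:
    """One protein symbol per line; blanks skipped."""
    with open(path) as fh:
        symbols = [line.strip() for line in fh if line.strip()]
    if not symbols:
        raise ValueError(f"no symbols in {path}")
    return symbols
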