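"""Tiered evidence classification for noncanonical ORFs.

Implements the two-peptide rule for tryptic evidence (>=2 nonnested,
uniquely mapping peptides, each >=9 residues, joint coverage >=18 amino
acids) and the seven-tier framework mapping evidence combinations onto
standardized outcome labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .errors import ValidationError

__all__ = [
    "PeptideEvidence",
    "EvidenceRecord",
    "TierResult",
    "TIER_LABELS",
    "hupo_hpp_check",
    "assign_tier",
    "tier_table",
]

TIER_LABELS = {
    "1A": "Protein candidate",
    "1B": "Presented",
    "2A": "Detected",
    "2B": "Detected",
    "3": "Putative",
    "4": "Ribo-Seq ORF",
    "5": "Predicted",
}

MIN_PEPTIDE_LEN = 9
MIN_EXTENT = 18


@dataclass(frozen=True)
class PeptideEvidence:
    orf_id: str
    peptide_seq: str
    aa_start: int  # 0-based offset of the first residue within the ORF
    aa_len: int
    uniquely_mapping: bool
    evidence_type: str  # "tryptic" | "hla"
    sample_id: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.aa_len < 1:
            raise ValidationError(f"peptide on {self.orf_id}: aa_len must be >= 1")
        if self.peptide_seq and len(self.peptide_seq) != self.aa_len:
            raise ValidationError(
                f"peptide on {self.orf_id}: aa_len {self.aa_len} != sequence length"
            )
        if self.evidence_type not in ("tryptic", "hla"):
            raise ValidationError(f"unknown evidence_type {self.evidence_type!r}")

    @property
    def interval(self) -> tuple[int, int]:
        return self.aa_start, self.aa_start + self.aa_len


@dataclass(frozen=True)
class EvidenceRecord:
    orf_id: str
    riboseq_detected: bool = False
    insilico_predicted: bool = False
    tryptic: tuple[PeptideEvidence, ...] = ()
    hla: tuple[PeptideEvidence, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "tryptic", tuple(self.tryptic))
        object.__setattr__(self, "hla", tuple(self.hla))
        for pep, channel in [(p, "tryptic") for p in self.tryptic] + [
            (p, "hla") for p in self.hla
        ]:
            if pep.evidence_type != channel:
                raise ValidationError(
                    f"{self.orf_id}: {pep.evidence_type} peptide in {channel} channel"
                )


@dataclass(frozen=True)
class TierResult:
    tier: str
    label: str
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if TIER_LABELS.get(self.tier) != self.label:
            raise ValidationError(f"tier {self.tier} does not map to label {self.label!r}")


def _nested(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """True iff interval a is contained in b or b in a (identity counts)."""
    return (b[0] <= a[0] and a[1] <= b[1]) or (a[0] <= b[0] and b[1] <= a[1])


def hupo_hpp_check(
    peptides: Sequence[PeptideEvidence],
    min_len: int = MIN_PEPTIDE_LEN,
    min_extent: int = MIN_EXTENT,
    extent_mode: str = "union",
) -> tuple[bool, list[str]]:
    """Two-peptide rule: does a qualifying peptide set exist?

    A qualifying set has >=2 peptides, each uniquely mapping and >= min_len
    residues, pairwise nonnested, with total extent >= min_extent. Extent is
    the size of the union of covered residue positions (``extent_mode=
    "union"``, the default) or the sum of peptide lengths (``"sum"``).

    Pairwise-nonnested sets are cliques of the nonnested-compatibility
    graph, and coverage only grows with clique size, so it suffices to scan
    maximal cliques.
    """
    if extent_mode not in ("union", "sum"):
        raise ValueError(f"unknown extent_mode {extent_mode!r}")
    reasons: list[str] = []
    if not peptides:
        return False, ["no peptides"]
    candidates = [p for p in peptides if p.uniquely_mapping and p.aa_len >= min_len]
    if len({p.interval for p in candidates}) < len(candidates):
        # duplicated intervals are a single observation for spacing purposes
        seen: set[tuple[int, int]] = set()
        deduped = []
        for p in candidates:
            if p.interval not in seen:
                seen.add(p.interval)
                deduped.append(p)
        candidates = deduped
    if len(candidates) < 2:
        reasons.append("fewer than 2 qualifying peptides")
        if any(not p.uniquely_mapping for p in peptides):
            reasons.append("non-unique peptides excluded")
        if any(p.aa_len < min_len for p in peptides):
            reasons.append(f"peptides shorter than {min_len} excluded")
        return False, reasons

    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(range(len(candidates)))
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            if not _nested(candidates[i].interval, candidates[j].interval):
                graph.add_edge(i, j)

    best_extent = 0
    found_pair = False
    for clique in nx.find_cliques(graph):
        if len(clique) < 2:
            continue
        found_pair = True
        if extent_mode == "union":
            covered: set[int] = set()
            for idx in clique:
                covered.update(range(*candidates[idx].interval))
            extent = len(covered)
        else:
            extent = sum(candidates[idx].aa_len for idx in clique)
        best_extent = max(best_extent, extent)
        if extent >= min_extent:
            return True, []
    if not found_pair:
        reasons.append("nested pair")
    else:
        reasons.append(f"extent<{min_extent} (best {best_extent})")
    return False, reasons


def assign_tier(
    ev: EvidenceRecord,
    hla_source_field: str = "source_id",
    extent_mode: str = "union",
) -> TierResult:
    """Evaluate the tier rules in priority order; first match wins.

    1A: Ribo-Seq + tryptic peptides passing the two-peptide rule.
    1B: Ribo-Seq + >=2 HLA observations from >=2 distinct sources.
    2A: Ribo-Seq + any tryptic evidence (including sets failing spacing).
    2B: Ribo-Seq + a single HLA observation.
    3:  proteomic evidence of either kind without Ribo-Seq.
    4:  Ribo-Seq only.
    5:  in-silico prediction only.
    """
    if hla_source_field not in ("source_id", "sample_id"):
        raise ValueError(f"unknown HLA source granularity {hla_source_field!r}")
    has_proteomic = bool(ev.tryptic or ev.hla)
    if not (has_proteomic or ev.riboseq_detected or ev.insilico_predicted):
        raise ValidationError(f"{ev.orf_id}: no evidence and no prediction flag")

    reasons: list[str] = []

    def result(tier: str) -> TierResult:
        return TierResult(tier, TIER_LABELS[tier], tuple(reasons))

    hpp_ok, hpp_reasons = hupo_hpp_check(ev.tryptic, extent_mode=extent_mode)
    hla_sources = {getattr(p, hla_source_field) for p in ev.hla}
    hla_multi = len(ev.hla) >= 2 and len(hla_sources) >= 2

    if ev.riboseq_detected:
        reasons.append("riboseq: detected")
        if hpp_ok:
            reasons.append("tryptic: passes HUPO/HPP two-peptide rule")
            if hla_multi:
                reasons.append("hla: also qualifies for 1B")
            return result("1A")
        if ev.tryptic:
            reasons.append(f"tryptic: fails HUPO/HPP ({'; '.join(hpp_reasons)})")
        if hla_multi:
            reasons.append(f"hla: >=2 observations from {len(hla_sources)} sources")
            return result("1B")
        if ev.tryptic:
            reasons.append(f"tryptic: {len(ev.tryptic)} peptide(s)")
            return result("2A")
        if ev.hla:
            reasons.append("hla: single observation")
            return result("2B")
        reasons.append("no proteomic evidence")
        return result("4")

    reasons.append("riboseq: not detected")
    if has_proteomic:
        reasons.append("proteomic evidence without Ribo-Seq")
        return result("3")
    reasons.append("in-silico prediction only")
    return result("5")


def tier_table(records: Iterable[EvidenceRecord], **kwargs) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-ORF tier assignments plus counts per (tier, label)."""
    seen: set[str] = set()
    rows = []
    for rec in records:
        if rec.orf_id in seen:
            raise ValidationError(f"duplicated orf_id {rec.orf_id}")
        seen.add(rec.orf_id)
        res = assign_tier(rec, **kwargs)
        rows.append(
            {
                "orf_id": rec.orf_id,
                "tier": res.tier,
                "label": res.label,
                "reasons": "; ".join(res.reasons),
            }
        )
    per_orf = pd.DataFrame(rows, columns=["orf_id", "tier", "label", "reasons"])
    counts = (
        per_orf.groupby(["tier", "label"]).size().reset_index(name="n")
        if len(per_orf)
        else pd.DataFrame(columns=["tier", "label", "n"])
    )
    return per_orf, counts
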