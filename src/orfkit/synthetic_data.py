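"""Synthetic transcriptomes, ORF call sets, P-site tables, and peptide
evidence with known ground truth.

Everything is deterministic under a fixed seed: draws are made from a
single ``numpy`` generator in a fixed iteration order, never from hash or
set iteration. Jitter moves ORF starts downstream in whole codons and
never crosses the stop codon, so every jittered variant shares its
parent's stop position and is contained in the longest variant; clustering
at min_frac = (L - max_jitter_nt)/L therefore recovers the ground-truth
partition exactly when jitter is the only noise source.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .evidence_tiers import EvidenceRecord, PeptideEvidence
from .orf_model import (
    GenomicInterval,
    ORFCategory,
    ORFRecord,
    ProvenanceTag,
    TranscriptModel,
    orf_from_tx_interval,
)

__all__ = [
    "CallerProfile",
    "GroundTruth",
    "gen_transcriptome",
    "gen_orf_callsets",
    "gen_psite_table",
    "gen_peptide_evidence",
]

NEAR_COGNATE = ("CTG", "GTG", "TTG", "ACG")
AA_ALPHABET = "ACDEFGHIKLNPQRSTVWY"  # no M: Met placed deliberately


@dataclass(frozen=True)
class CallerProfile:
    name: str
    start_codon_set: frozenset[str] = frozenset({"ATG", *NEAR_COGNATE})
    jitter_prob: float = 0.0
    dropout_prob: float = 0.0
    spurious_rate: float = 0.0
    category_bias: Mapping[str, float] = field(default_factory=dict)
    max_jitter_codons: int = 2

    def __post_init__(self) -> None:
        for p in (self.jitter_prob, self.dropout_prob):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0,1]")
        if self.spurious_rate < 0:
            raise ValueError("spurious_rate must be >= 0")
        object.__setattr__(self, "start_codon_set", frozenset(self.start_codon_set))


@dataclass
class GroundTruth:
    """Links every emitted synthetic record back to its generator truth."""

    orf_to_cluster: dict[str, str] = field(default_factory=dict)  # call id -> true id | "noise"
    cluster_category: dict[str, ORFCategory] = field(default_factory=dict)
    true_orfs: dict[str, ORFRecord] = field(default_factory=dict)
    psite_frame: Optional[float] = None  # true in-frame fraction used for P-sites


def gen_transcriptome(
    n_coding: int, n_noncoding: int, seed: int
) -> dict[str, TranscriptModel]:
    """Generate multi-exon transcripts on one synthetic chromosome.

    Coding transcripts carry a 5'UTR / CDS / 3'UTR partition with UTRs long
    enough to host uORFs and dORFs; every transcript has 1-4 exons.
    """
    if n_coding < 0 or n_noncoding < 0 or n_coding + n_noncoding < 1:
        raise ValueError("need at least one transcript and nonnegative sizes")
    rng = np.random.default_rng(seed)
    cursor = 1000
    models: dict[str, TranscriptModel] = {}
    kinds = ["coding"] * n_coding + ["noncoding"] * n_noncoding
    for idx, kind in enumerate(kinds):
        tid = f"TX{idx:04d}"
        if kind == "coding":
            utr5 = int(rng.integers(120, 241))
            cds_len = 3 * int(rng.integers(60, 161))  # stop codon included
            utr3 = int(rng.integers(120, 241))
            length = utr5 + cds_len + utr3
            cds_tx = (utr5, utr5 + cds_len)
            biotype = "protein_coding"
        else:
            length = int(rng.integers(300, 901))
            cds_tx = None
            biotype = "lncRNA"
        n_exons = int(rng.integers(1, 5))
        # split length into n_exons parts, each >= 50 nt
        cuts = sorted(rng.choice(np.arange(50, length - 49), size=n_exons - 1, replace=False)) if n_exons > 1 else []
        bounds = [0, *map(int, cuts), length]
        widths = [b - a for a, b in zip(bounds, bounds[1:])]
        if min(widths) < 30:  # re-draw pathological splits deterministically
            widths = [length // n_exons] * n_exons
            widths[-1] += length - sum(widths)
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = cursor
        for w in widths:
            exons.append(GenomicInterval("chrS", pos, pos + w, strand))
            pos += w + int(rng.integers(80, 501))  # intron
        cursor = pos + int(rng.integers(200, 1001))  # intergenic gap
        # genomic exon order == transcript order for +; reversed for -
        if strand == "-":
            # widths were laid out left-to-right; transcript 5' end must be
            # the rightmost exon, which tx coordinate logic already handles.
            pass
        models[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=f"G{idx:04d}",
            biotype=biotype,
            exons=tuple(exons),
            cds_tx=cds_tx,
        )
    return models


def _draw_true_interval(
    rng: np.random.Generator,
    tx: TranscriptModel,
    category: ORFCategory,
    min_codons: int,
) -> Optional[tuple[int, int]]:
    """A transcript-coordinate (start, end) interval of the given category.

    Intervals are stop-inclusive and codon-multiple; returns None when the
    transcript cannot host the category.
    """
    L = tx.length
    if category is ORFCategory.LNCRNA_ORF:
        if tx.cds_tx is not None or L < 3 * min_codons + 3:
            return None
        n_cod = int(rng.integers(min_codons, min(40, L // 3) + 1))
        s = int(rng.integers(0, L - 3 * n_cod + 1))
        return s, s + 3 * n_cod
    if tx.cds_tx is None:
        return None
    cs, ce = tx.cds_tx
    if category is ORFCategory.UORF:
        max_cod = (cs // 3) - 1
        if max_cod < min_codons:
            return None
        n_cod = int(rng.integers(min_codons, min(max_cod, 30) + 1))
        s = int(rng.integers(0, cs - 3 * n_cod + 1))
        return s, s + 3 * n_cod
    if category is ORFCategory.UOORF:
        # start in the 5'UTR out of frame; end inside the CDS
        for _ in range(20):
            u = int(rng.integers(6, min(cs, 60) + 1))
            if u % 3 == 0:
                continue
            s = cs - u
            lo = max((cs - s) // 3 + 1, min_codons)
            hi = (ce - s) // 3
            if hi < lo:
                continue
            n_cod = int(rng.integers(lo, hi + 1))
            return s, s + 3 * n_cod
        return None
    if category is ORFCategory.INTORF:
        f = int(rng.integers(1, 3))
        s = cs + 3 * int(rng.integers(1, 6)) + f
        hi = (ce - s) // 3
        if hi < min_codons:
            return None
        n_cod = int(rng.integers(min_codons, hi + 1))
        return s, s + 3 * n_cod
    if category is ORFCategory.DOORF:
        f = int(rng.integers(1, 3))
        s = cs + 3 * int(rng.integers(1, 6)) + f
        lo = (ce - s) // 3 + 1  # end strictly past the CDS end
        hi = (L - s) // 3
        if hi < max(lo, min_codons):
            return None
        n_cod = int(rng.integers(max(lo, min_codons), hi + 1))
        return s, s + 3 * n_cod
    if category is ORFCategory.DORF:
        if L - ce < 3 * min_codons:
            return None
        s = ce + int(rng.integers(0, max(1, L - ce - 3 * min_codons + 1)))
        hi = (L - s) // 3
        if hi < min_codons:
            return None
        n_cod = int(rng.integers(min_codons, hi + 1))
        return s, s + 3 * n_cod
    raise ValueError(f"cannot generate category {category}")


def gen_orf_callsets(
    txs: Mapping[str, TranscriptModel],
    true_orfs_per_category: Mapping[str, int],
    profiles: Sequence[CallerProfile],
    n_replicates: int,
    seed: int,
) -> tuple[dict[tuple[str, str], list[ORFRecord]], GroundTruth]:
    """Per (caller, replicate) ORF call sets plus ground truth.

    Jittered variants always share the parent's stop codon; spurious calls
    carry the ground-truth cluster label "noise".
    """
    valid = {c.value for c in ORFCategory} - {"CANONICAL_VARIANT", "EXCLUDED"}
    for key in true_orfs_per_category:
        if key not in valid:
            raise ValueError(f"unknown category key {key!r}")
    rng = np.random.default_rng(seed)
    tx_ids = sorted(txs)
    coding = [t for t in tx_ids if txs[t].cds_tx is not None]
    noncoding = [t for t in tx_ids if txs[t].cds_tx is None]

    max_jitter = max((p.max_jitter_codons for p in profiles), default=0)
    min_codons = max_jitter + 3  # keep >= 2 codons (start+stop) after jitter

    truth = GroundTruth()
    used_stops: set[tuple[str, int]] = set()
    true_list: list[tuple[ORFRecord, TranscriptModel, tuple[int, int]]] = []
    counter = 0
    for cat_name in sorted(true_orfs_per_category):
        category = ORFCategory(cat_name)
        pool = noncoding if category is ORFCategory.LNCRNA_ORF else coding
        if not pool and true_orfs_per_category[cat_name] > 0:
            raise ValueError(f"no transcripts available to host {cat_name} ORFs")
        placed = 0
        attempts = 0
        while placed < true_orfs_per_category[cat_name]:
            attempts += 1
            if attempts > 200 * true_orfs_per_category[cat_name] + 200:
                raise RuntimeError(f"could not place all {cat_name} ORFs")
            tid = pool[int(rng.integers(0, len(pool)))]
            tx = txs[tid]
            interval = _draw_true_interval(rng, tx, category, min_codons)
            if interval is None:
                continue
            if (tid, interval[1]) in used_stops:  # enforce distinct stop codons
                continue
            used_stops.add((tid, interval[1]))
            orf_id = f"true{counter:04d}"
            counter += 1
            start_codon = (
                "ATG"
                if rng.random() < 0.8
                else NEAR_COGNATE[int(rng.integers(0, len(NEAR_COGNATE)))]
            )
            orf = orf_from_tx_interval(tx, *interval, orf_id, start_codon, category=category)
            truth.cluster_category[orf_id] = category
            truth.true_orfs[orf_id] = orf
            true_list.append((orf, tx, interval))
            placed += 1

    callsets: dict[tuple[str, str], list[ORFRecord]] = {}
    for profile in profiles:
        for rep in range(1, n_replicates + 1):
            rep_id = f"rep{rep}"
            calls: list[ORFRecord] = []
            for orf, tx, (s, e) in true_list:
                if orf.start_codon not in profile.start_codon_set:
                    continue
                bias = profile.category_bias.get(truth.cluster_category[orf.orf_id].value, 1.0)
                p_call = min(1.0, max(0.0, (1.0 - profile.dropout_prob) * bias))
                jitter_draw = rng.random()  # drawn unconditionally for determinism
                jitter_codons = int(rng.integers(1, profile.max_jitter_codons + 1)) if profile.max_jitter_codons else 0
                if rng.random() >= p_call:
                    continue
                s_call = s
                if jitter_draw < profile.jitter_prob and jitter_codons:
                    # downstream shift, never crossing the stop codon
                    s_call = min(s + 3 * jitter_codons, e - 6)
                call_id = f"{profile.name}_{rep_id}_{orf.orf_id}"
                calls.append(
                    orf_from_tx_interval(
                        tx, s_call, e, call_id, orf.start_codon,
                        source=ProvenanceTag("synthetic", profile.name, rep_id, "sampleA"),
                    )
                )
                truth.orf_to_cluster[call_id] = orf.orf_id
            n_spurious = int(rng.poisson(profile.spurious_rate))
            for j in range(n_spurious):
                tid = tx_ids[int(rng.integers(0, len(tx_ids)))]
                tx = txs[tid]
                n_cod = int(rng.integers(2, 20))
                if tx.length < 3 * n_cod:
                    continue
                s = int(rng.integers(0, tx.length - 3 * n_cod + 1))
                call_id = f"{profile.name}_{rep_id}_noise{j:03d}"
                calls.append(
                    orf_from_tx_interval(
                        tx, s, s + 3 * n_cod, call_id, "ATG",
                        source=ProvenanceTag("synthetic", profile.name, rep_id, "sampleA"),
                    )
                )
                truth.orf_to_cluster[call_id] = "noise"
            callsets[(profile.name, rep_id)] = calls
    return callsets, truth


def gen_psite_table(
    txs: Mapping[str, TranscriptModel],
    periodicity: float,
    depth: int,
    read_len_weights: Optional[Mapping[int, float]] = None,
    seed: int = 0,
    cds_fraction: float = 0.85,
) -> pd.DataFrame:
    """Simulate a per-position P-site count table.

    Over CDS positions each P-site lands in frame 0 with probability
    ``periodicity`` and otherwise uniformly in frames 1/2; the remaining
    ``1 - cds_fraction`` of the depth is scattered over UTRs and noncoding
    transcripts.
    """
    if not 0 <= periodicity <= 1:
        raise ValueError(f"periodicity {periodicity} outside [0,1]")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    read_len_weights = dict(read_len_weights or {28: 1.0, 29: 1.0, 30: 1.0})
    wsum = sum(read_len_weights.values())
    if wsum <= 0:
        raise ValueError("read length weights must sum to a positive value")
    lengths = sorted(read_len_weights)
    probs = np.array([read_len_weights[k] / wsum for k in lengths])

    if depth == 0:
        return pd.DataFrame(columns=["transcript_id", "tx_position", "read_length", "count", "frame", "region"])

    rng = np.random.default_rng(seed)
    coding = sorted(t for t in txs if txs[t].cds_tx is not None)
    others = sorted(txs)
    rows: list[tuple[str, int, int, int, object, str]] = []

    n_cds = int(round(depth * cds_fraction)) if coding else 0
    n_other = depth - n_cds

    if n_cds:
        weights = np.array([txs[t].cds_tx[1] - txs[t].cds_tx[0] for t in coding], dtype=float)
        weights /= weights.sum()
        tx_idx = rng.choice(len(coding), size=n_cds, p=weights)
        frames = np.where(
            rng.random(n_cds) < periodicity,
            0,
            rng.integers(1, 3, size=n_cds),
        )
        rls = np.asarray(lengths)[rng.choice(len(lengths), size=n_cds, p=probs)]
        for i in range(n_cds):
            tx = txs[coding[int(tx_idx[i])]]
            cs, ce = tx.cds_tx
            n_codons = (ce - cs) // 3 - 1  # keep frames 1/2 inside the CDS
            codon = int(rng.integers(0, max(1, n_codons)))
            pos = cs + 3 * codon + int(frames[i])
            rows.append((tx.transcript_id, pos, int(rls[i]), 1, int(frames[i]), "CDS"))

    for _ in range(n_other):
        tid = others[int(rng.integers(0, len(others)))]
        tx = txs[tid]
        rl = int(np.asarray(lengths)[int(rng.choice(len(lengths), p=probs))])
        if tx.cds_tx is None:
            pos = int(rng.integers(0, tx.length))
            rows.append((tid, pos, rl, 1, pd.NA, "noncoding"))
        else:
            cs, ce = tx.cds_tx
            if rng.random() < 0.5 and cs > 0:
                pos = int(rng.integers(0, cs))
                rows.append((tid, pos, rl, 1, pd.NA, "UTR5"))
            elif tx.length > ce:
                pos = int(rng.integers(ce, tx.length))
                rows.append((tid, pos, rl, 1, pd.NA, "UTR3"))
            else:
                pos = int(rng.integers(0, max(1, cs)))
                rows.append((tid, pos, rl, 1, pd.NA, "UTR5"))

    df = pd.DataFrame(
        rows, columns=["transcript_id", "tx_position", "read_length", "count", "frame", "region"]
    )
    df = (
        df.groupby(["transcript_id", "tx_position", "read_length", "frame", "region"], dropna=False)["count"]
        .sum()
        .reset_index()[["transcript_id", "tx_position", "read_length", "count", "frame", "region"]]
    )
    df["frame"] = df["frame"].astype("Int64")
    return df.sort_values(["transcript_id", "tx_position", "read_length"]).reset_index(drop=True)


def gen_peptide_evidence(
    orf_aa_lengths: Mapping[str, int],
    scenario: Mapping[str, Mapping],
    seed: int = 0,
) -> tuple[list[PeptideEvidence], list[EvidenceRecord]]:
    """Emit peptide observations and per-ORF evidence records from a scenario.

    ``scenario`` maps orf_id to a dict with optional keys:
    ``riboseq_detected`` (bool), ``insilico_predicted`` (bool),
    ``tryptic`` (list of (offset, length, uniquely_mapping)) and
    ``hla`` (list of (offset, length, source_id)). Peptides are emitted
    exactly as specified; sequences are deterministic random strings.
    """
    rng = np.random.default_rng(seed)
    peptides: list[PeptideEvidence] = []
    records: list[EvidenceRecord] = []
    for orf_id in sorted(scenario):
        spec = scenario[orf_id]
        aa_len = orf_aa_lengths.get(orf_id)
        if aa_len is None:
            raise ValueError(f"unknown orf_id {orf_id!r} in scenario")
        tryptic: list[PeptideEvidence] = []
        hla: list[PeptideEvidence] = []
        for offset, length, unique in spec.get("tryptic", []):
            if offset < 0 or offset + length > aa_len:
                raise ValueError(
                    f"{orf_id}: tryptic peptide ({offset},{length}) outside ORF of {aa_len} aa"
                )
            seq = "".join(
                AA_ALPHABET[int(i)] for i in rng.integers(0, len(AA_ALPHABET), size=length)
            )
            tryptic.append(
                PeptideEvidence(orf_id, seq, offset, length, bool(unique), "tryptic", "s1", "study1")
            )
        for offset, length, source_id in spec.get("hla", []):
            if offset < 0 or offset + length > aa_len:
                raise ValueError(
                    f"{orf_id}: HLA peptide ({offset},{length}) outside ORF of {aa_len} aa"
                )
            seq = "".join(
                AA_ALPHABET[int(i)] for i in rng.integers(0, len(AA_ALPHABET), size=length)
            )
            hla.append(
                PeptideEvidence(orf_id, seq, offset, length, True, "hla", str(source_id), str(source_id))
            )
        peptides.extend(tryptic)
        peptides.extend(hla)
        records.append(
            EvidenceRecord(
                orf_id=orf_id,
                riboseq_detected=bool(spec.get("riboseq_detected", False)),
                insilico_predicted=bool(spec.get("insilico_predicted", False)),
                tryptic=tuple(tryptic),
                hla=tuple(hla),
            )
        )
    return peptides, records
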