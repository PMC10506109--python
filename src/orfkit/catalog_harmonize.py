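"""Harmonization of heterogeneous published ORF catalogs.

Covers the inclusion filter (AUG start, internal-AUG rescue, >=16 aa),
per-dataset nomenclature remapping with exclusion rules, cross-dataset
replication counting (meta-catalogs reported against but never counted as
primary support), and per-dataset summary arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .orf_model import ORFCategory

__all__ = [
    "CatalogRecord",
    "BUILTIN_DIALECTS",
    "rescue_internal_aug",
    "apply_inclusion_filter",
    "remap_category",
    "cross_dataset_replication",
    "per_dataset_summary",
    "load_dialects",
]

MIN_AA = 16

SMALL_RNA_LABELS = frozenset({"rrna", "snorna", "trna", "snrna", "mirna"})

# Labels observed in the three published catalog dialects. Identity mappings
# for the six standard category names are carried in every dialect since the
# native tables use them alongside their idiosyncratic labels. The Chothani
# "ncORF" -> lncRNA-ORF mapping is assumed (flagged in the dialect registry).
_IDENTITY = {
    "uorf": ORFCategory.UORF,
    "uoorf": ORFCategory.UOORF,
    "intorf": ORFCategory.INTORF,
    "doorf": ORFCategory.DOORF,
    "dorf": ORFCategory.DORF,
    "lncrna-orf": ORFCategory.LNCRNA_ORF,
}

BUILTIN_DIALECTS: dict[str, dict[str, ORFCategory]] = {
    "duffy": {
        **_IDENTITY,
        "external": ORFCategory.DOORF,
        "internal": ORFCategory.INTORF,
        "noncoding": ORFCategory.LNCRNA_ORF,
        "lncrna": ORFCategory.LNCRNA_ORF,
        "antisense_rna": ORFCategory.LNCRNA_ORF,
        "misc_rna": ORFCategory.LNCRNA_ORF,
        "tec": ORFCategory.LNCRNA_ORF,
        "processed_transcript": ORFCategory.LNCRNA_ORF,
    },
    "ouspenskaia": {
        **_IDENTITY,
        "3' dorf": ORFCategory.DORF,
        "3' overlap dorf": ORFCategory.DOORF,
        "5' overlap uorf": ORFCategory.UOORF,
        "5' uorf": ORFCategory.UORF,
        "lncrna": ORFCategory.LNCRNA_ORF,
        "out-of-frame": ORFCategory.INTORF,
    },
    "chothani": {
        **_IDENTITY,
        "ncorf": ORFCategory.LNCRNA_ORF,  # assumed one-to-one
        "overlap_uorf": ORFCategory.UOORF,
    },
}


@dataclass(frozen=True)
class CatalogRecord:
    dataset: str
    orf_id: str
    aa_seq: str
    start_codon: str
    source_label: str = ""
    transcript_biotype: str = ""
    final_classification: str = ""

    def __post_init__(self) -> None:
        if not self.aa_seq:
            raise ValueError(f"catalog record {self.orf_id}: empty aa_seq")


def _norm_label(label: str) -> str:
    """Case-fold and normalize typographic prime/quote variants (3′ vs 3')."""
    for prime in ("′", "’", "‘", "`"):
        label = label.replace(prime, "'")
    return label.strip().lower()


def _is_aug(codon: str) -> bool:
    return codon.strip().upper().replace("U", "T") == "ATG"


def rescue_internal_aug(aa_seq: str) -> Optional[str]:
    """Trim a non-Met-initiated sequence to its first methionine.

    Sequences already starting with M are returned unchanged; when no M
    exists there is nothing to rescue and None is returned.
    """
    if not aa_seq:
        raise ValueError("empty amino-acid sequence")
    if aa_seq[0] == "M":
        return aa_seq
    idx = aa_seq.find("M")
    return aa_seq[idx:] if idx >= 0 else None


def apply_inclusion_filter(
    records: Iterable[CatalogRecord], min_aa: int = MIN_AA
) -> tuple[list[CatalogRecord], pd.DataFrame]:
    """AUG/length inclusion filter with internal-AUG rescue.

    AUG-start records are kept iff their length is >= ``min_aa``. Non-AUG
    records are replaced by the suffix starting at the first internal Met
    (a leading Met on a near-cognate record is the initiator itself, so the
    search starts at residue 1) and kept iff the rescued length passes.
    Rescued records are emitted with start_codon ATG, making the filter
    idempotent. The audit table conserves the input count.
    """
    kept: list[CatalogRecord] = []
    audit_counts: dict[str, int] = {"kept": 0, "kept_rescued": 0, "no_aug": 0, "length<16": 0}
    for rec in records:
        if _is_aug(rec.start_codon):
            if len(rec.aa_seq) >= min_aa:
                kept.append(rec)
                audit_counts["kept"] += 1
            else:
                audit_counts["length<16"] += 1
            continue
        search_space = rec.aa_seq[1:] if rec.aa_seq.startswith("M") else rec.aa_seq
        rescued = rescue_internal_aug(search_space) if search_space else None
        if rescued is None:
            audit_counts["no_aug"] += 1
        elif len(rescued) >= min_aa:
            kept.append(replace(rec, aa_seq=rescued, start_codon="ATG"))
            audit_counts["kept_rescued"] += 1
        else:
            audit_counts["length<16"] += 1
    audit = pd.DataFrame(
        [{"reason": reason, "n": n} for reason, n in audit_counts.items()],
        columns=["reason", "n"],
    )
    return kept, audit


def load_dialects(path) -> dict[str, dict[str, ORFCategory]]:
    """Load a YAML dialect registry: dataset -> {label: category|EXCLUDED}."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    dialects: dict[str, dict[str, ORFCategory]] = {}
    for dataset, table in raw.items():
        dialects[dataset.lower()] = {
            _norm_label(k): ORFCategory(v) for k, v in table.items()
        }
    return dialects


def remap_category(
    dataset: str,
    source_label: str,
    transcript_biotype: str = "",
    final_classification: str = "",
    dialects: Optional[Mapping[str, Mapping[str, ORFCategory]]] = None,
) -> ORFCategory:
    """Map a dataset-native label onto the standardized taxonomy.

    Exclusion rules run first: pseudogene final classifications, then
    small-RNA labels/biotypes. Unknown (dataset, label) pairs raise rather
    than defaulting silently.
    """
    dialects = dialects if dialects is not None else BUILTIN_DIALECTS
    if _norm_label(final_classification) == "pseudogene":
        return ORFCategory.EXCLUDED
    if (
        _norm_label(source_label) in SMALL_RNA_LABELS
        or _norm_label(transcript_biotype) in SMALL_RNA_LABELS
    ):
        return ORFCategory.EXCLUDED
    key = dataset.strip().lower()
    if key not in dialects:
        raise KeyError(f"dataset {dataset!r} not registered in the dialect table")
    table = dialects[key]
    label = _norm_label(source_label)
    if label not in table:
        raise KeyError(f"unknown label {source_label!r} for dataset {dataset!r}")
    return table[label]


def cross_dataset_replication(
    harmonized: Mapping[str, Sequence[CatalogRecord]],
    meta_datasets: Sequence[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replication of ORFs across primary datasets by amino-acid identity.

    Returns (per-ORF table, dataset x dataset overlap matrix). The matching
    key is the exact amino-acid sequence after rescue/filter. Datasets
    listed in ``meta_datasets`` appear in both outputs but never contribute
    to the primary replication count.
    """
    if not harmonized:
        raise ValueError("empty dataset mapping")
    meta = {m.strip().lower() for m in meta_datasets}
    seq_datasets: dict[str, set[str]] = {}
    for dataset in sorted(harmonized):
        for rec in harmonized[dataset]:
            seq_datasets.setdefault(rec.aa_seq, set()).add(dataset)

    rows = []
    for dataset in sorted(harmonized):
        is_meta = dataset.strip().lower() in meta
        for rec in harmonized[dataset]:
            primaries = {
                d for d in seq_datasets[rec.aa_seq] if d.strip().lower() not in meta
            }
            rows.append(
                {
                    "dataset": dataset,
                    "orf_id": rec.orf_id,
                    "aa_seq": rec.aa_seq,
                    "is_meta_dataset": is_meta,
                    "n_primary_datasets": len(primaries),
                }
            )
    per_orf = pd.DataFrame(
        rows,
        columns=["dataset", "orf_id", "aa_seq", "is_meta_dataset", "n_primary_datasets"],
    )

    names = sorted(harmonized)
    seqs = {d: {r.aa_seq for r in harmonized[d]} for d in names}
    matrix = pd.DataFrame(
        [[len(seqs[a] & seqs[b]) for b in names] for a in names],
        index=names,
        columns=names,
    )
    return per_orf, matrix


def per_dataset_summary(
    harmonized: Mapping[str, Sequence[CatalogRecord]],
    sample_counts: Mapping[str, int],
    cell_type_counts: Mapping[str, int],
) -> tuple[pd.DataFrame, list[str]]:
    """ORF counts against sample/cell-type metadata, with guarded ratios."""
    rows = []
    warnings: list[str] = []
    for dataset in sorted(harmonized):
        n_orfs = len(harmonized[dataset])
        n_samples = sample_counts.get(dataset)
        n_cell_types = cell_type_counts.get(dataset)
        if n_samples is None or n_cell_types is None:
            warnings.append(f"missing metadata for dataset {dataset}")
        per_sample = n_orfs / n_samples if n_samples else None
        per_cell_type = n_orfs / n_cell_types if n_cell_types else None
        if n_samples == 0 or n_cell_types == 0:
            warnings.append(f"zero sample/cell-type count for dataset {dataset}")
        ratio = (
            per_cell_type / per_sample
            if per_cell_type is not None and per_sample
            else None
        )
        rows.append(
            {
                "dataset": dataset,
                "n_orfs": n_orfs,
                "n_samples": n_samples,
                "n_cell_types": n_cell_types,
                "orfs_per_sample": per_sample,
                "orfs_per_cell_type": per_cell_type,
                "ratio_cell_type_to_sample": ratio,
            }
        )
    columns = [
        "dataset",
        "n_orfs",
        "n_samples",
        "n_cell_types",
        "orfs_per_sample",
        "orfs_per_cell_type",
        "ratio_cell_type_to_sample",
    ]
    return pd.DataFrame(rows, columns=columns), warnings
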