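"""Ribo-Seq quality metrics: codon periodicity, detected-CDS counts,
footprint-yield arithmetic, and the CDS-mapping fraction, each with a
verdict following the published thresholds (>=70% periodicity pass, 60-70%
gray, <60% fail; >80% CDS mapping; >9000 detected CDSs)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .orf_classify import ClassifiedORF
from .orf_model import TranscriptModel

__all__ = [
    "PSITE_COLUMNS",
    "QCThresholds",
    "QCReport",
    "read_psites",
    "write_psites",
    "codon_periodicity",
    "periodicity_verdict",
    "detected_cds_count",
    "footprint_yield",
    "cds_mapping_fraction",
    "qc_report",
]

PSITE_COLUMNS = ["transcript_id", "tx_position", "read_length", "count", "frame", "region"]

PASS = "pass"
GRAY = "gray"
FAIL = "fail"
NOT_EVALUATED = "not_evaluated"


@dataclass(frozen=True)
class QCThresholds:
    """All verdict boundaries in one place; defaults follow the printed rules."""

    periodicity_pass: float = 0.70  # inclusive
    periodicity_gray: float = 0.60  # inclusive lower edge of the gray zone
    cds_mapping_pass: float = 0.80  # strict (>)
    detected_cds_pass: int = 9000  # strict (>)
    footprint_frac_low: float = 0.15
    footprint_frac_high: float = 0.30


def read_psites(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"frame": "Int64"})
    missing = [c for c in PSITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing P-site columns {missing}")
    return df


def write_psites(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _validate(psites: pd.DataFrame) -> None:
    missing = [c for c in PSITE_COLUMNS if c not in psites.columns]
    if missing:
        raise ValueError(f"P-site table missing columns {missing}")
    if (psites["count"] < 0).any():
        raise ValueError("negative P-site counts")


def codon_periodicity(
    psites: pd.DataFrame, read_lengths: Sequence[int] = (28, 29, 30)
) -> tuple[dict[int, Optional[float]], Optional[float]]:
    """In-frame fraction over CDS rows, per read length and pooled.

    Returns (per-length map, aggregate); entries are None (not evaluated)
    where no CDS counts exist for a length.
    """
    _validate(psites)
    cds = psites[(psites["region"] == "CDS") & psites["read_length"].isin(read_lengths)]
    per_length: dict[int, Optional[float]] = {}
    for rl in read_lengths:
        sub = cds[cds["read_length"] == rl]
        total = int(sub["count"].sum())
        per_length[rl] = (
            float(sub.loc[sub["frame"] == 0, "count"].sum()) / total if total else None
        )
    total = int(cds["count"].sum())
    aggregate = (
        float(cds.loc[cds["frame"] == 0, "count"].sum()) / total if total else None
    )
    return per_length, aggregate


def periodicity_verdict(
    fraction: Optional[float], thresholds: QCThresholds = QCThresholds()
) -> str:
    """>=70% pass, 60-70% gray, <60% fail; None -> not_evaluated."""
    if fraction is None:
        return NOT_EVALUATED
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction {fraction} outside [0,1]")
    if fraction >= thresholds.periodicity_pass:
        return PASS
    if fraction >= thresholds.periodicity_gray:
        return GRAY
    return FAIL


@dataclass(frozen=True)
class DetectedCDSResult:
    count: Optional[int]
    verdict: str
    warning: Optional[str] = None


def detected_cds_count(
    txs: Mapping[str, TranscriptModel],
    callset: Optional[Iterable[ClassifiedORF]] = None,
    psites: Optional[pd.DataFrame] = None,
    min_psites_per_cds: int = 10,
    threshold: Optional[int] = None,
    thresholds: QCThresholds = QCThresholds(),
) -> DetectedCDSResult:
    """Count annotated CDSs with supporting evidence, plus a verdict.

    Default rule: a CDS counts as detected when the caller output contains
    an ORF classified as identical to it. Fallback rule (when only a P-site
    table is supplied): >= ``min_psites_per_cds`` in-frame CDS P-sites.
    The pass threshold is strict (>) and must be overridden for synthetic
    scale; using the published default against a small annotation attaches
    a scale warning.
    """
    if threshold is None:
        threshold = thresholds.detected_cds_pass
    coding = {tid for tid, tx in txs.items() if tx.cds_tx is not None}
    detected: Optional[set[str]] = None
    if callset is not None:
        detected = {
            c.orf.transcript_id
            for c in callset
            if c.canonical_relation == "identical" and c.orf.transcript_id in coding
        }
    elif psites is not None and len(psites):
        _validate(psites)
        cds_rows = psites[(psites["region"] == "CDS") & (psites["frame"] == 0)]
        per_tx = cds_rows.groupby("transcript_id")["count"].sum()
        detected = {
            tid for tid, n in per_tx.items() if tid in coding and n >= min_psites_per_cds
        }
    if detected is None:
        return DetectedCDSResult(None, NOT_EVALUATED)
    count = len(detected)
    warning = None
    if threshold >= len(coding) > 0 and threshold == thresholds.detected_cds_pass:
        warning = (
            f"threshold {threshold} exceeds the {len(coding)} annotated CDSs; "
            f"override it for synthetic scale"
        )
    return DetectedCDSResult(count, PASS if count > threshold else FAIL, warning)


def footprint_yield(
    total_reads: int, frac_low: float = 0.15, frac_high: float = 0.30
) -> tuple[float, float]:
    """Expected (low, high) ribosome-footprint counts for a sequencing depth."""
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    if not 0 <= frac_low <= frac_high <= 1:
        raise ValueError(f"inverted or out-of-range fractions ({frac_low}, {frac_high})")
    return total_reads * frac_low, total_reads * frac_high


def cds_mapping_fraction(
    psites: pd.DataFrame, thresholds: QCThresholds = QCThresholds()
) -> tuple[Optional[float], str]:
    """Fraction of footprint counts in CDS regions; pass iff strictly > 80%."""
    _validate(psites)
    total = int(psites["count"].sum())
    if total == 0:
        return None, NOT_EVALUATED
    frac = float(psites.loc[psites["region"] == "CDS", "count"].sum()) / total
    return frac, PASS if frac > thresholds.cds_mapping_pass else FAIL


@dataclass
class QCReport:
    periodicity_by_length: dict[int, Optional[float]]
    aggregate_periodicity: Optional[float]
    n_detected_cds: Optional[int]
    cds_mapping_fraction: Optional[float]
    footprint_yield_range: Optional[tuple[float, float]]
    verdicts: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "periodicity_by_length": {
                str(k): v for k, v in self.periodicity_by_length.items()
            },
            "aggregate_periodicity": self.aggregate_periodicity,
            "n_detected_cds": self.n_detected_cds,
            "cds_mapping_fraction": self.cds_mapping_fraction,
            "footprint_yield_range": self.footprint_yield_range,
            "verdicts": self.verdicts,
        }


def qc_report(
    psites: pd.DataFrame,
    txs: Optional[Mapping[str, TranscriptModel]] = None,
    callset: Optional[Iterable[ClassifiedORF]] = None,
    total_reads: Optional[int] = None,
    read_lengths: Sequence[int] = (28, 29, 30),
    detected_cds_threshold: Optional[int] = None,
    min_psites_per_cds: int = 10,
    thresholds: QCThresholds = QCThresholds(),
) -> QCReport:
    """Assemble the full QC report with one verdict per metric."""
    per_length, aggregate = codon_periodicity(psites, read_lengths)
    frac_cds, cds_verdict = cds_mapping_fraction(psites, thresholds)
    if txs is not None:
        det = detected_cds_count(
            txs,
            callset=callset,
            psites=psites if callset is None else None,
            min_psites_per_cds=min_psites_per_cds,
            threshold=detected_cds_threshold,
            thresholds=thresholds,
        )
    else:
        det = DetectedCDSResult(None, NOT_EVALUATED)
    yield_range = (
        footprint_yield(total_reads, thresholds.footprint_frac_low, thresholds.footprint_frac_high)
        if total_reads is not None
        else None
    )
    return QCReport(
        periodicity_by_length=per_length,
        aggregate_periodicity=aggregate,
        n_detected_cds=det.count,
        cds_mapping_fraction=frac_cds,
        footprint_yield_range=yield_range,
        verdicts={
            "periodicity": periodicity_verdict(aggregate, thresholds),
            "cds_mapping": cds_verdict,
            "detected_cds": det.verdict,
        },
    )
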