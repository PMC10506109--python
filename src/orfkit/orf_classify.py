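"""Category assignment for ORFs relative to a transcript's annotated CDS.

The decision runs entirely in transcript coordinates on half-open,
stop-inclusive intervals: ``o`` is the ORF interval, ``c`` the CDS interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .errors import MappingError, ValidationError
from .orf_model import ORFCategory, ORFRecord, TranscriptModel, to_transcript_coords

__all__ = ["ClassifiedORF", "classify_orf", "classify_all"]

CANONICAL_RELATIONS = (
    "none",
    "identical",
    "N_extension",
    "N_truncation",
    "C_extension",
    "other_in_frame",
)


@dataclass(frozen=True)
class ClassifiedORF:
    orf: ORFRecord
    category: ORFCategory
    frame_offset: Optional[int]  # (orf_tx_start - cds_tx_start) mod 3, if a CDS exists
    canonical_relation: str = "none"

    def __post_init__(self) -> None:
        if self.canonical_relation not in CANONICAL_RELATIONS:
            raise ValidationError(f"unknown canonical relation {self.canonical_relation!r}")
        is_variant = self.category is ORFCategory.CANONICAL_VARIANT
        if is_variant != (self.canonical_relation != "none"):
            raise ValidationError(
                "category CANONICAL_VARIANT iff canonical_relation != none"
            )


def classify_orf(orf: ORFRecord, tx: TranscriptModel) -> ClassifiedORF:
    """Assign exactly one category to ``orf`` on its stated transcript.

    Decision order (o = ORF, c = CDS, both half-open with stops included):

    1. transcript without CDS                      -> lncRNA-ORF
    2. o == c                                      -> CANONICAL_VARIANT(identical)
    3. in frame, same stop                         -> N_extension / N_truncation
    4. o.end <= c.start                            -> uORF
    5. o.start < c.start < o.end <= c.end          -> uoORF
    6. c.start <= o.start, o.end <= c.end:
         out of frame                              -> intORF
         in frame (different stop)                 -> validation error
    7. c.start <= o.start < c.end < o.end:
         out of frame                              -> doORF
         in frame, same start                      -> C_extension
         in frame otherwise                        -> other_in_frame
    8. o.start >= c.end                            -> dORF
    9. o spans c entirely:
         out of frame                              -> uoORF
         in frame                                  -> other_in_frame
    """
    o = to_transcript_coords(orf, tx)
    if tx.cds_tx is None:
        return ClassifiedORF(orf, ORFCategory.LNCRNA_ORF, frame_offset=None)
    c = tx.cds_tx
    frame = (o[0] - c[0]) % 3

    def variant(relation: str) -> ClassifiedORF:
        return ClassifiedORF(orf, ORFCategory.CANONICAL_VARIANT, frame, relation)

    def cat(category: ORFCategory) -> ClassifiedORF:
        return ClassifiedORF(orf, category, frame)

    if o == c:
        return variant("identical")
    if frame == 0 and o[1] == c[1]:
        return variant("N_extension" if o[0] < c[0] else "N_truncation")
    if o[1] <= c[0]:
        return cat(ORFCategory.UORF)
    if o[0] < c[0] < o[1] <= c[1]:
        return cat(ORFCategory.UOORF)
    if c[0] <= o[0] and o[1] <= c[1]:
        if frame != 0:
            return cat(ORFCategory.INTORF)
        raise ValidationError(
            f"ORF {orf.orf_id}: in-frame interval inside CDS with a different stop "
            f"is impossible on one transcript"
        )
    if c[0] <= o[0] < c[1] < o[1]:
        if frame != 0:
            return cat(ORFCategory.DOORF)
        if o[0] == c[0]:
            return variant("C_extension")
        return variant("other_in_frame")
    if o[0] >= c[1]:
        return cat(ORFCategory.DORF)
    # remaining: o spans c entirely (o.start < c.start and o.end > c.end)
    if frame != 0:
        return cat(ORFCategory.UOORF)
    return variant("other_in_frame")


def classify_all(
    orfs: Iterable[ORFRecord], txs: Mapping[str, TranscriptModel]
) -> tuple[list[ClassifiedORF], pd.DataFrame, list[tuple[str, str]]]:
    """Classify every record; return (classified, category count table, errors).

    Missing transcripts and mapping failures produce per-record error entries
    instead of aborting. The count table reports the six noncanonical
    categories plus CANONICAL_VARIANT and EXCLUDED separately.
    """
    classified: list[ClassifiedORF] = []
    errors: list[tuple[str, str]] = []
    for orf in orfs:
        tx = txs.get(orf.transcript_id)
        if tx is None:
            errors.append((orf.orf_id, f"missing transcript {orf.transcript_id}"))
            continue
        try:
            classified.append(classify_orf(orf, tx))
        except (MappingError, ValidationError) as exc:
            errors.append((orf.orf_id, str(exc)))
    counts = (
        pd.Series([c.category.value for c in classified], dtype=str)
        .value_counts()
        .rename_axis("category")
        .reset_index(name="n")
    )
    return classified, counts, errors
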