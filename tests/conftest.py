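"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from orfkit.orf_model import (
    GenomicInterval,
    ORFRecord,
    ProvenanceTag,
    TranscriptModel,
)

CHROM = "chrT"


def make_orf(
    orf_id: str,
    blocks: list[tuple[int, int]],
    strand: str = "+",
    chrom: str = CHROM,
    transcript_id: str = "",
    replicate: str = "rep1",
    caller: str = "callerA",
    category=None,
) -> ORFRecord:
    return ORFRecord(
        orf_id=orf_id,
        transcript_id=transcript_id,
        blocks=tuple(GenomicInterval(chrom, s, e, strand) for s, e in blocks),
        source=ProvenanceTag("ds", caller, replicate, "s1"),
        category=category,
    )


def single_exon_tx(
    tid: str = "TX1",
    length: int = 3000,
    cds: tuple[int, int] | None = (900, 1800),
    strand: str = "+",
    biotype: str | None = None,
) -> TranscriptModel:
    if biotype is None:
        biotype = "protein_coding" if cds else "lncRNA"
    return TranscriptModel(
        transcript_id=tid,
        gene_id="G1",
        biotype=biotype,
        exons=(GenomicInterval(CHROM, 0, length, strand),),
        cds_tx=cds,
    )


# ---------------------------------------------------------------------------
# Independent clustering oracle (brute-force, kept free of orf_compare logic)
# ---------------------------------------------------------------------------


def oracle_is_similar(child: ORFRecord, parent: ORFRecord, min_frac: float) -> bool:
    if (child.chrom, child.strand) != (parent.chrom, parent.strand):
        return False
    if child.stop_codon_pos != parent.stop_codon_pos:
        return False
    cset = {p for b in child.blocks for p in range(b.start, b.end)}
    pset = {p for b in parent.blocks for p in range(b.start, b.end)}
    if not cset <= pset:
        return False
    return (len(cset) - 3) / (len(pset) - 3) >= min_frac


def oracle_clusters(orfs: list[ORFRecord], min_frac: float) -> set[frozenset[str]]:
    """Transitive closure by repeated merging until fixpoint."""
    groups: list[set[str]] = [{o.orf_id} for o in orfs]
    by_id = {o.orf_id: o for o in orfs}
    pairs = [
        (a.orf_id, b.orf_id)
        for i, a in enumerate(orfs)
        for b in orfs[i + 1 :]
        if oracle_is_similar(a, b, min_frac) or oracle_is_similar(b, a, min_frac)
    ]
    changed = True
    while changed:
        changed = False
        for x, y in pairs:
            gx = next(g for g in groups if x in g)
            gy = next(g for g in groups if y in g)
            if gx is not gy:
                gx |= gy
                groups.remove(gy)
                changed = True
    assert by_id  # silence linters
    return {frozenset(g) for g in groups}


def random_orf_set(rng: np.random.Generator, n_max: int = 50) -> list[ORFRecord]:
    """Random single/two-block ORFs organized into shared-stop groups."""
    n = int(rng.integers(2, n_max + 1))
    n_groups = int(rng.integers(1, 6))
    orfs: list[ORFRecord] = []
    for i in range(n):
        g = int(rng.integers(0, n_groups))
        strand = "+" if g % 2 == 0 else "-"
        anchor = 5000 * (g + 1)
        codons = int(rng.integers(2, 40))
        total = 3 * codons + 3
        blocks: list[tuple[int, int]]
        if rng.random() < 0.35 and codons >= 4:
            b2 = 3 * int(rng.integers(1, codons - 1))
            b1 = total - b2
            gap = int(rng.integers(1, 60))
            if strand == "+":
                # anchor is the shared high end; last block >= 3 nt
                blocks = [
                    (anchor - b2 - gap - b1, anchor - b2 - gap),
                    (anchor - b2, anchor),
                ]
            else:
                # anchor is the shared low end; first block >= 3 nt
                blocks = [(anchor, anchor + b1), (anchor + b1 + gap, anchor + b1 + gap + b2)]
        else:
            if strand == "+":
                blocks = [(anchor - total, anchor)]
            else:
                blocks = [(anchor, anchor + total)]
        orfs.append(
            make_orf(
                f"orf{i:03d}",
                blocks,
                strand=strand,
                replicate=f"rep{int(rng.integers(1, 7))}",
            )
        )
    return orfs


@pytest.fixture(scope="session")
def small_transcriptome():
    from orfkit.synthetic_data import gen_transcriptome

    return gen_transcriptome(30, 10, seed=11)
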