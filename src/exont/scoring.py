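"""EXONT coverage scores.

The score of a term on an exon is the number of coding nucleotides the
term's annotations cover, divided by the exon's coding length in
kilo-nucleotides — i.e. covered nt per knt, in [0, 1000].  Only the
coding part of the exon counts, overlapping hits of the same term are
unioned before measuring, and a feature that partially overlaps an exon
contributes only the overlapping region.  For a set of exons the score
pools numerators and denominators, which equals the coding-length-
weighted mean of per-exon scores.
"""

from __future__ import annotations

import pandas as pd

from .annotation import AnnotationStore
from .genome_model import ExonRecord, ExonSet
from .intervals import clip, total_length

SCALE = 1000.0  # nucleotides per kilo-nucleotide


class ScoringError(ValueError):
    pass


def covered_in_coding(store: AnnotationStore, exon: ExonRecord, term_id: str) -> int:
    """Union length of the term's hits clipped to the exon's coding part."""
    return total_length(
        clip(store.intervals(exon.exon_id, term_id), (exon.coding_start, exon.coding_end))
    )


def exon_score(store: AnnotationStore, exon: ExonRecord, term_id: str) -> float:
    """Score of one term on one exon, nt per knt of coding sequence."""
    if exon.coding_length < 1:
        raise ScoringError(f"exon {exon.exon_id} has zero coding length")
    return SCALE * covered_in_coding(store, exon, term_id) / exon.coding_length


def set_score(store: AnnotationStore, exons: ExonSet, term_id: str) -> float:
    """Pooled score of one term over a set of exons."""
    total = exons.total_coding_nt
    if total < 1:
        raise ScoringError("exon set has zero total coding length")
    covered = sum(covered_in_coding(store, e, term_id) for e in exons)
    return SCALE * covered / total


def score_table(
    store: AnnotationStore, exons: ExonSet, term_ids: list[str] | None = None
) -> pd.DataFrame:
    """Per-term covered_nt, total_nt and score over an exon set."""
    if term_ids is None:
        term_ids = store.terms
    total = exons.total_coding_nt
    rows = []
    for term_id in term_ids:
        covered = sum(covered_in_coding(store, e, term_id) for e in exons)
        rows.append((term_id, covered, total, SCALE * covered / total))
    return pd.DataFrame(rows, columns=["term_id", "covered_nt", "total_nt", "score"])
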