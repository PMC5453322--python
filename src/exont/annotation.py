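"""Projection of protein features onto genomic exons.

A protein feature lives in 1-based amino-acid coordinates on one
transcript's protein.  Amino acid *i* occupies coding nucleotides
``3(i-1)+1 .. 3i``; those positions are threaded through the
transcript's ordered CDS segments (strand-aware) to produce genomic
intervals, which are then clipped to the coding part of each
overlapping genomic exon.  When a feature only partially overlaps an
exon, only the overlapping region counts; overlapping hits of the same
term on the same exon are unioned, so a nucleotide covered twice counts
once.  A codon split across a junction contributes its nucleotides to
both flanking exons.

Localization signals (NLS, NES, PTS1, ...) are found by scanning
protein sequences with per-term regular expressions; the patterns are
configuration, not code.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_model import ExonSet, GeneModels, TranscriptModel
from .intervals import Interval, clip, merge, total_length
from .ontology import OntologyTree

log = logging.getLogger(__name__)

#: Default localization-motif patterns (term id -> regex over the
#: one-letter amino-acid alphabet).  Shipped as editable data.
DEFAULT_MOTIFS = {
    "NLS_monopartite": r"K[KR].[KR]",
    "NLS_bipartite": r"[KR][KR].{10,12}[KR]{3}",
    "NES": r"L.{2,3}[LIVFM].{2,3}L.[LI]",
    "PTS1": r"[SAC][KRH][LM]$",
}


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinFeature:
    """A term-bearing protein segment in amino-acid coordinates."""

    transcript_id: str
    term_id: str
    aa_start: int  # 1-based inclusive
    aa_end: int
    evidence: str = ""

    def __post_init__(self):
        if not 1 <= self.aa_start <= self.aa_end:
            raise AnnotationError(
                f"bad aa interval {self.aa_start}-{self.aa_end} for {self.term_id}"
            )


@dataclass
class FeatureHit:
    """One feature's footprint on one exon's coding part."""

    exon_id: str
    term_id: str
    intervals: list[Interval]
    provenance: str = ""


def map_feature_to_genome(
    feature: ProteinFeature, transcript: TranscriptModel
) -> list[Interval]:
    """Genomic intervals (0-based half-open) encoding the feature.

    Output is split at CDS-segment boundaries and totals exactly
    ``3 * (aa_end - aa_start + 1)`` nucleotides.
    """
    if not transcript.cds_segments:
        raise AnnotationError(f"transcript {transcript.transcript_id} has no CDS")
    if 3 * feature.aa_end > transcript.cds_length:
        raise AnnotationError(
            f"feature {feature.term_id} aa_end {feature.aa_end} beyond CDS of "
            f"{transcript.transcript_id} ({transcript.aa_length} aa)"
        )
    c_lo = 3 * (feature.aa_start - 1)  # 0-based coding interval
    c_hi = 3 * feature.aa_end
    out: list[Interval] = []
    offset = 0
    for s, e in transcript.cds_segments:
        seg_len = e - s
        lo = max(c_lo, offset)
        hi = min(c_hi, offset + seg_len)
        if lo < hi:
            if transcript.strand == "+":
                out.append((s + (lo - offset), s + (hi - offset)))
            else:
                out.append((e - (hi - offset), e - (lo - offset)))
        offset += seg_len
    return sorted(out)


def coding_index_of(transcript: TranscriptModel, genomic_pos: int) -> int:
    """Inverse mapping: 0-based coding index of one genomic position."""
    offset = 0
    for s, e in transcript.cds_segments:
        if s <= genomic_pos < e:
            if transcript.strand == "+":
                return offset + (genomic_pos - s)
            return offset + (e - 1 - genomic_pos)
        offset += e - s
    raise AnnotationError(f"position {genomic_pos} not in CDS")


def project_to_exons(
    feature: ProteinFeature, intervals: list[Interval], models: GeneModels
) -> list[FeatureHit]:
    """Clip genomic intervals to the coding parts of overlapping exons.

    Intervals touching no model exon are dropped with a log message.
    """
    gene_id = models.transcripts[feature.transcript_id].gene_id
    per_exon: dict[str, list[Interval]] = {}
    for s, e in intervals:
        tr = models.transcripts[feature.transcript_id]
        found = False
        for exon in models.overlapping_exons(tr.chrom, s, e):
            if exon.gene_id != gene_id:
                continue
            pieces = clip([(s, e)], (exon.coding_start, exon.coding_end))
            if pieces:
                found = True
                per_exon.setdefault(exon.exon_id, []).extend(pieces)
        if not found:
            log.info(
                "interval %d-%d of %s overlaps no coding exon; dropped",
                s, e, feature.term_id,
            )
    return [
        FeatureHit(exon_id, feature.term_id, merge(iv), feature.evidence)
        for exon_id, iv in sorted(per_exon.items())
    ]


def scan_localization_motifs(
    sequence: str,
    patterns: dict[str, str],
    transcript_id: str = "",
    evidence: str = "motif_scan",
) -> list[ProteinFeature]:
    """Scan one protein for localization motifs.

    Every leftmost non-overlapping match of each pattern is emitted as a
    single-segment feature spanning the matched residues.  Patterns are
    compiled at call time; an invalid regex is a configuration error.
    """
    out: list[ProteinFeature] = []
    for term_id in sorted(patterns):
        try:
            rx = re.compile(patterns[term_id])
        except re.error as err:
            raise AnnotationError(f"invalid regex for {term_id}: {err}") from err
        for m in rx.finditer(sequence):
            if m.end() == m.start():
                continue
            out.append(
                ProteinFeature(
                    transcript_id=transcript_id,
                    term_id=term_id,
                    aa_start=m.start() + 1,
                    aa_end=m.end(),
                    evidence=evidence,
                )
            )
    return out


def load_motif_config(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``term_id<TAB>regex`` motif configuration."""
    patterns: dict[str, str] = {}
    for ln in Path(path).read_text().splitlines():
        ln = ln.rstrip("\n")
        if not ln.strip() or ln.startswith("#"):
            continue
        term_id, rx = ln.split("\t")[:2]
        patterns[term_id] = rx
    return patterns


class AnnotationStore:
    """Merged per-(exon, term) coverage intervals.

    Adding the same intervals twice is a no-op on coverage length
    (union semantics); queries are idempotent.
    """

    def __init__(self):
        self._cov: dict[tuple[str, str], list[Interval]] = {}

    def add(self, exon_id: str, term_id: str, intervals: list[Interval]) -> None:
        key = (exon_id, term_id)
        self._cov[key] = merge(self._cov.get(key, []) + list(intervals))

    def intervals(self, exon_id: str, term_id: str) -> list[Interval]:
        return list(self._cov.get((exon_id, term_id), []))

    def covered_nt(self, exon_id: str, term_id: str) -> int:
        return total_length(self._cov.get((exon_id, term_id), []))

    @property
    def terms(self) -> list[str]:
        return sorted({t for _, t in self._cov})

    def annotated_exon_count(self, term_id: str) -> int:
        return sum(1 for (_, t), iv in self._cov.items() if t == term_id and iv)

    def coverage_matrix(
        self, exon_ids: list[str], term_ids: list[str]
    ) -> np.ndarray:
        """Covered-nucleotide counts, exons x terms."""
        mat = np.zeros((len(exon_ids), len(term_ids)), dtype=np.int64)
        tpos = {t: j for j, t in enumerate(term_ids)}
        epos = {e: i for i, e in enumerate(exon_ids)}
        for (exon_id, term_id), iv in self._cov.items():
            i, j = epos.get(exon_id), tpos.get(term_id)
            if i is not None and j is not None:
                mat[i, j] = total_length(iv)
        return mat

    def items(self):
        return self._cov.items()


def annotate_exons(
    features: list[ProteinFeature],
    models: GeneModels,
    tree: OntologyTree | None = None,
    propagate: bool = True,
) -> AnnotationStore:
    """Project features onto exons and populate the hit store.

    With ``propagate`` on, each hit is recorded for every ancestor term
    as well (interval union per ancestor), so coverage of a parent term
    is always at least that of any child.  Features with unknown terms
    or transcripts are skipped per record.
    """
    store = AnnotationStore()
    for feat in features:
        if feat.transcript_id not in models.transcripts:
            log.error("unknown transcript %s; feature skipped", feat.transcript_id)
            continue
        if tree is not None and feat.term_id not in tree:
            log.error("unknown term %s; feature skipped", feat.term_id)
            continue
        tr = models.transcripts[feat.transcript_id]
        try:
            genomic = map_feature_to_genome(feat, tr)
        except AnnotationError as err:
            log.error("feature dropped: %s", err)
            continue
        term_ids = [feat.term_id]
        if propagate and tree is not None:
            term_ids += sorted(tree.ancestors(feat.term_id))
        for hit in project_to_exons(feat, genomic, models):
            for term_id in term_ids:
                store.add(hit.exon_id, term_id, hit.intervals)
    return store


def read_feature_table(path: str | Path) -> list[ProteinFeature]:
    """Read features from TSV: transcript_id, term_id, aa_start, aa_end, evidence."""
    feats: list[ProteinFeature] = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        f = ln.rstrip("\n").split("\t")
        if f[0] == "transcript_id":
            continue
        feats.append(
            ProteinFeature(
                transcript_id=f[0],
                term_id=f[1],
                aa_start=int(f[2]),
                aa_end=int(f[3]),
                evidence=f[4] if len(f) > 4 else "",
            )
        )
    return feats


def term_frequency(store: AnnotationStore, universe: ExonSet) -> dict[str, float]:
    """Fraction of universe exons bearing >=1 hit, per term."""
    if len(universe) == 0:
        raise AnnotationError("empty exon universe")
    member = set(universe.exon_ids)
    counts: dict[str, int] = {}
    for (exon_id, term_id), iv in store.items():
        if exon_id in member and iv:
            counts[term_id] = counts.get(term_id, 0) + 1
    return {t: c / len(universe) for t, c in sorted(counts.items())}
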