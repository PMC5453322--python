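"""Gene models, coding exons and control-pool categories.

Reads GFF3 gene/mRNA/exon/CDS records, derives the universe of *coding
genomic exons* (one record per distinct genomic exon of a gene that
overlaps CDS in at least one transcript), and classifies each exon two
ways:

* position along the gene — first, internal or last coding exon, in
  transcription order on the union of coding exons;
* splice class — *constitutive* when an exon with identical genomic
  coordinates appears in every transcript of its gene, *alternative*
  otherwise.

These categories define the control pools from which size-matched
random exon sets are drawn during enrichment testing: comparing, say, a
list of regulated internal exons against all coding exons confounds
position effects, so each category doubles as a null universe.

Coordinates are 0-based half-open internally; GFF3 I/O is 1-based
inclusive and BED I/O 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

POSITION_CATEGORIES = ("first_coding", "internal_coding", "last_coding")

#: Named control pools selectable for enrichment.
POOLS = (
    "all_coding",
    "first",
    "internal",
    "last",
    "internal_constitutive",
    "internal_alternative",
)


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ExonRecord:
    """A coding genomic exon of one gene."""

    exon_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int           # 0-based
    end: int             # half-open
    coding_start: int    # sub-interval overlapping CDS
    coding_end: int
    position_category: str = "internal_coding"
    splice_class: str = "unclassified"

    @property
    def coding_length(self) -> int:
        return self.coding_end - self.coding_start

    def __post_init__(self):
        if not (self.start <= self.coding_start < self.coding_end <= self.end):
            raise ModelError(
                f"coding interval outside exon for {self.exon_id}"
            )


@dataclass
class TranscriptModel:
    """One transcript with its CDS segments in coding (5'->3') order."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    cds_segments: list[tuple[int, int]]   # coding order
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    @property
    def aa_length(self) -> int:
        return self.cds_length // 3


@dataclass
class ExonSet:
    """A list of distinct exons with its total coding size."""

    exons: list[ExonRecord]

    def __post_init__(self):
        ids = [e.exon_id for e in self.exons]
        if len(ids) != len(set(ids)):
            raise ModelError("duplicate exon ids in set")

    @property
    def exon_ids(self) -> list[str]:
        return [e.exon_id for e in self.exons]

    @property
    def total_coding_nt(self) -> int:
        return sum(e.coding_length for e in self.exons)

    def __len__(self) -> int:
        return len(self.exons)

    def __iter__(self):
        return iter(self.exons)


class GeneModels:
    """Container for genes, transcripts and categorized coding exons."""

    def __init__(self, transcripts: dict[str, TranscriptModel]):
        self.transcripts = transcripts
        self.genes: dict[str, list[str]] = {}
        for tid, tr in sorted(transcripts.items()):
            self.genes.setdefault(tr.gene_id, []).append(tid)
        self.exons: dict[str, ExonRecord] = {}
        self._index: dict[str, IntervalTree] = {}
        self._build_exons()

    # -- exon derivation ---------------------------------------------

    def _build_exons(self) -> None:
        for gene_id, tids in sorted(self.genes.items()):
            trs = [self.transcripts[t] for t in tids]
            chrom, strand = trs[0].chrom, trs[0].strand
            coords = sorted({ex for tr in trs for ex in tr.exons})
            all_cds = sorted({seg for tr in trs for seg in tr.cds_segments})
            records = []
            for s, e in coords:
                touching = [c for c in all_cds if c[0] < e and c[1] > s]
                if not touching:
                    continue  # non-coding exon: outside the universe
                cs = max(s, min(c[0] for c in touching))
                ce = min(e, max(c[1] for c in touching))
                in_all = all((s, e) in tr.exons for tr in trs)
                records.append(
                    dict(
                        exon_id=f"{gene_id}:{s + 1}-{e}",
                        gene_id=gene_id,
                        chrom=chrom,
                        strand=strand,
                        start=s,
                        end=e,
                        coding_start=cs,
                        coding_end=ce,
                        splice_class="constitutive" if in_all else "alternative",
                    )
                )
            if not records:
                continue
            # transcription order on the union of coding exons
            records.sort(key=lambda r: r["start"], reverse=(strand == "-"))
            for i, rec in enumerate(records):
                if len(records) == 1:
                    cat = "first_coding"
                    log.info(
                        "single coding exon gene %s: exon assigned "
                        "first_coding, excluded from internal pools",
                        gene_id,
                    )
                elif i == 0:
                    cat = "first_coding"
                elif i == len(records) - 1:
                    cat = "last_coding"
                else:
                    cat = "internal_coding"
                exon = ExonRecord(position_category=cat, **rec)
                self.exons[exon.exon_id] = exon
                self._index.setdefault(chrom, IntervalTree()).addi(
                    exon.start, exon.end, exon.exon_id
                )

    # -- queries ------------------------------------------------------

    def overlapping_exons(self, chrom: str, start: int, end: int) -> list[ExonRecord]:
        tree = self._index.get(chrom)
        if tree is None:
            return []
        return sorted(
            (self.exons[iv.data] for iv in tree.overlap(start, end)),
            key=lambda e: (e.start, e.end, e.exon_id),
        )

    def control_pool(self, which: str = "all_coding") -> ExonSet:
        """Deterministic, sorted exon universe for a named category."""
        if which not in POOLS:
            raise ModelError(f"unknown pool {which!r}; choose from {POOLS}")
        preds = {
            "all_coding": lambda e: True,
            "first": lambda e: e.position_category == "first_coding",
            "internal": lambda e: e.position_category == "internal_coding",
            "last": lambda e: e.position_category == "last_coding",
            "internal_constitutive": lambda e: e.position_category
            == "internal_coding" and e.splice_class == "constitutive",
            "internal_alternative": lambda e: e.position_category
            == "internal_coding" and e.splice_class == "alternative",
        }
        pool = sorted(
            (e for e in self.exons.values() if preds[which](e)),
            key=lambda e: (e.chrom, e.start, e.end, e.exon_id),
        )
        if not pool:
            raise ModelError(f"control pool {which!r} is empty")
        return ExonSet(pool)

    def match_exon(self, chrom: str, start: int, end: int, strand: str | None = None):
        """Resolve user coordinates to a model exon.

        Exact (chrom, start, end, strand) match first; falls back to the
        best >=90% reciprocal-overlap candidate with a warning.  Returns
        ``None`` when nothing qualifies.
        """
        candidates = [
            e
            for e in self.overlapping_exons(chrom, start, end)
            if strand is None or e.strand == strand
        ]
        for e in candidates:
            if e.start == start and e.end == end:
                return e
        best, best_frac = None, 0.0
        for e in candidates:
            ov = min(end, e.end) - max(start, e.start)
            frac = min(ov / (end - start), ov / (e.end - e.start))
            if frac > best_frac:
                best, best_frac = e, frac
        if best is not None and best_frac >= 0.9:
            log.warning(
                "no exact exon at %s:%d-%d; matched %s by %.0f%% reciprocal overlap",
                chrom, start, end, best.exon_id, 100 * best_frac,
            )
            return best
        return None


def read_gene_models(path: str | Path) -> GeneModels:
    """Parse a GFF3 file of gene/mRNA/exon/CDS records into models.

    CDS records falling outside every exon of their transcript discard
    the transcript with a logged error; records missing a ``Parent``
    attribute are skipped with a warning.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    tr_gene: dict[str, str] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype in ("mRNA", "transcript"):
            parents = feat.attributes.get("Parent", [])
            tr_gene[feat.id] = parents[0] if parents else feat.id
            meta[feat.id] = (feat.seqid, feat.strand)
        elif feat.featuretype in ("exon", "CDS"):
            parents = feat.attributes.get("Parent", [])
            if not parents:
                log.warning("%s record without Parent skipped", feat.featuretype)
                continue
            store = exons if feat.featuretype == "exon" else cds
            for p in parents:
                store.setdefault(p, []).append((feat.start - 1, feat.end))

    transcripts: dict[str, TranscriptModel] = {}
    for tid, gene_id in tr_gene.items():
        chrom, strand = meta[tid]
        tr_exons = sorted(set(exons.get(tid, [])))
        tr_cds = sorted(set(cds.get(tid, [])))
        bad = [
            c for c in tr_cds
            if not any(s <= c[0] and c[1] <= e for s, e in tr_exons)
        ]
        if bad:
            log.error(
                "transcript %s dropped: CDS %s outside its exons", tid, bad
            )
            continue
        if tr_cds and sum(e - s for s, e in tr_cds) % 3:
            log.warning("transcript %s CDS length not divisible by 3", tid)
        if strand == "-":
            tr_cds = tr_cds[::-1]
        transcripts[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            cds_segments=tr_cds,
            exons=tr_exons,
        )
    return GeneModels(transcripts)


def categorize_exons(models: GeneModels) -> list[ExonRecord]:
    """All coding exons with categories, sorted deterministically."""
    return models.control_pool("all_coding").exons


def read_exon_list(path: str | Path, models: GeneModels) -> ExonSet:
    """Read a test list of exons (BED6 or naked chrom/start/end TSV).

    BED coordinates are 0-based half-open.  Each line is resolved
    against the models via :meth:`GeneModels.match_exon`; unresolvable
    lines are dropped with a warning.
    """
    hits: list[ExonRecord] = []
    seen: set[str] = set()
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith(("#", "track", "browser")):
            continue
        f = ln.split("\t")
        chrom, start, end = f[0], int(f[1]), int(f[2])
        strand = f[5] if len(f) >= 6 and f[5] in "+-" else None
        exon = models.match_exon(chrom, start, end, strand)
        if exon is None:
            log.warning("no model exon matches %s:%d-%d; dropped", chrom, start, end)
        elif exon.exon_id not in seen:
            seen.add(exon.exon_id)
            hits.append(exon)
    if not hits:
        raise ModelError(f"no exon in {path} matched the gene models")
    return ExonSet(hits)
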