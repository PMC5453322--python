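"""Ground-truthed synthetic fixtures.

Generates a complete miniature study — gene models (GFF3), a protein
feature table, protein sequences, a small term DAG with the eight root
classes, a test exon list, and a PSI-MITAB interaction file — with
every planted quantity recorded in a truth JSON so downstream modules
can be validated without any external annotation resource.

What the generator emulates: multi-exon genes on both strands with
5'/3' UTR-bearing terminal exons; alternative internal exons created by
skipping transcripts; per-term coverage painted as randomly placed,
possibly overlapping intervals (geometric lengths, mean ~30 nt) at a
configured density; single-residue PTM sites; localization motifs
inserted into protein sequences; a planted (spiked) enrichment on a
chosen term and exon list.  Exon coding lengths are whole codons and
features are planted within a single exon's codon range, so every
planted frequency is exact by construction rather than subject to
junction spillover.

What it does not emulate: codon-split junction features (those are
exercised by hand-built fixtures in the test suite), realistic human
term-frequency spectra, or sequence-dependent annotation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import DEFAULT_MOTIFS, scan_localization_motifs
from .ontology import ROOT_CLASSES

log = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIMNPQSTVWY"  # K, R, L kept rare to limit chance motifs


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TermSpec:
    """One leaf term painted onto exons.

    exon_prob is the probability that a coding exon carries the term;
    density is the target fraction of the exon's coding nucleotides
    covered, given the exon carries it.  ``ptm`` marks single-residue
    terms.
    """

    term_id: str
    root: str
    exon_prob: float
    density: float
    ptm: bool = False


#: Leaf terms of the default fixture; exon probabilities straddle the
#: 4% testability filter on purpose.
DEFAULT_TERMS = (
    TermSpec("EX:domain_kinase", "catalytic", 0.30, 0.20),
    TermSpec("EX:active_site", "catalytic", 0.10, 0.08),
    TermSpec("EX:protein_binding", "binding", 0.45, 0.25),
    TermSpec("EX:rna_binding", "binding", 0.12, 0.15),
    TermSpec("EX:phospho_serine", "PTM", 0.25, 0.04, ptm=True),
    TermSpec("EX:acetylated_residue", "PTM", 0.02, 0.04, ptm=True),
    TermSpec("EX:iupr", "structure", 0.50, 0.35),
    TermSpec("EX:alpha_helix", "structure", 0.30, 0.30),
    TermSpec("EX:receptor_ligand_site", "receptor", 0.06, 0.20),
    TermSpec("EX:channel_pore", "transporter", 0.08, 0.25),
    TermSpec("EX:signal_peptide", "localization", 0.02, 0.10),
    TermSpec("EX:low_complexity", "other", 0.07, 0.20),
)


@dataclass
class FixtureConfig:
    n_genes: int = 30
    exons_per_gene: tuple[int, int] = (5, 9)
    exon_len_median: float = 130.0     # lognormal, nt
    exon_len_sigma: float = 0.6
    exon_len_bounds: tuple[int, int] = (30, 2000)
    intron_len: tuple[int, int] = (60, 300)
    utr_len: tuple[int, int] = (20, 200)
    alt_gene_fraction: float = 0.6     # genes gaining a skipping transcript
    terms: tuple[TermSpec, ...] = DEFAULT_TERMS
    n_test_exons: int = 12
    spike_term: str = "EX:domain_kinase"
    spike_multiplier: float = 1.0
    n_chroms: int = 3
    n_motif_transcripts: int = 8       # transcripts given an inserted motif
    n_partner_hubs: int = 2            # shared interaction partners

    def validate(self) -> None:
        for t in self.terms:
            if not (0.0 <= t.exon_prob <= 1.0 and 0.0 < t.density <= 1.0):
                raise ConfigError(f"term {t.term_id}: probabilities outside [0,1]")
            if t.term_id == self.spike_term and t.density * self.spike_multiplier > 1.0:
                raise ConfigError(
                    f"spiked density {t.density * self.spike_multiplier:.2f} > 1 "
                    f"for {self.spike_term}"
                )
        if self.spike_multiplier < 1.0:
            raise ConfigError("spike multiplier must be >= 1")
        if self.spike_term not in {t.term_id for t in self.terms}:
            raise ConfigError(f"spike term {self.spike_term!r} not in term list")


@dataclass
class SyntheticTruth:
    """Everything planted, recomputable from the emitted files."""

    seed: int
    config: dict
    n_exons: dict[str, int]
    term_exons: dict[str, list[str]]          # incl. ancestor closure
    term_frequencies: dict[str, float]        # vs the all-coding universe
    test_exons: list[str]
    spike: dict
    motif_sites: dict[str, dict[str, list[list[int]]]]
    shared_partners: dict[str, list[str]]


@dataclass
class Fixture:
    outdir: Path
    config: FixtureConfig
    seed: int
    paths: dict[str, Path]
    truth: SyntheticTruth


# -- internal gene layout -------------------------------------------------


@dataclass
class _Exon:
    # transcription-order record; genomic coords filled during layout
    coding_len: int
    total_len: int
    utr_head: int  # UTR nt at the 5' (transcription) end
    start: int = 0
    end: int = 0
    coding_start: int = 0
    coding_end: int = 0
    aa_lo: int = 0   # 1-based inclusive aa range encoded by this exon
    aa_hi: int = 0


@dataclass
class _Gene:
    gene_id: str
    chrom: str
    strand: str
    exons: list[_Exon]               # transcription order
    skip_idx: int | None             # internal exon absent from transcript 2

    @property
    def transcript_ids(self) -> list[str]:
        tids = [f"{self.gene_id}.t1"]
        if self.skip_idx is not None:
            tids.append(f"{self.gene_id}.t2")
        return tids

    def exon_id(self, ex: _Exon) -> str:
        return f"{self.gene_id}:{ex.start + 1}-{ex.end}"


def _draw_coding_len(cfg: FixtureConfig, rng: np.random.Generator) -> int:
    lo, hi = cfg.exon_len_bounds
    val = rng.lognormal(np.log(cfg.exon_len_median), cfg.exon_len_sigma)
    val = int(np.clip(val, lo, hi))
    return max(30, 3 * (val // 3))  # whole codons, >= 10 aa


def _make_genes(cfg: FixtureConfig, rng: np.random.Generator) -> list[_Gene]:
    genes: list[_Gene] = []
    cursors = {f"chr{i + 1}": 1000 for i in range(cfg.n_chroms)}
    for g in range(cfg.n_genes):
        gene_id = f"G{g + 1:03d}"
        chrom = f"chr{g % cfg.n_chroms + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        utr5 = int(rng.integers(*cfg.utr_len))
        utr3 = int(rng.integers(*cfg.utr_len))
        exons = []
        for i in range(n_ex):
            c = _draw_coding_len(cfg, rng)
            head = utr5 if i == 0 else 0
            tail = utr3 if i == n_ex - 1 else 0
            exons.append(_Exon(coding_len=c, total_len=head + c + tail, utr_head=head))
        introns = [int(rng.integers(*cfg.intron_len)) for _ in range(n_ex - 1)]
        # genomic layout: left-to-right order is transcription order on
        # '+', reversed on '-'
        order = list(range(n_ex)) if strand == "+" else list(range(n_ex))[::-1]
        x = cursors[chrom]
        for pos, idx in enumerate(order):
            ex = exons[idx]
            ex.start, ex.end = x, x + ex.total_len
            x = ex.end + (introns[pos] if pos < n_ex - 1 else 0)
        cursors[chrom] = x + int(rng.integers(500, 1500))
        # coding sub-interval: 5' UTR sits at the genomic left on '+',
        # at the genomic right on '-'; 3' UTR mirrors it
        off = 0
        for i, ex in enumerate(exons):
            tail = ex.total_len - ex.utr_head - ex.coding_len
            if strand == "+":
                ex.coding_start = ex.start + ex.utr_head
                ex.coding_end = ex.end - tail
            else:
                ex.coding_start = ex.start + tail
                ex.coding_end = ex.end - ex.utr_head
            ex.aa_lo = off // 3 + 1
            ex.aa_hi = (off + ex.coding_len) // 3
            off += ex.coding_len
        skip = None
        if n_ex >= 4 and rng.random() < cfg.alt_gene_fraction:
            skip = int(rng.integers(1, n_ex - 1))
        genes.append(_Gene(gene_id, chrom, strand, exons, skip))
    return genes


def _write_gff3(genes: list[_Gene], path: Path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        gstart = min(e.start for e in g.exons) + 1
        gend = max(e.end for e in g.exons)
        lines.append(
            f"{g.chrom}\tsynth\tgene\t{gstart}\t{gend}\t.\t{g.strand}\t.\tID={g.gene_id}"
        )
        for t, tid in enumerate(g.transcript_ids):
            keep = [
                i for i in range(len(g.exons))
                if not (t == 1 and i == g.skip_idx)
            ]
            tstart = min(g.exons[i].start for i in keep) + 1
            tend = max(g.exons[i].end for i in keep)
            lines.append(
                f"{g.chrom}\tsynth\tmRNA\t{tstart}\t{tend}\t.\t{g.strand}\t.\t"
                f"ID={tid};Parent={g.gene_id}"
            )
            for i in keep:
                ex = g.exons[i]
                lines.append(
                    f"{g.chrom}\tsynth\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{g.strand}\t.\tParent={tid}"
                )
                lines.append(
                    f"{g.chrom}\tsynth\tCDS\t{ex.coding_start + 1}\t{ex.coding_end}"
                    f"\t.\t{g.strand}\t0\tParent={tid}"
                )
    path.write_text("\n".join(lines) + "\n")


# -- ontology -------------------------------------------------------------


def _write_ontology(cfg: FixtureConfig, obo_path: Path, map_path: Path) -> dict[str, list[str]]:
    """Small DAG: 8 roots, one mid-level node per used root, leaves.

    Returns the ancestor map term -> ancestor ids (for truth closure).
    """
    mid_of = {
        "catalytic": "EX:catalytic_feature",
        "binding": "EX:binding_feature",
        "receptor": "EX:receptor_feature",
        "transporter": "EX:transporter_feature",
        "localization": "EX:localization_feature",
        "structure": "EX:structure_feature",
        "PTM": "EX:modified_residue",
        "other": "EX:misc_feature",
    }
    stanzas = ["format-version: 1.2", "ontology: exont-synthetic", ""]
    for cls in ROOT_CLASSES:
        stanzas += [f"[Term]", f"id: EX:root_{cls}", f"name: {cls} root", ""]
        stanzas += [
            "[Term]", f"id: {mid_of[cls]}",
            f"name: {cls} feature", f"is_a: EX:root_{cls}", "",
        ]
    ancestors: dict[str, list[str]] = {}
    for cls in ROOT_CLASSES:
        ancestors[mid_of[cls]] = [f"EX:root_{cls}"]
    for t in cfg.terms:
        stanzas += [
            "[Term]", f"id: {t.term_id}",
            f"name: {t.term_id.split(':', 1)[1].replace('_', ' ')}",
            f"is_a: {mid_of[t.root]}", "",
        ]
        ancestors[t.term_id] = [mid_of[t.root], f"EX:root_{t.root}"]
    obo_path.write_text("\n".join(stanzas))
    map_path.write_text(
        "".join(f"EX:root_{cls}\t{cls}\n" for cls in ROOT_CLASSES)
    )
    return ancestors


# -- coverage planting ----------------------------------------------------


def _plant_intervals(
    aa_lo: int, aa_hi: int, density: float, ptm: bool, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Random aa intervals within [aa_lo, aa_hi] until the union covers
    ~density of the span.  PTM terms place single residues."""
    span = aa_hi - aa_lo + 1
    target = max(1, int(round(density * span)))
    if ptm:
        n = min(target, span)
        sites = rng.choice(np.arange(aa_lo, aa_hi + 1), size=n, replace=False)
        return [(int(s), int(s)) for s in sorted(sites)]
    covered: set[int] = set()
    out: list[tuple[int, int]] = []
    guard = 0
    while len(covered) < target and guard < 200:
        guard += 1
        length = min(span, 1 + int(rng.geometric(1 / 10)))
        s = int(rng.integers(aa_lo, aa_hi - length + 2))
        e = s + length - 1
        out.append((s, e))
        covered.update(range(s, e + 1))
    return out


def _plant_features(
    cfg: FixtureConfig,
    genes: list[_Gene],
    test_exon_ids: set[str],
    seed: int,
) -> tuple[list[tuple[str, str, int, int, str]], dict[str, set[str]]]:
    """Feature rows (t1-based) and the per-term planted exon-id sets.

    Each (gene, exon, term) cell draws from its own seeded substream,
    so spiking one term on some exons perturbs no other cell.
    """
    rows: list[tuple[str, str, int, int, str]] = []
    planted: dict[str, set[str]] = {t.term_id: set() for t in cfg.terms}
    for gi, g in enumerate(genes):
        t1 = f"{g.gene_id}.t1"
        for ei, ex in enumerate(g.exons):
            eid = g.exon_id(ex)
            for ti, t in enumerate(cfg.terms):
                cell_rng = np.random.default_rng([seed % (2**31), 7, gi, ei, ti])
                spiked = (
                    t.term_id == cfg.spike_term
                    and cfg.spike_multiplier > 1.0
                    and eid in test_exon_ids
                )
                background = cell_rng.random() < t.exon_prob
                if spiked:
                    density = t.density * cfg.spike_multiplier
                elif background:
                    density = t.density
                else:
                    continue
                for s, e in _plant_intervals(ex.aa_lo, ex.aa_hi, density, t.ptm, cell_rng):
                    rows.append((t1, t.term_id, s, e, "synthetic"))
                planted[t.term_id].add(eid)
    return rows, planted


# -- proteins, motifs, interactome ---------------------------------------


def _write_proteins(
    cfg: FixtureConfig, genes: list[_Gene], fasta: Path, rng: np.random.Generator
) -> dict[str, dict[str, list[list[int]]]]:
    inserts = [("PTS1", "SKL"), ("NLS_monopartite", "KKAK")]
    chosen = {
        f"{genes[i].gene_id}.t1": inserts[k % len(inserts)]
        for k, i in enumerate(
            sorted(rng.choice(len(genes), size=min(cfg.n_motif_transcripts, len(genes)),
                              replace=False).tolist())
        )
    }
    sites: dict[str, dict[str, list[list[int]]]] = {}
    recs = []
    for g in genes:
        tid = f"{g.gene_id}.t1"
        n_aa = sum(ex.coding_len for ex in g.exons) // 3
        seq = list(rng.choice(list(AA_ALPHABET), size=n_aa))
        if tid in chosen:
            term, motif = chosen[tid]
            if term == "PTS1":
                seq[-len(motif):] = list(motif)
            else:
                pos = int(rng.integers(0, n_aa - len(motif)))
                seq[pos:pos + len(motif)] = list(motif)
        protein = "".join(seq)
        recs.append((tid, protein))
        found = scan_localization_motifs(protein, DEFAULT_MOTIFS, transcript_id=tid)
        by_term: dict[str, list[list[int]]] = {}
        for f in found:
            by_term.setdefault(f.term_id, []).append([f.aa_start, f.aa_end])
        if by_term:
            sites[tid] = by_term
    fasta.write_text("".join(f">{tid}\n{seq}\n" for tid, seq in recs))
    return sites


def _write_mitab(
    cfg: FixtureConfig, genes: list[_Gene], path: Path, rng: np.random.Generator
) -> dict[str, list[str]]:
    gene_ids = [g.gene_id for g in genes]
    shared: dict[str, list[str]] = {}
    lines = []

    def row(a: str, b: str) -> str:
        cols = ["-"] * 15
        cols[0] = f"synthdb:{a}"
        cols[1] = f"synthdb:{b}"
        cols[12] = "psi-mi:synthdb"
        return "\t".join(cols)

    for h in range(cfg.n_partner_hubs):
        hub = f"HUB{h + 1}"
        members = rng.choice(len(gene_ids), size=3, replace=False)
        shared[hub] = sorted(gene_ids[i] for i in members)
        for gid in shared[hub]:
            lines.append(row(gid, hub))
    for _ in range(2 * len(gene_ids)):
        i, j = rng.integers(0, len(gene_ids), size=2)
        lines.append(row(gene_ids[int(i)], f"P{int(rng.integers(1, 40)):02d}"))
        if i != j and rng.random() < 0.3:
            lines.append(row(gene_ids[int(i)], gene_ids[int(j)]))
    path.write_text("\n".join(lines) + "\n")
    return shared


# -- driver ---------------------------------------------------------------


def generate_fixture(
    config: FixtureConfig | None = None, seed: int = 0, outdir: str | Path = "."
) -> Fixture:
    """Emit a complete fixture into *outdir* and return it with truth.

    Same config and seed produce byte-identical files.
    """
    cfg = config or FixtureConfig()
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    genes = _make_genes(cfg, rng)
    paths = {
        "models": outdir / "models.gff3",
        "features": outdir / "features.tsv",
        "proteins": outdir / "proteins.fasta",
        "ontology": outdir / "ontology.obo",
        "root_map": outdir / "root_map.tsv",
        "motifs": outdir / "motifs.tsv",
        "test_bed": outdir / "test_exons.bed",
        "mitab": outdir / "interactions.mitab",
        "truth": outdir / "truth.json",
    }
    _write_gff3(genes, paths["models"])
    ancestor_map = _write_ontology(cfg, paths["ontology"], paths["root_map"])
    paths["motifs"].write_text(
        "".join(f"{t}\t{rx}\n" for t, rx in sorted(DEFAULT_MOTIFS.items()))
    )

    # test list: internal exons, sampled without replacement
    internal = [
        (g, ex)
        for g in genes
        for i, ex in enumerate(g.exons)
        if 0 < i < len(g.exons) - 1
    ]
    pick = sorted(
        rng.choice(len(internal), size=min(cfg.n_test_exons, len(internal)),
                   replace=False).tolist()
    )
    test = [internal[i] for i in pick]
    test_ids = [g.exon_id(ex) for g, ex in test]
    paths["test_bed"].write_text(
        "".join(
            f"{g.chrom}\t{ex.start}\t{ex.end}\t{g.exon_id(ex)}\t0\t{g.strand}\n"
            for g, ex in test
        )
    )

    rows, planted = _plant_features(cfg, genes, set(test_ids), seed)
    paths["features"].write_text(
        "transcript_id\tterm_id\taa_start\taa_end\tevidence\n"
        + "".join(f"{r[0]}\t{r[1]}\t{r[2]}\t{r[3]}\t{r[4]}\n" for r in rows)
    )

    motif_sites = _write_proteins(cfg, genes, paths["proteins"], rng)
    shared = _write_mitab(cfg, genes, paths["mitab"], rng)

    # truth: ancestor-closed planted sets against the all-coding universe
    n_all = sum(len(g.exons) for g in genes)
    term_exons: dict[str, set[str]] = {t: set(v) for t, v in planted.items()}
    for t in list(planted):
        for anc in ancestor_map.get(t, []):
            term_exons.setdefault(anc, set()).update(planted[t])
    n_exons = {
        "all_coding": n_all,
        "first": len(genes),
        "last": sum(1 for g in genes if len(g.exons) > 1),
        "internal": sum(max(0, len(g.exons) - 2) for g in genes),
    }
    truth = SyntheticTruth(
        seed=seed,
        config=dataclasses.asdict(cfg),
        n_exons=n_exons,
        term_exons={t: sorted(v) for t, v in sorted(term_exons.items())},
        term_frequencies={
            t: len(v) / n_all for t, v in sorted(term_exons.items())
        },
        test_exons=test_ids,
        spike={
            "term_id": cfg.spike_term,
            "multiplier": cfg.spike_multiplier,
            "exons": test_ids if cfg.spike_multiplier > 1.0 else [],
            "expected_enriched": cfg.spike_multiplier > 1.0,
        },
        motif_sites=motif_sites,
        shared_partners=shared,
    )
    paths["truth"].write_text(
        json.dumps(dataclasses.asdict(truth), indent=1, sort_keys=True) + "\n"
    )
    return Fixture(outdir=outdir, config=cfg, seed=seed, paths=paths, truth=truth)


def spike_in(
    fixture: Fixture, term_id: str, exons: list[str], multiplier: float
) -> Fixture:
    """Multiply a term's planted coverage density on the given exons.

    Regenerates the fixture deterministically with the spike applied;
    an empty exon list leaves every file byte-identical.  The listed
    exons must be the fixture's test list (coverage is planted relative
    to it); unknown exon ids are an error.
    """
    if not exons:
        return generate_fixture(fixture.config, fixture.seed, fixture.outdir)
    known = set(fixture.truth.test_exons)
    unknown = [e for e in exons if e not in known]
    if unknown:
        raise ConfigError(f"unknown or non-test exons: {unknown}")
    cfg = dataclasses.replace(
        fixture.config, spike_term=term_id, spike_multiplier=multiplier
    )
    return generate_fixture(cfg, fixture.seed, fixture.outdir)
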