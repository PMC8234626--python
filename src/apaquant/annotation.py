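"""Annotation handling: terminal fragments, polyA-site grouping, APA classification.

Alternative polyadenylation (APA) analysis starts from a genome annotation.
Because annotations tie upstream splicing choices to downstream 3' ends, the
quantification unit here is the *terminal fragment* — the last two exons of
each transcript (or its 3'-terminal 300 nt for 3'-end-sequencing libraries) —
which decouples APA from alternative splicing further upstream.

Transcript 3' ends lying within 25 nt of each other are single-linkage
clustered into polyA sites, sites are ordered from most gene-proximal to most
gene-distal (index ``m`` from 0 to ``n - 1``), and each multi-site gene is
classified by where its sites fall: all in one shared terminal exon (tandem
UTR, "TUTR"), all in distinct terminal exons (alternative last exons, "ALE"),
or neither ("mixed", only possible for n > 2).
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import gffutils

logger = logging.getLogger(__name__)

#: single-linkage window (nt) for grouping transcript 3' ends into polyA sites
POLYA_GROUPING_WINDOW = 25
#: length (nt) of the 3'-terminal window quantified in 3pseq mode
THREE_PRIME_SEQ_WINDOW = 300

#: annotation tag marking transcripts with ill-defined 3' ends (GENCODE)
ILL_DEFINED_END_TAG = "mRNA_end_NF"
PROTEIN_CODING = "protein_coding"

Mode = Literal["rnaseq", "3pseq"]
ApaClass = Literal["TUTR", "ALE", "mixed"]


class AnnotationError(ValueError):
    """Structured failure while parsing or interpreting a GFF3 annotation."""


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript: ordered exons plus the attributes APA filtering needs.

    Exons are 1-based inclusive genomic intervals sorted by ascending
    coordinate regardless of strand, as in GFF3.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    tags: frozenset[str] = frozenset()
    biotype: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id}: no exons")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exons overlap or are "
                    f"unsorted: ({s1},{e1}) then ({s2},{e2})"
                )

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def exons_transcription_order(self) -> tuple[tuple[int, int], ...]:
        return self.exons if self.strand == "+" else self.exons[::-1]


@dataclass(frozen=True)
class TerminalFragment:
    """The quantification unit for one transcript.

    ``fragment_exons`` are stored in transcription order; each interval is
    1-based inclusive. ``three_prime_end`` is the genomic coordinate of the
    annotated transcript 3' end (last base in transcription direction).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    fragment_exons: tuple[tuple[int, int], ...]
    three_prime_end: int
    fragment_length: int

    def __post_init__(self) -> None:
        last = self.fragment_exons[-1]
        expected = last[1] if self.strand == "+" else last[0]
        if self.three_prime_end != expected:
            raise AnnotationError(
                f"fragment {self.transcript_id}: 3' end {self.three_prime_end} "
                f"does not terminate its last exon {last}"
            )
        if self.fragment_length <= 0:
            raise AnnotationError(
                f"fragment {self.transcript_id}: non-positive length"
            )

    @property
    def terminal_exon(self) -> tuple[int, int]:
        """The exon interval containing the transcript 3' end."""
        return self.fragment_exons[-1]


@dataclass(frozen=True)
class PolyASite:
    """A cluster of transcript 3' ends treated as one polyadenylation site."""

    gene_id: str
    m: int
    member_fragments: tuple[TerminalFragment, ...]
    representative_end: int
    terminal_exon_key: tuple[int, int]


@dataclass(frozen=True)
class GeneAPAModel:
    """A gene's ordered polyA sites plus its structural class."""

    gene_id: str
    sites: tuple[PolyASite, ...]
    apa_class: ApaClass | None

    @property
    def n(self) -> int:
        return len(self.sites)


# ---------------------------------------------------------------------------
# GFF3 loading
# ---------------------------------------------------------------------------


def _file_md5(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _open_gff_db(gff3_path: Path) -> gffutils.FeatureDB:
    """Index the GFF3 with gffutils, caching the database next to the file.

    The cache is keyed on the file's checksum so a modified or truncated
    annotation never silently reuses a stale index.
    """
    db_path = Path(str(gff3_path) + ".db")
    stamp_path = Path(str(db_path) + ".md5")
    checksum = _file_md5(gff3_path)
    if db_path.exists() and stamp_path.exists():
        if stamp_path.read_text().strip() == checksum:
            return gffutils.FeatureDB(str(db_path))
        db_path.unlink()
        stamp_path.unlink()
    try:
        db = gffutils.create_db(
            str(gff3_path),
            dbfn=str(db_path),
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            sort_attribute_values=True,
        )
    except Exception as exc:  # gffutils raises bare sqlite/ValueError variants
        raise AnnotationError(f"failed to index {gff3_path}: {exc}") from exc
    stamp_path.write_text(checksum + "\n")
    return db


def _attr(feature: gffutils.Feature, *names: str) -> list[str]:
    for name in names:
        if name in feature.attributes:
            return list(feature.attributes[name])
    return []


def load_annotation(gff3_path: str | os.PathLike) -> dict[str, list[TranscriptModel]]:
    """Parse a GFF3 annotation into transcripts grouped by gene.

    Expects a gene -> transcript/mRNA -> exon hierarchy with ``ID``/``Parent``
    attributes (GENCODE dialect). Annotation ``tag`` values and the transcript
    biotype (``transcript_type`` or ``biotype``) are captured per transcript.

    Returns a mapping gene_id -> list of :class:`TranscriptModel`.

    Raises
    ------
    AnnotationError
        If an exon's Parent transcript is absent from the file (the error
        names the offending exon), or the file cannot be indexed.
    """
    gff3_path = Path(gff3_path)
    if not gff3_path.exists():
        raise AnnotationError(f"annotation not found: {gff3_path}")
    db = _open_gff_db(gff3_path)

    transcript_ids = set()
    tx_features: dict[str, gffutils.Feature] = {}
    for ftype in ("transcript", "mRNA"):
        for tx in db.features_of_type(ftype):
            tx_features[tx.id] = tx
            transcript_ids.add(tx.id)

    exons_by_tx: dict[str, list[tuple[int, int]]] = {}
    for exon in db.features_of_type("exon"):
        parents = _attr(exon, "Parent")
        if not parents or all(p not in transcript_ids for p in parents):
            exon_id = _attr(exon, "ID") or [exon.id]
            raise AnnotationError(
                f"exon {exon_id[0]} has no parent transcript in the annotation"
            )
        for parent in parents:
            if parent in transcript_ids:
                exons_by_tx.setdefault(parent, []).append((exon.start, exon.end))

    genes: dict[str, list[TranscriptModel]] = {}
    for tx_id, tx in tx_features.items():
        if tx.strand not in ("+", "-"):
            logger.warning("transcript %s has undefined strand; skipped", tx_id)
            continue
        exons = sorted(exons_by_tx.get(tx_id, []))
        if not exons:
            logger.warning("transcript %s has no exons; skipped", tx_id)
            continue
        gene_ids = _attr(tx, "Parent", "gene_id")
        if not gene_ids:
            raise AnnotationError(f"transcript {tx_id} has no Parent gene")
        biotype = (_attr(tx, "transcript_type", "transcript_biotype", "biotype") or [""])[0]
        model = TranscriptModel(
            transcript_id=tx_id,
            gene_id=gene_ids[0],
            chrom=tx.seqid,
            strand=tx.strand,
            exons=tuple(exons),
            tags=frozenset(_attr(tx, "tag")),
            biotype=biotype,
        )
        genes.setdefault(model.gene_id, []).append(model)

    # genes whose transcripts disagree on strand or chromosome are unusable
    for gene_id in list(genes):
        txs = genes[gene_id]
        if len({t.strand for t in txs}) > 1 or len({t.chrom for t in txs}) > 1:
            logger.warning(
                "gene %s has strand- or chromosome-inconsistent transcripts; dropped",
                gene_id,
            )
            del genes[gene_id]
    return genes


def filter_transcripts(
    genes: Mapping[str, Sequence[TranscriptModel]],
    require_protein_coding: bool = False,
) -> dict[str, list[TranscriptModel]]:
    """Remove transcripts with ill-defined 3' ends (tag ``mRNA_end_NF``).

    With ``require_protein_coding`` set, transcripts whose biotype is not
    ``protein_coding`` are also removed (immature transcripts are enriched in
    non-coding biotypes). Genes left with no transcripts are dropped.
    """
    out: dict[str, list[TranscriptModel]] = {}
    for gene_id, txs in genes.items():
        kept = [t for t in txs if ILL_DEFINED_END_TAG not in t.tags]
        if require_protein_coding:
            kept = [t for t in kept if t.biotype == PROTEIN_CODING]
        if kept:
            out[gene_id] = list(kept)
    return out


# ---------------------------------------------------------------------------
# Terminal fragments
# ---------------------------------------------------------------------------


def make_terminal_fragment(
    transcript: TranscriptModel, mode: Mode = "rnaseq"
) -> TerminalFragment:
    """Build the quantification unit for one transcript.

    rnaseq mode: the last two exons in transcription order (a single-exon
    transcript yields the whole transcript). 3pseq mode: the 3'-terminal
    300 nt of the spliced transcript (the whole transcript if shorter),
    matching the footprint of oligo-dT-anchored 3'-end reads.
    """
    tx_exons = transcript.exons_transcription_order
    if mode == "rnaseq":
        frag = tx_exons[-2:]
    elif mode == "3pseq":
        frag = _trailing_window(tx_exons, transcript.strand, THREE_PRIME_SEQ_WINDOW)
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'rnaseq' or '3pseq'")
    three_prime = frag[-1][1] if transcript.strand == "+" else frag[-1][0]
    return TerminalFragment(
        transcript_id=transcript.transcript_id,
        gene_id=transcript.gene_id,
        chrom=transcript.chrom,
        strand=transcript.strand,
        fragment_exons=tuple(frag),
        three_prime_end=three_prime,
        fragment_length=sum(e - s + 1 for s, e in frag),
    )


def _trailing_window(
    tx_exons: Sequence[tuple[int, int]], strand: str, window: int
) -> list[tuple[int, int]]:
    """Genomic intervals covering the last ``window`` spliced nt of a transcript."""
    remaining = window
    out: list[tuple[int, int]] = []
    for start, end in reversed(tx_exons):  # walk 3' -> 5'
        length = end - start + 1
        if length >= remaining:
            if strand == "+":
                out.append((end - remaining + 1, end))
            else:
                out.append((start, start + remaining - 1))
            remaining = 0
            break
        out.append((start, end))
        remaining -= length
    return out[::-1]


# ---------------------------------------------------------------------------
# PolyA-site grouping and classification
# ---------------------------------------------------------------------------


def group_polya_sites(
    fragments: Sequence[TerminalFragment], window: int = POLYA_GROUPING_WINDOW
) -> list[PolyASite]:
    """Single-linkage cluster fragment 3' ends into ordered polyA sites.

    Ends are sorted by genomic coordinate and chained: consecutive ends no
    more than ``window`` nt apart join the same cluster (so transitively a
    cluster can span more than ``window`` nt). Sites are then ordered in
    transcription direction and indexed ``m = 0 .. n-1`` from proximal to
    distal. The representative end of each site is its most distal member
    end; the site's terminal exon is the exon containing that end.
    """
    if not fragments:
        return []
    gene_ids = {f.gene_id for f in fragments}
    strands = {f.strand for f in fragments}
    if len(gene_ids) > 1 or len(strands) > 1:
        raise AnnotationError(
            f"fragments span multiple genes ({gene_ids}) or strands ({strands})"
        )
    strand = fragments[0].strand

    by_end = sorted(fragments, key=lambda f: f.three_prime_end)
    clusters: list[list[TerminalFragment]] = [[by_end[0]]]
    for frag in by_end[1:]:
        if frag.three_prime_end - clusters[-1][-1].three_prime_end <= window:
            clusters[-1].append(frag)
        else:
            clusters.append([frag])

    if strand == "-":  # transcription order is descending coordinate
        clusters = clusters[::-1]

    sites = []
    for m, members in enumerate(clusters):
        ends = [f.three_prime_end for f in members]
        rep = max(ends) if strand == "+" else min(ends)
        rep_frag = next(f for f in members if f.three_prime_end == rep)
        sites.append(
            PolyASite(
                gene_id=fragments[0].gene_id,
                m=m,
                member_fragments=tuple(
                    sorted(members, key=lambda f: f.transcript_id)
                ),
                representative_end=rep,
                terminal_exon_key=rep_frag.terminal_exon,
            )
        )
    return sites


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def classify_apa(sites: Sequence[PolyASite]) -> ApaClass | None:
    """Classify a gene's APA structure from its polyA sites' terminal exons.

    Exon records from different isoforms are considered "the same exon" when
    their genomic intervals overlap. TUTR: every pair of sites shares a
    terminal exon. ALE: no pair does. Anything in between is mixed (requires
    n > 2). Genes with fewer than two sites have no defined class (None).
    """
    if len(sites) < 2:
        return None
    exons = [s.terminal_exon_key for s in sites]
    pairs = [
        _overlaps(exons[i], exons[j])
        for i in range(len(exons))
        for j in range(i + 1, len(exons))
    ]
    if all(pairs):
        return "TUTR"
    if not any(pairs):
        return "ALE"
    return "mixed"


def build_gene_models(
    genes: Mapping[str, Sequence[TranscriptModel]],
    mode: Mode = "rnaseq",
    window: int = POLYA_GROUPING_WINDOW,
) -> dict[str, GeneAPAModel]:
    """Terminal fragments -> grouped, ordered polyA sites -> classified genes."""
    models = {}
    for gene_id, txs in genes.items():
        fragments = [make_terminal_fragment(t, mode=mode) for t in txs]
        sites = group_polya_sites(fragments, window=window)
        models[gene_id] = GeneAPAModel(
            gene_id=gene_id,
            sites=tuple(sites),
            apa_class=classify_apa(sites),
        )
    return models


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def write_terminal_fragment_fasta(
    fragments: Iterable[TerminalFragment],
    genome_fasta: str | os.PathLike,
    out_fasta: str | os.PathLike,
) -> int:
    """Write spliced terminal-fragment sequences for external quantification.

    Minus-strand fragments are reverse-complemented; the record header is the
    transcript id. Returns the number of records written.
    """
    from Bio.Seq import Seq
    from pyfaidx import Fasta

    genome = Fasta(str(genome_fasta))
    n = 0
    with open(out_fasta, "w") as out:
        for frag in fragments:
            if frag.chrom not in genome:
                raise AnnotationError(
                    f"chromosome {frag.chrom!r} (fragment {frag.transcript_id}) "
                    f"is absent from {genome_fasta}"
                )
            genomic_order = sorted(frag.fragment_exons)
            seq = "".join(
                str(genome[frag.chrom][s - 1 : e]) for s, e in genomic_order
            )
            if frag.strand == "-":
                seq = str(Seq(seq).reverse_complement())
            out.write(f">{frag.transcript_id}\n{seq}\n")
            n += 1
    return n


def write_site_table(
    models: Mapping[str, GeneAPAModel], out_tsv: str | os.PathLike
) -> None:
    """Write the per-site TSV: gene, site index m, n, representative end, class."""
    with open(out_tsv, "w") as out:
        out.write(
            "gene_id\tsite_index\tn_sites\trepresentative_end\tapa_class\ttranscript_ids\n"
        )
        for gene_id in sorted(models):
            model = models[gene_id]
            for site in model.sites:
                members = ",".join(f.transcript_id for f in site.member_fragments)
                out.write(
                    f"{gene_id}\t{site.m}\t{model.n}\t{site.representative_end}\t"
                    f"{model.apa_class or 'NA'}\t{members}\n"
                )
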