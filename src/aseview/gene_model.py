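"""Gene structural scaffold: transcripts, exons, meta-exons and overlaps.

All internal coordinates are 0-based half-open; GTF input/output converts
at the boundary (GTF is 1-based inclusive).  A splice junction is
identified by its intron as ``(chrom, donor_end, acceptor_start)`` where
``donor_end`` is the half-open end of the upstream exon and
``acceptor_start`` the start of the downstream exon, so the intron spans
``[donor_end, acceptor_start)``.  Note the "donor"/"acceptor" field names
follow the genomic-left/right convention of a plus-strand gene; for minus
strand genes the biological donor site is at ``acceptor_start``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from intervaltree import IntervalTree


class AnnotationError(ValueError):
    """Raised for malformed or unusable annotation input."""


class GeneLookupError(KeyError):
    """Raised when a requested gene id is absent from an annotation."""


@dataclass(frozen=True)
class Exon:
    """One exon in internal 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    transcript_ids: frozenset = field(default_factory=frozenset, compare=False)

    def __post_init__(self):
        if self.start >= self.end:
            raise AnnotationError(
                f"exon start must precede end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Transcript:
    """An ordered, non-overlapping chain of exons on one strand."""

    id: str
    chrom: str
    strand: str
    exons: list[Exon]
    is_incomplete: bool = False

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise AnnotationError(
                f"transcript {self.id}: unstranded annotations are rejected "
                "(sense/antisense overlap classes require a strand)"
            )
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"transcript {self.id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def introns(self) -> list[tuple[int, int]]:
        """(donor_end, acceptor_start) for each consecutive exon pair."""
        return [(a.end, b.start) for a, b in zip(self.exons, self.exons[1:])]


@dataclass
class MetaExon:
    """Union interval of a maximal set of transitively overlapping exons.

    Spans from the minimum start to the maximum end of its members.
    """

    chrom: str
    start: int
    end: int
    member_exons: tuple[Exon, ...] = ()
    highlight: bool = False

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ExonGroup:
    """A meta-exon-level testing unit; ``positions`` is the base interval
    whose per-base coverage ratios enter the ratio test."""

    meta_exon: MetaExon
    positions: tuple[int, int]


@dataclass(frozen=True)
class OverlapAnnotation:
    """A transcript of another gene intersecting the query gene span."""

    other_transcript_id: str
    orientation: str  # sense | antisense
    overlap_kind: str  # exonic | non_exonic
    interval: tuple[int, int]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript]

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise AnnotationError(
                f"gene {self.gene_id}: unstranded annotations are rejected"
            )

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end

    @property
    def exons(self) -> list[Exon]:
        return [e for t in self.transcripts for e in t.exons]

    @property
    def introns(self) -> set[tuple[int, int]]:
        """All annotated introns, as (donor_end, acceptor_start)."""
        return {i for t in self.transcripts for i in t.introns}

    def transcript(self, transcript_id: str) -> Transcript:
        for t in self.transcripts:
            if t.id == transcript_id:
                return t
        raise GeneLookupError(transcript_id)


# ---------------------------------------------------------------------------
# GTF I/O


def _prescan_gtf(path: Path) -> None:
    """Cheap structural validation so errors can name the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{fields[3]!r}/{fields[4]!r}"
                ) from None
            if start < 1 or end < start:
                raise AnnotationError(
                    f"{path}:{lineno}: invalid coordinate range {start}-{end}"
                )


def parse_gtf_all(path: str | Path) -> dict[str, GeneModel]:
    """Parse a GTF file into gene models keyed by gene id.

    Coordinates are converted from GTF 1-based inclusive to internal
    0-based half-open.  Only ``exon`` features are used; ``gene_id`` and
    ``transcript_id`` attributes are required (Ensembl/GENCODE dialect).
    """
    path = Path(path)
    _prescan_gtf(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    # (gene_id, transcript_id) -> accumulated exon records
    per_tx: dict[tuple[str, str], dict] = {}
    for f in db.features_of_type("exon"):
        try:
            gene_id = f.attributes["gene_id"][0]
            tx_id = f.attributes["transcript_id"][0]
        except KeyError as exc:
            raise AnnotationError(
                f"{path}: exon at {f.seqid}:{f.start}-{f.end} lacks "
                f"required attribute {exc}"
            ) from None
        rec = per_tx.setdefault(
            (gene_id, tx_id),
            {"chrom": f.seqid, "strand": f.strand, "exons": []},
        )
        rec["exons"].append((f.start - 1, f.end))  # to 0-based half-open
    genes: dict[str, GeneModel] = {}
    for (gene_id, tx_id), rec in per_tx.items():
        exons = [
            Exon(rec["chrom"], s, e, transcript_ids=frozenset({tx_id}))
            for s, e in sorted(rec["exons"])
        ]
        tx = Transcript(tx_id, rec["chrom"], rec["strand"], exons)
        if gene_id not in genes:
            genes[gene_id] = GeneModel(gene_id, rec["chrom"], rec["strand"], [tx])
        else:
            genes[gene_id].transcripts.append(tx)
    return genes


def parse_gtf(path: str | Path, gene_id: str) -> GeneModel:
    """Parse one gene from a GTF file; raises GeneLookupError if absent."""
    genes = parse_gtf_all(path)
    if gene_id not in genes:
        raise GeneLookupError(
            f"gene {gene_id!r} not found in {path} "
            f"(available: {sorted(genes)[:10]})"
        )
    return genes[gene_id]


def write_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as Ensembl-dialect GTF (1-based inclusive)."""
    lines = []
    for gene in genes:
        attrs = f'gene_id "{gene.gene_id}";'
        lines.append(
            "\t".join(
                [gene.chrom, "aseview", "gene", str(gene.start + 1),
                 str(gene.end), ".", gene.strand, ".", attrs]
            )
        )
        for tx in gene.transcripts:
            tattrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx.id}";'
            lines.append(
                "\t".join(
                    [gene.chrom, "aseview", "transcript", str(tx.start + 1),
                     str(tx.end), ".", tx.strand, ".", tattrs]
                )
            )
            for exon in tx.exons:
                lines.append(
                    "\t".join(
                        [gene.chrom, "aseview", "exon", str(exon.start + 1),
                         str(exon.end), ".", tx.strand, ".", tattrs]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Structure derivation


def build_meta_exons(
    gene: GeneModel | Sequence[Transcript],
) -> list[MetaExon]:
    """Merge transitively overlapping exons into disjoint meta-exons.

    Book-ended exons ([0,100) and [100,200)) share zero bases and are NOT
    merged.  Output is sorted and pairwise disjoint; every input exon is a
    member of exactly one meta-exon.
    """
    transcripts = gene.transcripts if isinstance(gene, GeneModel) else list(gene)
    exons = sorted(
        (e for t in transcripts for e in t.exons), key=lambda e: (e.start, e.end)
    )
    if not exons:
        return []
    metas: list[MetaExon] = []
    chrom = exons[0].chrom
    cur_start, cur_end = exons[0].start, exons[0].end
    members = [exons[0]]
    for exon in exons[1:]:
        if exon.start < cur_end:  # strict: book-ended exons stay apart
            cur_end = max(cur_end, exon.end)
            members.append(exon)
        else:
            metas.append(MetaExon(chrom, cur_start, cur_end, tuple(members)))
            cur_start, cur_end = exon.start, exon.end
            members = [exon]
    metas.append(MetaExon(chrom, cur_start, cur_end, tuple(members)))
    return metas


def annotate_overlaps(
    gene: GeneModel, all_genes: Iterable[GeneModel]
) -> list[OverlapAnnotation]:
    """Classify transcripts of other genes intersecting the query span.

    orientation is sense/antisense relative to the query gene's strand;
    overlap_kind is ``exonic`` iff any exon of the other transcript shares
    bases with any exon of the query gene, else ``non_exonic``.
    """
    gstart, gend = gene.span
    query_exons = IntervalTree()
    for e in gene.exons:
        query_exons[e.start:e.end] = e
    out: list[OverlapAnnotation] = []
    for other in all_genes:
        if other.gene_id == gene.gene_id or other.chrom != gene.chrom:
            continue
        for tx in other.transcripts:
            if tx.end <= gstart or tx.start >= gend:
                continue
            orientation = "sense" if tx.strand == gene.strand else "antisense"
            exonic = any(query_exons.overlap(e.start, e.end) for e in tx.exons)
            interval = (max(tx.start, gstart), min(tx.end, gend))
            out.append(
                OverlapAnnotation(
                    tx.id,
                    orientation,
                    "exonic" if exonic else "non_exonic",
                    interval,
                )
            )
    out.sort(key=lambda o: (o.interval, o.other_transcript_id))
    return out


def make_incomplete_isoform(
    gene: GeneModel, junction, flank: int = 50
) -> Transcript:
    """Represent an unannotated junction as a reduced two-exon isoform.

    The upstream exon ends at the junction donor and the downstream exon
    starts at the acceptor; each stub has length ``flank``, clipped to the
    gene span.
    """
    gstart, gend = gene.span
    donor_end = junction.donor_end
    acceptor_start = junction.acceptor_start
    # the stubs need >=1 exonic base on each side of the intron
    if not (gstart < donor_end and acceptor_start < gend):
        raise AnnotationError(
            f"junction ({donor_end},{acceptor_start}) lies outside gene "
            f"span [{gstart},{gend})"
        )
    if flank <= 0:
        raise AnnotationError("flank must be positive")
    up = Exon(gene.chrom, max(gstart, donor_end - flank), donor_end)
    down = Exon(gene.chrom, acceptor_start, min(gend, acceptor_start + flank))
    tx_id = f"novel_{gene.chrom}_{donor_end}_{acceptor_start}"
    return Transcript(tx_id, gene.chrom, gene.strand, [up, down],
                      is_incomplete=True)
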