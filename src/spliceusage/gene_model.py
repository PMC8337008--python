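"""Partition gene annotations into splice-site-bounded segments.

A gene's transcripts define a set of exon start sites (3' acceptor splice
sites and transcription start sites) and exon end sites (5' donor splice
sites and transcription end sites).  Taken together these sites cut the
gene span into minimal, contiguous, non-overlapping *segments*: any
transcript either contains a segment completely or not at all.  Segments
are indexed 1..M in transcription direction (for minus-strand genes,
segment 1 is the genomically rightmost one).

The 5'-most start site (the gene TSS) and the 3'-most end site (the gene
TES) bound the first and last segment but carry no usage parameter; every
other distinct site becomes a typed internal boundary and maps onto one
entry of the usage parameter vectors p (start sites) and q (end sites),
so M = M_s + M_e + 1.

Coordinates are 0-based half-open internally (GTF input is 1-based
inclusive and converted on read; tables are converted back on output).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

START_SITE = "start_site"
END_SITE = "end_site"


@dataclass(frozen=True)
class TranscriptAnnotation:
    """Exon structure of one transcript.

    Exons are 0-based half-open genomic intervals, sorted in genomic
    order, strictly non-overlapping and non-adjacent (touching exons
    would collapse into one).
    """

    transcript_id: str
    gene_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    chrom: str = "."

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        for s, e in exons:
            if e <= s:
                raise ValueError(
                    f"transcript {self.transcript_id}: empty exon [{s}, {e})"
                )
        for (s1, e1), (s2, e2) in itertools.pairwise(exons):
            if s2 <= e1:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons [{s1},{e1}) and "
                    f"[{s2},{e2}) overlap, touch or are unsorted"
                )

    @property
    def span(self) -> tuple[int, int]:
        """Genomic TSS-to-TES interval (0-based half-open)."""
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class Segment:
    """One gene segment; ``index`` is 1-based in transcription order."""

    index: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Boundary:
    """Internal segment boundary.

    ``coord`` is the genomic cut point (0-based, i.e. the position between
    the base pairs flanking the boundary).  ``param_index`` is the 1-based
    index into p (start sites) or q (end sites); the gene's outermost
    TSS/TES are not represented as Boundary objects and carry no index.
    """

    coord: int
    kind: str
    param_index: int | None


@dataclass(frozen=True)
class GeneSegmentation:
    """Ordered segments X_1..X_M with typed internal boundaries."""

    gene_id: str
    chrom: str
    strand: str
    segments: tuple[Segment, ...]
    boundaries: tuple[Boundary, ...]

    @property
    def M(self) -> int:
        return len(self.segments)

    @property
    def M_s(self) -> int:
        return sum(1 for b in self.boundaries if b.kind == START_SITE)

    @property
    def M_e(self) -> int:
        return sum(1 for b in self.boundaries if b.kind == END_SITE)

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.array([s.length for s in self.segments], dtype=np.int64)

    @property
    def tss(self) -> int:
        """Genomic cut coordinate of the gene's 5'-most start site."""
        first = self.segments[0]
        return first.start if self.strand == "+" else first.end

    @property
    def tes(self) -> int:
        """Genomic cut coordinate of the gene's 3'-most end site."""
        last = self.segments[-1]
        return last.end if self.strand == "+" else last.start

    @property
    def genomic_span(self) -> tuple[int, int]:
        return (
            min(s.start for s in self.segments),
            max(s.end for s in self.segments),
        )

    @classmethod
    def from_lengths(
        cls,
        lengths,
        boundary_kinds,
        gene_id: str = "synthetic",
        chrom: str = ".",
        strand: str = "+",
        origin: int = 0,
    ) -> "GeneSegmentation":
        """Build a segmentation directly from segment lengths and boundary
        kinds (no transcripts needed); used by the simulator and tests."""
        lengths = [int(x) for x in lengths]
        kinds = list(boundary_kinds)
        if len(kinds) != len(lengths) - 1:
            raise ValueError("need exactly M-1 boundary kinds")
        if any(x < 1 for x in lengths):
            raise ValueError("segment lengths must be >= 1")
        if strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        cuts = origin + np.concatenate([[0], np.cumsum(lengths)])
        if strand == "-":
            # transcription runs right-to-left; segment 1 is rightmost
            total = cuts[-1] - origin
            cuts = origin + total - (cuts - origin)
        segments, boundaries = [], []
        n_s = n_e = 0
        for i, length in enumerate(lengths):
            a, b = int(cuts[i]), int(cuts[i + 1])
            segments.append(Segment(index=i + 1, start=min(a, b), end=max(a, b)))
            if i < len(kinds):
                if kinds[i] == START_SITE:
                    n_s += 1
                    idx = n_s
                elif kinds[i] == END_SITE:
                    n_e += 1
                    idx = n_e
                else:
                    raise ValueError(f"unknown boundary kind {kinds[i]!r}")
                boundaries.append(Boundary(coord=int(cuts[i + 1]), kind=kinds[i], param_index=idx))
        return cls(gene_id, chrom, strand, tuple(segments), tuple(boundaries))


def _tx_key(strand: str):
    """Sort key placing coordinates in transcription order."""
    return (lambda c: c) if strand == "+" else (lambda c: -c)


def build_segmentation(transcripts) -> GeneSegmentation:
    """Partition one gene into segments bounded by splice sites, TSS and TES.

    All transcripts must share gene_id, chromosome and strand and must form
    a single overlapping locus (use :func:`segment_gene` to split disjoint
    loci sharing a gene_id).  Alternative transcription starts/ends other
    than the gene's outermost ones are modeled as ordinary start/end sites.
    """
    transcripts = list(transcripts)
    if not transcripts:
        raise ValueError("build_segmentation requires at least one transcript")
    gene_ids = {t.gene_id for t in transcripts}
    strands = {t.strand for t in transcripts}
    chroms = {t.chrom for t in transcripts}
    if len(gene_ids) > 1:
        raise ValueError(f"transcripts from multiple genes: {sorted(gene_ids)}")
    if len(strands) > 1:
        raise ValueError(f"gene {gene_ids.pop()} has transcripts on mixed strands")
    if len(chroms) > 1:
        raise ValueError(f"gene {gene_ids.pop()} spans multiple chromosomes")
    gene_id, strand, chrom = gene_ids.pop(), strands.pop(), chroms.pop()

    for cluster in _overlap_clusters(transcripts):
        if len(cluster) != len(transcripts):
            raise ValueError(
                f"gene {gene_id}: transcripts form disjoint loci; "
                "split them first (see segment_gene)"
            )
        break

    start_cuts, end_cuts = set(), set()
    for t in transcripts:
        for s, e in t.exons:
            if strand == "+":
                start_cuts.add(s)
                end_cuts.add(e)
            else:
                start_cuts.add(e)
                end_cuts.add(s)
    key = _tx_key(strand)
    tss = min(start_cuts, key=key)
    tes = max(end_cuts, key=key)
    internal_starts = start_cuts - {tss}
    internal_ends = end_cuts - {tes}
    clash = internal_starts & internal_ends
    if clash:
        raise ValueError(
            f"gene {gene_id}: coordinate(s) {sorted(clash)} are both an exon "
            "start and an exon end; zero-length segments are not supported"
        )

    cuts = sorted(internal_starts | internal_ends, key=key)
    all_cuts = [tss] + cuts + [tes]
    segments, boundaries = [], []
    n_s = n_e = 0
    for i, (a, b) in enumerate(itertools.pairwise(all_cuts)):
        segments.append(Segment(index=i + 1, start=min(a, b), end=max(a, b)))
    for c in cuts:
        if c in internal_starts:
            n_s += 1
            boundaries.append(Boundary(coord=c, kind=START_SITE, param_index=n_s))
        else:
            n_e += 1
            boundaries.append(Boundary(coord=c, kind=END_SITE, param_index=n_e))
    return GeneSegmentation(gene_id, chrom, strand, tuple(segments), tuple(boundaries))


def _overlap_clusters(transcripts):
    """Group transcripts whose TSS-TES spans overlap transitively."""
    order = sorted(transcripts, key=lambda t: t.span)
    clusters, current, cur_end = [], [], None
    for t in order:
        s, e = t.span
        if current and s < cur_end:
            current.append(t)
            cur_end = max(cur_end, e)
        else:
            if current:
                clusters.append(current)
            current, cur_end = [t], e
    if current:
        clusters.append(current)
    return clusters


def segment_gene(transcripts) -> list[GeneSegmentation]:
    """Segment a gene, splitting disjoint loci under one gene_id.

    Returns one GeneSegmentation per overlapping transcript cluster; when
    a gene splits, cluster gene_ids are suffixed ``.1``, ``.2``, ... in
    genomic order.
    """
    clusters = _overlap_clusters(list(transcripts))
    if len(clusters) == 1:
        return [build_segmentation(clusters[0])]
    out = []
    for i, cluster in enumerate(clusters, start=1):
        renamed = [
            TranscriptAnnotation(
                t.transcript_id, f"{t.gene_id}.{i}", t.strand, t.exons, t.chrom
            )
            for t in cluster
        ]
        out.append(build_segmentation(renamed))
    return out


def boundary_order_check(seg: GeneSegmentation) -> list[str]:
    """Validate a segmentation; returns a list of violation messages
    (empty iff the segmentation invariants hold)."""
    violations = []
    M = seg.M
    if len(seg.boundaries) != M - 1:
        violations.append(
            f"expected {M - 1} internal boundaries, found {len(seg.boundaries)}"
        )
    if seg.M_s + seg.M_e + 1 != M:
        violations.append(
            f"M_s + M_e + 1 = {seg.M_s + seg.M_e + 1} does not equal M = {M}"
        )
    for i, s in enumerate(seg.segments):
        if s.index != i + 1:
            violations.append(f"segment at position {i} has index {s.index}")
        if s.length < 1:
            violations.append(f"segment {s.index} has non-positive length")
    for i, (a, b) in enumerate(itertools.pairwise(seg.segments)):
        if seg.strand == "+":
            contiguous = a.end == b.start
        else:
            contiguous = a.start == b.end
        if not contiguous:
            violations.append(f"gap or overlap between segments {a.index} and {b.index}")
        if i < len(seg.boundaries):
            expected = a.end if seg.strand == "+" else a.start
            if seg.boundaries[i].coord != expected:
                violations.append(
                    f"boundary {i + 1} coordinate {seg.boundaries[i].coord} "
                    f"does not sit between segments {a.index} and {b.index}"
                )
    for kind, label in ((START_SITE, "start"), (END_SITE, "end")):
        idx = [b.param_index for b in seg.boundaries if b.kind == kind]
        if idx != list(range(1, len(idx) + 1)):
            violations.append(f"{label}-site parameter indices {idx} are not 1..{len(idx)}")
    for b in seg.boundaries:
        if b.kind not in (START_SITE, END_SITE):
            violations.append(f"boundary at {b.coord} has unknown kind {b.kind!r}")
    return violations


# ---------------------------------------------------------------------------
# annotation input / segmentation output


def read_gtf(path) -> dict[str, list[TranscriptAnnotation]]:
    """Read exon features from a GTF/GFF2 file.

    Requires exon features carrying gene_id and transcript_id attributes;
    all other feature types are ignored.  Returns transcripts grouped by
    gene_id.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_transcripts=True,
        disable_infer_genes=True,
    )
    exons: dict[tuple[str, str], dict] = {}
    for f in db.features_of_type("exon"):
        gene_id = f.attributes["gene_id"][0]
        tx_id = f.attributes["transcript_id"][0]
        rec = exons.setdefault(
            (gene_id, tx_id),
            {"strand": f.strand, "chrom": f.seqid, "intervals": []},
        )
        # GTF is 1-based inclusive; convert to 0-based half-open
        rec["intervals"].append((f.start - 1, f.end))
    genes: dict[str, list[TranscriptAnnotation]] = {}
    for (gene_id, tx_id), rec in exons.items():
        tx = TranscriptAnnotation(
            transcript_id=tx_id,
            gene_id=gene_id,
            strand=rec["strand"],
            exons=tuple(sorted(rec["intervals"])),
            chrom=rec["chrom"],
        )
        genes.setdefault(gene_id, []).append(tx)
    return genes


def write_gtf(path, transcripts, source: str = "spliceusage") -> None:
    """Write transcripts as GTF exon features (1-based inclusive)."""
    with open(path, "w") as fh:
        for t in transcripts:
            for s, e in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def segmentation_table(seg: GeneSegmentation) -> pd.DataFrame:
    """Segmentation as a table with 1-based inclusive genomic coordinates.

    ``left_boundary_*`` describes the boundary on the transcription-direction
    5' side of each segment (the gene TSS for segment 1).
    """
    rows = []
    for i, s in enumerate(seg.segments):
        if i == 0:
            kind, idx = "tss", None
        else:
            b = seg.boundaries[i - 1]
            kind, idx = b.kind, b.param_index
        rows.append(
            {
                "gene_id": seg.gene_id,
                "segment_index": s.index,
                "chrom": seg.chrom,
                "start": s.start + 1,
                "end": s.end,
                "strand": seg.strand,
                "left_boundary_kind": kind,
                "left_boundary_param_index": idx,
            }
        )
    return pd.DataFrame(rows)


def boundary_position(seg: GeneSegmentation, boundary: Boundary) -> int:
    """1-based genomic base position conventionally reported for a boundary:
    the first base of the downstream exonic segment for a start site
    (acceptor position), the last base of the upstream segment for an end
    site (donor position)."""
    if boundary.kind == START_SITE:
        return boundary.coord + 1 if seg.strand == "+" else boundary.coord
    return boundary.coord if seg.strand == "+" else boundary.coord + 1
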