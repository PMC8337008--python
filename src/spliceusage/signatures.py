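"""Read signatures and signature counts.

The *signature* of a mapped read is the ordered set of gene segments its
aligned blocks overlap, in transcription order.  Reads with equal
signatures are interchangeable for inference, so the sufficient
statistics of a gene are its signature counts c_1..c_J together with the
read length L.

Reads whose junctions do not coincide with modeled segment boundaries
(novel splice sites), or that overhang the gene span, are discarded and
tallied; paired-end mates are treated as independent single-end reads.
"""

from __future__ import annotations

import collections
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gene_model import GeneSegmentation

logger = logging.getLogger(__name__)

#: A signature is a strictly increasing tuple of 1-based segment indices.
Signature = tuple[int, ...]


def validate_signature(sig: Signature, seg: GeneSegmentation) -> Signature:
    sig = tuple(int(i) for i in sig)
    if not sig:
        raise ValueError("signature must be non-empty")
    if any(b <= a for a, b in zip(sig, sig[1:])):
        raise ValueError(f"signature {sig} is not strictly increasing")
    if sig[0] < 1 or sig[-1] > seg.M:
        raise ValueError(f"signature {sig} outside segments 1..{seg.M}")
    return sig


@dataclass
class SignatureCounts:
    """Signature counts for one gene: the sufficient statistics.

    ``entries`` maps signatures to counts; counts may be fractional
    (e.g. expected counts used in testing).  ``discarded`` tallies reads
    rejected during counting.
    """

    gene_id: str
    entries: dict[Signature, float]
    read_length: int
    discarded: int = 0

    def __post_init__(self):
        if self.read_length < 1:
            raise ValueError("read length must be >= 1")
        self.entries = {tuple(int(i) for i in k): float(v) for k, v in self.entries.items()}
        if any(v < 0 for v in self.entries.values()):
            raise ValueError("signature counts must be non-negative")

    @property
    def N(self) -> float:
        total = sum(self.entries.values())
        return int(total) if float(total).is_integer() else total

    @property
    def J(self) -> int:
        return len(self.entries)

    def sorted_items(self):
        """Entries in a deterministic (lexicographic) order."""
        return sorted(self.entries.items())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": self.gene_id, "signature": "-".join(map(str, sig)), "count": c}
            for sig, c in self.sorted_items()
        ]
        return pd.DataFrame(rows, columns=["gene_id", "signature", "count"])

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# read_length={self.read_length}\n")
            fh.write(f"# total={self.N}\n")
            fh.write(f"# discarded={self.discarded}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> dict[str, "SignatureCounts"]:
        """Read a signature-count TSV; returns counts per gene_id."""
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
        table = pd.read_csv(path, sep="\t", comment="#")
        if "read_length" not in meta:
            raise ValueError(f"{path}: missing '# read_length=' header")
        L = int(meta["read_length"])
        discarded = int(meta.get("discarded", 0))
        out = {}
        for gene_id, sub in table.groupby("gene_id", sort=True):
            entries = {
                tuple(int(x) for x in s.split("-")): float(c)
                for s, c in zip(sub["signature"], sub["count"])
            }
            out[str(gene_id)] = cls(str(gene_id), entries, L, discarded=discarded)
        return out


def start_position_count(sig: Signature, seg: GeneSegmentation, L: int) -> int:
    """Number of read start positions producing this signature.

    Counted within any transcript containing exactly the signature's
    segments over the signature's span (segments outside the span are
    irrelevant): the read must start in the first segment of the
    signature and end inside its last segment.  Returns 0 when the
    geometry makes the signature impossible for reads of length L.
    """
    if L < 1:
        raise ValueError("read length L must be >= 1")
    sig = validate_signature(sig, seg)
    lengths = seg.segment_lengths
    lens = lengths[[i - 1 for i in sig]]
    if len(sig) == 1:
        return max(int(lens[0]) - L + 1, 0)
    first = int(lens[0])
    span = int(lens.sum())
    before_last = span - int(lens[-1])
    lo = max(0, before_last - L + 1)
    hi = min(first - 1, span - L)
    return max(hi - lo + 1, 0)


def signatures_of_path(Z, seg: GeneSegmentation) -> list[Signature]:
    """All signatures a transcript with states Z can emit (its maximal
    run of transcribed segments sliced into first/last pairs)."""
    ts = [i + 1 for i, z in enumerate(Z) if z]
    sigs = []
    for a in range(len(ts)):
        for b in range(a, len(ts)):
            sigs.append(tuple(ts[a : b + 1]))
    return sigs


# ---------------------------------------------------------------------------
# alignment -> signature


def signature_of_alignment(aligned_blocks, seg: GeneSegmentation) -> Signature | None:
    """Map a read's aligned blocks to its segment signature.

    ``aligned_blocks`` are the read's match blocks as 0-based half-open
    genomic intervals in genomic order (junction reads have more than one
    block).  Returns None — the read is to be discarded and tallied — when
    the read overhangs the gene span, overlaps no segment, or splices at
    a junction that is not a modeled segment boundary.  Blocks that
    overlap each other are rejected with an error.
    """
    blocks = [(int(s), int(e)) for s, e in aligned_blocks]
    if not blocks:
        return None
    for s, e in blocks:
        if e <= s:
            raise ValueError(f"empty aligned block [{s}, {e})")
    for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
        if s2 < e1:
            raise ValueError("aligned blocks overlap each other")
        if s2 == e1:
            raise ValueError("adjacent aligned blocks must be merged")

    lo, hi = seg.genomic_span
    if blocks[0][0] < lo or blocks[-1][1] > hi:
        return None  # overhangs the gene span

    # genomic-order segment bounds
    order = sorted(seg.segments, key=lambda s: s.start)
    starts = np.array([s.start for s in order])
    ends = np.array([s.end for s in order])
    cut_set = set(starts) | set(ends)

    genomic_idx: list[int] = []
    for k, (s, e) in enumerate(blocks):
        i0 = int(np.searchsorted(starts, s, side="right") - 1)
        i1 = int(np.searchsorted(ends, e, side="left"))
        genomic_idx.extend(range(i0, i1 + 1))
        # splice junction edges must land exactly on modeled boundaries
        if k > 0 and s not in cut_set:
            return None
        if k < len(blocks) - 1 and e not in cut_set:
            return None
    if seg.strand == "+":
        tx_idx = [order[i].index for i in genomic_idx]
    else:
        tx_idx = [order[i].index for i in reversed(genomic_idx)]
    if tx_idx != sorted(tx_idx) or len(set(tx_idx)) != len(tx_idx):
        return None
    return tuple(tx_idx)


def blocks_from_cigar(reference_start: int, cigartuples) -> list[tuple[int, int]]:
    """Aligned reference blocks from a CIGAR, splitting on N (intron)
    operations only; deletions extend the current block, soft clips and
    insertions are ignored."""
    blocks = []
    pos = reference_start
    block_start = None
    for op, length in cigartuples:
        if op in (0, 2, 7, 8):  # M, D, =, X consume reference
            if block_start is None:
                block_start = pos
            pos += length
        elif op == 3:  # N: splice junction
            if block_start is not None:
                blocks.append((block_start, pos))
                block_start = None
            pos += length
        # I, S, H, P do not consume reference
    if block_start is not None:
        blocks.append((block_start, pos))
    return blocks


def count_signatures(alignments, seg: GeneSegmentation, L: int) -> SignatureCounts:
    """Aggregate signature counts from a stream of block lists.

    ``alignments`` yields lists of 0-based half-open genomic intervals
    (one list per read).  Input order does not affect the result.
    """
    entries: dict[Signature, float] = collections.defaultdict(float)
    discarded = 0
    for blocks in alignments:
        sig = signature_of_alignment(blocks, seg)
        if sig is None:
            discarded += 1
        else:
            entries[sig] += 1
    return SignatureCounts(seg.gene_id, dict(entries), L, discarded=discarded)


def count_signatures_sam(
    path,
    seg: GeneSegmentation,
    read_length: int | None = None,
    strict_length: bool = False,
) -> SignatureCounts:
    """Count signatures from a coordinate-sorted SAM/BAM file.

    Only primary alignments on the gene's chromosome that overlap its
    span are used; each paired-end mate is an independent read.  If
    ``read_length`` is None the modal read length in the file is used as
    L; reads of any other length are skipped with a tally (or rejected
    when ``strict_length``).
    """
    import pysam

    lo, hi = seg.genomic_span

    def gene_reads(af):
        for r in af.fetch(until_eof=True):
            if r.is_unmapped or r.is_secondary or r.is_supplementary:
                continue
            if r.reference_name != seg.chrom:
                continue
            if r.reference_end <= lo or r.reference_start >= hi:
                continue
            yield r

    mode = "rb" if str(path).endswith(".bam") else "r"
    if read_length is None:
        with pysam.AlignmentFile(str(path), mode) as af:
            tally = collections.Counter(r.query_length for r in gene_reads(af))
        if not tally:
            raise ValueError(f"no reads overlap gene {seg.gene_id} in {path}")
        read_length = max(sorted(tally), key=tally.get)
        logger.info("gene %s: using modal read length L=%d", seg.gene_id, read_length)

    entries: dict[Signature, float] = collections.defaultdict(float)
    discarded = skipped_length = 0
    with pysam.AlignmentFile(str(path), mode) as af:
        for r in gene_reads(af):
            if r.query_length != read_length:
                if strict_length:
                    raise ValueError(
                        f"read {r.query_name} has length {r.query_length}, expected {read_length}"
                    )
                skipped_length += 1
                continue
            blocks = blocks_from_cigar(r.reference_start, r.cigartuples)
            sig = signature_of_alignment(blocks, seg)
            if sig is None:
                discarded += 1
            else:
                entries[sig] += 1
    if skipped_length:
        logger.warning(
            "gene %s: skipped %d reads with length != %d",
            seg.gene_id,
            skipped_length,
            read_length,
        )
    return SignatureCounts(
        seg.gene_id, dict(entries), read_length, discarded=discarded + skipped_length
    )
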