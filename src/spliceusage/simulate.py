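"""Generative simulator, ground truth and evaluation utilities.

The simulator follows the same generative story the estimator inverts:
a transcript (state path Z) is drawn with probability proportional to
l(Z) w(Z) — chain probability weighted by effective length — a read
start is drawn uniformly over the transcript's l(Z) start positions,
and the read's signature is the set of segments it covers.  Sampling is
exact via path enumeration (genes with M <= 20).

Ground-truth usage of a site is the relative contribution of transcripts
in which an exon starts (ends) exactly at the site, computed from the
transcript abundances; accuracy of an estimate against the truth is
scored with the Bernoulli Kullback-Leibler divergence per site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gene_model import (
    END_SITE,
    START_SITE,
    GeneSegmentation,
    TranscriptAnnotation,
    build_segmentation,
)
from .signatures import SignatureCounts
from .splicing_chain import ChainParameters, enumerate_paths

KL_EPS = 1e-6


@dataclass
class SimulationConfig:
    """Study conditions for one simulated gene."""

    seg: GeneSegmentation
    theta: ChainParameters
    n_reads: int = 100_000
    read_length: int = 100
    seed: int = 0

    def __post_init__(self):
        self.theta.check(self.seg)
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


@dataclass
class GroundTruth:
    """True per-transcript abundances and per-boundary usages.

    ``paths`` are the positive-probability transcripts (state vectors),
    ``abundances`` their chain probabilities renormalized over
    transcripts (paths with at least one transcribed segment).
    ``boundary_usage[i]`` is the fraction of transcript output in which
    an exon starts/ends exactly at internal boundary i+1;
    ``first_segment_usage`` is the fraction containing segment 1.
    """

    paths: np.ndarray
    abundances: np.ndarray
    boundary_usage: np.ndarray
    first_segment_usage: float
    theta: ChainParameters | None = None

    def to_frame(self, seg: GeneSegmentation) -> pd.DataFrame:
        rows = [
            {
                "boundary": 0,
                "kind": "tss",
                "param_index": None,
                "true_usage": self.first_segment_usage,
            }
        ]
        for i, b in enumerate(seg.boundaries):
            rows.append(
                {
                    "boundary": i + 1,
                    "kind": b.kind,
                    "param_index": b.param_index,
                    "true_usage": self.boundary_usage[i],
                }
            )
        return pd.DataFrame(rows)


def path_from_transcript(tx: TranscriptAnnotation, seg: GeneSegmentation) -> np.ndarray:
    """Binary state vector of a transcript on a segmentation.

    Each segment must be either fully exonic or fully absent in the
    transcript; anything else is inconsistent and rejected."""
    Z = np.zeros(seg.M, dtype=np.int64)
    for s in seg.segments:
        overlap = sum(
            max(0, min(s.end, e) - max(s.start, b)) for b, e in tx.exons
        )
        if overlap == s.length:
            Z[s.index - 1] = 1
        elif overlap != 0:
            raise ValueError(
                f"transcript {tx.transcript_id} covers segment {s.index} partially; "
                "inconsistent with the segmentation"
            )
    return Z


def true_usage_from_paths(paths, abundances, seg: GeneSegmentation) -> GroundTruth:
    """Ground-truth usage from transcripts given as state vectors.

    A transcript uses start site s (boundary i) iff an exon starts
    exactly there (Z_i = 0, Z_{i+1} = 1), and end site e iff an exon
    ends exactly there (Z_i = 1, Z_{i+1} = 0).  Structurally impossible
    paths (exon ending at a start site or starting at an end site, or no
    transcribed segment) are rejected.
    """
    paths = np.atleast_2d(np.asarray(paths, dtype=np.int64))
    w = np.asarray(abundances, dtype=float)
    if len(w) != len(paths):
        raise ValueError("one abundance per transcript required")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("abundances must be non-negative and not all zero")
    if paths.shape[1] != seg.M:
        raise ValueError(f"paths must have length M={seg.M}")
    for Z in paths:
        if Z.sum() == 0:
            raise ValueError("a transcript must contain at least one segment")
        for i, b in enumerate(seg.boundaries):
            if b.kind == START_SITE and Z[i] == 1 and Z[i + 1] == 0:
                raise ValueError(f"exon cannot end at start site (boundary {i + 1})")
            if b.kind == END_SITE and Z[i] == 0 and Z[i + 1] == 1:
                raise ValueError(f"exon cannot start at end site (boundary {i + 1})")
    w = w / w.sum()
    usage = np.zeros(seg.M - 1)
    for i, b in enumerate(seg.boundaries):
        if b.kind == START_SITE:
            used = (paths[:, i] == 0) & (paths[:, i + 1] == 1)
        else:
            used = (paths[:, i] == 1) & (paths[:, i + 1] == 0)
        usage[i] = float(w[used].sum())
    return GroundTruth(
        paths=paths,
        abundances=w,
        boundary_usage=usage,
        first_segment_usage=float(w[paths[:, 0] == 1].sum()),
    )


def true_usage_from_abundances(transcripts, abundances, seg: GeneSegmentation) -> GroundTruth:
    """Ground-truth usage from annotated transcripts and abundances."""
    paths = np.array([path_from_transcript(t, seg) for t in transcripts])
    return true_usage_from_paths(paths, abundances, seg)


def chain_ground_truth(theta: ChainParameters, seg: GeneSegmentation) -> GroundTruth:
    """Ground truth implied by chain parameters: all positive-probability
    paths with at least one transcribed segment, abundances w(Z)
    renormalized over them."""
    Z, w = enumerate_paths(theta, seg)
    keep = (w > 0) & (Z.sum(axis=1) > 0)
    gt = true_usage_from_paths(Z[keep], w[keep], seg)
    gt.theta = theta
    return gt


def _path_signature_table(Z, lengths, L):
    """Signatures of one path with their start-position counts.

    Returns (signatures, counts) where counts sum to the path's
    effective length whenever its transcribed length is >= L."""
    ts = np.flatnonzero(Z) + 1
    if len(ts) == 0:
        return [], np.array([], dtype=np.int64)
    lens = lengths[ts - 1]
    cum = np.concatenate([[0], np.cumsum(lens)])
    tl = int(cum[-1])
    n_start = max(tl - L + 1, 0)
    if n_start == 0:
        return [], np.array([], dtype=np.int64)
    starts = np.arange(n_start)
    first = np.searchsorted(cum, starts, side="right") - 1
    last = np.searchsorted(cum, starts + L - 1, side="right") - 1
    sigs, counts = [], []
    pairs, n = np.unique(np.column_stack([first, last]), axis=0, return_counts=True)
    for (a, b), k in zip(pairs, n):
        sigs.append(tuple(int(x) for x in ts[a : b + 1]))
        counts.append(int(k))
    return sigs, np.array(counts, dtype=np.int64)


def signature_distribution_exact(
    theta: ChainParameters, seg: GeneSegmentation, L: int
) -> dict:
    """Exact signature distribution P(g | Theta) by path enumeration."""
    Z, w = enumerate_paths(theta, seg)
    lengths = seg.segment_lengths
    probs: dict = {}
    total = 0.0
    for path, wz in zip(Z, w):
        if wz == 0.0:
            continue
        sigs, counts = _path_signature_table(path, lengths, L)
        for sig, k in zip(sigs, counts):
            probs[sig] = probs.get(sig, 0.0) + wz * k
        total += wz * counts.sum()
    if total == 0.0:
        raise ValueError("no positive-probability path can emit a read")
    return {sig: v / total for sig, v in probs.items()}


def simulate_reads(cfg: SimulationConfig, return_reads: bool = False):
    """Draw N read signatures from the generative model.

    Returns (SignatureCounts, GroundTruth); with ``return_reads`` also a
    list of (path, transcript_offset) pairs for SAM export.
    """
    seg, theta, L = cfg.seg, cfg.theta, cfg.read_length
    Z, w = enumerate_paths(theta, seg)
    lengths = seg.segment_lengths
    eff = np.maximum(Z @ lengths - L + 1, 0) * (w > 0)
    weight = eff * w
    total = weight.sum()
    if total == 0.0:
        raise ValueError(
            "no positive-probability transcript is long enough to emit a read"
        )
    rng = np.random.default_rng(cfg.seed)
    n_per_path = rng.multinomial(cfg.n_reads, weight / total)
    entries: dict = {}
    reads = []
    for path_idx in np.flatnonzero(n_per_path):
        path = Z[path_idx]
        n = int(n_per_path[path_idx])
        ts = np.flatnonzero(path) + 1
        cum = np.concatenate([[0], np.cumsum(lengths[ts - 1])])
        offsets = rng.integers(0, int(eff[path_idx]), size=n)
        first = np.searchsorted(cum, offsets, side="right") - 1
        last = np.searchsorted(cum, offsets + L - 1, side="right") - 1
        pairs, k = np.unique(np.column_stack([first, last]), axis=0, return_counts=True)
        for (a, b), c in zip(pairs, k):
            sig = tuple(int(x) for x in ts[a : b + 1])
            entries[sig] = entries.get(sig, 0.0) + float(c)
        if return_reads:
            reads.extend((path_idx, int(o)) for o in offsets)
    counts = SignatureCounts(seg.gene_id, entries, L)
    gt = chain_ground_truth(theta, seg)
    if return_reads:
        return counts, gt, (Z, reads)
    return counts, gt


def kl_score(true_usage: float, estimate: float, eps: float = KL_EPS) -> float:
    """Bernoulli Kullback-Leibler divergence KL(u || u_hat), natural log.

    The estimate is clamped to [eps, 1 - eps]; 0 log 0 = 0."""
    u = float(true_usage)
    if not 0.0 <= u <= 1.0:
        raise ValueError("true usage must lie in [0, 1]")
    v = float(np.clip(estimate, eps, 1.0 - eps))
    out = 0.0
    if u > 0.0:
        out += u * np.log(u / v)
    if u < 1.0:
        out += (1.0 - u) * np.log((1.0 - u) / (1.0 - v))
    return float(out)


def evaluate_usage(truth: GroundTruth, estimates, seg: GeneSegmentation) -> pd.DataFrame:
    """Per-boundary KL divergence of estimated vs true usage.

    Sites with true usage exactly 0 or 1 (constitutive or unused) are
    marked non-variable and excluded from summary statistics downstream.
    """
    estimates = np.asarray(estimates, dtype=float)
    rows = []
    for i, b in enumerate(seg.boundaries):
        u = truth.boundary_usage[i]
        rows.append(
            {
                "boundary": i + 1,
                "kind": b.kind,
                "true_usage": u,
                "estimate": estimates[i],
                "variable": 0.0 < u < 1.0,
                "kl": kl_score(u, estimates[i]) if np.isfinite(estimates[i]) else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixtures


def random_segmentation(
    rng,
    M_s: int | None = None,
    M_e: int | None = None,
    length_range: tuple[int, int] = (20, 200),
    gene_id: str = "synthetic",
    strand: str = "+",
    origin: int = 1000,
) -> GeneSegmentation:
    """Random synthetic segmentation: random boundary typing and segment
    lengths, for property tests and simulations."""
    rng = np.random.default_rng(rng)
    if M_s is None:
        M_s = int(rng.integers(1, 4))
    if M_e is None:
        M_e = int(rng.integers(1, 4))
    kinds = [START_SITE] * M_s + [END_SITE] * M_e
    rng.shuffle(kinds)
    M = M_s + M_e + 1
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=M)
    return GeneSegmentation.from_lengths(
        lengths, kinds, gene_id=gene_id, strand=strand, origin=origin
    )


def example_transcripts(chrom: str = "chr1") -> list[TranscriptAnnotation]:
    """Three-transcript worked-example gene used throughout docs/tests.

    Its five distinct exon start sites and four distinct exon end sites
    induce eight segments (M_s = 4 modeled start sites, M_e = 3 modeled
    end sites); the transcripts correspond to state paths
    (1,1,0,1,0,0,1,1), (0,1,0,0,0,1,1,1) and (1,1,0,0,0,0,1,0).  Segment
    lengths are typical of mammalian genes: exonic segments 150-300 bp,
    intronic segments 300-1000 bp.  Cut coordinates (0-based): 1000,
    1200, 1450, 2250, 2430, 3430, 3650, 3950, 4150.
    """
    gene = "EXAMPLE"
    return [
        TranscriptAnnotation(
            "t1", gene, "+", ((1000, 1450), (2250, 2430), (3650, 4150)), chrom
        ),
        TranscriptAnnotation("t2", gene, "+", ((1200, 1450), (3430, 4150)), chrom),
        TranscriptAnnotation("t3", gene, "+", ((1000, 1450), (3650, 3950)), chrom),
    ]


def example_segmentation() -> GeneSegmentation:
    """Segmentation of the worked-example gene (M=8, M_s=4, M_e=3)."""
    return build_segmentation(example_transcripts())


def write_read_sam(path, seg: GeneSegmentation, Z, reads, L: int) -> None:
    """Write simulated reads ((path_index, transcript_offset) pairs) as a
    SAM file on a toy reference sized to the gene span."""
    import pysam

    lengths = seg.segment_lengths
    ref_len = max(s.end for s in seg.segments) + 100
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": seg.chrom, "LN": int(ref_len)}],
    }
    records = []
    for n, (path_idx, offset) in enumerate(reads):
        ts = np.flatnonzero(Z[path_idx]) + 1
        cum = np.concatenate([[0], np.cumsum(lengths[ts - 1])])
        blocks = []
        for k, t in enumerate(ts):
            a = max(offset, cum[k])
            b = min(offset + L, cum[k + 1])
            if b <= a:
                continue
            s = seg.segments[t - 1]
            if seg.strand == "+":
                g0 = s.start + (a - cum[k])
                g1 = s.start + (b - cum[k])
            else:
                g1 = s.end - (a - cum[k])
                g0 = s.end - (b - cum[k])
            blocks.append((int(g0), int(g1)))
        blocks.sort()
        merged = [list(blocks[0])]
        for s0, e0 in blocks[1:]:
            if s0 == merged[-1][1]:
                merged[-1][1] = e0
            else:
                merged.append([s0, e0])
        cigar = []
        for k, (s0, e0) in enumerate(merged):
            if k > 0:
                cigar.append((3, s0 - merged[k - 1][1]))
            cigar.append((0, e0 - s0))
        records.append((merged[0][0], cigar, n))
    records.sort()
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for start, cigar, n in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"read{n}"
            a.reference_id = 0
            a.reference_start = start
            a.flag = 16 if seg.strand == "-" else 0
            a.mapping_quality = 60
            a.cigartuples = cigar
            a.query_sequence = "A" * L
            out.write(a)
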