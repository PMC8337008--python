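"""Bootstrap uncertainty for usage estimates.

Signature counts are resampled from a multinomial with probabilities
c_j / N and total N, the EM fit is repeated on each replicate, and
percentile intervals are taken over the replicate estimates.  Replicate
fits are warm-started at the point estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gene_model import GeneSegmentation
from .inference import (
    FitResult,
    _fit_loop,
    _make_context,
    drop_impossible_signatures,
    em_fit,
)
from .signatures import SignatureCounts
from .splicing_chain import parameter_names


def resample_counts(counts: SignatureCounts, rng) -> SignatureCounts:
    """One multinomial bootstrap resample of the signature counts.

    Draws c^b ~ multinomial(c_1/N, ..., c_J/N; N); the resampled total
    always equals N.  ``rng`` is a numpy Generator or seed.
    """
    rng = np.random.default_rng(rng)
    items = counts.sorted_items()
    c = np.array([v for _, v in items], dtype=float)
    N = c.sum()
    if N < 1:
        raise ValueError("cannot resample empty counts")
    draw = rng.multinomial(int(round(N)), c / N)
    entries = {sig: float(n) for (sig, _), n in zip(items, draw) if n > 0}
    return SignatureCounts(counts.gene_id, entries, counts.read_length)


@dataclass
class BootstrapResult:
    """Point estimate plus B bootstrap re-estimates and percentile CIs."""

    point: FitResult
    replicates: np.ndarray  # (B, 1 + M_s + M_e) in to_vector order
    level: float
    seed: int
    names: list

    @property
    def B(self) -> int:
        return self.replicates.shape[0]

    @property
    def intervals(self) -> np.ndarray:
        """(n_params, 2) percentile interval bounds at the stored level."""
        alpha = (1.0 - self.level) / 2.0
        lo = np.quantile(self.replicates, alpha, axis=0)
        hi = np.quantile(self.replicates, 1.0 - alpha, axis=0)
        return np.column_stack([lo, hi])

    def to_frame(self) -> pd.DataFrame:
        iv = self.intervals
        flags = np.concatenate(
            [
                [self.point.identifiable["pi"]],
                self.point.identifiable["p"],
                self.point.identifiable["q"],
            ]
        ).astype(bool)
        est = self.point.theta.to_vector()
        return pd.DataFrame(
            {
                "parameter": self.names,
                "estimate": np.where(flags, est, np.nan),
                "ci_lower": np.where(flags, iv[:, 0], np.nan),
                "ci_upper": np.where(flags, iv[:, 1], np.nan),
                "identifiable": flags,
                "B": self.B,
                "level": self.level,
            }
        )


def bootstrap_fit(
    counts: SignatureCounts,
    seg: GeneSegmentation,
    B: int = 100,
    level: float = 0.95,
    seed: int = 0,
    max_retries: int = 5,
    **em_kwargs,
) -> BootstrapResult:
    """Point EM fit plus B multinomial-bootstrap re-fits.

    Deterministic given ``seed``.  A replicate whose EM fit fails is
    re-drawn up to ``max_retries`` times with a warning.
    """
    if B < 2:
        raise ValueError("bootstrap needs B >= 2 replicates")
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    point = em_fit(counts, seg, seed=seed, **em_kwargs)
    counts, _ = drop_impossible_signatures(counts, seg)
    ctx = _make_context(counts, seg)
    probs = ctx.c / ctx.c.sum()
    N = int(round(ctx.c.sum()))
    tol = em_kwargs.get("tol", 1e-6)
    max_iter = em_kwargs.get("max_iter", 1000)
    inner_sweeps = em_kwargs.get("inner_sweeps", 1)
    theta0 = point.theta.to_vector()
    ss = np.random.SeedSequence(seed)
    replicates = np.empty((B, 1 + seg.M_s + seg.M_e))
    for b, child in enumerate(ss.spawn(B)):
        rng = np.random.default_rng(child)
        for attempt in range(max_retries + 1):
            try:
                draw = rng.multinomial(N, probs).astype(float)
                vec, _, _, _ = _fit_loop(
                    ctx.with_counts(draw), theta0, tol, max_iter, inner_sweeps
                )
                replicates[b] = vec
                break
            except ValueError as err:
                if attempt == max_retries:
                    raise
                warnings.warn(
                    f"bootstrap replicate {b} failed ({err}); redrawing"
                )
    return BootstrapResult(
        point=point,
        replicates=replicates,
        level=level,
        seed=seed,
        names=parameter_names(seg),
    )


def intervals_disjoint(a: BootstrapResult, b: BootstrapResult, parameter: str) -> bool:
    """True if the two results' intervals for a named parameter do not
    overlap — the criterion used to call a usage difference between two
    samples significant.  No multiple-testing correction is applied; with
    many sites this inflates false positives (see docs)."""
    ia = a.intervals[a.names.index(parameter)]
    ib = b.intervals[b.names.index(parameter)]
    return bool(ia[1] < ib[0] or ib[1] < ia[0])
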