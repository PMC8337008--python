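"""Maximum-likelihood estimation of usage parameters from signature counts.

The probability of observing a read with signature g is

    P(g | Theta) = n_g * P_Z(g | Theta) / D(Theta)

where n_g is the number of read start positions producing g (a constant
of the geometry), P_Z(g) is the chain probability that the segments of g
are transcribed and the segments skipped inside g's span are not (states
outside the span marginalized), and D(Theta) = sum_Z l(Z) w(Z) is the
expected effective length — the normalizer of the length-weighted
read-generating distribution.  Summed over all geometrically possible
signatures, P(g | Theta) = 1.

EM treats the state path and read start position of each read as latent.
Because the number of start positions producing a signature does not
depend on the path, the posterior over paths given a signature is simply
the chain conditioned on the signature's required segment states, so the
E-step is a constrained forward-backward pass yielding expected boundary
transition counts.  The M-step maximizes

    Q(Theta) = sum_m [A_m log x_m + B_m log(1 - x_m)] - N log D(Theta)

by exact coordinate ascent: D is affine in each single parameter
(D = a + b x), so each coordinate optimum solves a quadratic in closed
form.  Each sweep increases Q and therefore the observed-data
log-likelihood (a generalized EM step); the outer loop accelerates the
resulting fixed-point map with guarded SQUAREM extrapolation, falling
back to the plain step whenever extrapolation would not improve the
observed likelihood, so the accepted trace is monotone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .gene_model import START_SITE, GeneSegmentation
from .signatures import SignatureCounts, start_position_count, validate_signature
from .splicing_chain import (
    ChainParameters,
    _eff_len_kernel,
    boundary_codes,
    expected_effective_length,
    marginal_site_usage,
)

CLAMP = 1e-9


def signature_masks(counts: SignatureCounts, seg: GeneSegmentation):
    """Per-signature state constraints, start-position factors and counts.

    Returns (sigs, mask, n_pos, c): mask has shape (J, M, 2) with
    mask[j, i, z] = 1 iff segment i+1 may be in state z under signature
    j — forced 1 on the signature's segments, forced 0 on segments
    skipped inside its span, free outside the span.
    """
    sigs = [validate_signature(s, seg) for s, _ in counts.sorted_items()]
    c = np.array([v for _, v in counts.sorted_items()], dtype=float)
    J, M = len(sigs), seg.M
    mask = np.ones((J, M, 2))
    for j, sig in enumerate(sigs):
        members = set(sig)
        for i in range(sig[0], sig[-1] + 1):
            if i in members:
                mask[j, i - 1, 0] = 0.0
            else:
                mask[j, i - 1, 1] = 0.0
    n_pos = np.array(
        [start_position_count(sig, seg, counts.read_length) for sig in sigs], dtype=float
    )
    return sigs, mask, n_pos, c


@dataclass
class _FitContext:
    """Precomputed per-gene quantities shared by all EM iterations."""

    seg: GeneSegmentation
    L: int
    mask: np.ndarray     # (J, M, 2)
    n_pos: np.ndarray    # (J,)
    c: np.ndarray        # (J,)
    kinds: np.ndarray    # (M-1,) 0=start site, 1=end site
    pidx: np.ndarray     # (M-1,) 0-based parameter index
    lengths: np.ndarray  # (M,)

    @property
    def N(self) -> float:
        return float(self.c.sum())

    def with_counts(self, c: np.ndarray) -> "_FitContext":
        return _FitContext(
            self.seg, self.L, self.mask, self.n_pos, c, self.kinds, self.pidx, self.lengths
        )

    def split(self, vec):
        Ms = self.seg.M_s
        return float(vec[0]), vec[1 : 1 + Ms], vec[1 + Ms :]


def _make_context(counts: SignatureCounts, seg: GeneSegmentation) -> _FitContext:
    _, mask, n_pos, c = signature_masks(counts, seg)
    kinds, pidx = boundary_codes(seg)
    return _FitContext(
        seg, counts.read_length, mask, n_pos, c, kinds, pidx, seg.segment_lengths
    )


@njit(cache=True)
def _trans_kernel(kinds, pidx, p, q):  # pragma: no cover
    n = kinds.shape[0]
    T = np.empty((n, 2, 2))
    for i in range(n):
        if kinds[i] == 0:
            x = p[pidx[i]]
            T[i, 0, 0], T[i, 0, 1], T[i, 1, 0], T[i, 1, 1] = 1.0 - x, x, 0.0, 1.0
        else:
            x = q[pidx[i]]
            T[i, 0, 0], T[i, 0, 1], T[i, 1, 0], T[i, 1, 1] = 1.0, 0.0, x, 1.0 - x
    return T


def _constrained_forward(theta, seg, mask):
    """Scaled forward pass under per-signature state constraints.

    Returns (F, log_pz): F[i] is the normalized filtering distribution
    P(Z_{i+1} | constraints up to i+1) of shape (J, 2); log_pz[j] is the
    log of the constrained chain mass P_Z(g_j).  Signatures whose
    constrained mass is exactly zero get log_pz = -inf.
    """
    kinds, pidx = boundary_codes(seg)
    T = _trans_kernel(kinds, pidx, np.asarray(theta.p, float), np.asarray(theta.q, float))
    J, M, _ = mask.shape
    F = np.zeros((M, J, 2))
    log_pz = np.zeros(J)
    f = mask[:, 0, :] * np.array([1.0 - theta.pi, theta.pi])[None, :]
    s = f.sum(axis=1)
    dead = s == 0.0
    log_pz[dead] = -np.inf
    s_safe = np.where(dead, 1.0, s)
    log_pz[~dead] = np.log(s[~dead])
    f = f / s_safe[:, None]
    F[0] = f
    for i in range(M - 1):
        f = (f[:, :, None] * T[i][None, :, :]).sum(axis=1) * mask[:, i + 1, :]
        s = f.sum(axis=1)
        dead |= s == 0.0
        log_pz[dead] = -np.inf
        s_safe = np.where(s == 0.0, 1.0, s)
        log_pz[~dead] += np.log(s_safe[~dead])
        f = f / s_safe[:, None]
        F[i + 1] = f
    return F, log_pz


def constrained_chain_mass(theta: ChainParameters, seg: GeneSegmentation, mask) -> np.ndarray:
    """P_Z(g) for each signature: chain mass under the state constraints."""
    _, log_pz = _constrained_forward(theta, seg, mask)
    return np.exp(log_pz)


def signature_probabilities(
    counts: SignatureCounts, theta: ChainParameters, seg: GeneSegmentation
) -> np.ndarray:
    """P(g_j | Theta) for each signature, in sorted-signature order."""
    theta.check(seg)
    _, mask, n_pos, _ = signature_masks(counts, seg)
    pz = constrained_chain_mass(theta, seg, mask)
    D = expected_effective_length(theta, seg, counts.read_length)
    if D <= 0.0:
        raise ValueError("expected effective length is zero: no path can emit a read")
    return n_pos * pz / D


def signature_log_likelihood(
    counts: SignatureCounts, theta: ChainParameters, seg: GeneSegmentation
) -> float:
    """Observed-data log-likelihood sum_j c_j log P(g_j | Theta).

    Signatures that are geometrically impossible (start-position count 0)
    or structurally incompatible with the chain contribute -inf.
    """
    probs = signature_probabilities(counts, theta, seg)
    _, _, _, c = signature_masks(counts, seg)
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    if np.any((c > 0) & ~np.isfinite(logp)):
        return -np.inf
    return float(np.dot(c[c > 0], logp[c > 0]))


@dataclass
class EStepStats:
    """Expected sufficient statistics of one E-step.

    ``c1`` is the expected number of reads with Z_1 = 1; ``a_p[m]/b_p[m]``
    are expected 0->1 / 0->0 transition counts at start site s_{m+1};
    ``a_q[m]/b_q[m]`` expected 1->0 / 1->1 counts at end site e_{m+1}.
    ``loglik`` is the observed-data log-likelihood at the E-step's Theta.
    """

    c1: float
    a_p: np.ndarray
    b_p: np.ndarray
    a_q: np.ndarray
    b_q: np.ndarray
    loglik: float


@njit(cache=True)
def _estep_kernel(mask, T, pi, c):  # pragma: no cover
    """Constrained forward-backward per signature.

    Returns (log_pz, xi, c1): xi[i] holds the count-weighted expected
    transition counts at boundary i+1; c1 the expected count of reads
    with Z_1 = 1.  Signatures with zero constrained mass get -inf log_pz
    and contribute nothing.
    """
    J, M, _ = mask.shape
    log_pz = np.zeros(J)
    xi = np.zeros((M - 1, 2, 2))
    c1 = 0.0
    F = np.zeros((M, 2))
    for j in range(J):
        f0 = mask[j, 0, 0] * (1.0 - pi)
        f1 = mask[j, 0, 1] * pi
        s = f0 + f1
        if s <= 0.0:
            log_pz[j] = -np.inf
            continue
        lp = np.log(s)
        f0 /= s
        f1 /= s
        F[0, 0], F[0, 1] = f0, f1
        dead = False
        for i in range(M - 1):
            g0 = (f0 * T[i, 0, 0] + f1 * T[i, 1, 0]) * mask[j, i + 1, 0]
            g1 = (f0 * T[i, 0, 1] + f1 * T[i, 1, 1]) * mask[j, i + 1, 1]
            s = g0 + g1
            if s <= 0.0:
                dead = True
                break
            lp += np.log(s)
            f0, f1 = g0 / s, g1 / s
            F[i + 1, 0], F[i + 1, 1] = f0, f1
        if dead:
            log_pz[j] = -np.inf
            continue
        log_pz[j] = lp
        b0 = b1 = 1.0
        for i in range(M - 2, -1, -1):
            m0 = mask[j, i + 1, 0] * b0
            m1 = mask[j, i + 1, 1] * b1
            x00 = F[i, 0] * T[i, 0, 0] * m0
            x01 = F[i, 0] * T[i, 0, 1] * m1
            x10 = F[i, 1] * T[i, 1, 0] * m0
            x11 = F[i, 1] * T[i, 1, 1] * m1
            tot = x00 + x01 + x10 + x11
            if tot > 0.0:
                w = c[j] / tot
                xi[i, 0, 0] += x00 * w
                xi[i, 0, 1] += x01 * w
                xi[i, 1, 0] += x10 * w
                xi[i, 1, 1] += x11 * w
            nb0 = T[i, 0, 0] * m0 + T[i, 0, 1] * m1
            nb1 = T[i, 1, 0] * m0 + T[i, 1, 1] * m1
            s = nb0 + nb1
            b0, b1 = nb0 / s, nb1 / s
        g = F[0, 0] * b0 + F[0, 1] * b1
        if g > 0.0:
            c1 += c[j] * F[0, 1] * b1 / g
    return log_pz, xi, c1


def _estats(ctx: _FitContext, pi, p, q) -> EStepStats:
    T = _trans_kernel(ctx.kinds, ctx.pidx, p, q)
    log_pz, xi, c1 = _estep_kernel(ctx.mask, T, pi, ctx.c)
    if np.any(~np.isfinite(log_pz) & (ctx.c > 0)):
        raise ValueError(
            "signature(s) structurally incompatible with the chain; "
            "drop them before fitting (see em_fit)"
        )
    D = float(
        _eff_len_kernel(
            ctx.lengths, ctx.kinds, ctx.pidx,
            np.array([pi]), p.reshape(1, -1), q.reshape(1, -1), ctx.L,
        )[0]
    )
    if D <= 0.0:
        raise ValueError("expected effective length is zero at current parameters")
    with np.errstate(divide="ignore", invalid="ignore"):
        log_npos = np.log(ctx.n_pos)
    live = ctx.c > 0
    loglik = float(
        np.dot(ctx.c[live], (log_npos + log_pz)[live]) - ctx.c.sum() * np.log(D)
    )
    Ms, Me = ctx.seg.M_s, ctx.seg.M_e
    a_p, b_p = np.zeros(Ms), np.zeros(Ms)
    a_q, b_q = np.zeros(Me), np.zeros(Me)
    for i in range(len(ctx.kinds)):
        m = ctx.pidx[i]
        if ctx.kinds[i] == 0:
            a_p[m], b_p[m] = xi[i, 0, 1], xi[i, 0, 0]
        else:
            a_q[m], b_q[m] = xi[i, 1, 0], xi[i, 1, 1]
    return EStepStats(c1, a_p, b_p, a_q, b_q, loglik)


def expected_stats(
    counts: SignatureCounts, theta: ChainParameters, seg: GeneSegmentation
) -> EStepStats:
    """E-step: constrained forward-backward over all signatures at once."""
    theta.check(seg)
    ctx = _make_context(counts, seg)
    return _estats(ctx, theta.pi, theta.p, theta.q)


@njit(cache=True)
def _maximize_coordinate(A, B, a, b, N):  # pragma: no cover
    """Maximize A log x + B log(1-x) - N log(a + b x) over x in (0, 1).

    The stationarity condition is a quadratic in x; candidates are its
    feasible roots plus the clamped interval endpoints.
    """
    lo = CLAMP
    hi = 1.0 - CLAMP
    c2 = b * (N - A - B)
    c1 = A * b - (A + B) * a - N * b
    c0 = A * a
    cands = np.empty(5)
    cands[0], cands[1] = lo, hi
    n_c = 2
    if abs(c2) > 0.0:
        disc = c1 * c1 - 4.0 * c2 * c0
        if disc >= 0.0:
            # numerically stable roots: t = -(c1 + sign(c1) sqrt(disc)) / 2,
            # roots t / c2 and c0 / t (avoids cancellation when c2 is tiny)
            r = math.sqrt(disc)
            t = -0.5 * (c1 + (r if c1 >= 0.0 else -r))
            if t != 0.0:
                for root in (t / c2, c0 / t):
                    x = root
                    if x < lo:
                        x = lo
                    elif x > hi:
                        x = hi
                    cands[n_c] = x
                    n_c += 1
            else:
                cands[n_c] = lo
                n_c += 1
    if abs(c1) > 0.0:
        x = -c0 / c1
        if x < lo:
            x = lo
        elif x > hi:
            x = hi
        cands[n_c] = x
        n_c += 1
    best_x = lo
    best_v = -np.inf
    for k in range(n_c):
        x = cands[k]
        d = a + b * x
        if d <= 0.0:
            continue
        v = -N * math.log(d)
        if A > 0.0:
            v += A * math.log(x)
        if B > 0.0:
            v += B * math.log(1.0 - x)
        if v > best_v:
            best_v = v
            best_x = x
    return best_x


@njit(cache=True)
def _m_step_kernel(
    lengths, kinds, pidx, pi, p, q, L, N, c1, a_p, b_p, a_q, b_q, n_sweeps
):  # pragma: no cover
    pi_w = np.empty(2)
    p_w = np.empty((2, p.shape[0]))
    q_w = np.empty((2, q.shape[0]))
    for _ in range(n_sweeps):
        # pi
        for k in range(2):
            pi_w[k] = float(k)
            for m in range(p.shape[0]):
                p_w[k, m] = p[m]
            for m in range(q.shape[0]):
                q_w[k, m] = q[m]
        d = _eff_len_kernel(lengths, kinds, pidx, pi_w, p_w, q_w, L)
        pi = _maximize_coordinate(c1, N - c1, d[0], d[1] - d[0], N)
        # start sites
        for m in range(p.shape[0]):
            for k in range(2):
                pi_w[k] = pi
                for mm in range(p.shape[0]):
                    p_w[k, mm] = p[mm]
                for mm in range(q.shape[0]):
                    q_w[k, mm] = q[mm]
                p_w[k, m] = float(k)
            d = _eff_len_kernel(lengths, kinds, pidx, pi_w, p_w, q_w, L)
            p[m] = _maximize_coordinate(a_p[m], b_p[m], d[0], d[1] - d[0], N)
        # end sites
        for m in range(q.shape[0]):
            for k in range(2):
                pi_w[k] = pi
                for mm in range(p.shape[0]):
                    p_w[k, mm] = p[mm]
                for mm in range(q.shape[0]):
                    q_w[k, mm] = q[mm]
                q_w[k, m] = float(k)
            d = _eff_len_kernel(lengths, kinds, pidx, pi_w, p_w, q_w, L)
            q[m] = _maximize_coordinate(a_q[m], b_q[m], d[0], d[1] - d[0], N)
    return pi, p, q


def _m_step(ctx: _FitContext, pi, p, q, stats: EStepStats, inner_sweeps=1):
    return _m_step_kernel(
        ctx.lengths, ctx.kinds, ctx.pidx,
        pi, p.copy(), q.copy(), ctx.L, ctx.N,
        stats.c1, stats.a_p, stats.b_p, stats.a_q, stats.b_q, inner_sweeps,
    )


@dataclass
class FitResult:
    """Outcome of an EM fit."""

    theta: ChainParameters
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    identifiable: dict
    dropped_signatures: list = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def check_identifiability(counts: SignatureCounts, seg: GeneSegmentation) -> dict:
    """Structural identifiability flags per parameter.

    A boundary parameter carries information only if some observed
    signature's span touches one of the two segments adjacent to the
    boundary; pi only if some span covers segment 1 (and M > 1, since a
    single-segment gene has a flat likelihood).  Also returns the number
    of supporting reads per boundary.
    """
    spans = [(sig[0], sig[-1]) for sig, _ in counts.sorted_items()]
    cvec = [v for _, v in counts.sorted_items()]
    p_flags = np.zeros(seg.M_s, dtype=bool)
    q_flags = np.zeros(seg.M_e, dtype=bool)
    n_support = np.zeros(seg.M - 1)
    for i, b in enumerate(seg.boundaries):
        support = sum(
            c for (lo, hi), c in zip(spans, cvec) if lo <= i + 2 and hi >= i + 1
        )
        n_support[i] = support
        flag = support > 0
        if b.kind == START_SITE:
            p_flags[b.param_index - 1] = flag
        else:
            q_flags[b.param_index - 1] = flag
    pi_flag = seg.M > 1 and any(
        c > 0 and lo == 1 for (lo, hi), c in zip(spans, cvec)
    )
    return {"pi": bool(pi_flag), "p": p_flags, "q": q_flags, "n_supporting": n_support}


def _fit_loop(ctx: _FitContext, theta0: np.ndarray, tol, max_iter, inner_sweeps):
    """SQUAREM-accelerated generalized EM on a raw parameter vector."""
    vec = np.clip(theta0, CLAMP, 1.0 - CLAMP)
    pi, p, q = ctx.split(vec)
    p, q = p.copy(), q.copy()
    stats = _estats(ctx, pi, p, q)
    if not np.isfinite(stats.loglik):
        raise ValueError("non-finite log-likelihood at initialization")
    trace = []
    converged = False
    it = 0
    while it < max_iter:
        trace.append(stats.loglik)
        pi1, p1, q1 = _m_step(ctx, pi, p, q, stats, inner_sweeps)
        s1 = _estats(ctx, pi1, p1, q1)
        pi2, p2, q2 = _m_step(ctx, pi1, p1, q1, s1, inner_sweeps)
        s2 = _estats(ctx, pi2, p2, q2)
        it += 2
        cand = (pi2, p2, q2)
        cand_stats = s2
        v0 = np.concatenate([[pi], p, q])
        v1 = np.concatenate([[pi1], p1, q1])
        v2 = np.concatenate([[pi2], p2, q2])
        r = v1 - v0
        v = (v2 - v1) - r
        vnorm = float(np.linalg.norm(v))
        if vnorm > 1e-14:
            alpha = min(-float(np.linalg.norm(r)) / vnorm, -1.0)
            acc = np.clip(v0 - 2.0 * alpha * r + alpha * alpha * v, CLAMP, 1.0 - CLAMP)
            pia, pa, qa = ctx.split(acc)
            try:
                sa = _estats(ctx, pia, pa.copy(), qa.copy())
                pi3, p3, q3 = _m_step(ctx, pia, pa, qa, sa, inner_sweeps)
                s3 = _estats(ctx, pi3, p3, q3)
                it += 1
                if np.isfinite(s3.loglik) and s3.loglik > cand_stats.loglik:
                    cand = (pi3, p3, q3)
                    cand_stats = s3
            except ValueError:
                pass  # extrapolation left the feasible region; keep plain step
        if cand_stats.loglik < stats.loglik - 1e-8:
            warnings.warn(
                f"log-likelihood decreased by {stats.loglik - cand_stats.loglik:.3g}; stopping"
            )
            break
        rel = abs(cand_stats.loglik - stats.loglik) / (abs(stats.loglik) + 1.0)
        (pi, p, q), stats = cand, cand_stats
        if rel < tol:
            converged = True
            break
    trace.append(stats.loglik)
    return np.concatenate([[pi], p, q]), np.asarray(trace), converged, it


def em_fit(
    counts: SignatureCounts,
    seg: GeneSegmentation,
    init: ChainParameters | str = "default",
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int | None = None,
    n_restarts: int = 3,
    inner_sweeps: int = 1,
) -> FitResult:
    """Fit Theta by generalized EM.

    ``init`` is "default" (all parameters 0.5), "random" (seeded), or an
    explicit ChainParameters.  Iterates until the relative change in
    observed-data log-likelihood drops below ``tol``.  Signatures that
    are structurally impossible under the chain (zero constrained mass
    or zero start positions) are dropped with a warning before fitting.
    Parameters are clamped to [1e-9, 1 - 1e-9] during iteration.
    """
    if counts.J == 0 or counts.N == 0:
        raise ValueError("cannot fit: no signature counts")
    counts, dropped = drop_impossible_signatures(counts, seg)
    ctx = _make_context(counts, seg)
    rng = np.random.default_rng(seed)

    def initial(attempt):
        if attempt == 0 and isinstance(init, ChainParameters):
            return init.check(seg).to_vector()
        if attempt == 0 and init == "default":
            return ChainParameters.uniform(seg).to_vector()
        return ChainParameters.random(seg, rng).to_vector()

    last_error = None
    for attempt in range(n_restarts + 1):
        try:
            vec, trace, converged, n_iter = _fit_loop(
                ctx, initial(attempt), tol, max_iter, inner_sweeps
            )
        except ValueError as err:
            last_error = err
            continue
        return FitResult(
            theta=ChainParameters.from_vector(vec, seg),
            loglik_trace=trace,
            converged=converged,
            n_iter=n_iter,
            identifiable=check_identifiability(counts, seg),
            dropped_signatures=dropped,
        )
    raise ValueError(f"EM failed after {n_restarts + 1} initializations: {last_error}")


def drop_impossible_signatures(counts: SignatureCounts, seg: GeneSegmentation):
    """Remove signatures no transcript/read geometry can produce.

    Returns (filtered counts, dropped signature list); warns when
    anything is dropped.  Such signatures arise from reads spliced at a
    modeled boundary of the wrong type (novel event relative to the
    chain) and carry no likelihood under any parameter value.
    """
    ref = ChainParameters.uniform(seg)
    _, mask, n_pos, _ = signature_masks(counts, seg)
    pz = constrained_chain_mass(ref, seg, mask)
    dropped = [
        sig
        for (sig, _), mass, n in zip(counts.sorted_items(), pz, n_pos)
        if mass == 0.0 or n == 0
    ]
    if not dropped:
        return counts, []
    warnings.warn(
        f"gene {counts.gene_id}: dropping {len(dropped)} signature(s) "
        f"inconsistent with the segmentation/chain: {dropped}"
    )
    filtered = SignatureCounts(
        counts.gene_id,
        {s: c for s, c in counts.entries.items() if tuple(s) not in set(dropped)},
        counts.read_length,
        discarded=counts.discarded,
    )
    if filtered.J == 0:
        raise ValueError("all signatures were inconsistent; nothing to fit")
    return filtered, dropped


def _snap(x: float) -> float:
    """Report boundary-clamped estimates as exact 0 or 1."""
    if x <= CLAMP * 10:
        return 0.0
    if x >= 1.0 - CLAMP * 10:
        return 1.0
    return float(x)


def estimates_table(
    fit: FitResult, seg: GeneSegmentation, counts: SignatureCounts
) -> pd.DataFrame:
    """Per-site estimates: one row for the first-segment inclusion pi and
    one per internal boundary.  Non-identifiable parameters are NA."""
    from .gene_model import boundary_position

    usage = marginal_site_usage(fit.theta, seg)
    flags = fit.identifiable
    rows = [
        {
            "gene_id": seg.gene_id,
            "boundary_coordinate": seg.tss if seg.strand == "-" else seg.tss + 1,
            "boundary_kind": "tss",
            "parameter": "pi",
            "estimate": _snap(fit.theta.pi) if flags["pi"] else np.nan,
            "marginal_usage": _snap(fit.theta.pi) if flags["pi"] else np.nan,
            "identifiable": flags["pi"],
            "n_supporting_reads": counts.N,
        }
    ]
    for i, b in enumerate(seg.boundaries):
        if b.kind == START_SITE:
            ident = bool(flags["p"][b.param_index - 1])
            name = f"p{b.param_index}"
        else:
            ident = bool(flags["q"][b.param_index - 1])
            name = f"q{b.param_index}"
        row = usage.iloc[i]
        rows.append(
            {
                "gene_id": seg.gene_id,
                "boundary_coordinate": boundary_position(seg, b),
                "boundary_kind": b.kind,
                "parameter": name,
                "estimate": _snap(row["conditional_usage"]) if ident else np.nan,
                "marginal_usage": _snap(row["marginal_usage"]) if ident else np.nan,
                "identifiable": ident,
                "n_supporting_reads": flags["n_supporting"][i],
            }
        )
    return pd.DataFrame(rows)
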