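"""Inhomogeneous binary Markov chain over gene segments.

Hidden state Z_i indicates whether segment X_i is transcribed.  The chain
starts with P(Z_1 = 1) = pi.  At a boundary separating X_i from X_{i+1}:

* start site s_m (acceptor / alternative TSS): an already-transcribing
  process reads through (1 -> 1 with probability 1); a silent process
  starts an exon with usage probability p_m (0 -> 1), else stays silent.
* end site e_m (donor / alternative TES): a silent process stays silent
  (0 -> 0 with probability 1); a transcribing process ends the exon with
  usage probability q_m (1 -> 0), else reads through.

A state path Z therefore represents one transcript; its chain probability
w(Z) is the transcript's relative abundance.  The all-zero path keeps its
chain probability (1-pi) * prod(1-p_m) but, like any path whose
transcribed length is below the read length, has effective length 0 and
so never emits a read.

All quantities with a dynamic-programming implementation here have a
brute-force counterpart via :func:`enumerate_paths` (guarded to M <= 20),
which serves as the in-package enumeration oracle for small genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .gene_model import START_SITE, GeneSegmentation

_ENUM_GUARD = 20


@dataclass
class ChainParameters:
    """Usage parameters Theta = {pi, p, q}.

    pi is the probability that transcription covers the first segment;
    p[m-1] and q[m-1] are the conditional usages of start site s_m and
    end site e_m.
    """

    pi: float
    p: np.ndarray
    q: np.ndarray

    def __post_init__(self):
        self.pi = float(self.pi)
        self.p = np.asarray(self.p, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        for name, val in (("pi", np.array([self.pi])), ("p", self.p), ("q", self.q)):
            if np.any(val < 0) or np.any(val > 1):
                raise ValueError(f"{name} must lie in [0, 1]")

    def check(self, seg: GeneSegmentation) -> "ChainParameters":
        if len(self.p) != seg.M_s or len(self.q) != seg.M_e:
            raise ValueError(
                f"parameter dimensions ({len(self.p)}, {len(self.q)}) do not "
                f"match segmentation (M_s={seg.M_s}, M_e={seg.M_e})"
            )
        return self

    @classmethod
    def uniform(cls, seg: GeneSegmentation, value: float = 0.5) -> "ChainParameters":
        return cls(value, np.full(seg.M_s, value), np.full(seg.M_e, value))

    @classmethod
    def random(cls, seg: GeneSegmentation, rng, low: float = 0.05, high: float = 0.95):
        rng = np.random.default_rng(rng)
        return cls(
            rng.uniform(low, high),
            rng.uniform(low, high, seg.M_s),
            rng.uniform(low, high, seg.M_e),
        )

    def to_vector(self) -> np.ndarray:
        return np.concatenate([[self.pi], self.p, self.q])

    @classmethod
    def from_vector(cls, vec, seg: GeneSegmentation) -> "ChainParameters":
        vec = np.asarray(vec, dtype=float)
        return cls(vec[0], vec[1 : 1 + seg.M_s], vec[1 + seg.M_s :]).check(seg)


def parameter_names(seg: GeneSegmentation) -> list[str]:
    """Names matching ChainParameters.to_vector order."""
    return (
        ["pi"]
        + [f"p{m}" for m in range(1, seg.M_s + 1)]
        + [f"q{m}" for m in range(1, seg.M_e + 1)]
    )


def transition_matrices(theta: ChainParameters, seg: GeneSegmentation) -> np.ndarray:
    """(M-1, 2, 2) array T with T[i, z, z'] = P(Z_{i+2}=z' | Z_{i+1}=z)."""
    theta.check(seg)
    T = np.empty((seg.M - 1, 2, 2))
    for i, b in enumerate(seg.boundaries):
        if b.kind == START_SITE:
            pm = theta.p[b.param_index - 1]
            T[i] = [[1.0 - pm, pm], [0.0, 1.0]]
        else:
            qm = theta.q[b.param_index - 1]
            T[i] = [[1.0, 0.0], [qm, 1.0 - qm]]
    return T


@dataclass(frozen=True)
class TranscriptPath:
    """A state path Z with its transcribed length in bp."""

    Z: tuple[int, ...]
    transcribed_length: int

    @classmethod
    def from_states(cls, Z, seg: GeneSegmentation) -> "TranscriptPath":
        Z = tuple(int(z) for z in Z)
        if len(Z) != seg.M:
            raise ValueError(f"path length {len(Z)} does not match M={seg.M}")
        if any(z not in (0, 1) for z in Z):
            raise ValueError("path states must be 0/1")
        tl = int(np.dot(Z, seg.segment_lengths))
        return cls(Z, tl)

    def effective_length(self, L: int) -> int:
        """Number of possible read start positions: tl - L + 1, or 0 if the
        transcript is shorter than the read."""
        return max(self.transcribed_length - L + 1, 0)


def path_probability(Z, theta: ChainParameters, seg: GeneSegmentation) -> float:
    """Chain probability w(Z) of a single state path.

    Computed in log space; any exactly-zero factor (e.g. a 1 -> 0
    transition at a start site) short-circuits to probability 0.
    """
    path = Z.Z if isinstance(Z, TranscriptPath) else tuple(int(z) for z in Z)
    if len(path) != seg.M:
        raise ValueError(f"path length {len(path)} does not match M={seg.M}")
    T = transition_matrices(theta, seg)
    init = theta.pi if path[0] == 1 else 1.0 - theta.pi
    if init == 0.0:
        return 0.0
    log_w = np.log(init)
    for i in range(seg.M - 1):
        f = T[i, path[i], path[i + 1]]
        if f == 0.0:
            return 0.0
        log_w += np.log(f)
    return float(np.exp(log_w))


def enumerate_paths(theta: ChainParameters, seg: GeneSegmentation):
    """All 2^M state paths with their chain probabilities (oracle).

    Returns (Z, w) with Z of shape (2^M, M) and w summing to 1.
    Refuses M > 20.
    """
    M = seg.M
    if M > _ENUM_GUARD:
        raise ValueError(f"enumeration limited to M <= {_ENUM_GUARD}, got M={M}")
    codes = np.arange(2**M, dtype=np.int64)
    Z = (codes[:, None] >> np.arange(M - 1, -1, -1)[None, :]) & 1
    T = transition_matrices(theta, seg)
    init = np.array([1.0 - theta.pi, theta.pi])
    w = init[Z[:, 0]]
    for i in range(M - 1):
        w = w * T[i, Z[:, i], Z[:, i + 1]]
    return Z, w


def _forward_state_dists(theta: ChainParameters, seg: GeneSegmentation) -> np.ndarray:
    """(M, 2) array of P(Z_i = z) for each segment."""
    T = transition_matrices(theta, seg)
    dists = np.empty((seg.M, 2))
    dists[0] = [1.0 - theta.pi, theta.pi]
    for i in range(seg.M - 1):
        dists[i + 1] = dists[i] @ T[i]
    return dists


def transcribed_marginals(theta: ChainParameters, seg: GeneSegmentation) -> np.ndarray:
    """Forward-pass marginals P(Z_i = 1), i = 1..M."""
    return _forward_state_dists(theta, seg)[:, 1]


def boundary_codes(seg: GeneSegmentation) -> tuple[np.ndarray, np.ndarray]:
    """Boundary kinds (0 = start site, 1 = end site) and 0-based parameter
    indices as arrays, for the compiled kernels."""
    kinds = np.array(
        [0 if b.kind == START_SITE else 1 for b in seg.boundaries], dtype=np.int64
    )
    pidx = np.array([b.param_index - 1 for b in seg.boundaries], dtype=np.int64)
    return kinds, pidx


@njit(cache=True)
def _eff_len_kernel(lengths, kinds, pidx, pis, ps, qs, L):  # pragma: no cover
    K = pis.shape[0]
    M = lengths.shape[0]
    out = np.empty(K)
    for k in range(K):
        # m0[z, c]: probability of state z with transcribed length capped at c;
        # m1[z, c]: expectation of the true transcribed length on that event
        m0 = np.zeros((2, L + 1))
        m1 = np.zeros((2, L + 1))
        ell0 = lengths[0]
        c0 = ell0 if ell0 < L else L
        m0[0, 0] = 1.0 - pis[k]
        m0[1, c0] = pis[k]
        m1[1, c0] = pis[k] * ell0
        for i in range(M - 1):
            if kinds[i] == 0:
                x = ps[k, pidx[i]]
                t00, t01, t10, t11 = 1.0 - x, x, 0.0, 1.0
            else:
                x = qs[k, pidx[i]]
                t00, t01, t10, t11 = 1.0, 0.0, x, 1.0 - x
            ell = lengths[i + 1]
            n0_m0 = np.zeros(L + 1)
            n0_m1 = np.zeros(L + 1)
            n1_m0 = np.zeros(L + 1)
            n1_m1 = np.zeros(L + 1)
            for c in range(L + 1):
                n0_m0[c] = t00 * m0[0, c] + t10 * m0[1, c]
                n0_m1[c] = t00 * m1[0, c] + t10 * m1[1, c]
                s0 = t01 * m0[0, c] + t11 * m0[1, c]
                s1 = t01 * m1[0, c] + t11 * m1[1, c]
                cp = c + ell
                if cp > L:
                    cp = L
                n1_m0[cp] += s0
                n1_m1[cp] += s1 + ell * s0
            m0[0], m0[1] = n0_m0, n1_m0
            m1[0], m1[1] = n0_m1, n1_m1
        out[k] = (m1[0, L] + m1[1, L]) - (L - 1.0) * (m0[0, L] + m0[1, L])
    return out


def effective_length_batch(
    pis: np.ndarray,
    ps: np.ndarray,
    qs: np.ndarray,
    seg: GeneSegmentation,
    L: int,
) -> np.ndarray:
    """Expected effective length sum_Z l(Z) w(Z) for K parameter settings.

    ``pis`` has shape (K,), ``ps`` (K, M_s), ``qs`` (K, M_e).  Exact
    dynamic program over (state, transcribed-length-capped-at-L): tracks
    per cell the probability mass and the expectation of the true
    transcribed length, then reads off
    E[tl ; tl >= L] - (L - 1) P(tl >= L).
    """
    if L < 1:
        raise ValueError("read length L must be >= 1")
    pis = np.ascontiguousarray(pis, dtype=np.float64)
    ps = np.ascontiguousarray(ps, dtype=np.float64).reshape(len(pis), seg.M_s)
    qs = np.ascontiguousarray(qs, dtype=np.float64).reshape(len(pis), seg.M_e)
    kinds, pidx = boundary_codes(seg)
    return _eff_len_kernel(seg.segment_lengths, kinds, pidx, pis, ps, qs, int(L))


def expected_effective_length(theta: ChainParameters, seg: GeneSegmentation, L: int) -> float:
    """sum_Z l(Z) w(Z): the normalizer of the read-generating distribution."""
    theta.check(seg)
    return float(
        effective_length_batch(
            np.array([theta.pi]), theta.p[None, :], theta.q[None, :], seg, L
        )[0]
    )


def marginal_site_usage(theta: ChainParameters, seg: GeneSegmentation) -> pd.DataFrame:
    """Conditional and marginal usage per internal boundary.

    The conditional usage is the chain parameter itself (p_m, q_m): the
    probability the site is used given the splicing process considers it.
    The marginal usage is the probability an exon actually starts/ends at
    the site: P(Z_i=0) p_m for start site s_m between X_i and X_{i+1},
    P(Z_i=1) q_m for end site e_m.
    """
    theta.check(seg)
    dists = _forward_state_dists(theta, seg)
    rows = []
    for i, b in enumerate(seg.boundaries):
        if b.kind == START_SITE:
            cond = theta.p[b.param_index - 1]
            marg = dists[i, 0] * cond
        else:
            cond = theta.q[b.param_index - 1]
            marg = dists[i, 1] * cond
        rows.append(
            {
                "boundary": i + 1,
                "kind": b.kind,
                "param_index": b.param_index,
                "conditional_usage": cond,
                "marginal_usage": marg,
            }
        )
    return pd.DataFrame(rows)


def terminal_end_usage(theta: ChainParameters, seg: GeneSegmentation) -> float:
    """Conditional usage of the gene TES, by brute-force enumeration.

    Transcription cannot continue past the last annotated segment, so
    every path still transcribing when it reaches the TES terminates
    there: P(terminate at TES | Z_M = 1) is identically 1.  Computed
    literally as the ratio of enumerated path masses.
    """
    Z, w = enumerate_paths(theta, seg)
    reach = w[Z[:, -1] == 1]
    considered = float(reach.sum())
    if considered == 0.0:
        raise ValueError("no path reaches the terminal segment with positive probability")
    terminated = float(reach.sum())  # no path extends beyond the TES
    return terminated / considered


def dump_paths(theta: ChainParameters, seg: GeneSegmentation, max_M: int = 12) -> pd.DataFrame:
    """Enumerated paths as a table (debug helper, M <= max_M)."""
    if seg.M > max_M:
        raise ValueError(f"path dump limited to M <= {max_M}")
    Z, w = enumerate_paths(theta, seg)
    lengths = seg.segment_lengths
    return pd.DataFrame(
        {
            "path": ["".join(map(str, row)) for row in Z],
            "probability": w,
            "transcribed_length": Z @ lengths,
        }
    )
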