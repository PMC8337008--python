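"""Brute-force oracles: independent reference implementations used only
to check the package's dynamic-programming and EM code on small genes.

Everything here enumerates all 2^M state paths and, where reads are
involved, literally loops over every read start position in every path.
"""

import numpy as np
from scipy.optimize import minimize

from spliceusage import ChainParameters, enumerate_paths


def enum_marginals(theta, seg):
    Z, w = enumerate_paths(theta, seg)
    return np.array([w[Z[:, i] == 1].sum() for i in range(seg.M)])


def enum_effective_length(theta, seg, L):
    Z, w = enumerate_paths(theta, seg)
    tl = Z @ seg.segment_lengths
    return float((np.maximum(tl - L + 1, 0) * w).sum())


def enum_marginal_usage(theta, seg):
    """Probability an exon starts/ends exactly at each internal boundary."""
    Z, w = enumerate_paths(theta, seg)
    out = np.zeros(seg.M - 1)
    for i, b in enumerate(seg.boundaries):
        if b.kind == "start_site":
            used = (Z[:, i] == 0) & (Z[:, i + 1] == 1)
        else:
            used = (Z[:, i] == 1) & (Z[:, i + 1] == 0)
        out[i] = w[used].sum()
    return out


def path_read_signatures(path, lengths, L):
    """(signature, count) pairs from literally walking every read start
    position of one transcript."""
    ts = np.flatnonzero(path) + 1
    cum = np.concatenate([[0], np.cumsum(lengths[ts - 1])])
    tl = int(cum[-1])
    out = {}
    for b in range(max(tl - L + 1, 0)):
        first = int(np.searchsorted(cum, b, side="right") - 1)
        last = int(np.searchsorted(cum, b + L - 1, side="right") - 1)
        sig = tuple(int(x) for x in ts[first : last + 1])
        out[sig] = out.get(sig, 0) + 1
    return out


def enum_signature_distribution(theta, seg, L):
    """P(g | Theta) by full enumeration of paths x read positions."""
    Z, w = enumerate_paths(theta, seg)
    lengths = seg.segment_lengths
    num = {}
    D = 0.0
    for path, wz in zip(Z, w):
        if wz == 0.0:
            continue
        for sig, k in path_read_signatures(path, lengths, L).items():
            num[sig] = num.get(sig, 0.0) + wz * k
            D += wz * k
    return {sig: v / D for sig, v in num.items()}


def enum_posterior_transitions(theta, seg, sig):
    """Posterior P(Z_i, Z_{i+1} | signature) over consistent paths: the
    chain restricted to paths carrying the signature's pattern."""
    Z, w = enumerate_paths(theta, seg)
    members = set(sig)
    ok = np.ones(len(Z), dtype=bool)
    for i in range(sig[0], sig[-1] + 1):
        want = 1 if i in members else 0
        ok &= Z[:, i - 1] == want
    w = np.where(ok, w, 0.0)
    total = w.sum()
    out = np.zeros((seg.M - 1, 2, 2))
    for i in range(seg.M - 1):
        for a in (0, 1):
            for b in (0, 1):
                out[i, a, b] = w[(Z[:, i] == a) & (Z[:, i + 1] == b)].sum() / total
    return out


def enum_log_likelihood(counts, theta, seg):
    dist = enum_signature_distribution(theta, seg, counts.read_length)
    ll = 0.0
    for sig, c in counts.sorted_items():
        p = dist.get(sig, 0.0)
        if p == 0.0:
            return -np.inf
        ll += c * np.log(p)
    return ll


def direct_mle(counts, seg, starts, bound=1e-7):
    """Numerical maximization of the enumeration-based likelihood from
    multiple starting points; returns (best vector, best log-likelihood)."""

    def neg(vec):
        theta = ChainParameters.from_vector(np.clip(vec, bound, 1 - bound), seg)
        ll = enum_log_likelihood(counts, theta, seg)
        return -ll if np.isfinite(ll) else 1e15

    best = None
    for v0 in starts:
        res = minimize(
            neg,
            np.asarray(v0, dtype=float),
            method="L-BFGS-B",
            bounds=[(bound, 1 - bound)] * len(v0),
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x, -best.fun
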