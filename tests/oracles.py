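"""Independent oracles used by the test suite.

Everything here is deliberately written without reusing the package's
evaluation paths: matrix exponentials by truncated series, marginal
likelihoods by fixed-grid Riemann sums, hemiplasy/homoplasy probabilities by
direct numeric integration over coalescent histories with hand-written
mutation-placement factors.
"""

import math

import numpy as np


def series_expm(q: np.ndarray, t: float, terms: int = 60) -> np.ndarray:
    """Matrix exponential by scaling-and-squaring of the Taylor series."""
    k = max(0, int(np.ceil(np.log2(max(1.0, np.abs(q).max() * t)))) + 4)
    x = q * (t / 2 ** k)
    acc = np.eye(q.shape[0])
    term = np.eye(q.shape[0])
    for i in range(1, terms):
        term = term @ x / i
        acc = acc + term
    for _ in range(k):
        acc = acc @ acc
    return acc


def two_state_p(t, a, b):
    """Closed-form 2-state transition matrix (independent rewrite)."""
    s = a + b
    if s == 0:
        return np.eye(2)
    e = math.exp(-s * t)
    return np.array([[(b + a * e) / s, (a - a * e) / s],
                     [(b - b * e) / s, (a + b * e) / s]])


def riemann_two_taxon(tdiv, s1, s2, a, b, pi, upper=60.0, steps=60_000):
    """Marginal pattern probability for two lineages diverging at ``tdiv``,
    by midpoint Riemann integration of the Exp(1) coalescence density."""
    dt = upper / steps
    w = (np.arange(steps) + 0.5) * dt
    tot = 0.0
    for wi in w:
        tau = tdiv + wi
        p = two_state_p(tau, a, b)
        tot += math.exp(-wi) * dt * sum(pi[j] * p[j, s1] * p[j, s2]
                                        for j in (0, 1))
    return tot


def enumerate_three_leaf(tau1, tau2, sx, sy, sz, a, b, pi):
    """Pruning likelihood of genealogy ((x,y)@tau1, z)@tau2 by brute-force
    summation over the internal-node and root states."""
    p1 = two_state_p(tau1, a, b)
    pup = two_state_p(tau2 - tau1, a, b)
    p2 = two_state_p(tau2, a, b)
    tot = 0.0
    for r in (0, 1):
        for k in (0, 1):
            tot += pi[r] * pup[r, k] * p1[k, sx] * p1[k, sy] * p2[r, sz]
    return tot


def discordance_probability(internal_branch: float) -> float:
    """MSC probability of each discordant rooted triplet topology."""
    return math.exp(-internal_branch) / 3.0


# ---------------------------------------------------------------------------
# HRF quadrature oracle (three-taxon tree, all lineages sampled at age 0)
# ---------------------------------------------------------------------------

def hrf_quadrature(t_low, t_high, a, b, grid=600, upper=40.0):
    """E[P_hemiplasy] and E[P_homoplasy] for the focal internal branch
    [t_low, t_high] of a three-taxon tree, by fixed-grid integration over the
    triplet coalescent histories.

    Lineages: d and n below the focal branch, s the sister; the target
    pattern is d and s derived.  Mutation placements use per-branch Poisson
    factors: gain = 1-exp(-a*len), no-gain = exp(-a*len), and below a gain
    the no-loss factor exp(-b*len).
    """

    def case_dn(tau1, tau2):
        # concordant: branches d,n pendant to tau1; internal {d,n}; s to tau2
        hemi = np.zeros(np.broadcast(tau1, tau2).shape)
        homo = ((1 - np.exp(-a * tau1)) * (1 - np.exp(-a * tau2))
                * np.exp(-a * tau1) * np.exp(-a * (tau2 - tau1)))
        return hemi, homo

    def case_ds(tau1, tau2):
        hemi = ((1 - np.exp(-a * (tau2 - tau1)))
                * np.exp(-b * tau1) * np.exp(-b * tau1)
                * np.exp(-a * tau2))
        homo = ((1 - np.exp(-a * tau1)) * (1 - np.exp(-a * tau1))
                * np.exp(-a * (tau2 - tau1)) * np.exp(-a * tau2))
        return hemi, homo

    def case_ns(tau1, tau2):
        hemi = np.zeros(np.broadcast(tau1, tau2).shape)
        homo = ((1 - np.exp(-a * tau2)) * (1 - np.exp(-a * tau1))
                * np.exp(-a * tau1) * np.exp(-a * (tau2 - tau1)))
        return hemi, homo

    e_hemi = e_homo = 0.0
    span = t_high - t_low
    dw = upper / grid
    w = (np.arange(grid) + 0.5) * dw
    # history A: d,n coalesce on the focal branch at tau1, root above t_high
    d1 = span / grid
    tau1 = t_low + (np.arange(grid) + 0.5) * d1
    w1 = np.exp(-(tau1 - t_low)) * d1
    w2 = np.exp(-w) * dw
    h, o = case_dn(tau1[:, None], (t_high + w)[None, :])
    e_hemi += float(w1 @ h @ w2)
    e_homo += float(w1 @ o @ w2)
    # history B: no coalescence below t_high; three lineages above
    pnc = math.exp(-span)
    x = (np.arange(grid) + 0.5) * (upper / 3.0) / grid
    wx = 3.0 * np.exp(-3.0 * x) * (upper / 3.0) / grid
    tau1b = (t_high + x)[:, None]
    tau2b = tau1b + w[None, :]
    for case in (case_dn, case_ds, case_ns):
        h, o = case(tau1b, tau2b)
        e_hemi += pnc * float(wx @ h @ w2) / 3.0
        e_homo += pnc * float(wx @ o @ w2) / 3.0
    return e_hemi, e_homo
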