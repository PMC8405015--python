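"""Binary-trait likelihoods on genealogies, species trees and networks.

The trait is a two-state Markov chain with forward rate ``u`` (0->1) and
backward rate ``v`` (1->0), scaled by the population mutation rate ``theta``
(substitution rate per coalescent unit, theta = 2N mu).  With the default
normalization ``pi0*u + pi1*v = 1`` -- the usual bi-allelic-marker convention
-- theta alone sets the expected substitution rate, and a forward/backward
ratio plus theta determines (u, v) uniquely.

Three evaluation routes are provided:

* :func:`genealogy_trait_likelihood` -- Felsenstein pruning on a fixed
  genealogy, with polymorphic species handled by summing over the
  exchangeable assignments of states to that species' sampled leaves;
* :func:`marginal_trait_likelihood_mc` -- Monte-Carlo marginalization of the
  pruning likelihood over genealogies sampled under the multispecies
  (network) coalescent;
* :func:`marginal_trait_likelihood_exact` -- quadrature over coalescent
  histories for instances of at most three species, one sampled individual
  each, and reticulations confined to pendant paths (where the network
  likelihood decomposes exactly as the gamma-weighted mixture of its
  displayed trees).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .network import PhyloNetwork, NetworkError, displayed_trees
from .simulate import Genealogy, SampleScheme, sample_genealogies, RngLike

__all__ = [
    "BinaryTraitModel",
    "TraitCounts",
    "LikelihoodEstimate",
    "transition_matrix",
    "genealogy_trait_likelihood",
    "marginal_trait_likelihood_mc",
    "marginal_trait_likelihood_exact",
]

_MAX_ASSIGNMENTS = 200_000


class BinaryTraitModel:
    """Two-state trait substitution model.

    Parameters
    ----------
    u, v:
        Forward (0->1) and backward (1->0) substitution rates.  When
        ``normalize`` is true (default) they are rescaled so that
        ``pi0*u + pi1*v = 1`` with ``(pi0, pi1) = (v, u)/(u+v)``; only the
        ratio u/v then matters and ``theta`` is the expected substitution
        rate per coalescent unit.
    theta:
        Default population mutation rate used when an operation is not given
        an explicit ``theta``.
    """

    def __init__(self, u: float, v: float, theta: Optional[float] = None,
                 normalize: bool = True):
        if u <= 0 or v <= 0:
            raise ValueError("u and v must be positive")
        if normalize:
            c = 2.0 * u * v / (u + v)
            u, v = u / c, v / c
        self.u = float(u)
        self.v = float(v)
        self.theta = theta
        self.normalized = bool(normalize)

    @classmethod
    def from_ratio(cls, ratio: float, theta: Optional[float] = None
                   ) -> "BinaryTraitModel":
        """Model with forward/backward ratio ``u/v = ratio``, normalized."""
        if ratio <= 0:
            raise ValueError("ratio must be positive")
        return cls(ratio, 1.0, theta=theta, normalize=True)

    def stationary(self) -> np.ndarray:
        s = self.u + self.v
        return np.array([self.v / s, self.u / s])

    def rates(self, theta: Optional[float] = None) -> tuple:
        """Instantaneous rates ``(a, b) = (theta*u, theta*v)``."""
        th = theta if theta is not None else self.theta
        if th is None:
            raise ValueError("theta must be given (argument or model default)")
        if th < 0:
            raise ValueError("theta must be >= 0")
        return th * self.u, th * self.v

    def __repr__(self):
        return (f"BinaryTraitModel(u={self.u:.6g}, v={self.v:.6g}, "
                f"theta={self.theta})")


@dataclass(frozen=True)
class TraitCounts:
    """Observed state counts: per species, the number of sampled individuals
    in state 0 and in state 1 (a "trait pattern" when one sample each)."""

    counts: dict

    def __post_init__(self):
        for sp, (n0, n1) in self.counts.items():
            if n0 < 0 or n1 < 0 or (n0 + n1) < 1 or n0 != int(n0) or n1 != int(n1):
                raise ValueError(f"invalid counts for species {sp!r}: {(n0, n1)}")

    @classmethod
    def from_pattern(cls, states: dict) -> "TraitCounts":
        """One sampled individual per species with the given binary state."""
        out = {}
        for sp, s in states.items():
            if s not in (0, 1):
                raise ValueError(f"state for {sp!r} must be 0 or 1")
            out[sp] = (1 - s, s)
        return cls(out)

    def species(self) -> list:
        return sorted(self.counts)

    def sample_scheme(self) -> SampleScheme:
        return SampleScheme({sp: n0 + n1 for sp, (n0, n1) in self.counts.items()})

    def is_pattern(self) -> bool:
        return all(n0 + n1 == 1 for n0, n1 in self.counts.values())

    def n_total(self) -> int:
        return sum(n0 + n1 for n0, n1 in self.counts.values())


@dataclass(frozen=True)
class LikelihoodEstimate:
    """A (possibly Monte-Carlo) estimate of a marginal trait likelihood."""

    estimate: float
    se: float
    n_genealogies: int
    method: str = "mc"

    @property
    def log_estimate(self) -> float:
        return math.log(self.estimate) if self.estimate > 0 else -math.inf

    @property
    def log_se(self) -> float:
        """Delta-method standard error of the log estimate."""
        if self.estimate <= 0:
            return math.inf
        return self.se / self.estimate


# ---------------------------------------------------------------------------
# transition probabilities
# ---------------------------------------------------------------------------

def transition_matrix(model: BinaryTraitModel, t: float,
                      theta: Optional[float] = None) -> np.ndarray:
    """2x2 transition matrix of the trait chain over duration ``t``.

    With ``a = theta*u`` and ``b = theta*v``::

        P00 = (b + a e^{-(a+b)t}) / (a+b)     P01 = 1 - P00
        P11 = (a + b e^{-(a+b)t}) / (a+b)     P10 = 1 - P11
    """
    if t < 0:
        raise ValueError("duration must be >= 0")
    a, b = model.rates(theta)
    s = a + b
    if s == 0:
        return np.eye(2)
    e = math.exp(-s * t)
    p00 = (b + a * e) / s
    p11 = (a + b * e) / s
    return np.array([[p00, 1.0 - p00], [1.0 - p11, p11]])


def _p_entries(t: np.ndarray, a: float, b: float):
    """Vectorized transition entries (P00, P01, P10, P11) for an array of
    durations."""
    s = a + b
    e = np.exp(-s * t)
    p00 = (b + a * e) / s
    p11 = (a + b * e) / s
    return p00, 1.0 - p00, 1.0 - p11, p11


# ---------------------------------------------------------------------------
# assignments of observed counts to exchangeable leaves
# ---------------------------------------------------------------------------

def _leaf_partials(leaf_labels, counts: TraitCounts) -> np.ndarray:
    """Per-assignment leaf state partials, shape ``(A, n, 2)``.

    For each species the observed counts are distributed over that species'
    exchangeable sampled leaves in every possible way; the likelihood of the
    counts is the sum of the pruning likelihood over the ``prod C(n0+n1, n1)``
    joint assignments.
    """
    n = len(leaf_labels)
    by_species: dict[str, list] = {}
    for i, (sp, _) in enumerate(leaf_labels):
        by_species.setdefault(sp, []).append(i)
    if set(by_species) != set(counts.counts):
        raise ValueError(
            f"genealogy species {sorted(by_species)} do not match counts "
            f"species {sorted(counts.counts)}")
    per_species = []
    total = 1
    for sp in sorted(by_species):
        idxs = by_species[sp]
        n0, n1 = counts.counts[sp]
        if n0 + n1 != len(idxs):
            raise ValueError(
                f"species {sp!r}: {len(idxs)} leaves but counts {(n0, n1)}")
        combos = [frozenset(c) for c in itertools.combinations(idxs, n1)]
        per_species.append(combos)
        total *= len(combos)
        if total > _MAX_ASSIGNMENTS:
            raise ValueError("too many count assignments; reduce sample sizes")
    out = np.zeros((total, n, 2))
    for ai, choice in enumerate(itertools.product(*per_species)):
        ones = frozenset().union(*choice) if choice else frozenset()
        for i in range(n):
            out[ai, i, 1 if i in ones else 0] = 1.0
    return out


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def genealogy_trait_likelihood(gen: Genealogy, counts: TraitCounts,
                               model: BinaryTraitModel,
                               theta: Optional[float] = None) -> float:
    """Probability of the observed state counts on one fixed genealogy.

    Post-order pruning with per-branch transition matrices; the root is
    weighted by the stationary distribution; polymorphic species are summed
    over assignments of states to their exchangeable leaves.
    """
    a, b = model.rates(theta)
    pi = model.stationary()
    partials = _leaf_partials(gen.leaf_labels, counts)  # (A, n, 2)
    n = gen.n_leaves
    full = np.empty((partials.shape[0], gen.n_nodes, 2))
    full[:, :n] = partials
    for j in range(n - 1):
        acc = np.ones((partials.shape[0], 2))
        for c in gen.children[j]:
            c = int(c)
            t = gen.coal_ages[j] - gen.node_age(c)
            p00, p01, p10, p11 = _p_entries(np.array(t), a, b)
            g = full[:, c]
            acc *= np.stack([p00 * g[:, 0] + p01 * g[:, 1],
                             p10 * g[:, 0] + p11 * g[:, 1]], axis=1)
        full[:, n + j] = acc
    per_assign = full[:, -1] @ pi
    return float(per_assign.sum())


def _batch_counts_likelihood(coal_ages: np.ndarray, children: np.ndarray,
                             leaf_partials: np.ndarray, a: float, b: float,
                             pi: np.ndarray) -> np.ndarray:
    """Pruning likelihood of fixed counts for a batch of genealogies.

    ``coal_ages``: (m, n-1); ``children``: (m, n-1, 2);
    ``leaf_partials``: (A, n, 2).  Returns per-genealogy probabilities (m,).
    """
    m, nm1 = coal_ages.shape
    n = nm1 + 1
    A = leaf_partials.shape[0]
    out = np.empty(m)
    # chunk so the partial-likelihood tensor stays ~tens of MB
    chunk = max(1, int(6_000_000 / ((2 * n - 1) * A)))
    lp = np.transpose(leaf_partials, (1, 0, 2))  # (n, A, 2)
    for lo in range(0, m, chunk):
        hi = min(m, lo + chunk)
        M = hi - lo
        ages = np.concatenate(
            [np.zeros((M, n)), coal_ages[lo:hi]], axis=1)  # (M, 2n-1)
        F = np.empty((M, 2 * n - 1, A, 2))
        F[:, :n] = lp[None, :, :, :]
        rows = np.arange(M)
        for j in range(n - 1):
            acc = None
            for ci in (0, 1):
                c = children[lo:hi, j, ci]
                t = coal_ages[lo:hi, j] - ages[rows, c]
                p00, p01, p10, p11 = _p_entries(t, a, b)
                g = F[rows, c]  # (M, A, 2)
                down = np.stack(
                    [p00[:, None] * g[..., 0] + p01[:, None] * g[..., 1],
                     p10[:, None] * g[..., 0] + p11[:, None] * g[..., 1]],
                    axis=-1)
                acc = down if acc is None else acc * down
            F[:, n + j] = acc
        out[lo:hi] = (F[:, -1] @ pi).sum(axis=1)
    return out


def marginal_trait_likelihood_mc(net: PhyloNetwork, counts: TraitCounts,
                                 model: BinaryTraitModel,
                                 theta: Optional[float] = None,
                                 n_genealogies: int = 10_000,
                                 rng_seed: RngLike = None
                                 ) -> LikelihoodEstimate:
    """Monte-Carlo estimate of f(A | Psi, Theta, Gamma, u, v).

    Genealogies are sampled under the multispecies (network) coalescent and
    the pruning likelihood of the counts is averaged; the standard error is
    the sample standard deviation divided by sqrt(n).
    """
    if n_genealogies < 1:
        raise ValueError("n_genealogies must be >= 1")
    a, b = model.rates(theta)
    pi = model.stationary()
    scheme = counts.sample_scheme()
    labels, ages, children = sample_genealogies(net, scheme, n_genealogies,
                                                rng_seed)
    partials = _leaf_partials(labels, counts)
    w = _batch_counts_likelihood(ages, children, partials, a, b, pi)
    est = float(w.mean())
    se = float(w.std(ddof=1) / math.sqrt(len(w))) if len(w) > 1 else math.inf
    return LikelihoodEstimate(est, se, int(n_genealogies), method="mc")


# ---------------------------------------------------------------------------
# exact small-instance evaluation (quadrature over coalescent histories)
# ---------------------------------------------------------------------------

_QUAD_CACHE: dict = {}


def _gauss(order: int):
    if ("leg", order) not in _QUAD_CACHE:
        x, w = np.polynomial.legendre.leggauss(order)
        _QUAD_CACHE[("leg", order)] = (x, w)
        y, v = np.polynomial.laguerre.laggauss(order)
        _QUAD_CACHE[("lag", order)] = (y, v)
    return _QUAD_CACHE[("leg", order)], _QUAD_CACHE[("lag", order)]


def _pmat(t, a, b):
    """Transition entries for array t, returned as (..., 2, 2)."""
    p00, p01, p10, p11 = _p_entries(np.asarray(t, dtype=float), a, b)
    return np.stack([np.stack([p00, p01], -1), np.stack([p10, p11], -1)], -2)


def _tree2_prob(tdiv, s1, s2, a, b, pi, order):
    """Exact pattern probability for two lineages diverging at ``tdiv``."""
    (_, _), (y, v) = _gauss(order)
    tau = tdiv + y  # coalescence times, Exp(1) above the divergence
    p = _pmat(tau, a, b)  # (order, 2, 2)
    like = (pi[None, :] * p[:, :, s1] * p[:, :, s2]).sum(axis=1)
    return float((v * like).sum())


def _tree3_prob(t1, t2, sx, sy, sz, a, b, pi, order):
    """Exact pattern probability for topology ((x,y) at t1, z) with root t2."""
    (xl, wl), (yg, vg) = _gauss(order)

    def joint(s, tau2):
        """Pruning likelihood for genealogy ((x,y)@s, z)@tau2 (arrays)."""
        ps = _pmat(s, a, b)
        m = ps[..., :, sx] * ps[..., :, sy]  # (..., k) state at (x,y) anc
        pup = _pmat(tau2 - s, a, b)
        pz = _pmat(tau2, a, b)
        inner = np.einsum("...jk,...k->...j", pup, m)
        return np.einsum("j,...j,...j->...", pi, inner, pz[..., :, sz])

    # history 1: x,y coalesce at s in (t1, t2), root coalescence at t2 + w
    hi = min(t2, t1 + 60.0)
    total = 0.0
    if hi > t1:
        s = 0.5 * (hi - t1) * (xl + 1.0) + t1        # (order,)
        ws = 0.5 * (hi - t1) * wl * np.exp(-(s - t1))
        tau2 = t2 + yg                                # (order,)
        val = joint(s[:, None], tau2[None, :])        # (order, order)
        total += float(ws @ val @ vg)

    # history 2: no coalescence below the root (prob e^{-(t2-t1)}), three
    # lineages above: first of three pairs at rate 3, uniform pair, then rate 1
    pnc = math.exp(-(t2 - t1))
    if pnc > 0:
        tau1 = t2 + yg / 3.0                          # (order,)
        acc = np.zeros((order, order))
        for (sa, sb, sc) in ((sx, sy, sz), (sx, sz, sy), (sy, sz, sx)):
            # pair (a,b) coalesces first at tau1, then with c at tau1 + w
            ps = _pmat(tau1, a, b)                    # (order, 2, 2)
            m = ps[:, :, sa] * ps[:, :, sb]
            pup = _pmat(yg[None, :], a, b)            # (1, order, 2, 2)
            pc = _pmat(tau1[:, None] + yg[None, :], a, b)
            inner = np.einsum("xwjk,xk->xwj", np.broadcast_to(
                pup, (order, order, 2, 2)), m)
            acc += np.einsum("j,xwj,xwj->xw", pi, inner, pc[..., :, sc])
        total += pnc * float(vg @ (acc / 3.0) @ vg)
    return total


def _tree_pattern_prob(tree: PhyloNetwork, states: dict, a, b, pi, order):
    leaves = tree.leaves()
    if len(leaves) == 1:
        return float(pi[states[leaves[0].label]])
    if len(leaves) == 2:
        return _tree2_prob(tree.root.age, states[leaves[0].label],
                           states[leaves[1].label], a, b, pi, order)
    if len(leaves) == 3:
        root = tree.root
        kids = [tree.nodes[e.child] for e in root.child_edges]
        inner = [k for k in kids if not k.is_leaf]
        outer = [k for k in kids if k.is_leaf]
        if len(inner) != 1 or len(outer) != 1:
            raise NetworkError("three-leaf tree must be fully resolved")
        cherry = [tree.nodes[e.child] for e in inner[0].child_edges]
        if not all(c.is_leaf for c in cherry):
            raise NetworkError("three-leaf tree must be fully resolved")
        return _tree3_prob(inner[0].age, root.age,
                           states[cherry[0].label], states[cherry[1].label],
                           states[outer[0].label], a, b, pi, order)
    raise NetworkError("exact evaluation supports at most three species")


def marginal_trait_likelihood_exact(net: PhyloNetwork, counts: TraitCounts,
                                    model: BinaryTraitModel,
                                    theta: Optional[float] = None,
                                    order: int = 96) -> LikelihoodEstimate:
    """Exact f(A | Psi, Theta, Gamma, u, v) for small instances.

    Requirements: at most three leaf species, one sampled individual per
    species, and every reticulation on a pendant path (a single leaf below
    it).  Then exactly one lineage can traverse each reticulation, the
    network coalescent is the gamma-weighted mixture of the coalescents on
    the displayed trees, and each tree term is integrated over coalescence
    times with Gauss-Legendre / Gauss-Laguerre quadrature (absolute accuracy
    well below 1e-10 at the default order).
    """
    net = net.copy()
    net.validate()
    if not counts.is_pattern():
        raise NetworkError("exact evaluation requires one sample per species")
    if len(net.leaf_labels()) > 3:
        raise NetworkError("exact evaluation supports at most three species")
    if set(net.leaf_labels()) != set(counts.species()):
        raise ValueError("counts species do not match network leaves")
    for r in net.reticulations():
        if len(net.leaves_below(r)) != 1:
            raise NetworkError(
                "exact evaluation requires reticulations on pendant paths")
    a, b = model.rates(theta)
    pi = model.stationary()
    states = {sp: (0 if n1 == 0 else 1)
              for sp, (n0, n1) in counts.counts.items()}
    total = 0.0
    for d in displayed_trees(net):
        if d.weight == 0.0:
            continue
        total += d.weight * _tree_pattern_prob(d.tree, states, a, b, pi, order)
    return LikelihoodEstimate(float(total), 0.0, 0, method="exact")
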