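"""Xenoplasy and hemiplasy risk factors.

The global xenoplasy risk factor (G-XRF) is the natural log of the posterior
odds of a species network Psi versus its gene-flow-free backbone tree T for a
given set of observed state counts:

    G-XRF = ln f(A | Psi, Theta, Gamma, u, v) - ln f(A | T, Theta, u, v)
            + ln(prior odds)

with equal prior odds by default.  Positive values mean the trait pattern is
better explained when introgression is available as a mode of inheritance;
the magnitude is the log Bayes-factor-style support for the network.

The per-branch hemiplasy risk factor (HRF) compares, for one internal branch
of a species *tree*, the probability that the incongruent pattern "one child
clade shares the derived state with the sister clade" arises from a single
mutation on a discordant genealogy (hemiplasy) against the probability that
it arises from two independent mutations (homoplasy).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .network import (PhyloNetwork, NetworkError, displayed_trees,
                      network_signature)
from .likelihood import (BinaryTraitModel, TraitCounts,
                         marginal_trait_likelihood_mc,
                         marginal_trait_likelihood_exact)
from .simulate import RngLike, as_rng, _Draws

__all__ = [
    "GXRFResult",
    "HRFResult",
    "gxrf",
    "gxrf_posterior",
    "likelihood_profile",
    "hrf",
    "hrf_all_branches",
]


@dataclass(frozen=True)
class GXRFResult:
    """G-XRF with the two log marginal likelihoods and Monte-Carlo errors."""

    logL_network: float
    logL_tree: float
    se_network: float
    se_tree: float
    log_prior_odds: float
    gxrf: float
    se: float
    n_genealogies: int
    method: str = "mc"
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "logL_network": self.logL_network,
            "logL_tree": self.logL_tree,
            "se_network": self.se_network,
            "se_tree": self.se_tree,
            "log_prior_odds": self.log_prior_odds,
            "gxrf": self.gxrf,
            "se": self.se,
            "n_genealogies": self.n_genealogies,
            "method": self.method,
            "note": self.note,
        }


def _estimate(phylo, counts, model, theta, n_genealogies, seed, method):
    if method == "exact":
        return marginal_trait_likelihood_exact(phylo, counts, model, theta)
    return marginal_trait_likelihood_mc(phylo, counts, model, theta,
                                        n_genealogies, seed)


def _spawn_seeds(rng_seed, k):
    if isinstance(rng_seed, np.random.Generator):
        base = int(rng_seed.integers(2 ** 31))
    else:
        base = rng_seed
    return [np.random.default_rng(s) for s in np.random.SeedSequence(base).spawn(k)]


def gxrf(net: PhyloNetwork, tree: PhyloNetwork, counts: TraitCounts,
         model: BinaryTraitModel, theta: Optional[float] = None,
         n_genealogies: int = 10_000, rng_seed: RngLike = None,
         log_prior_odds: float = 0.0, method: str = "mc") -> GXRFResult:
    """Global xenoplasy risk factor of ``net`` versus backbone ``tree``.

    The two marginal likelihoods are estimated on independent genealogy
    streams (``method="mc"``, the default) so the combined standard error is
    ``sqrt(se_net^2 + se_tree^2)``; ``method="exact"`` uses quadrature where
    the instance permits.  A warning is issued when ``tree`` is not displayed
    by ``net``.  A zero likelihood estimate yields an infinite G-XRF with a
    diagnostic note.
    """
    tree_sig = network_signature(tree)
    if not any(network_signature(d.tree) == tree_sig
               for d in displayed_trees(net)):
        warnings.warn("backbone tree is not a displayed tree of the network",
                      stacklevel=2)
    r1, r2 = _spawn_seeds(rng_seed, 2)
    est_net = _estimate(net, counts, model, theta, n_genealogies, r1, method)
    est_tree = _estimate(tree, counts, model, theta, n_genealogies, r2, method)
    note = ""
    if est_net.estimate <= 0 or est_tree.estimate <= 0:
        note = ("zero marginal likelihood estimate under "
                + ("network" if est_net.estimate <= 0 else "tree")
                + "; increase n_genealogies")
    value = est_net.log_estimate - est_tree.log_estimate + log_prior_odds
    se = math.hypot(est_net.log_se, est_tree.log_se)
    return GXRFResult(
        logL_network=est_net.log_estimate, logL_tree=est_tree.log_estimate,
        se_network=est_net.log_se, se_tree=est_tree.log_se,
        log_prior_odds=float(log_prior_odds), gxrf=value, se=se,
        n_genealogies=n_genealogies if method == "mc" else 0,
        method=method, note=note)


def gxrf_posterior(pairs: Sequence, counts: TraitCounts,
                   model: Optional[BinaryTraitModel] = None,
                   theta: Optional[float] = None,
                   n_genealogies: int = 10_000,
                   rng_seed: RngLike = None, method: str = "mc"):
    """G-XRF across paired posterior samples of (network, backbone tree).

    Each pair is ``(net, tree)`` or ``(net, tree, params)`` where ``params``
    may override ``theta`` and ``model`` per pair (posterior samples carry
    their own parameter draws).  Returns ``(results, summary)`` where
    ``summary`` holds the box-plot quantiles (min, quartiles, max) of the
    per-pair G-XRF values.
    """
    seeds = _spawn_seeds(rng_seed, max(1, len(pairs)))
    results = []
    for pair, rng in zip(pairs, seeds):
        if len(pair) == 2:
            net, tree = pair
            params = {}
        else:
            net, tree, params = pair[0], pair[1], dict(pair[2])
        results.append(gxrf(net, tree, counts,
                            params.get("model", model),
                            params.get("theta", theta),
                            n_genealogies, rng, method=method))
    if not results:
        return [], {"n": 0, "min": math.nan, "q1": math.nan,
                    "median": math.nan, "q3": math.nan, "max": math.nan}
    values = np.array([r.gxrf for r in results])
    summary = {
        "n": len(results),
        "min": float(values.min()),
        "q1": float(np.quantile(values, 0.25)),
        "median": float(np.quantile(values, 0.5)),
        "q3": float(np.quantile(values, 0.75)),
        "max": float(values.max()),
    }
    return results, summary


def likelihood_profile(phylogenies: Sequence, counts: TraitCounts,
                       model: Optional[BinaryTraitModel] = None,
                       theta: Optional[float] = None,
                       n_genealogies: int = 10_000,
                       rng_seed: RngLike = None,
                       method: str = "mc") -> pd.DataFrame:
    """Log marginal likelihood of the counts under each fixed phylogeny.

    ``phylogenies`` is a sequence of ``(label, phylo)`` or
    ``(label, phylo, params)``; under equal prior odds the log likelihoods
    are directly comparable as log posterior densities across phylogenies.
    """
    seeds = _spawn_seeds(rng_seed, max(1, len(phylogenies)))
    rows = []
    for entry, rng in zip(phylogenies, seeds):
        label, phylo = entry[0], entry[1]
        params = dict(entry[2]) if len(entry) > 2 else {}
        est = _estimate(phylo, counts, params.get("model", model),
                        params.get("theta", theta), n_genealogies, rng, method)
        rows.append({"label": label, "logL": est.log_estimate,
                     "se": est.log_se, "likelihood": est.estimate,
                     "n_genealogies": est.n_genealogies})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hemiplasy risk factor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HRFResult:
    """Per-branch hemiplasy risk: P(hemiplasy)/P(homoplasy) for the pattern
    in which ``derived_clade`` and the sister clade share the derived state."""

    branch: tuple
    derived_clade: tuple
    sister_clade: tuple
    p_hemiplasy: float
    p_homoplasy: float
    hrf: float
    se_hemiplasy: float
    se_homoplasy: float
    se_hrf: float
    n_genealogies: int


def _resolve_branch(tree: PhyloNetwork, branch):
    """Find the internal node whose subtending clade matches ``branch``.

    ``branch`` is a set/sequence of leaf labels (the clade below the branch's
    child node) or a node id.
    """
    if isinstance(branch, (int, np.integer)):
        node = tree.nodes[int(branch)]
    else:
        want = frozenset(branch)
        node = None
        for n in tree.nodes.values():
            if not n.is_leaf and tree.leaves_below(n) == want:
                node = n
                break
        if node is None:
            raise NetworkError(f"no internal branch subtends clade {sorted(want)}")
    if node.is_leaf:
        raise NetworkError("branch must be internal (child node has children)")
    if not node.parent_edges:
        raise NetworkError("the root has no branch above it")
    return node


def _triplet_of_branch(tree: PhyloNetwork, node):
    """Reduce to the rooted triplet induced by the focal internal branch.

    The two clades below the branch's child node and the sister clade are
    each treated as a single lineage originating at its MRCA age; node ages
    are preserved.
    """
    parent = tree.nodes[node.parent_edges[0].parent]
    sisters = [tree.nodes[e.child] for e in parent.child_edges
               if e.child != node.id]
    if len(sisters) != 1:
        raise NetworkError("focal branch parent must be binary")
    sister = sisters[0]
    kids = [tree.nodes[e.child] for e in node.child_edges]
    if len(kids) != 2:
        raise NetworkError("focal branch child must be binary")
    return {
        "t_low": node.age, "t_high": parent.age,
        "child_ages": [kids[0].age, kids[1].age],
        "child_clades": [tuple(sorted(tree.leaves_below(k))) for k in kids],
        "sister_age": sister.age,
        "sister_clade": tuple(sorted(tree.leaves_below(sister))),
    }


def _sample_triplet(t_low, t_high, draws):
    """One MSC genealogy of lineages (d, n, s): d and n may coalesce on the
    focal branch [t_low, t_high); all pairs coalesce at rate 1 above t_high.

    Returns (first_pair, tau1, tau2) with first_pair in {"dn","ds","ns"}.
    """
    w = draws.exp()
    if t_low + w < t_high:
        return "dn", t_low + w, t_high + draws.exp()
    tau1 = t_high + draws.exp() / 3.0
    u = draws.unif()
    pair = "dn" if u < 1.0 / 3.0 else ("ds" if u < 2.0 / 3.0 else "ns")
    return pair, tau1, tau1 + draws.exp()


def _mutation_probs(pair, tau1, tau2, ages, a, b):
    """Exactly-one-mutation (hemiplasy) and exactly-two-mutation (homoplasy)
    probabilities of the pattern "d and s derived, n ancestral" on one
    genealogy, using per-branch Poisson no-mutation / at-least-one factors.

    ``ages`` maps lineage name -> origin age.  The ancestral state at the
    genealogy root is 0; branches below a gain carry the 1-background
    no-back-mutation factor exp(-b*len).
    """
    # branch list: (clade frozenset, length)
    members = {"dn": ("d", "n"), "ds": ("d", "s"), "ns": ("n", "s")}[pair]
    other = ({"d", "n", "s"} - set(members)).pop()
    branches = [
        (frozenset(members[0]), tau1 - ages[members[0]]),
        (frozenset(members[1]), tau1 - ages[members[1]]),
        (frozenset(members), tau2 - tau1),
        (frozenset(other), tau2 - ages[other]),
    ]
    D = frozenset("ds")
    no0 = [math.exp(-a * l) for _, l in branches]  # no forward mutation
    no1 = [math.exp(-b * l) for _, l in branches]  # no backward mutation
    gain = [1.0 - p for p in no0]
    loss = [1.0 - p for p in no1]

    def prob(mutated):
        """P(the given {branch: kind} placements and no other mutation)."""
        p = 1.0
        gains = [i for i, k in mutated.items() if k == "gain"]
        losses = [i for i, k in mutated.items() if k == "loss"]
        for i, (clade, l) in enumerate(branches):
            if i in mutated:
                p *= gain[i] if mutated[i] == "gain" else loss[i]
                continue
            below_gain = any(clade < branches[g][0] for g in gains)
            below_loss = any(clade < branches[lo][0] for lo in losses)
            # background is 1 only strictly below a gain and not below a loss
            p *= no1[i] if (below_gain and not below_loss) else no0[i]
        return p

    p_hemi = 0.0
    for i, (clade, l) in enumerate(branches):
        if clade == D:
            p_hemi += prob({i: "gain"})
    p_homo = 0.0
    nb = len(branches)
    for i in range(nb):
        for j in range(i + 1, nb):
            ci, cj = branches[i][0], branches[j][0]
            if ci.isdisjoint(cj) and (ci | cj) == D:
                p_homo += prob({i: "gain", j: "gain"})
            # gain-then-loss: two mutations, net derived set = D
            for g, lo in ((i, j), (j, i)):
                cg, cl = branches[g][0], branches[lo][0]
                if cl < cg and (cg - cl) == D:
                    p_homo += prob({g: "gain", lo: "loss"})
    return p_hemi, p_homo


def hrf(tree: PhyloNetwork, branch, model: BinaryTraitModel,
        theta: Optional[float] = None, n_genealogies: int = 20_000,
        rng_seed: RngLike = None, derived_child: int = 0) -> HRFResult:
    """Hemiplasy risk factor for one internal branch of a species tree.

    The focal branch is reduced to a rooted triplet (its two child clades and
    its sister clade, each collapsed to a single lineage at its MRCA age);
    genealogies of the triplet are sampled under the multispecies coalescent,
    and for each one the probabilities of producing the incongruent pattern
    (child clade ``derived_child`` and the sister clade derived) with exactly
    one and exactly two mutations are averaged.  HRF is the ratio of the two
    means; it is 0 when hemiplasy is impossible, and large on short, ILS-prone
    branches.
    """
    if not tree.is_tree:
        raise NetworkError("HRF is defined on species trees (no reticulations)")
    tree = tree.copy()
    tree.validate()
    node = _resolve_branch(tree, branch)
    trip = _triplet_of_branch(tree, node)
    a, b = model.rates(theta)
    ages = {"d": trip["child_ages"][derived_child],
            "n": trip["child_ages"][1 - derived_child],
            "s": trip["sister_age"]}
    draws = _Draws(as_rng(rng_seed))
    hemi = np.empty(n_genealogies)
    homo = np.empty(n_genealogies)
    for r in range(n_genealogies):
        pair, tau1, tau2 = _sample_triplet(trip["t_low"], trip["t_high"], draws)
        hemi[r], homo[r] = _mutation_probs(pair, tau1, tau2, ages, a, b)
    mh, mo = float(hemi.mean()), float(homo.mean())
    sh = float(hemi.std(ddof=1) / math.sqrt(n_genealogies))
    so = float(homo.std(ddof=1) / math.sqrt(n_genealogies))
    if mo > 0:
        ratio = mh / mo
        se_r = ratio * math.hypot(sh / mh if mh > 0 else 0.0, so / mo)
    else:
        ratio, se_r = (0.0, 0.0) if mh == 0 else (math.inf, math.inf)
    return HRFResult(
        branch=tuple(sorted(tree.leaves_below(node))),
        derived_clade=trip["child_clades"][derived_child],
        sister_clade=trip["sister_clade"],
        p_hemiplasy=mh, p_homoplasy=mo, hrf=ratio,
        se_hemiplasy=sh, se_homoplasy=so, se_hrf=se_r,
        n_genealogies=n_genealogies)


def hrf_all_branches(tree: PhyloNetwork, model: BinaryTraitModel,
                     theta: Optional[float] = None,
                     n_genealogies: int = 20_000,
                     rng_seed: RngLike = None,
                     derived_child: int = 0) -> pd.DataFrame:
    """HRF for every internal branch of ``tree`` (one row per branch)."""
    tree = tree.copy()
    tree.validate()
    internal = [n for n in tree.nodes.values()
                if not n.is_leaf and n.parent_edges]
    internal.sort(key=lambda n: (len(tree.leaves_below(n)),
                                 sorted(tree.leaves_below(n))))
    seeds = _spawn_seeds(rng_seed, max(1, len(internal)))
    rows = []
    for node, rng in zip(internal, seeds):
        res = hrf(tree, node.id, model, theta, n_genealogies, rng,
                  derived_child=derived_child)
        d = res.__dict__.copy()
        rows.append(d)
    return pd.DataFrame(rows)
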