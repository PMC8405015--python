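"""Benchmark networks and parameter-grid studies.

Two fixture families are provided:

* :func:`three_taxon_network` -- the canonical three-taxon scenario: an
  underlying species tree (A,(B,C)) with divergence times T1 < T2, plus a
  reticulation from A's lineage into B's pendant edge at time T_r with
  inheritance probability gamma (the probability that a locus in B traces
  its ancestry through A's lineage).
* :func:`six_taxon_network` -- a six-taxon, two-reticulation benchmark whose
  topology follows a published anopheline phylogeny, with two introgression
  events at time 0.25 (lineage retention probabilities 0.3 and 0.8) and
  divergences at 0.5, 0.75, 1.0, 2.0 and 2.5.

:func:`run_grid` sweeps G-XRF over grids of the evolutionary parameters
(internal branch length, gamma, reticulation time, theta, forward/backward
rate ratio, and the derived-allele frequency in taxon B).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd

from .network import PhyloNetwork, parse_extended_newick, backbone_tree
from .likelihood import BinaryTraitModel, TraitCounts
from .risk import gxrf

__all__ = [
    "three_taxon_network",
    "six_taxon_network",
    "GridSpec",
    "run_grid",
    "GRID_AXES",
]

#: Parameter ranges explored in the grid studies; values outside are allowed
#: but flagged in the output table.
GRID_AXES = {
    "internal_branch": (0.001, 10.0),
    "gamma": (0.0, 1.0),
    "t_r": (0.0, 1.0),
    "theta": (0.001, 0.01),
    "rate_ratio": (0.1, 10.0),
    "b_derived_freq": (0.0, 1.0),
}


def three_taxon_network(t1: float = 1.0, t2: float = 2.0, t_r: float = 0.1,
                        gamma: float = 0.3) -> PhyloNetwork:
    """Species network (A,(B,C)) with introgression from A into B.

    ``t1`` is the (B,C) divergence, ``t2`` the root age, ``t_r`` the
    reticulation time and ``gamma`` the inheritance probability of the
    introgression (transfer) edge; all times in coalescent units.  The
    transfer edge is marked secondary, so ``backbone_tree(net, "primary")``
    always returns the underlying species tree (A,(B,C)).
    """
    if not (0.0 < t_r < t1 < t2):
        raise ValueError(f"need 0 < t_r < t1 < t2, got {(t_r, t1, t2)}")
    if not (0.0 <= gamma <= 1.0):
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    s = (f"((A:{t_r!r},#H1:0::{gamma!r}):{t2 - t_r!r},"
         f"((B:{t_r!r})#H1:{t1 - t_r!r}::{1.0 - gamma!r},C:{t1!r})"
         f":{t2 - t1!r});")
    return parse_extended_newick(s)


#: Six-taxon two-reticulation benchmark (see :func:`six_taxon_network`).
#: Event times are carried verbatim from the generating coalescent-simulation
#: recipe; note that Hudson-style simulators measure time in units of 4N
#: generations while this package uses 2N, so absolute ages here differ from
#: that convention by a factor of two if rescaled.  The fixture preserves the
#: printed numbers.
SIX_TAXON_NEWICK = (
    "((((Q:0.25)#H1:0.5::0.3,R:0.75):1.25,"
    "(((A:0.25)#H2:0.25::0.8,#H1:0.25::0.7):0.5,L:1.0):1.0):0.5,"
    "(G:1.0,(#H2:0.25::0.2,C:0.5):0.5):1.5);"
)


def six_taxon_network() -> PhyloNetwork:
    """Six-taxon benchmark network with two reticulations.

    Taxa A, C, G, L, Q, R; divergences at 0.5, 0.75, 1.0, 2.0, 2.5 and two
    introgression events at time 0.25: Q's lineage traces through A's
    ancestral population with probability 0.7 (retention 0.3), and A's
    lineage traces through C's ancestral population with probability 0.2
    (retention 0.8).  The major tree therefore removes the two
    lower-probability edges (0.3 and 0.2).
    """
    return parse_extended_newick(SIX_TAXON_NEWICK)


@dataclass
class GridSpec:
    """A G-XRF parameter grid.

    ``axes`` maps parameter names (keys of :data:`GRID_AXES`) to value lists;
    ``fixed`` overrides the scenario defaults for non-axis parameters.
    Defaults: t1 = 1 (the baseline internode interval), internal branch 1,
    gamma 0.5, t_r 0.1, theta 0.01, rate ratio 1, monomorphic pattern
    (A=1, B=1, C=0); ``b_samples`` individuals are drawn from B when the
    ``b_derived_freq`` axis is used.
    """

    axes: dict
    fixed: dict = dc_field(default_factory=dict)
    n_genealogies: int = 5_000
    seed: Optional[int] = None
    backbone: object = "primary"
    b_samples: int = 10

    def __post_init__(self):
        if len(self.axes) > 4:
            raise ValueError("at most 4 varying axes")
        for name in list(self.axes) + list(self.fixed):
            if name not in GRID_AXES and name not in ("t1",):
                raise ValueError(f"unknown grid parameter {name!r}")


_DEFAULTS = {"t1": 1.0, "internal_branch": 1.0, "gamma": 0.5, "t_r": 0.1,
             "theta": 0.01, "rate_ratio": 1.0}

_TR_FLOOR = 1e-6  # a reticulation at age 0 would coincide with the leaves


def _cell_counts(params, b_samples) -> TraitCounts:
    if "b_derived_freq" in params:
        k = int(round(params["b_derived_freq"] * b_samples))
        return TraitCounts({"A": (0, 1), "B": (b_samples - k, k), "C": (1, 0)})
    return TraitCounts.from_pattern({"A": 1, "B": 1, "C": 0})


def run_grid(grid: GridSpec, counts_template: Optional[TraitCounts] = None
             ) -> pd.DataFrame:
    """Evaluate G-XRF on every cell of the grid (one row per cell).

    Each cell builds the three-taxon network from its parameters, extracts
    the gene-flow-free backbone per ``grid.backbone``, and estimates the two
    marginal likelihoods with ``grid.n_genealogies`` genealogies on per-cell
    substreams of ``grid.seed`` (the table is deterministic for a fixed
    spec and seed).
    """
    names = list(grid.axes)
    cells = list(itertools.product(*[grid.axes[n] for n in names]))
    seeds = np.random.SeedSequence(grid.seed).spawn(max(1, len(cells)))
    rows = []
    for cell, cell_seed in zip(cells, seeds):
        params = dict(_DEFAULTS)
        params.update(grid.fixed)
        params.update(dict(zip(names, cell)))
        t1 = params["t1"]
        t2 = t1 + params["internal_branch"]
        t_r = max(params["t_r"], _TR_FLOOR)
        net = three_taxon_network(t1=t1, t2=t2, t_r=t_r,
                                  gamma=params["gamma"])
        tree = backbone_tree(net, grid.backbone)
        model = BinaryTraitModel.from_ratio(params["rate_ratio"])
        counts = counts_template if counts_template is not None \
            else _cell_counts(params, grid.b_samples)
        res = gxrf(net, tree, counts, model, theta=params["theta"],
                   n_genealogies=grid.n_genealogies,
                   rng_seed=np.random.default_rng(cell_seed))
        row = {n: params[n] for n in names}
        row.update({
            "logL_network": res.logL_network, "logL_tree": res.logL_tree,
            "gxrf": res.gxrf, "se_network": res.se_network,
            "se_tree": res.se_tree, "se": res.se,
            "in_paper_range": all(
                GRID_AXES[n][0] <= params[n] <= GRID_AXES[n][1]
                for n in names if n in GRID_AXES),
        })
        rows.append(row)
    return pd.DataFrame(rows)


def plot_grid(table: pd.DataFrame, x: str, y: str, value: str = "gxrf",
              path: Optional[str] = None):
    """Heat-map of a two-axis grid table (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = table.pivot_table(index=y, columns=x, values=value)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.pcolormesh(pivot.columns, pivot.index, pivot.values,
                       shading="nearest", cmap="RdBu_r")
    fig.colorbar(im, ax=ax, label=value)
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
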