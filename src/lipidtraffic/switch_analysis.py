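"""Binary Switch Analysis.

For each phenotype, lipid variables are categorised by where they are
detected on the compartment network:

* **A** — present in every compartment (ubiquitous);
* **B(axis)** — present at both endpoints of an axis but not ubiquitous,
  labelled with the axis direction code (e.g. ``B_LS``);
* **U(compartment)** — present in a compartment and absent from all of its
  neighbours.  Co-presence in *non-adjacent* compartments still counts as
  U in each (the rule is literally "not its neighbours").

Phenotypes are then compared per axis: the two lists of variables
travelling the axis are scored with the Jaccard-Tanimoto coefficient
J = |X∩Y| / |X∪Y|, and a p-value for the probability that a dissimilarity
at least as large arises when both lists are redrawn as uniformly random
subsets (of the observed sizes) of their union.  Re-routing — a variable
leaving one hub axis in the control phenotype and appearing on another hub
axis in the experimental phenotype — is detected set-theoretically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Set

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .dataset_io import PresenceMap
from .errors import DataError, NetworkError, UndefinedStatisticError
from .network_model import CompartmentNetwork

__all__ = [
    "SwitchCategories",
    "SwitchReport",
    "AxisComparison",
    "categorize",
    "jaccard",
    "jaccard_pvalue",
    "compare_axis",
    "compare_all_axes",
    "find_rerouted",
    "routing_diagram",
    "routing_dot",
    "counts_table",
    "report_frame",
]


# ----------------------------------------------------------------------
# Categorisation
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SwitchCategories:
    """A/B/U assignment for one phenotype."""

    phenotype: str
    set_a: frozenset[str]
    set_b: Mapping[str, frozenset[str]]  # axis label -> variables
    set_u: Mapping[str, frozenset[str]]  # compartment -> variables

    def all_variables(self) -> frozenset[str]:
        out = set(self.set_a)
        for s in self.set_b.values():
            out |= s
        for s in self.set_u.values():
            out |= s
        return frozenset(out)


def categorize(
    presence: PresenceMap, network: CompartmentNetwork, phenotype: str
) -> SwitchCategories:
    """Assign every detected variable of one phenotype to A, B and/or U.

    A is the intersection over all compartments; B(axis) is presence at both
    axis endpoints minus A; U(c) is presence at c with absence from every
    neighbour of c.
    """
    present = {c: presence.present(c, phenotype) for c in network.nodes}
    set_a = frozenset(frozenset.intersection(*present.values()))
    set_b = {
        ax.label: frozenset((present[ax.source] & present[ax.target]) - set_a)
        for ax in network.axes
    }
    set_u = {
        c: frozenset(
            present[c].difference(*(present[n] for n in network.neighbours(c)))
        )
        for c in network.nodes
    }
    return SwitchCategories(phenotype=phenotype, set_a=set_a, set_b=set_b, set_u=set_u)


# ----------------------------------------------------------------------
# Jaccard-Tanimoto statistics
# ----------------------------------------------------------------------
def jaccard(list_x: Set[str], list_y: Set[str]) -> float:
    """Jaccard-Tanimoto coefficient |X∩Y| / |X∪Y|.

    Undefined (raises) when both sets are empty: neither 0 nor 1 would be a
    faithful similarity of two empty lists.
    """
    x, y = set(list_x), set(list_y)
    union = x | y
    if not union:
        raise UndefinedStatisticError("Jaccard coefficient of two empty sets")
    return len(x & y) / len(union)


def _mc_intersections(
    n: int, size_x: int, size_y: int, draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulate |X'∩Y'| for independent uniform random subsets of sizes
    (size_x, size_y) from an n-element universe, by genuinely drawing the
    subsets (kept distinct from the closed-form route on purpose)."""
    member_x = np.zeros((draws, n), dtype=bool)
    member_y = np.zeros((draws, n), dtype=bool)
    rows = np.arange(draws)[:, None]
    if size_x:
        idx = np.argpartition(rng.random((draws, n)), size_x - 1, axis=1)[:, :size_x]
        member_x[rows, idx] = True
    if size_y:
        idx = np.argpartition(rng.random((draws, n)), size_y - 1, axis=1)[:, :size_y]
        member_y[rows, idx] = True
    return (member_x & member_y).sum(axis=1)


def jaccard_pvalue(
    list_x: Set[str],
    list_y: Set[str],
    universe: Optional[Set[str]] = None,
    method: str = "exact",
    draws: int = 10_000,
    seed: Optional[int | np.random.Generator] = None,
) -> float:
    """p-value that the observed dissimilarity of two variable lists arose
    by random chance.

    Null model: X′ and Y′ are redrawn independently as uniformly random
    subsets of the universe with the observed sizes |X| and |Y|; the
    p-value is P(J(X′, Y′) ≤ J_observed).  With fixed sizes J is a strictly
    increasing function of the intersection size k, and k is
    hypergeometric, so ``method="exact"`` sums the hypergeometric mass over
    all subset-pair configurations with k ≤ k_observed — a complete
    enumeration collapsed by symmetry, tractable at any size.
    ``method="montecarlo"`` simulates ``draws`` actual subset pairs with
    the given ``seed`` (an integer or a shared ``numpy.random.Generator``).
    """
    x, y = set(list_x), set(list_y)
    uni = set(universe) if universe is not None else x | y
    if not x and not y:
        raise UndefinedStatisticError("Jaccard p-value of two empty sets")
    if not x <= uni or not y <= uni:
        raise UndefinedStatisticError("lists must be subsets of the universe")
    n, sx, sy = len(uni), len(x), len(y)
    k_obs = len(x & y)
    if method == "exact":
        # P(K <= k_obs), K ~ Hypergeometric(population n, successes sx, draws sy)
        return float(hypergeom.cdf(k_obs, n, sx, sy))
    if method == "montecarlo":
        if draws < 1:
            raise UndefinedStatisticError(f"draws must be >= 1, got {draws}")
        rng = np.random.default_rng(seed)
        k = _mc_intersections(n, sx, sy, draws, rng)
        # J monotone in k at fixed sizes, so J' <= J_obs  <=>  k' <= k_obs
        return float(np.mean(k <= k_obs))
    raise UndefinedStatisticError(f"unknown method {method!r}")


# ----------------------------------------------------------------------
# Per-axis phenotype comparison
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class AxisComparison:
    """Counts, Jaccard-Tanimoto coefficient and p-value for one axis."""

    axis_label: str
    n_control: int
    n_experimental: int
    jaccard: float
    p_value: float
    include_ubiquitous: bool = True
    method: str = "exact"


@dataclass(frozen=True)
class SwitchReport:
    """Full switch analysis of a control/experimental phenotype pair."""

    network: CompartmentNetwork
    control: str
    experimental: str
    categories: Mapping[str, SwitchCategories]
    presence: PresenceMap

    @classmethod
    def build(
        cls,
        presence: PresenceMap,
        network: CompartmentNetwork,
        control: str,
        experimental: str,
    ) -> "SwitchReport":
        cats = {
            p: categorize(presence, network, p) for p in (control, experimental)
        }
        return cls(
            network=network,
            control=control,
            experimental=experimental,
            categories=cats,
            presence=presence,
        )

    def axis_variables(
        self, phenotype: str, axis_label: str, include_ubiquitous: bool = True
    ) -> frozenset[str]:
        """Variables travelling an axis: present at both endpoints.  With
        ``include_ubiquitous`` (default) A-type variables are included, since
        they demonstrably traverse every axis; otherwise B-type only."""
        cats = self.categories[phenotype]
        b = cats.set_b[self._check_axis(axis_label)]
        return frozenset(b | cats.set_a) if include_ubiquitous else b

    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for cats in self.categories.values():
            out |= cats.all_variables()
        return frozenset(out)

    def _check_axis(self, axis_label: str) -> str:
        self.network.axis(axis_label)  # raises NetworkError if unknown
        return axis_label


def compare_axis(
    report: SwitchReport,
    axis_label: str,
    include_ubiquitous: bool = True,
    method: str = "exact",
    draws: int = 10_000,
    seed: Optional[int] = None,
) -> AxisComparison:
    """Compare the two phenotypes' variable lists on one axis."""
    lx = report.axis_variables(report.control, axis_label, include_ubiquitous)
    ly = report.axis_variables(report.experimental, axis_label, include_ubiquitous)
    if lx or ly:
        j = jaccard(lx, ly)
        p = jaccard_pvalue(lx, ly, method=method, draws=draws, seed=seed)
    else:
        j = math.nan
        p = math.nan
    return AxisComparison(
        axis_label=axis_label,
        n_control=len(lx),
        n_experimental=len(ly),
        jaccard=j,
        p_value=p,
        include_ubiquitous=include_ubiquitous,
        method=method,
    )


def compare_all_axes(
    report: SwitchReport,
    include_ubiquitous: bool = True,
    method: str = "exact",
    draws: int = 10_000,
    seed: Optional[int] = None,
) -> list[AxisComparison]:
    return [
        compare_axis(report, ax.label, include_ubiquitous, method, draws, seed)
        for ax in report.network.axes
    ]


def find_rerouted(
    report: SwitchReport, from_axis: str, to_axis: str
) -> frozenset[str]:
    """Variables re-routed between two hub axes across phenotypes.

    A variable is re-routed when it travels ``from_axis`` in the control
    phenotype but not in the experimental one, and travels ``to_axis`` in
    the experimental phenotype but not in the control.  The two axes must
    share an endpoint (the hub) for re-routing to be meaningful.
    """
    ax_from = report.network.axis(from_axis)
    ax_to = report.network.axis(to_axis)
    if from_axis == to_axis:
        raise NetworkError("from_axis and to_axis must differ")
    if not ax_from.endpoints & ax_to.endpoints:
        raise NetworkError(
            f"axes {from_axis!r} and {to_axis!r} share no endpoint; "
            "re-routing is defined between axes with a common compartment"
        )
    on = report.axis_variables
    ctrl, expt = report.control, report.experimental
    return frozenset(
        (on(ctrl, from_axis) - on(expt, from_axis))
        & (on(expt, to_axis) - on(ctrl, to_axis))
    )


# ----------------------------------------------------------------------
# Routing diagrams and tabular exports
# ----------------------------------------------------------------------
def routing_diagram(report: SwitchReport, variables: Set[str]) -> nx.MultiGraph:
    """Routing graph for a set of variables: one edge per (variable,
    phenotype, axis) where the variable is present at both axis endpoints —
    the machine-readable form of an underground-map style wiring diagram."""
    unknown = set(variables) - report.universe()
    if unknown:
        raise DataError(f"variables not in the switch report: {sorted(unknown)}")
    g = nx.MultiGraph()
    g.add_nodes_from(report.network.nodes)
    for phenotype in (report.control, report.experimental):
        for ax in report.network.axes:
            on_axis = report.axis_variables(phenotype, ax.label) & set(variables)
            for var in sorted(on_axis):
                g.add_edge(
                    ax.source,
                    ax.target,
                    key=f"{var}|{phenotype}",
                    variable=var,
                    phenotype=phenotype,
                    axis=ax.label,
                )
    return g


def routing_dot(graph: nx.MultiGraph) -> str:
    """Serialise a routing graph as Graphviz DOT."""
    lines = ["graph routing {"]
    for node in graph.nodes:
        lines.append(f'  "{node}";')
    for u, v, data in graph.edges(data=True):
        label = f"{data.get('variable', '')} [{data.get('phenotype', '')}]"
        lines.append(f'  "{u}" -- "{v}" [label="{label}", axis="{data.get("axis", "")}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def counts_table(report: SwitchReport) -> pd.DataFrame:
    """Category counts per phenotype — the numbers behind pie-chart style
    summaries: one row per (phenotype, category) where category is ``A``,
    ``B:<axis>`` or ``U:<compartment>``."""
    rows = []
    for phenotype, cats in report.categories.items():
        rows.append({"phenotype": phenotype, "category": "A", "count": len(cats.set_a)})
        for label, s in cats.set_b.items():
            rows.append(
                {"phenotype": phenotype, "category": f"B:{label}", "count": len(s)}
            )
        for comp, s in cats.set_u.items():
            rows.append(
                {"phenotype": phenotype, "category": f"U:{comp}", "count": len(s)}
            )
    return pd.DataFrame(rows)


def report_frame(report: SwitchReport) -> pd.DataFrame:
    """Long-form switch report: one row per variable × phenotype × category
    assignment (a variable can hold several B/U assignments)."""
    rows = []
    for phenotype, cats in report.categories.items():
        for var in sorted(cats.set_a):
            rows.append(
                {"variable": var, "phenotype": phenotype, "category": "A", "where": "all"}
            )
        for label, s in cats.set_b.items():
            for var in sorted(s):
                rows.append(
                    {"variable": var, "phenotype": phenotype, "category": "B", "where": label}
                )
        for comp, s in cats.set_u.items():
            for var in sorted(s):
                rows.append(
                    {"variable": var, "phenotype": phenotype, "category": "U", "where": comp}
                )
    return pd.DataFrame(rows, columns=["variable", "phenotype", "category", "where"])
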