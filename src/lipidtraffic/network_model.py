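"""Tissue-compartment networks.

The traffic network models systemic lipid distribution driven by hepatic
biosynthesis: lipids made in the liver (origin) enter the circulation
(serum, the hub) and reach terminal tissues — CNS compartments for
structural lipids, heart for fatty-acid oxidation, adipose for storage.
Edges are read origin → terminus and labelled with pairs of one-letter
codes (``LS`` = liver→serum).  The network carries topology only; no
fluxes or rates are attached to edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import networkx as nx

from .errors import NetworkError

__all__ = ["Axis", "CompartmentNetwork", "preset_network", "axes", "PRESET_NAMES"]


@dataclass(frozen=True)
class Axis:
    """One network edge read origin→terminus, with its two-letter label."""

    source: str
    target: str
    label: str

    @property
    def endpoints(self) -> frozenset[str]:
        return frozenset((self.source, self.target))


@dataclass(frozen=True)
class CompartmentNetwork:
    """A star-shaped traffic network: origin — hub — termini.

    ``nodes`` keeps a deterministic order (origin, hub, termini in the order
    given); edges are exactly origin→hub plus hub→terminus for every
    terminus, so each axis is hub-mediated.
    """

    origin: str
    hub: str
    termini: tuple[str, ...]
    name: Optional[str] = None

    def __post_init__(self) -> None:
        seen = [self.origin, self.hub, *self.termini]
        if len(set(seen)) != len(seen):
            raise NetworkError(f"duplicate compartment names in {seen}")
        if not self.termini:
            raise NetworkError("a network needs at least one terminus")
        # letter codes are computed eagerly so an unlabellable network fails fast
        object.__setattr__(self, "_codes", _assign_letter_codes(seen))

    # -- structure -----------------------------------------------------
    @property
    def nodes(self) -> tuple[str, ...]:
        return (self.origin, self.hub, *self.termini)

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        """Ordered pairs read origin→terminus direction."""
        return ((self.origin, self.hub),) + tuple((self.hub, t) for t in self.termini)

    @property
    def letter_codes(self) -> Mapping[str, str]:
        return dict(self._codes)  # type: ignore[attr-defined]

    @property
    def axes(self) -> tuple[Axis, ...]:
        codes = self._codes  # type: ignore[attr-defined]
        return tuple(
            Axis(u, v, codes[u] + codes[v]) for (u, v) in self.edges
        )

    def axis(self, label: str) -> Axis:
        for ax in self.axes:
            if ax.label == label:
                return ax
        raise NetworkError(
            f"unknown axis {label!r}; available: {[a.label for a in self.axes]}"
        )

    def neighbours(self, node: str) -> frozenset[str]:
        if node not in self.nodes:
            raise NetworkError(f"unknown compartment {node!r}")
        out = set()
        for u, v in self.edges:
            if u == node:
                out.add(v)
            elif v == node:
                out.add(u)
        return frozenset(out)

    # -- interop -------------------------------------------------------
    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(name=self.name or "")
        for n in self.nodes:
            g.add_node(n, code=self._codes[n])  # type: ignore[attr-defined]
        for ax in self.axes:
            g.add_edge(ax.source, ax.target, label=ax.label)
        return g

    def to_dot(self) -> str:
        lines = [f'digraph "{self.name or "lipid_traffic"}" {{']
        for n in self.nodes:
            role = (
                "origin" if n == self.origin else "hub" if n == self.hub else "terminus"
            )
            lines.append(f'  "{n}" [role={role}];')
        for ax in self.axes:
            lines.append(f'  "{ax.source}" -> "{ax.target}" [label="{ax.label}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, config: Mapping[str, object]) -> "CompartmentNetwork":
        """Build a custom network from a config mapping with keys ``origin``,
        ``hub``, ``termini`` and optional ``name``."""
        try:
            origin = str(config["origin"])
            hub = str(config["hub"])
            termini = tuple(str(t) for t in config["termini"])  # type: ignore[union-attr]
        except (KeyError, TypeError) as exc:
            raise NetworkError(
                "network config must provide 'origin', 'hub' and 'termini'"
            ) from exc
        return cls(origin=origin, hub=hub, termini=termini, name=config.get("name"))  # type: ignore[arg-type]


def _assign_letter_codes(nodes: Sequence[str]) -> dict[str, str]:
    """One uppercase letter per compartment: the first letter of its name not
    already taken, falling back to subsequent letters deterministically."""
    codes: dict[str, str] = {}
    used: set[str] = set()
    for node in nodes:
        letters = [c.upper() for c in node if c.isalpha()]
        if not letters:
            raise NetworkError(f"compartment name {node!r} has no letters")
        for letter in letters:
            if letter not in used:
                codes[node] = letter
                used.add(letter)
                break
        else:
            raise NetworkError(
                f"cannot assign a distinct letter to {node!r}: all of {letters} taken"
            )
    return codes


#: Study-design presets.  Neonates lack adipose (too small to dissect); the
#: brains of F1 adults and F2 neonates were split into cerebellum and right
#: hemisphere, profiled separately.
_PRESETS: dict[str, CompartmentNetwork] = {
    "F1N": CompartmentNetwork("liver", "serum", ("brain", "heart"), name="F1N"),
    "F1A": CompartmentNetwork(
        "liver", "serum", ("cerebellum", "right brain", "heart", "adipose"), name="F1A"
    ),
    "F2N": CompartmentNetwork(
        "liver", "serum", ("cerebellum", "right brain", "heart"), name="F2N"
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset_network(name: str) -> CompartmentNetwork:
    """Return one of the study networks: ``F1N`` (4 nodes), ``F1A`` (6) or
    ``F2N`` (5)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise NetworkError(
            f"unknown preset {name!r}; available presets: {sorted(_PRESETS)}"
        ) from None


def axes(network: CompartmentNetwork) -> list[Axis]:
    """Enumerate the network's axes origin→terminus with direction labels."""
    return list(network.axes)
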