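"""Lipid shorthand nomenclature at sum-composition resolution.

Lipidomics by direct-infusion MS reports species as ``CLASS(C:D)`` where
``C`` is the total number of acyl carbons and ``D`` the total number of
carbon-carbon double bonds, e.g. ``TG(52:5)`` is a triglyceride with 52
carbons and 5 double bonds across its three chains.  Ether/plasmalogen
classes carry an ``-O`` suffix on the class code (``PC-O``, ``PE-O``).
Composition-free species such as cholesterol are plain class codes
(``Chol``).  No sn-position or individual-chain information is modelled:
sum composition is the resolution at which the traffic analysis operates.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

from .errors import LipidNameError

__all__ = [
    "KNOWN_CLASSES",
    "COMPOSITION_FREE_CLASSES",
    "LipidSpecies",
    "UnknownLipidClassWarning",
    "parse_lipid_name",
    "is_odd_chain",
    "tag_dnl_markers",
    "DnlTags",
]

#: Class codes recognised without a warning.  Covers the glycerolipids,
#: glycerophospholipids, lyso-species, sphingolipids and sterols commonly
#: annotated in direct-infusion lipidomics.
KNOWN_CLASSES = frozenset(
    {
        "CE",
        "Cer",
        "Chol",
        "DG",
        "DG-O",
        "FA",
        "LPA",
        "LPC",
        "LPC-O",
        "LPE",
        "LPE-O",
        "LPG",
        "LPI",
        "LPS",
        "MG",
        "PA",
        "PC",
        "PC-O",
        "PE",
        "PE-O",
        "PG",
        "PI",
        "PS",
        "SM",
        "TG",
        "TG-O",
    }
)

#: Classes reported without a (C:D) composition.
COMPOSITION_FREE_CLASSES = frozenset({"Chol", "CE"})


class UnknownLipidClassWarning(UserWarning):
    """Emitted when a class code is not in :data:`KNOWN_CLASSES`; the name is
    preserved verbatim rather than rejected."""


_NAME_RE = re.compile(
    r"""^\s*
        (?P<cls>[A-Za-z][A-Za-z0-9]*(?:-O)?)        # class code, optional ether suffix
        \s*
        (?:\(\s*(?P<c>\d+)\s*:\s*(?P<d>\d+)\s*\))?  # optional sum composition
        \s*
        (?P<pw>\(PW\))?                             # petrol-washed provenance tag
        \s*$""",
    re.VERBOSE,
)


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid variable at sum-composition resolution.

    Attributes
    ----------
    raw_name:
        The name as supplied, whitespace and provenance tags included.
    lipid_class:
        Class code, e.g. ``TG``, ``PC-O``.
    total_carbons, double_bonds:
        Sum composition; both present or both absent (composition-free
        classes such as ``Chol``).
    ether:
        True iff the class code carries the ``-O`` plasmalogen/ether suffix.
    mode_hint:
        Optional ionisation-mode tag (``positive``/``negative``) carried as
        annotation only.
    petrol_washed:
        Provenance flag stripped from a trailing ``(PW)`` tag (adipose
        samples washed with petroleum spirit to concentrate phospholipids).
        Not part of species identity.
    recognized:
        False when the class code is not in :data:`KNOWN_CLASSES`.
    """

    raw_name: str = field(compare=False)
    lipid_class: str
    total_carbons: Optional[int] = None
    double_bonds: Optional[int] = None
    ether: bool = False
    mode_hint: Optional[str] = None
    petrol_washed: bool = field(default=False, compare=False)
    recognized: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        if (self.total_carbons is None) != (self.double_bonds is None):
            raise LipidNameError(
                f"{self.raw_name!r}: total_carbons and double_bonds must both "
                "be present or both absent"
            )
        if self.ether != self.lipid_class.endswith("-O"):
            raise LipidNameError(
                f"{self.raw_name!r}: ether flag must mirror the '-O' class suffix"
            )
        if self.total_carbons is not None and (
            self.total_carbons < 0 or self.double_bonds < 0
        ):
            raise LipidNameError(f"{self.raw_name!r}: negative composition")

    @property
    def has_composition(self) -> bool:
        return self.total_carbons is not None

    @property
    def canonical_name(self) -> str:
        """Canonical form ``CLASS(C:D)`` (or bare ``CLASS``); provenance tags
        and whitespace are not part of identity."""
        if self.total_carbons is None:
            return self.lipid_class
        return f"{self.lipid_class}({self.total_carbons}:{self.double_bonds})"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical_name


def parse_lipid_name(name: str, mode_hint: Optional[str] = None) -> LipidSpecies:
    """Parse a shorthand lipid name into a :class:`LipidSpecies`.

    Accepts ``CLASS`` or ``CLASS(C:D)`` with an optional ``-O`` suffix on the
    class code and an optional trailing ``(PW)`` provenance tag.  Unknown
    class codes are preserved verbatim with an :class:`UnknownLipidClassWarning`.

    Raises
    ------
    LipidNameError
        For malformed composition tokens, naming the offending token.
    """
    if not isinstance(name, str) or not name.strip():
        raise LipidNameError(f"empty or non-text lipid name: {name!r}")
    m = _NAME_RE.match(name)
    if m is None:
        # Diagnose the offending token for a useful message.
        stripped = name.strip()
        if stripped.count("(") != stripped.count(")"):
            raise LipidNameError(
                f"{name!r}: unbalanced parentheses in composition token"
            )
        comp = re.search(r"\(([^)]*)\)", stripped)
        if comp is not None and comp.group(1) != "PW":
            raise LipidNameError(
                f"{name!r}: malformed composition token ({comp.group(1)!r}); "
                "expected integer C:D such as (52:5)"
            )
        raise LipidNameError(f"{name!r}: not of the form CLASS or CLASS(C:D)")
    cls = m.group("cls")
    carbons = m.group("c")
    bonds = m.group("d")
    recognized = cls in KNOWN_CLASSES
    if not recognized:
        warnings.warn(
            f"unknown lipid class code {cls!r} in {name!r}; kept verbatim",
            UnknownLipidClassWarning,
            stacklevel=2,
        )
    return LipidSpecies(
        raw_name=name,
        lipid_class=cls,
        total_carbons=None if carbons is None else int(carbons),
        double_bonds=None if bonds is None else int(bonds),
        ether=cls.endswith("-O"),
        mode_hint=mode_hint,
        petrol_washed=m.group("pw") is not None,
        recognized=recognized,
    )


def is_odd_chain(species: LipidSpecies | str) -> bool:
    """True iff the species must contain at least one odd-numbered fatty-acid
    chain: an odd *total* carbon count cannot be assembled from even-length
    chains only.

    Raises
    ------
    LipidNameError
        For composition-free classes (e.g. ``Chol``) where the question does
        not apply.
    """
    if isinstance(species, str):
        species = parse_lipid_name(species)
    if species.total_carbons is None:
        raise LipidNameError(
            f"{species.canonical_name}: odd-chain status is not applicable to a "
            "composition-free class"
        )
    return species.total_carbons % 2 == 1


class DnlTags(NamedTuple):
    """Result of :func:`tag_dnl_markers`: per-species boolean tags plus any
    marker names that matched no species."""

    tags: tuple[bool, ...]
    unmatched_markers: tuple[str, ...]


def tag_dnl_markers(
    species_list: Sequence[LipidSpecies | str],
    marker_names: Iterable[str],
) -> DnlTags:
    """Tag species that are in a user-supplied list of de novo lipogenesis
    (DNL) markers, by exact canonical-name match.

    The marker set is study-specific configuration (typically a handful of
    saturated/monounsaturated TG species); it is matched after
    canonicalisation so ``"TG( 48:0 )"`` matches ``"TG(48:0)"``.
    """

    def canon(item: LipidSpecies | str) -> str:
        return item.canonical_name if isinstance(item, LipidSpecies) else parse_lipid_name(item).canonical_name

    markers = {canon(m) for m in marker_names}
    if not markers:
        warnings.warn(
            "empty DNL marker list: every species tagged False",
            UserWarning,
            stacklevel=2,
        )
        return DnlTags(tuple(False for _ in species_list), ())
    names = [canon(s) for s in species_list]
    tags = tuple(n in markers for n in names)
    unmatched = tuple(sorted(markers.difference(names)))
    return DnlTags(tags, unmatched)
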