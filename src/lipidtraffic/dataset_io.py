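"""Reading, correcting and binarising sample-by-lipid tables.

A dataset is one row per biological sample (with compartment, phenotype,
generation, ionisation-mode and petrol-wash metadata) and one column per
lipid variable.  Direct-infusion MS signals are semi-quantitative, so each
sample is *signal corrected*: every analyte signal is divided by the total
signal of that sample excluding internal standards and expressed per mille
(‰), making samples comparable regardless of total lipid mass.

The binary (switch) analysis needs only detection calls.  A variable is
*present* in a (compartment, phenotype) cell when it has signal > 0 in at
least half of that cell's samples; a variable is present in a compartment
for the study overall when it passes that rule in either phenotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "AbundanceTable",
    "PresenceMap",
    "read_table",
    "signal_correct",
    "detect_presence",
    "apply_petrol_wash_policy",
    "DEFAULT_COLUMNS",
]

#: Logical metadata fields -> default CSV column names.  ``generation`` and
#: ``petrol_washed`` are optional in input files; the rest are mandatory
#: (mode is mandatory because positive- and negative-mode blocks are
#: analysed separately end to end).
DEFAULT_COLUMNS: dict[str, str] = {
    "sample_id": "sample_id",
    "compartment": "compartment",
    "phenotype": "phenotype",
    "generation": "generation",
    "mode": "mode",
    "petrol_washed": "petrol_washed",
    "variable": "variable",
    "value": "value",
}

_META_FIELDS = ("compartment", "phenotype", "generation", "mode", "petrol_washed")
_REQUIRED_META = ("compartment", "phenotype", "mode")

PERMILLE_TOTAL = 1000.0


@dataclass(frozen=True)
class AbundanceTable:
    """Samples × lipid variables with per-sample metadata.

    Attributes
    ----------
    values:
        DataFrame of non-negative analyte signals, index = sample ids,
        columns = lipid variable names (internal standards excluded).
    samples:
        DataFrame indexed like ``values`` with columns ``compartment``,
        ``phenotype``, ``generation``, ``mode``, ``petrol_washed``.
    internal_standards:
        Names of internal-standard columns; their raw signals are kept in
        ``standards`` for provenance but never analysed.
    units:
        ``"raw"`` or ``"permille"`` (after :func:`signal_correct`).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    internal_standards: tuple[str, ...] = ()
    units: str = "raw"
    standards: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.samples.index):
            raise DataError("values and samples must share the same sample index")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise DataError(f"duplicate sample id {dup!r}")
        for col in _META_FIELDS:
            if col not in self.samples.columns:
                raise DataError(f"missing metadata column {col!r}")
        meta = self.samples[list(_REQUIRED_META)]
        if meta.isna().any().any() or (meta.astype(str) == "").any().any():
            bad = meta.index[meta.isna().any(axis=1) | (meta.astype(str) == "").any(axis=1)][0]
            raise DataError(f"sample {bad!r} has missing metadata")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise DataError(
                f"missing value at sample {self.values.index[r]!r}, "
                f"variable {self.values.columns[c]!r}"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise DataError(
                f"negative value {arr[r, c]} at sample {self.values.index[r]!r}, "
                f"variable {self.values.columns[c]!r}"
            )

    # ------------------------------------------------------------------
    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values.index)

    def filter(
        self,
        *,
        mode: Optional[str] = None,
        compartment: Optional[str] = None,
        phenotype: Optional[str] = None,
    ) -> "AbundanceTable":
        """Row subset by metadata; keeps all variable columns."""
        mask = pd.Series(True, index=self.samples.index)
        if mode is not None:
            mask &= self.samples["mode"] == mode
        if compartment is not None:
            mask &= self.samples["compartment"] == compartment
        if phenotype is not None:
            mask &= self.samples["phenotype"] == phenotype
        return replace(
            self,
            values=self.values.loc[mask],
            samples=self.samples.loc[mask],
            standards=None if self.standards is None else self.standards.loc[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        """Single wide DataFrame: metadata columns then variable columns."""
        return pd.concat([self.samples, self.values], axis=1)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="sample_id")


def _coerce_bool(series: pd.Series) -> pd.Series:
    truthy = {"true", "1", "yes", "y", "t"}
    return series.map(
        lambda v: bool(v) if isinstance(v, (bool, np.bool_)) else str(v).strip().lower() in truthy
    )


def read_table(
    path: str | Path,
    layout: str = "wide",
    columns: Optional[Mapping[str, str]] = None,
    internal_standards: Iterable[str] = (),
    units: str = "raw",
) -> AbundanceTable:
    """Read a CSV lipidomics table.

    Parameters
    ----------
    layout:
        ``"wide"`` — one row per sample, metadata columns plus one column per
        lipid variable; or ``"long"`` — one row per (sample, variable) with a
        value column, pivoted to wide.
    columns:
        Overrides for metadata column names (keys of :data:`DEFAULT_COLUMNS`).
    internal_standards:
        Variable names to treat as internal standards.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        unknown = set(columns) - set(cols)
        if unknown:
            raise DataError(f"unknown column-mapping keys: {sorted(unknown)}")
        cols.update(columns)
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    raw = pd.read_csv(path)
    if layout == "wide":
        wide = raw
    elif layout == "long":
        needed = [cols["sample_id"], cols["variable"], cols["value"]]
        for c in needed:
            if c not in raw.columns:
                raise DataError(f"long layout requires column {c!r}")
        dup = raw.duplicated(subset=[cols["sample_id"], cols["variable"]])
        if dup.any():
            row = raw.loc[dup.idxmax()]
            raise DataError(
                f"duplicate cell for sample {row[cols['sample_id']]!r}, "
                f"variable {row[cols['variable']]!r} in long layout"
            )
        meta_cols = [
            cols[f] for f in _META_FIELDS if cols[f] in raw.columns
        ]
        meta = raw[[cols["sample_id"], *meta_cols]].drop_duplicates()
        if meta[cols["sample_id"]].duplicated().any():
            bad = meta[cols["sample_id"]][meta[cols["sample_id"]].duplicated()].iloc[0]
            raise DataError(f"conflicting metadata for sample {bad!r}")
        pivot = raw.pivot(
            index=cols["sample_id"], columns=cols["variable"], values=cols["value"]
        ).fillna(0.0)
        pivot.columns.name = None
        wide = meta.set_index(cols["sample_id"]).join(pivot).reset_index()
    else:
        raise DataError(f"unknown layout {layout!r}; use 'wide' or 'long'")

    if cols["sample_id"] not in wide.columns:
        raise DataError(f"missing sample id column {cols['sample_id']!r}")
    wide = wide.set_index(cols["sample_id"])
    wide.index = wide.index.astype(str)
    wide.index.name = "sample_id"

    meta = pd.DataFrame(index=wide.index)
    for f in _REQUIRED_META:
        if cols[f] not in wide.columns:
            raise DataError(f"missing metadata column {cols[f]!r}")
        meta[f] = wide[cols[f]].astype(str)
    meta["generation"] = (
        wide[cols["generation"]].astype(str) if cols["generation"] in wide.columns else ""
    )
    meta["petrol_washed"] = (
        _coerce_bool(wide[cols["petrol_washed"]])
        if cols["petrol_washed"] in wide.columns
        else False
    )
    meta_src = [cols[f] for f in _META_FIELDS if cols[f] in wide.columns]
    value_cols = [c for c in wide.columns if c not in meta_src]
    try:
        values = wide[value_cols].astype(float)
    except ValueError as exc:
        raise DataError(f"non-numeric abundance value: {exc}") from exc

    standards = tuple(s for s in internal_standards)
    missing_std = [s for s in standards if s not in values.columns]
    if missing_std:
        raise DataError(f"declared internal standards not in table: {missing_std}")
    std_frame = values[list(standards)] if standards else None
    analytes = values.drop(columns=list(standards)) if standards else values
    return AbundanceTable(
        values=analytes,
        samples=meta,
        internal_standards=standards,
        units=units,
        standards=std_frame,
    )


def signal_correct(table: AbundanceTable, tolerance: float = 1e-9) -> AbundanceTable:
    """Rescale every sample to per-mille of its total analyte signal.

    The denominator is the sum of signals for that sample *excluding*
    internal standards (which were split off at read time).  Idempotent on
    already-corrected rows.  Raises :class:`DataError` for a sample with no
    positive analyte signal.
    """
    totals = table.values.sum(axis=1)
    zero = totals <= tolerance
    if zero.any():
        raise DataError(
            f"sample {totals.index[zero.argmax()]!r} has no positive analyte signal"
        )
    corrected = table.values.div(totals, axis=0) * PERMILLE_TOTAL
    return replace(table, values=corrected, units="permille")


def apply_petrol_wash_policy(table: AbundanceTable, compartment: str = "adipose") -> AbundanceTable:
    """Resolve duplicated adipose measurements: when a compartment was
    profiled both untreated and petrol-washed (phospholipid-concentrated),
    negative-mode analysis keeps the washed samples and positive-mode the
    untreated ones.  Other samples pass through unchanged."""
    meta = table.samples
    keep = pd.Series(True, index=meta.index)
    in_comp = meta["compartment"] == compartment
    for mode, want_washed in (("negative", True), ("positive", False)):
        block = in_comp & (meta["mode"] == mode)
        if (meta.loc[block, "petrol_washed"] == want_washed).any():
            keep &= ~block | (meta["petrol_washed"] == want_washed)
    return replace(
        table,
        values=table.values.loc[keep],
        samples=meta.loc[keep],
        standards=None if table.standards is None else table.standards.loc[keep],
    )


@dataclass(frozen=True)
class PresenceMap:
    """Detection calls per (compartment, phenotype).

    ``entries[(compartment, phenotype)]`` is the frozenset of variables with
    signal > 0 in at least ``min_fraction`` of that cell's samples.
    ``no_data`` lists cells with zero samples, which are flagged rather than
    silently empty.
    """

    entries: Mapping[tuple[str, str], frozenset[str]]
    sample_counts: Mapping[tuple[str, str], int]
    compartments: tuple[str, ...]
    phenotypes: tuple[str, ...]
    no_data: frozenset[tuple[str, str]] = frozenset()
    min_fraction: float = 0.5

    def present(self, compartment: str, phenotype: str) -> frozenset[str]:
        key = (compartment, phenotype)
        if key in self.no_data:
            raise DataError(
                f"no samples for compartment {compartment!r}, phenotype {phenotype!r}"
            )
        try:
            return self.entries[key]
        except KeyError:
            raise DataError(
                f"presence map has no entry for ({compartment!r}, {phenotype!r})"
            ) from None

    def overall(self, compartment: str) -> frozenset[str]:
        """Variables present in the compartment for the study overall: the
        ≥min_fraction rule satisfied in *either* phenotype group."""
        out: set[str] = set()
        for p in self.phenotypes:
            if (compartment, p) not in self.no_data:
                out |= self.entries[(compartment, p)]
        return frozenset(out)

    def universe(self, phenotype: Optional[str] = None) -> frozenset[str]:
        """All variables present anywhere (optionally for one phenotype)."""
        out: set[str] = set()
        for (c, p), s in self.entries.items():
            if phenotype is None or p == phenotype:
                out |= s
        return frozenset(out)


def detect_presence(
    table: AbundanceTable,
    network_compartments: Sequence[str],
    rule: str = "per-phenotype",
    min_fraction: float = 0.5,
) -> PresenceMap:
    """Apply the detection rule to every (compartment, phenotype) cell.

    ``rule="per-phenotype"`` (default) evaluates the ≥``min_fraction``
    positive-signal rule within each phenotype's samples of the compartment —
    this is what the per-phenotype Switch Analysis consumes.
    ``rule="pooled"`` evaluates it over all samples of the compartment and
    assigns the same set to every phenotype.
    """
    if rule not in ("per-phenotype", "pooled"):
        raise DataError(f"unknown presence rule {rule!r}")
    if not 0 < min_fraction <= 1:
        raise DataError(f"min_fraction must be in (0, 1], got {min_fraction}")
    comps = tuple(network_compartments)
    sample_comps = set(table.samples["compartment"])
    stray = sample_comps - set(comps)
    if stray:
        raise DataError(
            f"samples from compartments outside the network: {sorted(stray)}"
        )
    phenos = tuple(dict.fromkeys(table.samples["phenotype"]))
    entries: dict[tuple[str, str], frozenset[str]] = {}
    counts: dict[tuple[str, str], int] = {}
    no_data: set[tuple[str, str]] = set()
    positive = table.values.to_numpy(dtype=float) > 0
    comp_arr = table.samples["compartment"].to_numpy()
    pheno_arr = table.samples["phenotype"].to_numpy()
    for c in comps:
        if rule == "pooled":
            mask = comp_arr == c
            n = int(mask.sum())
            pooled = (
                frozenset(
                    str(v)
                    for v in np.asarray(table.variables)[
                        positive[mask].mean(axis=0) >= min_fraction
                    ]
                )
                if n
                else frozenset()
            )
        for p in phenos:
            mask = (comp_arr == c) & (pheno_arr == p)
            n = int(mask.sum())
            counts[(c, p)] = n
            if n == 0:
                no_data.add((c, p))
                entries[(c, p)] = frozenset()
                continue
            if rule == "pooled":
                entries[(c, p)] = pooled
            else:
                frac = positive[mask].mean(axis=0)
                entries[(c, p)] = frozenset(
                    str(v) for v in np.asarray(table.variables)[frac >= min_fraction]
                )
    return PresenceMap(
        entries=entries,
        sample_counts=counts,
        compartments=comps,
        phenotypes=phenos,
        no_data=frozenset(no_data),
        min_fraction=min_fraction,
    )
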