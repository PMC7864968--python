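"""Seeded generator of multi-compartment, two-phenotype lipidomics datasets.

No public MS dataset accompanies the traffic-analysis study design this
package targets, so every analysis stage is exercised against simulated
data with known ground truth.  The generator emulates the study
conditions: a liver–serum–termini network, two phenotype groups
(control ``NP-NC`` and experimental ``LP-HC``) of ~6–8 samples per
compartment, several hundred lipid variables spread over the major
classes, log-normal signal noise, per-mille signal correction and an
optional detection dropout.  Planted structure — re-routed variables and
multiplicative mean shifts — is recorded in a ground-truth manifest so
recovery can be asserted exactly.

What it does *not* emulate: mass spectra, isotopes, ionisation physics,
isobaric overlap, batch effects or inter-variable correlation beyond the
compositional closure introduced by per-mille normalisation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .dataset_io import AbundanceTable, signal_correct
from .errors import DataError, NetworkError
from .network_model import CompartmentNetwork, preset_network

__all__ = ["ScenarioConfig", "generate", "fixture_suite", "DEFAULT_CLASS_PROFILE"]

#: Per-class (number of variables, ln-scale location of the raw signal,
#: carbon range).  Locations give TGs and PCs the large shares and lyso
#: species the small ones, mimicking a ‰-scale lipid composition; counts
#: total ~500 variables ("several hundred").
DEFAULT_CLASS_PROFILE: dict[str, tuple[int, float, tuple[int, int]]] = {
    "TG": (120, 9.0, (40, 62)),
    "PC": (90, 8.2, (30, 44)),
    "PE": (60, 7.4, (32, 44)),
    "DG": (40, 7.0, (28, 40)),
    "SM": (35, 6.8, (30, 42)),
    "PC-O": (25, 6.2, (30, 42)),
    "PI": (25, 6.4, (32, 42)),
    "Cer": (25, 6.0, (30, 42)),
    "PE-O": (20, 6.0, (32, 42)),
    "PS": (20, 6.0, (32, 42)),
    "LPC": (20, 5.8, (14, 24)),
    "PG": (15, 5.5, (32, 40)),
    "LPE": (12, 5.4, (14, 24)),
    "PA": (12, 5.2, (32, 40)),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one synthetic study; same config + seed gives a
    byte-identical dataset.

    ``category_weights`` are the probabilities that a (non-planted) variable
    is ubiquitous (A), travels one random axis (B) or sits in one random
    compartment (U).  ``sigma`` is the log-normal noise SD in natural-log
    units; ``dropout`` is the per-cell probability that a present variable's
    signal is zeroed in one sample (detection dropout).
    """

    network: Union[str, CompartmentNetwork] = "F1N"
    n_samples: int = 8
    class_profile: Mapping[str, tuple[int, float, tuple[int, int]]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROFILE)
    )
    category_weights: Tuple[float, float, float] = (0.45, 0.35, 0.20)
    sigma: float = 0.25
    dropout: float = 0.05
    planted_reroutes: Tuple[Tuple[str, str, str], ...] = ()  # (variable, from_axis, to_axis)
    planted_effects: Tuple[Tuple[str, str, float], ...] = ()  # (variable, compartment, fold)
    control: str = "NP-NC"
    experimental: str = "LP-HC"
    generation: str = "F1N"
    mode: str = "positive"
    seed: int = 0

    def resolve_network(self) -> CompartmentNetwork:
        if isinstance(self.network, CompartmentNetwork):
            return self.network
        return preset_network(self.network)


def _variable_names(
    profile: Mapping[str, tuple[int, float, tuple[int, int]]]
) -> tuple[list[str], dict[str, float]]:
    """Deterministic species names per class, cycling (carbons, double
    bonds) lexicographically within the class carbon range."""
    names: list[str] = []
    locations: dict[str, float] = {}
    for cls, (count, loc, (c_lo, c_hi)) in profile.items():
        made = 0
        for carbons in range(c_lo, c_hi + 1):
            for bonds in range(0, 9):
                if made >= count:
                    break
                name = f"{cls}({carbons}:{bonds})"
                names.append(name)
                locations[name] = loc
                made += 1
            if made >= count:
                break
        if made < count:
            raise DataError(
                f"class {cls}: carbon range {c_lo}-{c_hi} cannot host {count} variables"
            )
    return names, locations


def generate(config: ScenarioConfig) -> tuple[AbundanceTable, dict]:
    """Generate a signal-corrected table plus a ground-truth manifest.

    The manifest records, per phenotype, every variable's compartment
    membership, its A/B/U category draw, and the planted re-routes and
    abundance effects, so tests can assert exact recovery.
    """
    network = config.resolve_network()
    rng = np.random.default_rng(config.seed)
    names, locations = _variable_names(config.class_profile)
    if len(set(names)) != len(names):
        raise DataError("duplicate generated variable names")
    phenotypes = (config.control, config.experimental)
    axes = {ax.label: ax for ax in network.axes}

    # -- compartment membership ---------------------------------------
    w = np.asarray(config.category_weights, dtype=float)
    if w.min() < 0 or w.sum() <= 0:
        raise DataError(f"bad category weights {config.category_weights}")
    w = w / w.sum()
    categories = rng.choice(["A", "B", "U"], size=len(names), p=w)
    axis_pick = rng.integers(0, len(axes), size=len(names))
    comp_pick = rng.integers(0, len(network.nodes), size=len(names))
    membership: dict[str, dict[str, frozenset[str]]] = {p: {} for p in phenotypes}
    axis_labels = list(axes)
    for i, var in enumerate(names):
        if categories[i] == "A":
            comps = frozenset(network.nodes)
        elif categories[i] == "B":
            comps = axes[axis_labels[axis_pick[i]]].endpoints
        else:
            comps = frozenset({network.nodes[comp_pick[i]]})
        for p in phenotypes:
            membership[p][var] = comps

    # -- planted structure --------------------------------------------
    for var, from_axis, to_axis in config.planted_reroutes:
        if var not in locations:
            raise DataError(f"planted re-route names unknown variable {var!r}")
        if from_axis not in axes or to_axis not in axes:
            raise NetworkError(
                f"planted re-route uses non-existent axis ({from_axis!r} -> {to_axis!r})"
            )
        if not axes[from_axis].endpoints & axes[to_axis].endpoints:
            raise NetworkError(
                f"planted re-route axes {from_axis!r}/{to_axis!r} share no endpoint"
            )
        membership[config.control][var] = axes[from_axis].endpoints
        membership[config.experimental][var] = axes[to_axis].endpoints
    for var, comp, fold in config.planted_effects:
        if var not in locations:
            raise DataError(f"planted effect names unknown variable {var!r}")
        if comp not in network.nodes:
            raise NetworkError(f"planted effect names unknown compartment {comp!r}")
        if fold <= 0:
            raise DataError(f"planted fold change must be positive, got {fold}")
        # the effect needs the variable detectable in that compartment in
        # both phenotypes; force membership there
        for p in phenotypes:
            membership[p][var] = membership[p][var] | {comp}

    effect_lookup = {(v, c): f for v, c, f in config.planted_effects}

    # -- signals -------------------------------------------------------
    base = np.array([locations[v] for v in names]) + rng.normal(0.0, 0.8, len(names))
    rows: list[pd.Series] = []
    meta_rows: list[dict] = []
    for comp in network.nodes:
        for pheno in phenotypes:
            present = np.array(
                [comp in membership[pheno][v] for v in names], dtype=bool
            )
            noise = rng.normal(0.0, config.sigma, size=(config.n_samples, len(names)))
            block = np.exp(base[None, :] + noise) * present[None, :]
            for j, var in enumerate(names):
                fold = effect_lookup.get((var, comp))
                if fold is not None and pheno == config.experimental:
                    block[:, j] *= fold
            if config.dropout > 0:
                drop = rng.random(block.shape) < config.dropout
                block = np.where(drop, 0.0, block)
            for i in range(config.n_samples):
                sid = f"{pheno}-{comp}-{i + 1:02d}"
                rows.append(pd.Series(block[i], index=names, name=sid))
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "compartment": comp,
                        "phenotype": pheno,
                        "generation": config.generation,
                        "mode": config.mode,
                        "petrol_washed": False,
                    }
                )
    values = pd.DataFrame(rows)
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    samples.index.name = "sample_id"
    values.index = samples.index
    table = signal_correct(
        AbundanceTable(values=values, samples=samples, units="raw")
    )

    manifest = {
        "config": _config_dict(config, network),
        "variables": names,
        "categories": {v: str(categories[i]) for i, v in enumerate(names)},
        "membership": {
            p: {v: sorted(m) for v, m in membership[p].items()} for p in phenotypes
        },
        "planted_reroutes": [list(r) for r in config.planted_reroutes],
        "planted_effects": [[v, c, float(f)] for v, c, f in config.planted_effects],
    }
    return table, manifest


def _config_dict(config: ScenarioConfig, network: CompartmentNetwork) -> dict:
    d = dataclasses.asdict(config)
    d["network"] = network.name or {
        "origin": network.origin,
        "hub": network.hub,
        "termini": list(network.termini),
    }
    d["class_profile"] = {
        k: [v[0], v[1], list(v[2])] for k, v in config.class_profile.items()
    }
    return d


#: Reduced class profile for fast fixtures (~60 variables).
_SMALL_PROFILE: dict[str, tuple[int, float, tuple[int, int]]] = {
    "TG": (20, 9.0, (40, 56)),
    "PC": (20, 8.2, (30, 40)),
    "PE": (12, 7.4, (32, 40)),
    "SM": (8, 6.8, (30, 38)),
}


def fixture_suite() -> dict[str, object]:
    """Small named scenarios used throughout the test-suite and docs.

    * ``jtc_two_thirds`` — the worked similarity example: a control list of
      three variables against an experimental list holding two of them
      (J = 2/3; its exact subset-null p-value is 1).
    * ``null_dataset`` — an F1N-shaped dataset with no planted structure.
    * ``f1n_reroute`` — one TG variable moved from the serum–heart axis
      (control) to the serum–brain axis (experimental), dropout-free.
    """
    return {
        "jtc_two_thirds": {
            "x": frozenset({"v1", "v2", "v3"}),
            "y": frozenset({"v1", "v2"}),
        },
        "null_dataset": ScenarioConfig(
            network="F1N",
            class_profile=_SMALL_PROFILE,
            n_samples=6,
            dropout=0.0,
            seed=11,
        ),
        "f1n_reroute": ScenarioConfig(
            network="F1N",
            class_profile=_SMALL_PROFILE,
            n_samples=6,
            dropout=0.0,
            planted_reroutes=(("TG(40:0)", "SH", "SB"),),
            seed=12,
        ),
    }
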