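"""Quantitative Abundance Analysis.

Two complementary effect measures per lipid variable per compartment:

* **margin change** — the raw difference of phenotype group means,
  x̄_E − x̄_C, interpreted with a two-tailed two-sample Student's t-test;
* **error-normalised fold change (ENFC)** —
  log10(x̄_E / x̄_C) / sqrt((a² + b²) / 2), where ``a`` and ``b`` are the
  control and experimental group standard deviations: a fold change with
  the propagated group error built into its scale.  The denominator is the
  root-mean-square of the raw-scale SDs, as the measure is defined — it is
  deliberately not converted to log units.

Because the lipid variables are strongly inter-correlated (they share
chains, classes and totals), a Bonferroni correction over N variables is
too severe; the default dependent-variable correction divides alpha by
sqrt(N) (586 variables at alpha 0.05 gives a per-test threshold of
0.0021).  Plain Bonferroni is available as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset_io import AbundanceTable
from .errors import DataError, UndefinedStatisticError
from .network_model import CompartmentNetwork

__all__ = [
    "MarginResult",
    "margin_change",
    "enfc",
    "corrected_threshold",
    "round_sig",
    "abundance_report",
    "enfc_matrix",
]


class MarginResult(NamedTuple):
    margin: float
    p_value: float  # nan when a group has < 2 samples


def margin_change(
    values_E: Sequence[float], values_C: Sequence[float], equal_var: bool = True
) -> MarginResult:
    """Difference of group means x̄_E − x̄_C with a two-tailed two-sample
    t-test p-value (classical equal-variance Student's test by default;
    ``equal_var=False`` gives Welch's).

    The margin is always returned; the p-value is NaN when either group has
    fewer than 2 samples, 1.0 when both groups are constant and equal, and
    0.0 when both are constant but different (the degenerate t limits).
    """
    e = np.asarray(values_E, dtype=float)
    c = np.asarray(values_C, dtype=float)
    if e.size == 0 or c.size == 0:
        raise DataError("margin_change needs at least one sample per group")
    margin = float(e.mean() - c.mean())
    if e.size < 2 or c.size < 2:
        return MarginResult(margin, math.nan)
    if e.var(ddof=1) == 0.0 and c.var(ddof=1) == 0.0:
        return MarginResult(margin, 1.0 if margin == 0.0 else 0.0)
    p = float(stats.ttest_ind(e, c, equal_var=equal_var).pvalue)
    return MarginResult(margin, p)


def enfc(values_E: Sequence[float], values_C: Sequence[float]) -> float:
    """Error-normalised fold change log10(x̄_E/x̄_C) / sqrt((a²+b²)/2).

    ``a``/``b`` are the sample (n−1) standard deviations of the control and
    experimental group values on their stored scale.  Undefined (raises)
    when either group mean is not positive or when both SDs are zero.
    """
    e = np.asarray(values_E, dtype=float)
    c = np.asarray(values_C, dtype=float)
    mean_e, mean_c = e.mean(), c.mean()
    if mean_e <= 0 or mean_c <= 0:
        raise UndefinedStatisticError(
            f"ENFC undefined: non-positive group mean (experimental {mean_e}, "
            f"control {mean_c})"
        )
    a = c.std(ddof=1) if c.size > 1 else 0.0
    b = e.std(ddof=1) if e.size > 1 else 0.0
    rms = math.sqrt((a * a + b * b) / 2.0)
    if rms == 0.0:
        raise UndefinedStatisticError("ENFC undefined: zero pooled standard deviation")
    return float(np.log10(mean_e / mean_c) / rms)


def corrected_threshold(
    n_variables: int, alpha: float = 0.05, method: str = "sqrt"
) -> float:
    """Per-test significance threshold corrected for multiple dependent
    variables: ``alpha / sqrt(N)`` (default, suited to strongly correlated
    lipid variables) or Bonferroni ``alpha / N``.  Full precision is
    returned; use :func:`round_sig` for 2-significant-figure display."""
    if n_variables < 1:
        raise DataError(f"n_variables must be >= 1, got {n_variables}")
    if not 0 < alpha < 1:
        raise DataError(f"alpha must be in (0, 1), got {alpha}")
    if method == "sqrt":
        return alpha / math.sqrt(n_variables)
    if method == "bonferroni":
        return alpha / n_variables
    raise DataError(f"unknown correction method {method!r}")


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (display convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class AbundanceComparison:
    """One (variable, compartment) phenotype comparison."""

    variable: str
    compartment: str
    n_control: int
    n_experimental: int
    mean_control: float
    mean_experimental: float
    sd_control: float
    sd_experimental: float
    margin_change: float
    t_pvalue: float
    enfc: float
    significant: bool
    note: str = ""


def abundance_report(
    table: AbundanceTable,
    network: CompartmentNetwork,
    control: str,
    experimental: str,
    alpha: float = 0.05,
    equal_var: bool = True,
    correction: str = "sqrt",
) -> pd.DataFrame:
    """Per-variable, per-compartment phenotype comparison.

    Requires a signal-corrected (per-mille) table.  Returns a DataFrame with
    one row per (variable, compartment); rows where a group is missing or a
    group mean is zero are marked not-computable in ``note`` with NaN
    statistics rather than dropped.  The significance threshold
    ``corrected_threshold(n_variables, alpha, correction)`` is attached as
    ``frame.attrs["threshold"]``.
    """
    if table.units != "permille":
        raise DataError(
            "abundance_report requires a signal-corrected table "
            "(apply signal_correct first)"
        )
    variables = list(table.variables)
    threshold = corrected_threshold(len(variables), alpha, correction)
    meta = table.samples
    frames = []
    for comp in network.nodes:
        in_comp = meta["compartment"] == comp
        e_mask = in_comp & (meta["phenotype"] == experimental)
        c_mask = in_comp & (meta["phenotype"] == control)
        n_e, n_c = int(e_mask.sum()), int(c_mask.sum())
        base = pd.DataFrame(
            {
                "variable": variables,
                "compartment": comp,
                "n_control": n_c,
                "n_experimental": n_e,
            }
        )
        if n_e == 0 or n_c == 0:
            for col in (
                "mean_control",
                "mean_experimental",
                "sd_control",
                "sd_experimental",
                "margin_change",
                "t_pvalue",
                "enfc",
            ):
                base[col] = np.nan
            base["significant"] = False
            base["note"] = "no-samples"
            frames.append(base)
            continue
        e_vals = table.values.loc[e_mask].to_numpy(dtype=float)
        c_vals = table.values.loc[c_mask].to_numpy(dtype=float)
        mean_e, mean_c = e_vals.mean(axis=0), c_vals.mean(axis=0)
        sd_e = e_vals.std(axis=0, ddof=1) if n_e > 1 else np.zeros(len(variables))
        sd_c = c_vals.std(axis=0, ddof=1) if n_c > 1 else np.zeros(len(variables))
        margin = mean_e - mean_c
        with np.errstate(divide="ignore", invalid="ignore"):
            if n_e > 1 and n_c > 1:
                pvals = stats.ttest_ind(e_vals, c_vals, axis=0, equal_var=equal_var).pvalue
                degenerate = (sd_e == 0) & (sd_c == 0)
                pvals = np.where(
                    degenerate, np.where(margin == 0.0, 1.0, 0.0), pvals
                )
            else:
                pvals = np.full(len(variables), np.nan)
            rms = np.sqrt((sd_c**2 + sd_e**2) / 2.0)
            computable = (mean_e > 0) & (mean_c > 0)
            enfc_vals = np.where(
                computable & (rms > 0), np.log10(mean_e / mean_c) / rms, np.nan
            )
        note = np.where(computable, "", "absent-in-group")
        note = np.where(computable & (rms == 0), "zero-variance", note)
        base["mean_control"] = mean_c
        base["mean_experimental"] = mean_e
        base["sd_control"] = sd_c
        base["sd_experimental"] = sd_e
        base["margin_change"] = np.where(computable, margin, np.nan)
        base["t_pvalue"] = np.where(computable, pvals, np.nan)
        base["enfc"] = enfc_vals
        base["significant"] = computable & (pvals < threshold)
        base["note"] = note
        frames.append(base)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["threshold"] = threshold
    out.attrs["threshold_display"] = round_sig(threshold, 2)
    out.attrs["alpha"] = alpha
    out.attrs["correction"] = correction
    out.attrs["n_variables"] = len(variables)
    out.attrs["control"] = control
    out.attrs["experimental"] = experimental
    return out


def enfc_matrix(report: pd.DataFrame) -> pd.DataFrame:
    """Wide ENFC matrix (variables × compartments) for radar-style export."""
    return report.pivot(index="variable", columns="compartment", values="enfc")
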