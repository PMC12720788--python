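"""Wood's-plot differential analysis of peptide-level deuterium uptake.

Two conditions are contrasted peptide by peptide and timepoint by
timepoint on relative uptake (percent of exchangeable amides).  The
significance cutoff is a global, replicate-based pooled standard
deviation: replicate values are grouped by (peptide, state, time), the
within-group variances are pooled across all groups and both states, and
a difference is called significant when it exceeds ``multiplier x sigma``.
Positive differences (condition B takes up more deuterium) indicate
increased flexibility; negative differences indicate rigidification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Peptide, ProteinState

__all__ = [
    "PooledSigma",
    "pooled_sigma",
    "woods_table",
    "significant_peptides",
    "mean_delta",
    "residue_deltas",
    "DIRECTION_FLEXIBLE",
    "DIRECTION_RIGID",
    "DIRECTION_UNCHANGED",
]

DIRECTION_FLEXIBLE = "more flexible"
DIRECTION_RIGID = "more rigid"
DIRECTION_UNCHANGED = "unchanged"

_GROUP_KEYS = ["protein", "start", "end", "variant", "ligand", "exposure_s"]


@dataclass(frozen=True)
class PooledSigma:
    """Pooled replicate variability of relative uptake, in percent.

    ``sigma_pct`` is the square root of the degrees-of-freedom-weighted
    mean within-group variance over all (peptide, state, time) groups;
    ``n_groups``/``n_values`` record how much data was pooled.
    """

    sigma_pct: float
    n_groups: int
    n_values: int

    def __post_init__(self) -> None:
        if self.sigma_pct < 0:
            raise ValueError("sigma_pct must be >= 0")
        if self.n_values < self.n_groups:
            raise ValueError("n_values must be >= n_groups")


def pooled_sigma(records: pd.DataFrame, mode: str = "pooled-within") -> PooledSigma:
    """Global replicate-variability estimate from an uptake table.

    ``mode="pooled-within"`` (default) pools within-group replicate
    variances, weighted by their degrees of freedom — the quantity that
    reflects experimental (not biological/positional) variability.
    ``mode="raw"`` instead takes the standard deviation of the flat pooled
    value distribution, which mixes between-peptide spread into the
    estimate and is provided only for comparison.  Exposure-0 groups are
    excluded (their uptake is zero by construction).
    """
    df = records[records["exposure_s"] > 0]
    if df.empty:
        raise ValueError("no non-zero-exposure records to pool")
    groups = df.groupby(_GROUP_KEYS)["relative_uptake_pct"]
    sizes = groups.size()
    if (sizes < 2).all():
        raise ValueError(
            "no (peptide, state, time) group has >= 2 replicates; supply a "
            "user-defined sigma instead"
        )
    if (sizes < 2).any():
        warnings.warn(
            f"{int((sizes < 2).sum())} group(s) with a single replicate "
            "contribute no variance information",
            stacklevel=2,
        )
    if mode == "pooled-within":
        var = groups.var(ddof=1)  # NaN for singleton groups
        dfree = sizes - 1
        ok = dfree > 0
        pooled_var = float((var[ok] * dfree[ok]).sum() / dfree[ok].sum())
    elif mode == "raw":
        pooled_var = float(df["relative_uptake_pct"].var(ddof=1))
    else:
        raise ValueError(f"unknown sigma mode {mode!r}")
    return PooledSigma(
        sigma_pct=float(np.sqrt(pooled_var)),
        n_groups=int((sizes >= 2).sum()),
        n_values=int(sizes[sizes >= 2].sum()),
    )


def _state_frame(records: pd.DataFrame, state: ProteinState) -> pd.DataFrame:
    ligand = state.ligand if state.ligand else "apo"
    out = records[
        (records["variant"] == state.variant) & (records["ligand"] == ligand)
    ]
    if out.empty:
        raise ValueError(f"state {state.label} not present in the uptake table")
    return out


def woods_table(
    records: pd.DataFrame,
    condition_a: ProteinState,
    condition_b: ProteinState,
    sigma: PooledSigma | float,
    multiplier: float = 1.0,
    timepoints: list[float] | None = None,
) -> pd.DataFrame:
    """Per-peptide, per-timepoint uptake differences B - A with a
    sigma-based significance cutoff.

    Replicate relative uptakes are averaged within each (peptide, time,
    condition) cell; ``delta_pct`` is the B-minus-A difference of those
    means, flagged significant when strictly beyond
    ``multiplier x sigma_pct``.  Exposure 0 is excluded; ``timepoints``
    optionally restricts the analysis to a subset of exposures.  Peptides
    present in only one condition are reported via a warning and the
    frame's ``attrs["missing_peptides"]``, never dropped silently.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    sigma_pct = sigma.sigma_pct if isinstance(sigma, PooledSigma) else float(sigma)
    threshold = multiplier * sigma_pct

    frames = {}
    for cond, tag in ((condition_a, "a"), (condition_b, "b")):
        f = _state_frame(records, cond)
        f = f[f["exposure_s"] > 0]
        if timepoints is not None:
            f = f[f["exposure_s"].isin(timepoints)]
        frames[tag] = (
            f.groupby(["protein", "start", "end", "sequence", "exposure_s"])[
                "relative_uptake_pct"
            ]
            .mean()
            .rename(f"rel_{tag}")
            .reset_index()
        )

    pep_a = set(map(tuple, frames["a"][["start", "end"]].drop_duplicates().values))
    pep_b = set(map(tuple, frames["b"][["start", "end"]].drop_duplicates().values))
    missing = sorted(pep_a ^ pep_b)
    if not (pep_a & pep_b):
        raise ValueError("conditions share no peptides")
    if missing:
        warnings.warn(
            f"peptides present in only one condition: "
            f"{['%d-%d' % m for m in missing]}",
            stacklevel=2,
        )

    merged = frames["a"].merge(
        frames["b"], on=["protein", "start", "end", "sequence", "exposure_s"]
    )
    merged["delta_pct"] = merged["rel_b"] - merged["rel_a"]
    merged["threshold_pct"] = threshold
    # strict inequality with a relative epsilon so exact ties computed in
    # floating point stay non-significant
    merged["significant"] = merged["delta_pct"].abs() > threshold * (1 + 1e-12)
    merged["direction"] = np.select(
        [merged["significant"] & (merged["delta_pct"] > 0),
         merged["significant"] & (merged["delta_pct"] < 0)],
        [DIRECTION_FLEXIBLE, DIRECTION_RIGID],
        default=DIRECTION_UNCHANGED,
    )
    merged = merged.sort_values(["start", "end", "exposure_s"]).reset_index(drop=True)
    merged.attrs["condition_a"] = condition_a.label
    merged.attrs["condition_b"] = condition_b.label
    merged.attrs["sigma_pct"] = sigma_pct
    merged.attrs["multiplier"] = multiplier
    merged.attrs["missing_peptides"] = missing
    return merged


def significant_peptides(
    table: pd.DataFrame, min_timepoints: int = 1
) -> pd.DataFrame:
    """Peptides significant at >= ``min_timepoints`` exposures, labelled
    with their dominant direction (sign of the time-averaged delta),
    ordered by start coordinate."""
    if table.empty:
        raise ValueError("empty Wood's table")
    if min_timepoints < 1:
        raise ValueError("min_timepoints must be >= 1")
    rows = []
    for (start, end), grp in table.groupby(["start", "end"], sort=True):
        n_sig = int(grp["significant"].sum())
        if n_sig < min_timepoints:
            continue
        mean = float(grp["delta_pct"].mean())
        rows.append(
            {
                "start": start,
                "end": end,
                "sequence": grp["sequence"].iloc[0],
                "n_significant_timepoints": n_sig,
                "mean_delta_pct": mean,
                "direction": DIRECTION_FLEXIBLE if mean > 0 else DIRECTION_RIGID,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "start",
            "end",
            "sequence",
            "n_significant_timepoints",
            "mean_delta_pct",
            "direction",
        ],
    )


def mean_delta(table: pd.DataFrame, peptide: Peptide | tuple[int, int]) -> float:
    """Time-averaged delta_pct of one peptide over the exposures used in
    the Wood's analysis."""
    start, end = (peptide.start, peptide.end) if isinstance(peptide, Peptide) else peptide
    sel = table[(table["start"] == start) & (table["end"] == end)]
    if sel.empty:
        raise ValueError(f"peptide {start}-{end} not in the Wood's table")
    return float(sel["delta_pct"].mean())


def residue_deltas(table: pd.DataFrame) -> dict[int, float]:
    """Per-residue time-averaged delta_pct: each residue receives the mean
    of the time-averaged deltas of the peptides covering it (used for
    structure mapping)."""
    acc: dict[int, list[float]] = {}
    for (start, end), grp in table.groupby(["start", "end"]):
        mean = float(grp["delta_pct"].mean())
        for r in range(int(start), int(end) + 1):
            acc.setdefault(r, []).append(mean)
    return {r: float(np.mean(v)) for r, v in sorted(acc.items())}
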