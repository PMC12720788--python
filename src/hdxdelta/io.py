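"""Peptide-level HDX-MS data model, uptake-table readers/writers, and
peptide-set utilities.

The canonical in-memory container is a long-format :class:`pandas.DataFrame`
with one row per peptide x state x exposure x replicate measurement
(columns listed in :data:`CANONICAL_COLUMNS`).  Readers accept the common
column-name variants found in community summary-table exports (HDX Workbench
style ``Exposure``/``State`` headers) and normalise them.

Coordinates are 1-based inclusive residue numbers on the expressed
construct, so a peptide labelled 12-29 spans residues 12..29.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "CANONICAL_COLUMNS",
    "Peptide",
    "ProteinState",
    "UptakeRecord",
    "compute_uptake",
    "exchangeable_amides",
    "read_uptake_table",
    "write_uptake_table",
    "select_nonoverlapping",
    "coverage",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Tolerance (Da) below which a negative centroid difference is treated as
#: measurement noise and clipped to zero; more negative values are rejected
#: as data errors.
NEGATIVE_UPTAKE_TOLERANCE_DA = 0.1

#: Maximum allowed disagreement (Da) between an explicit uptake column and
#: the centroid difference when a table carries both.
CENTROID_CONSISTENCY_TOLERANCE_DA = 0.05

CANONICAL_COLUMNS = [
    "protein",
    "start",
    "end",
    "sequence",
    "variant",
    "ligand",
    "exposure_s",
    "replicate",
    "centroid_undeuterated",
    "centroid_deuterated",
    "uptake_da",
    "relative_uptake_pct",
]

# column-name shim: lower-cased alias -> canonical name
_COLUMN_ALIASES = {
    "protein": "protein",
    "protein_id": "protein",
    "start": "start",
    "peptide_start": "start",
    "end": "end",
    "peptide_end": "end",
    "sequence": "sequence",
    "peptide": "sequence",
    "variant": "variant",
    "ligand": "ligand",
    "state": "state",
    "protein_state": "state",
    "exposure": "exposure_s",
    "exposure_s": "exposure_s",
    "time": "exposure_s",
    "time_s": "exposure_s",
    "replicate": "replicate",
    "rep": "replicate",
    "file": "replicate",
    "centroid_undeuterated": "centroid_undeuterated",
    "centroid_und": "centroid_undeuterated",
    "centroid_deuterated": "centroid_deuterated",
    "centroid_deut": "centroid_deuterated",
    "uptake": "uptake_da",
    "uptake_da": "uptake_da",
    "d_uptake": "uptake_da",
    "relative_uptake": "relative_uptake_pct",
    "relative_uptake_pct": "relative_uptake_pct",
    "rfu": "relative_uptake_pct",
}


def exchangeable_amides(sequence: str) -> int:
    """Number of backbone amide protons observable by HDX-MS.

    Uses the dominant community convention: the N-terminal residue has no
    amide, the second residue back-exchanges too quickly to be observed,
    and prolines lack an amide proton entirely.  Hence

        count = len - 2 - (prolines at positions 3..len)

    floored at zero.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    seq = sequence.upper()
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(
            f"unknown residue code(s) {sorted(bad)} in sequence {sequence!r}"
        )
    n = len(seq) - 2 - seq[2:].count("P")
    return max(n, 0)


@dataclass(frozen=True, order=True)
class Peptide:
    """A proteolytic fragment located on the expressed construct.

    ``start``/``end`` are 1-based inclusive residue indices; the sequence
    length must equal ``end - start + 1``.  ``n_exchangeable`` defaults to
    the :func:`exchangeable_amides` convention but may be overridden (e.g.
    for a back-exchange-corrected denominator).
    """

    start: int
    end: int
    sequence: str
    protein_id: str = "protein"
    n_exchangeable: int = field(default=-1, compare=False)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"peptide end {self.end} < start {self.start}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match "
                f"coordinates {self.start}-{self.end}"
            )
        if self.n_exchangeable < 0:
            object.__setattr__(
                self, "n_exchangeable", exchangeable_amides(self.sequence)
            )
        if self.n_exchangeable > len(self.sequence) - 1:
            raise ValueError("n_exchangeable exceeds length - 1")

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def label(self) -> str:
        return f"{self.start}-{self.end}"

    def overlaps(self, other: "Peptide") -> bool:
        return self.start <= other.end and other.start <= self.end

    def residues(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class ProteinState:
    """One experimental condition: protein variant x ligand status.

    ``ligand is None`` denotes the apo state.  The (variant, ligand) pair
    uniquely keys a condition in every table.
    """

    variant: str
    ligand: str | None = None

    @property
    def label(self) -> str:
        return f"{self.variant}:{self.ligand if self.ligand else 'apo'}"

    @classmethod
    def from_label(cls, label: str) -> "ProteinState":
        """Parse ``"variant:ligand"``; ``"variant"`` or ``"variant:apo"``
        denote the apo state."""
        variant, _, ligand = label.partition(":")
        if not variant:
            raise ValueError(f"cannot parse state label {label!r}")
        if ligand in ("", "apo", "none", "None"):
            return cls(variant=variant, ligand=None)
        return cls(variant=variant, ligand=ligand)

    @property
    def apo_counterpart(self) -> "ProteinState":
        return ProteinState(variant=self.variant, ligand=None)


@dataclass(frozen=True)
class UptakeRecord:
    """One deuterium-uptake measurement (peptide x state x time x replicate)."""

    peptide: Peptide
    state: ProteinState
    exposure_s: float
    replicate: int
    uptake_da: float
    relative_uptake_pct: float
    centroid_undeuterated: float | None = None
    centroid_deuterated: float | None = None


def compute_uptake(
    centroid_deuterated: float,
    centroid_undeuterated: float,
    label: str = "record",
) -> float:
    """Deuterium uptake (Da) as the centroid-mass difference
    deuterated - undeuterated.

    Small negative differences (above ``-0.1`` Da) are clipped to zero with
    a warning; larger negatives indicate a data error and are rejected.
    """
    if not (np.isfinite(centroid_deuterated) and np.isfinite(centroid_undeuterated)):
        raise ValueError(f"non-finite centroid mass for {label}")
    if centroid_deuterated <= 0 or centroid_undeuterated <= 0:
        raise ValueError(f"non-positive centroid mass for {label}")
    uptake = centroid_deuterated - centroid_undeuterated
    if uptake < 0:
        if uptake < -NEGATIVE_UPTAKE_TOLERANCE_DA:
            raise ValueError(
                f"{label}: uptake {uptake:.3f} Da below "
                f"-{NEGATIVE_UPTAKE_TOLERANCE_DA} Da tolerance"
            )
        warnings.warn(
            f"{label}: negative uptake {uptake:.3f} Da clipped to 0",
            stacklevel=2,
        )
        uptake = 0.0
    return uptake


def _normalise_columns(df: pd.DataFrame) -> pd.DataFrame:
    renamed = {}
    for col in df.columns:
        key = str(col).strip().lower().replace(" ", "_")
        if key in _COLUMN_ALIASES:
            renamed[col] = _COLUMN_ALIASES[key]
    df = df.rename(columns=renamed)
    if "state" in df.columns and "variant" not in df.columns:
        states = df["state"].map(ProteinState.from_label)
        df["variant"] = [s.variant for s in states]
        df["ligand"] = [s.ligand if s.ligand else "apo" for s in states]
        df = df.drop(columns=["state"])
    return df


def read_uptake_table(path_or_buffer, sep: str = ",") -> pd.DataFrame:
    """Read a long-format HDX summary table into the canonical frame.

    Required columns (any common alias): peptide start/end, sequence, a
    state (either a combined ``state`` label or ``variant``/``ligand``
    columns), exposure time and either centroid masses or an uptake column.
    A missing replicate column defaults to replicate 1.

    Validation performed per row: sequences consistent for identical
    coordinates; centroid/uptake agreement within 0.05 Da when both are
    present; negative uptake handled by the :func:`compute_uptake` rule;
    zero uptake enforced at exposure 0.
    """
    df = pd.read_csv(path_or_buffer, sep=sep)
    if df.empty:
        warnings.warn("empty uptake table", stacklevel=2)
        return pd.DataFrame(columns=CANONICAL_COLUMNS)
    df = _normalise_columns(df)

    required = ["start", "end", "sequence", "variant", "exposure_s"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"uptake table missing mandatory column(s): {missing}")
    has_centroids = {"centroid_undeuterated", "centroid_deuterated"} <= set(df.columns)
    if "uptake_da" not in df.columns and not has_centroids:
        raise ValueError(
            "uptake table needs either an uptake column or both centroid columns"
        )

    if "protein" not in df.columns:
        df["protein"] = "protein"
    if "ligand" not in df.columns:
        df["ligand"] = "apo"
    df["ligand"] = df["ligand"].fillna("apo")
    if "replicate" not in df.columns:
        df["replicate"] = 1

    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    df["exposure_s"] = df["exposure_s"].astype(float)
    df["sequence"] = df["sequence"].str.upper()

    # one sequence per coordinate pair
    seq_check = df.groupby(["protein", "start", "end"])["sequence"].nunique()
    bad = seq_check[seq_check > 1]
    if not bad.empty:
        raise ValueError(
            f"inconsistent sequences for peptide coordinates: {list(bad.index)}"
        )

    n_exch = df["sequence"].map(exchangeable_amides)
    if (n_exch == 0).any():
        bad_seqs = df.loc[n_exch == 0, "sequence"].unique()
        raise ValueError(f"peptides with no exchangeable amides: {list(bad_seqs)}")

    if not has_centroids:
        df["centroid_undeuterated"] = np.nan
        df["centroid_deuterated"] = np.nan
    with_centroids = (
        df["centroid_undeuterated"].notna() & df["centroid_deuterated"].notna()
    )
    if with_centroids.any():
        computed = pd.Series(
            [
                compute_uptake(d, u, label=f"row {i}")
                for i, (d, u) in zip(
                    df.index[with_centroids],
                    zip(
                        df.loc[with_centroids, "centroid_deuterated"],
                        df.loc[with_centroids, "centroid_undeuterated"],
                    ),
                )
            ],
            index=df.index[with_centroids],
        )
        if "uptake_da" in df.columns:
            dev = (df.loc[with_centroids, "uptake_da"] - computed).abs()
            if (dev > CENTROID_CONSISTENCY_TOLERANCE_DA).any():
                raise ValueError(
                    "uptake column disagrees with centroid difference by more "
                    f"than {CENTROID_CONSISTENCY_TOLERANCE_DA} Da at rows "
                    f"{list(dev.index[dev > CENTROID_CONSISTENCY_TOLERANCE_DA])}"
                )
        else:
            df["uptake_da"] = np.nan
        df.loc[with_centroids, "uptake_da"] = computed
    if (~with_centroids).any():
        if "uptake_da" not in df.columns or df.loc[~with_centroids, "uptake_da"].isna().any():
            raise ValueError(
                "rows without centroid masses must carry an uptake value"
            )
        neg = (df["uptake_da"] < 0) & ~with_centroids
        if (df.loc[neg, "uptake_da"] < -NEGATIVE_UPTAKE_TOLERANCE_DA).any():
            raise ValueError(
                f"uptake below -{NEGATIVE_UPTAKE_TOLERANCE_DA} Da tolerance"
            )
        if neg.any():
            warnings.warn(
                f"{int(neg.sum())} negative uptake value(s) clipped to 0",
                stacklevel=2,
            )
            df.loc[neg, "uptake_da"] = 0.0

    df.loc[df["exposure_s"] == 0, "uptake_da"] = 0.0
    if "relative_uptake_pct" not in df.columns:
        df["relative_uptake_pct"] = 100.0 * df["uptake_da"] / n_exch

    df = df[CANONICAL_COLUMNS].sort_values(
        ["protein", "variant", "ligand", "start", "end", "exposure_s", "replicate"]
    )
    return df.reset_index(drop=True)


def write_uptake_table(df: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a canonical uptake frame as UTF-8 comma-separated text."""
    df.to_csv(path, sep=sep, index=False)


def peptides_from_table(df: pd.DataFrame) -> list[Peptide]:
    """Deduplicated peptides present in a canonical uptake frame,
    ordered by start coordinate."""
    unique = df[["protein", "start", "end", "sequence"]].drop_duplicates()
    peps = [
        Peptide(
            start=int(r.start),
            end=int(r.end),
            sequence=r.sequence,
            protein_id=r.protein,
        )
        for r in unique.itertuples()
    ]
    return sorted(peps)


def states_from_table(df: pd.DataFrame) -> list[ProteinState]:
    unique = df[["variant", "ligand"]].drop_duplicates()
    return [
        ProteinState(variant=r.variant, ligand=None if r.ligand == "apo" else r.ligand)
        for r in unique.itertuples()
    ]


def iter_records(df: pd.DataFrame) -> Iterable[UptakeRecord]:
    peptides = {(p.start, p.end): p for p in peptides_from_table(df)}
    for row in df.itertuples():
        yield UptakeRecord(
            peptide=peptides[(row.start, row.end)],
            state=ProteinState(
                variant=row.variant,
                ligand=None if row.ligand == "apo" else row.ligand,
            ),
            exposure_s=row.exposure_s,
            replicate=row.replicate,
            uptake_da=row.uptake_da,
            relative_uptake_pct=row.relative_uptake_pct,
            centroid_undeuterated=row.centroid_undeuterated
            if np.isfinite(row.centroid_undeuterated)
            else None,
            centroid_deuterated=row.centroid_deuterated
            if np.isfinite(row.centroid_deuterated)
            else None,
        )


def select_nonoverlapping(peptides: Sequence[Peptide]) -> list[Peptide]:
    """Largest-coverage pairwise non-overlapping subset of a peptide set.

    Solves the weighted interval-scheduling problem with each peptide
    weighted by its residue count, so the returned subset maximises the
    total number of residues covered.  Deterministic: peptides are
    processed in (end, start) order and ties resolved in favour of the
    earlier-sorting peptide.
    """
    if not peptides:
        return []
    proteins = {p.protein_id for p in peptides}
    if len(proteins) > 1:
        raise ValueError(f"peptides span multiple proteins: {sorted(proteins)}")
    peps = sorted(peptides, key=lambda p: (p.end, p.start))
    n = len(peps)
    ends = [p.end for p in peps]
    # pred[i]: rightmost j < i with ends[j] < peps[i].start, else -1
    pred = [int(np.searchsorted(ends, p.start) - 1) for p in peps]
    best = [0] * (n + 1)  # best[i]: optimum over first i peptides
    take = [False] * n
    for i in range(n):
        skip = best[i]
        with_i = len(peps[i]) + best[pred[i] + 1]
        # strict > keeps the earlier-sorting solution on ties
        if with_i > skip:
            best[i + 1] = with_i
            take[i] = True
        else:
            best[i + 1] = skip
    chosen: list[Peptide] = []
    i = n - 1
    while i >= 0:
        if take[i]:
            chosen.append(peps[i])
            i = pred[i]
        else:
            i -= 1
    return sorted(chosen)


def coverage(peptides: Sequence[Peptide], protein_length: int) -> float:
    """Fraction of residues 1..protein_length covered by the union of
    peptide intervals."""
    if protein_length < 1:
        raise ValueError("protein_length must be positive")
    covered = np.zeros(protein_length, dtype=bool)
    for p in peptides:
        if p.end > protein_length:
            raise ValueError(
                f"peptide {p.label} extends past protein length {protein_length}"
            )
        covered[p.start - 1 : p.end] = True
    return float(covered.sum()) / protein_length
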