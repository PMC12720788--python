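"""Shared fixtures and builders for the test suite.

All datasets are generated programmatically; nothing is read from disk
except files the tests themselves write into tmp_path.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from hdxdelta.io import Peptide, ProteinState
from hdxdelta.simulate import (
    SimulationDesign,
    k_open_for_rate,
    myoglobin_design,
    simulate_dataset,
)

REFERENCE_TIMEPOINTS = (0.0, 30.0, 90.0, 300.0, 1800.0, 3600.0, 5400.0)


def rate_design(
    peptide_rates: dict[tuple[int, int], dict[str, float]],
    sequence_length: int | None = None,
    noise_sd: float = 3.1,
    n_replicates: int = 2,
    seed: int = 0,
    k_int: float = 1.0,
    k_close: float = 100.0,
    timepoints: tuple[float, ...] = REFERENCE_TIMEPOINTS,
) -> SimulationDesign:
    """Build a design where every residue of a peptide shares that
    peptide's per-state observed exchange rate (EX2 regime).

    ``peptide_rates`` maps (start, end) to {state label: k_obs s^-1}; the
    first state label of the first peptide is the baseline condition.
    """
    length = sequence_length or max(e for _, e in peptide_rates)
    sequence = "A" * length
    state_labels = list(next(iter(peptide_rates.values())))
    states = [ProteinState.from_label(lbl) for lbl in state_labels]
    base = state_labels[0]

    peptides = [
        Peptide(start=s, end=e, sequence=sequence[s - 1 : e], protein_id="synthetic")
        for s, e in sorted(peptide_rates)
    ]
    k_int_arr = np.full(length, k_int)
    k_close_arr = np.full(length, k_close)
    k_open_arr = np.full(length, k_open_for_rate(1e-4, k_int, k_close))
    multipliers = {lbl: np.ones(length) for lbl in state_labels}
    for (s, e), rates in peptide_rates.items():
        base_open = k_open_for_rate(rates[base], k_int, k_close)
        k_open_arr[s - 1 : e] = base_open
        for lbl in state_labels:
            multipliers[lbl][s - 1 : e] = (
                k_open_for_rate(rates[lbl], k_int, k_close) / base_open
            )
    return SimulationDesign(
        protein_id="synthetic",
        sequence=sequence,
        peptides=peptides,
        k_int=k_int_arr,
        k_open=k_open_arr,
        k_close=k_close_arr,
        states=states,
        kop_multipliers=multipliers,
        timepoints=timepoints,
        n_replicates=n_replicates,
        noise_sd=noise_sd,
        seed=seed,
    )


def brute_force_best_coverage(peptides: list[Peptide]) -> int:
    """Exhaustive-search optimum of total residues covered by a pairwise
    non-overlapping subset (independent oracle for select_nonoverlapping)."""
    best = 0
    for r in range(len(peptides) + 1):
        for combo in itertools.combinations(peptides, r):
            if all(
                not a.overlaps(b) for a, b in itertools.combinations(combo, 2)
            ):
                best = max(best, sum(len(p) for p in combo))
    return best


@pytest.fixture(scope="session")
def reference_dataset():
    """The default myoglobin-like simulated experiment (seed 0)."""
    design = myoglobin_design(seed=0)
    records, truth = simulate_dataset(design)
    return design, records, truth
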