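"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from traitseg.allocation import TraitAffinityTable
from traitseg.models import gaussian_fit, nb_fit
from traitseg.synthetic import paperlike_scenario


@pytest.fixture
def feeding_affinity() -> TraitAffinityTable:
    """Tiny affinity table with the worked mayfly example (deposit feeder = 1,
    scraper = 3), a single-affinity taxon, an uncoded taxon, and an all-zero
    coded taxon."""
    cols = pd.MultiIndex.from_tuples(
        [("feeding_style", "deposit_feeder"), ("feeding_style", "scraper"),
         ("respiration_mode", "gill"), ("respiration_mode", "tegument")],
        names=["feature", "trait"],
    )
    scores = pd.DataFrame(
        [[1, 3, 5, 0],
         [5, 0, 0, 5],
         [0, 0, 2, 3],
         [0, 0, 1, 1]],
        index=pd.Index(["Baetidae", "Elmidae", "Physidae", "Chironomidae"], name="taxon"),
        columns=cols,
    )
    uncoded = {("Physidae", "feeding_style"): ("deposit_feeder", "scraper")}
    return TraitAffinityTable(scores=scores, uncoded=uncoded)


@pytest.fixture(scope="session")
def paperlike():
    return paperlike_scenario(seed=0)


def grid_search_psi(y, x, family: str, n_grid: int = 1000) -> tuple[float, float]:
    """Exhaustive profile-likelihood breakpoint search.

    Fits the hinge model ``y ~ 1 + x + (x - psi)+`` at every candidate on a
    uniform interior grid and returns (argmax psi, grid step).  Deliberately
    brute-force and independent of the iterative estimator it checks.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    lo, hi = np.quantile(x, [0.02, 0.98])
    grid = np.linspace(lo, hi, n_grid)
    step = grid[1] - grid[0]
    best_ll, best_psi = -np.inf, grid[0]
    for psi in grid:
        X = np.column_stack([np.ones_like(x), x, np.clip(x - psi, 0.0, None)])
        # candidate must leave both segments identifiable
        if (x < psi).sum() < 3 or (x > psi).sum() < 3:
            continue
        try:
            fit = gaussian_fit(y, X) if family == "gaussian" else nb_fit(y, X)
        except Exception:
            continue
        if fit.loglik > best_ll:
            best_ll, best_psi = fit.loglik, psi
    return float(best_psi), float(step)
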