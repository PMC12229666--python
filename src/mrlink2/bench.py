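"""Simulation benchmark harness: run estimators over replicate draws.

Drives the generative model of :mod:`mrlink2.simulate` through the
estimators and collects per-replicate estimates and P values, from which
type-I error, power, AUC and precision/recall summaries are computed with
:mod:`mrlink2.meta`.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .estimators import mr_ivw, mr_ivw_ld, mr_pca, wald_ratio
from .io import LDMatrix
from .likelihood import fit_region, ld_eigen_basis, rotate_effects
from .regions import select_instruments
from .simulate import (
    RegionSimulator,
    ScenarioInfeasible,
    ScenarioSpec,
    sample_reference_ld,
    theoretical_se,
)

logger = logging.getLogger(__name__)

ALL_METHODS = ("mr_link2", "ivw", "ivw_ld", "pca")


def _run_methods(
    betaX, betaY, spec: ScenarioSpec, ld_hat: LDMatrix, basis, methods,
    stats_pair_factory,
):
    seX, seY = theoretical_se(spec)
    rows = []
    for method in methods:
        if method == "mr_link2":
            eig = rotate_effects(basis, betaX, betaY, spec.nX, spec.nY)
            fit = fit_region(eig, compute_se=False)
            rows.append(
                {"method": method, "alpha": fit.params_full.alpha,
                 "p_alpha": fit.p_alpha, "p_h2y": fit.p_h2y,
                 "h2y": spec.m * fit.params_full.sigma2y,
                 "converged": fit.converged}
            )
            continue
        exp_stats, _ = stats_pair_factory()
        iv = select_instruments(exp_stats, ld_hat)
        if method in ("ivw", "ivw_ld") and iv.size == 0:
            continue
        if method == "ivw":
            if iv.size == 1:
                j = int(iv[0])
                res = wald_ratio(betaX[j], seX[j], betaY[j], seY[j])
            else:
                res = mr_ivw(betaX[iv], betaY[iv], seY[iv])
        elif method == "ivw_ld":
            res = mr_ivw_ld(betaX[iv], betaY[iv], seY[iv],
                            ld_hat.C[np.ix_(iv, iv)])
        elif method == "pca":
            res = mr_pca(betaX, betaY, seY, ld_hat.C)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append(
            {"method": method, "alpha": res.alpha_hat, "p_alpha": res.p_alpha,
             "p_h2y": np.nan, "h2y": np.nan, "converged": res.converged}
        )
    return rows


def benchmark_scenario(
    ld: LDMatrix,
    spec: ScenarioSpec,
    replicates: int | None = None,
    seed: int | np.random.Generator = 0,
    methods=("mr_link2",),
    variance_kept: float = 0.99,
) -> pd.DataFrame:
    """Simulate ``replicates`` draws under ``spec`` and fit each method.

    Returns one row per (replicate, method) with the estimate and P values.
    Replicates whose causal-set selection is infeasible are skipped and
    counted; scenarios where more than 25% of replicates fail are reported
    empty (mirroring the completion filter applied to simulation scenarios).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    replicates = replicates if replicates is not None else spec.replicates
    sim = RegionSimulator(ld=ld, spec=spec)
    exact = spec.n_ref is None
    basis = ld_eigen_basis(ld, variance_kept) if exact else None

    rows, failures = [], 0
    for rep in range(replicates):
        try:
            betaX, betaY = sim.replicate(rng)
        except ScenarioInfeasible:
            failures += 1
            continue
        ld_hat = ld if exact else sample_reference_ld(ld, spec.n_ref, seed=rng)
        basis_rep = basis if exact else ld_eigen_basis(ld_hat, variance_kept)
        for row in _run_methods(
            betaX, betaY, spec, ld_hat, basis_rep, methods,
            lambda: sim.to_summary_stats(betaX, betaY),
        ):
            rows.append({"replicate": rep, **row})
    if failures > 0.25 * replicates:  # scenario completion filter
        logger.warning(
            "scenario completion below 75%% (%d/%d failed); reporting empty",
            failures, replicates,
        )
        return pd.DataFrame(columns=["replicate", "method", "alpha", "p_alpha",
                                     "p_h2y", "h2y", "converged"])
    return pd.DataFrame(rows)


def rejection_rate(
    ld: LDMatrix,
    spec: ScenarioSpec,
    replicates: int,
    seed,
    p_column: str = "p_alpha",
    threshold: float = 0.05,
) -> float:
    """Fraction of MR-link-2 replicates with ``p_column`` below ``threshold``.

    Runs the full simulate-and-fit loop; this is the quantity the
    type-I-error, power and pleiotropy-detection summaries are built from.
    """
    df = benchmark_scenario(ld, spec, replicates=replicates, seed=seed,
                            methods=("mr_link2",))
    p = df[p_column].to_numpy(dtype=float)
    p = p[np.isfinite(p)]
    return float(np.mean(p < threshold))
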