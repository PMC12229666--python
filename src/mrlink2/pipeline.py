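"""End-to-end pipeline: harmonize, find associated regions, estimate, meta."""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .estimators import mr_ivw, mr_ivw_ld, mr_pca, wald_ratio
from .harmonize import harmonize_pair
from .io import (
    LDMatrix,
    MRResult,
    SummaryStats,
    compute_ld,
    read_ld_matrix,
    read_summary_stats,
    write_results,
)
from .likelihood import run_mr_link2
from .meta import cochran_q, meta_analyze
from .plink import read_genotype_panel
from .regions import clump, regions_from_clumps, select_instruments, variants_in_region

logger = logging.getLogger(__name__)

DEFAULTS = {
    "methods": ["mr_link2", "ivw", "ivw_ld", "pca"],
    "clump_kb": 250.0,
    "clump_r2": 0.01,
    "clump_p": 5e-8,
    "maf_threshold": 0.005,
    "completeness": 0.95,
    "variance_kept": 0.99,
    "keep_palindromic": False,
    "meta": True,
    "seed": 0,
}


class ConfigError(ValueError):
    """A run manifest is missing or misusing a field."""


def _load_reference(config) -> LDMatrix:
    if "ld_bed" in config:
        panel = read_genotype_panel(config["ld_bed"])
        return compute_ld(panel)
    if "ld_matrix" in config and "ld_variants" in config:
        return read_ld_matrix(config["ld_matrix"], config["ld_variants"])
    raise ConfigError(
        "manifest must provide an LD reference: either 'ld_bed' or "
        "'ld_matrix' + 'ld_variants'"
    )


def estimate_region(
    exposure: SummaryStats,
    outcome: SummaryStats,
    ld: LDMatrix,
    methods,
    region_bounds=None,
    clump_p: float = 5e-8,
    clump_r2: float = 0.01,
    variance_kept: float = 0.99,
) -> list[MRResult]:
    """All requested estimators on one harmonized, region-restricted input."""
    results = []
    nX = float(np.max(exposure.n))
    nY = float(np.max(outcome.n))
    iv = None
    for method in methods:
        if method == "mr_link2":
            res = run_mr_link2(
                exposure.beta, outcome.beta, ld, nX, nY,
                variance_kept=variance_kept, region_bounds=region_bounds,
            )
        elif method in ("ivw", "ivw_ld"):
            if iv is None:
                iv = select_instruments(exposure, ld, p_thresh=clump_p,
                                        r2_thresh=clump_r2)
            if iv.size == 0:
                logger.warning("region %s: no instruments for %s", region_bounds, method)
                continue
            if method == "ivw":
                if iv.size == 1:
                    j = int(iv[0])
                    res = wald_ratio(
                        exposure.beta[j], exposure.se[j],
                        outcome.beta[j], outcome.se[j], region=region_bounds,
                    )
                else:
                    res = mr_ivw(exposure.beta[iv], outcome.beta[iv],
                                 outcome.se[iv], region=region_bounds)
            else:
                res = mr_ivw_ld(
                    exposure.beta[iv], outcome.beta[iv], outcome.se[iv],
                    ld.C[np.ix_(iv, iv)], region=region_bounds,
                )
        elif method == "pca":
            res = mr_pca(exposure.beta, outcome.beta, outcome.se, ld.C,
                         variance_kept=variance_kept, region=region_bounds)
        else:
            raise ConfigError(f"unknown method {method!r}")
        results.append(res)
    return results


def run_pipeline(config: dict) -> list[MRResult]:
    """Execute a full run from a manifest dict; returns all regional results.

    Writes a results TSV and a JSON manifest (versions, thresholds, per-stage
    record counts) next to it when ``out`` is given.
    """
    cfg = {**DEFAULTS, **config}
    for required in ("exposure", "outcome"):
        if required not in cfg:
            raise ConfigError(f"manifest is missing required field {required!r}")

    counts = {}
    reference = _load_reference(cfg)
    exposure = read_summary_stats(
        cfg["exposure"], cfg.get("exposure_columns"), cfg.get("exposure_n")
    )
    outcome = read_summary_stats(
        cfg["outcome"], cfg.get("outcome_columns"), cfg.get("outcome_n")
    )
    counts["exposure_in"], counts["outcome_in"] = len(exposure), len(outcome)

    exp_h, out_h, ld = harmonize_pair(
        exposure, outcome, reference,
        maf_threshold=cfg["maf_threshold"],
        completeness=cfg["completeness"],
        keep_palindromic=cfg["keep_palindromic"],
    )
    counts["harmonized"] = len(exp_h)

    clumps = clump(exp_h, ld, window_kb=cfg["clump_kb"],
                   r2_thresh=cfg["clump_r2"], p_thresh=cfg["clump_p"])
    regions = regions_from_clumps(exp_h, clumps, window_kb=cfg["clump_kb"])
    counts["clumps"], counts["regions"] = len(clumps), len(regions)
    logger.info("pipeline: %d harmonized variants, %d regions", len(exp_h), len(regions))

    results: list[MRResult] = []
    for region in regions:
        rows = variants_in_region(exp_h, region)
        bounds = (region.chrom, region.start, region.end)
        results.extend(
            estimate_region(
                exp_h.take(rows), out_h.take(rows), ld.submatrix(rows),
                cfg["methods"], region_bounds=bounds,
                clump_p=cfg["clump_p"], clump_r2=cfg["clump_r2"],
                variance_kept=cfg["variance_kept"],
            )
        )

    meta_rows = []
    if cfg["meta"] and len(regions) >= 1:
        for method in cfg["methods"]:
            per_method = [r for r in results if r.method == method]
            try:
                mr = meta_analyze(per_method)
            except ValueError:
                continue
            q = cochran_q(per_method, mr) if mr.k >= 2 else np.nan
            meta_rows.append(
                {"method": method, "alpha_bar": mr.alpha_bar, "se_bar": mr.se_bar,
                 "p": mr.p, "q": q, "k": mr.k}
            )

    if "out" in cfg:
        out = Path(cfg["out"])
        out.parent.mkdir(parents=True, exist_ok=True)
        write_results(results, out)
        manifest = {
            "version": __version__,
            "seed": cfg["seed"],
            "thresholds": {
                k: cfg[k]
                for k in ("clump_kb", "clump_r2", "clump_p", "maf_threshold",
                          "completeness", "variance_kept")
            },
            "methods": cfg["methods"],
            "counts": counts,
            "meta": meta_rows,
        }
        out.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
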