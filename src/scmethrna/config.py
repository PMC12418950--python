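"""Pipeline configuration: defaults, schema validation, YAML loading.

The config is a nested mapping validated against the default schema before
any stage runs; unknown keys are rejected.  CLI flags override config
keys.  The single global ``seed`` fans out to per-stage seeds by stable
hashing of stage names (see :func:`scmethrna.synthetic_data.stream_rng`),
so enabling or reordering optional stages never perturbs the others.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "log_level": "INFO",
    "paths": {
        "data_dir": None,  # existing dataset dir; ignored when sim.enabled
    },
    "sim": {
        "enabled": True,
        # remaining keys are SimConfig fields; seed defaults to the global seed
        "n_cells_per_group": 16,
        "n_chrom": 2,
        "chrom_length": 2_000_000,
        "n_genes": 1000,
        "n_cgis": 150,
        "n_transposons": 80,
        "n_imprinted": 10,
        "baseline_meth": 0.47,
        "coverage_mean": 10.0,
        "cpg_capture_rate": 0.3,
        "bb_dispersion": 0.08,
        "n_dmrs_planted": 50,
        "dmr_delta": 0.4,
        "n_degs_planted": 150,
        "deg_log2fc": 2.5,
        "nb_dispersion": 0.3,
        "libsize_lognormal_sigma": 0.25,
        "mito_fraction": 0.02,
        "cpg_spacing": 80.0,
        "window_width": 1000,
    },
    "qc": {
        "rna": {
            "min_reads": 25_000,
            "min_genes": 5_000,
            "max_genes": 7_500,
            "max_counts": 2_000_000,
            "max_pct_mito": 5.0,
        },
        "bs": {
            "min_cpgs": 500_000,
            "min_global_meth_pct": 30.0,
            "max_global_meth_pct": 70.0,
        },
    },
    "regions": {
        "min_cov_per_cpg": 5,
        "pooling": "reads",
        "window_width": 1000,
        "promoter_flank": 2000,
        "vmr_top_fraction": 0.02,
        "vmr_min_cells": None,
        "imprint_tolerance": 0.1,
    },
    "dmr": {
        "min_cell_fraction_per_group": 0.5,
        "min_mean_reads_per_group": 10.0,
        "alpha": 0.05,
        "min_delta": 0.1,
        "hyper_threshold": 0.75,
        "hypo_threshold": 0.25,
        "test_variant": "welch",
        "rule3_mode": "region_reads",
        "bh_correct": False,
    },
    "deg": {
        "alpha": 0.05,
        "lfc_min": 2.0,
        "n_hvg": 2000,
        "n_pcs": 10,
        "pseudocount": 0.5,
        "min_cells_expressed": 3,
        "dispersion_shrinkage": 0.5,
    },
    "integration": {
        "K": 2,
        "lam": 1.0,
        "max_iter": 500,
        "tol": 1e-6,
        "marker_alpha": 0.05,
        "marker_min_fc": 0.25,
        "max_distance": 500_000,
        "min_abs_r": 0.5,
        "min_r_diff": 0.1,
        "guard_r": 0.2,
        "min_pairs": 5,
    },
}

#: scaled-down demo run: a small genome that exercises every stage quickly,
#: with QC thresholds scaled to the synthetic genome size
DEMO_OVERRIDES: dict[str, Any] = {
    "sim": {
        "enabled": True,
        "n_cells_per_group": 16,
        "chrom_length": 300_000,
        "n_genes": 150,
        "n_cgis": 40,
        "n_transposons": 30,
        "n_imprinted": 6,
        "n_dmrs_planted": 20,
        "n_degs_planted": 20,
        "cpg_capture_rate": 0.4,
    },
    "qc": {
        "rna": {"min_reads": 500, "min_genes": 50, "max_genes": 10_000,
                "max_counts": 10_000_000, "max_pct_mito": 5.0},
        "bs": {"min_cpgs": 1_000},
    },
    "deg": {"n_hvg": 100, "n_pcs": 5},
}


def _merge(defaults: Mapping[str, Any], override: Mapping[str, Any], path: str = "") -> dict:
    out = copy.deepcopy(dict(defaults))
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in out:
            raise ValueError(f"unknown config key: {here}")
        if isinstance(out[key], Mapping) and isinstance(value, Mapping):
            out[key] = _merge(out[key], value, here)
        elif isinstance(out[key], Mapping) != isinstance(value, Mapping):
            raise ValueError(f"config key {here} must be a {'mapping' if isinstance(out[key], Mapping) else 'scalar'}")
        else:
            out[key] = value
    return out


def build_config(overrides: Mapping[str, Any] | None = None) -> dict:
    """Defaults merged with ``overrides``; unknown keys raise."""
    return _merge(DEFAULTS, overrides or {})


def demo_config(seed: int | None = None) -> dict:
    cfg = _merge(DEFAULTS, DEMO_OVERRIDES)
    if seed is not None:
        cfg["seed"] = int(seed)
    return cfg


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: config must be a mapping")
    return build_config(raw)


def sim_config_from(cfg: Mapping[str, Any]):
    """Build a SimConfig from the pipeline config (global seed fans in)."""
    from .synthetic_data import SimConfig

    sim = {k: v for k, v in cfg["sim"].items() if k != "enabled"}
    sim["seed"] = cfg["seed"]
    return SimConfig.from_dict(sim)
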