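"""Pipeline configuration: defaults for every tunable threshold, YAML loading.

Defaults carry the study's stated values (quality cutoffs RD>10 / MQ>40 /
QD>2, 5% reference-MAF cap, the 1-homozygote / 2-heterozygote cohort caps,
CADD >= 20, k=4 clusters, 3 embedding dimensions, alpha=0.05).
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_config"]

DEFAULTS: dict = {
    "filters": {
        "rd_min": 10.0,
        "mq_min": 40.0,
        "qd_min": 2.0,
        "maf_cutoff": 0.05,
        "max_hom_carriers": 1,
        "max_het_carriers": 2,
        "cadd_damaging": 20.0,
    },
    "cohort": {
        "n_unrelated": 164,
        "n_sibpairs": 5,
        "n_genes": 101,
    },
    "clustering": {
        "k": 4,
        "dims": 3,
        "n_init": 50,
        "unit": "bits",
        "max_missing": 0.5,
    },
    "testing": {
        "alpha": 0.05,
        "bonferroni": False,
    },
    "seed": 0,
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise TypeError(f"configuration key {here} must be a mapping")
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config file, validated against and merged over the defaults."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise TypeError(f"config file {path} must contain a mapping")
    return _merge(DEFAULTS, user)
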