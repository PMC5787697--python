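"""Pipeline configuration: nested defaults, YAML overlay, strict keys.

Every random stage has an explicit seed in the config so a run is fully
reproducible; unknown keys anywhere in the overlay are rejected.
"""

from __future__ import annotations

import copy

import yaml

__all__ = ["default_config", "load_config", "merge_config"]


def default_config() -> dict:
    return {
        "run": {
            "output_dir": "clipshift_out",
            "log_level": "INFO",
        },
        "inputs": {
            # leave empty to simulate; otherwise paths to existing files
            "simulate": True,
            "fasta": None,
            "gtf": None,
            "reads": None,
            "events": None,
        },
        "simulate": {
            "seed": 11,
            "n_reads": 20_000,
            "n_events": 300,
            "genome": {
                "n_chromosomes": 2,
                "chromosome_length": 300_000,
                "n_genes": 30,
            },
            "binding": {
                "region_weights": {
                    "exon_boundary": 3.0,
                    "intron": 1.0,
                    "intergenic": 1.0,
                },
                "gc_bias_exponent": 1.0,
                "conversion_probability": 0.8,
                "background_rate": 0.1,
                "n_sites": 200,
            },
        },
        "callpeaks": {
            "min_conversion_frequency": 0.25,
            "min_converted_reads": 6,
            "min_conversion_sites": 2,
        },
        "annotate": {
            "promoter_width": 1000,
            "rescue_distance": 10_000,
        },
        "kmers": {
            "k": 4,
            "window": 20,
            "flank": 20,
            "shuffles": 20,
            "seed": 12,
            "mode": "flank",
        },
        "boundaries": {
            "method": "random-regions",
            "n_regions": 2_000,
            "region_length": 5_000,
            "seed": 13,
        },
        "splicemap": {
            "exon_flank": 50,
            "intron_window": 250,
            "smoothing_window": 50,
            "n_permutations": 200,
            "seed": 14,
        },
        "emsa": {
            "n_true": 1.75,
            "K_true": 1.95e6,
            "noise_sd": 0.03,
            "seed": 15,
        },
    }


def merge_config(base: dict, overlay: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in (overlay or {}).items():
        where = f"{path}.{key}" if path else key
        if key not in out:
            raise ValueError(f"unknown configuration key: {where}")
        if isinstance(out[key], dict) and isinstance(value, dict):
            # free-form subsections (e.g. region weights) replace wholesale
            if key in ("region_weights",):
                out[key] = copy.deepcopy(value)
            else:
                out[key] = merge_config(out[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path=None) -> dict:
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            overlay = yaml.safe_load(fh) or {}
        cfg = merge_config(cfg, overlay)
    _validate(cfg)
    return cfg


def _validate(cfg: dict):
    if not cfg["inputs"]["simulate"]:
        for field in ("fasta", "gtf", "reads"):
            if not cfg["inputs"][field]:
                raise ValueError(
                    f"inputs.{field} is required when inputs.simulate is false"
                )
    for section in ("simulate", "kmers", "boundaries", "splicemap", "emsa"):
        if "seed" in cfg[section] and cfg[section]["seed"] is None:
            raise ValueError(f"{section}.seed must be an explicit integer")
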