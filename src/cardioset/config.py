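"""Pipeline configuration with defaults for the reference analysis protocol."""

from __future__ import annotations

import copy

import yaml

__all__ = ["default_pipeline_config", "load_config", "merge_config"]


def default_pipeline_config() -> dict:
    """Nested default configuration for every pipeline stage."""
    return {
        "seed": 0,
        "workdir": "runs/default",
        "synthetic": {
            "sample_rate": 4000.0,
            "duration": 15.0,
            "n_channels": 4,
            "heart_rate": 60.0,
            "murmur_band": [150.0, 400.0],
            "murmur_snr_db": 0.0,
            "noise_snr_db": 20.0,
            "channel_delays": [0, 3, -2, 5],
            "n_subjects": 12,
        },
        "preprocess": {
            "window_seconds": 1.5,
            "window_overlap": 0.5,
            "dw_offset_seconds": 0.100,
            "dw_length_seconds": 0.128,
            "segment_kind": "full_cycle_window",  # or "diastolic_window"
            "use_annotations": True,  # prefer sidecar S2 onsets when present
        },
        "mp": {
            "n_atoms": 100,
            "octave_range": [2, 12],
            "freq_cap_hz": 1000.0,
        },
        "features": {
            "ablate_patient_id": False,
        },
        "split": {
            "fractions": [0.70, 0.15, 0.15],
            "batch_size": 16,
        },
        "search": {
            "n_trials": 25,
            "max_epochs": 200,
            "patience": 20,
            "space": {
                "latent_dim": [4, 512],
                "hidden_dim": [4, 512],
                "pooling": ["mean", "max", "attention", "sum"],
                "dropout_rate": [0.0, 0.5],
                "regularization": ["None", "LayerNorm", "BatchNorm"],
                "learning_rate": [1.0e-4, 1.0e-2],  # log scale
                "weight_decay": [1.0e-6, 1.0e-2],   # log scale
            },
        },
        "interpret": {
            "dbscan_eps": 0.5,
            "dbscan_min_points": 5,
            "gaussian_sigma": 5.0,
            "butter_order": 5,
            "butter_band_hz": [65.0, 400.0],
            "band_width_hz": 50.0,
            "band_range_hz": [0.0, 400.0],
            "group_tolerance": 1.0e-6,
            "umap_neighbors": 15,
        },
    }


def load_config(path: str | None) -> dict:
    config = default_pipeline_config()
    if path is not None:
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        config = merge_config(config, overrides)
    return config


def merge_config(base: dict, overrides: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in overrides.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], value)
        else:
            out[key] = value
    return out
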