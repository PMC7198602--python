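"""Default run configuration; every tunable of the pipeline in one place."""

from __future__ import annotations

import copy

DEFAULT_CONFIG: dict = {
    "scene": {
        "canvas_shape": [32, 256, 256],  # voxels, (Z, Y, X)
        "voxel_size_nm": [125.0, 40.0, 40.0],  # nm, (Z, Y, X)
        "n_rings": 12,
        "diameter_mean_nm": 240.0,  # MEF-like population
        "diameter_sd_nm": 60.0,
        "tube_sigma_nm": 40.0,
        "amplitude": 100.0,
        "coloc_mixing": 0.9,
        "jitter_sd_nm": 20.0,
    },
    "blur": {"sigma_xy_nm": 50.0, "sigma_z_nm": 150.0},
    "noise": {"photon_scale": 1.0, "read_sigma": 2.0, "background": 5.0},
    "coloc": {"n_perm": 199, "block_nm": 240.0},
    "rings": {
        "profile_length_nm": 1000.0,
        "min_voxels": 27,
        "psf_correction": True,  # subtract blur covariance in the plane fit
    },
    "compaction": {
        "region_bp": 15_000,
        "nm_per_nt": 0.33,
        "compaction_range": [6.0, 7.0],
    },
    "stages": {
        "simulate": True,
        "coloc": True,
        "rings": True,
        "compaction": True,
        "report": True,
    },
}


def merged_config(overrides: dict | None = None) -> dict:
    """Defaults deep-merged with user overrides (overrides win, per key)."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst: dict, src: dict) -> None:
        for key, val in src.items():
            if isinstance(val, dict) and isinstance(dst.get(key), dict):
                merge(dst[key], val)
            else:
                dst[key] = val

    if overrides:
        merge(cfg, overrides)
    return cfg
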