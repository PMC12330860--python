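"""End-to-end orchestration: simulate -> estimate -> analyze.

A single YAML config drives every stage; all randomness is routed
through one master seed that spawns per-stage seeds.  Each run writes a
JSON manifest with the config hash, seeds, output paths and content
digests, so identical configs reproduce identical results.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .callosum import (
    SECTION_NAMES,
    DiameterHistogram,
    effective_diameter,
    section_callosum,
    section_stats,
)
from .echo_model import EchoTrainSpec, TissueParams, add_magnitude_noise, simulate_se_signal
from .io import save_echo_volume, save_nifti, save_voxel_table
from .orientation import (
    bin_by_sin4,
    compute_dbar,
    comparison_table,
    model_comparison,
    select_voxels,
)
from .phantom import PhantomConfig, build_phantom, default_tracts
from .relaxometry import r2_map_pair_average

__all__ = ["run_all", "load_config", "default_config", "default_section_histograms"]


def default_config() -> dict:
    return {
        "seed": 20250707,
        "phantom": {
            "shape": [48, 56, 48],
            "voxel_size_mm": [1.0, 1.0, 2.0],
            "noise_sigma": 0.0,
            "n_voxels_per_tract": 250,
            "kappa": 8.0,
            "model_coeffs": [22.08, -6.06, 3.49, 0.0],
        },
        "estimate": {"n_min": 6, "n_max": 11},
        "orientation": {"fa_min": 0.4, "prob_min": 0.25, "weighted": False},
        "callosum": {"enabled": True},
    }


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "seed" not in cfg:
        raise ValueError("config must be a mapping with a mandatory 'seed'")
    return cfg


def default_section_histograms() -> dict[str, DiameterHistogram]:
    """Synthetic per-section diameter histograms (anterior sections finer)."""
    base_d = np.array([0.4, 0.8, 1.2, 2.0, 3.0])
    shifts = {"genu": 0.0, "anterior_body": 0.4, "isthmus": 0.9, "splenium": 0.6}
    freqs = np.array([40.0, 30.0, 15.0, 10.0, 5.0])
    return {
        name: DiameterHistogram(base_d + shift, freqs)
        for name, shift in shifts.items()
    }


def _phantom_config(cfg: dict, seed: int) -> PhantomConfig:
    p = cfg.get("phantom", {})
    tracts = default_tracts(
        n_voxels=int(p.get("n_voxels_per_tract", 250)),
        kappa=float(p.get("kappa", 8.0)),
    )
    return PhantomConfig(
        shape=tuple(p.get("shape", (48, 56, 48))),
        voxel_size_mm=tuple(p.get("voxel_size_mm", (1.0, 1.0, 2.0))),
        tracts=tracts,
        model_coeffs=tuple(p.get("model_coeffs", (22.08, -6.06, 3.49, 0.0))),
        noise_sigma=float(p.get("noise_sigma", 0.0)),
        seed=seed,
        b0_direction=tuple(p.get("b0_direction", (0.0, 0.0, 1.0))),
    )


def _digest(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def run_all(config: dict | str | Path, outdir) -> dict:
    """Run phantom -> echo simulation -> estimation -> analyses.

    Returns the manifest (also written to ``outdir/manifest.json``).
    """
    if not isinstance(config, dict):
        cfg_path = Path(config)
        cfg = load_config(cfg_path)
        cfg_bytes = cfg_path.read_bytes()
    else:
        cfg = config
        cfg_bytes = json.dumps(cfg, sort_keys=True).encode()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    master_seed = int(cfg["seed"])
    stage_seeds = {
        name: int(s.generate_state(1)[0])
        for name, s in zip(
            ("phantom", "noise"), np.random.SeedSequence(master_seed).spawn(2)
        )
    }
    manifest: dict = {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(cfg_bytes).hexdigest(),
        "master_seed": master_seed,
        "stage_seeds": stage_seeds,
        "stages": {},
    }
    digests = []

    def record(stage: str, outputs: dict, digest: str, **extra) -> None:
        manifest["stages"][stage] = {"outputs": outputs, "sha256": digest, **extra}
        digests.append(digest)

    # --- phantom -----------------------------------------------------------
    try:
        pconf = _phantom_config(cfg, stage_seeds["phantom"])
        vol = build_phantom(pconf)
    except Exception as exc:
        raise RuntimeError(f"stage 'phantom' failed: {exc}") from exc
    save_nifti(vol.labels, outdir / "labels.nii", vol.affine)
    save_nifti(vol.R2, outdir / "R2_true.nii", vol.affine)
    save_nifti(vol.FA, outdir / "FA.nii", vol.affine)
    save_nifti(vol.tract_prob, outdir / "tract_prob.nii", vol.affine)
    save_nifti(vol.pev, outdir / "pev.nii", vol.affine)
    record(
        "phantom",
        {k: f"{k}.nii" for k in ("labels", "R2_true", "FA", "tract_prob", "pev")},
        _digest(vol.labels, vol.R2, vol.FA, vol.tract_prob, vol.pev),
    )

    # --- echo simulation ---------------------------------------------------
    spec = (
        EchoTrainSpec.from_dict(cfg["echo"]) if "echo" in cfg else EchoTrainSpec.default()
    )
    try:
        tissue = TissueParams(M0=vol.M0, R2=vol.R2, R2prime=vol.R2prime)
        series = simulate_se_signal(tissue, spec.se_TEs, spec)
        if pconf.noise_sigma > 0:
            series = add_magnitude_noise(
                series, pconf.noise_sigma, model="rician", seed=stage_seeds["noise"]
            )
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    save_echo_volume(series.values, series.echo_TEs, outdir / "echoes.nii", vol.affine)
    spec.to_json(outdir / "echo_timing.json")
    record(
        "simulate",
        {"echoes": "echoes.nii", "timing": "echo_timing.json"},
        _digest(series.values),
        noise_sigma=pconf.noise_sigma,
    )

    # --- R2 estimation -----------------------------------------------------
    est = cfg.get("estimate", {})
    n_range = range(int(est.get("n_min", 6)), int(est.get("n_max", 11)) + 1)
    try:
        rates = r2_map_pair_average(series, spec, n_range)
    except Exception as exc:
        raise RuntimeError(f"stage 'estimate' failed: {exc}") from exc
    save_nifti(np.nan_to_num(rates.R2, nan=0.0), outdir / "R2_est.nii", vol.affine)
    save_nifti(rates.valid_mask.astype(np.int8), outdir / "valid_mask.nii", vol.affine)
    record(
        "estimate",
        {"R2": "R2_est.nii", "valid_mask": "valid_mask.nii"},
        _digest(np.nan_to_num(rates.R2, nan=-1.0), rates.valid_mask),
        n_min=n_range.start,
        n_max=n_range.stop - 1,
    )

    # --- orientation analysis ----------------------------------------------
    ocfg = cfg.get("orientation", {})
    try:
        table = vol.voxel_table(R2_map=rates.R2)
        selected = select_voxels(
            table,
            fa_min=float(ocfg.get("fa_min", 0.4)),
            prob_min=float(ocfg.get("prob_min", 0.25)),
        )
        d_bar = compute_dbar(selected)
        obs = bin_by_sin4(selected, b0=np.asarray(pconf.b0_direction))
        results = model_comparison(obs, d_bar, weighted=bool(ocfg.get("weighted", False)))
    except Exception as exc:
        raise RuntimeError(f"stage 'orientation' failed: {exc}") from exc
    save_voxel_table(selected, outdir / "voxel_table.tsv")
    obs.to_csv(outdir / "binned_observations.tsv", sep="\t", index=False)
    comp = comparison_table(results)
    comp.to_csv(outdir / "model_comparison.tsv", sep="\t", index=False)
    with open(outdir / "fit_summary.json", "w") as fh:
        json.dump([r.to_dict() for r in results], fh, indent=2)
    record(
        "orientation",
        {
            "voxel_table": "voxel_table.tsv",
            "binned": "binned_observations.tsv",
            "comparison": "model_comparison.tsv",
            "summary": "fit_summary.json",
        },
        hashlib.sha256(comp.to_csv(index=False).encode()).hexdigest(),
        n_selected=int(len(selected)),
        d_bar_um=float(d_bar),
    )

    # --- callosum analysis --------------------------------------------------
    if cfg.get("callosum", {}).get("enabled", True):
        try:
            sectioning = section_callosum(vol.cc_mask)
            hists = default_section_histograms()
            d_eff = {name: effective_diameter(h) for name, h in hists.items()}
            stats = section_stats(rates.R2, sectioning, d_eff=d_eff)
        except Exception as exc:
            raise RuntimeError(f"stage 'callosum' failed: {exc}") from exc
        with open(outdir / "callosum_stats.json", "w") as fh:
            json.dump(stats, fh, indent=2)
        record(
            "callosum",
            {"stats": "callosum_stats.json"},
            hashlib.sha256(json.dumps(stats, sort_keys=True).encode()).hexdigest(),
        )

    manifest["content_hash"] = hashlib.sha256("".join(digests).encode()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
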