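"""Run configuration and stage orchestration.

A ``RunConfig`` collects the acquisition, dictionary, noise and cohort
parameters (defaults match the study-stated constants: dictionary 3-300 ms
in 0.1 ms steps, nerve T1 1600 ms, muscle T1 1400 ms) and a seed.
``run_pipeline`` executes an ordered subset of stages on the demo phantom
chain and writes a manifest so that a run is reproducible from its config
and seed alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort_stats import (
    condition_table,
    pairwise_paired_t_bonferroni,
    rm_anova_oneway,
)
from .io import file_sha256, write_labels, write_t2_map, write_volume
from .roi_analysis import RoiMask, roi_stats
from .signal_models import AcquisitionParams
from .synthetic_data import (
    CohortSpec,
    NoiseSpec,
    add_rician_noise_pair,
    default_phantom_spec,
    make_phantom,
    simulate_cohort,
    simulate_dess,
    surrogate_denoise,
)
from .t2_mapping import compute_dess_t2_map

logger = logging.getLogger("desst2")

STAGES = ("simulate", "noise", "denoise", "map", "roi", "analyze")


@dataclass
class RunConfig:
    """Snapshot of every parameter a pipeline run depends on."""

    tr_ms: float = 20.0
    te_ms: float = 5.0
    flip_deg: float = 20.0
    dict_min_ms: float = 3.0
    dict_max_ms: float = 300.0
    dict_step_ms: float = 0.1
    t1_nerve_ms: float = 1600.0
    t1_muscle_ms: float = 1400.0
    snr: float = 20.0
    denoise_method: str = "gaussian"
    denoise_strength: float = 1.0
    n_subjects: int = 25
    seed: int = 0

    @property
    def acq(self) -> AcquisitionParams:
        return AcquisitionParams(self.tr_ms, self.te_ms, self.flip_deg)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: RunConfig, stages, out_dir) -> dict:
    """Execute pipeline stages in order on the demo phantom chain.

    Stage dependencies are checked (e.g. ``map`` needs echo volumes from
    ``simulate``/``noise``/``denoise``; ``roi`` needs a T2 map).  Every run
    writes a manifest (config snapshot, package version, seed, output
    hashes, timestamps) to ``manifest.json`` in ``out_dir``.
    """
    stages = list(stages)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; choose from {STAGES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    state: dict = {}
    t0 = time.time()

    def record(name: str, path: Path) -> None:
        outputs[name] = str(path)

    for stage in stages:
        logger.info("stage %s (config seed=%d)", stage, config.seed)
        if stage == "simulate":
            maps = make_phantom(default_phantom_spec())
            sp, sm = simulate_dess(maps, config.acq)
            state.update(maps=maps, s_plus=sp, s_minus=sm)
            write_volume(sp, out / "s_plus.nii.gz")
            write_volume(sm, out / "s_minus.nii.gz")
            write_labels(maps.labels, out / "labels.nii.gz", out / "labels.csv")
            record("s_plus", out / "s_plus.nii.gz")
            record("s_minus", out / "s_minus.nii.gz")
            record("labels", out / "labels.nii.gz")
        elif stage == "noise":
            if "s_plus" not in state:
                raise RuntimeError("stage 'noise' requires echo volumes from 'simulate'")
            noise = NoiseSpec(snr=config.snr, seed=config.seed)
            sp, sm = add_rician_noise_pair(
                state["s_plus"], state["s_minus"], noise, state["maps"].labels
            )
            state.update(s_plus=sp, s_minus=sm)
            write_volume(sp, out / "s_plus_noisy.nii.gz")
            write_volume(sm, out / "s_minus_noisy.nii.gz")
            record("s_plus_noisy", out / "s_plus_noisy.nii.gz")
            record("s_minus_noisy", out / "s_minus_noisy.nii.gz")
        elif stage == "denoise":
            if "s_plus" not in state:
                raise RuntimeError("stage 'denoise' requires echo volumes")
            sp = surrogate_denoise(state["s_plus"], config.denoise_method,
                                   config.denoise_strength)
            sm = surrogate_denoise(state["s_minus"], config.denoise_method,
                                   config.denoise_strength)
            state.update(s_plus=sp, s_minus=sm)
            write_volume(sp, out / "s_plus_denoised.nii.gz")
            write_volume(sm, out / "s_minus_denoised.nii.gz")
            record("s_plus_denoised", out / "s_plus_denoised.nii.gz")
            record("s_minus_denoised", out / "s_minus_denoised.nii.gz")
        elif stage == "map":
            if "s_plus" not in state:
                raise RuntimeError(
                    "stage 'map' requires echo volumes (run 'simulate' first)"
                )
            t2map = compute_dess_t2_map(
                state["s_plus"], state["s_minus"], state["maps"].labels, config.acq,
                t2_min=config.dict_min_ms, t2_max=config.dict_max_ms,
                step=config.dict_step_ms,
            )
            n_clamped = int(((t2map.flags == 1) | (t2map.flags == 2)).sum())
            if n_clamped:
                logger.warning("%d voxels clamped to the dictionary range", n_clamped)
            state["t2map"] = t2map
            write_t2_map(t2map, out / "t2_map.nii.gz", out / "t2_flags.nii.gz")
            record("t2_map", out / "t2_map.nii.gz")
        elif stage == "roi":
            if "t2map" not in state:
                raise RuntimeError(
                    "stage 'roi' requires a T2 map (file t2_map.nii.gz from 'map')"
                )
            mask = RoiMask(state["maps"].labels.labels)
            rows = ["label,n_voxels,mean_t2_ms,normalized_sd,n_invalid_excluded,n_clamped"]
            for lab in state["maps"].labels.present_labels():
                st = roi_stats(state["t2map"], mask, lab)
                rows.append(
                    f"{st.label},{st.n_voxels},{st.mean_t2_ms:.6f},"
                    f"{st.normalized_sd:.6f},{st.n_invalid_excluded},{st.n_clamped}"
                )
            (out / "roi_stats.csv").write_text("\n".join(rows) + "\n")
            record("roi_stats", out / "roi_stats.csv")
        elif stage == "analyze":
            cohort = simulate_cohort(
                CohortSpec(n_subjects=config.n_subjects, seed=config.seed)
            )
            cohort.to_csv(out / "cohort.csv", index=False)
            record("cohort", out / "cohort.csv")
            rows = ["tissue,f_value,p_anova,group_a,group_b,t,p_raw,p_adjusted"]
            for tissue in ("nerve", "muscle"):
                tab = condition_table(cohort, tissue)
                an = rm_anova_oneway(tab)
                for pr in pairwise_paired_t_bonferroni(tab):
                    rows.append(
                        f"{tissue},{an.f_value:.4f},{an.p_value:.3e},{pr.group_a},"
                        f"{pr.group_b},{pr.t_statistic:.4f},{pr.p_raw:.3e},"
                        f"{pr.p_adjusted:.3e}"
                    )
            (out / "analysis.csv").write_text("\n".join(rows) + "\n")
            record("analysis", out / "analysis.csv")

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": stages,
        "outputs": {k: file_sha256(v) for k, v in outputs.items()},
        "started": t0,
        "finished": time.time(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
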