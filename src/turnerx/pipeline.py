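"""End-to-end orchestration with a reproducible run manifest.

``run_all`` drives simulate/ingest -> filter -> variability -> burden ->
candidate -> mosaicism -> power from one YAML config and writes CSV/TSV
outputs plus ``manifest.json`` recording the config snapshot, the seed,
per-stage record counts (the filtering funnel) and a SHA-256 digest of
every output file, so a re-run with the same config reproduces identical
digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .burden import burden_frame, run_burden, PhenotypeGroups
from .candidate import allele_counts, candidate_frame
from .filtering import FilterConfig, apply_filter
from .io import (
    merge_cohort,
    read_annotated_export,
    read_sample_metadata,
    write_annotated_export,
    write_sample_metadata,
)
from .mosaicism import CopyMixtureModel, estimate_fraction, paired_signed_rank
from .power import power_two_proportion
from .synthetic import SimulationConfig, PlantedEffect, simulate_baf_profile, simulate_cohort
from .types import CohortTable, Group
from .variability import variability_report

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},               # SimulationConfig overrides; omit to ingest files
    "inputs": None,               # {"cohort": path, "meta": path} when not simulating
    "filters": {},                # FilterConfig overrides
    "burden": {"conditions": ["diabetes", "obesity", "autoimmunity", "hypothyroidism",
                              "hypertension", "cca"],
               "level": "gene", "af_low": 0.1, "af_high": 0.9,
               "effect_threshold": 0.35},
    "candidate": {"gene": "AG001", "condition": "cca"},
    "mosaic": {"preset": "ring", "n_profiles": 10, "n_markers": 500,
               "fraction_range": [0.1, 0.6], "drift": 0.8},
    "power": {"n1": 25, "n2": 24, "baseline": 0.3, "delta": 0.35, "alpha": 0.05},
}


@dataclass
class RunManifest:
    """Machine-readable record of one pipeline run."""

    seed: int
    config: dict
    package_version: str = __version__
    started: str = ""
    finished: str = ""
    stage_counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # filename -> sha256

    def to_json(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_config(config: str | Path | dict | None) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if config is None:
        return merged
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(config)
    for key, val in user.items():
        if key not in merged:
            raise ValueError(f"unknown config key: {key}")
        if isinstance(merged.get(key), dict) and isinstance(val, dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def _obtain_cohort(cfg: dict) -> CohortTable:
    if cfg.get("inputs"):
        paths = cfg["inputs"]
        variants = read_annotated_export(paths["cohort"])
        samples = read_sample_metadata(paths["meta"])
        return merge_cohort([variants], samples)
    sim = dict(cfg.get("simulate") or {})
    sim.setdefault("seed", cfg["seed"])
    planted = tuple(PlantedEffect(**p) for p in sim.pop("planted_effects", []))
    return simulate_cohort(SimulationConfig(planted_effects=planted, **sim))


def run_all(config: str | Path | dict | None, out_dir: str | Path) -> RunManifest:
    """Run every stage; returns the manifest (also written to disk)."""
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=int(cfg["seed"]), config=cfg,
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))

    def save(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.6g")
        manifest.outputs[name] = _digest(path)

    # stage 1: cohort
    cohort = _obtain_cohort(cfg)
    write_annotated_export(cohort.variants, out / "cohort.csv")
    write_sample_metadata(cohort.samples, out / "meta.tsv")
    manifest.outputs["cohort.csv"] = _digest(out / "cohort.csv")
    manifest.outputs["meta.tsv"] = _digest(out / "meta.tsv")
    manifest.stage_counts["cohort_variants"] = len(cohort.variants)
    manifest.stage_counts["cohort_samples"] = len(cohort.samples)

    # stage 2: the two parallel filters (the filtering funnel)
    fcfg = FilterConfig(**(cfg.get("filters") or {}))
    filtered = {}
    for mode in ("standard", "somatic"):
        sub = apply_filter(cohort.variants, mode, fcfg)
        filtered[mode] = CohortTable(variants=sub.reset_index(drop=True),
                                     samples=cohort.samples)
        save(sub, f"filtered_{mode}.csv")
        manifest.stage_counts[f"filtered_{mode}"] = len(sub)
        logger.info("filter %s: %d -> %d records", mode, len(cohort.variants), len(sub))

    # stage 3: variability
    for mode in ("standard", "somatic"):
        counts, kw = variability_report(filtered[mode], mode)
        save(counts, f"variability_counts_{mode}.csv")
        save(kw, f"variability_stats_{mode}.csv")

    # stage 4: burden screen (standard pipeline, monosomy X analysis set)
    bcfg = cfg["burden"]
    frames = []
    for condition in bcfg["conditions"]:
        results = run_burden(filtered["standard"], condition,
                             level=bcfg.get("level", "gene"),
                             af_low=bcfg.get("af_low", 0.1),
                             af_high=bcfg.get("af_high", 0.9),
                             effect_threshold=bcfg.get("effect_threshold", 0.35))
        frames.append(burden_frame(results))
    burden_all = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    save(burden_all, "burden.csv")
    manifest.stage_counts["burden_units"] = len(burden_all)

    # stage 5: candidate-gene replication
    ccfg = cfg["candidate"]
    groups = PhenotypeGroups.from_cohort(cohort, ccfg["condition"],
                                         groups=tuple(Group))
    cand = candidate_frame(allele_counts(cohort, ccfg["gene"], groups))
    save(cand, "candidate.csv")
    manifest.stage_counts["candidate_variants"] = len(cand)

    # stage 6: SNP-array mosaicism + paired comparison of original vs
    # array-derived fractions (a clonal-drift factor shrinks the variant line)
    mcfg = cfg["mosaic"]
    from .mosaicism import MODEL_PRESETS
    c1, c2 = MODEL_PRESETS[mcfg.get("preset", "ring")]
    lo, hi = mcfg.get("fraction_range", [0.1, 0.6])
    import numpy as np
    rng = np.random.default_rng(int(cfg["seed"]) + 1)
    originals = rng.uniform(lo, hi, int(mcfg.get("n_profiles", 10)))
    rows = []
    for i, f_orig in enumerate(originals):
        f_now = float(f_orig) * float(mcfg.get("drift", 1.0))
        model = CopyMixtureModel(c1=c1, a1=0, c2=c2, a2=1, f=f_now)
        profile = simulate_baf_profile(model, n_markers=int(mcfg.get("n_markers", 500)),
                                       seed=int(cfg["seed"]) * 1000 + i)
        est = estimate_fraction(profile, preset=mcfg.get("preset", "ring"))
        rows.append({"profile": i, "original_fraction": float(f_orig),
                     "array_fraction": est.f_hat, "n_markers": est.n_markers})
    mosaic_df = pd.DataFrame(rows)
    mosaic_df.attrs["wilcoxon_p"] = paired_signed_rank(
        mosaic_df["original_fraction"], mosaic_df["array_fraction"])
    save(mosaic_df, "mosaic.csv")
    manifest.stage_counts["mosaic_profiles"] = len(mosaic_df)

    # stage 7: power
    pcfg = cfg["power"]
    pw = power_two_proportion(n1=int(pcfg["n1"]), n2=int(pcfg["n2"]),
                              p_without=float(pcfg["baseline"]),
                              delta=float(pcfg["delta"]), alpha=float(pcfg["alpha"]))
    save(pd.DataFrame([{**pcfg, "power": pw}]), "power.csv")

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.to_json(out / "manifest.json")
    return manifest
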