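"""End-to-end simulated-subject experiment.

For each simulated subject: build a counterbalanced schedule, draw a
ground-truth phantom, simulate the crossed-design session (and optionally a
standard-localizer session per defining contrast), fit the GLMs, apply the
detection rule and the top-fraction fROI rule, compute split-half
selectivity profiles, and aggregate across subjects (mean profiles per
parcel, detection counts, Dice within/between sessions, selectivity ANOVA).

All randomness derives from one root seed: a PCG64 stream seeded with it
draws, in a fixed documented order, one (schedule, phantom, session A,
session B) seed tuple per subject, so re-running a config is reproducible
bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import froi as froi_mod
from . import validation
from .design import ALL_CONDITIONS, generate_schedule
from .froi import SPLITS, crossval_profile, detect_fixed_threshold, parcels_from_phantom
from .glm import CONTRASTS, compute_contrast, fit_session, get_contrast
from .simulate import (
    DEFAULT_GRID,
    DEFAULT_PARCELS,
    NoiseParams,
    ParcelSpec,
    StandardDesign,
    make_phantom,
    simulate_session,
    simulate_standard_localizer,
)

logger = logging.getLogger("emfl")

STAGE_VERSION = "1"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, subject: int, cause: Exception):
        super().__init__(f"stage {stage!r} failed for subject {subject}: {cause}")
        self.stage = stage
        self.subject = subject


@dataclass
class PipelineConfig:
    seed: int = 0
    n_subjects: int = 3
    grid_shape: tuple = DEFAULT_GRID
    parcels: tuple = DEFAULT_PARCELS
    noise: NoiseParams = field(default_factory=NoiseParams)
    base_amplitude: float = 0.5
    selectivity_ratio: float = 3.0
    split: str = "odd-even"
    top_fraction: float = 0.10
    detection_p: float = 0.001
    detection_min_voxels: int = 10
    contrasts: tuple = tuple(CONTRASTS)
    include_standard: bool = True
    standard_runs: int = 4
    out_dir: str = "emfl_out"

    def __post_init__(self):
        for name in self.contrasts:
            get_contrast(name)  # fail before any simulation
        for spec in self.parcels:
            if spec.contrast not in self.contrasts:
                raise ValueError(
                    f"parcel {spec.label!r} references contrast {spec.contrast!r} "
                    "not in the configured contrast list"
                )
        if self.split not in SPLITS:
            raise ValueError(f"unknown split scheme {self.split!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        if isinstance(raw.get("parcels"), str):
            if raw["parcels"] != "default":
                raise ValueError(f"unknown parcel preset {raw['parcels']!r}")
            raw.pop("parcels")
        elif "parcels" in raw:
            raw["parcels"] = tuple(ParcelSpec(**p) for p in raw["parcels"])
        if "noise" in raw:
            raw["noise"] = NoiseParams(**raw["noise"])
        if "contrasts" in raw:
            if raw["contrasts"] == "all":
                raw.pop("contrasts")
            else:
                raw["contrasts"] = tuple(raw["contrasts"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["parcels"] = [asdict(p) for p in self.parcels]
        d["noise"] = asdict(self.noise)
        d["grid_shape"] = list(self.grid_shape)
        d["contrasts"] = list(self.contrasts)
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def subject_seeds(root_seed: int, n_subjects: int) -> list:
    """Per-subject (schedule, phantom, session_a, session_b) seeds, drawn in
    subject order from a single PCG64 stream seeded with the root seed."""
    rng = np.random.default_rng(root_seed)
    return [tuple(int(s) for s in rng.integers(2 ** 31, size=4)) for _ in range(n_subjects)]


def _phantom_specs(config: PipelineConfig):
    return tuple(
        ParcelSpec(s.label, s.n_voxels, s.preferred, config.selectivity_ratio, s.contrast)
        for s in config.parcels
    )


def simulate_subject(config: PipelineConfig, seeds):
    """Simulate one subject: returns (phantom, emfl session, standard sessions)."""
    sched_seed, phantom_seed, seed_a, seed_b = seeds
    schedule = generate_schedule(5, seed=sched_seed)
    phantom = make_phantom(config.grid_shape, _phantom_specs(config), config.noise,
                           seed=phantom_seed, base_amplitude=config.base_amplitude)
    mask = phantom.parcels > 0
    emfl_session = simulate_session(phantom, schedule, seed=seed_a, mask=mask)
    standard = {}
    if config.include_standard:
        rng_b = np.random.default_rng(seed_b)
        needed = sorted({s.contrast for s in config.parcels})
        for contrast in needed:
            standard[contrast] = simulate_standard_localizer(
                phantom, StandardDesign(contrast, n_runs=config.standard_runs),
                seed=int(rng_b.integers(2 ** 31)), mask=mask)
    return phantom, emfl_session, standard


def _measure_pair(fit, voxels, parcel):
    pref, nonpref = parcel.preferred_pair
    return (froi_mod.condition_response(fit, pref, voxels),
            froi_mod.condition_response(fit, nonpref, voxels))


def analyze_subject(config: PipelineConfig, subject: int, phantom, emfl_session,
                    standard_sessions) -> dict:
    """All per-subject derived measures: detection flags, split-half
    profiles, Dice overlaps, and selectivity-table rows."""
    mask = phantom.parcels > 0
    parcels = parcels_from_phantom(phantom)
    split = SPLITS[config.split]
    fits = {}

    def emfl_fit(run_ids):
        key = frozenset(run_ids)
        if key not in fits:
            fits[key] = fit_session(emfl_session, run_ids, mask=mask)
        return fits[key]

    run_ids = emfl_session.run_indices
    odd = tuple(r for r in run_ids if r % 2 == 1)
    detection_rows, profile_rows, dice_rows, selectivity_rows = [], [], [], []
    for parcel in parcels:
        k = max(1, froi_mod.round_half_away(config.top_fraction * parcel.size))
        if k < 10:
            logger.warning("parcel %s: top-%d%% fROI has only %d voxels",
                           parcel.label, int(100 * config.top_fraction), k)
        for subset_name, subset in (("odd", odd), ("all", tuple(run_ids))):
            result = compute_contrast(emfl_fit(subset), parcel.defining_contrast)
            det = detect_fixed_threshold(result, parcel, config.detection_p,
                                         config.detection_min_voxels)
            detection_rows.append((subject, parcel.label, subset_name,
                                   det.detected, det.n_significant))
        profile = crossval_profile(emfl_session, parcel, split=split,
                                   fraction=config.top_fraction, mask=mask,
                                   fits=fits)
        for cond, resp in profile.response.items():
            profile_rows.append((subject, parcel.label, cond, profile.split_scheme,
                                 resp, profile.baseline))
        if standard_sessions:
            std = standard_sessions[parcel.defining_contrast]
            std_fits = {}
            for res in validation.compare_within_between(
                    emfl_session, std, parcel, fraction=config.top_fraction,
                    split=split, mask=mask, fits=std_fits):
                dice_rows.append((subject, res.parcel, res.kind, res.split_scheme,
                                  res.coefficient, res.chance_level))
            selectivity_rows.extend(
                _selectivity_rows(subject, parcel, emfl_session, std, split,
                                  config.top_fraction, mask, fits, std_fits))
    return {
        "detection": pd.DataFrame(
            detection_rows,
            columns=["subject", "parcel", "run_subset", "detected", "n_significant"]),
        "profiles": pd.DataFrame(
            profile_rows,
            columns=["subject", "parcel", "condition", "split", "response", "baseline"]),
        "dice": pd.DataFrame(
            dice_rows,
            columns=["subject", "parcel", "kind", "split", "dice", "chance"]),
        "selectivity": pd.DataFrame(
            selectivity_rows,
            columns=["subject", "parcel", "contrast_level", "definer", "measurer",
                     "response"]),
    }


def _selectivity_rows(subject, parcel, emfl_session, std_session, split, fraction,
                      mask, emfl_fits, std_fits):
    """Rows of the 2 x 2 x 2 selectivity design for one parcel.

    fROIs are defined on the first split half of the definer session and
    responses measured on the second split half of the measurer session, so
    definition and measurement never share runs."""
    def get_fit(session, run_ids, cache):
        key = (session.kind, frozenset(run_ids)) if cache is std_fits else frozenset(run_ids)
        if key not in cache:
            cache[key] = fit_session(session, run_ids, mask=mask)
        return cache[key]

    sessions = {"emfl": (emfl_session, emfl_fits), "standard": (std_session, std_fits)}
    halves = {
        name: split.directions(sess.run_indices)[0]
        for name, (sess, _) in sessions.items()
    }
    rows = []
    for definer in ("emfl", "standard"):
        d_sess, d_cache = sessions[definer]
        train = halves[definer][0]
        result = compute_contrast(get_fit(d_sess, train, d_cache),
                                  parcel.defining_contrast)
        voxels = froi_mod.define_froi_topk(result, parcel, fraction,
                                           defining_runs=train).voxels
        for measurer in ("emfl", "standard"):
            m_sess, m_cache = sessions[measurer]
            test = halves[measurer][1]
            fit = get_fit(m_sess, test, m_cache)
            pref, nonpref = _measure_pair(fit, voxels, parcel)
            rows.append((subject, parcel.label, "preferred", definer, measurer, pref))
            rows.append((subject, parcel.label, "nonpreferred", definer, measurer, nonpref))
    return rows


def summarize_detection(detection: pd.DataFrame) -> pd.DataFrame:
    """Per parcel x run-subset count of subjects passing the fixed-threshold
    detection rule."""
    if detection.empty:
        raise ValueError("no detection flags to summarize")
    out = (detection.groupby(["parcel", "run_subset"])["detected"].sum()
           .unstack("run_subset").fillna(0).astype(int))
    out.columns.name = None
    return out


def _write_with_sidecar(df: pd.DataFrame, path: Path, config: PipelineConfig, stage: str):
    df.to_csv(path, sep="\t", index=isinstance(df.index, pd.MultiIndex) or df.index.name is not None)
    sidecar = {"config_hash": config.config_hash, "seed": config.seed,
               "stage": stage, "stage_version": STAGE_VERSION}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full simulated experiment and write the report bundle.

    Outputs (TSV + JSON provenance sidecars) under ``config.out_dir``:
    per-subject and group-mean condition profiles, detection counts, Dice
    overlaps, the selectivity table and its ANOVA (when standard sessions are
    simulated).  Returns the same tables in a dict.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = subject_seeds(config.seed, config.n_subjects)
    per_subject = []
    for subject, subj_seeds in enumerate(seeds, start=1):
        t0 = time.time()
        try:
            phantom, emfl_session, standard = simulate_subject(config, subj_seeds)
        except Exception as exc:  # noqa: BLE001 - report stage and subject
            raise PipelineError("simulate", subject, exc) from exc
        try:
            per_subject.append(analyze_subject(config, subject, phantom,
                                               emfl_session, standard))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("analyze", subject, exc) from exc
        logger.info("subject %d/%d done in %.1fs", subject, config.n_subjects,
                    time.time() - t0)
    report = {
        key: pd.concat([s[key] for s in per_subject], ignore_index=True)
        for key in ("detection", "profiles", "dice", "selectivity")
    }
    report["detection_counts"] = summarize_detection(report["detection"])
    group = (report["profiles"].groupby(["parcel", "condition"])["response"]
             .mean().unstack("condition"))
    order = [c for c in ALL_CONDITIONS if c in group.columns]
    report["group_profiles"] = group[order]
    _write_with_sidecar(report["profiles"], out_dir / "profiles.tsv", config, "froi")
    _write_with_sidecar(report["group_profiles"].reset_index(),
                        out_dir / "group_profiles.tsv", config, "report")
    _write_with_sidecar(report["detection"], out_dir / "detection.tsv", config, "froi")
    _write_with_sidecar(report["detection_counts"].reset_index(),
                        out_dir / "detection_counts.tsv", config, "report")
    if config.include_standard:
        _write_with_sidecar(report["dice"], out_dir / "dice.tsv", config, "validate")
        _write_with_sidecar(report["selectivity"], out_dir / "selectivity.tsv",
                            config, "validate")
        anova = validation.selectivity_anova(report["selectivity"],
                                             include_parcel_factor=len(config.parcels) > 1)
        report["anova"] = anova
        _write_with_sidecar(anova.reset_index(names="term"), out_dir / "anova.tsv",
                            config, "validate")
    (out_dir / "config.json").write_text(json.dumps(
        {"config": config.to_dict(), "config_hash": config.config_hash,
         "stage_version": STAGE_VERSION}, indent=1))
    return report


# -- Monte-Carlo study helpers (used by the validation studies and the
#    acceptance script) --------------------------------------------------------

#: One representative parcel per modality family for Dice studies.
DICE_STUDY_PARCELS = ("FFA", "PPA", "Language", "FrontalMD")


def crossval_recovery_study(n_subjects: int = 50, seed: int = 0,
                            config: PipelineConfig | None = None,
                            dice_parcels=DICE_STUDY_PARCELS) -> dict:
    """Cohort study of held-out selectivity and localizer agreement.

    For each simulated subject: split-half profiles for every parcel (a
    subject x parcel cell "passes" when the held-out preferred response
    exceeds every same-modality non-preferred response) and, for the
    ``dice_parcels`` subset, within- and between-localizer Dice of top-10%
    fROIs against an independently simulated standard session.
    """
    config = config or PipelineConfig(seed=seed, include_standard=False)
    split = SPLITS[config.split]
    seeds = subject_seeds(seed, n_subjects)
    cell_rows, dice_rows = [], []
    dice_parcels = set(dice_parcels)
    for subject, (sched_seed, phantom_seed, seed_a, seed_b) in enumerate(seeds, start=1):
        schedule = generate_schedule(5, seed=sched_seed)
        phantom = make_phantom(config.grid_shape, _phantom_specs(config), config.noise,
                               seed=phantom_seed, base_amplitude=config.base_amplitude)
        mask = phantom.parcels > 0
        session = simulate_session(phantom, schedule, seed=seed_a, mask=mask)
        fits = {}
        parcels = parcels_from_phantom(phantom)
        rng_b = np.random.default_rng(seed_b)
        for parcel in parcels:
            profile = crossval_profile(session, parcel, split=split,
                                       fraction=config.top_fraction, mask=mask,
                                       fits=fits)
            pref = parcel.preferred_pair[0]
            pref_conds = ({"false_belief", "false_photo"} if pref == "english"
                          else {pref})
            same = profile.same_modality_conditions()
            non_pref = [c for c in same if c not in pref_conds]
            pref_resp = np.mean([profile.response[c] for c in pref_conds])
            ok = all(pref_resp > profile.response[c] for c in non_pref)
            cell_rows.append((subject, parcel.label, bool(ok)))
            if parcel.label in dice_parcels:
                std = simulate_standard_localizer(
                    phantom, StandardDesign(parcel.defining_contrast,
                                            n_runs=config.standard_runs),
                    seed=int(rng_b.integers(2 ** 31)), mask=mask)
                for res in validation.compare_within_between(
                        session, std, parcel, fraction=config.top_fraction,
                        split=split, mask=mask, fits={}):
                    dice_rows.append((subject, parcel.label, res.kind,
                                      res.coefficient, res.chance_level))
    cells = pd.DataFrame(cell_rows, columns=["subject", "parcel", "passed"])
    dice = pd.DataFrame(dice_rows, columns=["subject", "parcel", "kind", "dice",
                                            "chance"])
    within = dice[dice["kind"].isin(["within_A", "within_B"])]["dice"].mean()
    between = dice[dice["kind"] == "between_split"]["dice"].mean()
    return {
        "cells": cells,
        "dice": dice,
        "cell_pass_rate": float(cells["passed"].mean()),
        "dice_within_mean": float(within),
        "dice_between_mean": float(between),
        "dice_chance": float(dice["chance"].iloc[0]) if len(dice) else np.nan,
    }


def null_calibration_study(n_tests: int = 200_000, seed: int = 0,
                           parcel_size: int = 60) -> dict:
    """Voxelwise false-positive calibration on a signal-free phantom.

    Simulates full crossed-design sessions of white-noise null phantoms (no
    condition amplitude anywhere, serially independent noise so the OLS
    p-values are exact), fits the GLM, and measures the fraction of voxels
    with two-sided p < 0.001 for a defining contrast, plus the
    fixed-threshold detection rate over disjoint ``parcel_size``-voxel groups
    (whose oracle is Binomial(parcel_size, 0.001) in the positive direction).
    """
    from .simulate import make_null_phantom

    chunk_grid = (24, 24, 36)  # 20736 voxels per simulated session
    chunk_vox = int(np.prod(chunk_grid))
    n_chunks = int(np.ceil(n_tests / chunk_vox))
    noise = NoiseParams(noise_sd=1.0, ar_coefficient=0.0, drift_amplitude=0.3,
                        session_jitter_sd=0.0, nuisance_leak_sd=0.05)
    rng = np.random.default_rng(seed)
    n_small, n_detected, total = 0, 0, 0
    n_parcels = 0
    for _ in range(n_chunks):
        schedule = generate_schedule(5, seed=int(rng.integers(2 ** 31)))
        phantom = make_null_phantom(chunk_grid, (), noise)
        session = simulate_session(phantom, schedule,
                                   seed=int(rng.integers(2 ** 31)))
        fit = fit_session(session)
        result = compute_contrast(fit, "Faces>Objects")
        p, t = result.p_map, result.t_map
        n_small += int((p < 0.001).sum())
        total += p.size
        groups = p.size // parcel_size
        sig = ((p < 0.001) & (t > 0))[: groups * parcel_size].reshape(groups, parcel_size)
        n_detected += int((sig.sum(axis=1) >= 10).sum())
        n_parcels += groups
    return {
        "n_tests": total,
        "frac_p_001": n_small / total,
        "n_parcels": n_parcels,
        "detection_rate": n_detected / n_parcels,
    }


def interaction_type1_study(n_sims: int = 400, n_subjects: int = 10,
                            alpha: float = 0.05, seed: int = 0) -> dict:
    """Type-I error of the contrast x definer interaction when the two
    localizers are equally selective (no interaction in the generating
    model)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        table = validation.null_selectivity_table(
            n_subjects=n_subjects, seed=int(rng.integers(2 ** 31)))
        anova = validation.selectivity_anova(table)
        p = anova.loc["C(contrast_level):C(definer)", "PR(>F)"]
        rejections += p < alpha
    return {"n_sims": n_sims, "alpha": alpha, "rejection_rate": rejections / n_sims}
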