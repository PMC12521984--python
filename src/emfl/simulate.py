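"""Synthetic ground-truth phantoms and simulated BOLD sessions.

A phantom is a 3D grid containing labeled anatomical-constraint parcels.
Inside each parcel, voxels respond to the ten stimulus conditions with known
percent-signal amplitudes: the preferred condition of the parcel responds
``selectivity_ratio`` times more strongly than every other condition, with a
compact strong core (the most responsive ~10% of voxels, nearest the parcel
center) and a graded weaker periphery.  Background voxels carry no stimulus
response.  Each simulated voxel time course is

    baseline * (1 + sum_c amp_c/100 * (boxcar_c (x) HRF)
                  + drift + nuisance leakage) + AR(1) noise,

sampled at TR = 2 s.  Repeat sessions of the same phantom receive an
independent multiplicative voxel gain field (session-to-session pattern
variability), so two sessions share ground truth only up to realistic
session noise; splits *within* one session share the gain field exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .design import (
    ALL_CONDITIONS,
    AUDITORY_CONDITIONS,
    TR,
    VISUAL_CONDITIONS,
    ExperimentSchedule,
    schedule_to_events,
    validate_counterbalance,
)
from .glm import N_NUISANCE, HrfConfig, condition_regressor


@dataclass(frozen=True)
class NoiseParams:
    """Noise and nuisance structure of the simulated scanner time series.

    noise_sd is in raw intensity units; with the default baseline of 100 one
    unit equals 1% signal, so the default parameters give a block-level
    contrast-to-noise ratio of about 1 for the default phantom (preferred
    minus non-preferred amplitude of 1% signal against unit noise).
    """

    noise_sd: float = 1.0
    ar_coefficient: float = 0.3
    drift_amplitude: float = 0.5      # max percent-signal excursion of the linear drift
    baseline_intensity: float = 100.0
    session_jitter_sd: float = 0.15   # sd of the per-session voxel gain field
    nuisance_leak_sd: float = 0.05    # percent signal per unit nuisance regressor


@dataclass(frozen=True)
class ParcelSpec:
    """Request for one synthetic constraint parcel."""

    label: str
    n_voxels: int
    preferred: str            # condition label, or "english" (both story types)
    ratio: float = 3.0        # preferred / non-preferred amplitude
    contrast: str = ""        # defining contrast name (see glm.CONTRASTS)


#: Fourteen parcels mirroring the localizer's fROI inventory, 60 voxels each.
DEFAULT_PARCELS = (
    ParcelSpec("FFA", 60, "faces", contrast="Faces>Objects"),
    ParcelSpec("OFA", 60, "faces", contrast="Faces>Objects"),
    ParcelSpec("fSTS", 60, "faces", contrast="Faces>Objects"),
    ParcelSpec("PPA", 60, "scenes", contrast="Scenes>Objects"),
    ParcelSpec("OPA", 60, "scenes", contrast="Scenes>Objects"),
    ParcelSpec("RSC", 60, "scenes", contrast="Scenes>Objects"),
    ParcelSpec("LOC", 60, "objects", contrast="Objects>Words/scrambled"),
    ParcelSpec("EBA", 60, "bodies", contrast="Bodies>Objects"),
    ParcelSpec("VWFA", 60, "words_scrambled", contrast="Words/scrambled>Objects"),
    ParcelSpec("rTPJ", 60, "false_belief", contrast="FalseBelief>FalsePhoto"),
    ParcelSpec("Language", 60, "english", contrast="English>Nonwords"),
    ParcelSpec("STG", 60, "nonwords", contrast="Nonwords>Quilted"),
    ParcelSpec("FrontalMD", 60, "arithmetic", contrast="Arithmetic>English"),
    ParcelSpec("ParietalMD", 60, "arithmetic", contrast="Arithmetic>English"),
)

DEFAULT_GRID = (24, 24, 24)


@dataclass
class GroundTruthPhantom:
    grid_shape: tuple
    parcels: np.ndarray            # int labels, 0 = background
    parcel_names: dict             # label int -> name
    amplitude: dict                # condition -> 3D float array (% signal)
    core: np.ndarray               # bool grid flagging designed core voxels
    noise: NoiseParams
    parcel_specs: tuple
    seed: int

    def parcel_mask(self, name: str) -> np.ndarray:
        labels = {v: k for k, v in self.parcel_names.items()}
        return self.parcels == labels[name]

    def amplitude_matrix(self) -> np.ndarray:
        """(n conditions, n grid voxels) amplitude array in ALL_CONDITIONS order."""
        return np.stack([self.amplitude[c].reshape(-1) for c in ALL_CONDITIONS])


def _place_parcels(grid_shape, specs, rng):
    """Grow each parcel as the n nearest unassigned voxels around a lattice
    seed point (jittered), giving compact disjoint blobs of exact size."""
    n = len(specs)
    per_axis = int(np.ceil(n ** (1 / 3)))
    cells = [
        (i, j, k)
        for i in range(per_axis)
        for j in range(per_axis)
        for k in range(per_axis)
    ][:n]
    labels = np.zeros(grid_shape, dtype=np.int32)
    coords = np.indices(grid_shape).reshape(3, -1).T.astype(float)
    assigned = np.zeros(coords.shape[0], dtype=bool)
    centers = {}
    total = sum(s.n_voxels for s in specs)
    if total > np.prod(grid_shape):
        raise ValueError(f"{total} parcel voxels do not fit in grid {grid_shape}")
    for lab, (spec, cell) in enumerate(zip(specs, cells), start=1):
        center = np.array([
            (cell[d] + 0.5) * grid_shape[d] / per_axis + rng.uniform(-1, 1)
            for d in range(3)
        ])
        d2 = ((coords - center) ** 2).sum(axis=1)
        d2[assigned] = np.inf
        order = np.argsort(d2, kind="stable")[: spec.n_voxels]
        if not np.isfinite(d2[order]).all():
            raise ValueError("overlapping parcel requests exhaust the grid")
        labels.reshape(-1)[order] = lab
        assigned[order] = True
        centers[lab] = center
    return labels, centers


def _preferred_set(preferred: str) -> set:
    if preferred == "english":
        return {"false_belief", "false_photo"}
    if preferred not in ALL_CONDITIONS:
        raise KeyError(f"unknown preferred condition {preferred!r}")
    return {preferred}


def make_phantom(grid_shape=DEFAULT_GRID, parcel_specs=DEFAULT_PARCELS,
                 noise: NoiseParams | None = None, seed: int = 0,
                 base_amplitude: float = 0.5, core_fraction: float = 0.1,
                 periphery_start: float = 0.5,
                 periphery_floor: float = 0.2) -> GroundTruthPhantom:
    """Build a ground-truth phantom.

    Every in-parcel voxel responds ``base_amplitude`` (% signal) to each
    non-preferred condition and ``ratio * base_amplitude`` to the parcel's
    preferred condition(s), scaled by a radial gradient: the ceil(core_fraction
    * N) voxels nearest the parcel center keep the full amplitude (the
    "core", flagged in ground truth); the periphery steps down to
    ``periphery_start`` of the core amplitude and falls off linearly to
    ``periphery_floor`` at the parcel edge, emulating a selective hotspot
    surrounded by progressively weaker voxels.  The preferred/non-preferred
    ratio is constant across the parcel.
    """
    noise = noise or NoiseParams()
    for s in parcel_specs:
        if s.ratio < 1:
            raise ValueError(f"parcel {s.label}: selectivity ratio must be >= 1")
    seen = set()
    for s in parcel_specs:
        if s.label in seen:
            raise ValueError(f"duplicate parcel label {s.label!r}")
        seen.add(s.label)
    rng = np.random.default_rng(seed)
    labels, centers = _place_parcels(grid_shape, parcel_specs, rng)
    amplitude = {c: np.zeros(grid_shape) for c in ALL_CONDITIONS}
    core = np.zeros(grid_shape, dtype=bool)
    coords = np.indices(grid_shape).reshape(3, -1).T.astype(float)
    flat_labels = labels.reshape(-1)
    for lab, spec in enumerate(parcel_specs, start=1):
        idx = np.flatnonzero(flat_labels == lab)
        d2 = ((coords[idx] - centers[lab]) ** 2).sum(axis=1)
        order = idx[np.argsort(d2, kind="stable")]
        n = len(order)
        n_core = int(np.ceil(core_fraction * n))
        grade = np.ones(n)
        if n > n_core:
            grade[n_core:] = np.linspace(periphery_start, periphery_floor, n - n_core)
        core.reshape(-1)[order[:n_core]] = True
        pref = _preferred_set(spec.preferred)
        for c in ALL_CONDITIONS:
            amp = base_amplitude * (spec.ratio if c in pref else 1.0)
            amplitude[c].reshape(-1)[order] = amp * grade
    names = {lab: spec.label for lab, spec in enumerate(parcel_specs, start=1)}
    return GroundTruthPhantom(grid_shape=tuple(grid_shape), parcels=labels,
                              parcel_names=names, amplitude=amplitude, core=core,
                              noise=noise, parcel_specs=tuple(parcel_specs), seed=seed)


def make_null_phantom(grid_shape=DEFAULT_GRID, parcel_specs=DEFAULT_PARCELS,
                      noise: NoiseParams | None = None, seed: int = 0) -> GroundTruthPhantom:
    """Phantom with parcels in place but zero condition amplitude everywhere."""
    phantom = make_phantom(grid_shape, parcel_specs, noise, seed, base_amplitude=0.0)
    phantom.core[:] = False
    return phantom


# -- session simulation -------------------------------------------------------

@dataclass
class SimulatedRun:
    data: np.ndarray        # 4D (x, y, z, t)
    nuisance: np.ndarray    # (t, 6)
    run_index: int
    seed: int
    tr: float = TR


@dataclass
class Session:
    """A set of simulated runs plus the events and condition labels needed to
    model them."""

    runs: list
    events: pd.DataFrame
    condition_labels: list
    kind: str = "emfl"
    tr: float = TR

    @property
    def run_indices(self):
        return [r.run_index for r in self.runs]


def _ar1_noise(rng, shape_vox_t, sd, ar):
    """Stationary AR(1) series with marginal standard deviation ``sd``."""
    n_vox, n_t = shape_vox_t
    if sd == 0:
        return np.zeros((n_vox, n_t))
    w = rng.standard_normal((n_vox, n_t)) * sd
    if ar == 0:
        return w
    w *= np.sqrt(1 - ar ** 2)
    init = rng.standard_normal(n_vox) * sd
    zi = (ar * init)[:, None]
    out, _ = lfilter([1.0], [1.0, -ar], w, axis=1, zi=zi)
    return out


def _nuisance_courses(rng, n_t):
    """Six smooth zero-mean motion-like time courses (unit sd)."""
    raw = rng.standard_normal((n_t, N_NUISANCE))
    smooth, _ = lfilter([1.0], [1.0, -0.95], raw, axis=0,
                        zi=np.zeros((1, N_NUISANCE)))
    smooth -= smooth.mean(axis=0)
    sd = smooth.std(axis=0)
    sd[sd == 0] = 1.0
    return smooth / sd


def _session_gain(phantom, rng):
    jitter = phantom.noise.session_jitter_sd
    if jitter == 0:
        return np.ones(int(np.prod(phantom.grid_shape)))
    g = 1.0 + jitter * rng.standard_normal(int(np.prod(phantom.grid_shape)))
    return np.clip(g, 0.05, None)


def _simulate_runs(phantom, events, run_durations, condition_labels, seed,
                   mask, hrf_config, kind):
    """Shared machinery for crossed and standard sessions."""
    noise = phantom.noise
    grid = phantom.grid_shape
    n_grid = int(np.prod(grid))
    if mask is not None:
        vox = np.flatnonzero(np.asarray(mask).reshape(-1))
    else:
        vox = np.arange(n_grid)
    rng = np.random.default_rng(seed)
    gain = _session_gain(phantom, rng)[vox]
    amp = np.stack([phantom.amplitude[c].reshape(-1)[vox] for c in condition_labels])
    amp = amp * gain[None, :]
    leak = rng.standard_normal((len(vox), N_NUISANCE)) * noise.nuisance_leak_sd
    runs = []
    for run_idx in sorted(run_durations):
        dur = run_durations[run_idx]
        if abs(dur / TR - round(dur / TR)) > 1e-9:
            raise ValueError(f"TR {TR} does not divide run duration {dur}")
        n_t = int(round(dur / TR))
        run_seed = int(rng.integers(2 ** 31))
        run_rng = np.random.default_rng(run_seed)
        sub = events[events["run"] == run_idx]
        regs = np.stack([
            condition_regressor(
                sub.loc[sub["trial_type"].map(lambda tt, c=c: c in _event_conditions(tt)),
                        "onset"].to_numpy(float),
                sub.loc[sub["trial_type"].map(lambda tt, c=c: c in _event_conditions(tt)),
                        "duration"].to_numpy(float),
                n_t, TR, hrf_config)
            for c in condition_labels
        ])  # (n conditions, t)
        signal_pct = amp.T @ regs  # (vox, t)
        slope = run_rng.uniform(-1, 1) * noise.drift_amplitude
        drift = slope * np.linspace(-0.5, 0.5, n_t)
        nuis = _nuisance_courses(run_rng, n_t)
        signal_pct = signal_pct + drift[None, :] + leak @ nuis.T
        series = noise.baseline_intensity * (1.0 + signal_pct / 100.0)
        series = series + _ar1_noise(run_rng, (len(vox), n_t), noise.noise_sd,
                                     noise.ar_coefficient)
        data = np.full((n_grid, n_t), noise.baseline_intensity)
        data[vox] = series
        runs.append(SimulatedRun(data=data.reshape(*grid, n_t), nuisance=nuis,
                                 run_index=run_idx, seed=run_seed))
    return Session(runs=runs, events=events.reset_index(drop=True),
                   condition_labels=list(condition_labels), kind=kind)


def _event_conditions(trial_type):
    from .design import parse_trial_type

    v, a = parse_trial_type(trial_type)
    out = set()
    if v is not None:
        out.add(v)
    if a is not None:
        out.add(a)
        if a == "english":
            out.update({"english"})
    return out


def simulate_session(phantom: GroundTruthPhantom, schedule: ExperimentSchedule,
                     seed: int = 0, mask=None,
                     hrf_config: HrfConfig | None = None) -> Session:
    """Simulate the crossed-design session implied by ``schedule``.

    ``mask`` (boolean grid) restricts signal-and-noise simulation to a voxel
    subset (outside voxels are constant baseline), which keeps large Monte
    Carlo studies cheap without changing in-mask statistics.
    """
    report = validate_counterbalance(schedule)
    if schedule.n_runs == 5 and not report.passed:
        raise ValueError(f"invalid schedule: {report.violations[:3]}")
    events = schedule_to_events(schedule)
    durations = {run.index: run.total_duration for run in schedule.runs}
    labels = list(VISUAL_CONDITIONS) + list(AUDITORY_CONDITIONS)
    return _simulate_runs(phantom, events, durations, labels, seed, mask,
                          hrf_config or HrfConfig(), "emfl")


# -- standard (single-modality) localizer sessions ---------------------------

@dataclass(frozen=True)
class StandardDesign:
    """Alternating two-condition block design for one standard localizer.

    ``contrast`` names the target contrast; its positive condition(s) define
    the preferred blocks and its negative condition(s) the baseline blocks.
    Each run is fixation / 5 alternating block pairs of 18 s / fixation.
    """

    contrast: str
    n_runs: int = 4
    n_blocks: int = 10
    block_duration: float = 18.0
    fixation_duration: float = 18.0

    @property
    def run_duration(self) -> float:
        return self.n_blocks * self.block_duration + 3 * self.fixation_duration

    def conditions(self):
        from .glm import get_contrast

        spec = get_contrast(self.contrast)
        pos = [k for k, w in spec.weights.items() if w > 0]
        neg = [k for k, w in spec.weights.items() if w < 0]
        if len(pos) != 1 or len(neg) != 1:
            raise ValueError(f"contrast {self.contrast!r} is not a two-condition design")
        return pos[0], neg[0]

    def events(self) -> pd.DataFrame:
        pref, base = self.conditions()
        rows = []
        for r in range(1, self.n_runs + 1):
            rows.append((0.0, self.fixation_duration, "fixation", r))
            onset = self.fixation_duration
            for i in range(self.n_blocks):
                if i == self.n_blocks // 2:
                    rows.append((onset, self.fixation_duration, "fixation", r))
                    onset += self.fixation_duration
                cond = pref if i % 2 == 0 else base
                rows.append((onset, self.block_duration, cond, r))
                onset += self.block_duration
            rows.append((onset, self.fixation_duration, "fixation", r))
        return pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "run"])


def simulate_standard_localizer(phantom: GroundTruthPhantom, design: StandardDesign,
                                seed: int = 0, mask=None,
                                hrf_config: HrfConfig | None = None) -> Session:
    """Simulate a standard single-modality localizer session.

    Voxel amplitudes are the phantom's (the composite "english" condition
    responds with the mean of the false-belief and false-photo amplitudes);
    the noise, drift, nuisance and session gain field are drawn independently
    of any other session.
    """
    if design.n_runs < 2:
        raise ValueError("standard localizer needs >= 2 runs")
    pref, base = design.conditions()  # validates the contrast name
    events = design.events()
    durations = {r: design.run_duration for r in range(1, design.n_runs + 1)}
    labels = [pref, base]
    if "english" in labels:
        # give the composite condition its ground-truth amplitude
        eng = 0.5 * (phantom.amplitude["false_belief"] + phantom.amplitude["false_photo"])
        phantom = replace_amplitude(phantom, "english", eng)
    return _simulate_runs(phantom, events, durations, labels, seed, mask,
                          hrf_config or HrfConfig(), "standard")


def replace_amplitude(phantom: GroundTruthPhantom, label: str,
                      amp: np.ndarray) -> GroundTruthPhantom:
    amplitude = dict(phantom.amplitude)
    amplitude[label] = amp
    return GroundTruthPhantom(grid_shape=phantom.grid_shape, parcels=phantom.parcels,
                              parcel_names=phantom.parcel_names, amplitude=amplitude,
                              core=phantom.core, noise=phantom.noise,
                              parcel_specs=phantom.parcel_specs, seed=phantom.seed)


# -- NIfTI / TSV output -------------------------------------------------------

VOXEL_SIZE_MM = 2.0


def _affine():
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = VOXEL_SIZE_MM
    return aff


def write_nifti(session_or_masks, directory, prefix: str = "run"):
    """Write simulated runs (4D NIfTI + nuisance TSVs + events TSV) or a dict
    of 3D masks (one NIfTI each), with a 2 mm isotropic identity-scaled
    affine and the TR recorded in the header."""
    import nibabel as nib
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    if isinstance(session_or_masks, dict):
        for name, mask in session_or_masks.items():
            img = nib.Nifti1Image(np.asarray(mask).astype(np.int16), _affine())
            path = directory / f"{name}_mask.nii.gz"
            nib.save(img, path)
            paths.append(path)
        return paths
    session = session_or_masks
    for run in session.runs:
        img = nib.Nifti1Image(run.data.astype(np.float32), _affine())
        img.header.set_zooms((VOXEL_SIZE_MM,) * 3 + (run.tr,))
        path = directory / f"{prefix}-{run.run_index:02d}_bold.nii.gz"
        nib.save(img, path)
        pd.DataFrame(run.nuisance,
                     columns=[f"nuisance_{j+1}" for j in range(N_NUISANCE)]).to_csv(
            directory / f"{prefix}-{run.run_index:02d}_nuisance.tsv", sep="\t", index=False)
        paths.append(path)
    session.events.to_csv(directory / "events.tsv", sep="\t", index=False)
    return paths


def read_nifti_session(directory, condition_labels=None, prefix: str = "run") -> Session:
    """Load a session written by :func:`write_nifti`."""
    import nibabel as nib
    from pathlib import Path

    directory = Path(directory)
    events = pd.read_csv(directory / "events.tsv", sep="\t")
    runs = []
    for path in sorted(directory.glob(f"{prefix}-*_bold.nii.gz")):
        run_idx = int(path.name.split("-")[1].split("_")[0])
        img = nib.load(path)
        nuis = pd.read_csv(directory / f"{prefix}-{run_idx:02d}_nuisance.tsv", sep="\t")
        tr = float(img.header.get_zooms()[3])
        runs.append(SimulatedRun(data=np.asarray(img.dataobj, dtype=np.float64),
                                 nuisance=nuis.to_numpy(), run_index=run_idx,
                                 seed=-1, tr=tr))
    if condition_labels is None:
        from .design import parse_trial_type

        seen = set()
        for tt in events["trial_type"]:
            v, a = parse_trial_type(tt)
            seen.update(x for x in (v, a) if x)
        order = list(ALL_CONDITIONS) + ["english"]
        condition_labels = [c for c in order if c in seen]
    return Session(runs=runs, events=events, condition_labels=condition_labels)
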