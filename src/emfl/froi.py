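"""Functional ROI definition and cross-validated selectivity.

An fROI is the intersection of an anatomical constraint parcel with an
individual's activation for the parcel's defining contrast: either the top
10% most significant voxels in the parcel (always defined, any subject) or
all voxels beyond a fixed threshold (p < 0.001, at least 10 voxels, used to
ask *whether* a region is detectable).  Selectivity is always quantified in
held-out data: voxels are selected on one half of the runs and their
per-condition responses measured on the other half, in both directions, and
the two direction estimates averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import ALL_CONDITIONS, AUDITORY_CONDITIONS, VISUAL_CONDITIONS, modality_of
from .glm import ContrastResult, GlmFit, compute_contrast, fit_session, get_contrast


def round_half_away(x: float) -> int:
    """Round half away from zero (so 0.5 -> 1), as used for fROI sizes."""
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


@dataclass
class Parcel:
    label: str
    mask: np.ndarray           # boolean grid
    defining_contrast: str     # name in glm.CONTRASTS

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"parcel {self.label!r} is empty")
        get_contrast(self.defining_contrast)

    @property
    def size(self) -> int:
        return int(self.mask.sum())

    @property
    def flat_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask.reshape(-1))

    @property
    def preferred_pair(self):
        """(preferred, nonpreferred) condition labels from the defining
        contrast: its positive condition vs. its baseline condition."""
        spec = get_contrast(self.defining_contrast)
        pos = [k for k, w in spec.weights.items() if w > 0]
        neg = [k for k, w in spec.weights.items() if w < 0]
        return pos[0], neg[0]

    @property
    def modality(self) -> str:
        """Modality of the defining contrast's conditions."""
        pref = self.preferred_pair[0]
        return "auditory" if pref == "english" else modality_of(pref)


def parcels_from_phantom(phantom) -> list:
    """One :class:`Parcel` per phantom parcel, with its defining contrast."""
    out = []
    for lab, spec in enumerate(phantom.parcel_specs, start=1):
        out.append(Parcel(label=spec.label, mask=phantom.parcels == lab,
                          defining_contrast=spec.contrast))
    return out


def _values_at(result, flat_indices: np.ndarray, field_values: np.ndarray) -> np.ndarray:
    """Pick per-voxel values for grid flat indices from a fit/result that may
    have been computed on a voxel subset."""
    vox = result.voxel_indices
    if vox is None or len(vox) == int(np.prod(result.grid_shape)):
        return field_values[flat_indices]
    pos = np.searchsorted(vox, flat_indices)
    if np.any(pos >= len(vox)) or np.any(vox[np.minimum(pos, len(vox) - 1)] != flat_indices):
        raise ValueError("parcel voxels outside the fitted mask")
    return field_values[pos]


@dataclass
class FROI:
    parcel: Parcel
    voxels: np.ndarray            # flat grid indices, ordered by rank
    defining_runs: tuple
    selection_rule: dict

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.parcel.mask.size, dtype=bool)
        m[self.voxels] = True
        return m.reshape(self.parcel.mask.shape)


def rank_parcel_voxels(contrast_result: ContrastResult, parcel: Parcel) -> np.ndarray:
    """Parcel voxels ordered by decreasing positive-direction significance.

    Order: signed log-p descending, ties broken by linear voxel index
    ascending, so the ranking is deterministic across platforms.
    """
    flat = parcel.flat_indices
    slp = _values_at(contrast_result, flat, contrast_result.signed_log_p)
    order = np.lexsort((flat, -slp))
    return flat[order]


def define_froi_topk(contrast_result: ContrastResult, parcel: Parcel,
                     fraction: float = 0.10, defining_runs=()) -> FROI:
    """Top-fraction fROI: the round(fraction * parcel size) most significant
    voxels for the defining contrast inside the parcel (minimum one voxel)."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    ranked = rank_parcel_voxels(contrast_result, parcel)
    k = max(1, round_half_away(fraction * parcel.size))
    return FROI(parcel=parcel, voxels=ranked[:k], defining_runs=tuple(defining_runs),
                selection_rule={"top_fraction": fraction})


@dataclass
class DetectionResult:
    detected: bool
    n_significant: int


def detect_fixed_threshold(contrast_result: ContrastResult, parcel: Parcel,
                           p_threshold: float = 0.001,
                           min_voxels: int = 10) -> DetectionResult:
    """Fixed-threshold detection: the fROI counts as present when at least
    ``min_voxels`` parcel voxels reach p < ``p_threshold`` in the positive
    direction of the contrast."""
    if p_threshold <= 0 or min_voxels <= 0:
        raise ValueError("thresholds must be positive")
    flat = parcel.flat_indices
    p = _values_at(contrast_result, flat, contrast_result.p_map)
    t = _values_at(contrast_result, flat, contrast_result.t_map)
    n = int(np.count_nonzero((p < p_threshold) & (t > 0)))
    return DetectionResult(detected=n >= min_voxels, n_significant=n)


# -- run splits ---------------------------------------------------------------

@dataclass(frozen=True)
class Split:
    """Two-direction cross-validation split over a session's runs."""

    name: str

    def directions(self, run_indices):
        run_indices = sorted(run_indices)
        if len(run_indices) < 2:
            raise ValueError("cross-validation needs at least two runs")
        if self.name == "odd-even":
            a = tuple(r for r in run_indices if r % 2 == 1)
            b = tuple(r for r in run_indices if r % 2 == 0)
        elif self.name == "first-last":
            n_train = (len(run_indices) + 1) // 2
            a = tuple(run_indices[:n_train])
            b = tuple(run_indices[n_train:])
        else:
            raise ValueError(f"unknown split scheme {self.name!r}")
        if not a or not b:
            raise ValueError(f"split {self.name!r} leaves an empty half for {run_indices}")
        if set(a) & set(b):
            raise ValueError("train and test runs overlap")
        return [(a, b), (b, a)]


ODD_EVEN = Split("odd-even")
FIRST_LAST = Split("first-last")
SPLITS = {s.name: s for s in (ODD_EVEN, FIRST_LAST)}


def measured_conditions(fit: GlmFit):
    """The measurable condition labels of a fit, in canonical order."""
    order = list(ALL_CONDITIONS) + ["english"]
    return [c for c in order if c in fit.condition_labels]


def condition_response(fit: GlmFit, condition: str, voxels: np.ndarray) -> float:
    """Mean percent-signal response of a voxel set to one condition.

    The composite "english" response is the mean of the false-belief and
    false-photo responses when those regressors are present."""
    if condition == "english" and "english" not in fit.columns:
        return 0.5 * (condition_response(fit, "false_belief", voxels)
                      + condition_response(fit, "false_photo", voxels))
    return float(np.mean(_values_at(fit, voxels, fit.percent_signal(condition))))


@dataclass
class ResponseProfile:
    parcel_label: str
    response: dict               # condition -> mean held-out percent signal
    baseline: float              # mean over the five defining-modality conditions
    modality: str
    split_scheme: str
    froi_voxels: dict = field(default_factory=dict)  # direction -> voxel indices

    def same_modality_conditions(self):
        return VISUAL_CONDITIONS if self.modality == "visual" else AUDITORY_CONDITIONS


def crossval_profile(session, parcel: Parcel, split: Split | str = ODD_EVEN,
                     fraction: float = 0.10, mask=None, hrf_config=None,
                     fits: dict | None = None) -> ResponseProfile:
    """Split-half cross-validated condition profile of one fROI.

    For each direction of the split the fROI is defined (top-fraction rule)
    on the training runs and each condition's mean response measured on the
    held-out runs; the two direction estimates are averaged.  ``fits`` may
    carry precomputed GLM fits keyed by frozenset(run indices) to amortize
    fitting across parcels.
    """
    if isinstance(split, str):
        split = SPLITS[split]
    fits = fits if fits is not None else {}

    def get_fit(run_ids):
        key = frozenset(run_ids)
        if key not in fits:
            fits[key] = fit_session(session, run_ids, mask=mask, hrf_config=hrf_config)
        return fits[key]

    directions = split.directions(session.run_indices)
    conds = None
    totals = None
    froi_voxels = {}
    for i, (train, test) in enumerate(directions):
        train_fit = get_fit(train)
        test_fit = get_fit(test)
        result = compute_contrast(train_fit, parcel.defining_contrast)
        froi = define_froi_topk(result, parcel, fraction, defining_runs=train)
        froi_voxels[f"train{train}"] = froi.voxels
        if conds is None:
            conds = [c for c in measured_conditions(test_fit) if c != "english"]
            totals = np.zeros(len(conds))
        totals += np.array([condition_response(test_fit, c, froi.voxels) for c in conds])
    response = dict(zip(conds, totals / len(directions)))
    modality = parcel.modality
    same = VISUAL_CONDITIONS if modality == "visual" else AUDITORY_CONDITIONS
    baseline = float(np.mean([response[c] for c in same if c in response]))
    return ResponseProfile(parcel_label=parcel.label, response=response,
                           baseline=baseline, modality=modality,
                           split_scheme=split.name, froi_voxels=froi_voxels)


@dataclass
class SelectivityCurve:
    parcel_label: str
    sizes: np.ndarray            # 1..parcel size
    responses: dict              # condition -> array over sizes


def growing_window_curve(train_contrast_result: ContrastResult, test_fit: GlmFit,
                         parcel: Parcel) -> SelectivityCurve:
    """Held-out response as a function of fROI size.

    Voxels are ranked by training significance; for every k = 1..N the mean
    held-out response of the top-k voxels is computed (incrementally via
    cumulative sums).  At k = N the value equals the plain parcel mean.
    """
    ranked = rank_parcel_voxels(train_contrast_result, parcel)
    sizes = np.arange(1, len(ranked) + 1)
    responses = {}
    for c in measured_conditions(test_fit):
        if c == "english":
            continue
        vals = _values_at(test_fit, ranked, test_fit.percent_signal(c))
        responses[c] = np.cumsum(vals) / sizes
    return SelectivityCurve(parcel_label=parcel.label, sizes=sizes, responses=responses)
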