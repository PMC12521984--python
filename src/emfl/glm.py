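"""First-level GLM: HRF, design matrix, voxelwise OLS, contrasts.

All functional runs of a session are concatenated and fitted jointly with
ordinary least squares, as in a classic volume-based first-level stream:
one boxcar-convolved regressor per condition (shared across runs), the six
nuisance time courses, and a per-run intercept + linear drift term.  No
prewhitening is applied; the empirical consequences for p-value calibration
under autocorrelated noise are documented in the methods note.

Conventions
-----------
* canonical double-gamma HRF (response peak 6 s, undershoot peak 16 s,
  undershoot ratio 1/6, 32 s support) normalized to unit peak;
* the GLM is fitted on raw intensities and condition effects are rescaled to
  percent signal by dividing by the fitted per-run baseline (intercept), so
  betas are directly comparable to simulated percent-signal amplitudes;
* two-sided p-values with the sign of t carried separately; the map value
  -log10(p) * sgn(t) at +3 therefore corresponds to p < 0.001 in the
  positive direction of the contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import (
    ALL_CONDITIONS,
    AUDITORY_CONDITIONS,
    TR,
    VISUAL_CONDITIONS,
    parse_trial_type,
    schedule_to_events,
)

N_NUISANCE = 6
LOG10_E = np.log10(np.e)


@dataclass(frozen=True)
class HrfConfig:
    """Canonical double-gamma HRF parameters (seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 32.0
    oversampling: int = 20  # samples per TR when building regressors


def hrf_samples(dt: float, config: HrfConfig | None = None) -> np.ndarray:
    """Sample the canonical HRF on a grid of spacing ``dt``, unit-peak scaled."""
    config = config or HrfConfig()
    t = np.arange(0, config.duration + dt / 2, dt)
    peak = stats.gamma.pdf(t, config.peak_delay / config.dispersion, scale=config.dispersion)
    under = stats.gamma.pdf(
        t, config.undershoot_delay / config.undershoot_dispersion,
        scale=config.undershoot_dispersion,
    )
    h = peak - config.undershoot_ratio * under
    return h / h.max()


def condition_regressor(onsets, durations, n_volumes: int, tr: float = TR,
                        config: HrfConfig | None = None) -> np.ndarray:
    """Boxcar (x) HRF regressor sampled at volume acquisition times 0, TR, 2TR, ...

    The boxcar is built on an oversampled grid within the run, convolved with
    the HRF, and decimated back to the TR grid, so regressors are zero before
    the first block (and identically zero for conditions without blocks in
    the run).  The convolution kernel is scaled to unit sum, so a sustained
    block drives the regressor to a plateau of one and betas read as
    sustained percent-signal block responses.
    """
    config = config or HrfConfig()
    dt = tr / config.oversampling
    n_fine = int(round(n_volumes * tr / dt))
    box = np.zeros(n_fine)
    for onset, dur in zip(onsets, durations):
        i0 = int(round(onset / dt))
        i1 = min(int(round((onset + dur) / dt)), n_fine)
        box[i0:i1] = 1.0
    kernel = hrf_samples(dt, config)
    reg = np.convolve(box, kernel / kernel.sum())[:n_fine]
    return reg[:: config.oversampling][:n_volumes].copy()


class RankDeficientDesignError(ValueError):
    """Raised when the design matrix is rank deficient; names the offending columns."""


@dataclass
class DesignMatrix:
    matrix: np.ndarray            # (total volumes, n columns)
    columns: list                 # column labels
    run_indices: list             # 1-based run index per row
    condition_labels: list        # subset of columns that are condition regressors
    tr: float = TR
    rank: int = -1
    null_space: np.ndarray | None = None  # (n columns, deficiency) basis

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.columns)


def _modality_confound_vector(columns) -> np.ndarray | None:
    """Expected null vector of a fully crossed design.

    Every stimulus block carries exactly one visual and one auditory
    condition, so the five visual boxcars sum to the same "any stimulus"
    time course as the five auditory boxcars and the design loses one rank:
    only the *difference* between the modality means is unidentifiable.
    Returns the unit vector (+1 on visual, -1 on auditory condition columns)
    when both full condition sets are present, else None.
    """
    vis = [c for c in columns if c in VISUAL_CONDITIONS]
    aud = [c for c in columns if c in AUDITORY_CONDITIONS]
    if len(vis) != 5 or len(aud) != 5:
        return None
    v = np.zeros(len(columns))
    for c in vis:
        v[columns.index(c)] = 1.0
    for c in aud:
        v[columns.index(c)] = -1.0
    return v / np.linalg.norm(v)


def _check_rank(matrix: np.ndarray, columns):
    """Return (rank, null-space basis); raise unless any deficiency is the
    expected crossed-design modality confound."""
    u, s, vt = np.linalg.svd(matrix, full_matrices=False)
    tol = s.max() * max(matrix.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if rank == matrix.shape[1]:
        return rank, None
    null = vt[rank:].T  # (n columns, deficiency)
    expected = _modality_confound_vector(columns)
    if expected is not None and null.shape[1] == 1:
        if abs(abs(float(expected @ null[:, 0])) - 1.0) < 1e-8:
            return rank, expected[:, None]
    _, r = np.linalg.qr(matrix)
    diag = np.abs(np.diag(r))
    bad = [columns[i] for i in np.nonzero(diag < 1e-8 * diag.max())[0]]
    raise RankDeficientDesignError(
        f"design matrix rank {rank} < {matrix.shape[1]} columns; "
        f"collinear columns: {bad}"
    )


def build_design_matrix(events: pd.DataFrame, nuisance, n_volumes_per_run: dict,
                        condition_labels=None, tr: float = TR,
                        hrf_config: HrfConfig | None = None) -> DesignMatrix:
    """Assemble the concatenated-session design matrix.

    Parameters
    ----------
    events
        Long-format table with columns onset, duration, trial_type, run.
        Crossed trial types ("faces_arithmetic") contribute to both their
        visual and auditory condition regressor.
    nuisance
        Mapping run index -> (n_volumes, 6) array of nuisance time courses.
    n_volumes_per_run
        Mapping run index -> number of volumes.
    condition_labels
        Condition regressors to include; defaults to every condition present
        in the events.
    """
    hrf_config = hrf_config or HrfConfig()
    run_ids = sorted(n_volumes_per_run)
    if condition_labels is None:
        seen = set()
        for tt in events["trial_type"]:
            v, a = parse_trial_type(tt)
            seen.update(x for x in (v, a) if x is not None)
        condition_labels = [c for c in ALL_CONDITIONS + ("english",) if c in seen]
    # per-run onsets for each condition
    cond_cols = {c: [] for c in condition_labels}
    for r in run_ids:
        n_vol = n_volumes_per_run[r]
        nuis = np.asarray(nuisance[r], dtype=float)
        if nuis.shape != (n_vol, N_NUISANCE):
            raise ValueError(
                f"run {r}: nuisance shape {nuis.shape} != ({n_vol}, {N_NUISANCE})"
            )
        sub = events[events["run"] == r]
        for c in condition_labels:
            onsets, durs = [], []
            for _, row in sub.iterrows():
                v, a = parse_trial_type(row["trial_type"])
                if c in (v, a):
                    onsets.append(float(row["onset"]))
                    durs.append(float(row["duration"]))
            cond_cols[c].append(condition_regressor(onsets, durs, n_vol, tr, hrf_config))
    blocks, columns = [], []
    for c in condition_labels:
        blocks.append(np.concatenate(cond_cols[c]))
        columns.append(c)
    nuis_all = np.vstack([
        np.asarray(nuisance[r], dtype=float) - np.asarray(nuisance[r], dtype=float).mean(axis=0)
        for r in run_ids
    ])
    for j in range(N_NUISANCE):
        blocks.append(nuis_all[:, j])
        columns.append(f"nuisance_{j + 1}")
    total = sum(n_volumes_per_run[r] for r in run_ids)
    offset = 0
    run_rows = []
    for r in run_ids:
        n_vol = n_volumes_per_run[r]
        intercept = np.zeros(total)
        intercept[offset:offset + n_vol] = 1.0
        drift = np.zeros(total)
        drift[offset:offset + n_vol] = np.linspace(-0.5, 0.5, n_vol)
        blocks.append(intercept)
        columns.append(f"run{r}_intercept")
        blocks.append(drift)
        columns.append(f"run{r}_drift")
        run_rows.extend([r] * n_vol)
        offset += n_vol
    matrix = np.column_stack(blocks)
    rank, null_space = _check_rank(matrix, columns)
    return DesignMatrix(matrix=matrix, columns=columns, run_indices=run_rows,
                        condition_labels=list(condition_labels), tr=tr,
                        rank=rank, null_space=null_space)


def design_matrix_from_schedule(schedule, nuisance, tr: float = TR,
                                hrf_config: HrfConfig | None = None) -> DesignMatrix:
    """Design matrix for a crossed-design schedule (10 condition regressors)."""
    events = schedule_to_events(schedule)
    n_vols = {}
    for run in schedule.runs:
        dur = run.total_duration
        if abs(dur / tr - round(dur / tr)) > 1e-9:
            raise ValueError(f"TR {tr} does not divide run duration {dur}")
        n_vols[run.index] = int(round(dur / tr))
    labels = list(VISUAL_CONDITIONS) + list(AUDITORY_CONDITIONS)
    return build_design_matrix(events, nuisance, n_vols, condition_labels=labels,
                               tr=tr, hrf_config=hrf_config)


@dataclass
class GlmFit:
    """Voxelwise OLS fit of one (possibly multi-run) session.

    For the fully crossed design the solution is the minimum-norm least
    squares fit: the unidentifiable shared modality-mean component is split
    evenly between the visual and auditory condition betas, so each
    condition's response folds in the average response of the simultaneously
    presented opposite modality.  Within-modality contrasts are estimable
    and unaffected by this convention.
    """

    beta: np.ndarray              # (n columns, n voxels)
    columns: list
    condition_labels: list
    residual_variance: np.ndarray  # (n voxels,)
    dof: int
    xtx_pinv: np.ndarray
    baseline: np.ndarray           # (n voxels,) mean per-run intercept
    null_space: np.ndarray | None = None
    grid_shape: tuple | None = None
    voxel_indices: np.ndarray | None = None  # flat indices into grid

    def beta_map(self, label: str) -> np.ndarray:
        return self.beta[self.columns.index(label)]

    def percent_signal(self, label: str) -> np.ndarray:
        """Condition effect rescaled to percent of the fitted baseline."""
        return 100.0 * self.beta_map(label) / self.baseline


def _stack_runs(runs, mask=None):
    """Concatenate run data into (T, V); returns (Y, grid_shape, voxel_indices)."""
    arrays = []
    grid_shape = None
    for run in runs:
        if isinstance(run, np.ndarray):
            data = run
        elif hasattr(run, "get_fdata"):  # nibabel image
            data = run.get_fdata()
        else:
            data = run.data
        if data.ndim != 4:
            raise ValueError("each run must be a 4D (x, y, z, t) array")
        if grid_shape is None:
            grid_shape = data.shape[:3]
        elif data.shape[:3] != grid_shape:
            raise ValueError("voxel grids differ across runs")
        flat = data.reshape(-1, data.shape[3]).T  # (t, all voxels)
        arrays.append(flat)
    y = np.concatenate(arrays, axis=0)
    if mask is not None:
        voxel_indices = np.flatnonzero(np.asarray(mask).reshape(-1))
        y = y[:, voxel_indices]
    else:
        voxel_indices = np.arange(y.shape[1])
    return y, grid_shape, voxel_indices


def fit_glm(runs, design: DesignMatrix, mask=None) -> GlmFit:
    """Ordinary least squares per voxel on concatenated runs.

    ``runs`` is a list of 4D arrays / nibabel images / SimulatedRun objects
    in design order; ``mask`` optionally restricts fitting to a boolean 3D
    subset of the grid.
    """
    y, grid_shape, voxel_indices = _stack_runs(runs, mask)
    x = design.matrix
    if y.shape[0] != x.shape[0]:
        raise ValueError(
            f"data rows {y.shape[0]} != design rows {x.shape[0]}"
        )
    rank = design.rank if design.rank > 0 else np.linalg.matrix_rank(x)
    dof = x.shape[0] - rank
    if dof <= 0:
        raise ValueError("non-positive degrees of freedom")
    x_pinv = np.linalg.pinv(x)
    beta = x_pinv @ y
    resid = y - x @ beta
    sigma2 = np.einsum("tv,tv->v", resid, resid) / dof
    intercept_rows = [i for i, c in enumerate(design.columns) if c.endswith("_intercept")]
    baseline = beta[intercept_rows].mean(axis=0)
    return GlmFit(beta=beta, columns=list(design.columns),
                  condition_labels=list(design.condition_labels),
                  residual_variance=sigma2, dof=dof, xtx_pinv=x_pinv @ x_pinv.T,
                  baseline=baseline, null_space=design.null_space,
                  grid_shape=grid_shape, voxel_indices=voxel_indices)


# -- contrasts ----------------------------------------------------------------

@dataclass(frozen=True)
class ContrastSpec:
    """Named weighted combination of condition regressors.

    The composite label "english" may appear in the weights and expands to
    equal halves on the false-belief and false-photo conditions (the language
    condition is the average response to both story types).
    """

    name: str
    weights: dict

    def expanded_weights(self, available_columns=None) -> dict:
        """Weights over concrete regressor labels.

        "english" stays as-is when the fit models it explicitly (standard
        language sessions), otherwise it expands to 1/2 false-belief + 1/2
        false-photo."""
        keep_english = available_columns is not None and "english" in available_columns
        out = {}
        for label, w in self.weights.items():
            if label == "english" and not keep_english:
                out["false_belief"] = out.get("false_belief", 0.0) + 0.5 * w
                out["false_photo"] = out.get("false_photo", 0.0) + 0.5 * w
            else:
                out[label] = out.get(label, 0.0) + float(w)
        return {k: v for k, v in out.items() if v != 0.0}


#: The localizer's defining contrasts: five visual, four auditory.
CONTRASTS = {
    "Faces>Objects": ContrastSpec("Faces>Objects", {"faces": 1, "objects": -1}),
    "Scenes>Objects": ContrastSpec("Scenes>Objects", {"scenes": 1, "objects": -1}),
    "Bodies>Objects": ContrastSpec("Bodies>Objects", {"bodies": 1, "objects": -1}),
    "Words/scrambled>Objects": ContrastSpec(
        "Words/scrambled>Objects", {"words_scrambled": 1, "objects": -1}),
    "Objects>Words/scrambled": ContrastSpec(
        "Objects>Words/scrambled", {"objects": 1, "words_scrambled": -1}),
    "FalseBelief>FalsePhoto": ContrastSpec(
        "FalseBelief>FalsePhoto", {"false_belief": 1, "false_photo": -1}),
    "English>Nonwords": ContrastSpec("English>Nonwords", {"english": 1, "nonwords": -1}),
    "Nonwords>Quilted": ContrastSpec("Nonwords>Quilted", {"nonwords": 1, "quilted_audio": -1}),
    "Arithmetic>English": ContrastSpec("Arithmetic>English", {"arithmetic": 1, "english": -1}),
}


def get_contrast(name: str) -> ContrastSpec:
    try:
        return CONTRASTS[name]
    except KeyError:
        raise KeyError(f"unknown contrast {name!r}; known: {sorted(CONTRASTS)}") from None


@dataclass
class ContrastResult:
    name: str
    effect: np.ndarray        # percent signal
    t_map: np.ndarray
    p_map: np.ndarray         # two-sided
    signed_log_p: np.ndarray  # -log10(p) * sgn(t)
    dof: int
    grid_shape: tuple | None = None
    voxel_indices: np.ndarray | None = None

    def to_volume(self, field_name: str = "signed_log_p", fill: float = 0.0) -> np.ndarray:
        """Scatter a voxel vector back into the 3D grid."""
        values = getattr(self, field_name)
        vol = np.full(int(np.prod(self.grid_shape)), fill, dtype=float)
        vol[self.voxel_indices] = values
        return vol.reshape(self.grid_shape)


def compute_contrast(fit: GlmFit, spec: ContrastSpec | str) -> ContrastResult:
    """t-test of a contrast of condition betas.

    t = c'beta / sqrt(sigma2 * c'(X'X)^-1 c), with two-sided p from the
    Student t distribution at the fit's residual dof.  The effect is rescaled
    to percent signal via the fitted baseline.  The signed log-p map uses the
    t survival function on the log scale so extreme voxels do not underflow.
    """
    if isinstance(spec, str):
        spec = get_contrast(spec)
    weights = spec.expanded_weights(fit.columns)
    if not weights:
        raise ValueError(f"contrast {spec.name!r} has all-zero weights")
    unknown = set(weights) - set(fit.columns)
    if unknown:
        raise KeyError(f"contrast {spec.name!r} references unknown columns {sorted(unknown)}")
    c = np.zeros(len(fit.columns))
    for label, w in weights.items():
        c[fit.columns.index(label)] = w
    if fit.null_space is not None:
        overlap = np.abs(fit.null_space.T @ c)
        if overlap.max() > 1e-8 * max(1.0, np.abs(c).max()):
            raise ValueError(
                f"contrast {spec.name!r} is not estimable under the crossed "
                "design (it loads on the unidentifiable modality-mean split)"
            )
    est = c @ fit.beta
    var_factor = float(c @ fit.xtx_pinv @ c)
    se = np.sqrt(fit.residual_variance * var_factor)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), fit.dof)
    # -log10(p) computed from logsf to stay finite for very large |t|
    log10_p = (np.log(2.0) + stats.t.logsf(np.abs(t), fit.dof)) * LOG10_E
    slp = np.where(t == 0, 0.0, -log10_p * np.sign(t))
    effect = 100.0 * est / fit.baseline
    return ContrastResult(name=spec.name, effect=effect, t_map=t, p_map=p,
                          signed_log_p=slp, dof=fit.dof, grid_shape=fit.grid_shape,
                          voxel_indices=fit.voxel_indices)


def signed_log_p_map(result: ContrastResult, threshold: float = 3.0) -> np.ndarray:
    """Threshold the signed -log10(p) map at |value| >= threshold (else 0).

    A threshold of 3 keeps voxels with two-sided p <= 0.001; the sign of t is
    preserved, so negating every t negates the map exactly.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    slp = result.signed_log_p
    return np.where(np.abs(slp) >= threshold, slp, 0.0)


def fit_session(session, run_indices=None, mask=None,
                hrf_config: HrfConfig | None = None) -> GlmFit:
    """Fit the GLM for a (subset of a) simulated or loaded session.

    ``session`` needs .runs (with .run_index, .data, .nuisance), .events and
    .condition_labels; ``run_indices`` selects 1-based runs (default: all).
    """
    runs = [r for r in session.runs if run_indices is None or r.run_index in set(run_indices)]
    if not runs:
        raise ValueError(f"no runs selected from {run_indices}")
    runs = sorted(runs, key=lambda r: r.run_index)  # match design row order
    ids = [r.run_index for r in runs]
    events = session.events[session.events["run"].isin(ids)]
    n_vols = {r.run_index: r.data.shape[3] for r in runs}
    nuisance = {r.run_index: r.nuisance for r in runs}
    design = build_design_matrix(events, nuisance, n_vols,
                                 condition_labels=session.condition_labels,
                                 tr=session.tr, hrf_config=hrf_config)
    return fit_glm(runs, design, mask=mask)
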