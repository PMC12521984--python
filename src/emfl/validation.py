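"""Agreement between localizer sessions and selectivity ANOVAs.

Two sessions that target the same regions should (a) select overlapping
voxel sets (Dice coefficient of the top-10% fROI masks, compared within and
between sessions on matched even/odd splits and against the analytic chance
level), (b) show correlated contrast patterns across parcel voxels, and
(c) yield preferred > non-preferred responses whose strength does not depend
on which session defined the fROI (factorial ANOVA with factors contrast,
definer, measurer and optionally parcel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .froi import (
    ODD_EVEN,
    Parcel,
    Split,
    SPLITS,
    define_froi_topk,
    round_half_away,
)
from .glm import compute_contrast, fit_session


def dice(mask_a, mask_b) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) of two voxel sets.

    Accepts boolean arrays or integer index arrays; symmetric and bounded in
    [0, 1].
    """
    a, b = (np.asarray(m) for m in (mask_a, mask_b))
    if a.dtype == bool or b.dtype == bool:
        set_a = set(np.flatnonzero(np.asarray(a).reshape(-1)))
        set_b = set(np.flatnonzero(np.asarray(b).reshape(-1)))
    else:
        set_a, set_b = set(a.reshape(-1).tolist()), set(b.reshape(-1).tolist())
    if not set_a or not set_b:
        raise ValueError("dice requires two non-empty voxel sets")
    return 2.0 * len(set_a & set_b) / (len(set_a) + len(set_b))


def dice_chance_level(parcel_size: int, fraction: float, method: str = "analytic",
                      n_draws: int = 100_000, seed: int = 0) -> float:
    """Expected Dice of two independent random top-``fraction`` subsets.

    For two uniform random subsets of size k = round(fraction * N),
    E|A n B| = k^2 / N, so E[Dice] = 2 (k^2/N) / (2k) = k / N (the fraction,
    up to rounding).  ``method="monte_carlo"`` estimates the same quantity by
    simulation.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    k = max(1, round_half_away(fraction * parcel_size))
    if method == "analytic":
        return k / parcel_size
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        overlaps = np.empty(n_draws)
        for i in range(n_draws):
            a = rng.choice(parcel_size, size=k, replace=False)
            b = rng.choice(parcel_size, size=k, replace=False)
            overlaps[i] = len(set(a.tolist()) & set(b.tolist()))
        return float(np.mean(2 * overlaps / (2 * k)))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class DiceResult:
    parcel: str
    kind: str            # within_A | within_B | between_split | between_all
    split_scheme: str
    coefficient: float
    chance_level: float


def _topk_mask(session, run_ids, parcel, fraction, mask, fits):
    key = (session.kind, frozenset(run_ids))
    if key not in fits:
        fits[key] = fit_session(session, run_ids, mask=mask)
    result = compute_contrast(fits[key], parcel.defining_contrast)
    return define_froi_topk(result, parcel, fraction, defining_runs=run_ids).voxels


def compare_within_between(session_a, session_b, parcel: Parcel,
                           fraction: float = 0.10, split: Split | str = ODD_EVEN,
                           mask=None, fits: dict | None = None) -> list:
    """Dice overlap of top-fraction fROIs within and between two sessions.

    Within-session Dice uses the two halves of the split; between-session
    Dice is averaged over the four matched half-pairings (for equivalent
    statistical power) and also reported using all runs of each session.
    """
    if isinstance(split, str):
        split = SPLITS[split]
    for s, name in ((session_a, "A"), (session_b, "B")):
        if len(s.run_indices) < 2:
            raise ValueError(f"session {name} needs >= 2 runs for a within-split")
    fits = fits if fits is not None else {}
    (a1, a2), _ = split.directions(session_a.run_indices)
    (b1, b2), _ = split.directions(session_b.run_indices)
    chance = dice_chance_level(parcel.size, fraction)
    m = {
        ("A", a1): _topk_mask(session_a, a1, parcel, fraction, mask, fits),
        ("A", a2): _topk_mask(session_a, a2, parcel, fraction, mask, fits),
        ("B", b1): _topk_mask(session_b, b1, parcel, fraction, mask, fits),
        ("B", b2): _topk_mask(session_b, b2, parcel, fraction, mask, fits),
    }
    all_a = _topk_mask(session_a, tuple(session_a.run_indices), parcel, fraction, mask, fits)
    all_b = _topk_mask(session_b, tuple(session_b.run_indices), parcel, fraction, mask, fits)
    between = np.mean([
        dice(m[("A", a1)], m[("B", b1)]),
        dice(m[("A", a1)], m[("B", b2)]),
        dice(m[("A", a2)], m[("B", b1)]),
        dice(m[("A", a2)], m[("B", b2)]),
    ])
    make = lambda kind, coef: DiceResult(parcel=parcel.label, kind=kind,
                                         split_scheme=split.name,
                                         coefficient=float(coef), chance_level=chance)
    return [
        make("within_A", dice(m[("A", a1)], m[("A", a2)])),
        make("within_B", dice(m[("B", b1)], m[("B", b2)])),
        make("between_split", between),
        make("between_all", dice(all_a, all_b)),
    ]


def pattern_correlation(map_a: np.ndarray, map_b: np.ndarray, parcel: Parcel) -> float:
    """Pearson correlation of two contrast maps over the parcel's voxels."""
    idx = parcel.flat_indices
    if len(idx) < 3:
        raise ValueError("pattern correlation needs a parcel of >= 3 voxels")
    a = np.asarray(map_a).reshape(-1)[idx].astype(float)
    b = np.asarray(map_b).reshape(-1)[idx].astype(float)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values inside the parcel")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("pattern correlation undefined: zero variance within parcel")
    return float(np.corrcoef(a, b)[0, 1])


# -- selectivity ANOVA --------------------------------------------------------

ANOVA_FACTORS = ("contrast_level", "definer", "measurer")


class UnbalancedTableError(ValueError):
    pass


def _check_balance(table: pd.DataFrame, factors) -> None:
    levels = {
        "contrast_level": ["preferred", "nonpreferred"],
        "definer": ["emfl", "standard"],
        "measurer": ["emfl", "standard"],
    }
    counts = table.groupby(list(factors), observed=True).size()
    expected = 1
    for f in factors:
        expected *= table[f].nunique()
    if len(counts) < expected or counts.nunique() != 1:
        full = pd.MultiIndex.from_product(
            [sorted(table[f].unique()) for f in factors], names=list(factors))
        missing = [tuple(ix) for ix in full if tuple(ix) not in counts.index]
        raise UnbalancedTableError(
            f"unbalanced selectivity table; missing or unequal cells: "
            f"{missing if missing else counts[counts != counts.iloc[0]].index.tolist()}"
        )
    for f, lv in levels.items():
        extra = set(table[f].unique()) - set(lv)
        if extra:
            raise ValueError(f"unexpected {f} levels {sorted(extra)}")


def selectivity_anova(table: pd.DataFrame, include_parcel_factor: bool = False) -> pd.DataFrame:
    """Fixed-effects factorial ANOVA of fROI selectivity.

    ``table`` is tidy with columns subject, parcel, contrast_level
    (preferred/nonpreferred), definer (emfl/standard), measurer
    (emfl/standard) and response.  Without the parcel factor the model is the
    full 2 x 2 x 2 factorial (run per parcel); with it, the omnibus
    2 x 2 x 2 x n_parcels factorial.  Sums of squares are sequential, which
    on a balanced table equals the classic factorial cell-mean
    decomposition; the residual pools over subject replicates.  Returns a
    table with columns df, sum_sq, mean_sq, F, PR(>F).
    """
    factors = list(ANOVA_FACTORS) + (["parcel"] if include_parcel_factor else [])
    missing_cols = set(factors + ["response"]) - set(table.columns)
    if missing_cols:
        raise ValueError(f"table lacks columns {sorted(missing_cols)}")
    _check_balance(table, factors)
    formula = "response ~ " + " * ".join(f"C({f})" for f in factors)
    fit = smf.ols(formula, data=table).fit()
    anova = anova_lm(fit, typ=1)
    if "mean_sq" not in anova.columns:
        anova.insert(2, "mean_sq", anova["sum_sq"] / anova["df"])
    anova["df"] = anova["df"].astype(int)
    return anova[["df", "sum_sq", "mean_sq", "F", "PR(>F)"]]


def null_selectivity_table(n_subjects: int = 10, n_parcels: int = 1,
                           contrast_effect: float = 1.0, definer_effect: float = 0.2,
                           measurer_effect: float = 0.2, noise_sd: float = 0.5,
                           seed: int = 0) -> pd.DataFrame:
    """Synthetic selectivity table with *no* contrast x definer interaction.

    Responses are cell means (main effects only, equal selectivity whichever
    session defined the fROI) plus independent Gaussian subject noise; used
    to check the type-I calibration of the interaction test.
    """
    rng = np.random.default_rng(seed)
    rows = []
    parcels = [f"P{i + 1}" for i in range(n_parcels)]
    parcel_shift = rng.normal(0, 0.5, size=n_parcels)
    for s in range(1, n_subjects + 1):
        for ip, parcel in enumerate(parcels):
            for level in ("preferred", "nonpreferred"):
                for definer in ("emfl", "standard"):
                    for measurer in ("emfl", "standard"):
                        mu = (
                            parcel_shift[ip]
                            + contrast_effect * (level == "preferred")
                            + definer_effect * (definer == "emfl")
                            + measurer_effect * (measurer == "emfl")
                        )
                        rows.append((f"S{s:02d}", parcel, level, definer, measurer,
                                     mu + rng.normal(0, noise_sd)))
    return pd.DataFrame(rows, columns=["subject", "parcel", "contrast_level",
                                       "definer", "measurer", "response"])
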