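"""Concurrent-validity statistics and parameter-grid tuning.

Bland-Altman agreement between a test and a reference device:

* ``bias``      — mean of (test - reference);
* ``loa``       — 95% limits of agreement, ``bias ± 1.96 * sd_diff`` with the
  sample SD (divisor n-1);
* ``bias_ci``   — t-based confidence interval of the bias;
* proportional bias — OLS slope of the difference on the pair mean, with a
  "no proportional bias" decision iff the slope CI covers zero;
* ``mape_pct``  — mean absolute percent error;
* ``percent_bias`` — bias relative to the reference mean, in percent.

Agreement can be computed per day or over per-participant daily means
(participant-level is the default pairing unit when a participant id is
available).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._util import DataError, round_half_up
from .metrics import PairedDaily
from .signal_io import RawRecording, vector_magnitude, resample_magnitude
from .step_core import StepParameters, _detect_on_magnitude

__all__ = [
    "AgreementResult",
    "TuningResult",
    "bland_altman",
    "proportional_bias",
    "mape",
    "percent_bias",
    "tune_parameters",
    "pairs_from_paired_daily",
]

logger = logging.getLogger(__name__)

LOA_MULTIPLIER = 1.96


@dataclass
class AgreementResult:
    n_pairs: int
    bias: float
    bias_ci: tuple[float, float]
    sd_diff: float
    loa: tuple[float, float]
    prop_slope: float | None = None
    prop_slope_ci: tuple[float, float] | None = None
    prop_intercept: float | None = None
    mape_pct: float | None = None
    percent_bias: float | None = None
    degenerate: bool = False  # zero difference variance; LoA collapsed to bias

    @property
    def proportional_bias_detected(self) -> bool | None:
        if self.prop_slope_ci is None:
            return None
        lo, hi = self.prop_slope_ci
        return not (lo <= 0.0 <= hi)

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "bias": self.bias,
            "bias_ci": list(self.bias_ci),
            "sd_diff": self.sd_diff,
            "loa": list(self.loa),
            "prop_slope": self.prop_slope,
            "prop_slope_ci": list(self.prop_slope_ci) if self.prop_slope_ci else None,
            "prop_intercept": self.prop_intercept,
            "mape_pct": self.mape_pct,
            "percent_bias": self.percent_bias,
            "degenerate": self.degenerate,
        }


def _as_pairs(pairs) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DataError("pairs must be a sequence of (test, reference) values")
    return arr[:, 0], arr[:, 1]


def bland_altman(pairs, level: float = 0.95) -> AgreementResult:
    """Mean bias, t-based bias CI, and 95% limits of agreement.

    ``bias = mean(test - reference)``; ``loa = bias ± 1.96 * sd`` where ``sd``
    is the sample standard deviation of the differences (divisor n-1);
    ``bias_ci = bias ± t(n-1, level) * sd / sqrt(n)``.
    """
    test, ref = _as_pairs(pairs)
    n = test.size
    if n < 2:
        raise DataError("Bland-Altman analysis needs at least 2 pairs")
    diffs = test - ref
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    degenerate = sd == 0.0
    if degenerate:
        warnings.warn("zero variance of differences; limits of agreement collapse to the bias")
    half = LOA_MULTIPLIER * sd
    t_crit = float(stats.t.ppf(0.5 + level / 2.0, n - 1))
    ci_half = t_crit * sd / np.sqrt(n)
    result = AgreementResult(
        n_pairs=n,
        bias=bias,
        bias_ci=(bias - ci_half, bias + ci_half),
        sd_diff=sd,
        loa=(bias - half, bias + half),
        degenerate=degenerate,
    )
    means = (test + ref) / 2.0
    if n >= 3 and np.ptp(means) > 0:
        slope, intercept, ci = proportional_bias(pairs, level=level)
        result = replace(result, prop_slope=slope, prop_intercept=intercept, prop_slope_ci=ci)
    if (ref > 0).all():
        result = replace(result, mape_pct=mape(pairs))
    if ref.mean() > 0:
        result = replace(result, percent_bias=percent_bias(bias, float(ref.mean())))
    return result


def proportional_bias(pairs, level: float = 0.95) -> tuple[float, float, tuple[float, float]]:
    """OLS of (test - reference) on the pair mean: (slope, intercept, slope CI)."""
    test, ref = _as_pairs(pairs)
    n = test.size
    if n < 3:
        raise DataError("proportional-bias regression needs at least 3 pairs")
    means = (test + ref) / 2.0
    diffs = test - ref
    if np.ptp(means) == 0:
        raise DataError("pair means are constant; slope is undefined")
    fit = stats.linregress(means, diffs)
    t_crit = float(stats.t.ppf(0.5 + level / 2.0, n - 2))
    ci = (fit.slope - t_crit * fit.stderr, fit.slope + t_crit * fit.stderr)
    return float(fit.slope), float(fit.intercept), ci


def mape(pairs) -> float:
    """Mean absolute percent error: mean of |test - reference| / reference * 100."""
    test, ref = _as_pairs(pairs)
    bad = np.nonzero(ref <= 0)[0]
    if bad.size:
        i = int(bad[0])
        raise DataError(
            f"reference value must be positive; pair {i} has reference {ref[i]}"
        )
    return float(np.mean(np.abs(test - ref) / ref) * 100.0)


def percent_bias(bias: float, reference_mean: float) -> float:
    """Bias relative to the reference mean, as a percentage at display precision (1 dp)."""
    if not reference_mean > 0:
        raise DataError("reference_mean must be positive")
    return round_half_up(bias / reference_mean * 100.0, 1)


def pairs_from_paired_daily(
    pairs: list[PairedDaily], metric: str = "total"
) -> np.ndarray:
    """(test, reference) array from paired day summaries; metric total|mvpa."""
    if metric == "total":
        rows = [(p.wrist_total, p.reference_total) for p in pairs]
    elif metric == "mvpa":
        rows = [(p.wrist_mvpa, p.reference_mvpa) for p in pairs]
    else:
        raise DataError(f"unknown metric {metric!r}; use 'total' or 'mvpa'")
    return np.asarray(rows, dtype=float)


# ---------------------------------------------------------------------------
# Parameter-grid tuning
# ---------------------------------------------------------------------------

#: canonical field order used to enumerate the Cartesian grid
GRID_FIELDS = (
    "peak_win_samples",
    "min_period_samples",
    "max_period_samples",
    "similarity_threshold_g",
    "continuity_window_samples",
    "continuity_count_threshold",
    "variance_threshold_g2",
    "magnitude_threshold_g",
)


@dataclass
class TuningResult:
    grid: list[StepParameters]
    scores: pd.DataFrame  # one row per combo: mean_bias, abs_mean_bias, n_over, n_under
    selected: StepParameters
    n_combos: int
    n_skipped: int = 0


def expand_grid(
    grid_spec: dict[str, list], algorithm_rate_hz: float = 15.0
) -> tuple[list[StepParameters], int]:
    """Cartesian product of per-field candidates, in canonical field order.

    Fields missing from the spec take the optimized-preset defaults.
    Infeasible combinations (min period > max period) are skipped and logged.
    """
    from .step_core import VERISENSE_2

    unknown = set(grid_spec) - set(GRID_FIELDS)
    if unknown:
        raise DataError(f"unknown grid fields: {sorted(unknown)}")
    candidates = [
        list(grid_spec.get(f, [getattr(VERISENSE_2, f)])) for f in GRID_FIELDS
    ]
    combos: list[StepParameters] = []
    skipped = 0
    for values in itertools.product(*candidates):
        kwargs = dict(zip(GRID_FIELDS, values))
        if kwargs["min_period_samples"] > kwargs["max_period_samples"]:
            skipped += 1
            logger.info("skipping infeasible combo: %s", kwargs)
            continue
        combos.append(StepParameters(algorithm_rate_hz=algorithm_rate_hz, **kwargs))
    if not combos:
        raise DataError("parameter grid is empty")
    return combos, skipped


def tune_parameters(
    grid_spec: dict[str, list],
    recordings: list[tuple[RawRecording, float]],
    objective=None,
    algorithm_rate_hz: float = 15.0,
) -> TuningResult:
    """Exhaustively score a parameter grid against reference step totals.

    For every combination, ``count_steps`` is run on every labelled recording
    and the signed bias (detected - reference) recorded.  The default
    objective is lexicographic: minimize |mean bias|, break ties on the
    imbalance between over- and under-estimated recordings, then on grid
    order.  A custom ``objective(row) -> sortable`` may be supplied.
    """
    if not recordings:
        raise DataError("tuning requires at least one labelled recording")
    combos, skipped = expand_grid(grid_spec, algorithm_rate_hz=algorithm_rate_hz)

    # the magnitude resample depends only on the rate: hoist it out of the loop
    mags = [
        resample_magnitude(vector_magnitude(rec), algorithm_rate_hz)
        for rec, _ in recordings
    ]
    refs = np.asarray([ref for _, ref in recordings], dtype=float)

    rows = []
    for combo_id, params in enumerate(combos):
        counts = np.asarray(
            [len(_detect_on_magnitude(mag, params)) for mag in mags], dtype=float
        )
        biases = counts - refs
        rows.append(
            {
                "combo_id": combo_id,
                "mean_bias": biases.mean(),
                "abs_mean_bias": abs(biases.mean()),
                "n_over": int((biases > 0).sum()),
                "n_under": int((biases < 0).sum()),
                **{f: getattr(params, f) for f in GRID_FIELDS},
            }
        )
    scores = pd.DataFrame(rows)
    if objective is None:
        key = lambda row: (row["abs_mean_bias"], abs(row["n_over"] - row["n_under"]), row["combo_id"])
    else:
        key = objective
    best = min((row for _, row in scores.iterrows()), key=key)
    selected = combos[int(best["combo_id"])]
    return TuningResult(
        grid=combos,
        scores=scores,
        selected=selected,
        n_combos=len(combos),
        n_skipped=skipped,
    )
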