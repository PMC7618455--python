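"""Dose-response normalization and drug-combination synergy scoring.

Raw plate readings are anchored to the negative (growth) and positive
(total-kill) controls to give percent inhibition.  Combination matrices
are scored against four reference null models — HSA (highest single
agent), Bliss (probabilistic independence), Loewe (dose additivity via
fitted 4PL monotherapy curves), and ZIP (potency-shift independence) —
as observed-minus-expected in percentage points.  A combination is
called synergistic when the mean score is at least 5; significance comes
from bootstrap resampling of replicate readings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

MODELS = ("hsa", "bliss", "loewe", "zip")
SYNERGY_CALL_THRESHOLD = 5.0


@dataclass
class DoseResponse:
    """Long-format dose-response readings plus plate controls.

    ``data`` columns: dose1, dose2, replicate, reading (raw viability
    signal).  ``neg_control`` is the growth-control mean, ``pos_control``
    the total-kill mean; both on the reading scale.
    """

    data: pd.DataFrame
    neg_control: float
    pos_control: float

    def __post_init__(self) -> None:
        required = {"dose1", "dose2", "replicate", "reading"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"data must have columns {sorted(required)}")
        if not np.isfinite([self.neg_control, self.pos_control]).all():
            raise ValueError("controls must be finite")
        if self.neg_control <= self.pos_control:
            raise ValueError("negative (growth) control must exceed positive control")
        d1 = np.sort(self.data["dose1"].unique())
        d2 = np.sort(self.data["dose2"].unique())
        if d1[0] != 0 or d2[0] != 0:
            raise ValueError("dose grid must include the zero dose for both drugs")
        if ((self.data["dose1"] == 0) & (self.data["dose2"] == 0)).sum() == 0:
            raise ValueError("zero-zero cell missing")


def to_inhibition(dr: DoseResponse) -> pd.DataFrame:
    """Percent-inhibition surface (dose1 rows x dose2 columns).

    inhibition% = 100 * (neg - reading) / (neg - pos), averaged over
    replicates.  Values outside [0, 100] are kept (a warning flags them).
    """
    span = dr.neg_control - dr.pos_control
    inh = 100.0 * (dr.neg_control - dr.data["reading"]) / span
    surface = (
        dr.data.assign(inhibition=inh)
        .pivot_table(index="dose1", columns="dose2", values="inhibition")
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    vals = surface.to_numpy()
    if np.any((vals < 0) | (vals > 100)):
        warnings.warn("inhibition values outside [0, 100] (noisy plate?)")
    return surface


def _monotherapies(surface: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    if 0 not in surface.index or 0 not in surface.columns:
        raise ValueError("surface lacks monotherapy row/column (zero doses)")
    return surface[0].copy(), surface.loc[0].copy()  # drug1 column, drug2 row


def _combo_mask(surface: pd.DataFrame) -> np.ndarray:
    return np.outer(surface.index.to_numpy() > 0, surface.columns.to_numpy() > 0)


def hsa_excess(surface: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Observed minus the higher single agent, per combination cell."""
    y1, y2 = _monotherapies(surface)
    expected = np.maximum.outer(y1.to_numpy(), y2.to_numpy())
    excess = surface - expected
    mask = _combo_mask(surface)
    return excess.where(mask), float(excess.to_numpy()[mask].mean())


def bliss_excess(surface: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Observed minus Bliss independence (fractions: y1 + y2 - y1*y2)."""
    y1, y2 = _monotherapies(surface)
    f1, f2 = y1.to_numpy() / 100.0, y2.to_numpy() / 100.0
    expected = 100.0 * (f1[:, None] + f2[None, :] - np.outer(f1, f2))
    excess = surface - expected
    mask = _combo_mask(surface)
    return excess.where(mask), float(excess.to_numpy()[mask].mean())


def _4pl(d, ymin, ymax, ec50, hill):
    d = np.asarray(d, dtype=float)
    out = np.full(d.shape, float(ymin))
    nz = d > 0
    out[nz] = ymin + (ymax - ymin) / (1.0 + (ec50 / d[nz]) ** hill)
    return out


@dataclass
class FourPL:
    """Four-parameter logistic dose-response curve (percent inhibition)."""

    ymin: float
    ymax: float
    ec50: float
    hill: float
    notes: list[str] = field(default_factory=list)

    def __call__(self, d) -> np.ndarray:
        return _4pl(d, self.ymin, self.ymax, self.ec50, self.hill)

    def inverse(self, y: float) -> float:
        """Dose producing response y; inf/0 outside the response range."""
        lo, hi = sorted((self.ymin, self.ymax))
        if not lo < y < hi:
            return np.inf if (y >= hi) == (self.ymax >= self.ymin) else 0.0
        ratio = (y - self.ymin) / (self.ymax - y)
        return self.ec50 * ratio ** (1.0 / self.hill)


def fit_4pl(doses: np.ndarray, responses: np.ndarray) -> FourPL:
    """Least-squares 4PL fit of a monotherapy curve.

    The zero dose maps to the lower asymptote; initialization uses the
    endpoint responses and the median positive dose.  A decreasing curve
    is accommodated by ymax < ymin rather than a negative slope.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if (doses > 0).sum() < 3:
        raise ValueError("need >=3 nonzero doses to fit a 4PL curve")
    order = np.argsort(doses)
    doses, responses = doses[order], responses[order]
    p0 = [
        responses[0],
        responses[-1],
        float(np.median(doses[doses > 0])),
        1.0,
    ]
    bounds = (
        [-100.0, -100.0, doses[doses > 0].min() / 1e3, 0.05],
        [200.0, 200.0, doses.max() * 1e3, 20.0],
    )
    p0[2] = np.clip(p0[2], bounds[0][2], bounds[1][2])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, _ = curve_fit(
            _4pl, doses, responses, p0=p0, bounds=bounds, maxfev=20000
        )
    fit = FourPL(*popt)
    fit.notes.append(f"init={p0}")
    return fit


def _loewe_expected(d1: float, d2: float, c1: FourPL, c2: FourPL) -> tuple[float, bool]:
    """Solve d1/D1(y) + d2/D2(y) = 1 for y; fall back to the nearer asymptote."""
    lo = max(min(c1.ymin, c1.ymax), min(c2.ymin, c2.ymax))
    hi = min(max(c1.ymin, c1.ymax), max(c2.ymin, c2.ymax))
    eps = 1e-9 * max(1.0, hi - lo)

    def f(y: float) -> float:
        D1, D2 = c1.inverse(y), c2.inverse(y)
        # large finite stand-in keeps brentq happy near the asymptote
        t1 = min(d1 / D1, 1e12) if D1 > 0 else 1e12
        t2 = min(d2 / D2, 1e12) if D2 > 0 else 1e12
        return t1 + t2 - 1.0

    a, b = lo + eps, hi - eps
    if a >= b:
        return max(c1(d1), c2(d2)), True
    fa, fb = f(a), f(b)
    if fa * fb > 0:
        # even the extreme responses cannot balance the equation
        return (hi if fb > 0 else lo), True
    y = brentq(f, a, b, xtol=1e-6)
    return y, False


def loewe_excess(surface: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Observed minus Loewe dose-additive expectation.

    Monotherapy 4PL curves are fitted per drug; the expected combination
    response solves the Loewe equation by bisection on the response
    scale.  Non-bracketing cells fall back to the nearer asymptote and
    are flagged in the returned frame's attrs.
    """
    y1, y2 = _monotherapies(surface)
    c1 = fit_4pl(y1.index.to_numpy(), y1.to_numpy())
    c2 = fit_4pl(y2.index.to_numpy(), y2.to_numpy())
    expected = pd.DataFrame(
        np.nan, index=surface.index, columns=surface.columns
    )
    fallbacks = []
    for d1 in surface.index:
        for d2 in surface.columns:
            if d1 > 0 and d2 > 0:
                val, fell_back = _loewe_expected(float(d1), float(d2), c1, c2)
                expected.loc[d1, d2] = val
                if fell_back:
                    fallbacks.append((d1, d2))
    excess = surface - expected
    mask = _combo_mask(surface)
    vals = excess.to_numpy()[mask]
    excess.attrs["fallback_cells"] = fallbacks
    return excess.where(mask), float(np.nanmean(vals))


def _fit_conditional_ec(
    doses: np.ndarray, responses: np.ndarray, ymin: float, init: FourPL
) -> Callable[[np.ndarray], np.ndarray]:
    """2-parameter potency-shift fit: 4PL from fixed ymin to 100."""

    def model(d, ec50, hill):
        return _4pl(d, ymin, 100.0, ec50, hill)

    pos = doses > 0
    p0 = [np.clip(init.ec50, 1e-6, 1e6), np.clip(init.hill, 0.1, 10.0)]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model,
                doses,
                responses,
                p0=p0,
                bounds=([doses[pos].min() / 1e3, 0.05], [doses.max() * 1e3, 20.0]),
                maxfev=20000,
            )
        return lambda d: model(d, *popt)
    except RuntimeError:
        return None


def zip_excess(surface: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """ZIP delta: potency-shift fits minus the Bliss-form expectation.

    Monotherapy 4PL fits give the expectation
    y1 + y2 - y1*y2 (fractions).  The observed combination response is
    smoothed by refitting each row (drug 1 varying at fixed drug 2) and
    each column as a 4PL anchored at the partner drug's fitted effect and
    saturating at 100%; the delta at each combination cell is the mean of
    the two conditional fits minus the expectation, in percentage points.
    """
    y1, y2 = _monotherapies(surface)
    c1 = fit_4pl(y1.index.to_numpy(), y1.to_numpy())
    c2 = fit_4pl(y2.index.to_numpy(), y2.to_numpy())
    d1 = surface.index.to_numpy(dtype=float)
    d2 = surface.columns.to_numpy(dtype=float)
    f1 = np.clip(c1(d1), 0.0, 100.0) / 100.0
    f2 = np.clip(c2(d2), 0.0, 100.0) / 100.0
    expected = 100.0 * (f1[:, None] + f2[None, :] - np.outer(f1, f2))

    row_fit = np.full(surface.shape, np.nan)
    for j, dd2 in enumerate(d2):
        if dd2 == 0:
            continue
        fitted = _fit_conditional_ec(
            d1, surface.iloc[:, j].to_numpy(), float(100.0 * f2[j]), c1
        )
        if fitted is not None:
            row_fit[:, j] = fitted(d1)
    col_fit = np.full(surface.shape, np.nan)
    for i, dd1 in enumerate(d1):
        if dd1 == 0:
            continue
        fitted = _fit_conditional_ec(
            d2, surface.iloc[i, :].to_numpy(), float(100.0 * f1[i]), c2
        )
        if fitted is not None:
            col_fit[i, :] = fitted(d2)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        smoothed = np.nanmean(np.stack([row_fit, col_fit]), axis=0)
    delta = pd.DataFrame(
        smoothed - expected, index=surface.index, columns=surface.columns
    )
    mask = _combo_mask(surface)
    vals = delta.to_numpy()[mask]
    return delta.where(mask), float(np.nanmean(vals))


_SCORERS: dict[str, Callable[[pd.DataFrame], tuple[pd.DataFrame, float]]] = {
    "hsa": hsa_excess,
    "bliss": bliss_excess,
    "loewe": loewe_excess,
    "zip": zip_excess,
}


def mean_synergy(dr: DoseResponse, model: str) -> float:
    if model not in _SCORERS:
        raise ValueError(f"model must be one of {MODELS}")
    return _SCORERS[model](to_inhibition(dr))[1]


def classify(mean_score: float) -> bool:
    """Synergistic iff the mean synergy score is at least 5 (inclusive)."""
    if not np.isfinite(mean_score):
        raise ValueError("mean synergy score must be finite")
    return mean_score >= SYNERGY_CALL_THRESHOLD


def bootstrap_significance(
    dr: DoseResponse, model: str, n_boot: int = 10, seed: int = 0
) -> float:
    """Bootstrap P for the mean synergy score under replicate resampling.

    Replicate readings are resampled with replacement within each dose
    cell; P is twice the (+1-corrected) fraction of bootstrap means on
    the opposite side of zero from the observed mean (capped at 1).  The
    default 10 iterations bounds P from below at 2/11 — a warning
    recommends more for stable values.
    """
    reps = dr.data.groupby(["dose1", "dose2"])["replicate"].nunique()
    if (reps < 2).any():
        raise ValueError(
            "bootstrap needs >=2 replicates per dose cell; "
            "consider a parametric test for single-replicate data"
        )
    if n_boot < 100:
        warnings.warn(
            f"n_boot={n_boot} gives coarse P resolution (minimum {2.0/(n_boot+1):.2f})"
        )
    observed = mean_synergy(dr, model)
    if abs(observed) < 1e-9:  # no effect in either direction
        return 1.0
    rng = np.random.default_rng(seed)
    groups = [g for _, g in dr.data.groupby(["dose1", "dose2"], sort=True)]
    opposite = 0
    for _ in range(n_boot):
        resampled = pd.concat(
            [g.sample(n=len(g), replace=True, random_state=rng) for g in groups],
            ignore_index=True,
        )
        boot_dr = DoseResponse(resampled, dr.neg_control, dr.pos_control)
        if mean_synergy(boot_dr, model) * np.sign(observed) < 0:
            opposite += 1
    return min(1.0, 2.0 * (opposite + 1) / (n_boot + 1))


@dataclass
class SynergyResult:
    scores: pd.DataFrame  # per model: mean_score, pval, synergistic

    def __str__(self) -> str:
        return self.scores.to_string()


def score_combination(
    dr: DoseResponse,
    models: tuple[str, ...] = MODELS,
    n_boot: int = 10,
    seed: int = 0,
    with_bootstrap: bool = True,
) -> SynergyResult:
    """Mean synergy scores, bootstrap P, and the >=5 call for each model."""
    rows = []
    for model in models:
        mean = mean_synergy(dr, model)
        p = (
            bootstrap_significance(dr, model, n_boot=n_boot, seed=seed)
            if with_bootstrap
            else np.nan
        )
        rows.append((model, mean, p, classify(mean)))
    return SynergyResult(
        pd.DataFrame(
            rows, columns=["model", "mean_score", "pval", "synergistic"]
        ).set_index("model")
    )
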