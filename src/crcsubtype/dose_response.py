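"""Bioluminescence spheroid cytotoxicity analysis.

Luciferase-labelled spheroids report viable mass as luminescence counts;
a day-0 titration of seeded cells checks that signal scales linearly with
cell amount (QC), then a seven-day oxaliplatin dilution series is fitted
with the four-parameter logistic (4PL) model

    R(d) = bottom + (top - bottom) / (1 + 10**(hill * (log10 d - log10 IC50)))

on signals normalized to the dose-0 mean. IC50 is the relative convention
(curve midpoint: R(IC50) = (top + bottom)/2). Its SD comes from refitting
each replicate's own curve; 2D-vs-spheroid IC50 shifts are tested with a
Welch unequal-variance t-test on log10 per-replicate IC50s.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger("crcsubtype")

PLATE_COLUMNS = ("model_id", "condition", "dose_uM", "replicate", "day", "signal")


@dataclass
class PlateReadout:
    """Long-format luminescence records for one or more models.

    Columns: model_id, condition (2D | spheroid), dose_uM (0 = untreated
    control), replicate, day, signal (counts >= 0). ``seeded_cells`` maps
    model_id -> cells seeded per well (the study seeds 150-1500 per line).
    """

    table: pd.DataFrame
    seeded_cells: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in PLATE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"plate table missing columns: {missing}")
        if (self.table["signal"] < 0).any():
            raise ValueError("negative luminescence signal")
        if (self.table["dose_uM"] < 0).any():
            raise ValueError("negative dose")

    def endpoint(self, model_id: str, condition: str, day: int | None = None) -> pd.DataFrame:
        sub = self.table[
            (self.table["model_id"] == model_id) & (self.table["condition"] == condition)
        ]
        if sub.empty:
            raise ValueError(f"no records for {model_id!r}/{condition!r}")
        day = int(sub["day"].max()) if day is None else day
        return sub[sub["day"] == day]


# ---------------------------------------------------------------------------
# Growth-kinetics QC


def growth_linearity(cells: np.ndarray, signal: np.ndarray) -> dict[str, float]:
    """Least-squares line signal ~ seeded cells; R^2 gates assay validity.

    A freshly formed spheroid's luminescence should be proportional to its
    cell amount; a poor R^2 flags saturation or seeding problems.
    """
    cells = np.asarray(cells, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if len(np.unique(cells)) < 3:
        raise ValueError("growth linearity needs >= 3 distinct seeded-cell values")
    fit = stats.linregress(cells, signal)
    ss_res = np.sum((signal - (fit.intercept + fit.slope * cells)) ** 2)
    ss_tot = np.sum((signal - signal.mean()) ** 2)
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(r2),
        "slope_stderr": float(fit.stderr),
    }


# ---------------------------------------------------------------------------
# 4PL fitting


def four_pl(dose: np.ndarray, top: float, bottom: float, hill: float, log_ic50: float) -> np.ndarray:
    """4PL response at dose (µM); parameterized by log10 IC50 for stable fitting."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (np.log10(dose) - log_ic50)))


@dataclass
class FourPLFit:
    top: float
    bottom: float
    hill: float
    ic50: float
    ic50_sd: float | None
    replicate_ic50s: list[float]
    residual_ss: float
    converged: bool
    n_points: int


def _fit_single(
    doses: np.ndarray,
    responses: np.ndarray,
    log_ic50_grid: np.ndarray,
    constrain: bool,
) -> tuple[np.ndarray, float]:
    """Multi-start least squares; returns (params, rss) of the best start."""
    best: tuple[np.ndarray, float] | None = None
    top0 = float(np.max(responses))
    bot0 = float(np.min(responses))
    if constrain:
        # with <4 distinct doses, pin top/bottom to the data envelope
        def model(d, hill, log_ic50):
            return four_pl(d, top0, bot0, hill, log_ic50)

        for start in log_ic50_grid:
            try:
                popt, _ = optimize.curve_fit(
                    model, doses, responses, p0=[1.0, start], maxfev=5000
                )
            except RuntimeError:
                continue
            rss = float(np.sum((model(doses, *popt) - responses) ** 2))
            params = np.array([top0, bot0, popt[0], popt[1]])
            if best is None or rss < best[1]:
                best = (params, rss)
    else:
        for start in log_ic50_grid:
            try:
                popt, _ = optimize.curve_fit(
                    four_pl, doses, responses,
                    p0=[top0, bot0, 1.0, start],
                    bounds=([-np.inf, -np.inf, 0.05, -8.0], [np.inf, np.inf, 20.0, 8.0]),
                    maxfev=5000,
                )
            except RuntimeError:
                continue
            rss = float(np.sum((four_pl(doses, *popt) - responses) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
    if best is None:
        raise RuntimeError(
            "4PL fit failed to converge from any start "
            f"(grid {log_ic50_grid.min():.1f}..{log_ic50_grid.max():.1f})"
        )
    return best


def fit_4pl(
    doses: np.ndarray,
    responses: np.ndarray,
    replicate: np.ndarray | None = None,
    n_starts: int = 5,
) -> FourPLFit:
    """Fit the 4PL model to (dose, normalized response) pairs.

    Doses are µM; dose-0 controls must already have been used to normalize
    (dose-0 mean = 1) and are excluded from the fit. Multi-start on a
    log10-IC50 grid spanning the dosed range guards against local minima.
    When ``replicate`` labels are given and >= 2 replicates exist, each
    replicate's curve is refitted alone and the SD of those IC50s is
    reported — the dispersion the Welch comparison uses.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    keep = doses > 0
    doses, responses = doses[keep], responses[keep]
    if replicate is not None:
        replicate = np.asarray(replicate)[keep]
    distinct = np.unique(doses)
    if len(distinct) < 2:
        raise ValueError("need >= 2 distinct positive doses")
    constrain = len(distinct) < 4

    if stats.spearmanr(doses, responses).statistic > 0.5:
        warnings.warn("response increases with dose: no inhibition detected")

    lo, hi = np.log10(distinct.min()), np.log10(distinct.max())
    grid = np.linspace(lo, hi, n_starts)
    params, rss = _fit_single(doses, responses, grid, constrain)
    top, bottom, hill, log_ic50 = params
    if bottom > top:
        # canonicalize: report the larger asymptote as top
        top, bottom, hill = bottom, top, -hill

    rep_ic50s: list[float] = []
    if replicate is not None:
        for rep in np.unique(replicate):
            mask = replicate == rep
            if len(np.unique(doses[mask])) < 2:
                continue
            try:
                p, _ = _fit_single(doses[mask], responses[mask], grid, constrain)
                rep_ic50s.append(float(10.0 ** p[3]))
            except RuntimeError:
                logger.warning("replicate %s: 4PL refit failed, excluded from SD", rep)
    ic50_sd = float(np.std(rep_ic50s, ddof=1)) if len(rep_ic50s) >= 2 else None

    return FourPLFit(
        top=float(top), bottom=float(bottom), hill=float(hill),
        ic50=float(10.0 ** log_ic50), ic50_sd=ic50_sd,
        replicate_ic50s=rep_ic50s, residual_ss=rss, converged=True,
        n_points=int(len(doses)),
    )


def normalize_to_control(sub: pd.DataFrame) -> pd.DataFrame:
    """Divide signals by the dose-0 mean of the same condition/day slice."""
    control = sub.loc[sub["dose_uM"] == 0, "signal"]
    if control.empty:
        raise ValueError("no dose-0 control wells to normalize against")
    norm = sub.copy()
    norm["response"] = sub["signal"] / control.mean()
    return norm


def fit_plate(readout: PlateReadout, model_id: str, condition: str) -> FourPLFit:
    """Normalize a model/condition's endpoint wells and fit its 4PL curve."""
    sub = normalize_to_control(readout.endpoint(model_id, condition))
    treated = sub[sub["dose_uM"] > 0]
    return fit_4pl(
        treated["dose_uM"].to_numpy(),
        treated["response"].to_numpy(),
        replicate=treated["replicate"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# Welch comparison


@dataclass
class IC50Comparison:
    model_id: str
    ic50_2d: float
    ic50_3d: float
    welch_t: float
    welch_df: float
    p_value: float
    significant: bool
    alpha: float


def welch_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch unequal-variance t with Welch-Satterthwaite df; two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def compare_ic50(
    fit_2d: FourPLFit,
    fit_3d: FourPLFit,
    model_id: str = "",
    alpha: float = 0.05,
) -> IC50Comparison:
    """Welch test of 2D vs spheroid IC50s on the log10 scale.

    IC50s are positive and roughly log-normal across replicates, so the
    test is run on log10 per-replicate IC50s from each fit.
    """
    if len(fit_2d.replicate_ic50s) < 2 or len(fit_3d.replicate_ic50s) < 2:
        raise ValueError("compare_ic50 needs >= 2 per-replicate IC50s on each side")
    t, df, p = welch_test(
        np.log10(fit_2d.replicate_ic50s), np.log10(fit_3d.replicate_ic50s)
    )
    return IC50Comparison(
        model_id=model_id,
        ic50_2d=fit_2d.ic50, ic50_3d=fit_3d.ic50,
        welch_t=t, welch_df=df, p_value=p,
        significant=bool(p < alpha), alpha=alpha,
    )
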