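"""Time-to-seizure quantification for heat- and mechanically-induced assays.

Heat assay: vials of flies are immersed in a hot water bath and the
cumulative number showing seizure-like behavior is scored at fixed intervals
(typically every 5 min for 80 min).  Seizure susceptibility is summarized by
T50, the time at which half the flies have seized, obtained by fitting a
variable-slope sigmoid in log10 time — the four-parameter logistic family of
dose-response analysis, with time playing the role of dose:

    f(t) = bottom + (top - bottom) / (1 + 10**((log10(T50) - log10(t)) * h))

``h`` is the Hill slope.  The bottom asymptote is fixed at 0 (no fly has
seized at t -> 0); the top defaults to free in (0, 1] since not every fly
seizes within the assay window.  log10(T50) is the logEC50 of the fit.
Because absolute T50 drifts day to day, genotypes are compared as the ratio
of their T50 to a same-day background control's (ratio > 1: protected,
< 1: susceptible).

Mechanical ("bang-sensitive") assay: the per-vial fraction of flies seizing
after vortex stimulation, summarized per genotype for downstream rank tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DataError, FormatError, ParameterError

__all__ = [
    "SeizureTimeCourse",
    "SigmoidFitResult",
    "AssaySummary",
    "sigmoid",
    "fit_sigmoid",
    "normalize_t50",
    "summarize_bang_assay",
]

TIME_COURSE_COLUMNS = ["vial_id", "genotype", "time_min", "n_total", "n_seized_cum"]


@dataclass
class SeizureTimeCourse:
    """Per-vial cumulative seized counts over strictly increasing timepoints."""

    data: pd.DataFrame  # columns vial_id, genotype, time_min, n_total, n_seized_cum

    def __post_init__(self) -> None:
        missing = set(TIME_COURSE_COLUMNS) - set(self.data.columns)
        if missing:
            raise FormatError(f"time course lacks columns {sorted(missing)}")
        d = self.data
        if (d["n_seized_cum"] < 0).any() or (d["n_total"] < 1).any():
            raise DataError("counts must be non-negative and vials non-empty")
        if (d["n_seized_cum"] > d["n_total"]).any():
            raise DataError("cumulative seized count exceeds flies in vial")
        for vial, grp in d.groupby("vial_id", sort=False):
            t = grp["time_min"].to_numpy()
            if not np.all(np.diff(t) > 0):
                raise DataError(f"vial {vial}: timepoints must be strictly increasing")
            if not np.all(np.diff(grp["n_seized_cum"].to_numpy()) >= 0):
                raise DataError(f"vial {vial}: seized counts must be non-decreasing")

    @property
    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self.data["genotype"]))

    def for_genotype(self, genotype: str) -> "SeizureTimeCourse":
        sub = self.data[self.data["genotype"] == genotype]
        if sub.empty:
            raise ParameterError(f"no vials for genotype {genotype!r}")
        return SeizureTimeCourse(sub.reset_index(drop=True))

    def fractions(self) -> pd.DataFrame:
        """Long table of per-vial seized fractions at each timepoint."""
        d = self.data.copy()
        d["fraction"] = d["n_seized_cum"] / d["n_total"]
        return d

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "SeizureTimeCourse":
        return cls(pd.read_csv(path))


@dataclass
class SigmoidFitResult:
    t50: float
    log_t50: float
    hill_slope: float
    bottom: float
    top: float
    rss: float
    converged: bool
    extrapolated: bool
    n_points: int

    def __post_init__(self) -> None:
        if self.bottom > self.top + 1e-12:
            raise ParameterError("bottom asymptote must not exceed top")


def sigmoid(
    t: np.ndarray | float,
    t50: float,
    hill_slope: float,
    bottom: float = 0.0,
    top: float = 1.0,
) -> np.ndarray | float:
    """Variable-slope logistic in log10 time; f(T50) = (bottom + top) / 2."""
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        logt = np.where(t > 0, np.log10(np.maximum(t, 1e-300)), -np.inf)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((np.log10(t50) - logt) * hill_slope))


def _initial_t50(t: np.ndarray, frac: np.ndarray, top_guess: float) -> float:
    """First crossing of half the apparent maximum, by linear interpolation
    on the time-averaged fraction curve."""
    order = np.argsort(t)
    tt, ff = t[order], frac[order]
    uniq_t = np.unique(tt)
    mean_f = np.array([ff[tt == u].mean() for u in uniq_t])
    half = top_guess / 2.0
    above = np.nonzero(mean_f >= half)[0]
    if len(above) == 0:
        return float(uniq_t[-1])
    i = above[0]
    if i == 0 or mean_f[i] == mean_f[i - 1]:
        return float(uniq_t[i])
    w = (half - mean_f[i - 1]) / (mean_f[i] - mean_f[i - 1])
    return float(uniq_t[i - 1] + w * (uniq_t[i] - uniq_t[i - 1]))


def fit_sigmoid(
    tc: SeizureTimeCourse,
    genotype: str | None = None,
    top: float | None = None,
    bottom: float = 0.0,
) -> SigmoidFitResult:
    """Least-squares fit of the variable-slope sigmoid to pooled vial fractions.

    All vials of the genotype (or of the whole table when it holds a single
    genotype) contribute their per-timepoint fractions as data points.
    ``top=None`` (default) frees the top asymptote in (0, 1]; pass a number
    to fix it.  The bottom asymptote is fixed (default 0).  Initialization is
    deterministic: T50 at the first crossing of half-maximum by linear
    interpolation, Hill slope 1.

    Requires >= 4 distinct timepoints; all-zero or saturated-constant
    responses raise :class:`DataError`.  ``extrapolated`` is set when the
    pooled fraction never reaches 0.5, so T50 lies beyond the data.
    """
    if genotype is not None:
        tc = tc.for_genotype(genotype)
    elif len(tc.genotypes) > 1:
        raise ParameterError(
            "table holds several genotypes; pass genotype= to select one"
        )
    frame = tc.fractions()
    t = frame["time_min"].to_numpy(dtype=float)
    y = frame["fraction"].to_numpy(dtype=float)
    if np.any(t <= 0):
        raise DataError("timepoints must be positive (log-time model)")
    if len(np.unique(t)) < 4:
        raise DataError("need at least 4 distinct timepoints to fit a sigmoid")
    if np.allclose(y, 0):
        raise DataError(
            "no fly ever seized: T50 is undefined; extend the assay window"
        )
    if np.allclose(y, y[0]) and y[0] > 0:
        raise DataError("response is constant; the sigmoid is unidentifiable")

    fixed_top = top is not None
    top_guess = top if fixed_top else max(float(y.max()), 1e-6)
    t50_init = _initial_t50(t, y, top_guess)
    log_t50_init = np.log10(np.clip(t50_init, t.min() / 10, t.max() * 10))

    lo_t, hi_t = np.log10(t.min()) - 2.0, np.log10(t.max()) + 2.0
    if fixed_top:
        x0 = np.array([log_t50_init, 1.0])
        lower = np.array([lo_t, 1e-3])
        upper = np.array([hi_t, 100.0])
    else:
        x0 = np.array([log_t50_init, 1.0, np.clip(top_guess, 1e-6, 1.0)])
        lower = np.array([lo_t, 1e-3, 1e-6])
        upper = np.array([hi_t, 100.0, 1.0])
    x0 = np.clip(x0, lower, upper)

    def residuals(x: np.ndarray) -> np.ndarray:
        t50_x = 10.0 ** x[0]
        top_x = top if fixed_top else x[2]
        return sigmoid(t, t50_x, x[1], bottom, top_x) - y

    sol = least_squares(
        residuals, x0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    rss = float(np.sum(sol.fun**2))
    flat_rss = float(np.sum((y - y.mean()) ** 2))
    converged = bool(sol.success) and rss <= flat_rss + 1e-12
    top_fit = float(top if fixed_top else sol.x[2])
    pooled_max = float(
        frame.groupby("time_min")["fraction"].mean().max()
    )
    return SigmoidFitResult(
        t50=float(10.0 ** sol.x[0]),
        log_t50=float(sol.x[0]),
        hill_slope=float(sol.x[1]),
        bottom=float(bottom),
        top=top_fit,
        rss=rss,
        converged=converged,
        extrapolated=pooled_max < 0.5,
        n_points=len(y),
    )


def normalize_t50(fit: SigmoidFitResult, control_fit: SigmoidFitResult) -> float:
    """T50 ratio of a genotype to its same-day background control.

    > 1 means the genotype seizes later than the control (protected),
    < 1 earlier (susceptible).  Both fits must have converged.
    """
    if not (fit.converged and control_fit.converged):
        raise DataError("normalization requires converged fits on both sides")
    return fit.t50 / control_fit.t50


@dataclass
class AssaySummary:
    """Per-vial seized fractions of the mechanical assay, grouped by genotype."""

    fractions: pd.DataFrame  # columns vial_id, genotype, fraction

    def by_genotype(self) -> dict[str, np.ndarray]:
        return {
            g: grp["fraction"].to_numpy()
            for g, grp in self.fractions.groupby("genotype", sort=False)
        }


def summarize_bang_assay(table: pd.DataFrame) -> AssaySummary:
    """Fraction seized per vial from columns vial_id, genotype, n_total, n_seized."""
    required = {"vial_id", "genotype", "n_total", "n_seized"}
    if not required.issubset(table.columns):
        raise FormatError(f"bang-assay table needs columns {sorted(required)}")
    if (table["n_seized"] < 0).any() or (table["n_total"] < 1).any():
        raise DataError("counts must be non-negative and vials non-empty")
    if (table["n_seized"] > table["n_total"]).any():
        raise DataError("seized count exceeds flies in vial")
    out = table[["vial_id", "genotype"]].copy()
    out["fraction"] = table["n_seized"] / table["n_total"]
    return AssaySummary(out)
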