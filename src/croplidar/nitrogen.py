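"""Logistic nitrogen dose-response model for crop height.

Applied nitrogen accelerates growth but the effect saturates; per-parcel
mean canopy height h as a function of cumulative applied N (kg N/ha) is
modelled by the three-parameter logistic

    h(N) = c1 / (1 + exp(-c0 * N)) + hmin

where ``c0`` (per kg N/ha) sets the steepness, ``c1`` (m) the total rise
of the logistic term, and ``hmin`` (m) a height offset.  At N = 0 the
curve sits at ``hmin + c1/2`` and it saturates towards ``hmin + c1``.

The module follows the statsmodels convention: build a
:class:`NitrogenResponse` model from data (or a DataFrame), call
``fit()``, and read estimates, uncertainties and a ``summary()`` table
off the returned :class:`NitrogenResponseResults`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "NResponseParams",
    "TreatmentRecord",
    "logistic_height",
    "saturation_dose",
    "NitrogenResponse",
    "NitrogenResponseResults",
    "FitError",
]


class FitError(RuntimeError):
    """Nonlinear fit failed to converge or the data cannot identify it."""


@dataclass(frozen=True)
class NResponseParams:
    """Parameters of the logistic height response."""

    c0: float  # steepness, per kg N/ha
    c1: float  # logistic rise, m
    hmin: float  # height offset, m

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.c0, self.c1, self.hmin)):
            raise ValueError("parameters must be finite")
        if self.c1 < 0 or self.hmin < 0:
            raise ValueError("c1 and hmin must be non-negative")


@dataclass(frozen=True)
class TreatmentRecord:
    """One parcel's cumulative N dose and observed mean height."""

    parcel_id: str
    n_applied: float  # kg N/ha, cumulative to the recording date
    mean_height: float  # m

    def __post_init__(self) -> None:
        if self.n_applied < 0:
            raise ValueError("applied nitrogen must be non-negative")
        if not self.mean_height > 0:
            raise ValueError("observed height must be positive")


def logistic_height(n_applied, params: NResponseParams):
    """Evaluate h(N) = c1 / (1 + exp(-c0 N)) + hmin."""
    n = np.asarray(n_applied, dtype=float)
    out = params.c1 / (1.0 + np.exp(-params.c0 * n)) + params.hmin
    return float(out) if np.isscalar(n_applied) else out


def saturation_dose(params: NResponseParams, fraction: float = 0.95) -> float:
    """Dose at which the rising half of the logistic has covered ``fraction``
    of its remaining range.

    For N >= 0 the logistic term runs from c1/2 towards c1; solving
    h(N) = hmin + c1 (0.5 + fraction/2) gives the closed form
    N = ln((1 + fraction) / (1 - fraction)) / c0.  Past this dose, extra
    nitrogen buys less than (1 - fraction) of the attainable height gain.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be strictly between 0 and 1")
    if params.c0 <= 0:
        raise ValueError("saturation dose requires a rising curve (c0 > 0)")
    return math.log((1.0 + fraction) / (1.0 - fraction)) / params.c0


class NitrogenResponse:
    """Logistic nitrogen-response model bound to per-parcel observations.

    Parameters
    ----------
    n_applied : array-like
        Cumulative applied nitrogen per parcel, kg N/ha.
    height : array-like
        Observed mean canopy height per parcel, m.
    parcel_ids : sequence of str, optional
        Labels carried through to results and bootstrap resampling.
    """

    #: multi-start grid for the steepness parameter; logistic fits are
    #: initialisation-sensitive, so the best of these starts is kept
    C0_STARTS = (0.005, 0.01, 0.05, 0.1)

    def __init__(self, n_applied, height, parcel_ids=None):
        self.n_applied = np.asarray(n_applied, dtype=float).reshape(-1)
        self.height = np.asarray(height, dtype=float).reshape(-1)
        if self.n_applied.shape != self.height.shape:
            raise ValueError("n_applied and height must have equal length")
        if self.n_applied.size < 3 or np.unique(self.n_applied).size < 3:
            raise FitError("need >= 3 records with >= 3 distinct N doses to identify the model")
        if np.any(self.n_applied < 0):
            raise ValueError("applied nitrogen must be non-negative")
        if parcel_ids is None:
            parcel_ids = [str(i) for i in range(self.n_applied.size)]
        self.parcel_ids = list(parcel_ids)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        dose_col: str = "n_applied_kg_ha",
        height_col: str = "mean_height_m",
        id_col: str = "parcel_id",
    ) -> "NitrogenResponse":
        ids = df[id_col].astype(str).tolist() if id_col in df.columns else None
        return cls(df[dose_col].to_numpy(), df[height_col].to_numpy(), ids)

    @classmethod
    def from_records(cls, records: list[TreatmentRecord]) -> "NitrogenResponse":
        return cls(
            [r.n_applied for r in records],
            [r.mean_height for r in records],
            [r.parcel_id for r in records],
        )

    # -- fitting ---------------------------------------------------------

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        c0, c1, hmin = theta
        return c1 / (1.0 + np.exp(-c0 * self.n_applied)) + hmin - self.height

    def _fit_once(self, theta0: np.ndarray):
        return least_squares(
            self._residuals,
            theta0,
            bounds=([-np.inf, 0.0, 0.0], [np.inf, np.inf, np.inf]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )

    def fit(self, bootstrap: int = 0, seed: int | None = None) -> "NitrogenResponseResults":
        """Least-squares fit of (c0, c1, hmin).

        Runs a small multi-start over ``c0`` with ``hmin`` initialised at
        the minimum observed height and ``c1`` at the observed range,
        keeping the start with the lowest residual sum of squares.  With
        ``bootstrap > 0``, parcel-level resampling provides standard
        errors (seeded for reproducibility).
        """
        hmin0 = float(self.height.min())
        c10 = max(float(self.height.max() - self.height.min()), 1e-6)
        best = None
        for c0_start in self.C0_STARTS:
            sol = self._fit_once(np.array([c0_start, c10, hmin0]))
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise FitError("all multi-start fits failed to converge")
        params = NResponseParams(*[float(v) for v in best.x])
        rss = float(2.0 * best.cost)

        height_range = float(self.height.max() - self.height.min())
        flat = height_range < 1e-12
        if flat:
            warnings.warn(
                "observed heights are constant across doses; c0 is not identified "
                "and the fitted curve is flat within the data range",
                RuntimeWarning,
                stacklevel=2,
            )

        bse = bparams = None
        if bootstrap > 0:
            rng = np.random.default_rng(seed)
            n = self.n_applied.size
            draws = []
            for _ in range(bootstrap):
                idx = rng.integers(0, n, size=n)
                if np.unique(self.n_applied[idx]).size < 3:
                    continue
                res = least_squares(
                    lambda th: NitrogenResponse(
                        self.n_applied[idx], self.height[idx]
                    )._residuals(th),
                    best.x,
                    bounds=([-np.inf, 0.0, 0.0], [np.inf, np.inf, np.inf]),
                )
                if res.success:
                    draws.append(res.x)
            if len(draws) < 2:
                raise FitError("bootstrap produced too few successful refits")
            bparams = np.asarray(draws)
            bse = bparams.std(axis=0, ddof=1)
        return NitrogenResponseResults(self, params, rss, flat, bse, bparams)


class NitrogenResponseResults:
    """Fitted nitrogen-response curve with uncertainties and diagnostics."""

    def __init__(self, model, params, rss, flat=False, bse=None, bootstrap_params=None):
        self.model = model
        self.params = params
        self.rss = rss
        self.nobs = model.n_applied.size
        self.flat = flat
        self.bse = bse  # (3,) bootstrap standard errors, or None
        self.bootstrap_params = bootstrap_params

    def predict(self, n_applied):
        return logistic_height(n_applied, self.params)

    def saturation_dose(self, fraction: float = 0.95) -> float:
        return saturation_dose(self.params, fraction)

    @property
    def resid(self) -> np.ndarray:
        return self.model.height - self.predict(self.model.n_applied)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Logistic Nitrogen Response Results",
            "=" * 58,
            f"{'No. observations:':<28}{self.nobs:>10d}",
            f"{'Residual sum of squares:':<28}{self.rss:>10.6g}",
            f"{'Residual std (m):':<28}{math.sqrt(self.rss / max(self.nobs - 3, 1)):>10.4g}",
            "-" * 58,
            f"{'param':<8}{'estimate':>14}{'boot. std err':>16}",
        ]
        names = ("c0", "c1", "hmin")
        for i, (name, val) in enumerate(zip(names, (p.c0, p.c1, p.hmin))):
            se = f"{self.bse[i]:>16.4g}" if self.bse is not None else f"{'--':>16}"
            lines.append(f"{name:<8}{val:>14.6g}{se}")
        lines.append("-" * 58)
        lines.append(f"{'Height at N=0 (m):':<28}{p.hmin + p.c1 / 2:>10.4g}")
        lines.append(f"{'Asymptotic height (m):':<28}{p.hmin + p.c1:>10.4g}")
        if p.c0 > 0 and not self.flat:
            lines.append(f"{'95% saturation dose (kgN/ha):':<29}{self.saturation_dose(0.95):>9.4g}")
        if self.flat:
            lines.append("WARNING: constant heights; steepness c0 is not identified")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter the observations with the fitted curve overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        ax.scatter(m.n_applied, m.height, s=12, label="parcels")
        grid = np.linspace(0.0, max(m.n_applied.max(), 1.0), 200)
        ax.plot(grid, self.predict(grid), color="C1", label="logistic fit")
        ax.set_xlabel("applied nitrogen (kg N/ha)")
        ax.set_ylabel("mean crop height (m)")
        ax.legend()
        return ax
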