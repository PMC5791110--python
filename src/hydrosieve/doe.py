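"""Absorption-kinetics statistics: 2² + center-point factorial design,
two-factor-interaction regression, standardized effects, response surface,
and the absorbance-based absorption percentage.

The model for the pesticide retention percentage is

    retention% = b0 + b1·A + b2·B + b3·A·B + ε

with A the coded contact time and B the coded hydrogel mass (both scaled
to [−1, 1]).  :class:`FactorialModel` is built from a design and
``fit()`` returns a :class:`FactorialResults` carrying the coefficients,
their standard errors, t statistics against the Student-t critical value
(the Pareto-chart line), R² on the percent scale, and a ``summary()``
table.  The reference seven-run design (four factorial corners plus three
center points) ships as package data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import ArgumentError, HydrosieveError

TERMS = ("Intercept", "A", "B", "AB")


class SingularDesignError(HydrosieveError):
    """Design matrix [1, A, B, AB] is rank deficient."""


class UndefinedRSquaredError(HydrosieveError):
    """Response has zero variance; R² undefined."""


class DegreesOfFreedomError(HydrosieveError):
    """No residual degrees of freedom for inference."""


# ---------------------------------------------------------------------
# Coding
# ---------------------------------------------------------------------

def code_levels(x, center: float, half_range: float):
    """Map a natural factor value onto the coded scale: (x − c) / h."""
    if half_range <= 0:
        raise ArgumentError("half_range must be positive")
    return (np.asarray(x, float) - center) / half_range


def decode_levels(coded, center: float, half_range: float):
    """Exact inverse of :func:`code_levels`."""
    if half_range <= 0:
        raise ArgumentError("half_range must be positive")
    return center + half_range * np.asarray(coded, float)


def recover_coding(x, coded) -> tuple[float, float]:
    """Least-squares (center, half_range) from printed (value, code) pairs."""
    x = np.asarray(x, float)
    coded = np.asarray(coded, float)
    A = np.column_stack([np.ones_like(coded), coded])
    (center, half_range), *_ = np.linalg.lstsq(A, x, rcond=None)
    return float(center), float(half_range)


def absorption_percent(a0: float, a: float) -> float:
    """Percent absorbance drop, 100·(A₀ − A)/A₀."""
    if a0 <= 0:
        raise ArgumentError("initial absorbance must be positive")
    return (a0 - a) / a0 * 100.0


@dataclass(frozen=True)
class AbsorptionMeasurement:
    """One spectrophotometric absorption reading (λ in nm)."""

    a0: float
    a: float
    wavelength: float = 280.0

    def __post_init__(self):
        if self.a0 <= 0:
            raise ArgumentError("initial absorbance must be positive")
        if self.a < 0:
            raise ArgumentError("final absorbance cannot be negative")

    @property
    def percent(self) -> float:
        return absorption_percent(self.a0, self.a)


# ---------------------------------------------------------------------
# Design container
# ---------------------------------------------------------------------

@dataclass
class FactorialDesign:
    """Two-factor design runs with coded levels and a percent response.

    ``runs`` columns: coded_A, coded_B, response (plus optional natural
    time_min / mass_mg columns, kept for provenance).
    """

    runs: pd.DataFrame
    factor_names: tuple[str, str] = ("time", "mass")

    def __post_init__(self):
        need = {"coded_A", "coded_B", "response"}
        missing = need - set(self.runs.columns)
        if missing:
            raise ArgumentError(f"design is missing columns {sorted(missing)}")
        coded = self.runs[["coded_A", "coded_B"]].to_numpy()
        if (np.abs(coded) > 1.001).any():
            raise ArgumentError("coded levels must lie in [-1.001, 1.001]")
        resp = self.runs["response"].to_numpy()
        if ((resp < 0) | (resp > 100)).any():
            raise ArgumentError("responses must be percentages in [0, 100]")
        if len(self.runs) < 5:
            raise ArgumentError("need at least p+1 = 5 runs for the 4-parameter fit")

    def __len__(self) -> int:
        return len(self.runs)

    @property
    def exog(self) -> np.ndarray:
        a = self.runs["coded_A"].to_numpy(float)
        b = self.runs["coded_B"].to_numpy(float)
        return np.column_stack([np.ones_like(a), a, b, a * b])

    @property
    def endog(self) -> np.ndarray:
        return self.runs["response"].to_numpy(float)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str = "response") -> "FactorialDesign":
        df = df.rename(columns={response: "response"})
        return cls(runs=df.reset_index(drop=True))


def load_reference_design() -> FactorialDesign:
    """The seven-run retention design shipped with the package (four
    factorial corners + three replicated center points; printed coded
    levels used verbatim, including the center points' small nonzero B
    codes)."""
    with resources.files("hydrosieve.data").joinpath("factorial_runs.csv").open() as fh:
        df = pd.read_csv(fh)
    return FactorialDesign.from_dataframe(df, response="retention_pct")


# ---------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------

class FactorialModel:
    """OLS model ``response ~ A + B + A:B`` over a :class:`FactorialDesign`."""

    def __init__(self, design: FactorialDesign):
        self.design = design

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str = "response"):
        return cls(FactorialDesign.from_dataframe(df, response=response))

    def fit(self) -> "FactorialResults":
        X = self.design.exog
        y = self.design.endog
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise SingularDesignError("design matrix [1, A, B, AB] is rank deficient")
        if np.ptp(y) == 0.0:
            raise UndefinedRSquaredError("response is constant; R² undefined")
        res = sm.OLS(y, X).fit()
        return FactorialResults(self, res)


class FactorialResults:
    """Fitted coefficients, uncertainties and diagnostics."""

    def __init__(self, model: FactorialModel, sm_results):
        self.model = model
        self._res = sm_results
        self.params = pd.Series(sm_results.params, index=TERMS)
        self.bse = pd.Series(sm_results.bse, index=TERMS)
        self.tvalues = pd.Series(sm_results.tvalues, index=TERMS)
        self.df_resid = int(sm_results.df_resid)
        self.resid = np.asarray(sm_results.resid)

    @property
    def r_squared(self) -> float:
        """Coefficient of determination, percent scale (0-100)."""
        return float(100.0 * self._res.rsquared)

    def critical_t(self, alpha: float = 0.05) -> float:
        """Two-sided Student-t critical value at 1−alpha confidence (the
        Pareto chart's reference line)."""
        if self.df_resid < 1:
            raise DegreesOfFreedomError("no residual degrees of freedom")
        return float(stats.t.ppf(1.0 - alpha / 2.0, self.df_resid))

    def standardized_effects(self, alpha: float = 0.05) -> pd.DataFrame:
        """|t| per effect (A, B, AB) with significance flags, sorted for a
        Pareto chart."""
        tcrit = self.critical_t(alpha)
        rows = []
        for term in ("A", "B", "AB"):
            t = float(self.tvalues[term])
            rows.append({"term": term, "coefficient": float(self.params[term]),
                         "t": t, "abs_t": abs(t),
                         "significant": abs(t) >= tcrit})
        df = pd.DataFrame(rows).sort_values("abs_t", ascending=False).reset_index(drop=True)
        df.attrs["critical_t"] = tcrit
        return df

    def predict(self, coded_a, coded_b):
        a = np.asarray(coded_a, float)
        b = np.asarray(coded_b, float)
        p = self.params
        return p["Intercept"] + p["A"] * a + p["B"] * b + p["AB"] * a * b

    def response_surface(self, n_grid: int = 41):
        """Predicted retention on a coded [−1, 1]² grid.

        Returns (A_grid, B_grid, surface, argmax) where argmax is the
        (coded_A, coded_B, value) of the grid maximum.
        """
        if n_grid < 2:
            raise ArgumentError("grid must have at least 2 points per axis")
        g = np.linspace(-1.0, 1.0, n_grid)
        A, B = np.meshgrid(g, g, indexing="ij")
        S = self.predict(A, B)
        k = np.unravel_index(np.argmax(S), S.shape)
        return A, B, S, (float(A[k]), float(B[k]), float(S[k]))

    def summary(self) -> str:
        lines = [
            "Factorial interaction model: response = b0 + b1*A + b2*B + b3*A*B",
            f"runs: {len(self.model.design)}   df_resid: {self.df_resid}   "
            f"R^2: {self.r_squared:.2f}%",
            "",
            f"{'term':<10}{'coef':>10}{'std err':>10}{'t':>9}",
        ]
        for term in TERMS:
            lines.append(
                f"{term:<10}{self.params[term]:>10.3f}{self.bse[term]:>10.3f}"
                f"{self.tvalues[term]:>9.3f}"
            )
        try:
            tcrit = self.critical_t()
            eff = self.standardized_effects()
            sig = [r.term for r in eff.itertuples() if r.significant]
            lines += ["", f"critical |t| (95%): {tcrit:.3f}   "
                          f"significant terms: {', '.join(sig) if sig else 'none'}"]
        except DegreesOfFreedomError:
            pass
        return "\n".join(lines)


def fit_interaction_model(design: FactorialDesign) -> FactorialResults:
    """Convenience wrapper: build the model and fit it."""
    return FactorialModel(design).fit()
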