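"""Nonlinear least-squares fitting of growth-rate models and model selection.

The estimation problem: given per-individual growth increments
``(l_ref_i, gr_i)``, find ``(A1, r)`` minimising

    sum_i [gr_i - GR(family, l_ref_i; A1, r)]^2

for each of the three model families, then select the family with the lowest
mean squared residual (MSR = SSres/(n-2)); the coefficient of determination
R^2 is reported alongside and breaks exact MSR ties.

The interface follows the statsmodels convention: build a
:class:`GrowthRateModel` from data, call :meth:`~GrowthRateModel.fit`, and
read estimates, standard errors and diagnostics off the returned
:class:`GrowthRateResults` (``summary()`` renders a report table).

Every family is linear in a transformed parameterisation (e.g. the von
Bertalanffy rate is ``r*A1 - r*L``), so exact least-squares start values are
available in closed form; the nonlinear optimiser then refines in the
``(A1, r)`` parameterisation, whose curvature supplies the standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import NonIdentifiableError
from .models import FAMILY_ORDER, GrowthParams, ModelFamily, gr_rate

__all__ = [
    "GrowthRateModel",
    "GrowthRateResults",
    "ModelScore",
    "ModelComparison",
    "fit_model",
    "fit_all_families",
    "goodness",
    "linear_start_values",
    "compare_models",
]


def goodness(observed, predicted, n_params: int = 2) -> tuple[float, float]:
    """Mean squared residual and R^2 of predictions against observations.

    ``msr = SSres/(n - n_params)`` (residual degrees of freedom) and
    ``r2 = 1 - SSres/SStot`` about the observed mean.  Raises if the observed
    values have zero variance (R^2 undefined).
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    n = observed.size
    if n <= n_params:
        raise ValueError(f"need more than {n_params} observations, got {n}")
    if np.ptp(observed) == 0.0:
        raise NonIdentifiableError("observed values have zero variance; R^2 undefined")
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    return ss_res / (n - n_params), 1.0 - ss_res / ss_tot


def linear_start_values(family: ModelFamily, l, gr) -> tuple[float, float] | None:
    """Exact least-squares ``(a1, r)`` via the family's linear reparameterisation.

    von Bertalanffy:    GR = r*A1 - r*L          (intercept + slope in L)
    logistic-by-length: GR = r*L - (r/A1)*L^2    (no intercept, L and L^2)
    logistic-by-weight: GR = (r/3)*L - (r/(3*A1^3))*L^4

    Returns None when the unconstrained linear solution implies a
    non-positive ``a1`` or ``r`` (no admissible back-transformation).
    """
    l = np.asarray(l, dtype=float)
    gr = np.asarray(gr, dtype=float)
    family = ModelFamily(family)
    if family is ModelFamily.VON_BERTALANFFY:
        design = np.column_stack([np.ones_like(l), l])
    elif family is ModelFamily.LOGISTIC_BY_LENGTH:
        design = np.column_stack([l, l**2])
    else:
        design = np.column_stack([l, l**4])
    beta, *_ = np.linalg.lstsq(design, gr, rcond=None)
    b0, b1 = beta
    if family is ModelFamily.VON_BERTALANFFY:
        r = -b1
        if r <= 0 or b0 <= 0:
            return None
        return b0 / r, r
    if family is ModelFamily.LOGISTIC_BY_LENGTH:
        r = b0
        if r <= 0 or b1 >= 0:
            return None
        return -b0 / b1, r
    r = 3.0 * b0
    if r <= 0 or b1 >= 0:
        return None
    return float(np.cbrt(-b0 / b1)), r


class GrowthRateModel:
    """Growth-rate regression model for one family.

    Parameters
    ----------
    gr
        Observed growth rates, mm/day.
    l_ref
        Reference lengths (model predictor), mm.
    family
        Model family to fit.

    Examples
    --------
    >>> model = GrowthRateModel.from_intervals(intervals, "logistic_by_length")
    >>> res = model.fit()
    >>> res.params.a1, res.params.r, res.msr, res.r2   # doctest: +SKIP
    """

    def __init__(self, gr, l_ref, family: ModelFamily = ModelFamily.VON_BERTALANFFY):
        self.gr = np.asarray(gr, dtype=float)
        self.l_ref = np.asarray(l_ref, dtype=float)
        self.family = ModelFamily(family)
        if self.gr.shape != self.l_ref.shape or self.gr.ndim != 1:
            raise ValueError("gr and l_ref must be equal-length 1-d arrays")
        if not (np.isfinite(self.gr).all() and np.isfinite(self.l_ref).all()):
            raise ValueError("gr and l_ref must be finite")
        if self.gr.size < 3:
            raise ValueError("need at least 3 intervals to fit 2 parameters")
        if np.ptp(self.l_ref) == 0.0:
            raise NonIdentifiableError(
                "all reference lengths are equal; (a1, r) are not identifiable"
            )

    @classmethod
    def from_intervals(cls, intervals: pd.DataFrame, family: ModelFamily):
        """Build from an interval table (columns gr_mm_per_day, l_ref_mm)."""
        return cls(
            intervals["gr_mm_per_day"].to_numpy(),
            intervals["l_ref_mm"].to_numpy(),
            family,
        )

    @property
    def nobs(self) -> int:
        return self.gr.size

    def predict(self, params, l=None):
        """Predicted growth rate at ``l`` (defaults to the model's lengths)."""
        return gr_rate(self.family, self.l_ref if l is None else l, params)

    def _residuals(self, theta):
        a1, r = theta
        return gr_rate(self.family, self.l_ref, (a1, r)) - self.gr

    def fit(
        self,
        start_params: GrowthParams | tuple[float, float] | None = None,
        tol: float = 1e-12,
        max_nfev: int = 10_000,
    ) -> "GrowthRateResults":
        """Fit by nonlinear least squares; never raises on non-convergence.

        Start values come from the exact linear back-transformation when it
        is admissible, otherwise ``a1 = 1.1 * max(l_ref)``, ``r = 0.005``.
        The ``converged`` flag on the result is honest: inspect it.
        """
        if start_params is None:
            x0 = linear_start_values(self.family, self.l_ref, self.gr)
            if x0 is None:
                x0 = (1.1 * float(self.l_ref.max()), 0.005)
        elif isinstance(start_params, GrowthParams):
            x0 = (start_params.a1, start_params.r)
        else:
            x0 = tuple(start_params)
        res = least_squares(
            self._residuals,
            x0=np.asarray(x0, dtype=float),
            bounds=([1e-8, 1e-12], [np.inf, np.inf]),
            method="trf",
            xtol=tol,
            ftol=tol,
            gtol=tol,
            max_nfev=max_nfev,
            x_scale=[max(1.0, float(np.mean(self.l_ref))), 1e-3],
        )
        a1_hat, r_hat = res.x
        ss_res = float(2.0 * res.cost)
        n = self.nobs
        msr = ss_res / (n - 2)
        ss_tot = float(np.sum((self.gr - self.gr.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        se_a1, se_r = self._standard_errors(res.jac, msr)
        params = GrowthParams(a1=a1_hat, r=r_hat, se_a1=se_a1, se_r=se_r)
        return GrowthRateResults(
            model=self,
            family=self.family,
            params=params,
            n=n,
            msr=msr,
            r2=r2,
            converged=bool(res.success),
            residuals=-res.fun,  # observed - predicted
        )

    @staticmethod
    def _standard_errors(jac, msr) -> tuple[float, float]:
        # curvature of the least-squares surface: cov = msr * (J'J)^-1
        jtj = jac.T @ jac
        try:
            cov = msr * np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            cov = msr * np.linalg.pinv(jtj)
            warnings.warn("singular curvature; standard errors from pseudo-inverse")
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        return float(se[0]), float(se[1])


@dataclass
class GrowthRateResults:
    """Fit of one family: estimates, uncertainties and fit diagnostics."""

    model: GrowthRateModel
    family: ModelFamily
    params: GrowthParams
    n: int
    msr: float
    r2: float
    converged: bool
    residuals: np.ndarray

    @property
    def a1(self) -> float:
        return self.params.a1

    @property
    def r(self) -> float:
        return self.params.r

    @property
    def bse(self) -> tuple[float, float]:
        """Standard errors of (a1, r)."""
        return self.params.se_a1, self.params.se_r

    def predict(self, l=None):
        return self.model.predict(self.params, l)

    def summary(self) -> str:
        lines = [
            "Growth-rate model fit",
            "=" * 46,
            f"family:     {self.family.value}",
            f"n:          {self.n}",
            f"MSR:        {self.msr:.6g} (mm/day)^2",
            f"R^2:        {self.r2:.4f}",
            f"converged:  {self.converged}",
            "-" * 46,
            f"A1 (mm):    {self.a1:.4f} +/- {self.params.se_a1:.4f}",
            f"r (1/day):  {self.r:.6f} +/- {self.params.se_r:.6f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def to_row(self, sex: str | None = None) -> dict:
        """Flatten to the report-table layout (one CSV row)."""
        row = {
            "sex": sex,
            "family": self.family.value,
            "msr": self.msr,
            "r2": self.r2,
            "a1_mm": self.a1,
            "se_a1_mm": self.params.se_a1,
            "r_per_day": self.r,
            "se_r_per_day": self.params.se_r,
            "n": self.n,
        }
        if sex is None:
            row.pop("sex")
        return row


def fit_model(
    intervals: pd.DataFrame,
    family: ModelFamily,
    start_params=None,
) -> GrowthRateResults:
    """Convenience wrapper: build and fit a model from an interval table."""
    return GrowthRateModel.from_intervals(intervals, family).fit(start_params)


def fit_all_families(intervals: pd.DataFrame) -> list[GrowthRateResults]:
    """Fit every family to the same intervals, in canonical family order."""
    return [fit_model(intervals, fam) for fam in FAMILY_ORDER]


@dataclass(frozen=True)
class ModelScore:
    """Lightweight (family, msr, r2) triple for score-only model comparison."""

    family: ModelFamily
    msr: float
    r2: float
    converged: bool = True


@dataclass
class ModelComparison:
    """Outcome of the MSR-first selection rule over per-family fits."""

    fits: list  # ordered best-to-worst
    selected: ModelFamily
    msr_rank: list[ModelFamily] = field(default_factory=list)
    r2_rank: list[ModelFamily] = field(default_factory=list)
    criteria_conflict: bool = False
    warning: str | None = None

    @property
    def best(self):
        return self.fits[0]


def compare_models(fits) -> ModelComparison:
    """Select the best-fitting family: lowest MSR, highest R^2 on ties.

    ``fits`` holds one fit (or :class:`ModelScore`) per family.  When MSR and
    R^2 rank different families best, MSR wins and the conflict is recorded
    on the returned comparison; any unconverged member attaches a warning.
    """
    fits = list(fits)
    families = [ModelFamily(f.family) for f in fits]
    if len(set(families)) != len(fits):
        raise ValueError("duplicate family in comparison")
    order_idx = {fam: i for i, fam in enumerate(FAMILY_ORDER)}

    def sort_key(f):
        return (f.msr, -f.r2, order_idx[ModelFamily(f.family)])

    ranked = sorted(fits, key=sort_key)
    msr_rank = [ModelFamily(f.family) for f in ranked]
    r2_rank = [
        ModelFamily(f.family)
        for f in sorted(fits, key=lambda f: (-f.r2, f.msr, order_idx[ModelFamily(f.family)]))
    ]
    conflict = msr_rank[0] != r2_rank[0]
    warning = None
    unconverged = [f.family for f in fits if not getattr(f, "converged", True)]
    if unconverged:
        warning = "unconverged fit(s): " + ", ".join(str(ModelFamily(f)) for f in unconverged)
        warnings.warn(warning)
    return ModelComparison(
        fits=ranked,
        selected=msr_rank[0],
        msr_rank=msr_rank,
        r2_rank=r2_rank,
        criteria_conflict=conflict,
        warning=warning,
    )
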