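"""The three classical growth-rate models in differential and integrated form.

Each family relates the instantaneous growth rate ``GR`` (mm/day) to current
body length ``L`` (snout--vent length, mm) through an asymptotic size ``A1``
and a characteristic growth parameter ``r`` (per day):

===================  =============================  ==============================
family               differential form              integrated solution
===================  =============================  ==============================
von Bertalanffy      GR = A1*r*(1 - L/A1)           L(t) = A1*(1 - b*exp(-r*t))
logistic-by-length   GR = L*r*(1 - L/A1)            L(t) = A1/(1 + b*exp(-r*t))
logistic-by-weight   GR = (r*L/3)*(1 - L^3/A1^3)    L(t) = [A1^3/(1 + b*exp(-r*t))]^(1/3)
===================  =============================  ==============================

The shape constant ``b`` anchors the curve at hatchling size ``L0`` at age
zero: it is ``1 - L0/A1``, ``A1/L0 - 1`` and ``A1^3/L0^3 - 1`` for the three
families respectively.  Growth under the von Bertalanffy law decelerates
monotonically with length, whereas both logistic laws are sigmoid with an
interior maximum growth rate — at ``A1/2`` for logistic-by-length and at
``A1 * 4**(-1/3)`` (a larger length) for logistic-by-weight.

All solutions here are evaluated in closed form; numerical integration is
reserved for test oracles.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import UnreachableSizeError

__all__ = [
    "ModelFamily",
    "GrowthParams",
    "GrowthCurve",
    "gr_rate",
    "b_param",
    "length_at_age",
    "time_to_length",
    "inflection_length",
]


class ModelFamily(str, enum.Enum):
    """The three growth-model families."""

    VON_BERTALANFFY = "von_bertalanffy"
    LOGISTIC_BY_LENGTH = "logistic_by_length"
    LOGISTIC_BY_WEIGHT = "logistic_by_weight"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# canonical ordering used for deterministic tie-breaking in model selection
FAMILY_ORDER = (
    ModelFamily.VON_BERTALANFFY,
    ModelFamily.LOGISTIC_BY_LENGTH,
    ModelFamily.LOGISTIC_BY_WEIGHT,
)


@dataclass(frozen=True)
class GrowthParams:
    """Asymptotic length ``a1`` (mm) and growth constant ``r`` (per day).

    Standard errors are optional; they are populated by the fitting stage.
    """

    a1: float
    r: float
    se_a1: float | None = None
    se_r: float | None = None

    def __post_init__(self) -> None:
        if not (self.a1 > 0):
            raise ValueError(f"asymptotic length a1 must be positive, got {self.a1}")
        if not (self.r > 0):
            raise ValueError(f"growth parameter r must be positive, got {self.r}")


def _as_params(params) -> tuple[float, float]:
    if isinstance(params, GrowthParams):
        return params.a1, params.r
    a1, r = params
    return float(a1), float(r)


def gr_rate(family: ModelFamily, l, params):
    """Instantaneous growth rate (mm/day) at length ``l`` (mm).

    ``params`` may be a :class:`GrowthParams` or an ``(a1, r)`` pair; ``l``
    may be a scalar or array.  All families return 0 at ``l == a1``.
    """
    a1, r = _as_params(params)
    l = np.asarray(l, dtype=float)
    if np.any(l < 0):
        raise ValueError("length must be non-negative")
    family = ModelFamily(family)
    if family is ModelFamily.VON_BERTALANFFY:
        out = a1 * r * (1.0 - l / a1)
    elif family is ModelFamily.LOGISTIC_BY_LENGTH:
        out = l * r * (1.0 - l / a1)
    else:  # logistic-by-weight
        out = (r * l / 3.0) * (1.0 - l**3 / a1**3)
    return out if out.ndim else float(out)


def b_param(family: ModelFamily, a1: float, l0: float) -> float:
    """Shape constant ``b`` anchoring the integrated curve at ``L(0) = l0``."""
    if not (0 < l0 <= a1):
        raise ValueError(f"need 0 < l0 <= a1, got l0={l0}, a1={a1}")
    family = ModelFamily(family)
    if family is ModelFamily.VON_BERTALANFFY:
        return 1.0 - l0 / a1
    if family is ModelFamily.LOGISTIC_BY_LENGTH:
        return a1 / l0 - 1.0
    return a1**3 / l0**3 - 1.0


def inflection_length(family: ModelFamily, params) -> float | None:
    """Length at which the growth rate is maximal, or None.

    The von Bertalanffy rate decreases monotonically in length, so its
    maximum sits at the smallest observable length rather than at an interior
    inflection; None is returned for that family.
    """
    a1, _ = _as_params(params)
    family = ModelFamily(family)
    if family is ModelFamily.VON_BERTALANFFY:
        return None
    if family is ModelFamily.LOGISTIC_BY_LENGTH:
        return a1 / 2.0
    return a1 * 4.0 ** (-1.0 / 3.0)


@dataclass(frozen=True)
class GrowthCurve:
    """An integrated growth curve anchored at hatchling size ``l0``.

    The shape constant ``b`` is derived from ``(a1, l0)`` at construction and
    is not independently settable.
    """

    family: ModelFamily
    params: GrowthParams
    l0: float
    b: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0 < self.l0 < self.params.a1):
            raise ValueError(
                f"hatchling size l0={self.l0} must lie in (0, a1={self.params.a1})"
            )
        object.__setattr__(self, "family", ModelFamily(self.family))
        object.__setattr__(self, "b", b_param(self.family, self.params.a1, self.l0))

    def length_at_age(self, t):
        """Body length (mm) at age ``t`` days post-hatching (scalar or array)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("age must be non-negative")
        a1, r, b = self.params.a1, self.params.r, self.b
        decay = b * np.exp(-r * t)
        if self.family is ModelFamily.VON_BERTALANFFY:
            out = a1 * (1.0 - decay)
        elif self.family is ModelFamily.LOGISTIC_BY_LENGTH:
            out = a1 / (1.0 + decay)
        else:
            out = (a1**3 / (1.0 + decay)) ** (1.0 / 3.0)
        return out if out.ndim else float(out)

    def time_to_length(self, l_target: float) -> float:
        """Age (days) at which the curve reaches ``l_target`` mm (closed form)."""
        a1, r, b = self.params.a1, self.params.r, self.b
        if l_target >= a1:
            raise UnreachableSizeError(
                f"target length {l_target} mm is at or above the asymptote {a1} mm"
            )
        # tolerate float round-off at the anchor point L(0) = l0
        if l_target < self.l0 * (1.0 - 1e-12):
            raise ValueError(
                f"target length {l_target} mm is below hatchling size {self.l0} mm"
            )
        if self.family is ModelFamily.VON_BERTALANFFY:
            ratio = (1.0 - l_target / a1) / b
        elif self.family is ModelFamily.LOGISTIC_BY_LENGTH:
            ratio = (a1 / l_target - 1.0) / b
        else:
            ratio = (a1**3 / l_target**3 - 1.0) / b
        return -float(np.log(ratio)) / r

    def gr_at_length(self, l):
        """Growth rate of this curve's family at length ``l``."""
        return gr_rate(self.family, l, self.params)

    def to_frame(self, t_max: float, step: float = 1.0):
        """Tabulate the curve as a DataFrame with columns t_days, svl_mm."""
        import pandas as pd

        t = np.arange(0.0, t_max + step / 2, step)
        return pd.DataFrame({"t_days": t, "svl_mm": self.length_at_age(t)})


def length_at_age(curve: GrowthCurve, t):
    """Module-level alias for :meth:`GrowthCurve.length_at_age`."""
    return curve.length_at_age(t)


def time_to_length(curve: GrowthCurve, l_target: float) -> float:
    """Module-level alias for :meth:`GrowthCurve.time_to_length`."""
    return curve.time_to_length(l_target)
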