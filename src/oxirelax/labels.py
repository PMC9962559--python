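"""Chemical oxidation indices and the ordinal oil-quality classification.

Edible-oil oxidation is tracked by two wet-chemistry indices — the
peroxide value PV (primary oxidation products, hydroperoxides, mmol/kg)
and the p-anisidine value p-AV (secondary aldehydes, dimensionless) —
combined into the total oxidation value TOTOX = p-AV + 2*PV, and by the
self-diffusion coefficient D (m^2/s) measured by pulsed-field-gradient
spin echo (PFGSE), which drops as late-stage polymerization raises
viscosity.

Oils are binned into three ordinal classes by D and PV jointly:

    class    D (x 1e-9 m^2/s)     PV (mmol/kg)
    Good     > 0.03               < 20
    Fair     0.02 < D <= 0.03     20 <= PV < 50
    Bad      <= 0.02              >= 50

Bins are half-open so the two criteria each partition their axis; when
they disagree a configurable conflict policy decides.  An alternative
``prose_cutoffs`` preset moves the Good/Fair PV boundary to 30 mmol/kg,
a cutoff sometimes used for non-oxidized linseed oil.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, LabelConflictError


class OxidationClass(enum.IntEnum):
    """Ordinal oxidation level: Good (non-) < Fair (partially) < Bad (highly oxidized)."""

    GOOD = 0
    FAIR = 1
    BAD = 2

    @property
    def label(self) -> str:
        return {0: "Good", 1: "Fair", 2: "Bad"}[int(self)]

    @classmethod
    def from_label(cls, label: str) -> "OxidationClass":
        try:
            return {"good": cls.GOOD, "fair": cls.FAIR, "bad": cls.BAD}[str(label).lower()]
        except KeyError:
            raise InvalidInputError(f"unknown oxidation class label: {label!r}") from None


#: Fixed label ordering used everywhere downstream (classifier output, reports).
CLASS_ORDER: tuple[str, str, str] = ("Good", "Fair", "Bad")


@dataclass(frozen=True)
class ClassBins:
    """Decision boundaries for the (D, PV) -> class rule.

    ``d_good`` / ``d_bad``: D above d_good is Good, at or below d_bad is Bad,
    in between is Fair.  ``pv_good`` / ``pv_bad``: PV below pv_good is Good,
    at or above pv_bad is Bad, in between is Fair.
    """

    d_good: float = 0.03e-9   # m^2/s, exclusive lower edge of Good
    d_bad: float = 0.02e-9    # m^2/s, inclusive upper edge of Bad
    pv_good: float = 20.0     # mmol/kg, exclusive upper edge of Good
    pv_bad: float = 50.0      # mmol/kg, inclusive lower edge of Bad

    def classify_d(self, d: float) -> OxidationClass:
        if d > self.d_good:
            return OxidationClass.GOOD
        if d > self.d_bad:
            return OxidationClass.FAIR
        return OxidationClass.BAD

    def classify_pv(self, pv: float) -> OxidationClass:
        if pv < self.pv_good:
            return OxidationClass.GOOD
        if pv < self.pv_bad:
            return OxidationClass.FAIR
        return OxidationClass.BAD


TABLE_BINS = ClassBins()
#: Alternative preset with the 30 mmol/kg Good/Fair peroxide cutoff.
PROSE_BINS = ClassBins(pv_good=30.0)

_PRESETS = {"table": TABLE_BINS, "prose_cutoffs": PROSE_BINS}


def totox(pv: float, pav: float) -> float:
    """Total oxidation value, ``p-AV + 2*PV``."""
    if pv < 0 or pav < 0:
        raise InvalidInputError("pv and pav must be non-negative")
    return pav + 2.0 * pv


@dataclass(frozen=True)
class ChemAssay:
    """Chemistry panel for one oil sample; ``totox`` is always recomputed."""

    pv: float   # peroxide value, mmol/kg
    pav: float  # p-anisidine value, dimensionless
    d: float    # self-diffusion coefficient, m^2/s

    def __post_init__(self):
        if self.pv < 0 or self.pav < 0:
            raise InvalidInputError("pv and pav must be non-negative")
        if self.d <= 0:
            raise InvalidInputError("d must be positive")

    @property
    def totox(self) -> float:
        return totox(self.pv, self.pav)

    def to_dict(self) -> dict:
        return {"pv_mmol_per_kg": self.pv, "pav": self.pav,
                "totox": self.totox, "d_m2_per_s": self.d}


def classify_oxidation(
    d: float,
    pv: float,
    policy: str = "worst_case",
    bins: ClassBins | str = TABLE_BINS,
) -> OxidationClass:
    """Map (D, PV) to an oxidation class.

    When both criteria land in the same bin the policy is irrelevant.
    Otherwise ``worst_case`` returns the more-oxidized of the two
    single-criterion classes (food-safety conservative), ``d_priority``
    trusts the diffusion criterion, and ``strict`` raises
    :class:`LabelConflictError`.
    """
    if d <= 0:
        raise InvalidInputError("d must be positive")
    if pv < 0:
        raise InvalidInputError("pv must be non-negative")
    if isinstance(bins, str):
        try:
            bins = _PRESETS[bins]
        except KeyError:
            raise InvalidInputError(f"unknown bins preset: {bins!r}") from None
    if policy not in ("worst_case", "d_priority", "strict"):
        raise InvalidInputError(f"unknown policy: {policy!r}")

    d_class = bins.classify_d(d)
    pv_class = bins.classify_pv(pv)
    if d_class == pv_class:
        return d_class
    if policy == "worst_case":
        return max(d_class, pv_class)
    if policy == "d_priority":
        return d_class
    raise LabelConflictError(
        f"diffusion implies {d_class.label}, peroxide value implies {pv_class.label}",
        d_class=d_class, pv_class=pv_class,
    )


@dataclass(frozen=True)
class DiffusionFit:
    """Least-squares Stejskal-Tanner fit of a PFGSE attenuation series.

    ``d`` is the negated slope of ln(S) vs b.  ``in_model`` is False when
    the fitted d is not strictly positive (no attenuation, or noise-
    dominated data), in which case the estimate lies outside the physical
    model and should not be used for classification.
    """

    d: float
    r_squared: float
    residual_sd: float
    in_model: bool
    n_replicates: int = 1


def _fit_single(series: np.ndarray) -> DiffusionFit:
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[1] != 2:
        raise InvalidInputError("attenuation series must be an (n, 2) array of (b, signal)")
    b, s = series[:, 0], series[:, 1]
    if np.unique(b).size < 2:
        raise InvalidInputError("need at least 2 distinct b-values")
    if np.any(s <= 0):
        raise InvalidInputError("all signals must be positive to take logarithms")
    y = np.log(s)
    slope, intercept = np.polyfit(b, y, 1)
    resid = y - (slope * b + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(b.size - 2, 1)
    d = -float(slope)
    in_model = d > 0
    if not in_model:
        warnings.warn("fitted diffusion coefficient is not positive; out of model", stacklevel=3)
    return DiffusionFit(d=d, r_squared=r2, residual_sd=float(np.sqrt(ss_res / dof)),
                        in_model=in_model)


def estimate_d(series) -> DiffusionFit:
    """Estimate the self-diffusion coefficient from PFGSE attenuation data.

    ``series`` is either a single (n, 2) array of ``(b_value, relative
    signal)`` pairs or a list of such arrays (replicate mode, mirroring
    instrument practice of averaging repeated measurements).  In replicate
    mode the reported ``d`` is the mean of the per-replicate estimates.
    """
    if isinstance(series, (list, tuple)):
        if len(series) == 0:
            raise InvalidInputError("replicate list must be non-empty")
        fits = [_fit_single(s) for s in series]
        d = float(np.mean([f.d for f in fits]))
        return DiffusionFit(
            d=d,
            r_squared=float(np.mean([f.r_squared for f in fits])),
            residual_sd=float(np.mean([f.residual_sd for f in fits])),
            in_model=d > 0,
            n_replicates=len(fits),
        )
    return _fit_single(series)
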