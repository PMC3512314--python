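"""Work averages, the finite-sampling Jarzynski estimator, and corrections.

Given N_s terminal work values W_i, two upper bounds on the free-energy
change are computed:

* the plain average            W^a = (1/N_s) Σ W_i,
* the finite-sampling
  Jarzynski estimator          W^x = −kBT · ln[(1/N_s) Σ e^(−W_i/kBT)].

By Jensen's inequality W^x ≤ W^a for every sample (equality iff all works are
equal), and in expectation ΔG ≤ ⟨⟨W^x⟩⟩ ≤ ⟨⟨W^a⟩⟩: W^x is the sharper bound
and converges to ΔG as N_s → ∞, while W^a converges to the mean work.

W^x is evaluated through a shifted log-sum-exp, so samples with works of
thousands of kBT neither underflow nor overflow.  Uncertainties come from a
seeded bootstrap (primary) with SD/√N as the naive cross-check; the viscous
dissipation baseline is subtracted with errors propagated in quadrature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .errors import PullworkError, ValidationError
from .units import KB_J
from .work_integration import WorkSample

__all__ = [
    "EstimatorResult",
    "average_work",
    "jarzynski_work",
    "bootstrap_se",
    "estimate",
    "ordering_check",
    "OrderingReport",
    "viscous_correction",
    "display_correction",
    "delta_g_from_ka",
    "ka_from_delta_g",
]


@dataclass(frozen=True)
class EstimatorResult:
    """W^a and W^x with uncertainties for one work sample.

    Energies are in the sample's declared unit system; ``kBT`` is the thermal
    energy in those same units.  ``label`` tags the source system
    (``bound`` | ``viscous`` | ``corrected``).
    """

    Wa: float
    Wx: float
    se_Wa: float
    se_Wx: float
    N_s: int
    temperature_T: float
    kBT: float
    label: str = "bound"
    se_Wa_naive: float = float("nan")

    def __post_init__(self):
        if self.Wx > self.Wa + 1e-9 * max(self.kBT, abs(self.Wa), 1.0) \
                and self.label != "corrected":
            raise PullworkError(
                f"W^x = {self.Wx:g} > W^a = {self.Wa:g}: Jensen's inequality "
                "violated — implementation bug")
        if min(self.se_Wa, self.se_Wx) < 0:
            raise ValidationError("standard errors must be >= 0")


def average_work(sample: WorkSample) -> tuple[float, float]:
    """Plain average W^a with its naive standard error SD/√N_s."""
    w = sample.works
    mean = float(np.mean(w))
    if w.size == 1:
        warnings.warn("single-measurement sample: standard error undefined, "
                      "reporting 0", stacklevel=2)
        return mean, 0.0
    return mean, float(np.std(w, ddof=1) / np.sqrt(w.size))


def jarzynski_work(sample: WorkSample) -> tuple[float, float]:
    """Finite-sampling estimator W^x with a delta-method standard error.

    W^x = −kBT·ln[(1/N_s) Σ e^(−W_i/kBT)], evaluated as a shifted
    log-sum-exp.  The standard error linearises the log around the sample
    mean of the Boltzmann weights (a bootstrap is the sturdier alternative
    for strongly skewed samples; see :func:`bootstrap_se`).
    """
    w = sample.works
    kBT = sample.kBT
    if kBT <= 0:
        raise ValidationError("Jarzynski estimator requires kBT > 0")
    u = -w / kBT
    wx = -kBT * (logsumexp(u) - np.log(w.size))
    if w.size == 1:
        warnings.warn("single-measurement sample: standard error undefined, "
                      "reporting 0", stacklevel=2)
        return float(wx), 0.0
    # delta method on m = mean(e^u): se(Wx) = kBT · sd(e^u)/(m·sqrt(n)),
    # computed on shifted weights so the ratio never under/overflows
    shifted = np.exp(u - u.max())
    m = shifted.mean()
    se = kBT * float(np.std(shifted, ddof=1) / (m * np.sqrt(w.size)))
    return float(wx), se


def _statistic(works: np.ndarray, kBT: float, which: str) -> float:
    if which == "Wa":
        return float(np.mean(works))
    u = -works / kBT
    return float(-kBT * (logsumexp(u) - np.log(works.size)))


def bootstrap_se(sample: WorkSample, statistic: str = "Wx",
                 B: int = 1000, seed: int = 0) -> float:
    """Bootstrap standard error of W^a or W^x (resampling with replacement)."""
    if statistic not in ("Wa", "Wx"):
        raise ValidationError("statistic must be 'Wa' or 'Wx'")
    if B < 100:
        raise ValidationError("B must be >= 100 for a stable bootstrap SE")
    if sample.n == 1:
        raise ValidationError("bootstrap degenerate for a single measurement")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, sample.n, size=(B, sample.n))
    vals = np.array([_statistic(sample.works[row], sample.kBT, statistic)
                     for row in idx])
    return float(np.std(vals, ddof=1))


def estimate(sample: WorkSample, label: str = "bound",
             B: int = 1000, seed: int = 0) -> EstimatorResult:
    """Full estimator report for one sample: W^a, W^x, bootstrap errors."""
    wa, se_wa_naive = average_work(sample)
    wx, se_wx_delta = jarzynski_work(sample)
    if sample.n > 1:
        se_wa = bootstrap_se(sample, "Wa", B=B, seed=seed)
        se_wx = bootstrap_se(sample, "Wx", B=B, seed=seed + 1)
    else:
        se_wa = se_wx = 0.0
    return EstimatorResult(
        Wa=wa, Wx=wx, se_Wa=se_wa, se_Wx=se_wx, N_s=sample.n,
        temperature_T=sample.temperature_T, kBT=sample.kBT, label=label,
        se_Wa_naive=se_wa_naive)


@dataclass(frozen=True)
class OrderingReport:
    """Check of the two-sided bound ΔG ≤ W^x ≤ W^a for one experiment."""

    delta_g: float
    Wx: float
    Wa: float
    margin_dg_wx_kbt: float     # (Wx − ΔG)/kBT, ≥ 0 when the bound holds
    margin_wx_wa_kbt: float     # (Wa − Wx)/kBT, ≥ 0 always
    dg_le_wx: bool
    wx_le_wa: bool

    @property
    def passed(self) -> bool:
        return self.dg_le_wx and self.wx_le_wa


def ordering_check(delta_g: float,
                   bound_result: EstimatorResult) -> OrderingReport:
    """Report ΔG ≤ W^x ≤ W^a with margins in kBT.

    W^x ≤ W^a is a per-sample mathematical identity and a violation raises
    (it can only mean a bug); ΔG ≤ W^x holds in expectation but may fail on
    an unlucky finite sample, so it is reported, not asserted.
    """
    kBT = bound_result.kBT
    m2 = (bound_result.Wa - bound_result.Wx) / kBT
    if m2 < -1e-9:
        raise PullworkError("W^x > W^a: Jensen violated — implementation bug")
    m1 = (bound_result.Wx - delta_g) / kBT
    return OrderingReport(
        delta_g=delta_g, Wx=bound_result.Wx, Wa=bound_result.Wa,
        margin_dg_wx_kbt=float(m1), margin_wx_wa_kbt=float(m2),
        dg_le_wx=bool(m1 >= 0), wx_le_wa=bool(m2 >= -1e-9))


def viscous_correction(bound: EstimatorResult,
                       viscous: EstimatorResult) -> EstimatorResult:
    """Subtract the viscous (solvent-drag) baseline from the bound result.

    corrected W^x = W^x_bound − W^x_viscous, uncertainty propagated in
    quadrature.  Raw values are retained; rounding to the coarser input's
    display precision is a presentation step (:func:`display_correction`).
    """
    if not np.isclose(bound.temperature_T, viscous.temperature_T,
                      rtol=1e-9, atol=0.0):
        raise ValidationError(
            f"temperature mismatch: bound at T={bound.temperature_T:g}, "
            f"viscous at T={viscous.temperature_T:g}")
    return EstimatorResult(
        Wa=bound.Wa - viscous.Wa,
        Wx=bound.Wx - viscous.Wx,
        se_Wa=float(np.hypot(bound.se_Wa, viscous.se_Wa)),
        se_Wx=float(np.hypot(bound.se_Wx, viscous.se_Wx)),
        N_s=bound.N_s, temperature_T=bound.temperature_T, kBT=bound.kBT,
        label="corrected")


def _decimals_of(x: float, max_d: int = 12) -> int:
    for d in range(max_d + 1):
        if round(x, d) == round(x, max_d):
            return d
    return max_d


def display_correction(corrected: EstimatorResult, bound: EstimatorResult,
                       viscous: EstimatorResult,
                       scale: float = 1.0) -> tuple[float, float]:
    """(value, uncertainty) of corrected W^x in units of *scale*, rounded to
    the coarser decimal precision of the two stated input uncertainties."""
    d = min(_decimals_of(bound.se_Wx / scale),
            _decimals_of(viscous.se_Wx / scale))
    return (round(corrected.Wx / scale, d), round(corrected.se_Wx / scale, d))


def delta_g_from_ka(Ka: float, temperature_T: float,
                    standard_conc: float = 1.0) -> float:
    """Free-energy magnitude kB·T·ln(Ka·c°) in joules from an association
    constant Ka (in 1/M) at standard concentration c° (default 1 M).

    Follows the positive-magnitude convention for the unbinding comparison
    (the binding free energy proper is the negative of this value).
    """
    if Ka <= 0:
        raise ValidationError("Ka must be positive")
    if temperature_T <= 0:
        raise ValidationError("temperature must be positive")
    return KB_J * temperature_T * float(np.log(Ka * standard_conc))


def ka_from_delta_g(delta_g: float, temperature_T: float,
                    standard_conc: float = 1.0) -> float:
    """Inverse of :func:`delta_g_from_ka`."""
    if temperature_T <= 0:
        raise ValidationError("temperature must be positive")
    return float(np.exp(delta_g / (KB_J * temperature_T))) / standard_conc
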