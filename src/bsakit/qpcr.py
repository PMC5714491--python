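"""Efficiency-corrected qRT-PCR quantification and Mendelian segregation tests.

Relative expression of a target gene against a reference gene is
computed as ``E_ref**CP_ref / E_target**CP_target``, where CP is the
threshold-crossing cycle and E the per-cycle amplification efficiency
(E=2 is perfect doubling).  Efficiencies are estimated from a cDNA
dilution series by the standard-curve method: the least-squares slope m
of CP against log10(relative concentration) gives E = 10**(-1/m).

Segregation of phenotype classes in an F2 (or M2) family is tested
against an integer expected ratio (e.g. 1:2:1) with a Pearson
goodness-of-fit chi-square, df = classes - 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigError, FitError, ParameterError, UsageError


@dataclass(frozen=True)
class QpcrMeasurement:
    """One gene's amplification summary for one sample.

    ``cp`` may be a single cycle number or replicate cycle numbers;
    replicates are averaged before the expression formula and their SD
    is carried for first-order error propagation.
    """

    sample: str
    gene: str
    cp: tuple[float, ...]
    efficiency: float

    def __post_init__(self):
        cps = self.cp if isinstance(self.cp, tuple) else (float(self.cp),)
        object.__setattr__(self, "cp", tuple(float(c) for c in cps))
        if any(c <= 0 for c in self.cp):
            raise ParameterError("CP values must be positive")
        if not (1.0 < self.efficiency <= 2.2):
            raise ParameterError(
                f"efficiency must lie in (1, 2.2], got {self.efficiency}"
            )

    @property
    def cp_mean(self) -> float:
        return float(np.mean(self.cp))

    @property
    def cp_sd(self) -> float:
        return float(np.std(self.cp, ddof=1)) if len(self.cp) > 1 else 0.0


@dataclass(frozen=True)
class DilutionSeries:
    """Relative concentrations with CP readings (replicates allowed)."""

    concentrations: tuple[float, ...]
    cp: tuple[tuple[float, ...], ...]

    def __post_init__(self):
        if len(self.concentrations) != len(self.cp):
            raise ParameterError("one CP group per concentration required")
        if len(set(self.concentrations)) < 3:
            raise ParameterError("need >=3 distinct concentrations")
        if any(c <= 0 for c in self.concentrations):
            raise ParameterError("concentrations must be strictly positive")


@dataclass(frozen=True)
class EfficiencyFit:
    efficiency: float
    slope: float
    r_squared: float


def primer_efficiency(series: DilutionSeries) -> EfficiencyFit:
    """Estimate amplification efficiency from a dilution series.

    Fits CP = m*log10(concentration) + b by least squares and returns
    E = 10**(-1/m) with the fit R².  A slope of ~0 (flat CP) means the
    dilution had no effect and the efficiency is undefined.
    """
    x = np.log10(np.asarray(series.concentrations, dtype=float))
    y = np.array([np.mean(group) for group in series.cp], dtype=float)
    fit = stats.linregress(x, y)
    if not np.isfinite(fit.slope) or abs(fit.slope) < 1e-9:
        raise FitError("dilution series has (near-)zero slope; E undefined")
    return EfficiencyFit(
        efficiency=10.0 ** (-1.0 / fit.slope),
        slope=float(fit.slope),
        r_squared=float(fit.rvalue**2),
    )


def relative_expression(ref: QpcrMeasurement, target: QpcrMeasurement) -> float:
    """Relative expression of target vs reference: E_ref^CP_ref / E_tgt^CP_tgt.

    Replicate CPs are averaged before the formula is applied.
    """
    return (ref.efficiency**ref.cp_mean) / (target.efficiency**target.cp_mean)


def relative_expression_sd(ref: QpcrMeasurement, target: QpcrMeasurement) -> float:
    """First-order (delta-method) SD of the expression ratio.

    var(ln R) = (ln E_ref)^2 var(CP_ref_mean) + (ln E_tgt)^2 var(CP_tgt_mean);
    SD(R) ~ R * sqrt(var(ln R)).
    """
    r = relative_expression(ref, target)
    var_ln = 0.0
    for m in (ref, target):
        n = len(m.cp)
        var_ln += (math.log(m.efficiency) ** 2) * (m.cp_sd**2) / max(n, 1)
    return r * math.sqrt(var_ln)


def knockdown_fraction(transgenic_rel: float, wildtype_rel: float) -> float:
    """Fraction of expression lost in the transgenic line: 1 - T/W.

    May be negative (upregulation).  Invariant to rescaling both
    arguments by a common positive constant.
    """
    if wildtype_rel <= 0:
        raise UsageError("wild-type relative expression must be positive")
    return 1.0 - transgenic_rel / wildtype_rel


@dataclass(frozen=True)
class SegregationCounts:
    """Observed phenotype-class counts and the expected integer ratio."""

    observed: tuple[int, ...]
    ratio: tuple[int, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.observed) != len(self.ratio):
            raise ConfigError("observed and ratio must have equal length")
        if len(self.observed) < 2:
            raise ConfigError("need at least two classes")
        if any(o < 0 for o in self.observed):
            raise ConfigError("observed counts must be non-negative")
        if any(r <= 0 for r in self.ratio):
            raise ConfigError("expected ratio classes must be positive")
        if sum(self.observed) == 0:
            raise ConfigError("total observed count must be positive")


@dataclass(frozen=True)
class SegregationResult:
    chi2: float
    df: int
    p_value: float
    expected: tuple[float, ...]


def segregation_test(counts: SegregationCounts) -> SegregationResult:
    """Pearson goodness-of-fit of observed class counts to an integer ratio.

    Expected counts are the observed total split proportionally to the
    ratio; df = number of classes - 1.
    """
    obs = np.asarray(counts.observed, dtype=float)
    ratio = np.asarray(counts.ratio, dtype=float)
    expected = obs.sum() * ratio / ratio.sum()
    chi2, p = stats.chisquare(obs, f_exp=expected)
    return SegregationResult(
        chi2=float(chi2),
        df=len(obs) - 1,
        p_value=float(p),
        expected=tuple(float(e) for e in expected),
    )
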