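"""Heterogeneity, pleiotropy-adjacent diagnostics and sensitivity analyses.

Cochran's Q quantifies how much the per-SNP Wald ratios disagree beyond
their sampling error; under homogeneity it is chi-square with J-1 degrees of
freedom, and its per-SNP contributions point at outlying instruments.
Leave-one-out refits the pooled IVW estimate J times, each time excluding
one SNP, to detect single-instrument dominance. Instrument strength is
summarized by the per-SNP F statistic (beta/se)^2 — F > 10 is the
conventional weak-instrument threshold — and by the variance in the exposure
explained under the standardized-trait approximation 2p(1-p)beta^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MrEstimate, EstimationError, estimate_all, ivw, wald_ratios
from .summary_io import InstrumentSet


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q about the fixed-effect IVW center, with per-SNP terms."""

    q: float
    df: int
    pval: float
    contributions: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rsid": list(self.contributions), "q_contribution": list(self.contributions.values())}
        )


@dataclass(frozen=True)
class LeaveOneOutResult:
    """One IVW refit per excluded instrument, plus the full-set estimate."""

    rows: dict[str, MrEstimate]
    full: MrEstimate

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for rsid, est in self.rows.items():
            recs.append(
                {
                    "excluded_rsid": rsid,
                    "beta": est.beta,
                    "se": est.se,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "pval": est.pval,
                    "or_point": est.or_point,
                    "or_low": est.or_low,
                    "or_high": est.or_high,
                    "n_snp": est.n_snp,
                }
            )
        return pd.DataFrame(recs)


@dataclass(frozen=True)
class InstrumentStrength:
    """Per-SNP F statistics and approximate variance explained in the exposure."""

    per_snp_f: dict[str, float]
    r2_per_snp: dict[str, float]

    @property
    def r2_total(self) -> float:
        return float(sum(self.r2_per_snp.values()))

    @property
    def mean_f(self) -> float:
        return float(np.mean(list(self.per_snp_f.values())))

    @property
    def min_f(self) -> float:
        return float(min(self.per_snp_f.values()))


def cochran_q(s: InstrumentSet) -> HeterogeneityResult:
    """Cochran's Q = sum_j w_j (theta_j - theta_IVW)^2 with df = J - 1.

    The center is the fixed-effect IVW estimate (the multiplicative
    random-effects dispersion is itself derived from this Q, so using the
    fixed-effect center avoids circularity).
    """
    if len(s) < 2:
        raise EstimationError("Cochran's Q requires >= 2 instruments")
    ratios = wald_ratios(s)
    theta = np.array([r.theta for r in ratios])
    w = np.array([r.weight for r in ratios])
    center = float(np.sum(w * theta) / np.sum(w))
    terms = w * (theta - center) ** 2
    q = float(np.sum(terms))
    df = len(s) - 1
    return HeterogeneityResult(
        q=q,
        df=df,
        pval=float(stats.chi2.sf(q, df)),
        contributions={r.rsid: float(t) for r, t in zip(ratios, terms)},
    )


def leave_one_out(s: InstrumentSet, model: str = "multiplicative_random") -> LeaveOneOutResult:
    """IVW refit excluding each instrument in turn, in instrument order."""
    if len(s) < 3:
        raise EstimationError("leave-one-out requires >= 3 instruments")
    rows = {rsid: ivw(s.drop(rsid), model=model) for rsid in s.rsids}
    return LeaveOneOutResult(rows=rows, full=ivw(s, model=model))


def instrument_strength(s: InstrumentSet) -> InstrumentStrength:
    """Per-SNP F = (beta_exp/se_exp)^2 and r^2 = 2*eaf*(1-eaf)*beta_exp^2.

    The r^2 approximation assumes a standardized (unit-variance) exposure;
    entries are omitted (with a logged warning) for SNPs without an allele
    frequency.
    """
    if len(s) == 0:
        raise EstimationError("instrument strength requires >= 1 instrument")
    per_f = {i.rsid: (i.beta_exp / i.se_exp) ** 2 for i in s}
    r2 = {}
    for i in s:
        if i.eaf is None:
            logging.getLogger(__name__).warning("%s: missing eaf, r^2 omitted", i.rsid)
            continue
        r2[i.rsid] = 2.0 * i.eaf * (1.0 - i.eaf) * i.beta_exp ** 2
    return InstrumentStrength(per_snp_f=per_f, r2_per_snp=r2)


def reverse_analysis(exposure_as_outcome: InstrumentSet, **kwargs) -> list[MrEstimate]:
    """Run all estimators on a role-swapped instrument set.

    A named entry point so bidirectional analyses (does the outcome trait
    causally affect the original exposure?) are symmetric in reporting; the
    caller supplies a set already harmonized with the roles exchanged (see
    ``InstrumentSet.swapped``). Delegates to :func:`estimate_all`.
    """
    return estimate_all(exposure_as_outcome, **kwargs)
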