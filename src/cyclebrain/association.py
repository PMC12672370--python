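"""Brain-hormone association statistics.

Each retained component's standardized temporal scores are related to
square-root-transformed hormone levels (estradiol, progesterone and the
progesterone-to-estradiol ratio) within each individual by two complementary
statistics: an ordinary least-squares time-series regression (score on
contemporaneous sqrt-hormone, two-sided t test on the slope) and a
nonparametric Spearman rank correlation (exact permutation p-value for
n <= 7, t approximation otherwise).  P-values are Benjamini-Hochberg
FDR-adjusted within each individual's family of tests, separately for the
regression and rank-correlation statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

from .gam import fdr_adjust
from .hormones import HormoneSeries, sqrt_transform

__all__ = [
    "AssocResult",
    "time_series_regression",
    "spearman",
    "associate_all",
]

PREDICTORS = ("estradiol", "progesterone", "ratio")

#: largest n for which the exact permutation null of the Spearman statistic
#: is enumerated (n! grows too fast beyond this)
SPEARMAN_EXACT_N = 7


def time_series_regression(scores, hormone_sqrt) -> tuple[float, float, float]:
    """OLS of component scores on a sqrt-hormone predictor.

    Returns ``(beta0, beta1, p_beta)`` with a two-sided t test on the slope
    at n - 2 degrees of freedom.
    """
    y = np.asarray(scores, dtype=float)
    x = np.asarray(hormone_sqrt, dtype=float)
    if y.size != x.size:
        raise ValueError("scores and predictor must have equal length")
    n = y.size
    if n < 5:
        raise ValueError("need at least 5 sessions")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("constant predictor")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    beta1 = sxy / sxx
    beta0 = float(y.mean() - beta1 * x.mean())
    resid = y - (beta0 + beta1 * x)
    rss = float(np.sum(resid**2))
    if rss == 0:
        return beta0, beta1, 0.0
    se = np.sqrt(rss / (n - 2) / sxx)
    t = beta1 / se
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return beta0, beta1, min(p, 1.0)


def _midranks(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    den = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    if den == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    return float(np.sum(rx * ry) / den)


def spearman(scores, hormone) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks (ties get average ranks).
    For n <= 7 the p-value is exact: the fraction of all n! pairings of the
    observed rank vectors with |rho| at least as large as observed.  For
    larger n, the usual t approximation with n - 2 df is used.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(hormone, dtype=float)
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    rx, ry = _midranks(x), _midranks(y)
    rho = _rho_of_ranks(rx, ry)

    if n <= SPEARMAN_EXACT_N:
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in permutations(range(n)):
            r = _rho_of_ranks(rx, ry[list(perm)])
            count += abs(r) >= target
            total += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return rho, min(p, 1.0)


@dataclass
class AssocResult:
    """Association between one component's scores and one hormone."""

    individual_id: str
    component: int
    predictor: str
    beta0: float
    beta1: float
    p_beta: float
    rho: float
    p_rho: float
    n: int
    p_beta_fdr: float | None = None
    p_rho_fdr: float | None = None

    @property
    def significant(self) -> bool:
        """Concordant FDR significance (5% level) in both routes.

        A hormone-component association is flagged only when the parametric
        regression and the nonparametric Spearman test are both
        FDR-significant.  Requiring concordance guards against spurious
        flags from non-normality and from the temporal autocorrelation that
        contemporaneous OLS ignores; each route's adjusted p-value remains
        available separately.
        """
        return (
            self.p_beta_fdr is not None
            and self.p_rho_fdr is not None
            and self.p_beta_fdr < 0.05
            and self.p_rho_fdr < 0.05
        )


def associate_all(
    component_scores: dict[str, dict[int, np.ndarray]],
    hormone_series: list[HormoneSeries],
    alpha: float = 0.05,
    standardize_predictors: bool = False,
) -> list[AssocResult]:
    """Run both association statistics for every individual/component/hormone.

    ``component_scores[individual_id][component]`` holds the standardized
    temporal scores whose session days must align exactly with the
    individual's hormone series.  FDR adjustment is applied within each
    individual across its components x predictors family, separately for the
    regression and the Spearman p-values.
    """
    by_id = {h.individual_id: h for h in hormone_series}
    results: list[AssocResult] = []
    for ind, comps in component_scores.items():
        if ind not in by_id:
            raise ValueError(f"no hormone series for individual {ind!r}")
        horm = by_id[ind]
        block: list[AssocResult] = []
        for comp_idx, scores in sorted(comps.items()):
            scores = np.asarray(scores, dtype=float)
            if scores.size != len(horm):
                raise ValueError(
                    f"individual {ind!r}: component {comp_idx} has "
                    f"{scores.size} scores but {len(horm)} hormone days "
                    f"(days {horm.day.tolist()})"
                )
            for predictor in PREDICTORS:
                values = getattr(horm, "estradiol" if predictor == "estradiol"
                                 else "progesterone" if predictor == "progesterone"
                                 else "ratio")
                x = sqrt_transform(values)
                if standardize_predictors:
                    x = (x - x.mean()) / x.std(ddof=1)
                beta0, beta1, p_beta = time_series_regression(scores, x)
                rho, p_rho = spearman(scores, values)
                block.append(
                    AssocResult(
                        individual_id=ind,
                        component=comp_idx,
                        predictor=predictor,
                        beta0=beta0,
                        beta1=beta1,
                        p_beta=p_beta,
                        rho=rho,
                        p_rho=p_rho,
                        n=scores.size,
                    )
                )
        p_beta_adj = fdr_adjust([r.p_beta for r in block])
        p_rho_adj = fdr_adjust([r.p_rho for r in block])
        for r, pb, pr in zip(block, p_beta_adj, p_rho_adj):
            r.p_beta_fdr = float(pb)
            r.p_rho_fdr = float(pr)
        results.extend(block)
    return results
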