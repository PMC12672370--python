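"""Between-individual comparison of endocrine profiles.

Sessions are treated as independent observations (as is conventional for
these dense-sampling designs) and the three hormone variables — estradiol,
progesterone and the progesterone-to-estradiol ratio — are compared across
individuals with a one-way MANOVA (Pillai's trace and Roy's largest root
with their F approximations and partial eta squared), post hoc one-way
ANOVAs per variable, and Bonferroni-corrected pairwise two-tailed t-tests
using the pooled within-group variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ManovaResult",
    "one_way_manova",
    "one_way_anova",
    "pairwise_t_bonferroni",
]


@dataclass
class ManovaResult:
    groups: int
    variables: int
    total_n: int
    H: np.ndarray                 # between-group SSCP (p x p)
    E: np.ndarray                 # within-group SSCP (p x p)
    eigenvalues: np.ndarray       # of E^{-1} H, descending
    pillai: float
    roy: float
    f_pillai: float
    df_pillai: tuple[float, float]
    p_pillai: float
    f_roy: float
    df_roy: tuple[float, float]
    p_roy: float
    partial_eta2_pillai: float
    partial_eta2_roy: float


def _split_groups(values: np.ndarray, groups: np.ndarray):
    groups = np.asarray(groups)
    uniq = list(dict.fromkeys(groups.tolist()))  # preserve input order
    parts = [values[groups == g] for g in uniq]
    return uniq, parts


def one_way_manova(values: np.ndarray, groups) -> ManovaResult:
    """One-way MANOVA of a (N, p) response matrix against a group factor.

    Pillai's trace V = sum lambda_i / (1 + lambda_i) with its standard F
    approximation; Roy's largest root theta = max lambda_i with the
    upper-bound F approximation df1 = max(p, g-1), df2 = N - df1 - 1 and
    F = theta * df2 / df1.  Partial eta squared is V/s for Pillai and
    theta/(1+theta) for Roy.
    """
    Y = np.asarray(values, dtype=float)
    if Y.ndim != 2:
        raise ValueError("values must be an (N, p) matrix")
    N, p = Y.shape
    uniq, parts = _split_groups(Y, np.asarray(groups))
    g = len(uniq)
    if g < 2:
        raise ValueError("need at least 2 groups")
    for label, part in zip(uniq, parts):
        if part.shape[0] < p + 1:
            raise ValueError(f"group {label!r} smaller than p + 1 = {p + 1}")

    grand = Y.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for part in parts:
        m = part.mean(axis=0)
        d = (m - grand)[:, None]
        H += part.shape[0] * (d @ d.T)
        c = part - m
        E += c.T @ c

    # eigenvalues of E^{-1} H via the symmetric generalized problem
    try:
        Einv_H = np.linalg.solve(E, H)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular within-group SSCP matrix") from err
    lam = np.linalg.eigvals(Einv_H)
    lam = np.sort(np.clip(lam.real, 0.0, None))[::-1]

    s = min(p, g - 1)
    V = float(np.sum(lam / (1.0 + lam)))
    theta = float(lam[0])

    m_par = (abs(p - g + 1) - 1) / 2.0
    n_par = (N - g - p - 1) / 2.0
    df1_p = s * (2 * m_par + s + 1)
    df2_p = s * (2 * n_par + s + 1)
    f_pillai = (df2_p / df1_p) * (V / (s - V))
    p_pillai = float(stats.f.sf(f_pillai, df1_p, df2_p))

    df1_r = max(p, g - 1)
    df2_r = N - df1_r - 1
    f_roy = theta * df2_r / df1_r
    p_roy = float(stats.f.sf(f_roy, df1_r, df2_r))

    return ManovaResult(
        groups=g,
        variables=p,
        total_n=N,
        H=H,
        E=E,
        eigenvalues=lam,
        pillai=V,
        roy=theta,
        f_pillai=float(f_pillai),
        df_pillai=(float(df1_p), float(df2_p)),
        p_pillai=p_pillai,
        f_roy=float(f_roy),
        df_roy=(float(df1_r), float(df2_r)),
        p_roy=p_roy,
        partial_eta2_pillai=V / s,
        partial_eta2_roy=theta / (1.0 + theta),
    )


def one_way_anova(values, groups) -> tuple[float, int, int, float, float]:
    """One-way ANOVA: returns ``(F, df1, df2, p, eta2)`` with eta2 = SSB/SST."""
    v = np.asarray(values, dtype=float)
    uniq, parts = _split_groups(v, np.asarray(groups))
    g = len(uniq)
    if g < 2:
        raise ValueError("need at least 2 groups")
    if any(part.size == 0 for part in parts):
        raise ValueError("empty group")
    N = v.size
    if N <= g:
        raise ValueError("need more observations than groups")
    grand = v.mean()
    ssb = float(sum(part.size * (part.mean() - grand) ** 2 for part in parts))
    ssw = float(sum(np.sum((part - part.mean()) ** 2) for part in parts))
    df1, df2 = g - 1, N - g
    if ssw == 0:
        return np.inf, df1, df2, 0.0, 1.0
    F = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(F, df1, df2))
    eta2 = ssb / (ssb + ssw)
    return float(F), df1, df2, p, eta2


def pairwise_t_bonferroni(values, groups, pooled: bool = True) -> list[dict]:
    """All pairwise two-tailed t-tests with Bonferroni correction.

    With ``pooled=True`` (default) the t denominator uses the pooled
    within-group mean square from the one-way ANOVA with N - g degrees of
    freedom (the SPSS post hoc convention); otherwise independent two-sample
    t-tests with per-pair pooled variance are used.
    """
    v = np.asarray(values, dtype=float)
    uniq, parts = _split_groups(v, np.asarray(groups))
    g = len(uniq)
    if g < 2:
        raise ValueError("need at least 2 groups")
    if any(part.size == 0 for part in parts):
        raise ValueError("empty group")
    n_pairs = g * (g - 1) // 2
    N = v.size

    msw = sum(np.sum((part - part.mean()) ** 2) for part in parts) / (N - g)
    out = []
    for i in range(g):
        for j in range(i + 1, g):
            a, b = parts[i], parts[j]
            if pooled:
                df = N - g
                denom = np.sqrt(msw * (1.0 / a.size + 1.0 / b.size))
            else:
                df = a.size + b.size - 2
                sp2 = (
                    np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)
                ) / df
                denom = np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
            if denom == 0:
                t, p_raw = 0.0, 1.0
            else:
                t = float((a.mean() - b.mean()) / denom)
                p_raw = 2.0 * float(stats.t.sf(abs(t), df))
                p_raw = min(p_raw, 1.0)
            out.append(
                {
                    "pair": (uniq[i], uniq[j]),
                    "t": t,
                    "df": df,
                    "p_raw": p_raw,
                    "p_adj": min(1.0, p_raw * n_pairs),
                }
            )
    return out
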