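"""Convergent and discriminant validity statistics.

The primary outcome is the Pearson correlation between out-of-sample
predicted and observed severity, with a Fisher-z confidence interval.
Discriminant validity compares that convergent correlation against the
predicted score's correlations with depression (DASS-21), negative affect
and positive affect (PANAS) using Steiger's (1980) Z for two dependent
correlations sharing one variable.  Missing discriminant measures are
handled by chained-equation multiple imputation with Rubin's rules pooling
on the Fisher-z scale.  A partial correlation (predicted vs observed
severity controlling for the three affect measures) and the proportions of
the sample above the SIAS clinical cutoffs (34 and 36, comparator >=)
complete the report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ValidityReport",
    "pearson_ci",
    "pearson_test",
    "dependent_corr_z",
    "partial_corr",
    "impute_and_pool",
    "cutoff_proportions",
    "build_report",
]


def _atanh(r: float) -> float:
    # clip so a numerically perfect correlation stays finite on the z scale
    return math.atanh(min(max(r, -1.0 + 1e-12), 1.0 - 1e-12))


def pearson_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher z-transform confidence interval for a Pearson correlation.

    (lower, upper) = tanh(atanh(r) +/- z_level / sqrt(n - 3)), rounded to
    3 decimals.
    """
    if not -1 < r < 1:
        raise ValueError("|r| must be strictly below 1")
    if n < 4:
        raise ValueError("need n >= 4")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z / math.sqrt(n - 3)
    zr = _atanh(r)
    return (round(math.tanh(zr - half), 3), round(math.tanh(zr + half), 3))


def pearson_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p (t distribution, n-2 df)."""
    r, p = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)


def dependent_corr_z(r_jk: float, r_jh: float, r_kh: float,
                     n: int) -> tuple[float, float]:
    """Steiger's Z for two dependent correlations sharing variable j.

    Tests r_jk = r_jh where j is shared (here: predicted severity), k and h
    are the two compared measures, and r_kh is their intercorrelation.
    Uses the pooled-correlation variant: with rbar = (r_jk + r_jh)/2,

        psi  = r_kh (1 - 2 rbar^2) - rbar^2 (1 - 2 rbar^2 - r_kh^2) / 2
        cbar = psi / (1 - rbar^2)^2
        Z    = (z_jk - z_jh) sqrt((n - 3) / (2 - 2 cbar))

    Returns (Z, two-sided p).
    """
    if n < 10:
        raise ValueError("need n >= 10")
    c = np.array([[1.0, r_jk, r_jh],
                  [r_jk, 1.0, r_kh],
                  [r_jh, r_kh, 1.0]])
    if np.linalg.eigvalsh(c).min() < -1e-10:
        raise ValueError("correlation matrix is not positive semidefinite")
    rbar = 0.5 * (r_jk + r_jh)
    psi = r_kh * (1.0 - 2.0 * rbar ** 2) \
        - 0.5 * rbar ** 2 * (1.0 - 2.0 * rbar ** 2 - r_kh ** 2)
    cbar = psi / (1.0 - rbar ** 2) ** 2
    z = (_atanh(r_jk) - _atanh(r_jh)) * math.sqrt((n - 3) / (2.0 - 2.0 * cbar))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def partial_corr(x, y, controls) -> tuple[float, tuple[float, float]]:
    """Partial correlation of x and y after linear adjustment for controls.

    Residualizes both variables on the control matrix (with intercept) and
    correlates the residuals; the CI uses Fisher z with n - 3 - k effective
    observations for k controls.  Collinear controls raise ValueError.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    C = np.asarray(controls, float)
    if C.ndim == 1:
        C = C[:, None]
    n, k = C.shape
    if len(x) != n or len(y) != n:
        raise ValueError("length mismatch")
    if n < k + 4:
        raise ValueError(f"need at least {k + 4} complete rows")
    design = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear controls")
    bx, *_ = np.linalg.lstsq(design, x, rcond=None)
    by, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ bx
    ry = y - design @ by
    # a variable fully explained by the controls has nothing left to correlate
    if np.std(rx) < 1e-12 * max(1.0, np.std(x)) \
            or np.std(ry) < 1e-12 * max(1.0, np.std(y)):
        r = 0.0
    else:
        r = float(np.corrcoef(rx, ry)[0, 1])
    z = stats.norm.ppf(0.975)
    half = z / math.sqrt(n - 3 - k)
    ci = (round(math.tanh(_atanh(r) - half), 3),
          round(math.tanh(_atanh(r) + half), 3))
    return r, ci


def _rubin_pool_z(zs: np.ndarray, within_var: float,
                  m: int) -> tuple[float, float, float]:
    """Rubin's rules on the Fisher-z scale -> (zbar, total SE, t df)."""
    zbar = float(np.mean(zs))
    b = float(np.var(zs, ddof=1)) if m > 1 else 0.0
    t_var = within_var + (1.0 + 1.0 / m) * b
    if b > 0:
        df = (m - 1) * (1.0 + within_var / ((1.0 + 1.0 / m) * b)) ** 2
    else:
        df = math.inf
    return zbar, math.sqrt(t_var), df


def impute_and_pool(table: pd.DataFrame, pairs: list[tuple[str, str]],
                    m: int = 20, seed: int = 0,
                    level: float = 0.95) -> pd.DataFrame:
    """Multiply-imputed, Rubin-pooled correlations for the given column pairs.

    Chained-equation imputation (IterativeImputer, posterior sampling) fills
    the missing cells m times; each completed table yields a Pearson r per
    pair, pooled on the Fisher-z scale with within-imputation variance
    1/(n-3).  With no missing cells the result equals the complete-data
    correlations exactly.  Deterministic given *seed*.
    """
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    if m < 1:
        raise ValueError("m must be >= 1")
    for col in table.columns:
        if table[col].isna().all():
            raise ValueError(f"column '{col}' is entirely MISSING")
    n = len(table)
    X = table.to_numpy(dtype=float)
    any_missing = bool(np.isnan(X).any())
    completed: list[np.ndarray] = []
    if not any_missing:
        completed = [X]
    else:
        root = np.random.SeedSequence(seed)
        for child in root.spawn(m):
            sub_seed = int(child.generate_state(1)[0] % (2 ** 31 - 1))
            imp = IterativeImputer(sample_posterior=True, max_iter=10,
                                   random_state=sub_seed)
            completed.append(imp.fit_transform(X))

    cols = {c: j for j, c in enumerate(table.columns)}
    within = 1.0 / (n - 3)
    rows = []
    m_eff = len(completed)
    for a, b in pairs:
        zs = np.array([
            _atanh(float(np.corrcoef(Xc[:, cols[a]], Xc[:, cols[b]])[0, 1]))
            for Xc in completed
        ])
        zbar, se, df = _rubin_pool_z(zs, within, m_eff)
        if math.isinf(df):
            q = stats.norm.ppf(0.5 + level / 2.0)
        else:
            q = stats.t.ppf(0.5 + level / 2.0, df)
        r = math.tanh(zbar)
        lo, hi = math.tanh(zbar - q * se), math.tanh(zbar + q * se)
        p = 2.0 * stats.norm.sf(abs(zbar) / math.sqrt(within)) if math.isinf(df) \
            else 2.0 * stats.t.sf(abs(zbar) / se, df)
        rows.append((a, b, r, round(lo, 3), round(hi, 3), p))
    return pd.DataFrame(rows, columns=["x", "y", "r", "ci_low", "ci_high", "p"])


def cutoff_proportions(sias) -> tuple[float, float]:
    """Proportions of the sample at or above the SIAS cutoffs 34 and 36."""
    s = np.asarray(sias, dtype=float)
    if np.any((s < 0) | (s > 80)):
        raise ValueError("SIAS scores must lie within [0, 80]")
    return float(np.mean(s >= 34)), float(np.mean(s >= 36))


@dataclass
class ValidityReport:
    n_effective: int
    r_convergent: float
    ci_convergent: tuple[float, float]
    p_convergent: float
    r_dep: float
    ci_dep: tuple[float, float]
    p_dep: float
    r_na: float
    ci_na: tuple[float, float]
    p_na: float
    r_pa: float
    ci_pa: tuple[float, float]
    p_pa: float
    z_dep: float
    p_z_dep: float
    z_na: float
    p_z_na: float
    z_pa: float
    p_z_pa: float
    r_partial: float
    ci_partial: tuple[float, float]
    pct_above_34: float
    pct_above_36: float
    var_ratio_dep: float
    var_ratio_na: float
    var_ratio_pa: float

    def to_dict(self) -> dict:
        return asdict(self)

    def summary(self) -> str:
        lines = [
            f"n = {self.n_effective}",
            (f"convergent: r = {self.r_convergent:.3f} "
             f"(95% CI {self.ci_convergent[0]:.3f} to {self.ci_convergent[1]:.3f}, "
             f"p = {self.p_convergent:.3g})"),
            (f"depression:      r = {self.r_dep:+.3f}, "
             f"Z vs convergent = {self.z_dep:.3f} (p = {self.p_z_dep:.3g})"),
            (f"negative affect: r = {self.r_na:+.3f}, "
             f"Z vs convergent = {self.z_na:.3f} (p = {self.p_z_na:.3g})"),
            (f"positive affect: r = {self.r_pa:+.3f}, "
             f"Z vs convergent = {self.z_pa:.3f} (p = {self.p_z_pa:.3g})"),
            (f"partial r (controlling dep/NA/PA) = {self.r_partial:.3f} "
             f"(95% CI {self.ci_partial[0]:.3f} to {self.ci_partial[1]:.3f})"),
            (f"share at/above SIAS cutoff: 34 -> {self.pct_above_34:.1%}, "
             f"36 -> {self.pct_above_36:.1%}"),
        ]
        return "\n".join(lines)


def build_report(predictions: pd.Series, surveys: pd.DataFrame,
                 m_imputations: int = 20, seed: int = 0,
                 out_of_sample: bool = True,
                 level: float = 0.95) -> ValidityReport:
    """Assemble the full validity report.

    *predictions*: out-of-sample predicted severity indexed by participant;
    *surveys*: DataFrame with columns sias, dass_dep, panas_na, panas_pa
    (NaN = missing), same index.  Refuses in-sample predictions.
    """
    if not out_of_sample:
        raise ValueError(
            "predictions are flagged in-sample; validity statistics require "
            "out-of-sample predictions")
    surveys = surveys.loc[predictions.index]
    y_pred = predictions.to_numpy(dtype=float)
    sias = surveys["sias"].to_numpy(dtype=float)
    n = len(sias)

    r_conv, p_conv = pearson_test(y_pred, sias)
    if abs(r_conv) >= 1.0 - 1e-12:  # degenerate perfect correlation
        ci_conv = (r_conv, r_conv)
    else:
        ci_conv = pearson_ci(r_conv, n, level)

    table = pd.DataFrame({
        "y_pred": y_pred,
        "sias": sias,
        "dass_dep": surveys["dass_dep"].to_numpy(dtype=float),
        "panas_na": surveys["panas_na"].to_numpy(dtype=float),
        "panas_pa": surveys["panas_pa"].to_numpy(dtype=float),
    }, index=predictions.index)
    pairs = [("y_pred", "dass_dep"), ("y_pred", "panas_na"),
             ("y_pred", "panas_pa"),
             ("sias", "dass_dep"), ("sias", "panas_na"), ("sias", "panas_pa")]
    pooled = impute_and_pool(table, pairs, m=m_imputations, seed=seed,
                             level=level).set_index(["x", "y"])

    def pr(a, b):
        row = pooled.loc[(a, b)]
        return (float(row["r"]), (float(row["ci_low"]), float(row["ci_high"])),
                float(row["p"]))

    r_dep, ci_dep, p_dep = pr("y_pred", "dass_dep")
    r_na, ci_na, p_na = pr("y_pred", "panas_na")
    r_pa, ci_pa, p_pa = pr("y_pred", "panas_pa")
    # Steiger Z uses the CI convention n = observed sample size throughout.
    def steiger(r_other, r_between):
        rc = max(min(r_conv, 0.9999), -0.9999)
        try:
            return dependent_corr_z(rc, r_other, r_between, n)
        except ValueError:  # degenerate pooled correlation structure
            return math.nan, math.nan

    z_dep, p_z_dep = steiger(r_dep, pr("sias", "dass_dep")[0])
    z_na, p_z_na = steiger(r_na, pr("sias", "panas_na")[0])
    z_pa, p_z_pa = steiger(r_pa, pr("sias", "panas_pa")[0])

    # Partial correlation pooled over the same imputations.
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer
    X = table.to_numpy(dtype=float)
    zs = []
    if np.isnan(X).any():
        root = np.random.SeedSequence(seed)
        for child in root.spawn(m_imputations):
            sub_seed = int(child.generate_state(1)[0] % (2 ** 31 - 1))
            imp = IterativeImputer(sample_posterior=True, max_iter=10,
                                   random_state=sub_seed)
            Xc = imp.fit_transform(X)
            rp, _ = partial_corr(Xc[:, 0], Xc[:, 1], Xc[:, 2:5])
            zs.append(_atanh(rp))
    else:
        rp, _ = partial_corr(X[:, 0], X[:, 1], X[:, 2:5])
        zs.append(_atanh(rp))
    within = 1.0 / (n - 3 - 3)
    zbar, se, df = _rubin_pool_z(np.array(zs), within, len(zs))
    q = stats.norm.ppf(0.5 + level / 2.0) if math.isinf(df) \
        else stats.t.ppf(0.5 + level / 2.0, df)
    r_partial = math.tanh(zbar)
    ci_partial = (round(math.tanh(zbar - q * se), 3),
                  round(math.tanh(zbar + q * se), 3))

    p34, p36 = cutoff_proportions(sias)

    def ratio(r_other):
        return (r_conv ** 2) / (r_other ** 2) if r_other != 0 else math.inf

    return ValidityReport(
        n_effective=n,
        r_convergent=r_conv, ci_convergent=ci_conv, p_convergent=p_conv,
        r_dep=r_dep, ci_dep=ci_dep, p_dep=p_dep,
        r_na=r_na, ci_na=ci_na, p_na=p_na,
        r_pa=r_pa, ci_pa=ci_pa, p_pa=p_pa,
        z_dep=z_dep, p_z_dep=p_z_dep,
        z_na=z_na, p_z_na=p_z_na,
        z_pa=z_pa, p_z_pa=p_z_pa,
        r_partial=r_partial, ci_partial=ci_partial,
        pct_above_34=p34, pct_above_36=p36,
        var_ratio_dep=ratio(r_dep), var_ratio_na=ratio(r_na),
        var_ratio_pa=ratio(r_pa),
    )
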