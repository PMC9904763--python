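"""Touch scoring and the dual frequentist/Bayesian statistics layer.

Frequentist side: pooled two-proportion z-test (one- or two-tailed, with
Bonferroni correction across a comparison family), Student/Welch t-tests,
one-way ANOVA with Dunnett many-to-one comparisons (family-wise adjustment
by seeded Monte-Carlo evaluation of the multivariate-t maximum statistic),
and a within-subjects repeated-measures ANOVA.  Significance is assessed at
alpha = 0.05.

Bayesian side: the JZS two-sample t-test Bayes factor (Cauchy effect-size
prior, numerical integration), a Beta-Binomial A/B Bayes factor for
proportions in closed form, and the modified-Jeffreys category scheme for
reporting BF10: 'null hypothesis supported' (<1), 'weak' (1-3),
'substantial' (3-10), 'strong' (10-30), 'very strong' (30-100),
'decisive' (>100).

Figure conventions: '*' marks frequentist significance, a dagger weak BF
evidence, a double dagger substantial-or-stronger BF evidence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, special, stats as sps

from .errors import ValidationError

ALPHA = 0.05

BEHAVIOR_COLUMNS = ("pause", "head_withdrawal", "head_cast", "reverse")

GLYPH_SIGNIFICANT = "✱"       # heavy asterisk
GLYPH_WEAK_BF = "†"           # dagger
GLYPH_SUBSTANTIAL_BF = "‡"    # double dagger


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_raw: float
    p_adjusted: float
    tails: str = "two"
    alpha: float = ALPHA
    df: float | None = None
    detail: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_raw <= 1.0 and 0.0 <= self.p_adjusted <= 1.0):
            raise ValidationError("p values must lie in [0, 1]")
        if self.p_adjusted + 1e-12 < self.p_raw:
            raise ValidationError("adjusted p cannot be below raw p")

    @property
    def significant(self) -> bool:
        return self.p_adjusted < self.alpha

    @property
    def glyph(self) -> str:
        return GLYPH_SIGNIFICANT if self.significant else ""


BF_CATEGORIES = (
    (1.0, "null hypothesis supported"),
    (3.0, "weak"),
    (10.0, "substantial"),
    (30.0, "strong"),
    (100.0, "very strong"),
    (math.inf, "decisive"),
)


def interpret_bf(bf10: float) -> str:
    """Map a Bayes factor onto the modified-Jeffreys category scheme.

    Half-open intervals, boundaries assigned to the higher category
    (BF = 3 is 'substantial'), except BF = 1 which is 'weak'.
    """
    if not bf10 > 0:
        raise ValidationError("bf10 must be > 0")
    for upper, label in BF_CATEGORIES:
        if bf10 < upper:
            return label
    return "decisive"


@dataclass(frozen=True)
class BayesFactorResult:
    bf10: float
    prior: str = ""

    def __post_init__(self):
        if not self.bf10 > 0:
            raise ValidationError("bf10 must be > 0")

    @property
    def category(self) -> str:
        return interpret_bf(self.bf10)

    @property
    def glyph(self) -> str:
        if self.bf10 >= 3.0:
            return GLYPH_SUBSTANTIAL_BF
        if self.bf10 >= 1.0:
            return GLYPH_WEAK_BF
        return ""


@dataclass(frozen=True)
class ProportionSample:
    k: int
    n: int

    def __post_init__(self):
        if self.n < 1 or not 0 <= self.k <= self.n:
            raise ValidationError("need 0 <= k <= n, n >= 1")

    @property
    def p(self) -> float:
        return self.k / self.n


# ---------------------------------------------------------------------------
# touch scoring


@dataclass(frozen=True)
class TouchScoreSummary:
    per_trial_scores: pd.DataFrame   # subject x trial score (0-4)
    subject_sums: pd.Series          # 0-12 per subject
    mean: float
    sem: float
    trial_means: pd.Series           # mean score per trial


def score_touch(table: pd.DataFrame) -> TouchScoreSummary:
    """Kernan-style gentle-touch scoring.

    ``table`` has one row per subject x trial with four 0/1 behavior flags
    (pause/hesitate, head withdrawal, head cast/turn, reverse locomotion).
    Each trial scores the count of flags shown (max 4); the three trial
    scores sum to the subject score (max 12).
    """
    required = {"subject", "trial", *BEHAVIOR_COLUMNS}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"touch table missing columns: {sorted(missing)}")
    trials = sorted(table["trial"].unique())
    if len(trials) != 3:
        raise ValidationError(f"expected exactly 3 trials, got {len(trials)}")
    flags = table[list(BEHAVIOR_COLUMNS)]
    if not flags.isin([0, 1, True, False]).all().all():
        raise ValidationError("behavior flags must be 0/1")
    per_trial = table.assign(score=flags.sum(axis=1)).pivot_table(
        index="subject", columns="trial", values="score"
    )
    if per_trial.isna().any().any():
        raise ValidationError("every subject needs all 3 trials")
    sums = per_trial.sum(axis=1)
    n = len(sums)
    sem = float(sums.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return TouchScoreSummary(
        per_trial_scores=per_trial,
        subject_sums=sums,
        mean=float(sums.mean()),
        sem=sem,
        trial_means=per_trial.mean(axis=0),
    )


# ---------------------------------------------------------------------------
# frequentist tests


def ztest_two_proportions(
    a: ProportionSample,
    b: ProportionSample,
    tails: str = "two",
    direction: str = "less",
) -> TestResult:
    """Pooled two-proportion z-test.

    ``a`` is the treatment sample, ``b`` the control.  For ``tails="one"``
    the default alternative is the treatment proportion being *lower* than
    control (``direction="less"``, the 5 degC-style hypothesis); pass
    ``direction="greater"`` to flip.
    """
    if tails not in ("one", "two"):
        raise ValidationError("tails must be 'one' or 'two'")
    pool = (a.k + b.k) / (a.n + b.n)
    se = math.sqrt(pool * (1 - pool) * (1 / a.n + 1 / b.n))
    if se == 0:
        return TestResult(0.0, 1.0, 1.0, tails=tails)
    z = (a.p - b.p) / se
    if tails == "two":
        p = 2 * sps.norm.sf(abs(z))
    elif direction == "less":
        p = sps.norm.cdf(z)
    else:
        p = sps.norm.sf(z)
    return TestResult(float(z), float(min(p, 1.0)), float(min(p, 1.0)), tails=tails)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(p * m, 1)`` with family size ``m``."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValidationError("family size must be >= 1")
    if m < p.size:
        warnings.warn("family size smaller than number of p values", stacklevel=2)
    return np.minimum(p * m, 1.0)


def ttest(x, y, variant: str = "student", tails: str = "two") -> TestResult:
    """Two-sample t-test (Student pooled-variance or Welch)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("need >= 2 values per group")
    if variant not in ("student", "welch"):
        raise ValidationError("variant must be 'student' or 'welch'")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return TestResult(0.0, 1.0, 1.0, tails=tails, df=float(len(x) + len(y) - 2))
        return TestResult(math.inf, 0.0, 0.0, tails=tails, df=float(len(x) + len(y) - 2))
    res = sps.ttest_ind(
        x,
        y,
        equal_var=(variant == "student"),
        alternative="two-sided" if tails == "two" else "less",
    )
    return TestResult(float(res.statistic), float(res.pvalue), float(res.pvalue), tails=tails, df=float(res.df))


def anova_dunnett(
    groups,
    control_index: int = 0,
    reps: int = 100_000,
    seed: int = 0,
) -> dict:
    """One-way ANOVA plus Dunnett many-to-one comparisons against a control.

    Family-wise adjusted p values come from a seeded Monte-Carlo sample of
    the null maximum |T| over the correlated comparison statistics
    (multivariate t with correlations sqrt(lambda_i lambda_j),
    lambda_i = n_i / (n_i + n_0)); the Monte-Carlo standard error of each
    adjusted p is reported alongside.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("need >= 2 groups with >= 2 values each")
    if not 0 <= control_index < len(groups):
        raise ValidationError("control index out of range")
    ns = np.array([len(g) for g in groups])
    N, k = int(ns.sum()), len(groups)
    df = N - k
    grand = np.concatenate(groups)
    means = np.array([g.mean() for g in groups])
    ss_between = float(np.sum(ns * (means - grand.mean()) ** 2))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    mse = ss_within / df
    if mse == 0:
        F, p_anova = 0.0, 1.0
        if not np.allclose(means, means[0]):
            F, p_anova = math.inf, 0.0
    else:
        F = (ss_between / (k - 1)) / mse
        p_anova = float(sps.f.sf(F, k - 1, df))

    others = [i for i in range(k) if i != control_index]
    n0 = ns[control_index]
    tstats = []
    for i in others:
        se = math.sqrt(mse * (1 / ns[i] + 1 / n0)) if mse > 0 else 0.0
        tstats.append((means[i] - means[control_index]) / se if se > 0 else 0.0)
    tstats = np.array(tstats)

    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal(size=reps) / math.sqrt(n0)
    zi = rng.standard_normal(size=(reps, len(others))) / np.sqrt(ns[others])
    s = np.sqrt(rng.chisquare(df, size=reps) / df)
    T = (zi - z0[:, None]) / (np.sqrt(1 / ns[others] + 1 / n0)[None, :] * s[:, None])
    maxstat = np.abs(T).max(axis=1)

    comparisons = []
    for t, i in zip(tstats, others):
        p_raw = float(2 * sps.t.sf(abs(t), df)) if mse > 0 else 1.0
        p_adj = float(np.mean(maxstat >= abs(t))) if mse > 0 else 1.0
        p_adj = max(p_adj, p_raw)  # MC max-stat cannot undercut the single test
        mc_se = math.sqrt(p_adj * (1 - p_adj) / reps)
        comparisons.append(
            TestResult(
                float(t),
                p_raw,
                min(p_adj, 1.0),
                tails="two",
                df=float(df),
                detail={"group": int(i), "mc_se": mc_se},
            )
        )
    return {
        "anova_F": float(F),
        "anova_p": float(p_anova),
        "df": (k - 1, df),
        "comparisons": comparisons,
    }


def rm_anova_within(matrix, greenhouse_geisser: bool = False) -> TestResult:
    """One within-factor repeated-measures ANOVA on a subject x trial matrix.

    Sphericity is assumed by default; ``greenhouse_geisser=True`` scales
    both degrees of freedom by the Greenhouse-Geisser epsilon.  Missing
    cells are rejected (no imputation).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValidationError("need a complete subjects x trials matrix, >= 2 each")
    if not np.all(np.isfinite(m)):
        raise ValidationError("missing cells are not allowed")
    n, k = m.shape
    grand = m.mean()
    ss_subj = k * np.sum((m.mean(axis=1) - grand) ** 2)
    ss_trial = n * np.sum((m.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_trial
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_trial = ss_trial / df1
    ms_err = ss_err / df2
    if ms_err <= 1e-300:
        if ms_trial <= 1e-300:
            return TestResult(0.0, 1.0, 1.0, df=float(df1), detail={"df2": df2})
        return TestResult(math.inf, 0.0, 0.0, df=float(df1), detail={"df2": df2})
    F = ms_trial / ms_err
    eps = 1.0
    if greenhouse_geisser:
        # epsilon from the double-centered covariance of trials
        S = np.cov(m, rowvar=False, ddof=1)
        Jc = np.eye(k) - np.ones((k, k)) / k
        Sc = Jc @ S @ Jc
        eig = np.linalg.eigvalsh(Sc)
        eig = eig[eig > 1e-12]
        eps = float((eig.sum() ** 2) / ((k - 1) * np.sum(eig**2)))
        eps = min(max(eps, 1.0 / (k - 1)), 1.0)
    p = float(sps.f.sf(F, df1 * eps, df2 * eps))
    return TestResult(
        float(F), p, p, df=float(df1), detail={"df2": df2, "epsilon": eps}
    )


# ---------------------------------------------------------------------------
# Bayes factors


def bf_ttest_jzs(
    t: float, n1: int, n2: int, prior_scale: float = 0.707
) -> BayesFactorResult:
    """JZS two-sample t-test Bayes factor.

    The alternative places a Cauchy(0, ``prior_scale``) prior on the
    standardized effect size (equivalently g ~ InverseGamma(1/2, r^2/2) on
    the Zellner-Siow g); BF10 is the ratio of the marginal likelihood under
    that prior to the point-null likelihood, computed by adaptive
    quadrature.  The default scale 0.707 is the conventional medium prior;
    a Westfall-Johnson-Utts-style adjustment is expressed by passing a
    different scale.
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("need n1, n2 >= 2")
    if not math.isfinite(t):
        raise ValidationError("t must be finite")
    r = prior_scale
    N = n1 * n2 / (n1 + n2)
    nu = n1 + n2 - 2

    def null_like(tt):
        return (1 + tt**2 / nu) ** (-(nu + 1) / 2)

    def integrand(g):
        c = 1.0 + N * g
        like = c**-0.5 * (1 + t**2 / (c * nu)) ** (-(nu + 1) / 2)
        prior = sps.invgamma.pdf(g, 0.5, scale=r**2 / 2)
        return like * prior

    num, err = integrate.quad(integrand, 0, np.inf, limit=200)
    if num <= 0 or err > 1e-6 * max(num, 1e-12):
        raise ValidationError(f"quadrature failed to converge (estimate {num}, abs err {err})")
    bf10 = num / null_like(t)
    return BayesFactorResult(float(bf10), prior=f"JZS Cauchy(0, {r})")


def bf_ab_proportions(
    a: ProportionSample, b: ProportionSample, prior: tuple[float, float] = (1.0, 1.0)
) -> BayesFactorResult:
    """Beta-Binomial A/B Bayes factor for two proportions, in closed form.

    H1 gives each group an independent Beta(``prior``) rate; H0 shares a
    single Beta(``prior``) rate.  BF10 is the ratio of marginal likelihoods
    (binomial coefficients cancel), via log-Beta functions.
    """
    a0, b0 = prior
    if a0 <= 0 or b0 <= 0:
        raise ValidationError("prior parameters must be > 0")
    log_m1 = (
        special.betaln(a0 + a.k, b0 + a.n - a.k)
        + special.betaln(a0 + b.k, b0 + b.n - b.k)
        - 2 * special.betaln(a0, b0)
    )
    log_m0 = special.betaln(a0 + a.k + b.k, b0 + (a.n - a.k) + (b.n - b.k)) - special.betaln(
        a0, b0
    )
    return BayesFactorResult(
        float(np.exp(log_m1 - log_m0)), prior=f"Beta({a0:g}, {b0:g})"
    )


def report(test: TestResult, bf: BayesFactorResult | None = None) -> dict:
    """JSON-ready record of one comparison with the figure glyph conventions."""
    out = {
        "statistic": test.statistic,
        "p_raw": test.p_raw,
        "p_adjusted": test.p_adjusted,
        "tails": test.tails,
        "alpha": test.alpha,
        "significant": test.significant,
        "glyph": test.glyph,
    }
    if bf is not None:
        out.update({"bf10": bf.bf10, "bf_category": bf.category, "bf_glyph": bf.glyph})
    return out
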