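"""Association statistics: odds ratios, confounder adjustment, rank tests.

Protein-level exposure is the presence of one or more native lasso
entanglements; residue-level exposure is membership in a natively
entangled region.  The outcome at both levels is an age-associated
structural change detected by LiP-MS.  Crude associations come from a
2×2 table (cross-product odds ratio, Woolf logit confidence interval,
two-sided Fisher exact p); adjusted associations come from a logistic
regression of the outcome on exposure and standardized protein length,

    log p/(1-p) = β0 + β1·E + β2·L*,

whose adjusted odds ratio is exp(β1) with a Wald interval.  Protein
abundance calls normalize the aged/young protein fold change by the
transcript fold change when the transcript itself changed (|log2 FC| > 1,
Welch p < 0.01), so that only post-transcriptional increases remain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyResult",
    "LogisticFit",
    "AbundanceCall",
    "contingency",
    "adjusted_or",
    "bootstrap_median_ci",
    "brunner_munzel",
    "abundance_calls",
]


@dataclass
class ContingencyResult:
    a: int  # exposed, outcome+
    b: int  # exposed, outcome-
    c: int  # unexposed, outcome+
    d: int  # unexposed, outcome-
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    undefined: bool = False

    @property
    def prevalence_overall(self) -> float:
        return 100.0 * (self.a + self.c) / (self.a + self.b + self.c + self.d)

    @property
    def prevalence_exposed(self) -> float:
        return 100.0 * self.a / (self.a + self.b)

    @property
    def prevalence_unexposed(self) -> float:
        return 100.0 * self.c / (self.c + self.d)

    def summary(self) -> str:
        return (
            f"2x2 table a={self.a} b={self.b} c={self.c} d={self.d}\n"
            f"OR = {self.odds_ratio:.2f} (95% CI [{self.ci_low:.2f}, "
            f"{self.ci_high:.2f}]), Fisher p = {self.p_value:.2e}\n"
            f"prevalence: overall {self.prevalence_overall:.1f}%, "
            f"exposed {self.prevalence_exposed:.1f}%, "
            f"unexposed {self.prevalence_unexposed:.1f}%"
        )


@dataclass
class LogisticFit:
    beta0: float
    beta1: float
    beta2: float
    adjusted_or: float
    ci: tuple
    p_value: float
    converged: bool = True


@dataclass
class AbundanceCall:
    protein: str
    protein_fc: float
    transcript_factor: float
    normalized_fc: float
    p_value: float
    increased: bool


def contingency(exposure=None, outcome=None, counts=None,
                haldane: bool = False) -> ContingencyResult:
    """Crude odds ratio with Woolf CI and two-sided Fisher exact test.

    Either give two equal-length boolean vectors or ``counts=(a, b, c, d)``
    directly.  With any zero cell the OR is undefined and flagged unless
    ``haldane`` adds the 0.5 continuity correction (off by default).
    """
    if counts is not None:
        a, b, c, d = (int(x) for x in counts)
    else:
        exposure = np.asarray(exposure, dtype=bool)
        outcome = np.asarray(outcome, dtype=bool)
        if exposure.shape != outcome.shape:
            raise ValueError("exposure and outcome must be equal length")
        a = int(np.sum(exposure & outcome))
        b = int(np.sum(exposure & ~outcome))
        c = int(np.sum(~exposure & outcome))
        d = int(np.sum(~exposure & ~outcome))
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    zero = min(a, b, c, d) == 0
    if zero and not haldane:
        return ContingencyResult(a, b, c, d, np.nan, np.nan, np.nan, float(p),
                                 undefined=True)
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if haldane else (a, b, c, d)
    or_ = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = stats.norm.ppf(0.975)
    lo, hi = np.exp(np.log(or_) - z * se), np.exp(np.log(or_) + z * se)
    return ContingencyResult(a, b, c, d, float(or_), float(lo), float(hi), float(p))


def adjusted_or(outcome, exposure, length) -> LogisticFit:
    """Length-adjusted odds ratio from a maximum-likelihood logistic fit.

    ``length`` is standardized (mean 0, SD 1) internally.  Returns
    exp(β1) with its Wald 95% CI and p-value.  Perfect separation or a
    constant exposure column is flagged as non-converged.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    e = np.asarray(exposure, dtype=float)
    ln = np.asarray(length, dtype=float)
    if len(y) < 10:
        raise ValueError("need n >= 10")
    if np.all(e == e[0]):
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, (np.nan, np.nan),
                           np.nan, converged=False)
    l_std = (ln - ln.mean()) / ln.std()
    X = sm.add_constant(np.column_stack([e, l_std]))
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception:
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, (np.nan, np.nan),
                           np.nan, converged=False)
    b0, b1, b2 = res.params
    ci_b1 = res.conf_int()[1]
    return LogisticFit(
        beta0=float(b0),
        beta1=float(b1),
        beta2=float(b2),
        adjusted_or=float(np.exp(b1)),
        ci=(float(np.exp(ci_b1[0])), float(np.exp(ci_b1[1]))),
        p_value=float(res.pvalues[1]),
        converged=converged,
    )


def bootstrap_median_ci(values, iterations: int = 1_000_000, seed: int = 0,
                        ci: float = 0.95):
    """Percentile bootstrap CI of the median.

    Resamples with replacement ``iterations`` times (chunked to bound
    memory) and returns ``(median, ci_low, ci_high)``; deterministic for
    a fixed seed.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    iterations = int(iterations)
    medians = np.empty(iterations)
    chunk = max(1, int(2e7) // n)
    pos = 0
    while pos < iterations:
        m = min(chunk, iterations - pos)
        idx = rng.integers(0, n, size=(m, n))
        medians[pos : pos + m] = np.median(x[idx], axis=1)
        pos += m
    tail = (1.0 - ci) / 2.0
    lo, hi = np.quantile(medians, [tail, 1.0 - tail])
    return float(np.median(x)), float(lo), float(hi)


def brunner_munzel(x, y, alternative: str = "greater") -> float:
    """One-sided Brunner–Munzel rank test p-value.

    ``alternative="greater"`` tests the hypothesis that values in ``x``
    tend to be larger than values in ``y``.  All-tied data are flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5 or len(y) < 5:
        raise ValueError("need n >= 5 per sample")
    if np.ptp(np.concatenate([x, y])) == 0:
        raise ValueError("all observations tied")
    with np.errstate(all="ignore"):
        res = stats.brunnermunzel(x, y, alternative=alternative, distribution="t")
        p = float(res.pvalue)
        if np.isnan(p):
            # complete separation: t degrees of freedom are 0/0; the
            # normal approximation gives the limiting p (0 or 1)
            res = stats.brunnermunzel(x, y, alternative=alternative,
                                      distribution="normal")
            p = float(res.pvalue)
    return p


def abundance_calls(
    protein_table: pd.DataFrame,
    transcript_table: pd.DataFrame | None = None,
    fc_gate: float = 1.0,
    alpha_gate: float = 0.01,
    alpha_call: float = 0.01,
) -> list:
    """Transcript-normalized protein abundance increase calls.

    ``protein_table``: per protein, replicate abundance columns
    ``young_*`` and ``aged_*`` plus a ``protein`` id column; likewise
    ``transcript_table``.  The protein fold change mean(aged)/mean(young)
    is divided by the transcript fold change only when the transcript
    passed the gate (|log2 FC| > ``fc_gate`` and Welch two-tailed
    p < ``alpha_gate``); a protein is called increased when the
    normalized FC exceeds 1 and its own Welch p < ``alpha_call``.
    """
    tr_by_protein: dict = {}
    if transcript_table is not None:
        for _, row in transcript_table.iterrows():
            young = row.filter(like="young_").to_numpy(dtype=float)
            aged = row.filter(like="aged_").to_numpy(dtype=float)
            if young.mean() <= 0:
                raise ValueError(f"zero mean young transcript for {row['protein']}")
            fc = aged.mean() / young.mean()
            _, p = stats.ttest_ind(aged, young, equal_var=False)
            gated = abs(np.log2(fc)) > fc_gate and p < alpha_gate
            tr_by_protein[row["protein"]] = fc if gated else 1.0
    calls = []
    for _, row in protein_table.iterrows():
        young = row.filter(like="young_").to_numpy(dtype=float)
        aged = row.filter(like="aged_").to_numpy(dtype=float)
        if young.mean() <= 0:
            raise ValueError(f"zero mean young abundance for {row['protein']}")
        fc = aged.mean() / young.mean()
        factor = tr_by_protein.get(row["protein"], 1.0)
        norm = fc / factor
        _, p = stats.ttest_ind(aged, young, equal_var=False)
        calls.append(
            AbundanceCall(
                protein=row["protein"],
                protein_fc=float(fc),
                transcript_factor=float(factor),
                normalized_fc=float(norm),
                p_value=float(p),
                increased=bool(norm > 1.0 and p < alpha_call),
            )
        )
    return calls
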