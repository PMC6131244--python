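"""Cross-sectional cohort statistics.

2x2 contingency analyses (e.g. point mutation vs AI at an oncogene locus),
exact hypergeometric overlap enrichment, burden-controlled logistic
regression for peak-peak and peak-phenotype association, per-tumor event
counts over curated peaks, dosage-expression testing, and multiple-testing
procedures. Logistic/OLS fits go through statsmodels; complete separation
falls back to a Firth-type penalized fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from . import intervals
from .peaks import Peak

logger = logging.getLogger("aiscape")


# ---------------------------------------------------------------------------
# contingency and hypergeometric
# ---------------------------------------------------------------------------

@dataclass
class ContingencyResult:
    a: int
    b: int
    c: int
    d: int
    row1_pct: int          # round(100 * a / (a+b))
    row2_pct: int          # round(100 * c / (c+d))
    odds_ratio: float
    fisher_p: float
    haldane_corrected: bool


def contingency_2x2(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Odds ratio, two-sided Fisher p and integer row percentages.

    Rows are (exposed: a successes, b failures) and (unexposed: c, d);
    a zero cell triggers the Haldane-Anscombe 0.5 correction for the OR
    (the Fisher test uses the raw table).
    """
    cells = (a, b, c, d)
    if any(v < 0 for v in cells):
        raise ValueError("cell counts must be non-negative")
    if a + b == 0 or c + d == 0 or sum(cells) == 0:
        raise ValueError("contingency table has an empty margin")
    corrected = 0 in cells
    af, bf, cf, df = ((v + 0.5 for v in cells) if corrected else map(float, cells))
    odds_ratio = (af * df) / (bf * cf)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return ContingencyResult(a, b, c, d,
                             round(100.0 * a / (a + b)),
                             round(100.0 * c / (c + d)),
                             float(odds_ratio), float(p), corrected)


def hypergeometric_tail(N: int, K: int, n: int, x: int) -> float:
    """Exact upper tail P(X >= x) for X ~ Hypergeom(N, K, n), in log space."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= x <= n):
        raise ValueError("inconsistent hypergeometric counts")
    if x > K:
        return 0.0

    def log_c(m, k):
        return gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1)

    ks = np.arange(x, min(n, K) + 1)
    ks = ks[(n - ks) <= (N - K)]
    if not len(ks):
        return 0.0
    terms = log_c(K, ks) + log_c(N - K, n - ks) - log_c(N, n)
    return float(np.exp(logsumexp(terms)))


# ---------------------------------------------------------------------------
# logistic association with Firth fallback
# ---------------------------------------------------------------------------

def _firth_logit(y: np.ndarray, X: np.ndarray, max_iter: int = 100,
                 tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Firth-penalized logistic regression (Jeffreys-prior score correction).

    Returns (coefficients, standard errors). Used when the ML fit separates.
    """
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        XtW = X.T * w
        info = XtW @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        # hat-matrix diagonal of the weighted design
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    se = np.sqrt(np.diag(info_inv))
    return beta, se


@dataclass
class LogisticResult:
    coef: float
    se: float
    p_value: float
    separated: bool
    n: int


def logistic_association(y, x, covariates=None) -> LogisticResult:
    """Wald test on the coefficient of ``x`` in logit(y) ~ x + covariates.

    Complete or quasi-separation is flagged and the fit redone with Firth
    penalization so a finite coefficient and p-value are still reported.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.min() == y.max():
        # constant outcome: no information; report the degenerate fit
        return LogisticResult(0.0, np.inf, 1.0, True, len(y))
    cols = [np.ones_like(x), x]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        # standardize covariates for numeric stability (does not change the
        # Wald test on x)
        sd = cov.std(axis=0)
        sd[sd == 0] = 1.0
        cols.extend(((cov - cov.mean(axis=0)) / sd).T)
    X = np.column_stack(cols)
    separated = False
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        coef, se = fit.params[1], fit.bse[1]
        if not np.isfinite(se) or abs(coef) > 15 or not fit.mle_retvals.get("converged", True):
            separated = True
    except Exception:
        separated = True
    if separated:
        beta, ses = _firth_logit(y, X)
        coef, se = beta[1], ses[1]
    z = coef / se
    p = 2.0 * stats.norm.sf(abs(z))
    return LogisticResult(float(coef), float(se), float(p), separated, len(y))


def _ai_indicator(segments: pd.DataFrame, samples: Sequence[str],
                  peak: Peak) -> np.ndarray:
    """Sample has AI of the peak's class overlapping the peak apex."""
    sel = segments[(segments["chrom"] == peak.chrom)
                   & (segments["klass"] == peak.klass)
                   & (segments["start"] < peak.apex_end)
                   & (segments["end"] > peak.apex_start)]
    carriers = set(sel["sample_id"])
    return np.array([s in carriers for s in samples])


def burden_excluding(segments: pd.DataFrame, samples: Sequence[str],
                     exclude_chroms: Sequence[str]) -> np.ndarray:
    """Per-sample AI basepairs summed over chromosomes not in the excluded set."""
    keep = segments[segments["klass"].isin(("gain", "loss"))
                    & ~segments["chrom"].isin(list(exclude_chroms))]
    out = np.zeros(len(samples))
    index = {s: i for i, s in enumerate(samples)}
    for (sample, _), grp in keep.groupby(["sample_id", "chrom"]):
        if sample in index:
            out[index[sample]] += intervals.total_length(
                grp["start"].to_numpy(), grp["end"].to_numpy())
    return out


def peak_pair_logistic(segments: pd.DataFrame, samples: Sequence[str],
                       peak_i: Peak, peak_j: Peak) -> LogisticResult:
    """Association between AI at two peaks, controlling for AI burden.

    Model: P(AI at peak_j) ~ 1{AI at peak_i} + AI burden on chromosomes
    other than both peaks' chromosomes. Requires the peaks to lie on
    different chromosomes and at least 30 samples.
    """
    if peak_i.chrom == peak_j.chrom:
        raise ValueError("peak pair must lie on different chromosomes")
    if len(samples) < 30:
        raise ValueError("need at least 30 samples")
    xi = _ai_indicator(segments, samples, peak_i).astype(float)
    yj = _ai_indicator(segments, samples, peak_j).astype(float)
    burden = burden_excluding(segments, samples, [peak_i.chrom, peak_j.chrom])
    return logistic_association(yj, xi, burden)


def phenotype_logistic(segments: pd.DataFrame, samples: Sequence[str],
                       peak: Peak, phenotype) -> LogisticResult:
    """P(AI at peak) ~ binary phenotype + AI burden on other chromosomes."""
    ph = np.asarray(phenotype, dtype=float)
    if set(np.unique(ph)) - {0.0, 1.0}:
        raise ValueError("phenotype must be binary 0/1")
    if ph.min() == ph.max():
        raise ValueError("single-class phenotype")
    y = _ai_indicator(segments, samples, peak).astype(float)
    burden = burden_excluding(segments, samples, [peak.chrom])
    return logistic_association(y, ph, burden)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def multiple_testing(pvalues, method: str = "fdr_bh") -> np.ndarray:
    """Adjusted p-values: ``bonferroni`` or ``fdr_bh`` (step-up, monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0,1]")
    if method not in ("bonferroni", "fdr_bh"):
        raise ValueError(f"unknown method {method!r}")
    return multipletests(p, method=method)[1]


# ---------------------------------------------------------------------------
# expression-dosage testing
# ---------------------------------------------------------------------------

def expression_dosage_test(expression: pd.DataFrame,
                           fdr: float = 0.10) -> pd.DataFrame:
    """Per-gene linear model expression ~ LRR + purity; BH across genes.

    ``expression`` is long format with columns gene, sample_id, lrr,
    expression and (optionally) purity; genes with zero LRR variance are
    skipped with a flag. Returns gene, slope, p, q, flagged columns.
    """
    rows = []
    for gene, grp in expression.groupby("gene"):
        lrr = grp["lrr"].to_numpy(dtype=float)
        y = grp["expression"].to_numpy(dtype=float)
        if lrr.std() == 0:
            rows.append({"gene": gene, "slope": 0.0, "p": np.nan,
                         "flagged": True})
            continue
        if y.std() == 0:
            # constant expression: no dosage response, nothing to test
            rows.append({"gene": gene, "slope": 0.0, "p": 1.0,
                         "flagged": False})
            continue
        cols = [np.ones_like(lrr), lrr]
        if "purity" in grp.columns:
            cols.append(grp["purity"].to_numpy(dtype=float))
        X = np.column_stack(cols)
        fit = sm.OLS(y, X).fit()
        p = float(fit.pvalues[1])
        # too few samples for residual df, or collinear design: untestable
        rows.append({"gene": gene, "slope": float(fit.params[1]),
                     "p": p, "flagged": not np.isfinite(p)})
    out = pd.DataFrame(rows)
    tested = out[~out["flagged"]]
    out["q"] = np.nan
    if len(tested):
        out.loc[tested.index, "q"] = multiple_testing(tested["p"].to_numpy(),
                                                      "fdr_bh")
    out["significant"] = out["q"] < fdr
    return out


# ---------------------------------------------------------------------------
# events per tumor over curated peaks
# ---------------------------------------------------------------------------

def events_per_tumor(segments: pd.DataFrame, samples: Sequence[str],
                     peaks: Sequence[Peak]) -> pd.Series:
    """Per-sample count of curated peaks showing AI of the expected class.

    Only gain segments count at gain-type peaks and loss segments at
    loss-type peaks; a peak counts at most once per sample.
    """
    counts = np.zeros(len(samples), dtype=int)
    for peak in peaks:
        counts += _ai_indicator(segments, samples, peak).astype(int)
    return pd.Series(counts, index=list(samples), name="peak_events")


@dataclass
class StratifiedEvents:
    group1: str
    group2: str
    mean1: float
    mean2: float
    median1: float
    median2: float
    mannwhitney_p: float
    n1: int
    n2: int


def stratified_event_summary(counts: pd.Series, groups: pd.Series,
                             group1: str, group2: str) -> StratifiedEvents:
    """Compare per-tumor event counts between two strata (Mann-Whitney)."""
    groups = groups.reindex(counts.index)
    a = counts[groups == group1].to_numpy()
    b = counts[groups == group2].to_numpy()
    if not len(a) or not len(b):
        raise ValueError("empty stratum")
    # normal approximation with tie correction
    _, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return StratifiedEvents(group1, group2, float(a.mean()), float(b.mean()),
                            float(np.median(a)), float(np.median(b)),
                            float(p), len(a), len(b))
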