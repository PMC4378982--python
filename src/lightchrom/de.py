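"""Replicate-free differential expression for count data.

The test compares two single count observations (no replicates) under a
negative-binomial model whose variance is borrowed from the genome-wide
mean-variance trend: counts are size-factor normalized, genes in the lower
expression quantile are dropped, a local regression of log variance on log
mean across all samples (conditions treated as blind pseudo-replicates)
supplies sigma^2(mu), and a conditional two-sided exact test is computed by
enumerating all splits (a, b) of the observed total a + b = k_t + k_c:

    p = sum_{f(a,b) <= f(k_t,k_c)} f(a,b) / sum f(a,b),

where f(a,b) is the product of the two NB marginal probabilities.  Genes
are called light-inducible when any light timepoint shows p < 0.05 and a
>= 2-fold increase over dark, and classified by the shape of their
induction profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import RunConfig, split_sample_label
from .synth import DARK, LIGHT_TIMEPOINTS

_TIE_SLACK = 1e-12


# ---------------------------------------------------------------------------
# Size factors and filtering
# ---------------------------------------------------------------------------

def estimate_size_factors(table: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over genes (positive in every sample) of
    k[i,j] / geometric_mean_i.
    """
    if table.shape[1] < 2:
        raise ValueError("size factors need at least 2 samples")
    counts = table.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in all samples; "
            "consider a pseudo-reference normalization"
        )
    sub = counts[positive]
    geomean = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / geomean[:, None], axis=0)
    return pd.Series(factors, index=table.columns, name="size_factor")


def filter_low_expression(
    table: pd.DataFrame,
    quantile: float = 0.20,
    size_factors: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Drop genes whose mean normalized count falls in the lower quantile."""
    if table.empty:
        raise ValueError("empty count table")
    if quantile <= 0:
        return table
    if size_factors is None:
        size_factors = estimate_size_factors(table)
    means = (table / size_factors).mean(axis=1)
    cutoff = means.quantile(quantile)
    return table.loc[means >= cutoff]


# ---------------------------------------------------------------------------
# Mean-variance trend
# ---------------------------------------------------------------------------

@dataclass
class DispersionFit:
    """Smoothed mapping mu -> sigma^2(mu), floored at sigma^2 = mu.

    Evaluation interpolates the fitted curve on the log-mean axis, is
    flat beyond the fitted range, and is nondecreasing by construction.
    """

    log_mu_grid: np.ndarray
    var_grid: np.ndarray
    span: float
    n_genes: int

    def __call__(self, mu):
        mu_arr = np.asarray(mu, dtype=float)
        scalar = mu_arr.ndim == 0
        mu_arr = np.atleast_1d(mu_arr)
        out = np.empty_like(mu_arr)
        pos = mu_arr > 0
        out[~pos] = 0.0
        if pos.any():
            interp = np.interp(np.log(mu_arr[pos]), self.log_mu_grid, self.var_grid)
            out[pos] = np.maximum(interp, mu_arr[pos])
        return float(out[0]) if scalar else out

    def dispersion(self, mu: float) -> float:
        """Scale-invariant dispersion phi = (sigma^2(mu) - mu) / mu^2."""
        if mu <= 0:
            return 0.0
        return max(0.0, (self(mu) - mu) / mu**2)


def fit_mean_variance(
    table: pd.DataFrame,
    size_factors: pd.Series,
    span: float = 0.3,
) -> DispersionFit:
    """Fit the mean-variance relationship across all samples.

    All samples are pooled as blind pseudo-replicates (the design has no
    replicates); per-gene mean and variance of normalized counts are
    smoothed with locally-weighted linear regression of log variance on
    log mean (nearest-neighbour span ``span``).  The returned mapping is
    floored at sigma^2(mu) = mu and made nondecreasing.
    """
    if table.shape[1] < 2:
        raise ValueError("mean-variance fit needs at least 2 samples")
    norm = table.to_numpy(dtype=float) / size_factors.to_numpy()
    mean = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    usable = (mean > 0) & (var > 0)
    if usable.sum() < 50:
        raise ValueError(
            f"only {int(usable.sum())} genes usable for the mean-variance fit "
            "(need >= 50); the fit would be unstable"
        )
    log_mu = np.log(mean[usable])
    log_var = np.log(var[usable])
    fitted = lowess(log_var, log_mu, frac=span, it=1, return_sorted=True)
    # the log of a sample variance is biased low: under a chi-square
    # approximation E[log s^2] = log sigma^2 + psi(nu/2) - log(nu/2) with
    # nu = n_samples - 1; undo that bias so the smoothed trend targets
    # log sigma^2 rather than E[log s^2]
    nu = table.shape[1] - 1
    bias = float(digamma(nu / 2.0) - np.log(nu / 2.0))
    grid_mu, grid_logvar = fitted[:, 0], fitted[:, 1] - bias
    grid_mu, idx = np.unique(grid_mu, return_index=True)
    grid_var = np.exp(grid_logvar[idx])
    # floor at the Poisson variance, then enforce monotonicity
    grid_var = np.maximum(grid_var, np.exp(grid_mu))
    grid_var = np.maximum.accumulate(grid_var)
    return DispersionFit(grid_mu, grid_var, span=span, n_genes=int(usable.sum()))


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------

@dataclass
class ExactTestResult:
    gene_id: str
    mean_treat: float      # normalized mean, treatment condition
    mean_control: float
    fold: float            # treat / control of normalized means, pseudo-count 0.5
    p: float


def _pmf_vector(a: np.ndarray, mu: float, var: float) -> np.ndarray:
    """NB pmf with mean/variance parameterization; Poisson when var <= mu."""
    if mu <= 0:
        out = np.zeros(len(a))
        out[a == 0] = 1.0
        return out
    if var <= mu * (1.0 + 1e-8):
        return stats.poisson.pmf(a, mu)
    r = mu**2 / (var - mu)
    return stats.nbinom.pmf(a, r, r / (r + mu))


def exact_test(
    k_t: int,
    k_c: int,
    s_t: float,
    s_c: float,
    fit: DispersionFit,
    gene_id: str = "",
) -> ExactTestResult:
    """Two-sided conditional NB exact test of two single counts.

    The common normalized mean mu0 = (k_t/s_t + k_c/s_c)/2 sets the null;
    condition means are mu0 scaled by each size factor, with variance
    mu_cond + phi * mu_cond^2 where the dispersion phi is read off the
    genome-wide trend at mu0.  The two-sided p sums f(a,b) over all splits
    with f(a,b) <= f(k_t,k_c), normalized by the total.
    """
    if k_t < 0 or k_c < 0:
        raise ValueError("counts must be nonnegative")
    if s_t <= 0 or s_c <= 0:
        raise ValueError("size factors must be positive")
    nt, nc = k_t / s_t, k_c / s_c
    fold = (nt + 0.5) / (nc + 0.5)
    total = k_t + k_c
    if total == 0:
        return ExactTestResult(gene_id, nt, nc, fold, 1.0)

    mu0 = (nt + nc) / 2.0
    phi = fit.dispersion(mu0)
    mu_t, mu_c = mu0 * s_t, mu0 * s_c
    var_t = mu_t + phi * mu_t**2
    var_c = mu_c + phi * mu_c**2

    a = np.arange(total + 1)
    f = _pmf_vector(a, mu_t, var_t) * _pmf_vector(a[::-1], mu_c, var_c)
    if not np.all(np.isfinite(f)):
        raise FloatingPointError("non-finite probability in exact test")
    denom = f.sum()
    if denom <= 0:
        raise FloatingPointError("degenerate probability mass in exact test")
    p = f[f <= f[k_t] * (1.0 + _TIE_SLACK)].sum() / denom
    return ExactTestResult(gene_id, nt, nc, fold, min(1.0, float(p)))


def exact_test_table(
    table: pd.DataFrame,
    sample_treat: str,
    sample_control: str,
    size_factors: pd.Series,
    fit: DispersionFit,
) -> pd.DataFrame:
    """Run the exact test for every gene between two samples."""
    s_t = float(size_factors[sample_treat])
    s_c = float(size_factors[sample_control])
    rows = []
    for gene_id, k_t, k_c in zip(
        table.index, table[sample_treat].to_numpy(), table[sample_control].to_numpy()
    ):
        r = exact_test(int(k_t), int(k_c), s_t, s_c, fit, gene_id=gene_id)
        rows.append((gene_id, r.mean_treat, r.mean_control, r.fold, r.p))
    return pd.DataFrame(
        rows, columns=["gene_id", "mean_treat", "mean_control", "fold", "p"]
    ).set_index("gene_id")


# ---------------------------------------------------------------------------
# Light-induction calling and classification
# ---------------------------------------------------------------------------

@dataclass
class GeneCalls:
    """Light-inducible gene set with per-gene class and genotype flags."""

    table: pd.DataFrame  # index gene_id; called, class, p_/fold_ per timepoint

    @property
    def light_inducible(self) -> List[str]:
        return self.table.index[self.table["called"]].tolist()


def call_light_induced(
    results_by_timepoint: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
    min_fold: float = 2.0,
) -> GeneCalls:
    """Call and classify light-inducible genes from per-timepoint tests.

    A gene is light-inducible if any light timepoint (30/60/120 min) shows
    p < alpha together with a >= min_fold increase over dark.  Called genes
    are classified: immediate-early when induction reaches >= 2-fold within
    30 min; otherwise early when the profile is maximal at 30 min and
    decreases afterwards; otherwise late.
    """
    tps = [t for t in LIGHT_TIMEPOINTS if t in results_by_timepoint]
    if not tps:
        raise ValueError("need at least one light timepoint (30/60/120) versus DD")
    genes = results_by_timepoint[tps[0]].index
    out = pd.DataFrame(index=genes)
    for t in tps:
        res = results_by_timepoint[t]
        out[f"p_{t}"] = res["p"]
        out[f"fold_{t}"] = res["fold"]

    called = np.zeros(len(genes), dtype=bool)
    for t in tps:
        up = out[f"fold_{t}"] >= min_fold
        called |= (out[f"p_{t}"] < alpha) & up
    out["called"] = called

    classes = []
    for gene in genes:
        if not out.at[gene, "called"]:
            classes.append("")
            continue
        folds = {t: out.at[gene, f"fold_{t}"] for t in tps}
        if folds.get("30", 0.0) >= 2.0:
            classes.append("immediate-early")
        elif "30" in folds and folds["30"] == max(folds.values()) and _decreasing_after_30(folds):
            classes.append("early")
        else:
            classes.append("late")
    out["class"] = classes
    return GeneCalls(out)


def _decreasing_after_30(folds: Dict[str, float]) -> bool:
    seq = [folds[t] for t in ("30", "60", "120") if t in folds]
    return all(a >= b for a, b in zip(seq, seq[1:]))


def compare_genotypes(
    ref_table: pd.DataFrame,
    alt_table: pd.DataFrame,
    light_genes: Sequence[str],
    direction: str,
    alpha: float = 0.05,
    timepoints: Sequence[str] = LIGHT_TIMEPOINTS,
) -> pd.DataFrame:
    """Flag light-inducible genes whose light response differs by genotype.

    For each gene, each light timepoint present in both tables is compared
    between genotypes with the exact test (size factors and mean-variance
    trend fitted on the pooled tables); a gene is flagged when any
    timepoint differs at p < alpha in the stated direction (``"lower"``:
    alt below ref, as for a knock-out; ``"higher"``: alt above ref, as for
    an over-expressor).
    """
    if direction not in ("lower", "higher"):
        raise ValueError("direction must be 'lower' or 'higher'")
    missing = [g for g in light_genes if g not in alt_table.index]
    if missing:
        raise ValueError(f"genes absent from the comparison table: {missing[:5]}")

    ref_tp = {split_sample_label(c)[1]: c for c in ref_table.columns}
    alt_tp = {split_sample_label(c)[1]: c for c in alt_table.columns}
    shared = [t for t in timepoints if t in ref_tp and t in alt_tp]
    if not shared:
        raise ValueError("no matched light timepoints across genotypes")

    pooled = ref_table.join(alt_table, how="inner", lsuffix="", rsuffix="_alt")
    sf = estimate_size_factors(pooled)
    fit = fit_mean_variance(pooled, sf)
    alt_cols = {t: alt_tp[t] if alt_tp[t] in pooled.columns else alt_tp[t] + "_alt" for t in shared}

    records = {}
    for t in shared:
        res = exact_test_table(
            pooled.loc[list(light_genes)], alt_cols[t], ref_tp[t], sf, fit
        )
        sign_ok = res["fold"] < 1.0 if direction == "lower" else res["fold"] > 1.0
        records[t] = (res["p"] < alpha) & sign_ok
    flags = pd.DataFrame(records, index=list(light_genes))
    flags["flagged"] = flags.any(axis=1)
    return flags


# ---------------------------------------------------------------------------
# End-to-end driver
# ---------------------------------------------------------------------------

def run_de(
    table: pd.DataFrame,
    genotype: str = "wt",
    config: Optional[RunConfig] = None,
) -> Tuple[GeneCalls, pd.Series, DispersionFit]:
    """Full differential-expression pass for one genotype.

    Normalizes, drops the lower expression quantile, fits the
    mean-variance trend on all samples, tests each light timepoint against
    dark, and calls/classifies light-inducible genes.  Returns the calls,
    the size factors and the fitted trend.
    """
    config = config or RunConfig()
    sf = estimate_size_factors(table)
    kept = filter_low_expression(table, config.low_expr_quantile, sf)
    fit = fit_mean_variance(kept, sf, span=config.lowess_span)

    cols = {split_sample_label(c)[1]: c for c in table.columns
            if split_sample_label(c)[0] == genotype}
    if DARK not in cols:
        raise ValueError(f"no dark (DD) sample for genotype {genotype!r}")
    results = {}
    for t in LIGHT_TIMEPOINTS:
        if t in cols:
            results[t] = exact_test_table(kept, cols[t], cols[DARK], sf, fit)
    if not results:
        raise ValueError(f"no light timepoints for genotype {genotype!r}")
    calls = call_light_induced(results, alpha=config.de_alpha, min_fold=config.de_min_fold)
    return calls, sf, fit
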