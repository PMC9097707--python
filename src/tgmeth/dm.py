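"""Filtering, QC and per-generation differential methylation testing.

The test is a beta-binomial Wald test on group-pooled methylation
proportions.  Per-site overdispersion phi is estimated by method of moments
on the beta-binomial variance Var(k) = n p (1-p) (1 + (n-1) phi) and shrunk
towards a genome-wide log-normal prior (empirical Bayes, prior strength d0
in residual-degree-of-freedom units).  The Wald variance of a group
proportion p_g = sum(k_i) / sum(n_i) is

    Var(p_g) = sum_i n_i p_g (1 - p_g) (1 + (n_i - 1) phi*) / (sum_i n_i)^2

and z = (p1 - p0) / sqrt(Var1 + Var0), two-sided normal p-value.  At
phi* = 0 this reduces exactly to the two-proportion z statistic on the
pooled counts.  A logistic-regression (binomial LRT) alternative is
provided for confirmation; with a single binary group covariate its MLE is
the pair of group proportions, so the LRT is computed in closed form.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import GENERATIONS, TREATMENT_EXPERIMENT
from .matrix import MethylationMatrix, SampleSheet, SiteKey
from .stats_util import adjust_bh, round_half_up

log = logging.getLogger(__name__)

PHI_MIN, PHI_MAX = 1e-6, 0.99


# --------------------------------------------------------------------------
# Comparison design
# --------------------------------------------------------------------------

@dataclass
class ComparisonDesign:
    """One treatment's 3-vs-9 testing design.

    Cases are grouped per generation; the control pool is every control
    sample of the matched experiment across F1+F2+F4 (controlling for
    generational drift by always testing against the same pool).
    """

    treatment: str
    experiment: str
    case_samples: dict[str, list[str]]     # generation -> sample ids
    control_samples: dict[str, list[str]]  # generation -> sample ids

    def __post_init__(self) -> None:
        cases = {s for v in self.case_samples.values() for s in v}
        controls = {s for v in self.control_samples.values() for s in v}
        if cases & controls:
            raise ValueError("case and control samples overlap")
        if not controls:
            raise ValueError("control pool is empty")
        for gen, ids in self.case_samples.items():
            if len(ids) < 2:
                raise ValueError(f"generation {gen}: fewer than 2 case samples")

    @property
    def control_pool(self) -> list[str]:
        return [s for g in GENERATIONS if g in self.control_samples
                for s in self.control_samples[g]]

    @property
    def all_samples(self) -> list[str]:
        cases = [s for g in GENERATIONS if g in self.case_samples
                 for s in self.case_samples[g]]
        return cases + self.control_pool

    @property
    def generations(self) -> list[str]:
        return [g for g in GENERATIONS if g in self.case_samples]

    @classmethod
    def from_samplesheet(cls, sheet: SampleSheet, treatment: str,
                         experiment: str | None = None) -> "ComparisonDesign":
        if experiment is None:
            exps = sheet.frame.loc[sheet.frame["treatment"] == treatment,
                                   "experiment"].unique()
            if len(exps) != 1:
                experiment = TREATMENT_EXPERIMENT.get(treatment)
                if experiment is None:
                    raise ValueError(
                        f"treatment {treatment!r} spans experiments {list(exps)}; "
                        "pass experiment explicitly")
            else:
                experiment = str(exps[0])
        case = {g: sheet.samples_for(treatment=treatment, generation=g,
                                     experiment=experiment)
                for g in GENERATIONS}
        ctrl = {g: sheet.samples_for(treatment="control", generation=g,
                                     experiment=experiment)
                for g in GENERATIONS}
        case = {g: v for g, v in case.items() if v}
        return cls(treatment=treatment, experiment=experiment,
                   case_samples=case, control_samples=ctrl)


@dataclass
class DMPSet:
    """Significant sites with direction (hyper/hypo) for one test."""

    sites: dict[SiteKey, str]
    label: str = ""

    def keys(self) -> set[SiteKey]:
        return set(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    def __contains__(self, key: SiteKey) -> bool:
        return key in self.sites


# --------------------------------------------------------------------------
# QC and global methylation
# --------------------------------------------------------------------------

def call_methylated_sites(matrix: MethylationMatrix) -> np.ndarray:
    """Per-sample % of genome CpGs called methylated.

    A site is called methylated in a sample iff total >= 1 and
    methylated/total >= 0.5; the denominator is every CpG in the matrix.
    """
    if matrix.n_sites == 0:
        raise ValueError("empty matrix")
    covered = matrix.total >= 1
    called = covered & (matrix.meth * 2 >= matrix.total)
    return 100.0 * called.sum(axis=0) / matrix.n_sites


def qc_samples(matrix: MethylationMatrix, sheet: SampleSheet | None = None,
               mean_cov_min: float = 1.0, median_cov_min: float = 5.0,
               pct_meth_quantile: float = 0.97) -> pd.DataFrame:
    """Advisory per-sample QC report.

    Flags samples with mean coverage < 1X or median coverage < 5X, and
    samples whose global %methylated strictly exceeds the 97th percentile of
    the non-low-coverage samples.
    """
    mean_cov = matrix.total.mean(axis=0)
    median_cov = np.median(matrix.total, axis=0)
    pct = call_methylated_sites(matrix)
    low = (mean_cov < mean_cov_min) | (median_cov < median_cov_min)
    remaining = pct[~low]
    if remaining.size:
        cutoff = float(np.quantile(remaining, pct_meth_quantile))
        outlier = pct > cutoff
    else:
        cutoff = float("nan")
        outlier = np.zeros(len(pct), dtype=bool)
    report = pd.DataFrame({
        "sample_id": matrix.samples,
        "mean_coverage": mean_cov,
        "median_coverage": median_cov,
        "pct_methylated": pct,
        "flag_low_coverage": low,
        "flag_meth_outlier": outlier,
    })
    report.attrs["pct_meth_cutoff"] = cutoff
    return report


# --------------------------------------------------------------------------
# Filters and normalisation
# --------------------------------------------------------------------------

def filter_min_coverage(matrix: MethylationMatrix, sample_ids: list[str],
                        min_total: int = 5) -> MethylationMatrix:
    """Keep sites where every listed sample has total >= min_total."""
    idx = matrix.sample_index(sample_ids)
    mask = (matrix.total[:, idx] >= min_total).all(axis=1)
    if not mask.any():
        warnings.warn("min-coverage filter removed every site", stacklevel=2)
    return matrix.subset_sites(mask)


def normalize_median_coverage(matrix: MethylationMatrix,
                              sample_ids: list[str] | None = None
                              ) -> MethylationMatrix:
    """Median-coverage library scaling.

    The scaling factor of sample i is (median of per-sample medians) /
    median_i, with medians computed over sites with total > 0; counts are
    multiplied and rounded half-up, with methylated capped at total.
    """
    if sample_ids is None:
        sample_ids = list(matrix.samples)
    idx = matrix.sample_index(sample_ids)
    medians = np.empty(len(idx))
    for k, j in enumerate(idx):
        covered = matrix.total[:, j] > 0
        if not covered.any():
            raise ValueError(f"sample {matrix.samples[j]!r} has all-zero coverage; "
                             "scaling factor undefined")
        medians[k] = np.median(matrix.total[covered, j])
    reference = float(np.median(medians))
    meth = matrix.meth.copy()
    total = matrix.total.copy()
    for k, j in enumerate(idx):
        factor = reference / medians[k]
        total[:, j] = round_half_up(matrix.total[:, j] * factor)
        meth[:, j] = np.minimum(round_half_up(matrix.meth[:, j] * factor),
                                total[:, j])
    return MethylationMatrix(matrix.sites.reset_index(drop=True),
                             list(matrix.samples), meth, total)


def filter_variability(matrix: MethylationMatrix, sample_ids: list[str],
                       sd_min: float = 0.5) -> MethylationMatrix:
    """Keep sites whose percent-methylation SD across the listed samples is
    >= sd_min percentage points (inclusive)."""
    idx = matrix.sample_index(sample_ids)
    total = matrix.total[:, idx]
    if np.any(total == 0):
        raise ValueError("variability filter requires coverage > 0 everywhere; "
                         "apply the min-coverage filter first")
    pct = 100.0 * matrix.meth[:, idx] / total
    sd = pct.std(axis=1, ddof=1)
    return matrix.subset_sites(sd >= sd_min)


def prepare_comparison(matrix: MethylationMatrix, design: ComparisonDesign,
                       min_total: int = 5, sd_min: float = 0.5,
                       normalize: bool = True) -> MethylationMatrix:
    """Apply the standard filter chain for one comparison.

    Order: min-coverage filter, median-coverage normalisation, variability
    filter - each over all case + control samples of the comparison.
    """
    samples = design.all_samples
    sub = matrix.subset_samples(samples)
    n0 = sub.n_sites
    sub = filter_min_coverage(sub, samples, min_total=min_total)
    n1 = sub.n_sites
    if normalize:
        sub = normalize_median_coverage(sub, samples)
    sub = filter_variability(sub, samples, sd_min=sd_min)
    log.info("%s: %d sites -> %d after coverage >= %d -> %d after SD >= %.2f",
             design.treatment, n0, n1, min_total, sub.n_sites, sd_min)
    return sub


# --------------------------------------------------------------------------
# Dispersion estimation and shrinkage
# --------------------------------------------------------------------------

def estimate_dispersion(meth: np.ndarray, total: np.ndarray,
                        case_idx: np.ndarray, control_idx: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments raw phi per site, plus residual degrees of freedom.

    Residuals are taken around each group's pooled proportion p = K/N.  The
    moment equation accounts for p being estimated from the same counts:
    with Var(k_i) = p q [n_i + n_i (n_i - 1) phi],

        E[sum_i (k_i - n_i p)^2] = p q (A0 + A1 phi),
        A0 = N - sum(n_i^2) / N,
        A1 = sum n_i (n_i - 1) (1 - 2 n_i / N) + (sum n_i^2 / N^2) sum n_i (n_i - 1)

    (for equal n this reduces to the classic S = pq n (m-1) (1 + (n-1) phi)).
    Numerator and denominator are pooled over the two groups before solving;
    raw values are clamped to [1e-6, 0.99].
    """
    num = np.zeros(meth.shape[0])
    den = np.zeros(meth.shape[0])
    dof = np.zeros(meth.shape[0])
    k_all = np.zeros(meth.shape[0])
    n_all = np.zeros(meth.shape[0])
    for idx in (case_idx, control_idx):
        k = meth[:, idx].astype(float)
        n = total[:, idx].astype(float)
        N = n.sum(axis=1)
        safeN = np.maximum(N, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(N > 0, k.sum(axis=1) / safeN, 0.0)
        pq = p * (1 - p)
        S = ((k - n * p[:, None]) ** 2).sum(axis=1)
        sum_n2 = (n ** 2).sum(axis=1)
        sum_nn1 = (n * (n - 1)).sum(axis=1)
        a0 = N - sum_n2 / safeN
        a1 = ((n * (n - 1) * (1 - 2 * n / safeN[:, None])).sum(axis=1)
              + sum_n2 / safeN ** 2 * sum_nn1)
        num += S - pq * a0
        den += pq * a1
        dof += np.maximum((n > 0).sum(axis=1) - 1, 0)
        k_all += k.sum(axis=1)
        n_all += n.sum(axis=1)
    # a site only carries dispersion information when both allele classes
    # have real mass in the comparison (otherwise the MoM estimate is
    # clamp-censored noise that would distort the shrinkage prior)
    informative = (k_all >= 5) & (n_all - k_all >= 5)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(den > 0, num / np.where(den > 0, den, 1.0), PHI_MIN)
    return np.clip(phi, PHI_MIN, PHI_MAX), dof, informative


def shrink_dispersion(phi_raw: np.ndarray, dof: np.ndarray,
                      d0: float = 20.0, min_sites_for_prior: int = 50,
                      informative: np.ndarray | None = None) -> np.ndarray:
    """Empirical-Bayes shrinkage of log-dispersions toward a log-normal prior.

    phi*_s = exp(w_s log phi_s + (1 - w_s) mu0) with w_s = d_s / (d_s + d0).
    The prior location mu0 is fitted robustly as the median of raw log-phi
    over the dispersion-informative sites (``informative`` mask from
    :func:`estimate_dispersion`; at sparsely methylated sites the raw MoM
    value is clamp-censored noise and would drag the prior to the clamp).  A
    fixed prior log(0.01) is used with a warning when fewer than
    ``min_sites_for_prior`` informative sites are available.
    """
    phi_raw = np.asarray(phi_raw, dtype=float)
    if phi_raw.size == 0:
        return phi_raw.copy()
    log_phi = np.log(np.clip(phi_raw, PHI_MIN, PHI_MAX))
    fit_values = log_phi if informative is None else log_phi[np.asarray(informative)]
    if fit_values.size < min_sites_for_prior:
        warnings.warn(
            f"only {fit_values.size} sites available for dispersion prior; "
            "falling back to fixed prior mean log(0.01)", stacklevel=2)
        mu0 = np.log(0.01)
    else:
        mu0 = float(np.median(fit_values))
    w = np.asarray(dof, dtype=float) / (np.asarray(dof, dtype=float) + d0)
    return np.clip(np.exp(w * log_phi + (1 - w) * mu0), PHI_MIN, PHI_MAX)


# --------------------------------------------------------------------------
# Tests
# --------------------------------------------------------------------------

def _group_stats(meth: np.ndarray, total: np.ndarray, idx: np.ndarray,
                 phi: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    k = meth[:, idx].astype(float)
    n = total[:, idx].astype(float)
    tot_n = n.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot_n > 0, k.sum(axis=1) / np.maximum(tot_n, 1), np.nan)
    var = (n * (p * (1 - p))[:, None] * (1 + (n - 1) * phi[:, None])).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.where(tot_n > 0, var / np.maximum(tot_n, 1) ** 2, np.nan)
    return p, var, tot_n


def betabinom_wald_test(matrix: MethylationMatrix, case_ids: list[str],
                        control_ids: list[str],
                        phi_star: np.ndarray | float) -> pd.DataFrame:
    """Beta-binomial Wald test of case vs control pooled proportions.

    Returns one row per site with p_case, p_control, meth_diff (percentage
    points), phi, z, p_value and BH q_value.  Sites where either group has
    zero total coverage are skipped (count in ``attrs['n_skipped']``).
    Degenerate sites (both groups at 0 or 1) get z = 0, p = 1.
    """
    phi = np.broadcast_to(np.asarray(phi_star, dtype=float),
                          (matrix.n_sites,)).astype(float)
    ci = matrix.sample_index(case_ids)
    gi = matrix.sample_index(control_ids)
    p1, v1, n1 = _group_stats(matrix.meth, matrix.total, ci, phi)
    p0, v0, n0 = _group_stats(matrix.meth, matrix.total, gi, phi)
    ok = (n1 > 0) & (n0 > 0)
    n_skipped = int((~ok).sum())

    var = v1 + v0
    diff = p1 - p0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, diff / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    p_val = np.where(var > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)

    df = pd.DataFrame({
        "chrom": matrix.sites["chrom"], "pos": matrix.sites["pos"],
        "p_case": p1, "p_control": p0, "meth_diff": 100.0 * diff,
        "phi": phi, "z": z, "p_value": p_val,
    })
    df = df.loc[ok].reset_index(drop=True)
    df["q_value"] = adjust_bh(df["p_value"].to_numpy())
    df.attrs["n_skipped"] = n_skipped
    if n_skipped:
        log.info("Wald test: skipped %d site(s) with zero group coverage", n_skipped)
    return df


def _binom_ll(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood kernel (coefficient terms omitted; 0 log 0 = 0)."""
    p = np.clip(p, 0.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t1 = np.where(k > 0, k * np.log(np.where(p > 0, p, 1.0)), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log(np.where(p < 1, 1 - p, 1.0)), 0.0)
    ll = t1 + t2
    # impossible data under the restricted model (k > 0 with p = 0, etc.)
    ll = np.where((k > 0) & (p == 0), -np.inf, ll)
    ll = np.where((n - k > 0) & (p == 1), -np.inf, ll)
    return ll


def logistic_regression_test(matrix: MethylationMatrix, case_ids: list[str],
                             control_ids: list[str]) -> pd.DataFrame:
    """Binomial (logistic) regression on a group indicator, LRT p-values.

    With a single binary covariate the MLE of the full model is the pair of
    group pooled proportions and the null MLE is the overall pooled
    proportion, so the likelihood-ratio statistic is computed exactly.
    """
    ci = matrix.sample_index(case_ids)
    gi = matrix.sample_index(control_ids)
    k1 = matrix.meth[:, ci].sum(axis=1).astype(float)
    n1 = matrix.total[:, ci].sum(axis=1).astype(float)
    k0 = matrix.meth[:, gi].sum(axis=1).astype(float)
    n0 = matrix.total[:, gi].sum(axis=1).astype(float)
    ok = (n1 > 0) & (n0 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(n1 > 0, k1 / np.maximum(n1, 1), np.nan)
        p0 = np.where(n0 > 0, k0 / np.maximum(n0, 1), np.nan)
        pp = (k1 + k0) / np.maximum(n1 + n0, 1)
    ll_full = _binom_ll(k1, n1, p1) + _binom_ll(k0, n0, p0)
    ll_null = _binom_ll(k1, n1, pp) + _binom_ll(k0, n0, pp)
    lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    p_val = stats.chi2.sf(lrt, df=1)
    p_val = np.where(lrt == 0, 1.0, p_val)

    df = pd.DataFrame({
        "chrom": matrix.sites["chrom"], "pos": matrix.sites["pos"],
        "p_case": p1, "p_control": p0, "meth_diff": 100.0 * (p1 - p0),
        "lrt": lrt, "p_value": p_val,
    })
    df = df.loc[ok].reset_index(drop=True)
    df["q_value"] = adjust_bh(df["p_value"].to_numpy())
    df.attrs["n_skipped"] = int((~ok).sum())
    return df


def call_dmps(result: pd.DataFrame, fdr: float = 0.05,
              label: str = "") -> DMPSet:
    """Sites with q <= fdr; direction from the sign of meth_diff."""
    hits = result[(result["q_value"] <= fdr) & (result["meth_diff"] != 0)]
    sites = {(c, int(p)): ("hyper" if d > 0 else "hypo")
             for c, p, d in zip(hits["chrom"], hits["pos"], hits["meth_diff"])}
    return DMPSet(sites=sites, label=label)


def test_generation(prepared: MethylationMatrix, case_ids: list[str],
                    control_ids: list[str], d0: float = 20.0,
                    method: str = "wald") -> pd.DataFrame:
    """Dispersion estimation + shrinkage + test for one generation's comparison."""
    if method == "logistic":
        return logistic_regression_test(prepared, case_ids, control_ids)
    if method != "wald":
        raise ValueError("method must be 'wald' or 'logistic'")
    ci = prepared.sample_index(case_ids)
    gi = prepared.sample_index(control_ids)
    phi_raw, dof, informative = estimate_dispersion(prepared.meth,
                                                    prepared.total, ci, gi)
    phi_star = shrink_dispersion(phi_raw, dof, d0=d0, informative=informative)
    return betabinom_wald_test(prepared, case_ids, control_ids, phi_star)


def run_comparison(matrix: MethylationMatrix, design: ComparisonDesign,
                   fdr: float = 0.05, min_total: int = 5, sd_min: float = 0.5,
                   d0: float = 20.0, method: str = "wald",
                   normalize: bool = True
                   ) -> tuple[dict[str, pd.DataFrame], dict[str, DMPSet]]:
    """Full per-generation analysis for one treatment (filters + 3-vs-9 tests).

    BH adjustment happens inside each generation's test, never pooled across
    generations or treatments.
    """
    prepared = prepare_comparison(matrix, design, min_total=min_total,
                                  sd_min=sd_min, normalize=normalize)
    results: dict[str, pd.DataFrame] = {}
    dmps: dict[str, DMPSet] = {}
    for gen in design.generations:
        res = test_generation(prepared, design.case_samples[gen],
                              design.control_pool, d0=d0, method=method)
        results[gen] = res
        dmps[gen] = call_dmps(res, fdr=fdr, label=f"{design.treatment}:{gen}")
    return results, dmps
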