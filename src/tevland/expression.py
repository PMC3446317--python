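"""TEV-expression association: resampled differential expression and the
CTCF flanking-gene variance test.

Linking a TEV to an expression change is confounded by everything else that
segregates with it, so instead of one carrier-vs-noncarrier test the
resampling procedure repeatedly (default 100x) draws two carrier and two
non-carrier strains, tests the resulting 4-vs-4 count tables with a
negative-binomial test under a 10% BH FDR, and calls a gene only when it is
significant in at least one-third of the draws.  A matched sample of
TEV-free genes rides along in every table so the FDR operates on a
realistic p-value mixture.

The inner test is a two-sided conditional negative-binomial test with a
pooled method-of-moments dispersion (exact-style tail summation over the
conditional distribution of the group-A sum given the grand total); it
reduces to the conditional Poisson (binomial) test as dispersion -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stats import bh_adjust

__all__ = [
    "normalize_counts", "size_factors", "nb_test", "resampled_de",
    "DEResult", "ctcf_variance_test",
]


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (reference = per-gene geometric mean).

    Factors are rescaled so their median is 1: a sample scaled k-fold
    against an otherwise homogeneous panel gets factor k.
    """
    if (matrix.sum(axis=0) <= 0).any():
        raise ValueError("every sample needs a positive total count")
    log = np.log(matrix.replace(0, np.nan))
    ref = log.mean(axis=1)
    ok = ref.notna()
    factors = np.exp((log[ok].sub(ref[ok], axis=0)).median(axis=0))
    return factors / factors.median()


def normalize_counts(matrix: pd.DataFrame) -> pd.DataFrame:
    """Size-factor-scale a count matrix; genes with no expression anywhere
    are dropped."""
    keep = matrix.sum(axis=1) > 0
    m = matrix[keep]
    return m.div(size_factors(m), axis=1)


def _pooled_dispersion(a: np.ndarray, b: np.ndarray) -> float:
    """Method-of-moments NB dispersion pooled across the two groups."""
    disp = []
    for g in (a, b):
        m = g.mean()
        v = g.var(ddof=1)
        if m > 0:
            disp.append(max((v - m) / m ** 2, 0.0))
    return float(np.mean(disp)) if disp else 0.0


def nb_test(group_a, group_b, dispersion: float | None = None) -> float:
    """Two-sided NB test of equal means between two count groups.

    Conditions on the grand total S: under the null both group sums follow
    negative binomials with a common per-sample mean, and the p-value sums
    the probabilities of all splits of S no more likely than the observed
    one.  ``dispersion`` (var = mu + disp * mu^2) defaults to the pooled
    method-of-moments estimate; 0 gives the Poisson limit.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    if dispersion is None:
        dispersion = _pooled_dispersion(a, b)
    ka, kb = a.sum(), b.sum()
    s = int(ka + kb)
    if s == 0:
        return 1.0
    na, nb_ = len(a), len(b)
    mu = s / (na + nb_)
    k = np.arange(s + 1)
    if dispersion <= 1e-12:
        pa = stats.poisson.logpmf(k, na * mu)
        pb = stats.poisson.logpmf(k[::-1], nb_ * mu)
    else:
        size_a = na / dispersion
        size_b = nb_ / dispersion
        pa = stats.nbinom.logpmf(k, size_a, size_a / (size_a + na * mu))
        pb = stats.nbinom.logpmf(k[::-1], size_b,
                                 size_b / (size_b + nb_ * mu))
    joint = pa + pb
    joint -= joint.max()
    w = np.exp(joint)
    total = w.sum()
    obs = w[int(ka)]
    p = w[w <= obs * (1 + 1e-12)].sum() / total
    return float(min(p, 1.0))


@dataclass
class DEResult:
    gene: str
    tev_id: str
    n_tests_called: int
    n_tests_run: int
    called: bool
    reason: str | None = None


def resampled_de(matrix: pd.DataFrame, tev_genes: pd.DataFrame,
                 n_resample: int = 100, fdr: float = 0.10,
                 seed: int = 0, dispersion: float | None = None
                 ) -> list[DEResult]:
    """Resampled differential-expression calls for genes carrying a TEV.

    ``matrix`` is a raw gene x sample count matrix with ``strain.replicate``
    headers (two replicates per strain).  ``tev_genes`` has one row per
    (gene, tev_id) with a ``carriers`` column: the iterable of strains
    carrying the TEV.  Per resampling, two carrier and two non-carrier
    strains are drawn without replacement, each tested gene is paired with
    a random TEV-free gene, the 4-vs-4 tables are NB-tested and BH-corrected
    at ``fdr`` across the whole table; a gene is called when it is
    significant in at least ceil(n_resample / 3) resamplings.  Genes with
    fewer than two strains on either side are skipped with a reason.
    """
    rng = np.random.default_rng(seed)
    norm = normalize_counts(matrix)
    samples = list(norm.columns)
    strains = sorted({c.rsplit(".", 1)[0] for c in samples})
    reps = {s: [c for c in samples if c.rsplit(".", 1)[0] == s]
            for s in strains}
    tev_gene_set = set(tev_genes["gene"])
    free_genes = [g for g in norm.index if g not in tev_gene_set]

    testable, results = [], []
    for _, row in tev_genes.iterrows():
        carriers = [s for s in row["carriers"] if s in strains]
        noncarriers = [s for s in strains if s not in set(row["carriers"])]
        if row["gene"] not in norm.index:
            results.append(DEResult(row["gene"], row["tev_id"], 0, 0, False,
                                    reason="no_expression"))
        elif len(carriers) < 2 or len(noncarriers) < 2:
            results.append(DEResult(row["gene"], row["tev_id"], 0, 0, False,
                                    reason="too_few_strains"))
        else:
            testable.append((row["gene"], row["tev_id"], carriers,
                             noncarriers))

    hits = {(g, t): 0 for g, t, _, _ in testable}
    threshold = int(np.ceil(n_resample / 3))
    for _ in range(n_resample):
        pvals, keys = [], []
        for g, t, carriers, noncarriers in testable:
            ca = rng.choice(carriers, size=2, replace=False)
            nc = rng.choice(noncarriers, size=2, replace=False)
            cols_a = [c for s in ca for c in reps[s]]
            cols_b = [c for s in nc for c in reps[s]]
            va = norm.loc[g, cols_a].to_numpy()
            vb = norm.loc[g, cols_b].to_numpy()
            pvals.append(nb_test(np.round(va), np.round(vb), dispersion))
            keys.append((g, t))
            if free_genes:
                ctrl = free_genes[rng.integers(len(free_genes))]
                pvals.append(nb_test(
                    np.round(norm.loc[ctrl, cols_a].to_numpy()),
                    np.round(norm.loc[ctrl, cols_b].to_numpy()), dispersion))
                keys.append(None)
        q = bh_adjust(pvals)
        for key, qv in zip(keys, q):
            if key is not None and qv < fdr:
                hits[key] += 1
    for g, t, _, _ in testable:
        n = hits[(g, t)]
        results.append(DEResult(g, t, n, n_resample, n >= threshold))
    return results


def ctcf_variance_test(ratios: pd.DataFrame, n_perm: int = 10_000,
                       seed: int = 0) -> tuple[float, float]:
    """Do CTCF-binding TEVs inflate expression variance between their
    flanking genes?

    ``ratios`` has one row per (tev, strain) with columns ``tev_id``,
    ``ctcf`` (bool), ``carrier`` (bool) and ``log_ratio`` =
    ln(upstream / downstream expression), the up/down assignment having
    been randomized upstream.  The statistic is a robust (Brown-Forsythe)
    one-way ANOVA of carrier vs non-carrier absolute deviations from group
    medians, over the CTCF-flagged TEVs.  The empirical p is the fraction
    of ``n_perm`` equally sized random samples of non-CTCF TEVs whose
    ANOVA p is smaller, floored at ``1/(n_perm + 1)``.

    Returns (anova_p, p_empirical).
    """
    rng = np.random.default_rng(seed)
    df = ratios.dropna(subset=["log_ratio"])

    def anova_p(sub: pd.DataFrame) -> float:
        g1 = sub.loc[sub["carrier"], "log_ratio"].to_numpy()
        g0 = sub.loc[~sub["carrier"], "log_ratio"].to_numpy()
        if len(g1) < 2 or len(g0) < 2:
            return float("nan")
        if np.ptp(g1) == 0 and np.ptp(g0) == 0:
            return 1.0
        return float(stats.levene(g1, g0, center="median").pvalue)

    ctcf_ids = df.loc[df["ctcf"], "tev_id"].unique()
    other_ids = df.loc[~df["ctcf"], "tev_id"].unique()
    if len(ctcf_ids) == 0:
        raise ValueError("no CTCF-flagged TEVs")
    obs_p = anova_p(df[df["tev_id"].isin(ctcf_ids)])

    k = len(ctcf_ids)
    smaller = 0
    by_id = dict(tuple(df[~df["ctcf"]].groupby("tev_id")))
    for _ in range(n_perm):
        pick = rng.choice(other_ids, size=min(k, len(other_ids)),
                          replace=True)
        sub = pd.concat([by_id[i] for i in pick], ignore_index=True)
        if anova_p(sub) < obs_p:
            smaller += 1
    p_emp = (1 + smaller) / (n_perm + 1)
    return obs_p, float(p_emp)
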