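"""Closed-form selection and mutation-bias statistics.

* orientation bias of intronic TEVs (sense fraction; 0.5 under neutrality)
  and the fraction of sense insertions inferred purged;
* male germline insertion bias ``alpha`` from X vs autosome densities,
  ``alpha = (3r - 4) / (2 - 3r)`` with ``r = X/A``; ``r <= 2/3`` implies an
  exclusively male insertion pattern (``alpha = inf``);
* ERV provirus -> solo-LTR recombination half-life,
  ``lambda = Y * log(1/2) / log(Z)`` for divergence ``Y`` (My) and observed
  proviral fraction ``Z``, plus a per-event maximum-likelihood fit;
* an adaptation of the McDonald-Kreitman test to chromosomal TE densities:
  a per-chromosome G-test of the observed TEV count against the count
  expected from the distribution of apparently fixed TEs;
* local-GC (20 kb window) profiles of TEV families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .stats import bh_adjust

__all__ = [
    "orientation_bias", "chi_square_2x2", "deleterious_sense_fraction",
    "alpha_from_ratio", "male_bias_alpha", "AlphaResult",
    "solo_ltr_half_life", "fit_half_life", "mk_g_test", "gc_profile",
]


def orientation_bias(n_sense: int, n_antisense: int) -> float:
    """Fraction of TEVs in the host gene's transcriptional sense orientation."""
    if n_sense < 0 or n_antisense < 0:
        raise ValueError("counts must be non-negative")
    total = n_sense + n_antisense
    if total == 0:
        raise ValueError("orientation bias undefined for zero TEVs")
    return n_sense / total


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined for an empty row or column")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


def deleterious_sense_fraction(bias: float) -> float:
    """Fraction of sense insertions inferred purged, from the end-state bias.

    Assumes antisense insertions are neutral: the surviving sense/antisense
    ratio ``bias/(1-bias)`` is the retained fraction of an initially equal
    split, so ``1 - bias/(1-bias)`` of sense insertions were deleterious.
    Clipped at zero when the bias exceeds one half.
    """
    if not 0 < bias < 1:
        raise ValueError("bias must lie strictly between 0 and 1")
    return max(0.0, 1.0 - bias / (1.0 - bias))


def alpha_from_ratio(r: float) -> float:
    """Male insertion bias implied by the X/autosome density ratio ``r``.

    ``alpha = (3r - 4)/(2 - 3r)``; ``r <= 2/3`` maps to +inf (exclusively
    male); the result is only meaningful for ``r`` in (2/3, 4/3).
    """
    if r <= 2.0 / 3.0:
        return math.inf
    return (3.0 * r - 4.0) / (2.0 - 3.0 * r)


@dataclass
class AlphaResult:
    alpha: float
    ci_low: float
    ci_high: float
    ratio: float
    flagged: bool  # ratio outside (2/3, 4/3): alpha not meaningful as-is


def male_bias_alpha(n_x: int, n_a: int, x_bases: float, a_bases: float,
                    resamples: int = 1000, seed: int = 0) -> AlphaResult:
    """Male insertion bias with a bootstrap percentile CI.

    ``n_x``/``n_a`` are TEV counts on the X and autosomes, ``x_bases`` /
    ``a_bases`` the corresponding (GC-accounted) base totals.  The CI
    resamples the chromosome labels of the pooled TEVs (binomial bootstrap
    over positions); resampled ratios at or below 2/3 contribute +inf, so
    upper bounds can be infinite.
    """
    if min(x_bases, a_bases) <= 0:
        raise ValueError("base totals must be positive")
    if n_x < 0 or n_a < 0 or n_x + n_a == 0:
        raise ValueError("need a positive TEV count")
    r = (n_x / x_bases) / (n_a / a_bases)
    alpha = alpha_from_ratio(r)
    flagged = not (2.0 / 3.0 < r < 4.0 / 3.0)

    rng = np.random.default_rng(seed)
    n = n_x + n_a
    bx = rng.binomial(n, n_x / n, size=resamples)
    ba = n - bx
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = (bx / x_bases) / np.maximum(ba, 1) * a_bases
    alphas = np.array([alpha_from_ratio(v) if v > 0 else math.inf for v in rr])
    # nearest-rank percentiles: infinite upper bounds survive (no interpolation)
    lo, hi = np.percentile(alphas, [2.5, 97.5], method="nearest")
    return AlphaResult(alpha=float(alpha), ci_low=float(lo), ci_high=float(hi),
                       ratio=float(r), flagged=flagged)


def solo_ltr_half_life(divergence_my: float, proviral_fraction: float) -> float:
    """Half-life of provirus -> solo-LTR recombination, in My.

    ``lambda = Y * log(1/2) / log(Z)`` with ``Y`` the divergence time and
    ``Z`` the fraction of ERVs still proviral; assumes a constant rate and
    that every ERV inserts as a provirus.
    """
    if divergence_my <= 0:
        raise ValueError("divergence must be positive")
    if not 0 < proviral_fraction < 1:
        raise ValueError("proviral fraction must lie strictly in (0, 1)")
    return divergence_my * math.log(0.5) / math.log(proviral_fraction)


def fit_half_life(ages_my, is_solo) -> float:
    """Maximum-likelihood half-life from per-event end states.

    Each ERV of age ``a`` is a solo LTR with probability
    ``1 - (1/2)**(a / lambda)``; the 1-D likelihood is maximised over
    ``lambda``.  Robust to age groups whose observed fraction is 0 or 1,
    where the closed form is undefined.
    """
    a = np.asarray(ages_my, dtype=float)
    s = np.asarray(is_solo, dtype=bool)
    if len(a) == 0 or len(a) != len(s):
        raise ValueError("need matching, non-empty ages and states")

    def nll(log_lam):
        lam = math.exp(log_lam)
        q = np.power(0.5, a / lam)  # P(still proviral)
        q = np.clip(q, 1e-12, 1 - 1e-12)
        return -(np.log(1 - q)[s].sum() + np.log(q)[~s].sum())

    res = optimize.minimize_scalar(nll, bounds=(math.log(1e-3), math.log(1e3)),
                                   method="bounded")
    return float(math.exp(res.x))


def mk_g_test(densities: pd.DataFrame, fdr: float = 0.001) -> pd.DataFrame:
    """Per-chromosome McDonald-Kreitman-style G-test.

    ``densities`` carries one row per chromosome with columns ``chrom``,
    ``n_tev`` and ``n_fixed``.  For each chromosome, the TEV count expected
    from the fixed-TE distribution is ``E = total_tev * fixed_c / total_fixed``
    and the statistic is ``G = 2 * [O ln(O/E) + O' ln(O'/E')]`` with primes
    the rest-of-genome complements (df = 1).  ``direction`` is sign(O - E);
    a deficit of TEVs against the fixed background (direction -1) marks
    candidate positive selection for retention.  q-values are BH-adjusted
    and ``significant`` applies the requested FDR (default 0.1%).
    """
    df = densities.copy()
    if len(df) < 2:
        raise ValueError("need at least two chromosomes")
    t_tev = df["n_tev"].sum()
    t_fix = df["n_fixed"].sum()
    if t_tev <= 0 or t_fix <= 0:
        raise ValueError("zero totals")

    def xlogy(o, e):
        return 0.0 if o == 0 else o * math.log(o / e)

    g_vals, p_vals, direction = [], [], []
    for _, row in df.iterrows():
        o = float(row["n_tev"])
        e = t_tev * row["n_fixed"] / t_fix
        o2, e2 = t_tev - o, t_tev - e
        if e == 0 or e2 == 0:
            g = float("nan")
        else:
            g = 2.0 * (xlogy(o, e) + xlogy(o2, e2))
        g_vals.append(g)
        p_vals.append(float(stats.chi2.sf(g, df=1)) if not math.isnan(g)
                      else float("nan"))
        direction.append(int(np.sign(o - e)))
    out = df[["chrom"]].copy()
    out["n_tev"] = df["n_tev"].to_numpy()
    out["n_fixed"] = df["n_fixed"].to_numpy()
    out["expected_tev"] = t_tev * df["n_fixed"].to_numpy() / t_fix
    out["G"] = g_vals
    out["p"] = p_vals
    out["q"] = bh_adjust(p_vals)
    out["direction"] = direction
    out["significant"] = out["q"] < fdr
    return out


def gc_profile(records: pd.DataFrame, genome, span: int = 20_000
               ) -> pd.DataFrame:
    """Local-GC ECDF per TE family.

    The GC of the ``span`` bp window centred on each TEV's 5' base is
    collected per family and returned as a long table (family, gc, ecdf,
    truncated); windows running off a chromosome end are truncated and
    flagged.
    """
    rows = []
    for _, r in records.iterrows():
        gc, trunc = genome.local_gc(r["chrom"], int(r["start"]), span)
        rows.append((r["family"], gc, trunc))
    df = pd.DataFrame(rows, columns=["family", "gc", "truncated"])
    out = []
    for fam, grp in df.groupby("family"):
        grp = grp.sort_values("gc").reset_index(drop=True)
        n = len(grp)
        grp["ecdf"] = (np.arange(n) + 1) / n
        out.append(grp)
    if not out:
        return pd.DataFrame(columns=["family", "gc", "truncated", "ecdf"])
    return pd.concat(out, ignore_index=True)
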