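"""GC/isochore-matched randomization enrichment tests and density profiles.

TE insertion rates vary strongly with local GC, so naive overlap tests
conflate composition with function.  The core test here re-places every TEV
point uniformly within its own (chromosome, GC-stratum) cell and compares
the observed in-annotation count with the randomized distribution: a
confound that acts only through GC survives stratification as a null.

Also here: per-compartment and per-gene-category enrichment wrappers,
Fibonacci-binned proximity density profiles around gene/exon boundaries,
and the orientation-bias-by-intron-position analysis.

TEVs enter all of these as points at their 5' base, which treats reference
and non-reference insertions identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .selection import orientation_bias, chi_square_2x2
from .stats import bh_adjust

__all__ = [
    "AssociationResult", "make_isochores", "randomization_test",
    "compartment_enrichment", "category_enrichment", "gene_compartments",
    "proximity_profile", "intron_position_bias", "fibonacci_edges",
]


@dataclass
class AssociationResult:
    annotation: str
    observed: int
    expected: float
    fold: float
    p_empirical: float
    direction: int          # +1 enrichment, -1 depletion
    n_samples: int
    q: float = float("nan")


def make_isochores(genome, n_bins: int = 8) -> pd.DataFrame:
    """Partition each chromosome's isochore windows into GC-quantile strata.

    Returns a window table (chrom, start, end, gc, stratum); every base of
    the genome belongs to exactly one row.  Strata are per-chromosome
    quantiles, so randomizations condition on both chromosome and GC.
    """
    if n_bins < 2:
        raise ValueError("need at least two GC strata")
    rows = []
    for name, length, _ in genome.chromosomes:
        arr = np.asarray(genome.gc[name])
        edges = np.quantile(arr, np.linspace(0, 1, n_bins + 1)[1:-1])
        strata = np.searchsorted(edges, arr, side="right")
        for i, (gc, st) in enumerate(zip(arr, strata)):
            start = i * genome.window
            rows.append((name, start, min(start + genome.window, length),
                         float(gc), int(st)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gc",
                                       "stratum"])


def _interval_arrays(annotation: pd.DataFrame, genome) -> dict:
    """chrom -> flat sorted boundary array of merged intervals."""
    lens = genome.lengths
    out = {}
    for chrom, grp in annotation.groupby("chrom"):
        if chrom not in lens:
            raise ValueError(f"annotation on unknown chromosome {chrom}")
        ivs = sorted(zip(grp["start"].astype(int), grp["end"].astype(int)))
        if any(s < 0 or e > lens[chrom] for s, e in ivs):
            raise ValueError("annotation outside the genome")
        merged = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.array(merged, dtype=float).ravel()
    return out


def _count_inside(boundaries: dict, chroms, pos) -> int:
    total = 0
    for chrom in np.unique(chroms):
        b = boundaries.get(chrom)
        if b is None:
            continue
        p = pos[chroms == chrom]
        total += int((np.searchsorted(b, p, side="right") % 2 == 1).sum())
    return total


def randomization_test(points: pd.DataFrame, annotation: pd.DataFrame,
                       genome, strata: pd.DataFrame | None = None,
                       n_samples: int = 10_000, seed: int = 0,
                       name: str = "annotation") -> AssociationResult:
    """Stratified randomization test of point/annotation association.

    Every point is re-placed uniformly within its own (chromosome,
    GC-stratum) cell ``n_samples`` times; with ``strata=None`` the cell is
    the whole chromosome (the unstratified test).  The empirical p-value is
    two-sided (tail doubling) and reported with the direction of the
    observed deviation; its floor is ``2/(n_samples + 1)``.
    """
    if n_samples < 100:
        raise ValueError("need at least 100 randomizations")
    rng = np.random.default_rng(seed)
    boundaries = _interval_arrays(annotation, genome)
    chroms = points["chrom"].to_numpy()
    pos = points["pos"].to_numpy(dtype=float)
    observed = _count_inside(boundaries, chroms, pos)

    if strata is None:
        win = make_isochores(genome, 2)
        win = win.assign(stratum=0)
    else:
        win = strata
    wchrom = win["chrom"].to_numpy()
    wstart = win["start"].to_numpy(dtype=float)
    wlen = (win["end"] - win["start"]).to_numpy(dtype=float)
    wstrat = win["stratum"].to_numpy()

    # assign each point to its (chromosome, stratum) cell
    strat_by_chrom = {
        c: wstrat[np.flatnonzero(wchrom == c)] for c in np.unique(chroms)
    }
    counts = np.zeros(n_samples, dtype=int)
    cells: dict[tuple, int] = {}
    for c, p in zip(chroms, pos):
        key = (c, int(strat_by_chrom[c][int(p // genome.window)]))
        cells[key] = cells.get(key, 0) + 1

    for (c, st), n_p in cells.items():
        sel = np.flatnonzero((wchrom == c) & (wstrat == st))
        lens = wlen[sel]
        psel = lens / lens.sum()
        draws = n_samples * n_p
        widx = rng.choice(len(sel), size=draws, p=psel)
        rpos = wstart[sel][widx] + rng.random(draws) * lens[widx]
        b = boundaries.get(c)
        if b is None:
            continue
        inside = (np.searchsorted(b, rpos, side="right") % 2 == 1)
        counts += inside.reshape(n_samples, n_p).sum(axis=1)

    expected = float(counts.mean())
    fold = observed / expected if expected > 0 else float("nan")
    direction = 1 if observed >= expected else -1
    if direction > 0:
        k = int((counts >= observed).sum())
    else:
        k = int((counts <= observed).sum())
    # two-sided by tail doubling, reported with the deviation's direction
    p = min(1.0, 2.0 * (1 + k) / (n_samples + 1))
    return AssociationResult(annotation=name, observed=observed,
                             expected=expected, fold=fold, p_empirical=p,
                             direction=direction, n_samples=n_samples)


def _results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in results])
    if len(df):
        df["q"] = bh_adjust(df["p_empirical"])
    return df


def gene_compartments(genome, flank: int = 5_000) -> dict[str, pd.DataFrame]:
    """Exon / intron / flank / intergenic interval sets, by precedence.

    Overlaps resolve exon > intron > flank > intergenic on the union gene
    model; the four compartments tile the genome.
    """
    lens = genome.lengths
    comp = {k: [] for k in ("exon", "intron", "flank", "intergenic")}
    # paint per chromosome with a precedence code
    for chrom, length in lens.items():
        spans = {"exon": [], "intron": [], "flank": []}
        for g in genome.genes:
            if g.chrom != chrom:
                continue
            spans["exon"] += list(g.exons)
            spans["intron"] += g.introns
            spans["flank"] += [
                (max(0, g.start - flank), g.start),
                (g.end, min(length, g.end + flank)),
            ]
        events = []
        for rank, key in enumerate(("exon", "intron", "flank")):
            for s, e in spans[key]:
                events.append((s, e, rank, key))
        # sweep: assign each base the best-ranked cover
        cuts = sorted({0, length, *(s for s, *_ in events),
                       *(e for _, e, *_ in events)})
        for a, b in zip(cuts, cuts[1:]):
            best = None
            for s, e, rank, key in events:
                if s <= a and b <= e and (best is None or rank < best[0]):
                    best = (rank, key)
            key = best[1] if best else "intergenic"
            comp[key].append((chrom, a, b))
    return {
        k: pd.DataFrame(v, columns=["chrom", "start", "end"])
        for k, v in comp.items()
    }


def compartment_enrichment(points: pd.DataFrame, genome,
                           strata: pd.DataFrame | None = None,
                           n_samples: int = 1_000, seed: int = 0,
                           flank: int = 5_000) -> pd.DataFrame:
    """Per (TE class, compartment) stratified enrichment, BH-corrected.

    ``points`` needs columns chrom, pos, te_class.
    """
    comps = gene_compartments(genome, flank=flank)
    results = []
    for i, (cls, grp) in enumerate(points.groupby("te_class")):
        for j, (cname, ann) in enumerate(comps.items()):
            if ann.empty:
                continue
            r = randomization_test(
                grp, ann, genome, strata, n_samples=n_samples,
                seed=seed + 1000 * i + j, name=f"{cls}:{cname}")
            results.append(r)
    return _results_frame(results)


def category_enrichment(points: pd.DataFrame, genome,
                        strata: pd.DataFrame | None = None,
                        compartment: str = "intron",
                        n_samples: int = 1_000, seed: int = 0) -> pd.DataFrame:
    """Enrichment of TEVs in the introns (or bodies) of gene categories."""
    cats = sorted({c for g in genome.genes for c in g.categories})
    results = []
    for i, (cls, grp) in enumerate(points.groupby("te_class")):
        for j, cat in enumerate(cats):
            ivs = []
            for g in genome.genes:
                if cat not in g.categories:
                    continue
                spans = (g.introns if compartment == "intron"
                         else [(g.start, g.end)])
                ivs += [(g.chrom, s, e) for s, e in spans]
            if not ivs:
                continue
            ann = pd.DataFrame(ivs, columns=["chrom", "start", "end"])
            r = randomization_test(
                grp, ann, genome, strata, n_samples=n_samples,
                seed=seed + 1000 * i + j, name=f"{cls}:{cat}")
            results.append(r)
    return _results_frame(results)


def fibonacci_edges(base: int, n_bins: int) -> np.ndarray:
    """Cumulative Fibonacci bin edges: base * (1, 2, 3, 5, 8, 13, ...)."""
    fib = [1, 2]
    while len(fib) < n_bins:
        fib.append(fib[-1] + fib[-2])
    return np.array([0] + [base * f for f in fib[:n_bins]], dtype=float)


def proximity_profile(points: pd.DataFrame, genome, side: str = "upstream",
                      base: int = 100, n_bins: int = 10,
                      anchor: str = "tss") -> pd.DataFrame:
    """TEV density ratio in Fibonacci distance bins from gene boundaries.

    ``points`` needs chrom, pos and (for stratification) ``orientation``
    in {sense, antisense} relative to the nearest gene; rows with unknown
    orientation are dropped.  For each gene the usable span on the given
    side stops half-way to the next gene, and each bin's density is the
    TEV count divided by the bases actually available at that distance,
    expressed relative to the global TEV density.
    """
    if side not in ("upstream", "downstream"):
        raise ValueError("side must be upstream or downstream")
    edges = fibonacci_edges(base, n_bins)
    genes_by_chrom: dict[str, list] = {}
    for g in genome.genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    for gl in genes_by_chrom.values():
        gl.sort(key=lambda g: g.start)

    pts = points[points.get("orientation", pd.Series(dtype=str)).isin(
        ["sense", "antisense"])] if "orientation" in points else points
    total_points = len(pts)
    total_bases = sum(genome.lengths.values())
    global_density = total_points / total_bases if total_bases else np.nan

    rows = []
    for stratum in ("sense", "antisense"):
        sub = (pts[pts["orientation"] == stratum]
               if "orientation" in pts else pts)
        counts = np.zeros(n_bins)
        avail = np.zeros(n_bins)
        for chrom, gl in genes_by_chrom.items():
            ppos = np.sort(sub.loc[sub["chrom"] == chrom, "pos"].to_numpy())
            length = genome.lengths[chrom]
            for i, g in enumerate(gl):
                if g.strand == "+":
                    bound = g.start if side == "upstream" else g.end
                    left = side == "upstream"
                else:
                    bound = g.end if side == "upstream" else g.start
                    left = side == "downstream"
                if left:
                    prev_end = gl[i - 1].end if i > 0 else 0
                    maxd = max(0, (bound - prev_end) // 2)
                else:
                    nxt = gl[i + 1].start if i + 1 < len(gl) else length
                    maxd = max(0, (nxt - bound) // 2)
                if maxd == 0:
                    continue
                lim = np.minimum(edges, maxd)
                avail += np.diff(lim)
                if left:
                    d = bound - ppos[(ppos < bound) & (ppos >= bound - maxd)]
                else:
                    d = ppos[(ppos >= bound) & (ppos < bound + maxd)] - bound
                if len(d):
                    counts += np.histogram(d, bins=edges)[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            dens = counts / avail
            ratio = dens / global_density
        for b in range(n_bins):
            rows.append((side, stratum, edges[b], edges[b + 1],
                         int(counts[b]), avail[b], ratio[b]))
    return pd.DataFrame(rows, columns=[
        "side", "orientation", "bin_lo", "bin_hi", "count",
        "available_bases", "density_ratio"])


def intron_position_bias(records: pd.DataFrame, genome) -> pd.DataFrame:
    """Orientation bias in first/middle/last introns, per TE class.

    ``records`` needs chrom, start (the 5' base), strand and te_class.
    Intron indexing follows transcript orientation; a single-intron gene
    counts as "first", a two-intron gene as "first" and "last".  A
    heterogeneity chi-square across the three strata is attached per class
    (NaN when fewer than two strata are populated).
    """
    rows = []
    for _, r in records.iterrows():
        gene, where = genome.locate(r["chrom"], int(r["start"]))
        if where != "intron":
            continue
        idx = gene.intron_index(int(r["start"]))
        n_int = len(gene.introns)
        if idx == 0:
            stratum = "first"
        elif idx == n_int - 1:
            stratum = "last"
        else:
            stratum = "middle"
        sense = r["strand"] == gene.strand
        rows.append((r["te_class"], stratum, sense))
    df = pd.DataFrame(rows, columns=["te_class", "stratum", "sense"])
    out = []
    for cls, grp in df.groupby("te_class"):
        tab = []
        strata = ["first", "middle", "last"]
        per = {}
        for st in strata:
            sub = grp[grp["stratum"] == st]
            ns, na = int(sub["sense"].sum()), int((~sub["sense"]).sum())
            per[st] = (ns, na)
            if ns + na:
                tab.append([ns, na])
        het_p = float("nan")
        if len(tab) >= 2:
            from scipy.stats import chi2_contingency
            t = np.array(tab)
            if (t.sum(axis=0) > 0).all():
                het_p = float(chi2_contingency(t, correction=False).pvalue)
        for st in strata:
            ns, na = per[st]
            bias = orientation_bias(ns, na) if ns + na else float("nan")
            out.append((cls, st, ns, na, bias, het_p))
    return pd.DataFrame(out, columns=[
        "te_class", "stratum", "n_sense", "n_antisense", "bias",
        "heterogeneity_p"])
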