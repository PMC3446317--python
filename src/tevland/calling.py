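"""TEV discovery from discordant read-pair evidence.

Two complementary callers:

* the non-reference (``B6minus``) side clusters anchor reads -- confidently
  mapped ends of read pairs whose mates hit TE sequence -- into candidate
  windows, refines a breakpoint from the forward/reverse anchor structure,
  and genotypes every strain at each accepted site;
* the reference (``B6plus``) side classifies structural-variant deletions
  against repeat annotation into TE classes and ERV structures (solo-LTR,
  provirus, LTR-internal, pseudoelement, hybrids; LINEs shorter than 5 kb
  are fragments).

Thresholds live in :class:`CallerParams`; the defaults are the published
operating point (mapping quality >= 30, >= 10 supporting pairs, 450 bp
flanks, <2:1 flank balance, <120 bp forward-to-reverse gap, 50 bp repeat
exclusion, >= 5 anchors per flank to genotype).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CallerParams", "Candidate", "RefinedCall", "cluster_anchors",
    "refine_breakpoint", "genotype", "estimate_size_class",
    "classify_b6plus", "classify_b6plus_batch", "call_tevs",
    "estimate_error_rates",
]

REPEAT_EXCLUSION_CLASSES = {
    "SINE", "LINE", "ERV", "simple_repeat", "low_complexity",
}

LINE_FULL_LENGTH_MIN = 5_000  # bp; shorter LINEs are fragments


@dataclass
class CallerParams:
    min_mapq: int = 30
    min_support_pairs: int = 10
    window: int = 450            # anchor flank, bp
    max_fr_ratio: float = 2.0    # forward-upstream : reverse-downstream balance
    max_gap: int = 120           # last F anchor to first R anchor, bp
    repeat_exclusion: int = 50   # bp to an annotated reference repeat
    genotype_min_anchors: int = 5
    genotype_window: int = 300
    min_identity: float = 0.80   # mate-to-probe alignment (upstream of caller)
    min_hit_len: int = 36
    merge_distance: int = 100    # cross-strain call merging
    spanning_literal: bool = True  # see estimate_size_class

    def __post_init__(self):
        for name in ("min_mapq", "min_support_pairs", "window", "max_fr_ratio",
                     "max_gap", "repeat_exclusion", "genotype_min_anchors",
                     "genotype_window", "min_identity", "min_hit_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class Candidate:
    strain: str
    chrom: str
    start: int
    end: int
    family: str
    support: int


@dataclass
class RefinedCall:
    strain: str
    chrom: str
    breakpoint: int
    family: str
    n_forward: int
    n_reverse: int
    accepted: bool = True
    reason: str | None = None


def _qualifying(reads: pd.DataFrame, params: CallerParams) -> pd.DataFrame:
    ok = (reads["mapq"] >= params.min_mapq) & reads["mate_family"].notna()
    return reads[ok]


def cluster_anchors(reads: pd.DataFrame, params: CallerParams
                    ) -> list[Candidate]:
    """Cluster TE-supporting anchors into candidate insertion windows.

    Input must be sorted by (strain, chrom, pos).  Anchors qualify when
    their mapping quality reaches ``min_mapq`` and their mate was assigned
    a TE family; qualifying anchors closer than ``window`` bp chain into
    one cluster, and clusters with fewer than ``min_support_pairs``
    members are dropped.
    """
    for (_, _), grp in reads.groupby(["strain", "chrom"], sort=False):
        if not grp["pos"].is_monotonic_increasing:
            raise ValueError("anchor table must be sorted by (strain, chrom, pos)")
    out: list[Candidate] = []
    q = _qualifying(reads, params)
    for (strain, chrom), grp in q.groupby(["strain", "chrom"], sort=True):
        pos = grp["pos"].to_numpy()
        fam = grp["mate_family"].to_numpy()
        if len(pos) == 0:
            continue
        breaks = np.where(np.diff(pos) > params.window)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(pos)]])
        for s, e in zip(starts, ends):
            if e - s < params.min_support_pairs:
                continue
            fams, counts = np.unique(fam[s:e], return_counts=True)
            out.append(Candidate(
                strain=strain, chrom=chrom, start=int(pos[s]),
                end=int(pos[e - 1]) + 1, family=str(fams[np.argmax(counts)]),
                support=int(e - s)))
    return out


def _index_anchors(reads: pd.DataFrame, params: CallerParams) -> dict:
    """(strain, chrom) -> (sorted F positions, sorted R positions) of
    qualifying anchors."""
    q = _qualifying(reads, params)
    out = {}
    for (strain, chrom), grp in q.groupby(["strain", "chrom"], sort=False):
        f = np.sort(grp.loc[grp["anchor_orientation"] == "F", "pos"].to_numpy())
        r = np.sort(grp.loc[grp["anchor_orientation"] == "R", "pos"].to_numpy())
        out[(strain, chrom)] = (f, r)
    return out


def refine_breakpoint(candidate: Candidate, reads: pd.DataFrame,
                      params: CallerParams,
                      repeats: pd.DataFrame | None = None,
                      _index: dict | None = None) -> RefinedCall:
    """Pick a breakpoint for a candidate window, or reject it.

    A position ``bp`` qualifies when there are at least ``min_support_pairs``
    forward anchors in ``(bp - window, bp]`` and as many reverse anchors in
    ``[bp, bp + window)``, the forward-upstream and reverse-downstream
    support counts balance to better than ``max_fr_ratio``, and the gap from
    the last forward anchor to the first reverse anchor is below ``max_gap``.
    The leftmost qualifying position is reported.  Accepted breakpoints
    within ``repeat_exclusion`` bp of an annotated reference repeat
    (SINE/LINE/ERV/simple/low-complexity) are rejected instead.
    Rejection is a value (``accepted=False`` with a reason), not an error.
    """
    if _index is None:
        _index = _index_anchors(reads, params)
    f_all, r_all = _index.get((candidate.strain, candidate.chrom),
                              (np.array([]), np.array([])))
    w = params.window
    lo, hi = candidate.start - w, candidate.end + w
    f = f_all[(f_all >= lo) & (f_all < hi)]
    r = r_all[(r_all >= lo) & (r_all < hi)]

    def reject(reason):
        return RefinedCall(candidate.strain, candidate.chrom, -1,
                           candidate.family, 0, 0, accepted=False,
                           reason=reason)

    if len(f) == 0 or len(r) == 0:
        return reject("orientation_support")

    # balance of the call's total forward vs reverse support
    imbalance = max(len(f) / len(r), len(r) / len(f))

    bps = np.arange(candidate.start, candidate.end + 1)
    n_f = np.searchsorted(f, bps, side="right") - np.searchsorted(
        f, bps - w, side="right")
    n_r = np.searchsorted(r, bps + w, side="left") - np.searchsorted(
        r, bps, side="left")
    min_n = params.min_support_pairs
    support_ok = (n_f >= min_n) & (n_r >= min_n)
    if not support_ok.any():
        return reject("orientation_support")
    if imbalance >= params.max_fr_ratio:
        return reject("ratio")
    # gap from last F at-or-before bp to first R at-or-after bp
    last_f_idx = np.searchsorted(f, bps, side="right") - 1
    first_r_idx = np.searchsorted(r, bps, side="left")
    has_flank = (last_f_idx >= 0) & (first_r_idx < len(r))
    gap = np.full(len(bps), np.inf)
    ok_i = has_flank
    gap[ok_i] = r[np.minimum(first_r_idx[ok_i], len(r) - 1)] - f[last_f_idx[ok_i]]
    gap_ok = gap < params.max_gap

    qualifies = support_ok & gap_ok
    if not qualifies.any():
        return reject("gap")
    bp = int(bps[np.argmax(qualifies)])  # leftmost qualifying
    i = int(np.argmax(qualifies))

    if repeats is not None and len(repeats):
        rep = repeats[
            (repeats["chrom"] == candidate.chrom)
            & repeats["te_class"].isin(REPEAT_EXCLUSION_CLASSES)
        ]
        if len(rep):
            dist = np.maximum.reduce([
                rep["start"].to_numpy() - bp,
                bp - (rep["end"].to_numpy() - 1),
                np.zeros(len(rep), dtype=int),
            ])
            if (dist <= params.repeat_exclusion).any():
                return reject("repeat_proximity")

    return RefinedCall(candidate.strain, candidate.chrom, bp,
                       candidate.family, int(n_f[i]), int(n_r[i]))


def genotype(call: RefinedCall, reads: pd.DataFrame, strains,
             params: CallerParams, _index: dict | None = None) -> dict:
    """Presence map across strains for one accepted call.

    The discovery strain is present by construction; every other strain is
    scanned ``genotype_window`` bp either side of the breakpoint and called
    present iff it shows at least ``genotype_min_anchors`` forward anchors
    upstream and as many reverse anchors downstream.
    """
    if _index is None:
        _index = _index_anchors(reads, params)
    w = params.genotype_window
    bp = call.breakpoint
    out = {}
    for s in strains:
        if s == call.strain:
            out[s] = "present"
            continue
        f, r = _index.get((s, call.chrom), (np.array([]), np.array([])))
        n_f = np.searchsorted(f, bp) - np.searchsorted(f, bp - w)
        n_r = np.searchsorted(r, bp + w) - np.searchsorted(r, bp)
        present = (n_f >= params.genotype_min_anchors
                   and n_r >= params.genotype_min_anchors)
        out[s] = "present" if present else "absent"
    return out


def estimate_size_class(spanning_pairs: int,
                        params: CallerParams | None = None) -> str:
    """Size class from long-insert pairs spanning the breakpoint.

    The published rule is applied literally: more than two spanning pairs
    from the 3 kb jumping library => the element is called > 3 kb
    (``gt3kb``), otherwise ``le3kb``.  Set ``spanning_literal=False`` in
    :class:`CallerParams` for the opposite physical reading (a spanned
    breakpoint implies the element fits inside the insert).
    """
    if spanning_pairs < 0:
        raise ValueError("spanning pair count cannot be negative")
    params = params or CallerParams()
    spanned = spanning_pairs > 2
    if params.spanning_literal:
        return "gt3kb" if spanned else "le3kb"
    return "le3kb" if spanned else "gt3kb"


# ---------------------------------------------------------------------------
# reference-side (B6plus) classification
# ---------------------------------------------------------------------------

def _base_family(fam: str) -> str:
    return fam[:-4] if fam.endswith("-int") else fam


def classify_b6plus(sv, repeats: pd.DataFrame,
                    params: CallerParams | None = None) -> dict:
    """Classify one SV deletion into a TEV record or a rejection.

    ``sv`` needs ``chrom``, ``start``, ``end`` (and optionally ``strain``);
    ``repeats`` is a RepeatMasker-like table with columns chrom, start, end,
    strand, te_class, family (ERV internal segments suffixed ``-int``) and
    optionally ``partial`` for incomplete LTRs / poly-A remnants.  Returns a
    dict with either ``accepted=True`` and the typed record fields, or
    ``accepted=False`` with a rejection reason (no_te, breakpoint_distance
    or complex).
    """
    params = params or CallerParams()
    sv_chrom, sv_start, sv_end = sv["chrom"], int(sv["start"]), int(sv["end"])
    if sv_end <= sv_start:
        raise ValueError("malformed SV interval")

    def result(**kw):
        base = {"chrom": sv_chrom, "start": sv_start, "end": sv_end,
                "strain": sv.get("strain") if hasattr(sv, "get") else None}
        base.update(kw)
        return base

    ov = repeats[(repeats["chrom"] == sv_chrom)
                 & (repeats["end"] > sv_start)
                 & (repeats["start"] < sv_end)].sort_values("start")
    te = ov[ov["te_class"].isin({"SINE", "LINE", "ERV", "DNA"})]
    if te.empty:
        return result(accepted=False, reason="no_te")
    if (ov["te_class"].isin({"simple_repeat", "low_complexity"})).any():
        return result(accepted=False, reason="complex")

    te_start, te_end = int(te["start"].min()), int(te["end"].max())
    if (abs(te_start - sv_start) > params.repeat_exclusion
            and abs(te_end - sv_end) > params.repeat_exclusion):
        return result(accepted=False, reason="breakpoint_distance")

    # group annotation rows into elements: same base family, near-contiguous
    rows = te.to_dict("records")
    elements, cur = [], [rows[0]]
    for prev, row in zip(rows, rows[1:]):
        contiguous = row["start"] - prev["end"] <= params.repeat_exclusion
        if contiguous:
            cur.append(row)
        else:
            elements.append(cur)
            cur = [row]
    elements.append(cur)
    if len(elements) > 1:
        return result(accepted=False, reason="complex")
    elem = elements[0]

    classes = {r["te_class"] for r in elem}
    strand = elem[0]["strand"]
    length = int(elem[-1]["end"]) - int(elem[0]["start"])
    partial = any(bool(r.get("partial", 0)) for r in elem)

    if classes == {"ERV"}:
        fams = [r["family"] for r in elem]
        bases = {_base_family(f) for f in fams}
        hybrid = len(bases) > 1
        ints = [f for f in fams if f.endswith("-int")]
        ltrs = [f for f in fams if not f.endswith("-int")]
        if partial:
            structure = "hybrid_pseudoelement" if hybrid else "pseudoelement"
        elif ints and len(ltrs) >= 2:
            structure = "hybrid_provirus" if hybrid else "provirus"
        elif ints and not ltrs:
            structure = "LTR_int"
        elif not ints and len(ltrs) == 1:
            structure = "solo_LTR"
        elif not ints and len(ltrs) >= 2 and hybrid:
            structure = "hybrid_provirus"
        else:
            structure = "provirus"
        return result(accepted=True, te_class="ERV",
                      family=_base_family(fams[0]), structure=structure,
                      strand=strand, length=length)
    if classes == {"LINE"}:
        frag = length < LINE_FULL_LENGTH_MIN
        return result(accepted=True,
                      te_class="LINE_frag" if frag else "LINE",
                      family=elem[0]["family"],
                      structure="fragment" if frag else "full_length",
                      strand=strand, length=length)
    if classes == {"SINE"}:
        return result(accepted=True, te_class="SINE",
                      family=elem[0]["family"], structure="na",
                      strand=strand, length=length)
    if classes == {"DNA"}:
        return result(accepted=True, te_class="DNA",
                      family=elem[0]["family"], structure="na",
                      strand=strand, length=length)
    return result(accepted=False, reason="complex")


def classify_b6plus_batch(svs: pd.DataFrame, repeats: pd.DataFrame,
                          params: CallerParams | None = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify many SVs; every input lands in exactly one output table."""
    accepted, rejected = [], []
    for _, sv in svs.iterrows():
        res = classify_b6plus(sv, repeats, params)
        (accepted if res["accepted"] else rejected).append(res)
    acc = pd.DataFrame(accepted)
    rej = pd.DataFrame(rejected)
    return acc, rej


# ---------------------------------------------------------------------------
# end-to-end non-reference calling
# ---------------------------------------------------------------------------

def call_tevs(anchors: pd.DataFrame, params: CallerParams | None = None,
              repeats: pd.DataFrame | None = None,
              panel: list[str] | None = None
              ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Discovery + refinement + cross-strain merge + genotyping.

    Returns (records, presence, rejections): one record per merged TEV site
    with its breakpoint and family vote, a site x strain presence matrix
    ({1, 0}), and the per-candidate rejection log.
    """
    params = params or CallerParams()
    panel = panel or sorted(anchors["strain"].unique())
    candidates = cluster_anchors(anchors, params)
    index = _index_anchors(anchors, params)
    calls, rejections = [], []
    for cand in candidates:
        res = refine_breakpoint(cand, anchors, params, repeats, _index=index)
        if res.accepted:
            calls.append(res)
        else:
            rejections.append({
                "strain": cand.strain, "chrom": cand.chrom,
                "start": cand.start, "end": cand.end, "reason": res.reason})

    # merge per-strain calls into non-redundant sites
    calls.sort(key=lambda c: (c.chrom, c.breakpoint))
    sites: list[list[RefinedCall]] = []
    for c in calls:
        if (sites and sites[-1][0].chrom == c.chrom
                and c.breakpoint - sites[-1][-1].breakpoint
                <= params.merge_distance):
            sites[-1].append(c)
        else:
            sites.append([c])

    rec_rows, pres_rows = [], []
    for i, group in enumerate(sites):
        bp = int(np.median([c.breakpoint for c in group]))
        fams = pd.Series([c.family for c in group]).mode()
        site_id = f"site{i:05d}"
        proto = replace(group[0], breakpoint=bp)
        discovered = {c.strain for c in group}
        geno = genotype(proto, anchors, panel, params, _index=index)
        for s in discovered:
            geno[s] = "present"
        rec_rows.append({
            "tev_id": site_id, "side": "B6minus", "chrom": proto.chrom,
            "start": bp, "end": bp + 1, "te_class": "unknown",
            "family": str(fams.iloc[0]), "structure": "na",
            "strand": ".", "size_class": "unknown"})
        pres_rows.append({s: 1 if geno[s] == "present" else 0 for s in panel})
    records = pd.DataFrame(rec_rows)
    presence = pd.DataFrame(pres_rows,
                            index=[r["tev_id"] for r in rec_rows],
                            columns=panel, dtype=float)
    presence.index.name = "tev_id"
    return records, presence, pd.DataFrame(rejections)


# ---------------------------------------------------------------------------
# trio-based error rates
# ---------------------------------------------------------------------------

def estimate_error_rates(presence: pd.DataFrame, trio: tuple[str, str, str]
                         ) -> tuple[float, dict]:
    """False-negative rate from three near-identical substrains.

    Assuming the trio genomes are monomorphic for every TEV, any site called
    in at least two of the three must be present in all three; missing calls
    at such sites are false negatives.  The denominator is trio *calls*
    (3 per qualifying site).
    """
    for s in trio:
        if s not in presence.columns:
            raise ValueError(f"trio strain {s} absent from presence matrix")
    sub = presence[list(trio)].fillna(0).astype(int)
    counts = sub.sum(axis=1)
    sites = sub[counts >= 2]
    n_sites = len(sites)
    n_absent = int((sites == 0).to_numpy().sum())
    total = 3 * n_sites
    fnr = n_absent / total if total else 0.0
    return fnr, {"sites": n_sites, "absent_calls": n_absent,
                 "expected_calls": total}
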