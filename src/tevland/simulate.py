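"""Synthetic multi-strain genomes, TE insertion histories and evidence.

The generator emulates the statistical structure the downstream analyses
assume, at a scale the package can exercise end to end:

* a strain phylogeny (Newick, branch lengths in My) on which insertions
  arise as a Poisson process per branch and family;
* family-specific GC insertion preference (windows sampled with probability
  proportional to ``exp(weight * GC)``);
* a male-germline insertion bias ``alpha``: the X/autosome per-base density
  ratio is set to ``r = (2*alpha + 4) / (3*(alpha + 1))``, the inverse of
  the estimator ``alpha = (3r - 4)/(2 - 3r)`` (``r -> 2/3`` as
  ``alpha -> inf``);
* purifying selection against sense-orientated intronic insertions,
  modelled as an instantaneous purge at insertion time with class-specific
  probability (the end-state bias is all the analyses observe);
* ERV provirus -> solo-LTR decay: an element of age ``a`` (branch midpoint
  to present) is a solo LTR with probability ``1 - (1/2)**(a / halflife)``;
* discordant read-pair evidence around each true breakpoint, plus uniform
  background noise pairs;
* negative-binomial expression counts with cis effects for a fraction of
  genic TEVs and variance inflation of flanking genes for CTCF-flagged
  intergenic TEVs.

Every public function is deterministic given ``SimulationConfig.seed``;
sub-streams are derived from the seed by fixed offsets so the modules can
be re-run independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from intervaltree import IntervalTree

from .phylo import PhyloTree

__all__ = [
    "FamilyConfig", "SimulationConfig", "GeneModel", "GenomeModel",
    "InsertionEvent", "build_genome", "simulate_insertions",
    "emit_anchor_reads", "emit_sv_deletions", "simulate_expression",
    "write_truth", "events_to_frame", "alpha_to_density_ratio",
]

# stream offsets off the user seed
_S_GENOME, _S_EVENTS, _S_ANCHORS, _S_EXPR = 0, 1, 2, 3


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def alpha_to_density_ratio(alpha: float) -> float:
    """X/autosome density ratio implied by male bias alpha (2/3 at inf)."""
    if math.isinf(alpha):
        return 2.0 / 3.0
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return (2.0 * alpha + 4.0) / (3.0 * (alpha + 1.0))


# default 18-strain tree: 2 My to the deepest split, lab strains shallow,
# wild-derived strains (PWK, CAST, SPRET) deep, as in the Mus lineage
DEFAULT_TREE = (
    "((((((((C57BL6J:0.1,C57BL6NJ:0.1):0.1,(NOD:0.15,AKR:0.15):0.05):0.05,"
    "((BALBc:0.1,AJ:0.1):0.1,(C3H:0.08,CBA:0.08):0.12):0.05):0.05,"
    "((S129S1:0.05,(S129P2:0.04,S129S5:0.04):0.01):0.15,"
    "(DBA2J:0.12,LPJ:0.12):0.08):0.1):0.1,(NZO:0.3,WSB:0.3):0.1):0.5,"
    "PWK:0.9):0.2,CAST:1.1):0.9,SPRET:2.0);"
)

GENE_CATEGORIES = (
    "housekeeping", "development", "neural", "immune", "metabolic", "transport",
)


@dataclass
class FamilyConfig:
    """One TE family: class, insertion rate and family-specific biases."""

    name: str
    te_class: str                 # SINE, LINE or ERV
    rate: float                   # insertions per My, genome-wide
    gc_weight: float = 0.0        # softmax weight on window GC
    halflife: float | None = None  # ERV solo-LTR half-life, My
    frag_prob: float = 0.0        # LINE: probability of a <5 kb fragment


def _default_families() -> list[FamilyConfig]:
    return [
        FamilyConfig("B1", "SINE", rate=150.0, gc_weight=8.0),
        FamilyConfig("L1", "LINE", rate=200.0, gc_weight=-8.0, frag_prob=0.6),
        FamilyConfig("IAP", "ERV", rate=60.0, gc_weight=-3.0, halflife=0.7),
        FamilyConfig("ETn", "ERV", rate=30.0, gc_weight=-3.0, halflife=2.0),
        FamilyConfig("MuLV", "ERV", rate=20.0, gc_weight=8.0, halflife=0.8),
        FamilyConfig("MaLR", "ERV", rate=40.0, gc_weight=-3.0, halflife=0.8),
    ]


@dataclass
class SimulationConfig:
    seed: int = 0
    tree_spec: str = DEFAULT_TREE
    reference_strain: str = "C57BL6J"
    families: list[FamilyConfig] = field(default_factory=_default_families)
    alpha_true: float = 7.5
    sense_purge_prob: dict = field(
        default_factory=lambda: {"ERV": 0.5, "LINE": 1 / 3, "SINE": 1 / 3})
    # genome
    n_autosomes: int = 3
    autosome_length: int = 20_000_000
    x_length: int = 20_000_000
    isochore_window: int = 20_000
    n_genes: int = 300
    # read-pair evidence
    read_depth: float = 30.0       # expected anchors per flank per event
    anchor_window: int = 450
    noise_pair_rate: float = 0.5   # background discordant pairs per Mb
    # expression
    nb_mean: float = 500.0
    nb_dispersion: float = 0.05
    tev_effect_fraction: float = 0.1
    tev_effect_size: float = 4.0
    ctcf_fraction: float = 0.05
    ctcf_sd: float = 0.8

    def __post_init__(self):
        for name in ("tev_effect_fraction", "ctcf_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for cls, p in self.sense_purge_prob.items():
            if not 0 <= p <= 1:
                raise ValueError(f"sense_purge_prob[{cls}] outside [0, 1]")
        if any(f.rate < 0 for f in self.families):
            raise ValueError("family rates must be >= 0")
        if self.read_depth < 0 or self.noise_pair_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.alpha_true <= 0:
            raise ValueError("alpha_true must be > 0 (may be inf)")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fams = raw.pop("families", None)
        cfg = cls(**raw)
        if fams is not None:
            cfg.families = [FamilyConfig(**f) for f in fams]
        return cfg

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene: ordered, disjoint exons on one strand of one chromosome."""

    name: str
    chrom: str
    strand: str
    exons: list  # [(start, end), ...] 0-based half-open, sorted
    categories: frozenset = frozenset()

    def __post_init__(self):
        if not self.exons:
            raise ValueError("gene needs at least one exon")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if not (s1 < e1 <= s2 < e2):
                raise ValueError("exons must be sorted and disjoint")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    def intron_index(self, pos: int) -> int | None:
        """0-based intron index in transcript orientation, or None."""
        introns = self.introns
        for i, (s, e) in enumerate(introns):
            if s <= pos < e:
                return i if self.strand == "+" else len(introns) - 1 - i
        return None


@dataclass
class GenomeModel:
    chromosomes: list            # [(name, length, is_x), ...]
    window: int                  # isochore window size, bp
    gc: dict                     # chrom -> per-window GC fraction
    genes: list                  # [GeneModel, ...]

    def __post_init__(self):
        if not self.chromosomes:
            raise ValueError("genome needs at least one chromosome")
        if sum(1 for _, _, x in self.chromosomes if x) > 1:
            raise ValueError("at most one X chromosome")
        lens = dict(self.lengths.items())
        for name, arr in self.gc.items():
            arr = np.asarray(arr)
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError("GC fractions must lie in [0, 1]")
            need = -(-lens[name] // self.window)
            if len(arr) != need:
                raise ValueError(f"GC track does not cover {name}")
        for g in self.genes:
            if g.end > lens[g.chrom]:
                raise ValueError(f"gene {g.name} exceeds {g.chrom}")
        self._trees = None

    @property
    def lengths(self) -> dict:
        return {name: length for name, length, _ in self.chromosomes}

    @property
    def x_chrom(self) -> str | None:
        for name, _, is_x in self.chromosomes:
            if is_x:
                return name
        return None

    def window_gc(self, chrom: str, pos: int) -> float:
        return float(self.gc[chrom][pos // self.window])

    def local_gc(self, chrom: str, pos: int, span: int = 20_000):
        """Mean GC over the `span` bp centred on pos (window resolution).

        Returns (gc, truncated): truncated is True when the span runs off a
        chromosome end.
        """
        half = span // 2
        lo, hi = pos - half, pos + half
        length = self.lengths[chrom]
        truncated = lo < 0 or hi > length
        lo, hi = max(lo, 0), min(hi, length)
        w = self.window
        arr = self.gc[chrom]
        i0, i1 = lo // w, (hi - 1) // w + 1
        # weight windows by their overlap with [lo, hi)
        starts = np.arange(i0, i1) * w
        ends = np.minimum(starts + w, length)
        ov = np.minimum(ends, hi) - np.maximum(starts, lo)
        return float(np.average(arr[i0:i1], weights=ov)), truncated

    def _gene_trees(self):
        if self._trees is None:
            self._trees = {}
            for g in self.genes:
                self._trees.setdefault(g.chrom, IntervalTree()).addi(
                    g.start, g.end, g)
        return self._trees

    def locate(self, chrom: str, pos: int):
        """(gene, 'exon'|'intron') containing pos, or (None, 'intergenic')."""
        tree = self._gene_trees().get(chrom)
        if tree:
            for iv in tree[pos]:
                g = iv.data
                for s, e in g.exons:
                    if s <= pos < e:
                        return g, "exon"
                return g, "intron"
        return None, "intergenic"


def build_genome(config: SimulationConfig) -> GenomeModel:
    """Deterministically build autosomes + one X, GC track and gene models."""
    if config.n_autosomes < 1:
        raise ValueError("need at least one autosome")
    if config.n_genes < 1:
        raise ValueError("need at least one gene")
    rng = _rng(config.seed, _S_GENOME)

    chroms = [(f"chr{i + 1}", config.autosome_length, False)
              for i in range(config.n_autosomes)]
    chroms.append(("chrX", config.x_length, True))

    w = config.isochore_window
    gc = {}
    for name, length, _ in chroms:
        n = -(-length // w)
        raw = rng.normal(size=n + 48)
        kernel = np.ones(25) / 25.0
        smooth = np.convolve(raw, kernel, mode="valid")[:n]
        track = 0.45 + 0.35 * smooth  # sd of smooth ~ 0.2 -> spread ~ 0.07
        gc[name] = np.clip(track, 0.30, 0.65)

    total = sum(length for _, length, _ in chroms)
    # apportion genes to chromosomes by length, exactly n_genes in total
    quota = {}
    remaining = config.n_genes
    for i, (name, length, _) in enumerate(chroms):
        if i == len(chroms) - 1:
            quota[name] = remaining
        else:
            quota[name] = int(config.n_genes * length / total)
            remaining -= quota[name]
    genes: list[GeneModel] = []
    gid = 0
    for name, length, _ in chroms:
        n_c = quota[name]
        if n_c == 0:
            continue
        slot = length // n_c
        for k in range(n_c):
            n_ex = int(rng.integers(3, 11))
            ex_len = rng.integers(100, 400, size=n_ex)
            in_len = rng.integers(500, 5001, size=n_ex - 1)
            # shrink the gene until it fits its slot (dense-gene configs)
            while ex_len.sum() + in_len.sum() > slot - 4 and len(ex_len) > 1:
                shrunk = np.maximum(in_len // 2, 50)
                if in_len.sum() > shrunk.sum():
                    in_len = shrunk
                else:
                    ex_len, in_len = ex_len[:-1], in_len[:-1]
            g_len = int(ex_len.sum() + in_len.sum())
            n_ex = len(ex_len)
            room = slot - g_len - 2
            start = k * slot + int(rng.integers(1, max(room, 2)))
            exons, p = [], start
            for i in range(n_ex):
                exons.append((p, p + int(ex_len[i])))
                p += int(ex_len[i])
                if i < n_ex - 1:
                    p += int(in_len[i])
            n_cat = int(rng.integers(1, 4))
            cats = frozenset(
                rng.choice(GENE_CATEGORIES, size=n_cat, replace=False))
            genes.append(GeneModel(
                name=f"gene{gid:04d}", chrom=name,
                strand="+" if rng.random() < 0.5 else "-",
                exons=exons, categories=cats))
            gid += 1
    return GenomeModel(chromosomes=chroms, window=w, gc=gc, genes=genes)


# ---------------------------------------------------------------------------
# insertion histories
# ---------------------------------------------------------------------------

@dataclass
class InsertionEvent:
    tev_id: str
    chrom: str
    position: int                # 0-based insertion point
    te_class: str                # SINE, LINE, LINE_frag, ERV
    family: str
    orientation: str             # genome strand of the element, + or -
    branch: int                  # tree node id whose edge carries the event
    structure: str               # provirus, solo_LTR, full_length, fragment, na
    length: int                  # element length if placed in an assembly
    age: float                   # branch midpoint to present, My
    present_in: frozenset        # carrier strains
    side: str                    # B6plus / B6minus
    ctcf: bool = False


def _window_table(genome: GenomeModel):
    rows = []
    for name, length, is_x in genome.chromosomes:
        arr = genome.gc[name]
        for i, g in enumerate(arr):
            start = i * genome.window
            wlen = min(genome.window, length - start)
            rows.append((name, start, wlen, float(g), is_x))
    return rows


def simulate_insertions(genome: GenomeModel, config: SimulationConfig
                        ) -> tuple[list[InsertionEvent], pd.DataFrame]:
    """Simulate insertion events on the strain tree; no homoplasy.

    Returns the surviving events and the tev x strain presence matrix
    (carriers are exactly the leaves under the event's branch).
    """
    tree = PhyloTree.from_newick(config.tree_spec)
    if tree.n_leaves < 2:
        raise ValueError("tree needs at least two leaves")
    for n in tree.nodes[1:]:
        if n.length is None:
            raise ValueError("tree branches must carry lengths (My)")
    rng = _rng(config.seed, _S_EVENTS)
    depths = tree.depths()
    height = tree.height()
    r_alpha = alpha_to_density_ratio(config.alpha_true)

    windows = _window_table(genome)
    wchrom = np.array([w[0] for w in windows])
    wstart = np.array([w[1] for w in windows])
    wlen = np.array([w[2] for w in windows], dtype=float)
    wgc = np.array([w[3] for w in windows])
    wx = np.array([w[4] for w in windows])

    purge = config.sense_purge_prob
    events: list[InsertionEvent] = []
    eid = 0
    ref = config.reference_strain
    for fam in config.families:
        weight = np.exp(fam.gc_weight * wgc) * wlen
        weight[wx] *= r_alpha
        prob = weight / weight.sum()
        for node in tree.nodes[1:]:
            n_ev = rng.poisson(fam.rate * node.length)
            if n_ev == 0:
                continue
            widx = rng.choice(len(windows), size=n_ev, p=prob)
            offs = (rng.random(n_ev) * wlen[widx]).astype(int)
            orient = rng.random(n_ev) < 0.5
            age = height - (depths[node.parent] + node.length / 2.0)
            carriers = frozenset(tree.leaf_set(node.id))
            side = "B6plus" if ref in carriers else "B6minus"
            for j in range(n_ev):
                chrom = str(wchrom[widx[j]])
                pos = int(wstart[widx[j]] + offs[j])
                strand = "+" if orient[j] else "-"
                gene, where = genome.locate(chrom, pos)
                if where == "intron" and strand == gene.strand:
                    if rng.random() < purge.get(fam.te_class, 0.0):
                        continue  # purged at insertion
                te_class, structure, length = _structure(fam, age, rng)
                ctcf = (where == "intergenic"
                        and rng.random() < config.ctcf_fraction)
                events.append(InsertionEvent(
                    tev_id=f"tev{eid:06d}", chrom=chrom, position=pos,
                    te_class=te_class, family=fam.name, orientation=strand,
                    branch=node.id, structure=structure, length=length,
                    age=age, present_in=carriers, side=side, ctcf=ctcf))
                eid += 1

    presence = pd.DataFrame(
        [[1 if t in ev.present_in else 0 for t in tree.taxa] for ev in events],
        index=[ev.tev_id for ev in events], columns=tree.taxa, dtype=float)
    presence.index.name = "tev_id"
    return events, presence


def _structure(fam: FamilyConfig, age: float, rng) -> tuple[str, str, int]:
    if fam.te_class == "ERV":
        p_solo = 1.0 - 0.5 ** (age / fam.halflife) if fam.halflife else 0.0
        if rng.random() < p_solo:
            return "ERV", "solo_LTR", 400
        return "ERV", "provirus", 6000
    if fam.te_class == "LINE":
        if rng.random() < fam.frag_prob:
            return "LINE_frag", "fragment", int(rng.integers(500, 5000))
        return "LINE", "full_length", 6400
    return "SINE", "na", 150


def events_to_frame(events: list[InsertionEvent]) -> pd.DataFrame:
    """TEV record table (BED-ready) for a list of events."""
    return pd.DataFrame({
        "tev_id": [e.tev_id for e in events],
        "side": [e.side for e in events],
        "chrom": [e.chrom for e in events],
        "start": [e.position for e in events],
        "end": [e.position + (e.length if e.side == "B6plus" else 1)
                for e in events],
        "te_class": [e.te_class for e in events],
        "family": [e.family for e in events],
        "structure": [e.structure for e in events],
        "strand": [e.orientation for e in events],
        "size_class": ["unknown"] * len(events),
    })


# ---------------------------------------------------------------------------
# evidence
# ---------------------------------------------------------------------------

def emit_anchor_reads(genome: GenomeModel, events: list[InsertionEvent],
                      config: SimulationConfig) -> pd.DataFrame:
    """Discordant anchor read pairs supporting non-reference insertions.

    For every B6minus event and carrier strain, forward anchors are placed
    within ``anchor_window`` bp upstream of the breakpoint and reverse
    anchors within the same span downstream, each side Poisson(read_depth)
    deep.  Background pairs are scattered uniformly at ``noise_pair_rate``
    per Mb per strain.
    """
    rng = _rng(config.seed, _S_ANCHORS)
    win = config.anchor_window
    fams = [f.name for f in config.families]
    rows = []
    for ev in events:
        if ev.side != "B6minus":
            continue
        for strain in sorted(ev.present_in):
            for orient, sign in (("F", -1), ("R", +1)):
                n = rng.poisson(config.read_depth)
                if n == 0:
                    continue
                d = rng.integers(0, win, size=n)
                pos = ev.position + sign * d - (1 if sign < 0 else 0)
                pos = np.clip(pos, 0, genome.lengths[ev.chrom] - 1)
                mapq = np.where(rng.random(n) < 0.9, 60,
                                rng.integers(0, 30, size=n))
                for p, q in zip(pos, mapq):
                    rows.append((strain, ev.chrom, int(p), orient, int(q),
                                 ev.family, int(rng.random() < 0.5)))
    # background noise for every panel strain (an empty event list still
    # yields noise pairs)
    strains = [s for s in PhyloTree.from_newick(config.tree_spec).taxa
               if s != config.reference_strain]
    lens = genome.lengths
    chrom_names = list(lens)
    chrom_p = np.array([lens[c] for c in chrom_names], dtype=float)
    chrom_p /= chrom_p.sum()
    total_mb = sum(lens.values()) / 1e6
    for strain in strains:
        n = rng.poisson(config.noise_pair_rate * total_mb)
        for _ in range(n):
            c = chrom_names[rng.choice(len(chrom_names), p=chrom_p)]
            rows.append((
                strain, c, int(rng.integers(0, lens[c])),
                "F" if rng.random() < 0.5 else "R",
                int(rng.integers(0, 61)),
                rng.choice(fams) if rng.random() < 0.5 else None,
                int(rng.random() < 0.5)))
    df = pd.DataFrame(rows, columns=[
        "strain", "chrom", "pos", "anchor_orientation", "mapq",
        "mate_family", "mate_mapped"])
    return df.sort_values(["strain", "chrom", "pos"], kind="stable",
                          ignore_index=True)


def emit_sv_deletions(genome: GenomeModel, events: list[InsertionEvent],
                      config: SimulationConfig
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reference-side evidence for B6plus events.

    Returns (sv_deletions, repeat_annotations): each strain lacking a
    reference-lineage TEV shows a deletion spanning the element, and the
    element itself appears as RepeatMasker-like annotation rows (a provirus
    as LTR / internal / LTR with the internal family suffixed ``-int``).
    Events whose reference span overlaps an earlier element are skipped:
    nested elements do not resolve into independent SV deletions.
    """
    tree = PhyloTree.from_newick(config.tree_spec)
    strains = tree.taxa
    sv_rows, rep_rows = [], []
    occupied: dict[str, list] = {}
    b6plus = sorted((e for e in events if e.side == "B6plus"),
                    key=lambda e: (e.chrom, e.position))
    for ev in b6plus:
        spans = occupied.setdefault(ev.chrom, [])
        if spans and ev.position < spans[-1]:
            continue
        spans.append(ev.position + ev.length)
        start, end = ev.position, ev.position + ev.length
        div = round(ev.age * 2.0, 2)  # %, a simple age proxy
        if ev.structure == "provirus":
            ltr = 400
            rep_rows += [
                (ev.chrom, start, start + ltr, ev.orientation, "ERV",
                 ev.family, div),
                (ev.chrom, start + ltr, end - ltr, ev.orientation, "ERV",
                 f"{ev.family}-int", div),
                (ev.chrom, end - ltr, end, ev.orientation, "ERV",
                 ev.family, div),
            ]
        else:
            rep_rows.append((ev.chrom, start, end, ev.orientation,
                             "ERV" if ev.te_class == "ERV" else
                             ("LINE" if ev.te_class in ("LINE", "LINE_frag")
                              else "SINE"),
                             ev.family, div))
        for s in strains:
            if s not in ev.present_in:
                sv_rows.append((s, ev.chrom, start, end, ev.tev_id))
    sv = pd.DataFrame(sv_rows,
                      columns=["strain", "chrom", "start", "end", "tev_id"])
    reps = pd.DataFrame(rep_rows, columns=[
        "chrom", "start", "end", "strand", "te_class", "family",
        "divergence_pct"])
    return sv, reps


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(genome: GenomeModel, events: list[InsertionEvent],
                        config: SimulationConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x sample negative-binomial counts with TEV cis effects.

    Two replicates per strain.  A ``tev_effect_fraction`` of genic TEVs
    multiply their gene's mean in carrier strains by ``tev_effect_size``;
    CTCF-flagged intergenic TEVs add lognormal noise to both flanking genes
    in carrier strains, inflating the variance of the flanking log-ratio.
    Returns (counts, effects) where effects lists the planted causal TEVs.
    """
    if config.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be > 0")
    tree = PhyloTree.from_newick(config.tree_spec)
    strains = tree.taxa
    if len(strains) < 4:
        raise ValueError("need >= 4 strains for downstream resampling")
    rng = _rng(config.seed, _S_EXPR)
    genes = [g.name for g in genome.genes]
    gene_ix = {g: i for i, g in enumerate(genes)}
    base = rng.lognormal(mean=np.log(config.nb_mean), sigma=1.0,
                         size=len(genes))
    mean = np.tile(base[:, None], (1, len(strains)))

    by_chrom: dict[str, list] = {}
    for g in genome.genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for gl in by_chrom.values():
        gl.sort(key=lambda g: g.start)

    eff_rows = []
    for ev in events:
        gene, where = genome.locate(ev.chrom, ev.position)
        if gene is not None:
            if rng.random() < config.tev_effect_fraction:
                cols = [strains.index(s) for s in ev.present_in]
                mean[gene_ix[gene.name], cols] *= config.tev_effect_size
                eff_rows.append((ev.tev_id, gene.name, "cis",
                                 config.tev_effect_size))
        elif ev.ctcf:
            gl = by_chrom.get(ev.chrom, [])
            up = [g for g in gl if g.end <= ev.position]
            down = [g for g in gl if g.start > ev.position]
            if not up or not down:
                continue
            pair = (up[-1], down[0])
            cols = [strains.index(s) for s in ev.present_in]
            for g in pair:
                noise = rng.lognormal(0.0, config.ctcf_sd, size=len(cols))
                mean[gene_ix[g.name], cols] *= noise
            eff_rows.append((ev.tev_id, f"{pair[0].name}|{pair[1].name}",
                             "ctcf", config.ctcf_sd))

    disp = config.nb_dispersion
    nb_n = 1.0 / disp
    cols, data = [], []
    for j, s in enumerate(strains):
        for rep in (1, 2):
            mu = mean[:, j]
            p = nb_n / (nb_n + mu)
            data.append(rng.negative_binomial(nb_n, p))
            cols.append(f"{s}.{rep}")
    counts = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    counts.index.name = "gene"
    effects = pd.DataFrame(eff_rows,
                           columns=["tev_id", "gene", "kind", "size"])
    return counts, effects


# ---------------------------------------------------------------------------
# truth files
# ---------------------------------------------------------------------------

def write_truth(events: list[InsertionEvent], presence: pd.DataFrame,
                config: SimulationConfig, outdir) -> dict:
    """Write truth BED, strain-pattern TSV and the generating tree."""
    import os

    from . import io as tio
    os.makedirs(outdir, exist_ok=True)
    records = events_to_frame(events)
    paths = {
        "bed": os.path.join(outdir, "truth.bed"),
        "pattern": os.path.join(outdir, "truth_pattern.tsv"),
        "tree": os.path.join(outdir, "tree.nwk"),
        "assignments": os.path.join(outdir, "truth_branches.tsv"),
    }
    tio.write_tev_bed(records, paths["bed"])
    tio.write_pattern(records, presence, paths["pattern"])
    with open(paths["tree"], "w") as fh:
        fh.write(config.tree_spec.strip() + "\n")
    pd.DataFrame({
        "tev_id": [e.tev_id for e in events],
        "branch": [e.branch for e in events],
        "age": [e.age for e in events],
    }).to_csv(paths["assignments"], sep="\t", index=False)
    return paths
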