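"""Birth-death gene-family simulator with ground truth.

Gene lineages evolve along a species tree under per-branch duplication
(rate ``lambda``, events per gene per unit time) and loss (rate ``mu``)
processes; lineage-specific "expansion waves" multiply the duplication
rate over a leading fraction of a branch.  Coding sequences evolve under
an MG94-style codon model with transition bias ``kappa`` and per-region
``omega`` (stop codons are excluded from the state space, so no in-frame
stop is ever produced).  Chromosomal placement puts a configurable
fraction of duplicates in tandem (< 10 kb downstream of the parent copy),
and expression profiles give stable genes a mean offset ``delta`` over a
noise floor ``sigma``.

Randomness discipline: every public operation derives its generator from
``params.seed`` through a fixed stream id (family history 0, sequences 1,
loci 2, expression 3), so a given ``SimParams`` always reproduces the same
outputs regardless of call order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np

from .trees import SpeciesTree

__all__ = [
    "Region",
    "Wave",
    "SimParams",
    "SimTruth",
    "BranchEvents",
    "simulate_family",
    "evolve_sequences",
    "place_loci",
    "simulate_expression",
    "GENETIC_CODE",
    "STOP_CODONS",
    "SENSE_CODONS",
]

# -- genetic code ---------------------------------------------------------

_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
GENETIC_CODE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
_PURINES = {"A", "G"}


def _is_transition(x: str, y: str) -> bool:
    return (x in _PURINES) == (y in _PURINES)


# -- parameter containers -------------------------------------------------


@dataclass(frozen=True)
class Region:
    """Codon interval [start, end) with its own omega."""

    name: str
    start: int
    end: int
    omega: float

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad region bounds for {self.name!r}")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")


@dataclass(frozen=True)
class Wave:
    """Duplication-rate burst on one species-tree branch.

    The multiplier applies over the leading ``duration_frac`` of the branch
    (measured from the parent node).
    """

    branch: str
    multiplier: float
    duration_frac: float

    def __post_init__(self):
        if self.multiplier < 0:
            raise ValueError("wave multiplier must be >= 0")
        if not (0 < self.duration_frac <= 1):
            raise ValueError("wave duration fraction must be in (0, 1]")


@dataclass(frozen=True)
class SimParams:
    """Simulator configuration; defaults give a modest angiosperm-style
    family with a conserved N-terminal domain and a diversifying
    C-terminal target-recruiting domain."""

    dup_rate: float | dict = 0.3
    loss_rate: float | dict = 0.1
    waves: tuple[Wave, ...] = ()
    kappa: float = 2.0
    n_codons: int = 200
    regions: tuple[Region, ...] = (
        Region("fbox", 0, 50, 0.1),
        Region("cterm", 80, 200, 1.5),
    )
    background_omega: float = 0.5
    tandem_prob: float = 0.4
    tandem_max_offset: int = 8000
    expr_delta: float = 1.5
    expr_sigma: float = 1.0
    expr_baseline: float = 6.0
    expr_clade_tau: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for r in self._rates(self.dup_rate) + self._rates(self.loss_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.n_codons < 1:
            raise ValueError("need at least one codon")
        if not (0 <= self.tandem_prob <= 1):
            raise ValueError("tandem probability must be in [0, 1]")
        if self.tandem_max_offset <= 0:
            raise ValueError("tandem max offset must be positive")
        if self.expr_sigma <= 0:
            raise ValueError("expression noise sigma must be > 0")
        if self.background_omega < 0:
            raise ValueError("omega must be >= 0")
        spans = sorted((r.start, r.end) for r in self.regions)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("regions overlap")

    @staticmethod
    def _rates(r) -> list[float]:
        return list(r.values()) if isinstance(r, dict) else [r]

    def rate_on(self, which: str, branch: str) -> float:
        r = self.dup_rate if which == "dup" else self.loss_rate
        if isinstance(r, dict):
            return float(r.get(branch, r.get("default", 0.0)))
        return float(r)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), stream])


@dataclass
class BranchEvents:
    duplications: list[float] = field(default_factory=list)
    losses: list[float] = field(default_factory=list)


@dataclass
class SimTruth:
    """Ground truth from one :func:`simulate_family` run."""

    events: dict[str, BranchEvents]
    lineage_counts: dict[str, int]
    gene_species: dict[str, str]
    gene_clade: dict[str, int]
    categories: dict[str, str]
    species_span: frozenset
    tandem_parent: dict[str, str | None]

    @property
    def empty(self) -> bool:
        return not self.gene_species

    def clade_composition(self) -> dict[int, dict[str, int]]:
        """Per Dollo clade: species -> extant gene count."""
        out: dict[int, dict[str, int]] = {}
        for g, c in self.gene_clade.items():
            sp = self.gene_species[g]
            out.setdefault(c, {}).setdefault(sp, 0)
            out[c][sp] += 1
        return out

    def placement_input(self) -> dict[str, list[tuple[str, str | None]]]:
        """Per species: (gene, parent copy) pairs in simulation order."""
        out: dict[str, list[tuple[str, str | None]]] = {}
        for g, sp in self.gene_species.items():
            out.setdefault(sp, []).append((g, self.tandem_parent.get(g)))
        return out

    def to_json(self) -> str:
        d = {
            "events": {
                b: {"duplications": e.duplications, "losses": e.losses}
                for b, e in self.events.items()
            },
            "lineage_counts": self.lineage_counts,
            "gene_species": self.gene_species,
            "gene_clade": self.gene_clade,
            "categories": self.categories,
            "species_span": sorted(self.species_span),
            "tandem_parent": self.tandem_parent,
        }
        return json.dumps(d, indent=1, sort_keys=True)


# -- gene-family history --------------------------------------------------


class _Tip:
    __slots__ = ("node", "clade", "ident", "anchor")

    def __init__(self, node, clade, ident, anchor=None):
        self.node = node
        self.clade = clade
        self.ident = ident
        self.anchor = anchor


class _GNode:
    __slots__ = ("children", "length", "label")

    def __init__(self):
        self.children = []
        self.length = 0.0
        self.label = None


def _segments(T: float, lam: float, wave: Wave | None):
    """Piecewise-constant duplication rate along a branch of length T."""
    if wave is None or wave.duration_frac >= 1.0:
        if wave is not None:
            return [(T, lam * wave.multiplier)]
        return [(T, lam)]
    cut = wave.duration_frac * T
    return [(cut, lam * wave.multiplier), (T - cut, lam)]


def simulate_family(
    species_tree: SpeciesTree, params: SimParams
) -> tuple[dendropy.Tree | None, SimTruth]:
    """Evolve one gene family along a species tree.

    Starts from a single gene at the root node and applies a Gillespie
    birth-death process per lineage on every branch.  Returns the pruned
    gene tree of extant genes (``None`` if the family went extinct) and a
    :class:`SimTruth` with every event and derived label.
    """
    rng = params.rng(0)
    waves = {w.branch: w for w in params.waves}
    events = {child: BranchEvents() for _, child, _ in species_tree.branches()}
    lineage_counts: dict[str, int] = {species_tree.root: 1}
    clade_counter = [0]
    ident_counter = [0]
    genes: list[tuple[str, str, int, str | None, _GNode]] = []
    gene_counters: dict[str, int] = {}

    def new_ident():
        ident_counter[0] += 1
        return f"i{ident_counter[0]}"

    def run_branch(tips: list[_Tip], child: str) -> list[_Tip]:
        nd = species_tree.nodes[child]
        T = nd.length
        lam = params.rate_on("dup", child)
        mu = params.rate_on("loss", child)
        segs = _segments(T, lam, waves.get(child))
        # absolute segment boundaries
        bounds = []
        acc = 0.0
        for seg_len, seg_lam in segs:
            bounds.append((acc, acc + seg_len, seg_lam))
            acc += seg_len
        ev = events[child]
        out: list[_Tip] = []
        queue: list[tuple[_Tip, float]] = [(tip, 0.0) for tip in tips]
        while queue:
            tip, t = queue.pop()
            born = t
            alive = True
            for seg_start, seg_end, seg_lam in bounds:
                if seg_end <= t or not alive:
                    continue
                total = seg_lam + mu
                while alive and t < seg_end:
                    if total <= 0:
                        t = seg_end
                        break
                    w = rng.exponential(1.0 / total)
                    if t + w >= seg_end:
                        t = seg_end
                        break
                    t += w
                    if rng.random() < seg_lam / total:
                        ev.duplications.append(t)
                        tip.node.length += t - born
                        cont = _GNode()
                        new = _GNode()
                        tip.node.children = [cont, new]
                        clade_counter[0] += 1
                        new_tip = _Tip(new, clade_counter[0], new_ident(), tip.ident)
                        tip.node = cont
                        born = t
                        queue.append((new_tip, t))
                    else:
                        ev.losses.append(t)
                        tip.node.length += t - born
                        tip.node.label = "extinct"
                        alive = False
            if alive:
                tip.node.length += T - born
                out.append(tip)
        return out

    def descend(tips: list[_Tip], node_name: str):
        nd = species_tree.nodes[node_name]
        if nd.is_leaf:
            for tip in tips:
                k = gene_counters.get(node_name, 0) + 1
                gene_counters[node_name] = k
                gene = f"{node_name}_g{k:03d}"
                tip.node.label = gene
                genes.append((gene, node_name, tip.clade, tip.anchor, tip.node))
                ident_to_gene.setdefault(node_name, {})[tip.ident] = gene
            return
        for child in nd.children:
            child_tips = []
            for tip in tips:
                cn = _GNode()
                tip.node.children.append(cn)
                child_tips.append(_Tip(cn, tip.clade, new_ident(), None))
            survivors = run_branch(child_tips, child)
            lineage_counts[child] = len(survivors)
            descend(survivors, child)

    ident_to_gene: dict[str, dict[str, str]] = {}
    root_node = _GNode()
    root_tip = _Tip(root_node, 0, new_ident(), None)
    descend([root_tip], species_tree.root)

    # resolve tandem anchors: parent copy must be extant in the same species
    tandem_parent: dict[str, str | None] = {}
    gene_species: dict[str, str] = {}
    gene_clade: dict[str, int] = {}
    for gene, sp, clade, anchor, _ in genes:
        gene_species[gene] = sp
        gene_clade[gene] = clade
        parent = None
        if anchor is not None:
            parent = ident_to_gene.get(sp, {}).get(anchor)
        tandem_parent[gene] = parent

    span = frozenset(gene_species.values())
    if len(span) >= 2:
        categories = {g: "stable" for g in gene_species}
    elif len(gene_species) >= 2:
        categories = {g: "unstable" for g in gene_species}
    else:
        categories = {g: "singleton" for g in gene_species}

    truth = SimTruth(
        events=events,
        lineage_counts=lineage_counts,
        gene_species=gene_species,
        gene_clade=gene_clade,
        categories=categories,
        species_span=span,
        tandem_parent=tandem_parent,
    )
    if not genes:
        return None, truth

    gene_tree = _to_dendropy(root_node)
    return gene_tree, truth


def _to_dendropy(root: _GNode) -> dendropy.Tree:
    """Prune extinct subtrees, suppress unifurcations, convert."""

    def prune(n: _GNode) -> _GNode | None:
        if not n.children:
            return n if n.label and n.label != "extinct" else None
        kept = [prune(c) for c in n.children]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            kept[0].length += n.length
            return kept[0]
        n.children = kept
        return n

    pruned = prune(root)
    labels = []

    def collect(n):
        if not n.children:
            labels.append(n.label)
        for c in n.children:
            collect(c)

    collect(pruned)
    tns = dendropy.TaxonNamespace(sorted(labels))

    def build(n: _GNode) -> dendropy.Node:
        dn = dendropy.Node()
        dn.edge.length = n.length
        if not n.children:
            dn.taxon = tns.get_taxon(n.label)
        for c in n.children:
            dn.add_child(build(c))
        return dn

    seed = build(pruned)
    seed.edge.length = None
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=seed)
    tree.is_rooted = True
    return tree


# -- codon sequence evolution ---------------------------------------------


def _codon_rate_matrix(kappa: float, omega: float) -> np.ndarray:
    n = len(SENSE_CODONS)
    q = np.zeros((n, n))
    for i, ci in enumerate(SENSE_CODONS):
        for pos in range(3):
            for b in _BASES:
                if b == ci[pos]:
                    continue
                cj = ci[:pos] + b + ci[pos + 1:]
                if cj in STOP_CODONS:
                    continue
                j = _CODON_INDEX[cj]
                rate = kappa if _is_transition(ci[pos], b) else 1.0
                if GENETIC_CODE[ci] != GENETIC_CODE[cj]:
                    rate *= omega
                q[i, j] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _codon_scale(kappa: float) -> float:
    """Normalise so the mean leave rate over uniform sense codons is 1
    per codon position (3 per codon) at omega = 1."""
    q1 = _codon_rate_matrix(kappa, 1.0)
    return 3.0 / float(-np.diag(q1).mean())


_P_CACHE: dict[tuple, np.ndarray] = {}


def _transition_matrix(kappa: float, omega: float, t: float) -> np.ndarray:
    key = (round(kappa, 10), round(omega, 10), round(t, 12))
    if key not in _P_CACHE:
        from scipy.linalg import expm

        q = _codon_rate_matrix(kappa, omega) * _codon_scale(kappa)
        p = expm(q * t)
        _P_CACHE[key] = np.cumsum(np.clip(p, 0, None), axis=1)
    return _P_CACHE[key]


def _omega_per_codon(params: SimParams) -> np.ndarray:
    om = np.full(params.n_codons, params.background_omega)
    for r in params.regions:
        if r.end > params.n_codons:
            raise ValueError(
                f"region {r.name!r} [{r.start},{r.end}) exceeds CDS of "
                f"{params.n_codons} codons"
            )
        om[r.start:r.end] = r.omega
    return om


def evolve_sequences(
    gene_tree: dendropy.Tree,
    params: SimParams,
    rng: np.random.Generator | None = None,
    root_codons: np.ndarray | None = None,
) -> dict[str, str]:
    """Simulate a gap-free codon alignment down a gene tree.

    Branch lengths are expected substitutions per nucleotide site under
    neutrality (omega = 1); per-region omega rescales the nonsynonymous
    rates.  Substitution is exact CTMC sampling: per branch and region the
    61x61 transition matrix is exponentiated and child codons drawn from
    the parent rows, so in-frame stops can never appear.

    ``root_codons`` (sense-codon indices, length ``n_codons``) fixes the
    ancestral sequence; by default it is drawn uniformly at random.
    """
    if rng is None:
        rng = params.rng(1)
    omega = _omega_per_codon(params)
    distinct = sorted(set(omega.tolist()))
    if root_codons is None:
        root_codons = rng.integers(0, len(SENSE_CODONS), size=params.n_codons)
    else:
        root_codons = np.asarray(root_codons, dtype=np.int64)
        if root_codons.shape != (params.n_codons,):
            raise ValueError("root_codons length must equal n_codons")
    out: dict[str, str] = {}

    def walk(node, codons):
        for child in node.child_nodes():
            t = child.edge.length
            if t is None:
                raise ValueError("gene tree branch without length")
            if t == 0:
                new = codons.copy()
            else:
                new = np.empty_like(codons)
                for om in distinct:
                    mask = omega == om
                    if not mask.any():
                        continue
                    cum = _transition_matrix(params.kappa, om, float(t))
                    u = rng.random(int(mask.sum()))
                    rows = cum[codons[mask]]
                    idx = (rows < u[:, None] * rows[:, -1:]).sum(axis=1)
                    new[mask] = np.minimum(idx, len(SENSE_CODONS) - 1)
            if child.is_leaf():
                out[child.taxon.label] = "".join(
                    SENSE_CODONS[c] for c in new
                )
            else:
                walk(child, new)

    seed = gene_tree.seed_node
    if seed.is_leaf():  # single-gene family
        out[seed.taxon.label] = "".join(SENSE_CODONS[c] for c in root_codons)
    else:
        walk(seed, root_codons)
    return out


def mutate_codons(
    codons: np.ndarray,
    t: float,
    params: SimParams,
    omega: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve an array of sense-codon indices along a single branch."""
    if t <= 0:
        return np.asarray(codons, dtype=np.int64).copy()
    cum = _transition_matrix(params.kappa, omega, float(t))
    codons = np.asarray(codons, dtype=np.int64)
    u = rng.random(len(codons))
    rows = cum[codons]
    idx = (rows < u[:, None] * rows[:, -1:]).sum(axis=1)
    return np.minimum(idx, len(SENSE_CODONS) - 1)


# -- chromosomal placement ------------------------------------------------


@dataclass(frozen=True)
class GeneLocus:
    gene: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("locus start must be < end")


_N_CHROMS = 5
_BLOCK_GAP = 100_000  # inter-block spacing, far beyond the 10 kb rule


def place_loci(
    genes: dict[str, list[tuple[str, str | None]]],
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> tuple[list[GeneLocus], list[frozenset]]:
    """Assign synthetic coordinates; duplicates go in tandem with
    probability ``params.tandem_prob``.

    ``genes`` maps species -> ordered (gene, parent copy or None) pairs;
    a tandem placement appends the duplicate < 10 kb downstream of its
    parent's block, otherwise the gene starts a new block >= 10 kb from
    everything else (possibly on another chromosome).  Returns the loci
    and the intended tandem clusters (ground truth).
    """
    if not genes or all(not v for v in genes.values()):
        raise ValueError("gene list is non-empty")
    if rng is None:
        rng = params.rng(2)
    loci: list[GeneLocus] = []
    clusters: list[frozenset] = []
    for species in sorted(genes):
        entries = genes[species]
        parent_of = dict(entries)
        placed: dict[str, int] = {}  # gene -> block index
        blocks: list[list[tuple[str, int]]] = []  # (gene, length)
        tandem_pairs: list[tuple[str, str]] = []

        def place(gene: str):
            if gene in placed:
                return
            parent = parent_of.get(gene)
            length = int(rng.integers(900, 2400))
            if parent is not None and parent in parent_of:
                place(parent)
            tandem = (
                parent is not None
                and parent in placed
                and rng.random() < params.tandem_prob
            )
            if tandem:
                b = placed[parent]
                blocks[b].append((gene, length))
                placed[gene] = b
                tandem_pairs.append((gene, parent))
            else:
                blocks.append([(gene, length)])
                placed[gene] = len(blocks) - 1

        for gene, _ in entries:
            place(gene)

        # chromosome names are species-scoped so pooled multi-species locus
        # sets never collide on coordinates
        cursors = {f"{species}_chr{i + 1}": 50_000 for i in range(_N_CHROMS)}
        for block in blocks:
            chrom = f"{species}_chr{int(rng.integers(0, _N_CHROMS)) + 1}"
            pos = cursors[chrom]
            for k, (gene, length) in enumerate(block):
                if k > 0:
                    pos += int(rng.integers(200, params.tandem_max_offset))
                loci.append(GeneLocus(gene, chrom, pos, pos + length))
                pos += length
            cursors[chrom] = pos + _BLOCK_GAP

        # intended clusters: connected components of tandem parent-child pairs
        comp: dict[str, set] = {}
        for a, b in tandem_pairs:
            sa = comp.get(a, {a})
            sb = comp.get(b, {b})
            merged = sa | sb
            for g in merged:
                comp[g] = merged
        seen = set()
        for s in comp.values():
            fs = frozenset(s)
            if fs not in seen and len(fs) >= 2:
                seen.add(fs)
                clusters.append(fs)
    return loci, clusters


# -- expression -----------------------------------------------------------


def simulate_expression(
    categories: dict[str, str],
    params: SimParams,
    n_samples: int = 20,
    clade_map: dict[str, int] | None = None,
    rng: np.random.Generator | None = None,
):
    """Log-scale expression matrix (genes x samples).

    Values are ``baseline + delta * [stable] (+ clade effect) + N(0, sigma)``;
    the optional clade component adds a shared N(0, tau) offset per clade,
    linking co-expression to sequence clades.
    """
    import pandas as pd

    if not categories:
        raise ValueError("need at least one gene")
    if n_samples < 2:
        raise ValueError("need at least two samples")
    if params.expr_sigma <= 0:
        raise ValueError("expression noise sigma must be > 0")
    if rng is None:
        rng = params.rng(3)
    genes = list(categories)
    vals = np.full((len(genes), n_samples), params.expr_baseline)
    stable = np.array([categories[g] == "stable" for g in genes])
    vals = vals + params.expr_delta * stable[:, None]
    if clade_map is not None:
        clades = sorted({clade_map[g] for g in genes})
        effects = {
            c: rng.normal(0.0, params.expr_clade_tau, size=n_samples)
            for c in clades
        }
        for i, g in enumerate(genes):
            vals[i] += effects[clade_map[g]]
    vals = vals + rng.normal(0.0, params.expr_sigma, size=vals.shape)
    cols = [f"T{j + 1:03d}" for j in range(n_samples)]
    return pd.DataFrame(vals, index=genes, columns=cols)
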