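"""Coalescent simulation on a species network with introgression.

The generative model is the multispecies coalescent with introgression
(MSci): a rooted species tree whose nodes carry divergence times ``tau``
and whose branches carry mutation-scaled population sizes ``theta = 4*N*mu``
(both in expected substitutions per site), extended by timed introgression
events.  Tracing a sampled lineage backward in time, within a population
each pair of lineages coalesces at rate ``2/theta``; when the lineage
reaches an introgression event on its current branch it crosses to the
donor branch with probability ``gamma`` (the introgression probability of
the horizontal edge); at speciation nodes lineages merge into the parent
population.  Bidirectional introgression (BDI) is a pair of events at the
same time with opposite directions.

Sequences evolve along the resulting gene trees under JC69.  Diploid
individuals are two independent haplotype draws from their species.  A read
channel then produces VCF-like genotype calls: per site and individual the
read depth is drawn from a depth model, each read samples one of the two
alleles with equal probability and is miscalled as the other allele of the
site's allele pair with probability ``eps``, and the genotype is called by
maximum likelihood exactly as in :mod:`heliopipe.error_model`.  The
generator writes a reference FASTA, GFF3 annotation, BED repeat track, VCF
and truth files (gene trees, true alignments), so every downstream stage of
the pipeline can be scored against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import error_model
from ._iupac import BASES, alleles as _alleles, diploid_code

# =========================================================================
# species network

@dataclass
class Population:
    """A branch of the species network, named after its daughter node.

    The branch exists over the age interval ``[t_lower, t_upper)``:
    ``t_lower`` is the age of the daughter node (0 for extant species) and
    ``t_upper`` the age of the parent node (infinity for the root branch).
    """

    name: str
    theta: float
    t_lower: float
    t_upper: float
    parent: str | None
    children: tuple[str, ...] = ()


@dataclass(frozen=True)
class IntrogressionEvent:
    """A timed horizontal edge: recipient lineages cross to the donor.

    ``gamma`` is the introgression probability: the probability that a
    lineage traced backward through the recipient branch at ``time`` takes
    the horizontal edge into the donor branch.
    """

    time: float
    donor: str
    recipient: str
    gamma: float
    label: str = ""


@dataclass
class SpeciesNetwork:
    populations: dict[str, Population]
    events: list[IntrogressionEvent]
    root: str

    @classmethod
    def from_parents(
        cls,
        parents: Mapping[str, str | None],
        tau: Mapping[str, float],
        theta: Mapping[str, float] | float,
        events: Sequence[IntrogressionEvent] = (),
    ) -> "SpeciesNetwork":
        """Build from a child->parent map, node ages and branch thetas.

        ``tau`` gives ages for internal nodes (tips default to age 0);
        ``theta`` is per-branch or a single value for all branches.
        """
        children: dict[str, list[str]] = {}
        root = None
        for child, parent in parents.items():
            if parent is None:
                root = child
            else:
                children.setdefault(parent, []).append(child)
        if root is None:
            raise ValueError("no root (a node with parent None) in parents map")
        pops: dict[str, Population] = {}
        for name, parent in parents.items():
            t_lower = float(tau.get(name, 0.0))
            t_upper = float(tau[parent]) if parent is not None else math.inf
            th = theta if isinstance(theta, (int, float)) else theta[name]
            pops[name] = Population(
                name=name,
                theta=float(th),
                t_lower=t_lower,
                t_upper=t_upper,
                parent=parent,
                children=tuple(sorted(children.get(name, ()))),
            )
        return cls(populations=pops, events=sorted(events, key=lambda e: e.time), root=root)

    @property
    def tips(self) -> list[str]:
        return sorted(n for n, p in self.populations.items() if not p.children)


def validate_network(net: SpeciesNetwork) -> list[str]:
    """Check network invariants; an empty list means the network is valid."""
    issues: list[str] = []
    for name, pop in net.populations.items():
        if pop.theta <= 0:
            issues.append(f"branch {name}: theta must be > 0 (got {pop.theta})")
        if pop.t_upper <= pop.t_lower and name != net.root:
            issues.append(f"branch {name}: parent age {pop.t_upper} <= node age {pop.t_lower}")
        for child in pop.children:
            cpop = net.populations.get(child)
            if cpop is None:
                issues.append(f"branch {name}: unknown child {child}")
            elif cpop.t_lower >= pop.t_lower:
                issues.append(f"node {name}: child {child} is not younger")
    for ev in net.events:
        for role, branch in (("donor", ev.donor), ("recipient", ev.recipient)):
            pop = net.populations.get(branch)
            if pop is None:
                issues.append(f"event {ev.label or ev.time}: unknown {role} branch {branch}")
            elif not (pop.t_lower <= ev.time < pop.t_upper):
                issues.append(
                    f"event {ev.label or ev.time}: time {ev.time} outside lifespan of {role} branch {branch}"
                )
        if not (0.0 <= ev.gamma <= 1.0):
            issues.append(f"event {ev.label or ev.time}: gamma {ev.gamma} outside [0, 1]")
    return issues


def default_network() -> SpeciesNetwork:
    """The shipped six-species *Heliconius erato-sara* example network.

    Backbone (the Z-chromosome species tree): (((Era, Him), Sia), Tel) as
    the erato clade and (Dem, Sar) as the sara clade.  Four introgression
    events: an ancient bidirectional exchange between the Tel lineage and
    the sara-clade ancestor, strong unidirectional Tel -> Sia flow shortly
    after the Sia split (a hybrid-speciation signature), a bidirectional
    Era <-> Him exchange between the sister species, and weak Sar -> Dem
    flow.  Times and probabilities follow the noncoding-locus estimates for
    this system; population sizes default to theta = 0.01.
    """
    parents = {
        "Era": "eh", "Him": "eh", "eh": "ehc", "Sia": "ehc", "ehc": "ehtc",
        "Tel": "ehtc", "ehtc": "r", "Dem": "ds", "Sar": "ds", "ds": "r",
        "r": None,
    }
    tau = {"eh": 0.005, "ehc": 0.015, "ehtc": 0.021, "ds": 0.012, "r": 0.027}
    events = [
        IntrogressionEvent(time=0.001, donor="Sar", recipient="Dem", gamma=0.005, label="s->d"),
        IntrogressionEvent(time=0.014, donor="Tel", recipient="Sia", gamma=0.80, label="tc1->c"),
        IntrogressionEvent(time=0.002, donor="Era", recipient="Him", gamma=0.15, label="e->h"),
        IntrogressionEvent(time=0.002, donor="Him", recipient="Era", gamma=0.05, label="h->e"),
        IntrogressionEvent(time=0.018, donor="Tel", recipient="ds", gamma=0.35, label="tc2->ds2"),
        IntrogressionEvent(time=0.018, donor="ds", recipient="Tel", gamma=0.10, label="ds2->tc2"),
    ]
    return SpeciesNetwork.from_parents(parents, tau, theta=0.01, events=events)


# =========================================================================
# gene trees

@dataclass
class TreeNode:
    name: str
    age: float
    children: list["TreeNode"] = field(default_factory=list)

    def tips(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.tips())
        return out

    def to_newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if not self.children:
            return self.name
        parts = ",".join(c._newick_inner() + f":{self.age - c.age:.8g}" for c in self.children)
        return f"({parts})"


@dataclass
class GeneTree:
    """A coalescent genealogy with node ages in expected substitutions/site."""

    root: TreeNode
    #: per horizontal edge (event label or index), number of lineages that crossed
    edge_uses: dict[str, int] = field(default_factory=dict)

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.root.tips()]

    def to_newick(self) -> str:
        return self.root.to_newick()


def simulate_gene_tree(
    net: SpeciesNetwork,
    samples: Mapping[str, int] | Mapping[str, Sequence[str]],
    rng: np.random.Generator,
) -> GeneTree:
    """Simulate one genealogy backward in time on the species network.

    ``samples`` maps tip species either to a number of sampled (haploid)
    sequences or to explicit sequence names.  Coalescence within a branch of
    parameter ``theta`` occurs at rate ``2/theta`` per lineage pair; at
    introgression events each lineage in the recipient branch independently
    crosses to the donor with probability ``gamma``; at speciation nodes
    lineages merge into the parent population.
    """
    # active lineages per branch
    active: dict[str, list[TreeNode]] = {name: [] for name in net.populations}
    for species, spec in samples.items():
        if species not in net.populations:
            raise KeyError(f"unknown species {species!r}")
        names = [f"{species}_{i}" for i in range(spec)] if isinstance(spec, int) else list(spec)
        active[species] = [TreeNode(name=n, age=net.populations[species].t_lower) for n in names]

    edge_uses: dict[str, int] = {}
    # breakpoints: all internal node ages and event times
    node_ages = sorted({p.t_lower for p in net.populations.values() if p.children})
    event_times = sorted({e.time for e in net.events})
    breakpoints = sorted(set(node_ages) | set(event_times))

    merge_counter = [0]

    def coalesce_within(t0: float, t1: float) -> float:
        """Run coalescence in every branch from time t0 to t1; return t1."""
        t = t0
        while True:
            best_dt, best_branch = math.inf, None
            for bname, lineages in active.items():
                k = len(lineages)
                if k < 2:
                    continue
                pop = net.populations[bname]
                if not (pop.t_lower <= t and (t < pop.t_upper or bname == net.root)):
                    continue
                rate = k * (k - 1) / pop.theta  # C(k,2) pairs x 2/theta
                dt = rng.exponential(1.0 / rate)
                if dt < best_dt:
                    best_dt, best_branch = dt, bname
            if best_branch is None or t + best_dt >= t1:
                return t1
            t += best_dt
            lineages = active[best_branch]
            i, j = rng.choice(len(lineages), size=2, replace=False)
            a, b = lineages[int(i)], lineages[int(j)]
            merge_counter[0] += 1
            parent = TreeNode(name=f"anc{merge_counter[0]}", age=t, children=[a, b])
            active[best_branch] = [x for x in lineages if x is not a and x is not b] + [parent]

    t = 0.0
    for bp in breakpoints:
        coalesce_within(t, bp)
        t = bp
        # introgression events first (they occur on branches existing at bp)
        todays = [e for e in net.events if e.time == bp]
        if todays:
            # snapshot recipients so paired BDI events act on the pre-event state
            snapshots = {e: list(active[e.recipient]) for e in todays}
            moves: list[tuple[TreeNode, str, str]] = []
            for ev in todays:
                label = ev.label or f"{ev.donor}->{ev.recipient}@{ev.time}"
                for lin in snapshots[ev]:
                    if rng.random() < ev.gamma:
                        moves.append((lin, ev.recipient, ev.donor))
                        edge_uses[label] = edge_uses.get(label, 0) + 1
            for lin, src, dst in moves:
                active[src].remove(lin)
                active[dst].append(lin)
        # speciation nodes whose age is bp: children merge into the parent branch
        for name, pop in net.populations.items():
            if pop.children and pop.t_lower == bp:
                for child in pop.children:
                    active[name].extend(active[child])
                    active[child] = []
    # root branch: coalesce to a single lineage
    coalesce_within(t, math.inf)
    remaining = [lin for lineages in active.values() for lin in lineages]
    if len(remaining) != 1:  # pragma: no cover - guarded by validate_network
        raise RuntimeError(f"simulation ended with {len(remaining)} lineages")
    return GeneTree(root=remaining[0], edge_uses=edge_uses)


# =========================================================================
# sequence evolution (JC69)

_BASE_CODES = np.frombuffer("ACGT".encode(), dtype=np.uint8)
_BASE_CHARS = np.array(list("ACGT"))


def simulate_alignment(tree: GeneTree, length: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Evolve a JC69 alignment along the gene tree.

    Branch lengths are already in expected substitutions per site; under
    JC69 a branch of length ``t`` changes a site with probability
    ``(3/4)(1 - exp(-4t/3))``, uniformly to one of the three other bases.
    Returns per-tip arrays of base codes 0..3 (A, C, G, T).
    """
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    out: dict[str, np.ndarray] = {}

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        if not node.children:
            out[node.name] = seq
            return
        for child in node.children:
            t = node.age - child.age
            p_change = 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))
            mask = rng.random(length) < p_change
            child_seq = seq.copy()
            if mask.any():
                shifts = rng.integers(1, 4, size=int(mask.sum()))
                child_seq[mask] = (child_seq[mask] + shifts) % 4
            descend(child, child_seq)

    root_seq = rng.integers(0, 4, size=length).astype(np.int64)
    descend(tree.root, root_seq)
    return out


def codes_to_str(codes: np.ndarray) -> str:
    return _BASE_CODES[codes].tobytes().decode()


# =========================================================================
# read channel: diploid genotyping

@dataclass(frozen=True)
class DepthModel:
    """Per-site read depth distribution: Poisson(mean) or fixed depth."""

    kind: str = "poisson"  # "poisson" | "fixed"
    mean: float = 30.0

    def draw(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "poisson":
            return rng.poisson(self.mean, size=size)
        if self.kind == "fixed":
            return np.full(size, int(self.mean), dtype=np.int64)
        raise ValueError(f"unknown depth model kind {self.kind!r}")


@dataclass
class SiteCalls:
    """Per-individual genotype calls for one locus (arrays over sites)."""

    called: list[np.ndarray]  # per individual: IUPAC char codes ('<U1'), 'N' = missing
    dp: list[np.ndarray]
    gq: list[np.ndarray]
    ad_major: list[np.ndarray]  # reads supporting the individual's primary allele
    ad_other: list[np.ndarray]  # reads supporting the companion allele
    major: list[np.ndarray]  # primary allele base codes
    other: list[np.ndarray]  # companion allele base codes


def _phred_gq(k: np.ndarray, n: np.ndarray, eps: float) -> np.ndarray:
    """GQ = 10 log10(best likelihood / runner-up), capped at 99."""
    eps = max(eps, 1e-10)
    with np.errstate(divide="ignore"):
        l00 = (n - k) * math.log10(1 - eps) + k * math.log10(eps)
        l01 = n * math.log10(0.5)
        l11 = k * math.log10(1 - eps) + (n - k) * math.log10(eps)
    stacked = np.stack([l00, l01, l11])
    order = np.sort(stacked, axis=0)
    gq = 10.0 * (order[-1] - order[-2])
    return np.minimum(np.round(gq), 99).astype(np.int64)


def diploidize_and_genotype(
    hap_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    ref: np.ndarray,
    depth_model: DepthModel,
    eps: float,
    rng: np.random.Generator,
    assumed_eps: float | None = None,
) -> SiteCalls:
    """Push diploid haplotype pairs through the binomial read channel.

    At each site of each individual the depth ``n`` is drawn from the depth
    model; every read samples one of the individual's two alleles with equal
    probability and is miscalled as the site's companion allele with
    probability ``eps`` (the two-allele error model: the companion of a
    homozygote is the reference allele, or a random alternative base when
    the individual is homozygous for the reference).  Genotypes are called
    by maximum likelihood at ``assumed_eps`` (defaults to ``eps``); a site
    with zero depth is missing.
    """
    if not (0.0 <= eps < 0.5):
        raise ValueError(f"eps must be in [0, 0.5), got {eps}")
    call_eps = eps if assumed_eps is None else assumed_eps
    length = len(ref)
    # site-level fallback alternative allele (for individuals homozygous = REF)
    site_alt = (ref + rng.integers(1, 4, size=length)) % 4

    max_n = 0
    drawn = []
    for _h1, _h2 in hap_pairs:
        n = depth_model.draw(length, rng)
        drawn.append(n)
        max_n = max(max_n, int(n.max(initial=0)))
    # calling table per depth: thresholds on k for call in {0:hom-major,1:het,2:hom-other}
    tables = [error_model._call_table(n, call_eps) if n >= 1 else None for n in range(max_n + 1)]

    calls = SiteCalls([], [], [], [], [], [], [])
    for (h1, h2), n in zip(hap_pairs, drawn):
        het = h1 != h2
        major = h1.copy()  # the individual's first allele
        other = np.where(het, h2, np.where(h1 == ref, site_alt, ref))
        # reads showing the companion allele:
        #   het: each read picks h1/h2 evenly, error flips within the pair -> P = 1/2
        #   hom: only miscalls show the companion -> P = eps
        p_other = np.where(het, 0.5, eps)
        k = rng.binomial(n, p_other)
        call_code = np.empty(length, dtype=np.int64)
        called = np.full(length, "N", dtype="<U1")
        gq = np.zeros(length, dtype=np.int64)
        covered = n >= 1
        for depth in np.unique(n[covered]):
            sel = n == depth
            call_code[sel] = tables[int(depth)][k[sel]]
        nz = covered
        gq[nz] = _phred_gq(k[nz], n[nz], call_eps)
        maj_chr = _BASE_CHARS[major]
        oth_chr = _BASE_CHARS[other]
        hom_major = nz & (call_code == 0)
        het_call = nz & (call_code == 1)
        hom_other = nz & (call_code == 2)
        called[hom_major] = maj_chr[hom_major]
        called[hom_other] = oth_chr[hom_other]
        if het_call.any():
            idx = np.nonzero(het_call)[0]
            called[idx] = [diploid_code(maj_chr[i], oth_chr[i]) for i in idx]
        calls.called.append(called)
        calls.dp.append(n)
        calls.gq.append(gq)
        calls.ad_major.append(n - k)
        calls.ad_other.append(k)
        calls.major.append(major)
        calls.other.append(other)
    return calls


# =========================================================================
# whole-dataset generation

@dataclass
class SimConfig:
    """Study-shaped defaults: ~200 bp loci, one diploid individual per species."""

    n_loci: int = 200
    locus_length: int | tuple[int, int] = (150, 300)
    individuals_per_species: int = 1
    eps: float = 0.001
    depth: DepthModel = field(default_factory=lambda: DepthModel("poisson", 30.0))
    locus_class: str = "noncoding"
    min_gap: int = 2100  # inter-locus spacer, > the 2 kb extraction gap
    chrom: str = "chr1"
    repeat_loci: Mapping[int, tuple[float, float]] = field(default_factory=dict)
    #: species whose first haplotype of the first individual is the reference
    reference_species: str | None = None
    qual: float = 999.0

    def __post_init__(self) -> None:
        if self.n_loci < 1 or self.individuals_per_species < 1:
            raise ValueError("counts must be >= 1")
        if not (0.0 <= self.eps < 0.5):
            raise ValueError("eps must be in [0, 0.5)")
        if isinstance(self.locus_length, tuple):
            lo, hi = self.locus_length
            if lo < 1 or hi < lo:
                raise ValueError("bad locus length range")
        elif self.locus_length < 1:
            raise ValueError("locus length must be >= 1")


@dataclass
class SimulatedDataset:
    config: SimConfig
    seed: int
    individuals: list[str]
    imap: dict[str, str]
    planted: list  # list[LocusSpec]
    gene_trees: list[GeneTree]
    true_alignments: dict[int, dict[str, str]]  # locus index -> individual -> IUPAC truth
    paths: dict[str, str]
    chrom_length: int


def _locus_lengths(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(cfg.locus_length, tuple):
        lo, hi = cfg.locus_length
        return rng.integers(lo, hi + 1, size=cfg.n_loci)
    return np.full(cfg.n_loci, int(cfg.locus_length), dtype=np.int64)


def generate_dataset(net: SpeciesNetwork, cfg: SimConfig, out_dir: str, seed: int) -> SimulatedDataset:
    """Simulate a full synthetic dataset and write it to ``out_dir``.

    Loci are laid on one synthetic chromosome separated by ``min_gap``
    spacers, and the annotation is written so that locus extraction
    re-derives exactly the planted loci: for a noncoding dataset the spacers
    are annotated as exons (making each planted locus one noncoding region);
    for a coding dataset each planted locus is an annotated exon.  Output is
    deterministic for a fixed seed.
    """
    import os

    from .locus_builder import LocusSpec, write_locus_bed

    issues = validate_network(net)
    if issues:
        raise ValueError("invalid network: " + "; ".join(issues))
    ref_species = cfg.reference_species or net.tips[0]
    if ref_species not in net.tips:
        raise ValueError(f"reference species {ref_species!r} is not a network tip")

    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    species = net.tips
    individuals = [f"{sp}{i}" for sp in species for i in range(cfg.individuals_per_species)]
    imap = {f"{sp}{i}": sp for sp in species for i in range(cfg.individuals_per_species)}
    samples = {sp: [f"{sp}{i}_{ab}" for i in range(cfg.individuals_per_species) for ab in "ab"] for sp in species}

    lengths = _locus_lengths(cfg, rng)
    starts = np.concatenate([[cfg.min_gap], cfg.min_gap + np.cumsum(lengths + cfg.min_gap)[:-1]])
    chrom_len = int(starts[-1] + lengths[-1] + cfg.min_gap)

    planted = [
        LocusSpec(cfg.chrom, int(s), int(s + l), cfg.locus_class, cfg.chrom)
        for s, l in zip(starts, lengths)
    ]

    # reference chromosome backbone: random sequence, locus spans overwritten below
    ref_codes = rng.integers(0, 4, size=chrom_len).astype(np.int64)

    gene_trees: list[GeneTree] = []
    true_alignments: dict[int, dict[str, str]] = {}
    vcf_rows: list[str] = []
    repeat_rows: list[tuple[int, int]] = []

    for li, spec in enumerate(planted):
        tree = simulate_gene_tree(net, samples, rng)
        haps = simulate_alignment(tree, spec.length, rng)
        gene_trees.append(tree)
        # reference = designated haplotype, projected onto the chromosome
        ref_hap = haps[f"{ref_species}0_a"]
        ref_codes[spec.start : spec.end] = ref_hap
        pairs = [(haps[f"{ind}_a"], haps[f"{ind}_b"]) for ind in individuals]
        truth = {
            ind: "".join(
                diploid_code(chr(_BASE_CODES[a]), chr(_BASE_CODES[b]))
                for a, b in zip(h1, h2)
            )
            for ind, (h1, h2) in zip(individuals, pairs)
        }
        true_alignments[li] = truth
        calls = diploidize_and_genotype(pairs, ref_hap, cfg.depth, cfg.eps, rng)
        vcf_rows.extend(_vcf_lines(cfg.chrom, spec.start, ref_hap, individuals, calls, cfg.qual))
        if li in cfg.repeat_loci:
            f0, f1 = cfg.repeat_loci[li]
            repeat_rows.append(
                (spec.start + int(f0 * spec.length), spec.start + int(f1 * spec.length))
            )

    paths = {
        "reference": os.path.join(out_dir, "reference.fa"),
        "gff": os.path.join(out_dir, "annotation.gff3"),
        "repeats": os.path.join(out_dir, "repeats.bed"),
        "vcf": os.path.join(out_dir, "calls.vcf"),
        "trees": os.path.join(out_dir, "gene_trees.nwk"),
        "loci": os.path.join(out_dir, "planted_loci.bed"),
        "imap": os.path.join(out_dir, "imap.txt"),
    }
    _write_fasta_codes(cfg.chrom, ref_codes, paths["reference"])
    _write_gff(cfg, planted, chrom_len, paths["gff"])
    with open(paths["repeats"], "w") as fh:
        for s, e in repeat_rows:
            fh.write(f"{cfg.chrom}\t{s}\t{e}\trepeat\n")
    _write_vcf(cfg.chrom, chrom_len, individuals, vcf_rows, paths["vcf"])
    with open(paths["trees"], "w") as fh:
        for li, tree in enumerate(gene_trees):
            fh.write(f"{tree.to_newick()}\n")
    write_locus_bed(planted, paths["loci"])
    from .locus_builder import write_imap

    write_imap(imap, paths["imap"])

    return SimulatedDataset(
        config=cfg,
        seed=seed,
        individuals=individuals,
        imap=imap,
        planted=planted,
        gene_trees=gene_trees,
        true_alignments=true_alignments,
        paths=paths,
        chrom_length=chrom_len,
    )


def _write_fasta_codes(chrom: str, codes: np.ndarray, path: str, width: int = 70) -> None:
    seq = codes_to_str(codes)
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def _write_gff(cfg: SimConfig, planted, chrom_len: int, path: str) -> None:
    """Exon annotation making extraction recover exactly the planted loci."""
    if cfg.locus_class == "coding":
        exons = [(spec.start, spec.end) for spec in planted]
    else:
        # annotate the spacers as exons; planted loci become the noncoding regions
        exons = []
        cursor = 0
        for spec in planted:
            if spec.start > cursor:
                exons.append((cursor, spec.start))
            cursor = spec.end
        if cursor < chrom_len:
            exons.append((cursor, chrom_len))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {cfg.chrom} 1 {chrom_len}\n")
        for i, (s, e) in enumerate(exons):
            fh.write(
                f"{cfg.chrom}\theliopipe\texon\t{s + 1}\t{e}\t.\t+\t.\tID=exon{i}\n"
            )


def _vcf_lines(
    chrom: str,
    start0: int,
    ref_hap: np.ndarray,
    individuals: Sequence[str],
    calls: SiteCalls,
    qual: float,
) -> list[str]:
    lines = []
    length = len(ref_hap)
    n_ind = len(individuals)
    for s in range(length):
        ref_base = chr(_BASE_CODES[ref_hap[s]])
        # collect alt alleles among called genotypes
        alts: list[str] = []
        sample_fields = []
        for j in range(n_ind):
            dp = int(calls.dp[j][s])
            if dp == 0 or calls.called[j][s] == "N":
                sample_fields.append("./.:%d:.:." % dp)
                continue
            maj = chr(_BASE_CODES[calls.major[j][s]])
            oth = chr(_BASE_CODES[calls.other[j][s]])
            code = calls.called[j][s]
            a1, a2 = _alleles(code)
            idx = []
            for a in (a1, a2):
                if a == ref_base:
                    idx.append(0)
                else:
                    if a not in alts:
                        alts.append(a)
                    idx.append(1 + alts.index(a))
            idx.sort()
            # AD ordered REF, then alts; reads split between major/other alleles
            ad = {ref_base: 0}
            ad[maj] = int(calls.ad_major[j][s])
            ad[oth] = ad.get(oth, 0) + int(calls.ad_other[j][s])
            sample_fields.append(
                (
                    f"{idx[0]}/{idx[1]}:{dp}:{int(calls.gq[j][s])}:" ,
                    ad,
                )
            )
        # second pass to format AD now that the alt list is complete
        formatted = []
        for field_ in sample_fields:
            if isinstance(field_, str):
                formatted.append(field_)
            else:
                prefix, ad = field_
                ordered = [ad.get(ref_base, 0)] + [ad.get(a, 0) for a in alts]
                formatted.append(prefix + ",".join(str(x) for x in ordered))
        alt_field = ",".join(alts) if alts else "."
        lines.append(
            f"{chrom}\t{start0 + s + 1}\t.\t{ref_base}\t{alt_field}\t{qual:g}\t.\t.\t"
            "GT:DP:GQ:AD\t" + "\t".join(formatted)
        )
    return lines


def _write_vcf(chrom: str, chrom_len: int, individuals: Sequence[str], rows: list[str], path: str) -> None:
    header = [
        "##fileformat=VCFv4.2",
        "##source=heliopipe-synthetic",
        f"##contig=<ID={chrom},length={chrom_len}>",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(individuals),
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        for row in rows:
            fh.write(row + "\n")
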