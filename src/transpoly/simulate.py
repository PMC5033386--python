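"""Synthetic data generator with known ground truth.

Emulates the assumed evolutionary and sequencing process behind a corvid-style
MHC IIB amplicon study: a handful of deep gene-duplication events founds
allelic lineages tens of My before the species radiate; within each lineage
the gene tree follows the species tree, with within-species allele
genealogies kept anciently divergent (balancing selection maintains allele
lineages far longer than neutral drift would); sequences evolve under HKY+G4
with an elevated nonsynonymous rate at peptide-binding-region codons;
optional short-tract gene conversion homogenises same-species alleles; and
finally individuals are genotyped by noisy, PCR-replicated amplicon reads
carrying MID tags, point errors and PCR chimeras.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from scipy.stats import gamma as gamma_dist

from .alignment import DEFAULT_PBR_CODONS, AlleleAlignment
from .codon import BASES, GENETIC_CODE, SENSE_CODONS, STOP_CODONS, is_transition
from .genotype import Read, ReadBatch, demultiplex

# Fixed 7-taxon, 4-genus corvid-like species set.
SPECIES_GENUS = {
    "Cobr": "Corvus",
    "Coco": "Corvus",
    "Coma": "Corvus",
    "Cofr": "Corvus",
    "Gagl": "Garrulus",
    "Pipi": "Pica",
    "Cycy": "Cyanopica",
}

# Ultrametric species tree (branch lengths in My): crows radiate recently,
# the four genera split successively back to a 20 My family root.
DEFAULT_SPECIES_TREE = (
    "((((((Cobr:1.5,Coco:1.5):1.0,Coma:2.5):3.5,Cofr:6.0):8.0,"
    "Pipi:14.0):3.0,Gagl:17.0):3.0,Cycy:20.0);"
)

PRIMER_F = "GAGTGTCATTTCTACAACGG"
PRIMER_R = "CTGGTAGTTGTGTCTGCAGT"


@dataclass
class SimConfig:
    """Parameters of the simulated evolutionary and sequencing process.

    Times are My before present; rates are substitutions/site/My unless
    noted.  Defaults encode the study scenario: four lineage-founding
    duplications (three at 53 My, one at 49.1 My), a 248 nt exon-2 fragment
    read in frame 0 (82 complete codons), a zebra-finch-scale neutral rate,
    and a PBR nonsynonymous multiplier that puts the whole-fragment dN/dS in
    the 1.3-1.6 band.
    """

    duplication_times: tuple[float, ...] = (53.0, 53.0, 53.0, 49.1)
    species_tree: str = DEFAULT_SPECIES_TREE
    species_genus: dict[str, str] = field(default_factory=lambda: dict(SPECIES_GENUS))
    n_alleles_per_species_per_lineage: int = 2
    n_individuals_per_species: int = 3
    neutral_rate: float = 2.21e-3  # subs/site/My (zebra-finch-scale)
    kappa: float = 4.0  # HKY transition/transversion rate ratio
    gamma_shape: float = 1.0
    pbr_omega: float = 3.0  # nonsynonymous rate multiplier at PBR codons
    pbr_codons: frozenset[int] = field(default_factory=lambda: DEFAULT_PBR_CODONS)
    conversion_rate: float = 0.0  # events per lineage per My
    conversion_tract: int = 30  # nt
    fragment_length: int = 248
    frame_offset: int = 0
    allele_floor_my: float = 6.0  # balancing-selection allele persistence floor
    coalescent_mean_my: float = 3.0  # within-species pairwise coalescent scale
    ancestral_jitter_my: float = 1.5  # extra waiting beyond speciation nodes
    tmrca_cap_fraction: float = 0.8  # lineage TMRCA forced below this x founding
    read_depth_mean: float = 60.0  # reads per allele per replicate
    error_rate: float = 0.003  # per base
    chimera_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if not self.duplication_times or any(t <= 0 for t in self.duplication_times):
            raise ValueError("duplication times must be positive")
        if self.n_alleles_per_species_per_lineage < 1:
            raise ValueError("need >= 1 allele per species per lineage")
        for name, v in (
            ("neutral_rate", self.neutral_rate),
            ("conversion_rate", self.conversion_rate),
            ("error_rate", self.error_rate),
        ):
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.chimera_fraction < 1:
            raise ValueError("chimera_fraction must be in [0, 1)")
        if not 0 < self.tmrca_cap_fraction < 1:
            raise ValueError("tmrca_cap_fraction must be in (0, 1)")
        root_age = species_tree_root_age(self.species_tree)
        if min(self.duplication_times) < root_age:
            raise ValueError(
                f"duplication time {min(self.duplication_times)} My younger than the "
                f"oldest species split ({root_age} My): scenario unrealizable"
            )

    def n_lineages(self) -> int:
        return len(self.duplication_times)


# ---------------------------------------------------------------------------
# gene-genealogy nodes


@dataclass
class GeneNode:
    label: str | None
    age: float  # My before present
    children: list["GeneNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["GeneNode"]:
        if self.is_leaf:
            return [self]
        out: list[GeneNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def newick(self) -> str:
        def fmt(node: GeneNode, parent_age: float) -> str:
            bl = parent_age - node.age
            if node.is_leaf:
                return f"{node.label}[&age={node.age:.6g}]:{bl:.6g}"
            inner = ",".join(fmt(c, node.age) for c in node.children)
            return f"({inner})[&age={node.age:.6g}]:{bl:.6g}"

        inner = ",".join(fmt(c, self.age) for c in self.children)
        return f"({inner})[&age={self.age:.6g}];"

    def scale_internal_ages(self, factor: float) -> None:
        for n in self.postorder():
            if not n.is_leaf:
                n.age *= factor


@dataclass
class SimTruth:
    genealogy: GeneNode | None = None
    lineage_membership: dict[str, str] = field(default_factory=dict)
    lineage_founding: dict[str, float] = field(default_factory=dict)
    conversion_events: list[dict] = field(default_factory=list)
    chimera_reads: list[dict] = field(default_factory=list)
    true_alignment: AlleleAlignment | None = None
    individuals: dict[str, dict] = field(default_factory=dict)
    # true substitution events tallied during sequence evolution
    substitution_counts: dict = field(default_factory=dict)
    # realized per-allele read depth: individual -> replicate -> allele -> n
    read_depths: dict[str, dict[str, dict[str, int]]] = field(default_factory=dict)

    def lineage_tmrcas(self) -> dict[str, float]:
        """TMRCA of each lineage's members in the genealogy."""
        out = {}
        for lid in sorted(set(self.lineage_membership.values())):
            members = {a for a, l in self.lineage_membership.items() if l == lid}
            out[lid] = _tmrca(self.genealogy, members)
        return out

    def to_json(self, path: str | Path) -> None:
        obj = {
            "genealogy_newick": self.genealogy.newick() if self.genealogy else None,
            "lineage_membership": self.lineage_membership,
            "lineage_founding": self.lineage_founding,
            "conversion_events": self.conversion_events,
            "chimera_reads": self.chimera_reads,
            "true_alleles": (
                dict(zip(self.true_alignment.labels, self.true_alignment.seqs))
                if self.true_alignment
                else None
            ),
            "individuals": self.individuals,
        }
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def _tmrca(root: GeneNode, members: set[str]) -> float:
    best = None
    for node in root.postorder():
        labs = {l.label for l in node.leaves()}
        if members <= labs and (best is None or node.age < best):
            best = node.age
    return best


# ---------------------------------------------------------------------------
# species tree parsing


def _parse_species_tree(newick: str) -> GeneNode:
    t = dendropy.Tree.get(data=newick, schema="newick")
    t.calc_node_ages(ultrametricity_precision=1e-3)

    def conv(nd) -> GeneNode:
        label = nd.taxon.label if nd.taxon else None
        return GeneNode(
            label=label,
            age=float(nd.age),
            children=[conv(c) for c in nd.child_nodes()],
        )

    return conv(t.seed_node)


def species_tree_root_age(newick: str) -> float:
    return _parse_species_tree(newick).age


# ---------------------------------------------------------------------------
# OP: simulate_gene_genealogy


def simulate_gene_genealogy(cfg: SimConfig) -> tuple[GeneNode, SimTruth]:
    """Simulate the multi-lineage gene genealogy.

    Each lineage carries a copy of the species tree; within a species the
    alleles of that lineage coalesce among themselves no more recently than
    ``allele_floor_my`` (balancing selection maintains divergent alleles) and
    the between-species joins happen at the species split or as soon after
    it as the allele lines allow.  Lineages are joined by a budding
    caterpillar at their founding duplication times (oldest outermost); a
    lineage's internal ages are rescaled if they would exceed
    ``tmrca_cap_fraction`` of its founding time, so every lineage TMRCA is
    strictly younger than its founding duplication.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0])
    sp_root = _parse_species_tree(cfg.species_tree)
    k = cfg.n_lineages()
    order = sorted(range(k), key=lambda i: (-cfg.duplication_times[i], i))
    truth = SimTruth()

    subtrees: dict[int, GeneNode] = {}
    for pos, li in enumerate(order):
        lid = f"L{li + 1}"
        # attach age: trunk (pos 0) attaches at the youngest other founding
        if pos == 0:
            attach = min(cfg.duplication_times[j] for j in order[1:]) if k > 1 else cfg.duplication_times[li]
        else:
            attach = cfg.duplication_times[li]
        sub = _lineage_gene_tree(lid, cfg, sp_root, rng)
        cap = cfg.tmrca_cap_fraction * attach
        if sub.age > cap:
            sub.scale_internal_ages(cap / sub.age)
        subtrees[li] = sub
        for leaf in sub.leaves():
            truth.lineage_membership[leaf.label] = lid
        truth.lineage_founding[lid] = float(cfg.duplication_times[li])

    # budding caterpillar: youngest lineages join the trunk first
    current = subtrees[order[0]]
    for li in sorted(order[1:], key=lambda i: (cfg.duplication_times[i], i)):
        t = cfg.duplication_times[li]
        current = GeneNode(label=None, age=t, children=[subtrees[li], current])
    truth.genealogy = current
    return current, truth


def _lineage_gene_tree(lid: str, cfg: SimConfig, sp_root: GeneNode, rng) -> GeneNode:
    theta = cfg.coalescent_mean_my
    floor = cfg.allele_floor_my

    def build(sp_node: GeneNode) -> GeneNode:
        if sp_node.is_leaf:
            n = cfg.n_alleles_per_species_per_lineage
            tips = [
                GeneNode(label=f"{sp_node.label}_{lid}_{a + 1}", age=0.0)
                for a in range(n)
            ]
            if n == 1:
                return tips[0]
            # within-species coalescent, started at the persistence floor
            nodes = tips
            t = floor
            while len(nodes) > 1:
                kk = len(nodes)
                t += float(rng.exponential(theta / (kk * (kk - 1) / 2.0)))
                i, j = sorted(rng.choice(kk, size=2, replace=False))
                joined = GeneNode(label=None, age=t, children=[nodes[i], nodes[j]])
                nodes = [nd for idx, nd in enumerate(nodes) if idx not in (i, j)]
                nodes.append(joined)
            return nodes[0]
        kids = [build(c) for c in sp_node.children]
        t = max([sp_node.age, floor] + [kid.age for kid in kids]) + float(
            rng.exponential(cfg.ancestral_jitter_my)
        )
        node = kids[0]
        for kid in kids[1:]:
            node = GeneNode(label=None, age=t, children=[node, kid])
        return node

    return build(sp_root)


# ---------------------------------------------------------------------------
# OP: evolve_alignment


def _gamma_category_rates(shape: float, ncat: int = 4) -> np.ndarray:
    """Discrete gamma rates, median method, normalised to mean 1."""
    q = (2 * np.arange(ncat) + 1) / (2.0 * ncat)
    r = gamma_dist.ppf(q, a=shape, scale=1.0 / shape)
    return r / r.mean()


def _codon_targets():
    """Per sense codon: list of (pos, base, target_index_or_None, is_ts, is_syn)."""
    table = []
    for c in SENSE_CODONS:
        rows = []
        for pos in range(3):
            for b in BASES:
                if b == c[pos]:
                    continue
                alt = c[:pos] + b + c[pos + 1 :]
                if alt in STOP_CODONS:
                    rows.append((pos, None, False, False))
                    continue
                rows.append(
                    (
                        pos,
                        SENSE_CODONS.index(alt),
                        is_transition(c[pos], b),
                        GENETIC_CODE[alt] == GENETIC_CODE[c],
                    )
                )
        table.append(rows)
    return table


_TARGETS = None


def _targets():
    global _TARGETS
    if _TARGETS is None:
        _TARGETS = _codon_targets()
    return _TARGETS


def evolve_alignment(
    genealogy: GeneNode, cfg: SimConfig, truth: SimTruth | None = None
) -> tuple[AlleleAlignment, SimTruth]:
    """Evolve sequences down the genealogy under HKY+G4 with selection.

    Substitutions are simulated codon-wise as a jump process; changes that
    would create a stop codon are forbidden, and nonsynonymous changes at
    PBR codons are accelerated by ``pbr_omega``.  Sites after the last
    complete codon evolve as unconstrained HKY sites.  Branch lengths are
    node-age differences (My) times ``neutral_rate``.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    if truth is None:
        truth = SimTruth(genealogy=genealogy)
    L = cfg.fragment_length
    off = cfg.frame_offset
    n_codons = (L - off) // 3
    tail = L - off - 3 * n_codons
    targets = _targets()
    beta = cfg.neutral_rate / (cfg.kappa + 2.0)  # per-site HKY scale
    cat_rates = _gamma_category_rates(cfg.gamma_shape)
    site_rates = cat_rates[rng.integers(0, 4, size=L)]
    pbr = cfg.pbr_codons

    root_codons = list(rng.integers(0, len(SENSE_CODONS), size=n_codons))
    root_head = [int(b) for b in rng.integers(0, 4, size=off)]
    root_tail = [int(b) for b in rng.integers(0, 4, size=tail)]

    exp = rng.exponential
    uni = rng.random

    events = {"syn": 0, "nonsyn": 0, "syn_pbr": 0, "nonsyn_pbr": 0}

    def evolve_codon(ci: int, codon_pos: int, dt_my: float) -> int:
        base0 = off + 3 * codon_pos
        in_pbr = codon_pos in pbr
        omega = cfg.pbr_omega if in_pbr else 1.0
        t = 0.0
        while True:
            rows = targets[ci]
            rates = []
            tot = 0.0
            for pos, tgt, ts, syn in rows:
                if tgt is None:
                    rates.append(0.0)
                    continue
                r = beta * (cfg.kappa if ts else 1.0) * site_rates[base0 + pos]
                if not syn:
                    r *= omega
                rates.append(r)
                tot += r
            if tot <= 0:
                return ci
            t += exp(1.0 / tot)
            if t > dt_my:
                return ci
            u = uni() * tot
            acc = 0.0
            for (pos, tgt, ts, syn), r in zip(rows, rates):
                acc += r
                if u <= acc:
                    ci = tgt
                    key = "syn" if syn else "nonsyn"
                    events[key] += 1
                    if in_pbr:
                        events[key + "_pbr"] += 1
                    break

    def evolve_site(b: int, site: int, dt_my: float) -> int:
        tot = beta * (cfg.kappa + 2.0) * site_rates[site]
        t = 0.0
        while True:
            t += exp(1.0 / tot)
            if t > dt_my:
                return b
            u = uni() * (cfg.kappa + 2.0)
            # targets: one transition (weight kappa) + two transversions
            trans = {0: 2, 1: 3, 2: 0, 3: 1}[b]  # A<->G, C<->T in ACGT coding
            if u <= cfg.kappa:
                b = trans
            else:
                others = [x for x in range(4) if x not in (b, trans)]
                b = others[0] if (u - cfg.kappa) <= 1.0 else others[1]

    seqs: dict[str, str] = {}

    def walk(node: GeneNode, codons: list[int], head: list[int], tl: list[int]) -> None:
        if node.is_leaf:
            s = (
                "".join("ACGT"[b] for b in head)
                + "".join(SENSE_CODONS[c] for c in codons)
                + "".join("ACGT"[b] for b in tl)
            )
            seqs[node.label] = s
            return
        for child in node.children:
            dt = node.age - child.age
            if dt < 0:
                raise ValueError("genealogy ages not monotone")
            cc = [evolve_codon(c, i, dt) for i, c in enumerate(codons)]
            hh = [evolve_site(b, i, dt) for i, b in enumerate(head)]
            tt = [evolve_site(b, off + 3 * n_codons + i, dt) for i, b in enumerate(tl)]
            walk(child, cc, hh, tt)

    walk(genealogy, root_codons, root_head, root_tail)
    labels = sorted(seqs)
    species = [lab.split("_")[0] for lab in labels]
    genus = [cfg.species_genus.get(sp, "unknown") for sp in species]
    aln = AlleleAlignment(
        labels=labels,
        seqs=[seqs[lab] for lab in labels],
        species=species,
        genus=genus,
        frame_offset=off,
        pbr_codons=frozenset(c for c in pbr if c < n_codons),
    )
    truth.true_alignment = aln
    truth.substitution_counts = events
    return aln, truth


def realized_dnds(truth: SimTruth, cfg: SimConfig, partition: str = "full") -> float:
    """Realized dN/dS from the true substitution events.

    Nonsynonymous and synonymous event counts are divided by the
    mutational-opportunity site counts of the true alignment (modified
    Nei-Gojobori sites with R = the simulating kappa, so a neutral run is
    calibrated to 1 by construction); ``partition`` in {'full', 'pbr',
    'non_pbr'}.
    """
    ev = truth.substitution_counts
    aln = truth.true_alignment
    if not ev or aln is None:
        raise ValueError("no substitution counts recorded")
    # mutational-opportunity weights per codon column, averaged over the true
    # sequences: transition weight kappa, transversion 1, stop targets
    # excluded — exactly the jump-process rates, so a neutral run has
    # expected ratio 1 by construction
    from .codon import CODON_INDEX, codons_of

    n_codons = aln.n_codons
    pbr = sorted(c for c in aln.pbr_codons if c < n_codons)
    import numpy as _np

    tgt = _targets()
    w_syn = _np.zeros(len(SENSE_CODONS))
    w_non = _np.zeros(len(SENSE_CODONS))
    for ci in range(len(SENSE_CODONS)):
        for pos, t, ts, syn in tgt[ci]:
            if t is None:
                continue
            w = cfg.kappa if ts else 1.0
            if syn:
                w_syn[ci] += w
            else:
                w_non[ci] += w
    N = _np.zeros(n_codons)
    S = _np.zeros(n_codons)
    for seq in aln.seqs:
        for k, c in enumerate(codons_of(seq, aln.frame_offset)):
            ci = CODON_INDEX.get(c)
            if ci is not None:
                N[k] += w_non[ci]
                S[k] += w_syn[ci]
    N /= len(aln.seqs)
    S /= len(aln.seqs)
    if partition == "full":
        cols = _np.arange(n_codons)
        nd = ev["nonsyn"]
        sd = ev["syn"]
    elif partition == "pbr":
        cols = _np.asarray(pbr, dtype=int)
        nd = ev["nonsyn_pbr"]
        sd = ev["syn_pbr"]
    elif partition == "non_pbr":
        cols = _np.setdiff1d(_np.arange(n_codons), _np.asarray(pbr, dtype=int))
        nd = ev["nonsyn"] - ev["nonsyn_pbr"]
        sd = ev["syn"] - ev["syn_pbr"]
    else:
        raise ValueError(f"unknown partition {partition!r}")
    if sd == 0:
        raise ValueError("no synonymous events recorded")
    return (nd / N[cols].sum()) / (sd / S[cols].sum())


# ---------------------------------------------------------------------------
# OP: apply_gene_conversion


def apply_gene_conversion(
    aln: AlleleAlignment, genealogy: GeneNode, cfg: SimConfig, truth: SimTruth
) -> tuple[AlleleAlignment, SimTruth]:
    """Copy short tracts between same-species alleles (non-reciprocal).

    The number of events per lineage is Poisson(conversion_rate x founding
    age); donor and acceptor are two distinct alleles of one species (any
    lineage), so conversion homogenises same-species alleles across
    paralogous lineages.
    """
    if cfg.conversion_tract > aln.length:
        raise ValueError("conversion tract longer than fragment")
    rng = np.random.default_rng([cfg.seed, 2])
    seqs = dict(zip(aln.labels, aln.seqs))
    by_species: dict[str, list[str]] = {}
    for lab, sp in zip(aln.labels, aln.species):
        by_species.setdefault(sp, []).append(lab)
    eligible = sorted(sp for sp, labs in by_species.items() if len(labs) >= 2)

    for lid, founding in sorted(truth.lineage_founding.items()):
        n_events = int(rng.poisson(cfg.conversion_rate * founding))
        for _ in range(n_events):
            if not eligible:
                break
            sp = eligible[int(rng.integers(0, len(eligible)))]
            labs = by_species[sp]
            i, j = rng.choice(len(labs), size=2, replace=False)
            donor, acceptor = labs[int(i)], labs[int(j)]
            start = int(rng.integers(0, aln.length - cfg.conversion_tract + 1))
            end = start + cfg.conversion_tract
            seqs[acceptor] = (
                seqs[acceptor][:start] + seqs[donor][start:end] + seqs[acceptor][end:]
            )
            truth.conversion_events.append(
                {"lineage": lid, "donor": donor, "acceptor": acceptor,
                 "start": start, "end": end}
            )
    new = AlleleAlignment(
        labels=list(aln.labels),
        seqs=[seqs[lab] for lab in aln.labels],
        species=list(aln.species),
        genus=list(aln.genus),
        frame_offset=aln.frame_offset,
        pbr_codons=aln.pbr_codons,
    )
    truth.true_alignment = new
    return new, truth


# ---------------------------------------------------------------------------
# OP: generate_amplicon_reads


@dataclass
class SimReads:
    raw_reads: list[tuple[str, str]]  # (read_id, tagged sequence)
    mid_table: dict[tuple[str, str], tuple[str, str]]
    batches: list[ReadBatch]  # trimmed, grouped by (individual, replicate)
    species_map: dict[str, tuple[str, str]]  # individual -> (species, genus)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, seq in self.raw_reads:
                fh.write(f">{rid}\n{seq}\n")

    def mid_table_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("fwd_tag\trev_tag\tindividual\treplicate\n")
            for (f, r), (ind, rep) in sorted(self.mid_table.items(), key=lambda x: x[1]):
                fh.write(f"{f}\t{r}\t{ind}\t{rep}\n")


def _random_tags(rng, n: int, length: int = 8) -> list[str]:
    tags: set[str] = set()
    while len(tags) < n:
        tags.add("".join("ACGT"[b] for b in rng.integers(0, 4, size=length)))
    return sorted(tags)


def generate_amplicon_reads(
    aln: AlleleAlignment, cfg: SimConfig, truth: SimTruth
) -> tuple[SimReads, SimTruth]:
    """Assign alleles to diploid individuals and emit replicated noisy reads.

    Every individual receives two allele copies per lineage (drawn with
    replacement from its species' lineage alleles, so homozygosity is
    possible); each distinct allele gets a Poisson read depth per replicate.
    A ``chimera_fraction`` of reads are two-parent recombinants with a
    single uniform breakpoint; point errors hit the fragment at
    ``error_rate`` per base.  Reads carry MID tags and primers.
    """
    if cfg.read_depth_mean < 1:
        raise ValueError("read_depth_mean must be >= 1")
    rng = np.random.default_rng([cfg.seed, 3])
    L = aln.length
    seq_of = dict(zip(aln.labels, aln.seqs))
    by_sp_lineage: dict[tuple[str, str], list[str]] = {}
    for lab, sp in zip(aln.labels, aln.species):
        lid = truth.lineage_membership.get(lab, "L1")
        by_sp_lineage.setdefault((sp, lid), []).append(lab)
    species = sorted(set(aln.species))
    lineages = sorted(set(truth.lineage_membership.values()) or {"L1"})

    # individuals and their allele assignments
    individuals: list[str] = []
    for sp in species:
        for i in range(cfg.n_individuals_per_species):
            ind = f"{sp}_i{i + 1}"
            individuals.append(ind)
            assigned: dict[str, list[str]] = {}
            for lid in lineages:
                pool = sorted(by_sp_lineage.get((sp, lid), []))
                if not pool:
                    continue
                picks = [pool[int(x)] for x in rng.integers(0, len(pool), size=2)]
                assigned[lid] = picks
            truth.individuals[ind] = {
                "species": sp,
                "genus": aln.genus[aln.species.index(sp)],
                "alleles_by_lineage": assigned,
            }

    # MID tags: one (fwd, rev) pair per (individual, replicate)
    n_pairs = 2 * len(individuals)
    fwd_tags = _random_tags(rng, n_pairs)
    rev_tags = _random_tags(rng, n_pairs)
    mid_table: dict[tuple[str, str], tuple[str, str]] = {}
    pair_of: dict[tuple[str, str], tuple[str, str]] = {}
    idx = 0
    for ind in individuals:
        for rep in ("A", "B"):
            mid_table[(fwd_tags[idx], rev_tags[idx])] = (ind, rep)
            pair_of[(ind, rep)] = (fwd_tags[idx], rev_tags[idx])
            idx += 1

    raw: list[tuple[str, str]] = []
    species_map = {
        ind: (truth.individuals[ind]["species"], truth.individuals[ind]["genus"])
        for ind in individuals
    }
    for ind in individuals:
        carried = sorted(
            {a for labs in truth.individuals[ind]["alleles_by_lineage"].values() for a in labs}
        )
        truth.read_depths[ind] = {"A": {}, "B": {}}
        for rep in ("A", "B"):
            counter = 0
            fwd, rev = pair_of[(ind, rep)]
            for allele in carried:
                depth = int(rng.poisson(cfg.read_depth_mean))
                truth.read_depths[ind][rep][allele] = depth
                for _ in range(depth):
                    counter += 1
                    rid = f"{ind}|{rep}|read{counter}"
                    if len(carried) >= 2 and rng.random() < cfg.chimera_fraction:
                        other = carried[int(rng.integers(0, len(carried)))]
                        while other == allele and len(carried) > 1:
                            other = carried[int(rng.integers(0, len(carried)))]
                        bp = int(rng.integers(1, L))
                        frag = seq_of[allele][:bp] + seq_of[other][bp:]
                        truth.chimera_reads.append(
                            {"read": rid, "parent1": allele, "parent2": other,
                             "breakpoint": bp}
                        )
                    else:
                        frag = seq_of[allele]
                    if cfg.error_rate > 0:
                        errs = np.nonzero(rng.random(L) < cfg.error_rate)[0]
                        if errs.size:
                            fl = list(frag)
                            for pos in errs:
                                cur = fl[pos]
                                alts = [b for b in "ACGT" if b != cur]
                                fl[pos] = alts[int(rng.integers(0, 3))]
                            frag = "".join(fl)
                    raw.append((rid, fwd + PRIMER_F + frag + PRIMER_R + rev))

    batches, _ = demultiplex(
        [seq for _, seq in raw],
        mid_table,
        fwd_primer_len=len(PRIMER_F),
        rev_primer_len=len(PRIMER_R),
    )
    reads = SimReads(
        raw_reads=raw, mid_table=mid_table, batches=batches, species_map=species_map
    )
    return reads, truth


# ---------------------------------------------------------------------------
# one-call convenience


def simulate_dataset(cfg: SimConfig):
    """Genealogy -> alignment -> (optional conversion) -> replicated reads."""
    genealogy, truth = simulate_gene_genealogy(cfg)
    aln, truth = evolve_alignment(genealogy, cfg, truth)
    if cfg.conversion_rate > 0:
        aln, truth = apply_gene_conversion(aln, genealogy, cfg, truth)
    reads, truth = generate_amplicon_reads(aln, cfg, truth)
    return aln, reads, truth


__all__ = [
    "SimConfig",
    "SimTruth",
    "SimReads",
    "GeneNode",
    "SPECIES_GENUS",
    "DEFAULT_SPECIES_TREE",
    "simulate_gene_genealogy",
    "evolve_alignment",
    "realized_dnds",
    "apply_gene_conversion",
    "generate_amplicon_reads",
    "simulate_dataset",
    "species_tree_root_age",
]
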