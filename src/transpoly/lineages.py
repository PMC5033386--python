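"""Trans-species allelic lineage detection and motif summaries.

An allelic lineage is a well-supported clade whose members span several
genera: alleles cluster by ancestral gene lineage rather than by species,
the phylogenetic signature of trans-species polymorphism.  Detection walks
the rooted supported tree outermost-first and reports maximal qualifying
clades (a reported lineage is never nested inside another).
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .alignment import AlleleAlignment
from .codon import translate
from .njtree import Node, SupportedTree, midpoint_root


@dataclass
class Lineage:
    id: str
    members: list[str]
    species: set[str]
    genera: set[str]
    support: float

    def __len__(self) -> int:
        return len(self.members)


def _rooted_with_supports(tree: SupportedTree) -> Node:
    root = midpoint_root(tree.root)
    SupportedTree(root=root, supports=tree.supports).annotate()
    return root


def detect_lineages(
    tree: SupportedTree,
    genus_map: dict[str, str],
    species_map: dict[str, str] | None = None,
    support_min: float = 0.75,
    min_genera: int = 4,
) -> list[Lineage]:
    """Maximal supported multi-genus clades, outermost-first.

    The tree is midpoint-rooted and walked from the root; a clade qualifies
    when its bootstrap support is >= ``support_min`` and its members span
    >= ``min_genera`` genera, and the walk does not descend into reported
    clades — with one aggregation guard: a qualifying clade whose leaves
    decompose exactly into two or more qualifying lineage units is reported
    as those units, not as one aggregate.  (Rooting places the root on the
    inter-lineage backbone, so the complement of one lineage can inherit
    that lineage's stem support; without the guard such a complement would
    swallow every other lineage.)  Numbering (L1, L2, ...) follows traversal
    order and is deterministic for a fixed tree.
    """
    root = _rooted_with_supports(tree)
    for leaf in root.leaves():
        if leaf.label not in genus_map:
            raise ValueError(f"leaf {leaf.label!r} missing from genus map")

    def qualifies(node: Node) -> bool:
        if node is root or node.is_leaf or node.support is None:
            return False
        genera = {genus_map[l] for l in node.leaf_labels()}
        return node.support >= support_min and len(genera) >= min_genera

    def cover(node: Node) -> list[Node] | None:
        """Decomposition of the clade into qualifying units, or None."""
        if node.is_leaf:
            return None
        parts: list[Node] = []
        complete = True
        for c in node.children:
            cc = cover(c)
            if cc is None:
                complete = False
            else:
                parts.extend(cc)
        if qualifies(node):
            if complete and len(parts) >= 2:
                return parts
            return [node]
        return parts if complete and parts else None

    def top(node: Node) -> list[Node]:
        cc = cover(node)
        if cc is not None:
            return cc
        out: list[Node] = []
        for c in node.children:
            if not c.is_leaf:
                out.extend(top(c))
        return out

    reported = top(root)
    # order by preorder position for stable numbering
    pre = {id(n): i for i, n in enumerate(_preorder(root))}
    reported.sort(key=lambda n: pre[id(n)])

    found: list[Lineage] = []
    for node in reported:
        labels = sorted(node.leaf_labels())
        genera = {genus_map[l] for l in labels}
        found.append(
            Lineage(
                id=f"L{len(found) + 1}",
                members=labels,
                species={species_map[l] for l in labels} if species_map else set(),
                genera=genera,
                support=float(node.support),
            )
        )
    return found


def _preorder(node: Node):
    yield node
    for c in node.children:
        yield from _preorder(c)


def candidate_clusters(
    tree: SupportedTree,
    genus_map: dict[str, str],
    support_min: float = 0.50,
    min_genera: int = 2,
    exclude: list[Lineage] | None = None,
) -> pd.DataFrame:
    """Secondary table of multi-genus clusters below the headline support
    threshold (flagged non-significant); observed-but-unsupported clusters
    are part of the full picture even when no lineage call is made."""
    root = _rooted_with_supports(tree)
    taken = set()
    for ln in exclude or []:
        taken.update(ln.members)
    rows = []
    for node in root.postorder():
        if node.is_leaf or node is root or node.support is None:
            continue
        labels = sorted(node.leaf_labels())
        genera = {genus_map[l] for l in labels}
        if node.support >= support_min and len(genera) >= min_genera and not (
            set(labels) <= taken
        ):
            rows.append(
                {
                    "members": ";".join(labels),
                    "n_members": len(labels),
                    "n_genera": len(genera),
                    "support": round(node.support, 3),
                    "significant": False,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# subsampling over-represented species


def subsample_lineage_members(
    aln: AlleleAlignment,
    lineages: list[Lineage],
    max_per_species: int = 6,
    read_support: dict[str, int] | None = None,
) -> AlleleAlignment:
    """Retain at most ``max_per_species`` alleles per species within each
    lineage (highest read support first, then lexicographic label); alleles
    outside any lineage are untouched."""
    read_support = read_support or {}
    drop: set[str] = set()
    for ln in lineages:
        by_sp: dict[str, list[str]] = defaultdict(list)
        for lab in ln.members:
            i = aln.labels.index(lab)
            by_sp[aln.species[i]].append(lab)
        for sp, labs in sorted(by_sp.items()):
            order = sorted(labs, key=lambda l: (-read_support.get(l, 0), l))
            if len(order) > max_per_species:
                drop.update(order[max_per_species:])
            if max_per_species == 0:
                genera_left = {
                    aln.genus[aln.labels.index(l)]
                    for l in ln.members
                    if l not in drop
                }
                warnings.warn(
                    f"lineage {ln.id}: cap 0 removed species {sp}; genus span "
                    f"now {len(genera_left)}",
                    stacklevel=2,
                )
    keep = [i for i, lab in enumerate(aln.labels) if lab not in drop]
    return aln.subset(keep)


# ---------------------------------------------------------------------------
# amino-acid motif summaries


def motif_summary(
    aln: AlleleAlignment, lineages: list[Lineage]
) -> dict[str, dict]:
    """Per-lineage peptide motifs and cross-lineage diagnostic columns.

    For each lineage: the consensus peptide, per-column conservation
    (modal-residue frequency), and peptides identical across >= 2 genera.
    ``diagnostic_columns`` lists alignment codon columns where the lineage
    consensuses are not all identical.
    """
    idx_of = {lab: i for i, lab in enumerate(aln.labels)}
    out: dict[str, dict] = {}
    consensi: dict[str, str] = {}
    for ln in lineages:
        peptides = {}
        for lab in ln.members:
            i = idx_of[lab]
            pep = translate(aln.seqs[i], aln.frame_offset)
            if "*" in pep:
                raise ValueError(f"internal stop codon in allele {lab!r}")
            peptides[lab] = pep
        L = len(next(iter(peptides.values())))
        cons = []
        conservation = []
        for j in range(L):
            col = Counter(p[j] for p in peptides.values())
            aa, cnt = sorted(col.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            cons.append(aa)
            conservation.append(cnt / len(peptides))
        # peptides shared identically by two or more genera
        by_pep: dict[str, set[str]] = defaultdict(set)
        for lab, pep in peptides.items():
            by_pep[pep].add(aln.genus[idx_of[lab]])
        shared = sorted(p for p, g in by_pep.items() if len(g) >= 2)
        consensus = "".join(cons)
        consensi[ln.id] = consensus
        out[ln.id] = {
            "consensus": consensus,
            "conservation": conservation,
            "cross_genus_identical": shared,
            "peptides": peptides,
        }
    if consensi:
        L = min(len(c) for c in consensi.values())
        diag = [
            j for j in range(L) if len({c[j] for c in consensi.values()}) > 1
        ]
        for ln_id in out:
            out[ln_id]["diagnostic_columns"] = diag
    return out


def annotated_newick(tree, lineages: list[Lineage]) -> str:
    """Newick of the (rooted) tree with leaf labels tagged by lineage id."""
    tag = {}
    for ln in lineages:
        for m in ln.members:
            tag[m] = ln.id
    t = tree.copy() if hasattr(tree, "copy") else tree
    for leaf in t.leaves():
        if leaf.label in tag:
            leaf.label = f"{leaf.label}|{tag[leaf.label]}"
    return t.newick()


def lineage_table(lineages: list[Lineage], aln: AlleleAlignment) -> pd.DataFrame:
    """Membership TSV layout: allele, species, genus, lineage, support."""
    idx_of = {lab: i for i, lab in enumerate(aln.labels)}
    rows = []
    for ln in lineages:
        for lab in ln.members:
            i = idx_of[lab]
            rows.append(
                {
                    "allele": lab,
                    "species": aln.species[i],
                    "genus": aln.genus[i],
                    "lineage": ln.id,
                    "support": round(ln.support, 3),
                }
            )
    return pd.DataFrame(rows)


__all__ = [
    "Lineage",
    "detect_lineages",
    "candidate_clusters",
    "subsample_lineage_members",
    "motif_summary",
    "annotated_newick",
    "lineage_table",
]
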