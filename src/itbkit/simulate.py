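"""Synthetic ground-truth generators for every pipeline stage.

Each generator is deterministic under a fixed seed and returns its inputs
together with an exact truth record, so detectors and the phylogenetic
pipeline can be validated end to end without any external data.

Protein families evolve on a known guide tree under a 20-state equal-rates
model: along a branch of length d (expected substitutions per site) each
site receives a Poisson(d) number of substitution events, each replacing the
residue with one of the 19 others uniformly.  Under this model the expected
observed proportion of differing sites between two sequences at total
distance d is

    E[p] = (19/20) * (1 - exp(-20 d / 19)),

which the tests check against simulation.  No indels are simulated: the
downstream distance stage operates on gap-filtered alignments, so the tested
path is gapless by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import MultipleAlignment
from .motifs import MotifHit, scan_cyto_motifs
from .pairing import PairingTable, format_receptor
from .phylo import FamilyPartition
from .records import AMINO_ACIDS, ProteinRecord
from .regulatory import NucleotideSequence
from .tree import PhyloTree, TreeNode

N_STATES = 20


@dataclass
class SimulationConfig:
    """Settings for simulating protein families on a known tree.

    ``guide_tree`` carries one leaf per family with branch lengths in
    expected substitutions per site; ``taxa_per_family`` leaves are attached
    under each family leaf with pendant lengths drawn uniformly from
    ``intra_family_range``.  ``root_length`` is the number of simulated
    columns.
    """

    guide_tree: PhyloTree
    root_length: int = 370
    taxa_per_family: dict[str, int] = field(default_factory=dict)
    default_taxa_per_family: int = 2
    intra_family_range: tuple[float, float] = (0.02, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.root_length < 1:
            raise ValueError("root_length must be >= 1")
        for node in self.guide_tree.root.walk():
            if node.length < 0:
                raise ValueError("guide tree branch lengths must be >= 0")


def evolve_sequence(parent: np.ndarray, distance: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve one sequence along a branch under the equal-rates model."""
    child = parent.copy()
    n_events = rng.poisson(distance, size=child.shape)
    for site in np.nonzero(n_events)[0]:
        state = child[site]
        for _ in range(n_events[site]):
            # Uniform over the 19 other states.
            step = rng.integers(1, N_STATES)
            state = (state + step) % N_STATES
        child[site] = state
    return child


def paper_style_guide_tree(
    inter_family_length: float = 0.3,
    structure_length: float = 0.15,
    outgroup_stem: float = 0.1,
) -> PhyloTree:
    """An 8-family + outgroup guide tree with the four-group structure
    supported by the vertebrate beta-integrin phylogeny: {ITB1, ITB2, ITB7},
    {ITB3, ITB5, ITB6}, {ITB4}, {ITB8}, rooted via the outgroup.

    ``inter_family_length`` is the pendant stem of every family (so any two
    families are at least twice that apart); ``structure_length`` sets the
    internal edges encoding the group topology.  The defaults keep the
    deepest expected pairwise p-distance near 0.71, well inside the domain
    of the Kimura protein correction (saturation at ~0.854), so distances
    stay finite at the point estimate and across bootstrap replicates, while
    a 0.15 internal edge over 370 columns carries ~55 expected
    substitutions - ample signal for near-unanimous bootstrap support.
    The ingroup root is a true four-way multifurcation ({ITB1,ITB2,ITB7},
    {ITB3,ITB5,ITB6}, ITB4, ITB8): the distance pipeline necessarily
    resolves it arbitrarily, and the support threshold is what collapses
    the arbitrary resolution back to the four groups."""
    d = inter_family_length
    s = structure_length

    def leaf(name: str, length: float) -> TreeNode:
        return TreeNode(label=name, length=length)

    group127 = TreeNode(
        length=s,
        children=[
            leaf("ITB1", d),
            TreeNode(length=s, children=[leaf("ITB2", d), leaf("ITB7", d)]),
        ],
    )
    group356 = TreeNode(
        length=s,
        children=[
            leaf("ITB3", d),
            TreeNode(length=s, children=[leaf("ITB5", d), leaf("ITB6", d)]),
        ],
    )
    ingroup = TreeNode(
        length=outgroup_stem,
        children=[group127, group356, leaf("ITB4", d), leaf("ITB8", d)],
    )
    root = TreeNode(children=[ingroup, leaf("OUTGROUP", d + outgroup_stem)])
    return PhyloTree(root=root)


def simulate_family_alignment(
    cfg: SimulationConfig,
) -> tuple[MultipleAlignment, PhyloTree, FamilyPartition]:
    """Simulate a gapless family alignment on the configured guide tree.

    Returns the alignment, the true taxon-level tree, and the true family
    partition implied by the guide tree's top-level ingroup structure (the
    outgroup marks the root side and belongs to no group).
    """
    rng = np.random.default_rng(cfg.seed)
    root_seq = rng.integers(0, N_STATES, size=cfg.root_length)

    records: list[ProteinRecord] = []
    rows: list[str] = []
    lo, hi = cfg.intra_family_range

    def decode(codes: np.ndarray) -> str:
        return "".join(AMINO_ACIDS[c] for c in codes)

    true_root = TreeNode()

    def recurse(node: TreeNode, seq: np.ndarray, true_parent: TreeNode) -> None:
        for child in node.children:
            child_seq = evolve_sequence(seq, child.length, rng)
            if child.is_leaf:
                family = child.label
                n_taxa = cfg.taxa_per_family.get(family, cfg.default_taxa_per_family)
                fam_node = TreeNode(length=child.length)
                true_parent.children.append(fam_node)
                for t in range(1, n_taxa + 1):
                    tip_len = float(rng.uniform(lo, hi))
                    tip_seq = evolve_sequence(child_seq, tip_len, rng)
                    taxon = f"{family}_t{t}"
                    fam_node.children.append(TreeNode(label=taxon, length=tip_len))
                    records.append(
                        ProteinRecord(id=taxon, sequence=decode(tip_seq), family=family)
                    )
                    rows.append(decode(tip_seq))
            else:
                inner = TreeNode(length=child.length)
                true_parent.children.append(inner)
                recurse(child, child_seq, inner)

    recurse(cfg.guide_tree.root, root_seq, true_root)
    msa = MultipleAlignment(records=tuple(records), rows=tuple(rows))

    # Truth partition: the family sets of the top-level ingroup branches.
    non_outgroup = [
        c
        for c in cfg.guide_tree.root.children
        if {l.label for l in c.leaves()} != {"OUTGROUP"}
    ]
    if len(non_outgroup) == 1 and not non_outgroup[0].is_leaf:
        top_level = non_outgroup[0].children  # single ingroup stem
    else:
        top_level = non_outgroup
    groups = []
    for sub in top_level:
        fams = frozenset(l.label for l in sub.leaves()) - {"OUTGROUP"}
        if fams:
            groups.append(fams)
    truth = FamilyPartition(
        groups=tuple(sorted(groups, key=sorted)), support_threshold=0
    )

    true_tree = PhyloTree(root=true_root)
    return msa, true_tree, truth


def plant_motif_tails(
    n: int,
    tail_length: int,
    motif_spec: list[list[tuple[str, int]]] | None = None,
    seed: int = 0,
) -> tuple[list[ProteinRecord], dict[str, list[MotifHit]]]:
    """Generate cytosolic-tail-like peptides with exactly known motif content.

    ``motif_spec[i]`` lists (motif_class, 1-based position) plants for tail i;
    None plants 0-2 motifs per tail at random non-overlapping positions.
    Non-motif positions exclude asparagine and tyrosine (and motif wildcard
    slots exclude N, P and Y), so the returned truth table is exact: no
    accidental N..Y window can arise.
    """
    if tail_length < 4:
        raise ValueError("tail_length must be at least 4")
    rng = np.random.default_rng(seed)
    background = [aa for aa in AMINO_ACIDS if aa not in ("N", "Y")]
    wildcard = [aa for aa in AMINO_ACIDS if aa not in ("N", "P", "Y")]

    records: list[ProteinRecord] = []
    truth: dict[str, list[MotifHit]] = {}
    for i in range(n):
        if motif_spec is not None:
            plants = sorted(motif_spec[i], key=lambda x: x[1])
        else:
            n_plants = int(rng.integers(0, 3))
            plants = []
            taken: set[int] = set()
            for _ in range(n_plants):
                for _attempt in range(50):
                    pos = int(rng.integers(1, tail_length - 2))
                    if all(abs(pos - q) >= 4 for q in taken):
                        taken.add(pos)
                        cls = "NPXY" if rng.random() < 0.5 else "NXXY"
                        plants.append((cls, pos))
                        break
            plants.sort(key=lambda x: x[1])
        for cls, pos in plants:
            if pos < 1 or pos + 3 > tail_length:
                raise ValueError(f"motif at {pos} does not fit in tail of {tail_length}")
        for (_, a), (_, b) in zip(plants, plants[1:]):
            if b - a < 4:
                raise ValueError("planted motifs overlap")

        seq = [background[int(k)] for k in rng.integers(0, len(background), size=tail_length)]
        rec_id = f"tail_{i}"
        hits = []
        for cls, pos in plants:
            x2 = wildcard[int(rng.integers(0, len(wildcard)))]
            if cls == "NPXY":
                motif = "NP" + x2 + "Y"
            else:
                x1 = wildcard[int(rng.integers(0, len(wildcard)))]
                motif = "N" + x1 + x2 + "Y"
            seq[pos - 1 : pos + 3] = list(motif)
            hits.append(
                MotifHit(record_id=rec_id, motif_class=cls, start=pos, matched_text=motif)
            )
        record = ProteinRecord(id=rec_id, sequence="".join(seq))
        records.append(record)
        truth[rec_id] = hits
    return records, truth


def plant_cpg_landscape(
    total_length: int,
    island_specs: list[tuple[int, int]],
    seed: int = 0,
    background_gc: float = 0.30,
    island_gc: float = 0.65,
    island_obs_exp: float = 0.8,
) -> tuple[NucleotideSequence, list[tuple[int, int]]]:
    """An AT-rich, CpG-depleted background with planted CpG-rich islands.

    ``island_specs`` is a list of (start, length) with 1-based starts; the
    intervals must fit and must not overlap.  Returns the sequence and the
    truth intervals as 1-based inclusive (start, end) pairs.  Each truth
    interval is snapped to the outermost CpG dinucleotides actually realised
    inside the planted region: sampled edge bases that happen to carry no
    CpG are indistinguishable from background and are not ground truth.
    """
    intervals = sorted((s, s + ln - 1) for s, ln in island_specs)
    for (a1, b1), (a2, b2) in zip(intervals, intervals[1:]):
        if a2 <= b1:
            raise ValueError("island specs overlap")
    if intervals and (intervals[0][0] < 1 or intervals[-1][1] > total_length):
        raise ValueError("island specs do not fit in the sequence")

    rng = np.random.default_rng(seed)
    in_island = np.zeros(total_length, dtype=bool)
    for a, b in intervals:
        in_island[a - 1 : b] = True

    bases = "ACGT"
    gc_b = background_gc
    p_bg = np.array([(1 - gc_b) / 2, gc_b / 2, gc_b / 2, (1 - gc_b) / 2])
    gc_i = island_gc
    p_is = np.array([(1 - gc_i) / 2, gc_i / 2, gc_i / 2, (1 - gc_i) / 2])

    seq = []
    prev = ""
    for i in range(total_length):
        p = p_is.copy() if in_island[i] else p_bg.copy()
        if prev == "C":
            # Suppress CpG: strongly in background, down to the target
            # obs/exp ratio inside islands.
            factor = island_obs_exp if in_island[i] else 0.05
            p[2] *= factor
            p /= p.sum()
        base = bases[int(rng.choice(4, p=p))]
        seq.append(base)
        prev = base
    text = "".join(seq)
    realised = []
    for a, b in intervals:
        region = text[a - 1 : b]
        first = region.find("CG")
        last = region.rfind("CG")
        if first == -1:
            continue  # degenerate draw: no CpG realised in the island
        realised.append((a + first, a + last + 1))
    return NucleotideSequence(id="synthetic_landscape", sequence=text), realised


def random_pairing_table(
    n_beta: int = 8,
    n_alpha: int = 12,
    n_ligands: int = 20,
    density: float = 0.25,
    seed: int = 0,
) -> tuple[PairingTable, dict[str, int], dict[str, int]]:
    """A random ligand/receptor table with exact truth counts.

    Each (ligand, beta) incidence is an independent Bernoulli(density) draw;
    an incident beta receives 1-3 random alpha partners in that row.  Returns
    the table plus truth maps: ligand rows per beta and distinct alpha
    partners per beta.
    """
    if not (0.0 < density <= 1.0):
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    betas = [str(i + 1) for i in range(n_beta)]
    alphas = [str(i + 1) for i in range(n_alpha)]
    rows = []
    ligand_truth = {b: 0 for b in betas}
    alpha_sets: dict[str, set[str]] = {b: set() for b in betas}
    for li in range(n_ligands):
        receptors = []
        for b in betas:
            if rng.random() < density:
                ligand_truth[b] += 1
                k = int(rng.integers(1, 4))
                chosen = rng.choice(n_alpha, size=min(k, n_alpha), replace=False)
                for idx in sorted(chosen):
                    alpha_sets[b].add(alphas[idx])
                    receptors.append(format_receptor(alphas[idx], b))
        if receptors:
            rows.append((f"ligand_{li}", tuple(receptors)))
    table = PairingTable(rows=tuple(rows))
    alpha_truth = {b: len(s) for b, s in alpha_sets.items()}
    return table, ligand_truth, alpha_truth
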