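"""Ligand / integrin-receptor pairing tables and the shared-alpha network.

An integrin receptor is an alpha-beta heterodimer written "α6β4".  The
pairing table maps each extracellular-matrix ligand to the receptors that
bind it.  From the table we derive, per beta subunit, the number of ligand
rows it appears in and its set of distinct alpha partners; beta subunits
that share alpha partners form the weighted shared-alpha graph; and a
breadth-first layering of that graph from a chosen ancestral beta yields an
evolutionary-path hypothesis (betas unreachable through shared alphas are
attached through a caller-supplied fallback grouping, e.g. the phylogenetic
family partition, and marked via "unshared").
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

ALPHA = "α"
BETA = "β"

# Alpha tokens appearing in canonical human integrin receptor names.
CANONICAL_ALPHAS = frozenset(
    [str(i) for i in range(1, 12)] + ["IIb", "v", "L", "M", "X", "D", "E"]
)
CANONICAL_BETAS = frozenset(str(i) for i in range(1, 9))

_RECEPTOR_RE = re.compile(
    rf"^{ALPHA}\s*(?P<alpha>IIb|[0-9]+|[vLMXDEH])\s*{BETA}\s*(?P<beta>[0-9]+)$"
)


def parse_receptor(text: str) -> tuple[str, str]:
    """Parse a receptor name like "α6β4" into its (alpha, beta) tokens.

    Returns bare tokens ("6", "4"); format with :func:`format_receptor` to
    get the display form back.  The order must be alpha-then-beta.
    """
    m = _RECEPTOR_RE.match(text.strip())
    if m is None:
        raise ValueError(f"malformed receptor name: {text!r}")
    return m.group("alpha"), m.group("beta")


def format_receptor(alpha: str, beta: str) -> str:
    return f"{ALPHA}{alpha}{BETA}{beta}"


@dataclass(frozen=True)
class PairingTable:
    """Rows of (ligand, receptor list); ligand names are unique."""

    rows: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ligand, receptors in self.rows:
            if ligand in seen:
                raise ValueError(f"duplicate ligand row {ligand!r}")
            seen.add(ligand)
            parsed = [parse_receptor(r) for r in receptors]
            if len(set(parsed)) != len(parsed):
                raise ValueError(f"duplicate receptor within row {ligand!r}")

    def betas(self) -> list[str]:
        out: set[str] = set()
        for _, receptors in self.rows:
            for r in receptors:
                out.add(parse_receptor(r)[1])
        return sorted(out)

    def noncanonical_receptors(self) -> list[tuple[str, str]]:
        """(ligand, receptor) entries whose alpha or beta token is outside
        the canonical set — transcription oddities worth flagging."""
        flagged = []
        for ligand, receptors in self.rows:
            for r in receptors:
                alpha, beta = parse_receptor(r)
                if alpha not in CANONICAL_ALPHAS or beta not in CANONICAL_BETAS:
                    flagged.append((ligand, r))
        return flagged


def load_pairing_table(path: str | Path | None = None) -> PairingTable:
    """Load the packaged ligand/receptor fixture (or a TSV of the same shape:
    columns ``ligand`` and semicolon-separated ``receptors``)."""
    if path is None:
        text = resources.files("itbkit.data").joinpath("table3_pairings.tsv").read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    rows = []
    for raw in csv.DictReader(lines, delimiter="\t"):
        receptors = tuple(tok.strip() for tok in raw["receptors"].split(";") if tok.strip())
        rows.append((raw["ligand"], receptors))
    return PairingTable(rows=tuple(rows))


def write_pairing_table(table: PairingTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ligand\treceptors\n")
        for ligand, receptors in table.rows:
            fh.write(f"{ligand}\t{';'.join(receptors)}\n")


def ligand_count_per_beta(table: PairingTable) -> dict[str, int]:
    """Number of ligand rows whose receptor list mentions each beta.

    Multiplicity counts table rows: a row naming several related molecules
    (e.g. an ICAM group) is one ligand.
    """
    counts: dict[str, int] = {}
    for _, receptors in table.rows:
        betas_here = {parse_receptor(r)[1] for r in receptors}
        for beta in betas_here:
            counts[beta] = counts.get(beta, 0) + 1
    return counts


def alpha_partners(table: PairingTable) -> dict[str, set[str]]:
    """Distinct alpha tokens co-occurring with each beta across all rows."""
    partners: dict[str, set[str]] = {}
    for _, receptors in table.rows:
        for r in receptors:
            alpha, beta = parse_receptor(r)
            partners.setdefault(beta, set()).add(alpha)
    return partners


def alpha_partner_count(table: PairingTable) -> dict[str, int]:
    return {beta: len(alphas) for beta, alphas in alpha_partners(table).items()}


@dataclass(frozen=True)
class SharedAlphaGraph:
    """Beta subunits joined by edges weighted by shared alpha-partner count."""

    nodes: tuple[str, ...]
    edges: dict[frozenset[str], int] = field(compare=False)
    shared: dict[frozenset[str], frozenset[str]] = field(compare=False)

    def weight(self, a: str, b: str) -> int:
        return self.edges.get(frozenset((a, b)), 0)

    def neighbors(self, node: str) -> list[str]:
        out = []
        for pair in self.edges:
            if node in pair:
                out.append(next(iter(pair - {node})))
        return sorted(out)

    def to_edge_tsv(self) -> str:
        lines = ["beta_i\tbeta_j\tshared_alpha_count\tshared_alphas"]
        for pair in sorted(self.edges, key=sorted):
            a, b = sorted(pair)
            alphas = ",".join(sorted(self.shared[pair]))
            lines.append(f"{a}\t{b}\t{self.edges[pair]}\t{alphas}")
        return "\n".join(lines) + "\n"


def shared_alpha_graph(table: PairingTable) -> SharedAlphaGraph:
    partners = alpha_partners(table)
    betas = sorted(partners)
    edges: dict[frozenset[str], int] = {}
    shared: dict[frozenset[str], frozenset[str]] = {}
    for i, a in enumerate(betas):
        for b in betas[i + 1 :]:
            common = partners[a] & partners[b]
            if common:
                key = frozenset((a, b))
                edges[key] = len(common)
                shared[key] = frozenset(common)
    return SharedAlphaGraph(nodes=tuple(betas), edges=edges, shared=shared)


@dataclass(frozen=True)
class EvolutionaryPathHypothesis:
    """A forest of parent -> child beta edges rooted at an ancestral beta.

    Each directed edge carries the alpha subunit that links parent and child
    in the shared-alpha graph, or "unshared" when the child was attached via
    the fallback grouping instead.
    """

    root: str
    edges: tuple[tuple[str, str, str], ...]  # (parent, child, via)
    unplaced: frozenset[str]

    def parents(self) -> dict[str, tuple[str, str]]:
        return {child: (parent, via) for parent, child, via in self.edges}

    def to_tsv(self) -> str:
        lines = ["parent_beta\tchild_beta\tvia"]
        for parent, child, via in self.edges:
            lines.append(f"{parent}\t{child}\t{via}")
        return "\n".join(lines) + "\n"

    def to_dot(self) -> str:
        lines = ["digraph beta_evolution {"]
        for parent, child, via in self.edges:
            style = ' style=dashed' if via == "unshared" else ""
            lines.append(f'  "b{parent}" -> "b{child}" [label="{via}"{style}];')
        for node in sorted(self.unplaced):
            lines.append(f'  "b{node}" [shape=box];')
        lines.append("}")
        return "\n".join(lines) + "\n"


def infer_evolutionary_paths(
    graph: SharedAlphaGraph,
    root_beta: str,
    fallback_grouping: list[set[str]] | None = None,
) -> EvolutionaryPathHypothesis:
    """Breadth-first layering of the shared-alpha graph from an ancestral beta.

    Each beta attaches to its earliest-layer neighbor; ties prefer the
    neighbor with the larger shared-alpha weight, then the lexicographically
    smallest name.  The reported ``via`` alpha is the smallest shared alpha
    with the chosen parent.  Betas with no shared-alpha route from the root
    are attached beneath a placed beta from the same fallback group (marked
    via="unshared") or listed as unplaced.
    """
    if root_beta not in graph.nodes:
        raise ValueError(f"root {root_beta!r} is not a node of the graph")
    layer = {root_beta: 0}
    frontier = [root_beta]
    order = []
    while frontier:
        nxt = []
        for node in sorted(frontier):
            for nb in graph.neighbors(node):
                if nb not in layer:
                    layer[nb] = layer[node] + 1
                    nxt.append(nb)
                    order.append(nb)
        frontier = nxt

    edges: list[tuple[str, str, str]] = []
    for child in order:
        candidates = [nb for nb in graph.neighbors(child) if layer.get(nb, 1 << 30) == layer[child] - 1]
        candidates.sort(key=lambda nb: (-graph.weight(child, nb), nb))
        parent = candidates[0]
        via = min(graph.shared[frozenset((parent, child))])
        edges.append((parent, child, via))

    unreached = [n for n in graph.nodes if n not in layer]
    unplaced: set[str] = set()
    for node in sorted(unreached):
        home = None
        for group in fallback_grouping or []:
            if node in group:
                placed = sorted(g for g in group if g in layer)
                if placed:
                    home = placed[0]
                break
        if home is None:
            unplaced.add(node)
        else:
            layer[node] = layer[home] + 1
            edges.append((home, node, "unshared"))
    return EvolutionaryPathHypothesis(
        root=root_beta, edges=tuple(edges), unplaced=frozenset(unplaced)
    )
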