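"""Input/output: codon alignments (FASTA), phylogenies (Newick), results (JSON).

Alignments are stored as integer matrices over the sense-codon state space
defined by a :class:`~busteds.genetic_code.GeneticCode`.  Ambiguous or gapped
codons are kept as *sets* of compatible sense codons and enter the likelihood
as partial-likelihood indicator vectors — they are never resolved to a single
codon.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import product

import dendropy
import numpy as np
from Bio import SeqIO

from .genetic_code import IUPAC, GeneticCode, get_code

log = logging.getLogger(__name__)


def expand_codon(codon: str, code: GeneticCode) -> list[int]:
    """Return the sense-codon state indices compatible with a codon string.

    Unambiguous sense codons give a single index; IUPAC ambiguity codes
    expand to every compatible sense codon.  A codon containing any gap
    character is incomplete and treated as fully missing (all sense codons).
    A codon compatible only with stop codons yields an empty list.
    """
    codon = codon.upper().replace("U", "T")
    if any(c in "-?." for c in codon):
        return list(range(code.n_states))
    try:
        sets = [IUPAC[c] for c in codon]
    except KeyError as e:
        raise ValueError(f"unrecognized nucleotide {e.args[0]!r} in codon {codon!r}")
    states = []
    for nucs in product(*sets):
        cand = "".join(nucs)
        idx = code.index.get(cand)
        if idx is not None:
            states.append(idx)
    return states


@dataclass
class CodonAlignment:
    """A taxa x codon-site matrix of sense-codon states.

    ``states[s, n]`` holds the codon state index, or ``-1`` when the cell is
    ambiguous; ambiguous cells list their compatible states in ``ambiguities``
    keyed by ``(s, n)``.  Sites are reported 1-based externally.
    """

    taxa: list[str]
    states: np.ndarray  # (S, N) int, -1 = ambiguous
    code: GeneticCode
    ambiguities: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    @property
    def n_sequences(self) -> int:
        return self.states.shape[0]

    @property
    def n_codons(self) -> int:
        return self.states.shape[1]

    @classmethod
    def from_strings(cls, named_seqs, code: GeneticCode | None = None):
        """Build an alignment from (name, nucleotide-string) pairs."""
        code = code or get_code()
        names = [n for n, _ in named_seqs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate taxon names in alignment")
        seqs = [s.upper().replace("U", "T") for _, s in named_seqs]
        if not seqs:
            raise ValueError("empty alignment")
        L = len(seqs[0])
        if any(len(s) != L for s in seqs):
            raise ValueError("ragged alignment: sequences have unequal lengths")
        if L % 3 != 0:
            raise ValueError(f"alignment length {L} is not divisible by 3")
        n_codons = L // 3
        states = np.full((len(seqs), n_codons), -1, dtype=np.int32)
        ambiguities: dict[tuple[int, int], np.ndarray] = {}
        for s, seq in enumerate(seqs):
            for n in range(n_codons):
                codon = seq[3 * n: 3 * n + 3]
                compat = expand_codon(codon, code)
                if not compat:
                    raise ValueError(
                        f"in-frame stop codon {codon!r} in taxon "
                        f"{names[s]!r} at codon site {n + 1}"
                    )
                if len(compat) == 1:
                    states[s, n] = compat[0]
                else:
                    ind = np.zeros(code.n_states, dtype=bool)
                    ind[compat] = True
                    ambiguities[(s, n)] = ind
        return cls(taxa=list(names), states=states, code=code,
                   ambiguities=ambiguities)

    def leaf_partials(self, s: int) -> np.ndarray:
        """Indicator matrix (n_states, N) for sequence ``s``."""
        N, K = self.n_codons, self.code.n_states
        out = np.zeros((K, N))
        unamb = self.states[s] >= 0
        out[self.states[s, unamb], np.nonzero(unamb)[0]] = 1.0
        for (si, n), ind in self.ambiguities.items():
            if si == s:
                out[:, n] = ind
        return out

    def to_fasta(self, path):
        with open(path, "w") as fh:
            for s, name in enumerate(self.taxa):
                codons = []
                for n in range(self.n_codons):
                    st = self.states[s, n]
                    if st >= 0:
                        codons.append(self.code.sense_codons[st])
                    else:
                        ind = self.ambiguities[(s, n)]
                        codons.append("NNN" if ind.sum() > 1 else
                                      self.code.sense_codons[int(ind.argmax())])
                fh.write(f">{name}\n{''.join(codons)}\n")


def read_codon_fasta(path, code: GeneticCode | None = None) -> CodonAlignment:
    """Read an in-frame coding alignment from a FASTA file."""
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return CodonAlignment.from_strings(records, code)


@dataclass
class Phylogeny:
    """A rooted-storage phylogeny with branch lengths.

    The substitution models used here are time-reversible, so the stored
    root position does not affect likelihoods; it only anchors the pruning
    recursion.  Node ``i``'s branch is the edge to its parent, of length
    ``edge_length[i]`` (expected substitutions per codon site under the
    fitted model's scaling).
    """

    children: list[list[int]]
    parent: np.ndarray
    edge_length: np.ndarray
    labels: list[str | None]
    root: int

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def leaves(self) -> list[int]:
        return [i for i, ch in enumerate(self.children) if not ch]

    @property
    def taxa(self) -> list[str]:
        return [self.labels[i] for i in self.leaves]

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    def total_length(self) -> float:
        return float(sum(self.edge_length[i] for i in range(self.n_nodes)
                         if i != self.root))

    def postorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        return order[::-1]

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        ids = {id(nd): i for i, nd in enumerate(nodes)}
        children: list[list[int]] = [[] for _ in nodes]
        parent = np.full(len(nodes), -1, dtype=int)
        lengths = np.zeros(len(nodes))
        labels: list[str | None] = [None] * len(nodes)
        missing = 0
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = ids[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
                if nd.edge.length is None:
                    missing += 1
                    lengths[i] = 0.0
                else:
                    lengths[i] = float(nd.edge.length)
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
        if missing:
            log.warning("%d branch lengths missing from tree; defaulting to 0",
                        missing)
        leaf_names = [labels[i] for i, ch in enumerate(children) if not ch]
        if any(n is None for n in leaf_names):
            raise ValueError("tree has unlabeled leaves")
        if len(set(leaf_names)) != len(leaf_names):
            raise ValueError("duplicate leaf names in tree")
        if np.any(lengths < 0) or not np.all(np.isfinite(lengths)):
            raise ValueError("branch lengths must be finite and non-negative")
        return cls(children=children, parent=parent, edge_length=lengths,
                   labels=labels, root=0)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as e:  # dendropy raises its own hierarchy
            raise ValueError(f"could not parse Newick tree: {e}") from e
        return cls.from_dendropy(tree)

    def to_newick(self) -> str:
        def rec(i):
            if not self.children[i]:
                s = self.labels[i]
            else:
                s = "(" + ",".join(rec(c) for c in self.children[i]) + ")"
            if i == self.root:
                return s + ";"
            return f"{s}:{self.edge_length[i]:.10g}"
        return rec(self.root)

    def scaled(self, factor: float) -> "Phylogeny":
        out = Phylogeny(children=[list(c) for c in self.children],
                        parent=self.parent.copy(),
                        edge_length=self.edge_length * factor,
                        labels=list(self.labels), root=self.root)
        return out


def read_newick(path) -> Phylogeny:
    """Read a Newick tree from a file."""
    with open(path) as fh:
        text = fh.read()
    return Phylogeny.from_newick(text)


def check_taxa(aln: CodonAlignment, tree: Phylogeny) -> None:
    """Require alignment and tree to reference the same taxa."""
    a, t = set(aln.taxa), set(tree.taxa)
    if a != t:
        raise ValueError(
            f"alignment/tree taxa mismatch: only-in-alignment={sorted(a - t)}, "
            f"only-in-tree={sorted(t - a)}"
        )


def write_result_json(result, path) -> None:
    """Serialize a result object (anything with ``to_dict``) to JSON."""
    payload = result.to_dict() if hasattr(result, "to_dict") else result
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_result_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
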