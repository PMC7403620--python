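"""Genetic-code tables, sense-codon indexing, and substitution classification.

Codon substitution models operate on the set of *sense* codons (61 for the
universal code).  This module fixes a deterministic codon ordering
(alphabetical over {A,C,G,T}^3 with stop codons removed) so that rate
matrices and serialized results are reproducible, and classifies single
nucleotide codon changes as synonymous or nonsynonymous — the trichotomy
that drives the MG94-style instantaneous rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

#: IUPAC ambiguity codes mapped to the compatible unambiguous nucleotides.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT", "X": "ACGT", ".": "ACGT",
}


class StopCodonError(ValueError):
    """Raised when a stop codon appears where a sense codon is required."""


@dataclass(frozen=True, eq=False)  # identity hash: instances are interned via get_code
class GeneticCode:
    """A genetic code with a stable sense-codon indexing.

    Attributes
    ----------
    code_id : str
        Registry name, e.g. ``"universal"``.
    codon_to_aa : dict
        Maps all 64 codon strings to a one-letter amino acid or ``"*"``.
    sense_codons : tuple of str
        Non-stop codons, alphabetical over {A,C,G,T}^3; defines the state
        indexing of every rate matrix built from this code.
    """

    code_id: str
    codon_to_aa: dict[str, str]
    sense_codons: tuple[str, ...]
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(
            self, "index", {c: i for i, c in enumerate(self.sense_codons)}
        )

    @property
    def n_states(self) -> int:
        return len(self.sense_codons)

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(
            c for c in sorted(self.codon_to_aa) if self.codon_to_aa[c] == "*"
        )

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon] == "*"

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]


def _all_codons():
    return ["".join(p) for p in product(NUCLEOTIDES, repeat=3)]


@lru_cache(maxsize=None)
def get_code(name: str = "universal") -> GeneticCode:
    """Look up a genetic code by registry name.

    ``"universal"`` (NCBI table 1) is the default; ``"vertebrate-mito"``
    (NCBI table 2) is provided for mitochondrial genes.  Integer NCBI table
    ids given as strings are also accepted.
    """
    aliases = {"universal": 1, "standard": 1, "vertebrate-mito": 2,
               "vertebrate-mitochondrial": 2}
    if name in aliases:
        table_id = aliases[name]
    else:
        try:
            table_id = int(name)
        except ValueError:
            raise KeyError(f"unknown genetic code: {name!r}") from None
    table = CodonTable.unambiguous_dna_by_id[table_id]
    codon_to_aa = {}
    for codon in _all_codons():
        if codon in table.stop_codons:
            codon_to_aa[codon] = "*"
        else:
            codon_to_aa[codon] = table.forward_table[codon]
    sense = tuple(c for c in _all_codons() if codon_to_aa[c] != "*")
    return GeneticCode(code_id=name, codon_to_aa=codon_to_aa, sense_codons=sense)


@dataclass(frozen=True)
class SubstitutionClass:
    """Classification of an ordered codon pair.

    ``kind`` is one of ``identical``, ``multi_step``, ``synonymous``,
    ``nonsynonymous``.  For one-step changes ``position`` is the differing
    codon position (1-3) and ``pair`` the unordered nucleotide pair.
    """

    kind: str
    position: int | None = None
    pair: frozenset[str] | None = None


def classify_substitution(code: GeneticCode, i: str, j: str) -> SubstitutionClass:
    """Classify the codon substitution ``i`` -> ``j`` under ``code``.

    Raises :class:`StopCodonError` if either codon is a stop codon.
    """
    for c in (i, j):
        if code.is_stop(c):
            raise StopCodonError(f"{c} is a stop codon under {code.code_id}")
    diffs = [p for p in range(3) if i[p] != j[p]]
    if not diffs:
        return SubstitutionClass("identical")
    if len(diffs) > 1:
        return SubstitutionClass("multi_step")
    p = diffs[0]
    kind = "synonymous" if code.translate(i) == code.translate(j) else "nonsynonymous"
    return SubstitutionClass(kind, position=p + 1, pair=frozenset({i[p], j[p]}))


def one_step_pairs(code: GeneticCode):
    """Yield (i, j, SubstitutionClass) over all ordered one-step sense pairs."""
    for i in code.sense_codons:
        for p in range(3):
            for n in NUCLEOTIDES:
                if n == i[p]:
                    continue
                j = i[:p] + n + i[p + 1:]
                if code.is_stop(j):
                    continue
                yield i, j, classify_substitution(code, i, j)
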