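"""Genetic-code tables, CDS translation, and codon / amino-acid usage.

Codon counting underlies the amino-acid usage term (``N_AA``) of the
tRNA-allocation model: the total number of codons encoding each amino acid
across all coding sequences of a genome.  Codon family size (CFS) is the
number of synonymous sense codons per amino acid under a given NCBI
translation table (1 for Trp and Met, 6 for Leu/Ser/Arg under the bacterial
table 11).
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field

from Bio.Data import CodonTable

__all__ = [
    "GeneticCode",
    "UsageTable",
    "CodonUsageWarning",
    "genetic_code",
    "codon_family_sizes",
    "translate",
    "amino_acid_usage",
    "rscu",
    "STANDARD_AMINO_ACIDS",
]

#: The 20 standard amino acids, one-letter codes, alphabetical.
STANDARD_AMINO_ACIDS = tuple(sorted("ACDEFGHIKLMNPQRSTVWY"))

STOP = "*"

_BASES = "TCAG"
ALL_CODONS = tuple("".join(c) for c in itertools.product(_BASES, repeat=3))


class CodonUsageWarning(UserWarning):
    """Non-fatal irregularity while counting codons (internal stops etc.)."""


@dataclass(frozen=True)
class GeneticCode:
    """A complete 64-codon translation table.

    Attributes
    ----------
    table_id : int
        NCBI translation-table number (11 for bacteria/archaea/plastids).
    codon_to_aa : dict
        Maps each of the 64 DNA codons to a one-letter amino acid, with
        stop codons mapped to ``"*"``.
    start_codons : frozenset
        Codons the table allows as initiation codons.
    """

    table_id: int
    codon_to_aa: dict[str, str]
    start_codons: frozenset[str]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(
                f"genetic code must map 64 codons, got {len(self.codon_to_aa)}"
            )

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codon_to_aa.items() if aa == STOP)

    def synonymous_family(self, amino_acid: str) -> tuple[str, ...]:
        """All sense codons encoding ``amino_acid``, in TCAG order."""
        return tuple(
            c for c in ALL_CODONS if self.codon_to_aa[c] == amino_acid
        )


def genetic_code(table_id: int = 11) -> GeneticCode:
    """Return the NCBI translation table ``table_id`` as a :class:`GeneticCode`.

    Table 11 (bacterial, archaeal and plant plastid) shares all codon→amino
    acid assignments with the standard table 1 but allows additional start
    codons (GTG, TTG, ...).
    """
    try:
        bio_table = CodonTable.unambiguous_dna_by_id[table_id]
    except KeyError:
        supported = sorted(CodonTable.unambiguous_dna_by_id)
        raise ValueError(
            f"unsupported translation table {table_id}; "
            f"available NCBI tables: {supported}"
        ) from None
    mapping = {c: bio_table.forward_table.get(c, STOP) for c in ALL_CODONS}
    return GeneticCode(
        table_id=table_id,
        codon_to_aa=mapping,
        start_codons=frozenset(bio_table.start_codons),
        name=bio_table.names[0] if bio_table.names else "",
    )


def codon_family_sizes(code: GeneticCode) -> dict[str, int]:
    """Number of synonymous sense codons (CFS) per amino acid.

    Over the 20 standard amino acids the sizes sum to the number of sense
    codons (61 under table 11).
    """
    sizes: Counter[str] = Counter()
    for aa in code.codon_to_aa.values():
        if aa != STOP:
            sizes[aa] += 1
    return dict(sizes)


def _clean(seq: str) -> str:
    return seq.upper().replace("U", "T")


def translate(cds: str, code: GeneticCode) -> str:
    """Translate a coding sequence codon by codon.

    A terminal stop codon is dropped; codons containing non-ACGT letters
    translate to ``X``; a trailing partial codon is dropped with a warning.
    """
    if not cds:
        raise ValueError("cannot translate an empty coding sequence")
    seq = _clean(cds)
    if len(seq) < 3:
        raise ValueError("coding sequence shorter than one codon")
    if len(seq) % 3:
        warnings.warn(
            f"CDS length {len(seq)} is not a multiple of 3; "
            "trailing partial codon dropped",
            CodonUsageWarning,
            stacklevel=2,
        )
    residues = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        aa = code.codon_to_aa.get(codon, "X")
        residues.append("X" if aa is None else aa)
    if residues and residues[-1] == STOP:
        residues.pop()
    return "".join(residues)


@dataclass
class UsageTable:
    """Genome-wide codon and amino-acid usage.

    ``codon_counts`` covers every clean in-frame codon including stops;
    ``n_aa`` (the N_AA of the allocation model) excludes stop codons.
    ``rscu`` is each codon's count divided by the mean count of its
    synonymous family.
    """

    codon_counts: dict[str, int] = field(default_factory=dict)
    n_aa: dict[str, int] = field(default_factory=dict)
    rscu: dict[str, float] = field(default_factory=dict)
    n_cds: int = 0
    n_skipped_codons: int = 0

    def total_sense_codons(self) -> int:
        return sum(self.n_aa.values())


def amino_acid_usage(cds_list: list[str], code: GeneticCode) -> UsageTable:
    """Count codon and amino-acid usage over a set of coding sequences.

    Every in-frame codon of every CDS is tallied, initiator codons
    included; codons containing ambiguous bases are skipped (counted in
    ``n_skipped_codons``).  Stop codons — terminal or internal — are
    excluded from ``n_aa``; internal stops additionally raise a warning
    since they usually indicate a mis-annotated or pseudogenised CDS.
    """
    counts: Counter[str] = Counter()
    skipped = 0
    internal_stops = 0
    for cds in cds_list:
        seq = _clean(cds)
        n_codons = len(seq) // 3
        for i in range(n_codons):
            codon = seq[3 * i : 3 * i + 3]
            if codon not in code.codon_to_aa:
                skipped += 1
                continue
            counts[codon] += 1
            if code.codon_to_aa[codon] == STOP and i < n_codons - 1:
                internal_stops += 1
    if internal_stops:
        warnings.warn(
            f"{internal_stops} internal stop codon(s) encountered; "
            "excluded from amino-acid usage",
            CodonUsageWarning,
            stacklevel=2,
        )
    n_aa: Counter[str] = Counter()
    for codon, n in counts.items():
        aa = code.codon_to_aa[codon]
        if aa != STOP:
            n_aa[aa] += n
    return UsageTable(
        codon_counts=dict(counts),
        n_aa=dict(n_aa),
        rscu=rscu(counts, code),
        n_cds=len(cds_list),
        n_skipped_codons=skipped,
    )


def rscu(codon_counts: dict[str, int], code: GeneticCode) -> dict[str, float]:
    """Relative synonymous codon usage.

    RSCU(c) = count(c) / mean count over c's synonymous family, so the
    family mean is 1 whenever the family has any usage.  Families with zero
    total get RSCU 0 for every member.  Stop codons are not scored.
    """
    out: dict[str, float] = {}
    families: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        aa = code.codon_to_aa[codon]
        if aa != STOP:
            families.setdefault(aa, []).append(codon)
    for codons in families.values():
        total = sum(codon_counts.get(c, 0) for c in codons)
        if total == 0:
            for c in codons:
                out[c] = 0.0
        else:
            mean = total / len(codons)
            for c in codons:
                out[c] = codon_counts.get(c, 0) / mean
    return out
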