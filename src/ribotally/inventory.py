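"""GenBank feature inventory of the bacterial translation machinery.

Parses GenBank flat files (.gbff/.gb) and counts the genomic components of
translation: ribosomal RNA (rrn) operons — each normally one 16S, one 23S
and one 5S gene — and tRNA genes, classified per amino acid.  Multi-replicon
assemblies (two-chromosome *Vibrio*, multi-contig drafts) are merged before
counting, so counts are always per genome, not per replicon.

The operon count is defined as the number of 16S rRNA genes: every rrn
operon contains exactly one, and the definition is robust on fragmented
assemblies where proximity clustering of rRNA genes would fail.  Unequal
16S/23S/5S class counts are surfaced as warnings, never reconciled
silently.
"""

from __future__ import annotations

import io
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .codons import STANDARD_AMINO_ACIDS, GeneticCode

__all__ = [
    "FeatureAnnotation",
    "GenomeAssembly",
    "TranslationInventory",
    "GenBankParseError",
    "InventoryWarning",
    "INITIATOR_MET",
    "SELENOCYSTEINE",
    "parse_genbank_flatfile",
    "parse_genbank_path",
    "merge_replicons",
    "count_rrn_operons",
    "classify_trna",
    "build_inventory",
    "extract_feature_sequences",
    "inventory_frame",
]

#: Classification labels outside the 20 standard amino acids.
INITIATOR_MET = "fMet"
SELENOCYSTEINE = "SeC"

_EXTRACTED_KINDS = ("CDS", "rRNA", "tRNA")

_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


class GenBankParseError(ValueError):
    """Raised when a GenBank flat file cannot be parsed."""


class InventoryWarning(UserWarning):
    """Non-fatal annotation irregularity (class-count mismatch etc.)."""


@dataclass(frozen=True)
class FeatureAnnotation:
    """One annotated CDS, rRNA or tRNA feature.

    ``location`` is an ordered list of (start, end) segments, 1-based
    inclusive (GenBank convention); multi-segment locations come from
    ``join(...)`` forms.
    """

    kind: str
    replicon_id: str
    location: tuple[tuple[int, int], ...]
    strand: str
    qualifiers: dict[str, str] = field(default_factory=dict, hash=False)

    def __post_init__(self) -> None:
        if self.kind not in _EXTRACTED_KINDS:
            raise ValueError(f"feature kind must be one of {_EXTRACTED_KINDS}")
        for start, end in self.location:
            if start > end:
                raise ValueError(f"segment start {start} > end {end}")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def is_pseudo(self) -> bool:
        return "pseudo" in self.qualifiers or "pseudogene" in self.qualifiers


@dataclass
class GenomeAssembly:
    """A parsed genome: one or more replicons plus typed features."""

    species_label: str
    accessions: list[str]
    replicons: dict[str, str]
    features: list[FeatureAnnotation]

    def __post_init__(self) -> None:
        if not self.accessions:
            raise ValueError("assembly needs at least one accession")
        for feat in self.features:
            length = len(self.replicons.get(feat.replicon_id, ""))
            if length:
                for _, end in feat.location:
                    if end > length:
                        raise ValueError(
                            f"feature on {feat.replicon_id} ends at {end}, "
                            f"beyond replicon length {length}"
                        )

    def features_of_kind(self, kind: str) -> list[FeatureAnnotation]:
        return [f for f in self.features if f.kind == kind]


@dataclass
class TranslationInventory:
    """Per-species counts of rrn operons and tRNA genes.

    ``m_trna`` maps each standard amino acid to its tRNA gene count
    (initiator tRNAs are inside Met, and also tracked in
    ``n_initiator_met``); selenocysteine tRNAs are a separate class.
    The identity ``n_trna == sum(m_trna) + n_sec + n_unclassified`` holds
    by construction.
    """

    species_label: str
    n_rrn: int
    rrna_class_counts: dict[str, int]
    n_trna: int
    m_trna: dict[str, int]
    n_initiator_met: int = 0
    n_sec: int = 0
    n_unclassified: int = 0

    def __add__(self, other: "TranslationInventory") -> "TranslationInventory":
        m = Counter(self.m_trna)
        m.update(other.m_trna)
        classes = Counter(self.rrna_class_counts)
        classes.update(other.rrna_class_counts)
        return TranslationInventory(
            species_label=self.species_label,
            n_rrn=self.n_rrn + other.n_rrn,
            rrna_class_counts=dict(classes),
            n_trna=self.n_trna + other.n_trna,
            m_trna=dict(m),
            n_initiator_met=self.n_initiator_met + other.n_initiator_met,
            n_sec=self.n_sec + other.n_sec,
            n_unclassified=self.n_unclassified + other.n_unclassified,
        )


def _segments(biopy_location) -> tuple[tuple[int, int], ...]:
    parts = getattr(biopy_location, "parts", [biopy_location])
    segs = tuple((int(p.start) + 1, int(p.end)) for p in parts)
    return tuple(sorted(segs))


def parse_genbank_flatfile(text: str) -> GenomeAssembly:
    """Parse GenBank flat-file content into a :class:`GenomeAssembly`.

    Accepts multi-record files (one record per replicon).  Only CDS, rRNA
    and tRNA features are kept; all other feature kinds are ignored.
    """
    try:
        records = list(SeqIO.parse(io.StringIO(text), "genbank"))
    except ValueError as exc:
        raise GenBankParseError(f"malformed GenBank input: {exc}") from exc
    if not records:
        raise GenBankParseError("no LOCUS record found in input")

    replicons: dict[str, str] = {}
    accessions: list[str] = []
    features: list[FeatureAnnotation] = []
    species = ""
    for rec in records:
        rep_id = rec.id or rec.name
        accessions.append(rep_id)
        try:
            replicons[rep_id] = str(rec.seq)
        except Exception:
            # CONTIG/ORIGIN-less records: defer sequence-dependent errors
            replicons[rep_id] = ""
        species = species or rec.annotations.get("organism", "") or rec.description
        for feat in rec.features:
            if feat.type not in _EXTRACTED_KINDS:
                continue
            if feat.location is None:
                raise GenBankParseError(
                    f"feature {feat.type} in {rep_id} has an "
                    "unparseable location"
                )
            quals = {
                k: (str(v[0]) if isinstance(v, list) and v else str(v))
                for k, v in feat.qualifiers.items()
            }
            features.append(
                FeatureAnnotation(
                    kind=feat.type,
                    replicon_id=rep_id,
                    location=_segments(feat.location),
                    strand="-" if feat.location.strand == -1 else "+",
                    qualifiers=quals,
                )
            )
    return GenomeAssembly(
        species_label=species or accessions[0],
        accessions=accessions,
        replicons=replicons,
        features=features,
    )


def parse_genbank_path(path) -> GenomeAssembly:
    with open(path) as fh:
        return parse_genbank_flatfile(fh.read())


def merge_replicons(
    assemblies: Sequence[GenomeAssembly], species_label: str | None = None
) -> GenomeAssembly:
    """Merge per-replicon assemblies of one species into a single genome."""
    if not assemblies:
        raise ValueError("nothing to merge")
    replicons: dict[str, str] = {}
    accessions: list[str] = []
    features: list[FeatureAnnotation] = []
    for asm in assemblies:
        for rep_id, seq in asm.replicons.items():
            if rep_id in replicons:
                raise ValueError(f"duplicate replicon id {rep_id!r}")
            replicons[rep_id] = seq
        accessions.extend(asm.accessions)
        features.extend(asm.features)
    return GenomeAssembly(
        species_label=species_label or assemblies[0].species_label,
        accessions=accessions,
        replicons=replicons,
        features=features,
    )


_RRNA_CLASSES = ("16S", "23S", "5S")


def _rrna_class(product: str) -> str | None:
    text = product.upper()
    # order matters: "5S" must not swallow "16S"/"23S"
    for cls in _RRNA_CLASSES:
        if cls in text:
            return cls
    return None


def count_rrn_operons(
    assembly: GenomeAssembly,
) -> tuple[int, dict[str, int]]:
    """Count rrn operons as the number of 16S rRNA genes.

    Returns ``(n_rrn, class_counts)`` with counts for all three rRNA
    classes.  Warns when the three class counts disagree or when an rRNA
    product matches none of 16S/23S/5S.
    """
    counts = {cls: 0 for cls in _RRNA_CLASSES}
    unmatched = 0
    for feat in assembly.features_of_kind("rRNA"):
        cls = _rrna_class(feat.qualifiers.get("product", ""))
        if cls is None:
            unmatched += 1
        else:
            counts[cls] += 1
    if unmatched:
        warnings.warn(
            f"{assembly.species_label}: {unmatched} rRNA feature(s) matched "
            "none of 16S/23S/5S and were not counted",
            InventoryWarning,
            stacklevel=2,
        )
    if len(set(counts.values())) > 1:
        warnings.warn(
            f"{assembly.species_label}: unequal rRNA class counts {counts}; "
            "operon count follows the 16S tally",
            InventoryWarning,
            stacklevel=2,
        )
    return counts["16S"], counts


_PRODUCT_RE = re.compile(r"tRNA[-_ ]([A-Za-z]{2,4}\d?)")
_ANTICODON_SEQ_RE = re.compile(r"seq\s*:\s*([acgtuACGTU]{3})")


def _decode_anticodon(anticodon: str, code: GeneticCode) -> str | None:
    """Amino acid decoded by an anticodon (reverse complement → codon)."""
    codon = str(Seq(anticodon.upper().replace("U", "T")).reverse_complement())
    aa = code.codon_to_aa.get(codon)
    return aa if aa in _ONE_TO_THREE else None


def classify_trna(feature: FeatureAnnotation, code: GeneticCode) -> str | None:
    """Assign a tRNA gene to an amino-acid class.

    Returns a one-letter amino acid, :data:`INITIATOR_MET` for initiator
    (fMet) tRNAs, :data:`SELENOCYSTEINE` for tRNA-Sec, or ``None`` when
    neither the ``product`` nor the ``anticodon`` qualifier identifies the
    isoacceptor.  The product string wins over the anticodon when both are
    present.
    """
    if feature.kind != "tRNA":
        raise ValueError("classify_trna expects a tRNA feature")
    product = feature.qualifiers.get("product", "")
    m = _PRODUCT_RE.search(product)
    if m:
        token = m.group(1)
        if token.lower() in ("fmet", "ini", "imet"):
            return INITIATOR_MET
        if token.lower() in ("sec", "sel"):
            return SELENOCYSTEINE
        aa = _THREE_TO_ONE.get(token[:3].capitalize())
        if aa:
            return aa
    anticodon = feature.qualifiers.get("anticodon", "")
    m = _ANTICODON_SEQ_RE.search(anticodon)
    if not m and re.fullmatch(r"[acgtuACGTU]{3}", anticodon.strip()):
        m = re.match(r"([acgtuACGTU]{3})", anticodon.strip())
    if m:
        return _decode_anticodon(m.group(1), code)
    return None


def build_inventory(
    assembly: GenomeAssembly,
    code: GeneticCode,
    exclude_pseudo: bool = True,
) -> TranslationInventory:
    """Tally rrn operons and per-amino-acid tRNA genes for one genome.

    tRNA pseudogenes are excluded by default (``exclude_pseudo=False`` to
    keep them).  Initiator tRNAs count inside Met; selenocysteine tRNAs
    count in ``n_trna`` but form their own class outside ``m_trna``.
    """
    n_rrn, class_counts = count_rrn_operons(assembly)
    m_trna: Counter[str] = Counter()
    n_init = n_sec = n_uncls = n_trna = 0
    for feat in assembly.features_of_kind("tRNA"):
        if exclude_pseudo and feat.is_pseudo:
            continue
        n_trna += 1
        label = classify_trna(feat, code)
        if label == INITIATOR_MET:
            m_trna["M"] += 1
            n_init += 1
        elif label == SELENOCYSTEINE:
            n_sec += 1
        elif label is None:
            n_uncls += 1
        else:
            m_trna[label] += 1
    return TranslationInventory(
        species_label=assembly.species_label,
        n_rrn=n_rrn,
        rrna_class_counts=class_counts,
        n_trna=n_trna,
        m_trna=dict(m_trna),
        n_initiator_met=n_init,
        n_sec=n_sec,
        n_unclassified=n_uncls,
    )


def extract_feature_sequences(
    assembly: GenomeAssembly, kind: str
) -> list[tuple[str, str]]:
    """Extract (identifier, sequence) pairs for all features of one kind.

    Minus-strand features are reverse-complemented; ``join`` segments are
    concatenated in location order.  Requires replicon sequence — raises if
    the record carried no ORIGIN.
    """
    out = []
    for i, feat in enumerate(assembly.features_of_kind(kind)):
        seq = assembly.replicons.get(feat.replicon_id, "")
        if not seq:
            raise GenBankParseError(
                f"replicon {feat.replicon_id} has no sequence (missing "
                "ORIGIN); cannot extract features"
            )
        parts = [seq[start - 1 : end] for start, end in feat.location]
        merged = "".join(parts)
        if feat.strand == "-":
            merged = str(Seq(merged).reverse_complement())
        name = (
            feat.qualifiers.get("locus_tag")
            or feat.qualifiers.get("gene")
            or f"{kind}_{i + 1}"
        )
        out.append((name, merged))
    return out


def inventory_frame(inventories: Iterable[TranslationInventory]):
    """One row per species: n_rrn, rRNA class counts, n_trna, 20 M_tRNA
    columns, initiator/Sec/unclassified tallies.  Returns a DataFrame."""
    import pandas as pd

    rows = []
    for inv in inventories:
        row: dict[str, object] = {
            "species": inv.species_label,
            "n_rrn": inv.n_rrn,
            "rrna_16S": inv.rrna_class_counts.get("16S", 0),
            "rrna_23S": inv.rrna_class_counts.get("23S", 0),
            "rrna_5S": inv.rrna_class_counts.get("5S", 0),
            "n_trna": inv.n_trna,
        }
        for aa in STANDARD_AMINO_ACIDS:
            row[f"trna_{aa}"] = inv.m_trna.get(aa, 0)
        row["n_initiator_met"] = inv.n_initiator_met
        row["n_sec"] = inv.n_sec
        row["n_unclassified"] = inv.n_unclassified
        rows.append(row)
    return pd.DataFrame(rows)
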