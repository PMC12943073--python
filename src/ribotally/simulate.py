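"""Synthetic inputs for every pipeline stage.

Three generators, all pure functions of their spec (seed included):

* annotated bacterial genomes in GenBank flat-file format, with a
  prescribed number of rrn operons (16S/23S/5S triplets), tRNA genes per
  amino acid, and CDSs of known codon composition — plus a ground-truth
  manifest, so parser and inventory can be checked by exact round-trip;
* (T, count) growth datasets drawn from the exponential-floor mean
  functions with additive Gaussian noise;
* allocation tables drawn from the linear tRNA-allocation model.

Sequence between features is random filler and rRNA gene bodies are
placeholder runs: downstream counting reads annotations, not rRNA
sequence content.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .allocation import AllocationRow
from .codons import STANDARD_AMINO_ACIDS, GeneticCode, genetic_code
from .growth import SpeciesGrowthRecord
from .inventory import _ONE_TO_THREE  # three-letter names for products

__all__ = [
    "SyntheticGenomeSpec",
    "GrowthSimSpec",
    "generate_synthetic_genome",
    "simulate_growth_dataset",
    "simulate_allocation_table",
]

_RRNA_PRODUCTS = {
    "16S": ("16S ribosomal RNA", 1540),
    "23S": ("23S ribosomal RNA", 2900),
    "5S": ("5S ribosomal RNA", 120),
}
_TRNA_LEN = 76
_SPACER = 40


@dataclass
class SyntheticGenomeSpec:
    """Blueprint for a synthetic annotated genome.

    ``cds_proteins`` is either a list of amino-acid strings (each
    back-translated codon by codon) or a tuple ``(n_cds, length,
    codon_weights)`` sampling codons from a weight map over sense codons
    (uniform if the map is ``None``).
    """

    n_rrn: int = 2
    m_trna: dict[str, int] = field(default_factory=dict)
    n_initiator_met: int = 0
    cds_proteins: list[str] | tuple = field(default_factory=list)
    table_id: int = 11
    seed: int = 0
    replicon_count: int = 1
    n_pseudo_trna: int = 0
    species_label: str = "Synthetica exempli"

    def __post_init__(self) -> None:
        if self.n_rrn < 0 or self.replicon_count < 1:
            raise ValueError("counts must be non-negative, replicons >= 1")
        for aa, n in self.m_trna.items():
            if aa not in STANDARD_AMINO_ACIDS or n < 0:
                raise ValueError(f"bad tRNA count entry {aa!r}: {n}")

    def expected_inventory(self) -> dict:
        """Ground-truth inventory totals, derivable before generation."""
        m = dict(self.m_trna)
        if self.n_initiator_met:
            m["M"] = m.get("M", 0) + self.n_initiator_met
        return {
            "n_rrn": self.n_rrn,
            "rrna_class_counts": {c: self.n_rrn for c in ("16S", "23S", "5S")},
            "n_trna": sum(m.values()),
            "m_trna": m,
            "n_initiator_met": self.n_initiator_met,
        }


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def _back_translate(
    protein: str, code: GeneticCode, rng: np.random.Generator
) -> tuple[str, dict[str, int]]:
    codons: list[str] = []
    counts: dict[str, int] = {}
    for aa in protein:
        family = code.synonymous_family(aa)
        if not family:
            raise ValueError(f"no codon for amino acid {aa!r}")
        codon = family[rng.integers(0, len(family))]
        codons.append(codon)
        counts[codon] = counts.get(codon, 0) + 1
    stop = sorted(code.stop_codons)[0]
    codons.append(stop)
    counts[stop] = counts.get(stop, 0) + 1
    return "".join(codons), counts


def _sampled_cds(
    n_codons: int, weights: dict[str, float] | None, code: GeneticCode,
    rng: np.random.Generator,
) -> tuple[str, dict[str, int]]:
    sense = [c for c, aa in sorted(code.codon_to_aa.items()) if aa != "*"]
    if weights:
        w = np.array([weights.get(c, 0.0) for c in sense], dtype=float)
        if w.sum() <= 0:
            raise ValueError("codon weight map has no mass on sense codons")
    else:
        w = np.ones(len(sense))
    w = w / w.sum()
    picks = rng.choice(len(sense), size=n_codons, p=w)
    counts: dict[str, int] = {}
    codons = []
    for idx in picks:
        codon = sense[idx]
        codons.append(codon)
        counts[codon] = counts.get(codon, 0) + 1
    stop = sorted(code.stop_codons)[0]
    codons.append(stop)
    counts[stop] = counts.get(stop, 0) + 1
    return "".join(codons), counts


def generate_synthetic_genome(spec: SyntheticGenomeSpec) -> tuple[str, dict]:
    """Emit GenBank flat-file text plus a ground-truth manifest.

    Features are laid out sequentially with random filler between them and
    distributed round-robin over ``replicon_count`` records.  Identical
    specs produce byte-identical output.
    """
    code = genetic_code(spec.table_id)
    rng = np.random.default_rng(spec.seed)

    # assemble the flat feature plan first, then deal it onto replicons
    plan: list[tuple[str, str, dict[str, str]]] = []  # (kind, seq, quals)
    for _ in range(spec.n_rrn):
        for cls in ("16S", "23S", "5S"):
            product, length = _RRNA_PRODUCTS[cls]
            plan.append(("rRNA", "A" * length, {"product": product}))
    for aa in sorted(spec.m_trna):
        family = code.synonymous_family(aa)
        for _ in range(spec.m_trna[aa]):
            codon = family[rng.integers(0, len(family))]
            anticodon = str(Seq(codon).reverse_complement())
            plan.append(
                (
                    "tRNA",
                    _random_dna(rng, _TRNA_LEN),
                    {
                        "product": f"tRNA-{_ONE_TO_THREE[aa]}",
                        "anticodon": f"(pos:complement(0..0),aa:"
                        f"{_ONE_TO_THREE[aa]},seq:{anticodon.lower()})",
                    },
                )
            )
    for _ in range(spec.n_initiator_met):
        plan.append(
            ("tRNA", _random_dna(rng, _TRNA_LEN), {"product": "tRNA-fMet"})
        )
    for _ in range(spec.n_pseudo_trna):
        plan.append(
            (
                "tRNA",
                _random_dna(rng, _TRNA_LEN),
                {"product": "tRNA-Ala", "pseudo": ""},
            )
        )

    codon_counts: dict[str, int] = {}
    if isinstance(spec.cds_proteins, tuple):
        n_cds, length, weights = spec.cds_proteins
        for _ in range(n_cds):
            seq, counts = _sampled_cds(length, weights, code, rng)
            plan.append(("CDS", seq, {}))
            for c, k in counts.items():
                codon_counts[c] = codon_counts.get(c, 0) + k
    else:
        for protein in spec.cds_proteins:
            seq, counts = _back_translate(protein, code, rng)
            plan.append(("CDS", seq, {}))
            for c, k in counts.items():
                codon_counts[c] = codon_counts.get(c, 0) + k

    records = []
    per_rep: list[list] = [[] for _ in range(spec.replicon_count)]
    for j, item in enumerate(plan):
        per_rep[j % spec.replicon_count].append((j, item))
    for r in range(spec.replicon_count):
        seq_parts: list[str] = []
        features: list[SeqFeature] = []
        pos = 0
        for j, (kind, fseq, quals) in per_rep[r]:
            gap = _SPACER + int(rng.integers(0, 20))
            seq_parts.append(_random_dna(rng, gap))
            pos += gap
            start = pos
            # alternate strands so minus-strand handling is exercised
            strand = 1 if j % 2 == 0 else -1
            body = fseq if strand == 1 else str(Seq(fseq).reverse_complement())
            seq_parts.append(body)
            pos += len(fseq)
            q = {k: [v] for k, v in quals.items()}
            if kind == "CDS":
                q["transl_table"] = [str(spec.table_id)]
            features.append(
                SeqFeature(
                    FeatureLocation(start, pos, strand=strand),
                    type=kind,
                    qualifiers=q,
                )
            )
        seq_parts.append(_random_dna(rng, _SPACER))
        rec = SeqRecord(
            Seq("".join(seq_parts)),
            id=f"SYN{r + 1:02d}.1",
            name=f"SYN{r + 1:02d}",
            description=f"{spec.species_label} synthetic replicon {r + 1}",
            annotations={
                "molecule_type": "DNA",
                "topology": "circular",
                "data_file_division": "BCT",
                "date": "01-JAN-2000",
                "organism": spec.species_label,
                "accessions": [f"SYN{r + 1:02d}"],
            },
            features=features,
        )
        records.append(rec)

    buf = io.StringIO()
    SeqIO.write(records, buf, "genbank")
    manifest = spec.expected_inventory()
    manifest["codon_counts"] = codon_counts
    manifest["n_cds"] = (
        spec.cds_proteins[0]
        if isinstance(spec.cds_proteins, tuple)
        else len(spec.cds_proteins)
    )
    manifest["n_pseudo_trna"] = spec.n_pseudo_trna
    manifest["replicon_count"] = spec.replicon_count
    manifest["species_label"] = spec.species_label
    return buf.getvalue(), manifest


@dataclass
class GrowthSimSpec:
    """Parameters for drawing a (T, count) dataset from a growth model.

    ``t_grid`` is either an explicit list of generation times (minutes) or
    a (low, high) tuple expanded to ``n`` log-spaced points — generation
    times span orders of magnitude, so log spacing is the natural design.
    """

    model_kind: str = "rrn_eq1"
    alpha: float = 9.0
    beta: float = 0.012
    gamma: float = 41.0
    sigma: float = 1.0
    n: int = 20
    t_grid: tuple[float, float] | list[float] = (10.0, 10080.0)
    seed: int = 0
    round_to_integers: bool = False

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n < 3:
            raise ValueError("need n >= 3")
        if self.model_kind not in ("rrn_eq1", "trna_eq2"):
            raise ValueError(f"unknown model kind {self.model_kind!r}")

    def times(self) -> np.ndarray:
        if isinstance(self.t_grid, tuple) and len(self.t_grid) == 2:
            lo, hi = self.t_grid
            return np.geomspace(lo, hi, self.n)
        t = np.asarray(self.t_grid, dtype=float)
        if len(t) != self.n:
            raise ValueError("explicit t_grid length must equal n")
        return t


def simulate_growth_dataset(spec: GrowthSimSpec) -> list[SpeciesGrowthRecord]:
    """Draw counts from a floor model with additive Gaussian noise.

    With ``round_to_integers`` the draws are rounded; rrn counts are then
    clipped at 1 (a genome has at least one operon) and tRNA counts at 0.
    The model floor gamma is *not* re-imposed on noisy draws.
    """
    rng = np.random.default_rng(spec.seed)
    t = spec.times()
    floor = 1.0 if spec.model_kind == "rrn_eq1" else spec.gamma
    mu = floor + spec.alpha * np.exp(-spec.beta * t)
    y = mu + rng.normal(0.0, spec.sigma, len(t)) if spec.sigma > 0 else mu.copy()
    if spec.round_to_integers:
        y = np.round(y)
        y = np.maximum(y, 1.0 if spec.model_kind == "rrn_eq1" else 0.0)
    records = []
    for i, (ti, yi) in enumerate(zip(t, y)):
        records.append(
            SpeciesGrowthRecord(
                species_label=f"sim_{i + 1:03d}",
                kingdom="Simulata",
                t_minutes=float(ti),
                gt_rank=i + 1,
                n_rrn=float(yi) if spec.model_kind == "rrn_eq1" else None,
                n_trna=float(yi) if spec.model_kind == "trna_eq2" else None,
            )
        )
    return records


_CFS_CHOICES = (1, 2, 3, 4, 6)
_AA_POOL = tuple(aa for aa in STANDARD_AMINO_ACIDS if aa != "M")


def simulate_allocation_table(
    beta0: float,
    beta1: float,
    beta2: float,
    sigma: float,
    n: int,
    seed: int,
    round_to_integers: bool = True,
) -> list[AllocationRow]:
    """Draw allocation rows from the linear model.

    N_AA is log-uniform over [6e3, 2e5] (the span observed in fast-growing
    genomes), CFS uniform over {1, 2, 3, 4, 6}; M_tRNA is the linear mean
    plus Gaussian noise, optionally rounded and floored at 1.
    """
    if n < 4:
        raise ValueError("need n >= 4 rows")
    rng = np.random.default_rng(seed)
    n_aa = np.exp(rng.uniform(np.log(6e3), np.log(2e5), n)).astype(int)
    cfs = rng.choice(_CFS_CHOICES, size=n)
    m = beta0 + beta1 * n_aa + beta2 * cfs
    if sigma > 0:
        m = m + rng.normal(0.0, sigma, n)
    if round_to_integers:
        m = np.maximum(np.round(m), 1.0)
    return [
        AllocationRow(
            amino_acid=_AA_POOL[i % len(_AA_POOL)],
            n_aa=int(n_aa[i]),
            cfs=int(cfs[i]),
            m_trna=int(round(m[i])) if round_to_integers else m[i],
        )
        for i in range(n)
    ]
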