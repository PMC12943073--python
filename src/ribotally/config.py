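"""Study configuration: the packaged 20-species table and its loaders.

The default configuration lists the 20 bacterial genomes of the study —
10 Bacillati and 10 Pseudomonadati spanning generation times from ~10 min
(*Vibrio natriegens*) to ~7 days (*Mycobacterium leprae*) — with their
RefSeq accessions, printed generation-time ranges and growth-rate ranks.
Genome flat files themselves are not packaged; point ``genome_dir`` at a
directory of ``<accession>.gbff`` files (see ``scripts/fetch_genomes.py``)
to run the real inventory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .growth import SpeciesGrowthRecord, midpoint_generation_time

__all__ = [
    "StudySpecies",
    "StudyConfig",
    "load_species_table",
    "load_published_growth_fits",
    "packaged_allocation_table",
]

_DATA = resources.files("ribotally") / "data"

#: Packaged per-amino-acid allocation tables (fast grower per kingdom).
ALLOCATION_FIXTURES = {
    "vibrio_natriegens": "allocation_vibrio_natriegens.tsv",
    "clostridium_perfringens": "allocation_clostridium_perfringens.tsv",
}


@dataclass
class StudySpecies:
    species: str
    kingdom: str
    accessions: list[str]
    generation_time: str
    gt_rank: int
    gbff_paths: list[Path] = field(default_factory=list)

    @property
    def t_minutes(self) -> float:
        return midpoint_generation_time(self.generation_time)

    def growth_record(self, n_rrn=None, n_trna=None) -> SpeciesGrowthRecord:
        return SpeciesGrowthRecord(
            species_label=self.species,
            kingdom=self.kingdom,
            t_minutes=self.t_minutes,
            gt_rank=self.gt_rank,
            n_rrn=n_rrn,
            n_trna=n_trna,
        )


@dataclass
class StudyConfig:
    species: list[StudySpecies]
    table_id: int = 11
    exclude_pseudo: bool = True
    genome_dir: Path | None = None

    def resolve_genome_paths(self) -> None:
        """Attach ``<accession>.gbff`` paths found under ``genome_dir``."""
        if self.genome_dir is None:
            return
        root = Path(self.genome_dir)
        for sp in self.species:
            sp.gbff_paths = [
                p
                for acc in sp.accessions
                for p in (
                    root / f"{acc}.gbff",
                    root / f"{acc}.gb",
                )
                if p.exists()
            ]


def load_species_table() -> list[StudySpecies]:
    """The packaged 20-species study table."""
    out = []
    with (_DATA / "species.tsv").open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            out.append(
                StudySpecies(
                    species=row["species"],
                    kingdom=row["kingdom"],
                    accessions=row["accessions"].split(","),
                    generation_time=row["generation_time"],
                    gt_rank=int(row["gt_rank"]),
                )
            )
    return out


def default_config(genome_dir=None, **kwargs) -> StudyConfig:
    cfg = StudyConfig(
        species=load_species_table(),
        genome_dir=None if genome_dir is None else Path(genome_dir),
        **kwargs,
    )
    cfg.resolve_genome_paths()
    return cfg


def load_published_growth_fits() -> list[dict]:
    """Packaged maximum-likelihood fit summaries of the growth models.

    Each entry carries the fitted (alpha, beta[, gamma]) and the model and
    null log-likelihoods from which the likelihood-ratio chi-square is
    recomputed.
    """
    with (_DATA / "published_growth_fits.json").open() as fh:
        return json.load(fh)["fits"]


def packaged_allocation_table(species_key: str):
    """Load a packaged allocation table; keys per ALLOCATION_FIXTURES."""
    from .allocation import read_allocation_tsv

    try:
        name = ALLOCATION_FIXTURES[species_key]
    except KeyError:
        raise ValueError(
            f"no packaged allocation table {species_key!r}; "
            f"available: {sorted(ALLOCATION_FIXTURES)}"
        ) from None
    with resources.as_file(_DATA / name) as path:
        return read_allocation_tsv(path)
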