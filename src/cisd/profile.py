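"""Phylogenetic distribution profiling.

Builds the species-by-type distribution table: sequences are
species-deduplicated (multiple sequences of the same type in one species,
and sequences from multiple strains, count once), tabulated per taxon
group and CISD type, and normalised against a user-supplied reference set
of sequenced genomes (the "CA-set") to give CISD-positive fractions.
A within-genus retention statistic quantifies gene loss: over genera with
at least ``min_genomes`` sequenced genomes and at least one CISD-positive
species, the mean ± SD percentage of CISD-positive species per genus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import RecordMeta, superkingdom_of

TYPE_COLUMNS = ("1", "2", "3", "4", "5", "6", "7", "orphan")


@dataclass(frozen=True)
class SpeciesKey:
    """Case-insensitive species identity; strain designations are stripped
    upstream (the naming convention carries none)."""

    superkingdom: str
    phylum_abbrev: str
    genus: str
    species_epithet: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "superkingdom", self.superkingdom.lower())
        object.__setattr__(self, "phylum_abbrev", self.phylum_abbrev.lower())
        object.__setattr__(self, "genus", self.genus.lower())
        object.__setattr__(self, "species_epithet", self.species_epithet.lower())


def species_key(meta: RecordMeta) -> SpeciesKey:
    """Species key from parsed record metadata.

    The naming convention carries only the genus initial, so cross-genus
    initial collisions within one phylum collapse; this is accepted and
    matches the convention's resolution.
    """
    return SpeciesKey(
        superkingdom=superkingdom_of(meta.phylum_abbrev),
        phylum_abbrev=meta.phylum_abbrev,
        genus=meta.genus_initial,
        species_epithet=meta.species,
    )


def _fold_type(t: str) -> str:
    # 2a/2b are tabulated under type 2
    return "2" if t in ("2a", "2b") else t


def dedup_species(records: Iterable[RecordMeta]) -> dict[SpeciesKey, set[str]]:
    """One entry per species; the value is the union of its CISD types."""
    out: dict[SpeciesKey, set[str]] = {}
    skipped = 0
    for meta in records:
        if not meta.species:
            skipped += 1
            continue
        out.setdefault(species_key(meta), set()).add(_fold_type(meta.cisd_type))
    if skipped:
        warnings.warn(f"dedup_species: skipped {skipped} records without species",
                      stacklevel=2)
    return out


def tabulate_profile(species_types: Mapping[SpeciesKey, set[str]],
                     taxonomy: Mapping[SpeciesKey, Sequence[str]] | None = None,
                     genome_totals: Mapping[str, int] | None = None,
                     genome_set: Iterable[SpeciesKey] | None = None) -> pd.DataFrame:
    """Counts of species per taxon row and CISD type column.

    ``taxonomy`` maps each species to its taxon path (e.g.
    ``("Bacteria", "Proteobacteria")``); every path element gets a row, so
    parent rows aggregate their children.  Species not covered fall into
    an "unknown" row.  ``Any`` counts species with >= 1 type; ``CISD+``
    restricts to members of ``genome_set`` when given (else equals Any);
    ``percent`` = 100*CISD+/Total when ``genome_totals`` supplies a Total.
    """
    if genome_totals:
        for taxon, total in genome_totals.items():
            if total < 0:
                raise ValueError(f"negative genome total for {taxon!r}: {total}")
    genome_members = set(genome_set) if genome_set is not None else None

    def paths_for(key: SpeciesKey) -> Sequence[str]:
        if taxonomy is not None and key in taxonomy:
            return tuple(taxonomy[key])
        if taxonomy is None:
            return (key.superkingdom.capitalize(),)
        return ("unknown",)

    rows: dict[str, dict[str, set[SpeciesKey]]] = {}
    for key, types in species_types.items():
        for taxon in paths_for(key):
            cell = rows.setdefault(taxon, {c: set() for c in (*TYPE_COLUMNS, "Any", "CISD+")})
            for t in types:
                cell[_fold_type(t)].add(key)
            if types:
                cell["Any"].add(key)
                if genome_members is None or key in genome_members:
                    cell["CISD+"].add(key)

    records = []
    for taxon, cell in rows.items():
        rec: dict[str, object] = {"taxon": taxon}
        for c in (*TYPE_COLUMNS, "Any", "CISD+"):
            rec[c] = len(cell[c])
        total = genome_totals.get(taxon) if genome_totals else None
        rec["Total"] = total if total is not None else pd.NA
        rec["percent"] = (round(100.0 * rec["CISD+"] / total)
                          if total else pd.NA)
        records.append(rec)
    df = pd.DataFrame.from_records(
        records, columns=["taxon", *TYPE_COLUMNS, "Any", "CISD+", "Total", "percent"])
    return df.sort_values("taxon").reset_index(drop=True)


@dataclass(frozen=True)
class GenusLossResult:
    mean_percent: float
    sd_percent: float
    n_genera: int
    sd_percent_sample: float = float("nan")  # n-1 denominator, for comparison


def genus_loss_stat(positives: Iterable[SpeciesKey],
                    genome_set: Iterable[SpeciesKey],
                    min_genomes: int = 5) -> GenusLossResult:
    """Within-genus CISD retention over qualifying genera.

    A genus qualifies with >= ``min_genomes`` sequenced genomes and >= 1
    CISD-positive species.  Reports mean and population SD (and the n-1
    sample SD for comparison) of the per-genus positive percentage.
    """
    positives = set(positives)
    genera: dict[tuple[str, str], set[SpeciesKey]] = {}
    for key in genome_set:
        genera.setdefault((key.superkingdom, key.genus), set()).add(key)
    fractions = []
    for members in genera.values():
        pos = len(members & positives)
        if len(members) >= min_genomes and pos >= 1:
            fractions.append(100.0 * pos / len(members))
    if not fractions:
        return GenusLossResult(float("nan"), float("nan"), 0)
    arr = np.asarray(fractions)
    sample_sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return GenusLossResult(float(arr.mean()), float(arr.std(ddof=0)),
                           len(arr), sample_sd)
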