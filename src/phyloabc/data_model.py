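"""Domain types and I/O shared by every analysis stage.

The package's universal data carrier is the :class:`SequencePanel`: aligned
haplotype copies at one or more loci, each copy tagged with the individual,
population and region it came from.  mtDNA loci contribute one copy per
individual; nuclear loci contribute two phased allele copies per individual
(the cloning protocol that produced the original data yields phase-known
alleles, so allele records are treated as haplotypes throughout).

Sites containing a gap or ambiguity character in *any* sequence are excluded
listwise from all downstream statistics, matching the common Arlequin/DnaSP
default.  Internal site indices are 0-based; every reported position is
1-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "LocusSpec",
    "SeqRecordEntry",
    "SequencePanel",
    "HaplotypeTable",
    "PanelFormatError",
    "PanelMetadataError",
    "read_panel",
    "write_panel",
    "collapse_haplotypes",
    "write_stats_table",
    "read_stats_table",
    "usable_site_mask",
    "site_matrix",
]

VALID_BASES = frozenset("ACGT")
REGIONS = ("NWP", "NEP")


class PanelFormatError(ValueError):
    """Sequence data violates the panel contract (length, alphabet, duplicates)."""


class PanelMetadataError(ValueError):
    """Sample metadata is missing or inconsistent with the sequence data."""


@dataclass(frozen=True)
class LocusSpec:
    """Static description of one sequenced locus.

    Parameters
    ----------
    name : str
        Locus label (e.g. ``"CYTB"``).
    length_bp : int
        Alignment length in base pairs.
    inheritance_scalar : float
        Effective gene-copy number of the locus class relative to a nuclear
        autosome: 1.0 for nuclear, 0.25 for mtDNA (haploid, uniparental).
    mu_site_gen : float
        Mutation rate per site per generation.
    copies_per_individual : int
        Gene copies each individual contributes: 1 (mtDNA) or 2 (nuclear).
    """

    name: str
    length_bp: int
    inheritance_scalar: float = 1.0
    mu_site_gen: float = 1e-9
    copies_per_individual: int = 2

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"length_bp must be positive, got {self.length_bp}")
        if self.inheritance_scalar <= 0:
            raise ValueError("inheritance_scalar must be positive")
        if self.mu_site_gen <= 0:
            raise ValueError("mu_site_gen must be positive")
        if self.copies_per_individual < 1:
            raise ValueError("copies_per_individual must be >= 1")

    @property
    def mu_locus_gen(self) -> float:
        """Per-locus mutation rate per generation, u = mu_site_gen * length_bp."""
        return self.mu_site_gen * self.length_bp

    @property
    def is_mtdna(self) -> bool:
        return self.copies_per_individual == 1


@dataclass(frozen=True)
class SeqRecordEntry:
    """One aligned gene copy: who it came from and its sequence."""

    individual: str
    population: str
    region: str
    sequence: str
    allele_index: int = 0


@dataclass
class SequencePanel:
    """Aligned haplotype copies grouped by individual/population/locus."""

    loci: list[LocusSpec]
    records: dict[str, list[SeqRecordEntry]]

    def __post_init__(self) -> None:
        self.validate()

    def locus(self, name: str) -> LocusSpec:
        for sp in self.loci:
            if sp.name == name:
                return sp
        raise KeyError(f"unknown locus {name!r}")

    def populations(self, locus: str | None = None) -> list[str]:
        """Population labels in first-appearance order."""
        names = [locus] if locus else [sp.name for sp in self.loci]
        seen: dict[str, None] = {}
        for nm in names:
            for rec in self.records.get(nm, []):
                seen.setdefault(rec.population, None)
        return list(seen)

    def records_for(self, locus: str, population: str | None = None) -> list[SeqRecordEntry]:
        recs = self.records.get(locus)
        if recs is None:
            raise KeyError(f"unknown locus {locus!r}")
        if population is None:
            return list(recs)
        return [r for r in recs if r.population == population]

    def validate(self) -> None:
        locus_names = {sp.name for sp in self.loci}
        if set(self.records) - locus_names:
            raise PanelFormatError(
                f"records for unknown loci: {sorted(set(self.records) - locus_names)}"
            )
        for sp in self.loci:
            seen: set[tuple[str, int]] = set()
            for rec in self.records.get(sp.name, []):
                if len(rec.sequence) != sp.length_bp:
                    raise PanelFormatError(
                        f"{sp.name}: sequence for {rec.individual} has length "
                        f"{len(rec.sequence)}, expected {sp.length_bp}"
                    )
                key = (rec.individual, rec.allele_index)
                if key in seen:
                    raise PanelFormatError(
                        f"{sp.name}: duplicate record for individual "
                        f"{rec.individual!r} allele {rec.allele_index}"
                    )
                seen.add(key)
            by_ind: dict[str, int] = {}
            for rec in self.records.get(sp.name, []):
                by_ind[rec.individual] = by_ind.get(rec.individual, 0) + 1
            for ind, n in by_ind.items():
                if n != sp.copies_per_individual:
                    raise PanelFormatError(
                        f"{sp.name}: individual {ind!r} has {n} records, "
                        f"expected {sp.copies_per_individual}"
                    )


@dataclass
class HaplotypeTable:
    """Distinct sequences at one locus with overall/per-population/per-region counts.

    Haplotypes are ordered by descending total count, ties broken by
    lexicographic sequence, so the table (and hence every downstream network)
    is deterministic.
    """

    locus: str
    sequences: list[str]
    counts: np.ndarray
    pop_counts: pd.DataFrame  # rows: haplotype index, cols: population
    region_counts: pd.DataFrame  # rows: haplotype index, cols: region

    @property
    def n_haplotypes(self) -> int:
        return len(self.sequences)

    @property
    def n_records(self) -> int:
        return int(self.counts.sum())


def read_panel(
    fasta_paths: Mapping[str, str],
    metadata_path: str,
    locus_config: Sequence[LocusSpec],
) -> SequencePanel:
    """Read one FASTA per locus plus a tab-delimited metadata table.

    FASTA headers are ``>individualID|alleleIndex`` (the ``|alleleIndex``
    suffix is optional for mtDNA).  The metadata table must have columns
    ``individual``, ``population``, ``region``.

    Raises
    ------
    PanelFormatError
        On alignment-length mismatch or duplicate (individual, allele) pairs.
    PanelMetadataError
        When a FASTA header names an individual absent from the metadata.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"individual", "population", "region"}
    if not required.issubset(meta.columns):
        raise PanelMetadataError(
            f"metadata must have columns {sorted(required)}, got {list(meta.columns)}"
        )
    meta_map = {
        row.individual: (row.population, row.region) for row in meta.itertuples()
    }

    records: dict[str, list[SeqRecordEntry]] = {}
    by_name = {sp.name: sp for sp in locus_config}
    for locus_name, path in fasta_paths.items():
        if locus_name not in by_name:
            raise PanelFormatError(f"no LocusSpec configured for locus {locus_name!r}")
        sp = by_name[locus_name]
        entries: list[SeqRecordEntry] = []
        for rec in SeqIO.parse(path, "fasta"):
            header = rec.id
            if "|" in header:
                ind, _, idx_s = header.partition("|")
                try:
                    allele_index = int(idx_s)
                except ValueError as exc:
                    raise PanelFormatError(
                        f"{locus_name}: bad allele index in header {header!r}"
                    ) from exc
            else:
                ind, allele_index = header, 0
            if ind not in meta_map:
                raise PanelMetadataError(
                    f"{locus_name}: individual {ind!r} missing from metadata"
                )
            pop, region = meta_map[ind]
            seq = str(rec.seq).upper()
            if len(seq) != sp.length_bp:
                raise PanelFormatError(
                    f"{locus_name}: sequence {header!r} has length {len(seq)}, "
                    f"expected {sp.length_bp}"
                )
            entries.append(SeqRecordEntry(ind, pop, region, seq, allele_index))
        records[locus_name] = entries
    return SequencePanel(loci=list(locus_config), records=records)


def write_panel(panel: SequencePanel, fasta_paths: Mapping[str, str], metadata_path: str) -> None:
    """Inverse of :func:`read_panel`; round-trips losslessly."""
    rows: dict[str, tuple[str, str]] = {}
    for sp in panel.loci:
        out = []
        for rec in panel.records.get(sp.name, []):
            out.append(
                SeqRecord(
                    Seq(rec.sequence),
                    id=f"{rec.individual}|{rec.allele_index}",
                    description="",
                )
            )
            rows[rec.individual] = (rec.population, rec.region)
        SeqIO.write(out, fasta_paths[sp.name], "fasta")
    meta = pd.DataFrame(
        [(ind, pop, region) for ind, (pop, region) in rows.items()],
        columns=["individual", "population", "region"],
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def collapse_haplotypes(panel: SequencePanel, locus: str) -> HaplotypeTable:
    """Collapse identical sequences at one locus into a haplotype table."""
    recs = panel.records_for(locus)
    if not recs:
        raise ValueError(f"locus {locus!r} has no records")
    groups: dict[str, list[SeqRecordEntry]] = {}
    for rec in recs:
        groups.setdefault(rec.sequence, []).append(rec)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    seqs = [s for s, _ in ordered]
    counts = np.array([len(g) for _, g in ordered], dtype=int)
    pops = panel.populations(locus)
    pop_tab = pd.DataFrame(0, index=range(len(seqs)), columns=pops, dtype=int)
    reg_tab = pd.DataFrame(0, index=range(len(seqs)), columns=list(REGIONS), dtype=int)
    for i, (_, g) in enumerate(ordered):
        for rec in g:
            pop_tab.loc[i, rec.population] += 1
            if rec.region not in reg_tab.columns:
                reg_tab[rec.region] = 0
            reg_tab.loc[i, rec.region] += 1
    return HaplotypeTable(
        locus=locus, sequences=seqs, counts=counts, pop_counts=pop_tab, region_counts=reg_tab
    )


def write_stats_table(rows: Sequence[Mapping[str, object]], path: str) -> None:
    """Write named records as a tab-delimited table.

    Column order follows the first row; every row must have the same column
    set.  ``NaN``/``None`` values are written as the literal ``NA``.
    """
    if not rows:
        raise ValueError("no rows to write")
    cols = list(rows[0])
    for i, row in enumerate(rows):
        if list(row) != cols and set(row) != set(cols):
            raise ValueError(f"row {i} columns {sorted(row)} != {sorted(cols)}")
    df = pd.DataFrame([{c: row[c] for c in cols} for row in rows], columns=cols)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", encoding="utf-8")


def read_stats_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


# ---------------------------------------------------------------------------
# encoding helpers used by the statistics modules


def usable_site_mask(sequences: Sequence[str]) -> np.ndarray:
    """Boolean mask of sites free of gaps/ambiguity codes in every sequence."""
    if not sequences:
        return np.zeros(0, dtype=bool)
    arr = np.frombuffer("".join(sequences).encode(), dtype="S1").reshape(
        len(sequences), -1
    )
    return np.isin(arr, [b"A", b"C", b"G", b"T"]).all(axis=0)


def site_matrix(sequences: Sequence[str], mask: np.ndarray | None = None) -> np.ndarray:
    """Integer-coded alignment restricted to usable sites (rows = copies)."""
    if mask is None:
        mask = usable_site_mask(sequences)
    arr = np.frombuffer("".join(sequences).encode(), dtype=np.uint8).reshape(
        len(sequences), -1
    )
    return arr[:, mask]
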