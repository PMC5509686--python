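"""Readers, writers and dataset assembly for the delimitation pipeline.

On-disk formats are deliberately plain: a tab-separated specimen table, one
aligned FASTA per locus (headers are specimen IDs), Newick trees, and a
plot-by-OTU CSV community table with a per-plot covariate sidecar CSV.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_DOWN
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

SPECIMEN_COLUMNS = ["specimen_id", "plot_id", "sample_date", "morphospecies", "taxon_name"]

__all__ = [
    "SpecimenRecord",
    "LocusAlignment",
    "CommunityTable",
    "SampleSummary",
    "read_specimen_table",
    "write_specimen_table",
    "load_dataset",
    "summarize_samples",
    "read_newick",
    "write_newick",
    "newick_string",
]


@dataclass(frozen=True)
class SpecimenRecord:
    """One collected individual and its bookkeeping.

    ``loci_present`` lists the loci for which an aligned sequence exists;
    a specimen sequenced at neither locus never enters the dataset.
    """

    specimen_id: str
    plot_id: str
    sample_date: _dt.date | None = None
    morphospecies: str | None = None
    taxon_name: str | None = None
    loci_present: frozenset[str] = field(default_factory=frozenset)


@dataclass
class LocusAlignment:
    """A fixed-length alignment for one locus, keyed by specimen ID."""

    locus_name: str
    sequences: dict[str, str]
    length: int

    def __post_init__(self) -> None:
        for sid, seq in self.sequences.items():
            if len(seq) != self.length:
                raise ValueError(
                    f"ragged alignment in locus {self.locus_name}: sequence "
                    f"{sid!r} has length {len(seq)}, expected {self.length}"
                )

    @classmethod
    def from_fasta(cls, path, locus_name: str | None = None) -> "LocusAlignment":
        path = Path(path)
        name = locus_name or path.stem
        seqs: dict[str, str] = {}
        length: int | None = None
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicated specimen ID {rec.id!r} in {path}")
            seq = str(rec.seq).upper()
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise ValueError(
                    f"ragged alignment in {path}: record {rec.id!r} has "
                    f"length {len(seq)}, expected {length}"
                )
            seqs[rec.id] = seq
        if length is None:
            raise ValueError(f"no sequences found in {path}")
        return cls(locus_name=name, sequences=seqs, length=length)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid in sorted(self.sequences):
                fh.write(f">{sid}\n{self.sequences[sid]}\n")


@dataclass
class CommunityTable:
    """Plot-by-OTU abundance matrix with per-plot covariates.

    ``counts`` rows are plots, columns OTUs, values nonnegative integers.
    ``covariates`` is indexed by plot and typically carries habitat,
    altitude (m), mean temperature (°C) and a vegetation-density index
    (NDMI-like, dimensionless in [-1, 1]).
    """

    counts: pd.DataFrame
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("plot and OTU labels must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("community counts must be nonnegative")
        if self.covariates is not None:
            missing = set(self.counts.index) - set(self.covariates.index)
            if missing:
                raise ValueError(f"plots missing covariates: {sorted(missing)}")

    @property
    def plots(self) -> list[str]:
        return [str(p) for p in self.counts.index]

    @property
    def otus(self) -> list[str]:
        return [str(o) for o in self.counts.columns]

    def write_csv(self, counts_path, covariates_path=None) -> None:
        self.counts.to_csv(counts_path, index_label="plot_id")
        if covariates_path is not None and self.covariates is not None:
            self.covariates.to_csv(covariates_path, index_label="plot_id")

    @classmethod
    def read_csv(cls, counts_path, covariates_path=None) -> "CommunityTable":
        counts = pd.read_csv(counts_path, index_col=0, comment="#")
        cov = None
        if covariates_path is not None:
            cov = pd.read_csv(covariates_path, index_col=0, comment="#")
        return cls(counts=counts, covariates=cov)


@dataclass(frozen=True)
class SampleSummary:
    plot_id: str
    n_replicates: int
    total_individuals: int
    mean_individuals: float


def _round1(x: float) -> float:
    # Ties round toward zero (28.0 stays 28.0; 2.75 -> 2.7), matching the
    # printed precision of typical survey summary tables.
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_DOWN))


def summarize_samples(
    specimens: Iterable[SpecimenRecord] | Mapping[str, int],
    replicates: Mapping[str, int],
) -> tuple[list[SampleSummary], float]:
    """Per-plot totals and one-decimal mean individuals per trap replicate.

    ``specimens`` is either an iterable of :class:`SpecimenRecord` (counted
    by plot) or a ready-made mapping plot -> individual count.
    ``replicates`` maps each plot to its number of Malaise-trap replicates.
    Returns the per-plot summaries (ordered as in ``replicates``) and the
    overall mean = total individuals / total replicates.
    """
    if isinstance(specimens, Mapping):
        counts = dict(specimens)
    else:
        counts = {}
        for rec in specimens:
            counts[rec.plot_id] = counts.get(rec.plot_id, 0) + 1
    unknown = set(counts) - set(replicates)
    if unknown:
        raise ValueError(f"unknown plot ID(s) in specimen data: {sorted(unknown)}")
    summaries = []
    for plot, n_rep in replicates.items():
        if n_rep <= 0:
            raise ValueError(f"plot {plot!r} has nonpositive replicate count")
        total = int(counts.get(plot, 0))
        summaries.append(
            SampleSummary(plot, int(n_rep), total, _round1(total / n_rep))
        )
    grand_total = sum(s.total_individuals for s in summaries)
    grand_reps = sum(s.n_replicates for s in summaries)
    overall = _round1(grand_total / grand_reps)
    return summaries, overall


# ---------------------------------------------------------------------------
# specimen table

def read_specimen_table(path) -> pd.DataFrame:
    """Read the tab-separated specimen table (UTF-8, header row).

    Columns: specimen_id, plot_id, sample_date, morphospecies, taxon_name;
    the last two may be empty.  Duplicate specimen IDs are a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    missing = [c for c in SPECIMEN_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"specimen table missing column(s): {missing}")
    dups = df["specimen_id"][df["specimen_id"].duplicated()]
    if len(dups):
        raise ValueError(f"duplicated specimen ID(s): {sorted(set(dups))}")
    return df


def write_specimen_table(records: Sequence[SpecimenRecord], path) -> None:
    rows = [
        {
            "specimen_id": r.specimen_id,
            "plot_id": r.plot_id,
            "sample_date": r.sample_date.isoformat() if r.sample_date else "",
            "morphospecies": r.morphospecies or "",
            "taxon_name": r.taxon_name or "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=SPECIMEN_COLUMNS).to_csv(path, sep="\t", index=False)


def _parse_date(value: str) -> _dt.date | None:
    if not value:
        return None
    return _dt.date.fromisoformat(value)


def load_dataset(
    specimen_table_path,
    locus_fasta_paths: Mapping[str, str | Path],
) -> tuple[list[SpecimenRecord], list[LocusAlignment]]:
    """Assemble a cross-referenced dataset from a table and per-locus FASTAs.

    Specimens present in the table but in none of the alignments are
    dropped with a warning; alignment records absent from the table are a
    hard error.  Each retained record's ``loci_present`` reflects the
    alignments it appears in.
    """
    table = read_specimen_table(specimen_table_path)
    alignments = [
        LocusAlignment.from_fasta(path, locus_name=name)
        for name, path in locus_fasta_paths.items()
    ]
    known = set(table["specimen_id"])
    for aln in alignments:
        orphans = set(aln.sequences) - known
        if orphans:
            raise ValueError(
                f"alignment {aln.locus_name} contains specimen(s) absent from "
                f"the table: {sorted(orphans)}"
            )
    records: list[SpecimenRecord] = []
    dropped = []
    for row in table.itertuples(index=False):
        loci = frozenset(
            a.locus_name for a in alignments if row.specimen_id in a.sequences
        )
        if not loci:
            dropped.append(row.specimen_id)
            continue
        records.append(
            SpecimenRecord(
                specimen_id=row.specimen_id,
                plot_id=row.plot_id,
                sample_date=_parse_date(row.sample_date),
                morphospecies=row.morphospecies or None,
                taxon_name=getattr(row, "taxon_name", "") or None,
                loci_present=loci,
            )
        )
    if dropped:
        logger.warning(
            "dropped %d specimen(s) with no sequence at any locus: %s",
            len(dropped), dropped[:10],
        )
    return records, alignments


# ---------------------------------------------------------------------------
# Newick

def read_newick(source) -> dendropy.Tree:
    """Read a Newick tree (path or string), preserving labels verbatim."""
    text = str(source)
    looks_like_tree = "(" in text or ";" in text
    if not looks_like_tree:
        return dendropy.Tree.get(
            path=text, schema="newick", preserve_underscores=True
        )
    return dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True
    )


def newick_string(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        preserve_spaces=True,
        suppress_rooting=True,
    )


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(tree))
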