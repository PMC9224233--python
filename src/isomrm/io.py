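"""Readers and writers for the pipeline's tabular and sequence inputs.

Covers protein FASTA collections, detected-peptide evidence lists from
discovery (DDA) runs, and per-sample metadata (donor, condition, motility
percentages, semen-classification group).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

VALID_ROLES = ("family_target", "background", "control")
VALID_CONDITIONS = ("non_capacitated", "capacitated", "none")
VALID_GROUP_LABELS = ("asthenoterato", "normo", "terato", "none")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its role in the analysis.

    Parameters
    ----------
    accession : str
        Short unique identifier (e.g. a UniProt accession).
    sequence : str
        Uppercase amino-acid sequence over the 20 canonical letters.
    label : str
        Display name, e.g. the isoform name. Defaults to the accession.
    role : str
        One of ``family_target`` (isoform to discriminate), ``background``
        (rest of the searched proteome) or ``control`` (loading control).
    """

    accession: str
    sequence: str
    label: str = ""
    role: str = "family_target"

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.accession}: sequence must be non-empty")
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in CANONICAL_RESIDUES:
                raise ValueError(
                    f"{self.accession}: non-canonical residue {aa!r} "
                    f"at position {i}"
                )
        if self.role not in VALID_ROLES:
            raise ValueError(f"{self.accession}: unknown role {self.role!r}")
        if not self.label:
            object.__setattr__(self, "label", self.accession)


@dataclass(frozen=True)
class EvidenceSet:
    """Peptides previously observed in discovery runs.

    Used as a detectability filter: only evidenced peptides are eligible
    for the targeted assay.
    """

    peptides: frozenset[str]
    source_label: str = ""

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.peptides

    def __len__(self) -> int:
        return len(self.peptides)


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample experimental metadata.

    Motility percentages may be missing (``None``) for capacitation-mode
    datasets where they are not used; 0 is a legal measured value and is
    distinct from missing.
    """

    sample_id: str
    donor_id: str
    condition: str = "none"
    total_motility: float | None = None
    progressive_motility: float | None = None
    group_label: str = "none"

    def __post_init__(self) -> None:
        if self.condition not in VALID_CONDITIONS:
            raise ValueError(f"{self.sample_id}: bad condition {self.condition!r}")
        if self.group_label not in VALID_GROUP_LABELS:
            raise ValueError(f"{self.sample_id}: bad group {self.group_label!r}")
        for name in ("total_motility", "progressive_motility"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValueError(f"{self.sample_id}: {name}={v} outside [0, 100]")


def _split_fasta_header(header: str) -> tuple[str, str]:
    """Return (accession, label) from a FASTA id token.

    UniProt-style ``sp|ACC|NAME`` / ``tr|ACC|NAME`` ids yield the middle
    accession field with NAME as label; otherwise the whole first token is
    the accession.
    """
    token = header.split()[0]
    parts = token.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1], parts[2]
    return token, token


def read_fasta(
    path: str | Path,
    role: str = "family_target",
    on_invalid: str = "error",
) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Parameters
    ----------
    path : path
        FASTA file; sequences may be wrapped over any number of lines.
    role : str
        Role assigned to every record in the file.
    on_invalid : {"error", "drop"}
        Whether a record containing a non-canonical residue aborts the
        load or is dropped with a warning. Dropping silently would corrupt
        downstream uniqueness analysis, so it is never the default.
    """
    if on_invalid not in ("error", "drop"):
        raise ValueError(f"on_invalid must be 'error' or 'drop', got {on_invalid!r}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        accession, label = _split_fasta_header(entry.id)
        if accession in seen:
            raise ValueError(f"duplicate accession {accession!r} in {path}")
        seq = str(entry.seq).upper()
        try:
            rec = ProteinRecord(accession=accession, sequence=seq,
                                label=label, role=role)
        except ValueError:
            if on_invalid == "drop":
                warnings.warn(f"dropping record {accession!r}: invalid residue")
                continue
            raise
        seen.add(accession)
        records.append(rec)
    if not records and on_invalid == "error":
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA, one ``>accession label`` header each."""
    out = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.label)
        for r in records
    ]
    SeqIO.write(out, str(path), "fasta")


def load_evidence(
    path: str | Path,
    column: str | None = None,
    source_label: str = "",
) -> EvidenceSet:
    """Load a detected-peptide evidence list.

    Plain-text mode (default): one peptide sequence per line. CSV mode:
    pass ``column`` naming the peptide-sequence column. Sequences are
    uppercased and deduplicated. An empty input yields an empty set with a
    warning rather than an error, so that "nothing was detected" remains a
    representable state.
    """
    if column is not None:
        df = pd.read_csv(path)
        if column not in df.columns:
            raise ValueError(f"column {column!r} not found in {path}")
        raw = [str(v) for v in df[column].dropna()]
    else:
        raw = Path(path).read_text().split()
    peptides = frozenset(p.upper() for p in raw if p)
    if not peptides:
        warnings.warn(f"evidence file {path} contains no peptides")
    return EvidenceSet(peptides=peptides,
                       source_label=source_label or str(path))


SAMPLE_COLUMNS = ["sample_id", "donor_id", "condition", "total_motility",
                  "progressive_motility", "group_label"]


def load_samples(path: str | Path) -> list[SampleMeta]:
    """Load sample metadata from CSV with the standard columns.

    Required columns: sample_id, donor_id, condition, total_motility,
    progressive_motility, group_label. Empty motility fields mean missing.
    Duplicate (donor_id, condition) pairs are rejected because the paired
    design identifies a donor's measurement by that pair.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "donor_id": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    samples = []
    for row in df.itertuples(index=False):
        samples.append(SampleMeta(
            sample_id=str(row.sample_id),
            donor_id=str(row.donor_id),
            condition=(row.condition if isinstance(row.condition, str)
                       and row.condition else "none"),
            total_motility=(None if pd.isna(row.total_motility)
                            else float(row.total_motility)),
            progressive_motility=(None if pd.isna(row.progressive_motility)
                                  else float(row.progressive_motility)),
            group_label=(row.group_label if isinstance(row.group_label, str)
                         and row.group_label else "none"),
        ))
    pairs = [(s.donor_id, s.condition) for s in samples]
    if len(set(pairs)) != len(pairs):
        dupes = sorted({p for p in pairs if pairs.count(p) > 1})
        raise ValueError(f"{path}: duplicate (donor, condition) pairs {dupes}")
    return samples


def samples_to_frame(samples: Sequence[SampleMeta]) -> pd.DataFrame:
    """Tabulate SampleMeta records with the standard column order."""
    return pd.DataFrame(
        [(s.sample_id, s.donor_id, s.condition, s.total_motility,
          s.progressive_motility, s.group_label) for s in samples],
        columns=SAMPLE_COLUMNS,
    )


def write_samples(samples: Sequence[SampleMeta], path: str | Path) -> None:
    samples_to_frame(samples).to_csv(path, index=False)
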