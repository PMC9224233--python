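"""In-silico tryptic digestion and isoform-discriminating peptide selection.

Trypsin cleaves C-terminal to lysine (K) and arginine (R). Digesting every
member of a paralog family plus the background proteome yields a peptide →
parent-protein index; a peptide discriminates an isoform group when every
protein containing it belongs to that group. Isoforms whose tryptic peptide
sets cannot be told apart (e.g. gene duplicates with identical coding
peptides) are merged into a single quantification group, and a group is
quantifiable only when enough of its discriminating peptides were actually
observed in discovery data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io import EvidenceSet, ProteinRecord

#: Default peptide length bounds applied at selection time (typical MRM
#: practice: very short peptides are non-specific, very long ones fly badly).
DEFAULT_LENGTH_BOUNDS = (6, 30)

DEFAULT_MIN_PEPTIDES = 2


@dataclass(frozen=True)
class PeptideFragment:
    """One digestion product with its 1-based inclusive coordinates."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int


@dataclass
class IsoformGroup:
    """A set of family members quantified as one unit.

    Members are merged when no tryptic peptide (within the length filters)
    distinguishes them. ``discriminating_peptides`` occur only within the
    group across family plus background; ``selected_peptides`` additionally
    passed the evidence and length filters, in deterministic order
    (length, then lexicographic). The group is quantifiable when at least
    ``min_peptides`` selected peptides exist.
    """

    members: frozenset[str]
    label: str
    discriminating_peptides: set[str] = field(default_factory=set)
    selected_peptides: list[str] = field(default_factory=list)
    quantifiable: bool = False


def digest(sequence: str, max_missed_cleavages: int = 0,
           suppress_proline: bool = False) -> list[PeptideFragment]:
    """Tryptic digest: cut after every K and R.

    With ``max_missed_cleavages = 0`` the fragments tile the input exactly.
    ``suppress_proline`` disables cleavage when the following residue is
    proline (the classical KP/RP exception); off by default since the
    plain after-K/R rule is the one used for isoform discrimination here.

    Returns fragments ordered by start position, then by span.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")
    n = len(sequence)
    # boundaries[i] == True when a cut occurs after position i (0-based)
    cuts = [0]
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR" and not (suppress_proline and sequence[i + 1] == "P"):
            cuts.append(i + 1)
    cuts.append(n)
    fragments: list[PeptideFragment] = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + max_missed_cleavages, len(cuts))):
            start, end = cuts[a], cuts[b]
            fragments.append(PeptideFragment(
                sequence=sequence[start:end],
                start=start + 1,
                end=end,
                missed_cleavages=b - a - 1,
            ))
    fragments.sort(key=lambda f: (f.start, f.end))
    return fragments


def digest_peptide_set(sequence: str, max_missed_cleavages: int = 0,
                       suppress_proline: bool = False) -> set[str]:
    """The set of distinct peptide sequences produced by :func:`digest`."""
    return {f.sequence for f in
            digest(sequence, max_missed_cleavages, suppress_proline)}


def build_peptide_index(
    records: Sequence[ProteinRecord],
    max_missed_cleavages: int = 0,
    suppress_proline: bool = False,
) -> dict[str, set[str]]:
    """Map every digest peptide to the set of accessions containing it.

    The index must be built over family targets *and* background proteome
    for discrimination to be meaningful: a peptide shared with any
    background protein can never attribute signal to one isoform.
    """
    if not records:
        raise ValueError("no records to index")
    index: dict[str, set[str]] = {}
    for rec in records:
        for pep in digest_peptide_set(rec.sequence, max_missed_cleavages,
                                      suppress_proline):
            index.setdefault(pep, set()).add(rec.accession)
    return index


def _filtered(peptides: Iterable[str],
              length_bounds: tuple[int, int] | None) -> set[str]:
    if length_bounds is None:
        return set(peptides)
    lo, hi = length_bounds
    return {p for p in peptides if lo <= len(p) <= hi}


def merge_indistinguishable(
    family: Sequence[ProteinRecord],
    index: Mapping[str, set[str]],
    length_bounds: tuple[int, int] | None = None,
) -> list[IsoformGroup]:
    """Partition the family into groups of peptide-indistinguishable members.

    Two members merge when the symmetric difference of their digest peptide
    sets (restricted to ``length_bounds`` if given) is empty — i.e. no
    peptide, observable or not, could tell them apart. Merging is
    transitive. Group labels concatenate member labels with ``/`` in
    sorted order.
    """
    accs = [r.accession for r in family]
    labels = {r.accession: r.label for r in family}
    pepsets = {a: set() for a in accs}
    family_set = set(accs)
    for pep, parents in index.items():
        for a in parents & family_set:
            pepsets[a].add(pep)
    pepsets = {a: _filtered(s, length_bounds) for a, s in pepsets.items()}

    parent = {a: a for a in accs}

    def find(a: str) -> str:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, a in enumerate(accs):
        for b in accs[i + 1:]:
            if pepsets[a] == pepsets[b]:
                parent[find(b)] = find(a)

    groups: dict[str, set[str]] = {}
    for a in accs:
        groups.setdefault(find(a), set()).add(a)
    out = []
    for members in groups.values():
        label = "/".join(sorted(labels[m] for m in members))
        out.append(IsoformGroup(members=frozenset(members), label=label))
    out.sort(key=lambda g: g.label)
    return out


def select_discriminating(
    groups: Sequence[IsoformGroup],
    index: Mapping[str, set[str]],
    evidence: EvidenceSet,
    min_peptides: int = DEFAULT_MIN_PEPTIDES,
    length_bounds: tuple[int, int] | None = DEFAULT_LENGTH_BOUNDS,
) -> tuple[list[IsoformGroup], list[str]]:
    """Attach discriminating and selected peptides to each group.

    A peptide discriminates a group when its full parent set (over family
    plus background) is a non-empty subset of the group's members. It is
    *selected* when additionally present in the DDA evidence and within the
    length bounds. A group is quantifiable with >= ``min_peptides``
    selected peptides; others are returned unchanged and listed in the
    drop log, mirroring the rule that an isoform without at least two
    observable specific peptides cannot be reliably quantified.

    Returns (updated groups, drop-log lines).
    """
    if min_peptides < 1:
        raise ValueError("min_peptides must be >= 1")
    drop_log: list[str] = []
    out: list[IsoformGroup] = []
    for g in groups:
        disc = {pep for pep, parents in index.items()
                if parents and parents <= g.members}
        selected = sorted(
            _filtered(disc, length_bounds) & set(evidence.peptides),
            key=lambda p: (len(p), p),
        )
        quantifiable = len(selected) >= min_peptides
        out.append(IsoformGroup(
            members=g.members, label=g.label,
            discriminating_peptides=disc,
            selected_peptides=selected,
            quantifiable=quantifiable,
        ))
        if not quantifiable:
            reason = ("no discriminating peptide in evidence"
                      if not selected else
                      f"only {len(selected)} evidenced peptide(s), "
                      f"minimum is {min_peptides}")
            drop_log.append(f"{g.label}\t{reason}")
    return out, drop_log


def write_selection_report(groups: Sequence[IsoformGroup],
                           path: str | Path) -> None:
    """TSV report: one row per group with selection outcome."""
    lines = ["group_label\tmembers\tn_discriminating\tn_selected\t"
             "quantifiable\tselected_peptides"]
    for g in groups:
        lines.append("\t".join([
            g.label,
            ",".join(sorted(g.members)),
            str(len(g.discriminating_peptides)),
            str(len(g.selected_peptides)),
            str(g.quantifiable).lower(),
            ",".join(g.selected_peptides),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_drop_log(drop_log: Sequence[str], path: str | Path) -> None:
    Path(path).write_text(
        "group_label\treason\n" + "".join(line + "\n" for line in drop_log))
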