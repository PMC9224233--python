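"""MRM assay design: peptide/fragment masses, transitions, scheduling.

Monoisotopic arithmetic follows the standard electrospray conventions:
a peptide's neutral mass is the sum of its residue masses plus one water;
an observed m/z at charge z is (M + z * m_proton) / z. Cysteines carry the
fixed carbamidomethyl modification (+57.021464 Da) from iodoacetamide
alkylation, applied during sample preparation before digestion.

Fragment ions: b_k is the N-terminal piece of k residues (neutral mass =
sum of residue masses), y_k the C-terminal piece of k residues (sum of
residue masses + water). The complementarity identity
``neutral(b_k) + neutral(y_{n-k}) = neutral(precursor) + water`` holds
exactly under this arithmetic and is used as an internal consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Monoisotopic residue masses (Da), standard table at 6-decimal precision.
RESIDUE_MASS: dict[str, float] = {
    "G": 57.021464, "A": 71.037114, "S": 87.032028, "P": 97.052764,
    "V": 99.068414, "T": 101.047679, "C": 103.009185, "L": 113.084064,
    "I": 113.084064, "N": 114.042927, "D": 115.026943, "Q": 128.058578,
    "K": 128.094963, "E": 129.042593, "M": 131.040485, "H": 137.058912,
    "F": 147.068414, "R": 156.101111, "Y": 163.063329, "W": 186.079313,
}

PROTON_MASS = 1.00727646
WATER_MASS = 18.0105646
CARBAMIDOMETHYL = 57.021464

#: Fixed modifications applied to every occurrence of a residue.
DEFAULT_FIXED_MODS: dict[str, float] = {"C": CARBAMIDOMETHYL}

DEFAULT_MIN_PRODUCT_MZ = 300.0
DEFAULT_RT_WINDOW_MIN = 2.0
DEFAULT_CYCLE_TIME = 1.5
SCHEDULE_GRID_STEP_MIN = 0.01


def _residue_sum(fragment: str, fixed_mods: Mapping[str, float]) -> float:
    total = 0.0
    for aa in fragment:
        try:
            total += RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r}") from None
        total += fixed_mods.get(aa, 0.0)
    return total


def peptide_mass(sequence: str,
                 fixed_mods: Mapping[str, float] = DEFAULT_FIXED_MODS) -> float:
    """Neutral monoisotopic peptide mass in Da, fixed mods included."""
    if not sequence:
        raise ValueError("empty peptide")
    return _residue_sum(sequence, fixed_mods) + WATER_MASS


def mz(mass: float, charge: int) -> float:
    """m/z of a neutral mass at positive charge ``charge``."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (mass + charge * PROTON_MASS) / charge


def fragment_mz(sequence: str, ion_type: str, ordinal: int,
                fragment_charge: int = 1,
                fixed_mods: Mapping[str, float] = DEFAULT_FIXED_MODS) -> float:
    """m/z of the b- or y-ion of ``ordinal`` residues.

    ``ordinal`` must lie in [1, len(sequence) - 1]; a full-length "fragment"
    is the precursor, not a fragment.
    """
    n = len(sequence)
    if not 1 <= ordinal <= n - 1:
        raise ValueError(
            f"ordinal {ordinal} out of range [1, {n - 1}] for {sequence!r}")
    if ion_type == "b":
        neutral = _residue_sum(sequence[:ordinal], fixed_mods)
    elif ion_type == "y":
        neutral = _residue_sum(sequence[n - ordinal:], fixed_mods) + WATER_MASS
    else:
        raise ValueError(f"ion_type must be 'y' or 'b', got {ion_type!r}")
    return mz(neutral, fragment_charge)


@dataclass
class AssayPeptide:
    """A peptide slated for targeted acquisition."""

    sequence: str
    group_label: str = ""
    precursor_charge: int = 2
    retention_time: float | None = None  # minutes
    rt_window: float = DEFAULT_RT_WINDOW_MIN  # minutes, full width
    fixed_mods: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FIXED_MODS))

    def __post_init__(self) -> None:
        if self.precursor_charge < 1:
            raise ValueError("precursor_charge must be >= 1")
        if self.rt_window <= 0:
            raise ValueError("rt_window must be > 0")

    @property
    def monoisotopic_mass(self) -> float:
        return peptide_mass(self.sequence, self.fixed_mods)

    @property
    def precursor_mz(self) -> float:
        return mz(self.monoisotopic_mass, self.precursor_charge)


@dataclass(frozen=True)
class TransitionSpec:
    """One Q1/Q3 pair: the atomic monitored signal in MRM."""

    peptide: AssayPeptide
    ion_type: str
    ordinal: int
    fragment_charge: int
    q3_mz: float


def enumerate_transitions(
    peptide: AssayPeptide,
    n_transitions: int = 6,
    ion_types: Sequence[str] = ("y", "b"),
    fragment_charge: int = 1,
    min_product_mz: float = DEFAULT_MIN_PRODUCT_MZ,
) -> list[TransitionSpec]:
    """Pick a deterministic ranked transition list for one peptide.

    Vendors rank candidate transitions by observed intensity; absent
    spectral data, this uses a fixed proxy ranking: y ions before b ions,
    larger fragments first. Products below ``min_product_mz`` are excluded
    (the low-mass region is noise-prone). Returns at most ``n_transitions``
    and never more than the number of admissible fragments, so short
    peptides yield short lists. Identical inputs yield identical lists.
    """
    if n_transitions < 1:
        raise ValueError("n_transitions must be >= 1")
    n = len(peptide.sequence)
    candidates: list[TransitionSpec] = []
    for ion_type in ion_types:
        for ordinal in range(1, n):
            q3 = fragment_mz(peptide.sequence, ion_type, ordinal,
                             fragment_charge, peptide.fixed_mods)
            if q3 >= min_product_mz:
                candidates.append(TransitionSpec(
                    peptide=peptide, ion_type=ion_type, ordinal=ordinal,
                    fragment_charge=fragment_charge, q3_mz=q3))
    candidates.sort(key=lambda t: (t.ion_type != "y", -t.ordinal,
                                   t.fragment_charge))
    return candidates[:n_transitions]


@dataclass
class ScheduleReport:
    """Concurrency and dwell-time profile of a scheduled acquisition."""

    grid: np.ndarray  # minutes
    concurrency: np.ndarray  # transitions active at each grid point
    dwell: np.ndarray  # cycle_time / concurrency; NaN where idle
    violations: np.ndarray  # boolean mask: dwell below minimum
    cycle_time: float
    min_dwell: float | None

    @property
    def max_concurrency(self) -> int:
        return int(self.concurrency.max()) if self.concurrency.size else 0

    @property
    def n_violations(self) -> int:
        return int(self.violations.sum())


def schedule(
    transitions: Sequence[TransitionSpec],
    cycle_time: float = DEFAULT_CYCLE_TIME,
    min_dwell: float | None = None,
    grid_step: float = SCHEDULE_GRID_STEP_MIN,
) -> ScheduleReport:
    """Check scheduled-acquisition feasibility of a transition list.

    Each transition is acquired only within its peptide's retention-time
    window (full width ``rt_window`` centred on ``retention_time``). At
    each grid point, dwell time per transition is the cycle time divided
    by the number of concurrent transitions; points where it falls below
    ``min_dwell`` are flagged.
    """
    missing = sorted({t.peptide.sequence for t in transitions
                      if t.peptide.retention_time is None})
    if missing:
        raise ValueError(f"peptides without retention time: {missing}")
    if not transitions:
        raise ValueError("no transitions to schedule")
    starts = np.array([t.peptide.retention_time - t.peptide.rt_window / 2
                       for t in transitions])
    ends = np.array([t.peptide.retention_time + t.peptide.rt_window / 2
                     for t in transitions])
    lo = starts.min() - grid_step
    hi = ends.max() + grid_step
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    conc = ((grid[:, None] >= starts[None, :])
            & (grid[:, None] <= ends[None, :])).sum(axis=1)
    with np.errstate(divide="ignore"):
        dwell = np.where(conc > 0, cycle_time / np.maximum(conc, 1), np.nan)
    if min_dwell is None:
        violations = np.zeros_like(conc, dtype=bool)
    else:
        violations = (conc > 0) & (dwell < min_dwell)
    return ScheduleReport(grid=grid, concurrency=conc, dwell=dwell,
                          violations=violations, cycle_time=cycle_time,
                          min_dwell=min_dwell)


TRANSITION_LIST_COLUMNS = [
    "group_label", "peptide", "precursor_charge", "precursor_mz",
    "ion_type", "ordinal", "fragment_charge", "product_mz",
    "rt_min", "rt_window_min",
]


def transitions_to_frame(transitions: Sequence[TransitionSpec]) -> pd.DataFrame:
    """Vendor-neutral transition list as a DataFrame."""
    rows = []
    for t in transitions:
        p = t.peptide
        rows.append((p.group_label, p.sequence, p.precursor_charge,
                     round(p.precursor_mz, 6), t.ion_type, t.ordinal,
                     t.fragment_charge, round(t.q3_mz, 6),
                     p.retention_time, p.rt_window))
    return pd.DataFrame(rows, columns=TRANSITION_LIST_COLUMNS)


def write_transition_list(transitions: Sequence[TransitionSpec],
                          path: str | Path) -> None:
    transitions_to_frame(transitions).to_csv(path, index=False)
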