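"""From transition areas to normalized isoform abundances and fold changes.

Quantification model
--------------------
Per sample, transition areas are summed into a peptide area A. A protein
(isoform group) abundance on the natural-log scale is

    abundance = mean(ln A, target peptides) - mean(ln A, control peptides)

i.e. the log of the ratio of geometric means of target and loading-control
peptide areas. This makes the abundance invariant to any global
multiplicative rescaling of a sample (injection amount, instrument drift),
which is exactly what a loading control is for.

For a paired two-condition design, the per-donor fold change of a group is
exp(abundance_B - abundance_A): a positive ratio comparable across donors.
The study-level fold change is by default the arithmetic mean of the
per-donor ratios (a geometric-mean option exists).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SampleMeta
from .stats import PairedTestResult, paired_compare

#: Long-format area table columns (one row per transition measurement).
AREA_COLUMNS = ["sample_id", "peptide", "ion_type", "ordinal",
                "fragment_charge", "area"]


def integrate(times: Sequence[float], intensities: Sequence[float],
              window: tuple[float, float], baseline: str = "none") -> float:
    """Trapezoidal area under a chromatogram trace within a window.

    ``baseline="linear"`` first subtracts the chord joining the intensities
    at the two window-edge points (floored at zero), a simple stand-in for
    interactive baseline placement. ``"none"`` integrates the raw trace.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.ndim != 1 or t.shape != y.shape or t.size < 2:
        raise ValueError("times/intensities must be equal-length 1-D, >= 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(y < 0):
        raise ValueError("intensities must be non-negative")
    start, end = window
    if end <= start:
        raise ValueError("window end must exceed start")
    if end < t[0] or start > t[-1]:
        raise ValueError("integration window outside trace time span")
    mask = (t >= start) & (t <= end)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 trace points inside window")
    tw, yw = t[mask], y[mask]
    if baseline == "linear":
        chord = np.interp(tw, [tw[0], tw[-1]], [yw[0], yw[-1]])
        yw = np.maximum(yw - chord, 0.0)
    elif baseline != "none":
        raise ValueError(f"unknown baseline mode {baseline!r}")
    return float(np.trapezoid(yw, tw))


def integrate_chromatograms(chrom: pd.DataFrame,
                            windows: Mapping[str, tuple[float, float]],
                            baseline: str = "none") -> pd.DataFrame:
    """Integrate a long chromatogram table into a long area table.

    ``chrom`` columns: sample_id, peptide, ion_type, ordinal,
    fragment_charge, time_min, intensity. ``windows`` maps peptide
    sequence to its fixed integration window (minutes).
    """
    keys = ["sample_id", "peptide", "ion_type", "ordinal", "fragment_charge"]
    rows = []
    for key, grp in chrom.groupby(keys, sort=True):
        pep = key[1]
        if pep not in windows:
            raise ValueError(f"no integration window for peptide {pep!r}")
        grp = grp.sort_values("time_min")
        area = integrate(grp["time_min"].to_numpy(),
                         grp["intensity"].to_numpy(),
                         windows[pep], baseline=baseline)
        rows.append((*key, area))
    return pd.DataFrame(rows, columns=AREA_COLUMNS)


def sum_peptide(areas: Sequence[float]) -> tuple[float, float | None]:
    """Sum transition areas into one peptide area; ln after summing.

    Returns (area, ln_area); ln_area is None when the summed area is 0,
    which flags the peptide as missing in that sample rather than erroring.
    """
    if len(areas) == 0:
        raise ValueError("need at least one transition area")
    arr = np.asarray(areas, dtype=float)
    if np.any(arr < 0):
        raise ValueError("transition areas must be non-negative")
    total = float(arr.sum())
    return total, (math.log(total) if total > 0 else None)


def peptide_quants(areas: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long transition-area table to per-(sample, peptide) rows.

    Output columns: sample_id, peptide, area, ln_area (NaN when area 0).
    """
    missing = [c for c in ("sample_id", "peptide", "area")
               if c not in areas.columns]
    if missing:
        raise ValueError(f"area table missing columns {missing}")
    summed = (areas.groupby(["sample_id", "peptide"], sort=True)["area"]
              .sum().reset_index())
    with np.errstate(divide="ignore"):
        summed["ln_area"] = np.where(summed["area"] > 0,
                                     np.log(summed["area"].to_numpy()), np.nan)
    return summed


def protein_quants(
    pep_quants: pd.DataFrame,
    group_peptides: Mapping[str, Sequence[str]],
    control_peptides: Sequence[str],
    min_peptides: int = 2,
) -> pd.DataFrame:
    """Loading-control-normalized Ln abundance per (sample, isoform group).

    A group is quantified in a sample only when >= ``min_peptides`` of its
    peptides have positive area there and at least one control peptide
    does; otherwise the row is omitted (no imputation). Output columns:
    sample_id, group_label, abundance, n_peptides_used.
    """
    if min_peptides < 1:
        raise ValueError("min_peptides must be >= 1")
    if not control_peptides:
        raise ValueError("need at least one control peptide")
    ctrl = set(control_peptides)
    rows = []
    for sample_id, sub in pep_quants.groupby("sample_id", sort=True):
        present = sub.dropna(subset=["ln_area"])
        ln_by_pep = dict(zip(present["peptide"], present["ln_area"]))
        ctrl_ln = [ln_by_pep[p] for p in sorted(ctrl) if p in ln_by_pep]
        if not ctrl_ln:
            warnings.warn(f"sample {sample_id}: no control peptide with "
                          "positive area; sample unquantified")
            continue
        ctrl_mean = float(np.mean(ctrl_ln))
        for label, peps in group_peptides.items():
            target_ln = [ln_by_pep[p] for p in peps if p in ln_by_pep]
            if len(target_ln) < min_peptides:
                continue
            rows.append((sample_id, label,
                         float(np.mean(target_ln)) - ctrl_mean,
                         len(target_ln)))
    return pd.DataFrame(rows, columns=["sample_id", "group_label",
                                       "abundance", "n_peptides_used"])


@dataclass
class FoldChangeResult:
    """Paired between-condition fold change for one isoform group."""

    group_label: str
    fold_changes: dict[str, float]  # donor_id -> ratio B/A
    mean_fold_change: float
    n_pairs: int
    test: PairedTestResult | None  # None when < 3 complete pairs

    @property
    def p_value(self) -> float | None:
        return self.test.p_value if self.test else None


def fold_changes(
    quants: pd.DataFrame,
    samples: Sequence[SampleMeta],
    condition_a: str = "non_capacitated",
    condition_b: str = "capacitated",
    mean_mode: str = "arithmetic",
    alpha_normality: float = 0.05,
) -> list[FoldChangeResult]:
    """Per-group fold change B/A, paired by donor, with the paired test.

    Donors lacking either condition for a group are excluded with a
    warning. The dispatch between paired t-test and Wilcoxon signed-rank
    (decided by Shapiro-Wilk on the paired differences) is delegated to
    :func:`isomrm.stats.paired_compare` on the Ln abundances.
    """
    if mean_mode not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown mean_mode {mean_mode!r}")
    meta = {s.sample_id: s for s in samples}
    df = quants.copy()
    df["donor_id"] = df["sample_id"].map(
        lambda s: meta[s].donor_id if s in meta else None)
    df["condition"] = df["sample_id"].map(
        lambda s: meta[s].condition if s in meta else None)
    if df["donor_id"].isna().any():
        unknown = sorted(df.loc[df["donor_id"].isna(), "sample_id"].unique())
        raise ValueError(f"samples without metadata: {unknown}")

    results = []
    for label, sub in df.groupby("group_label", sort=True):
        a = sub[sub["condition"] == condition_a].set_index("donor_id")["abundance"]
        b = sub[sub["condition"] == condition_b].set_index("donor_id")["abundance"]
        donors = sorted(set(a.index) & set(b.index))
        unpaired = sorted(set(a.index) ^ set(b.index))
        if unpaired:
            warnings.warn(f"group {label}: donors {unpaired} lack one "
                          "condition and are excluded")
        per_donor = {d: math.exp(b[d] - a[d]) for d in donors}
        if not per_donor:
            warnings.warn(f"group {label}: no complete pairs")
            continue
        vals = np.array(list(per_donor.values()))
        mean_fc = (float(vals.mean()) if mean_mode == "arithmetic"
                   else float(np.exp(np.log(vals).mean())))
        test = None
        if len(donors) >= 3:
            test = paired_compare(b[donors].to_numpy(), a[donors].to_numpy(),
                                  alpha_normality=alpha_normality, label=label)
        results.append(FoldChangeResult(
            group_label=label, fold_changes=per_donor,
            mean_fold_change=mean_fc, n_pairs=len(donors), test=test))
    return results


def fold_changes_to_frame(results: Sequence[FoldChangeResult],
                          n_peptides: Mapping[str, int] | None = None
                          ) -> pd.DataFrame:
    """Summary table: group, n_peptides, mean fold change, test, p-value."""
    rows = []
    for r in results:
        rows.append((
            r.group_label,
            None if n_peptides is None else n_peptides.get(r.group_label),
            r.n_pairs,
            r.mean_fold_change,
            r.test.test_name if r.test else None,
            r.p_value,
        ))
    return pd.DataFrame(rows, columns=["group_label", "n_peptides", "n_pairs",
                                       "mean_fold_change", "test_name",
                                       "p_value"])
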