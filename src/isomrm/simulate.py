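"""Synthetic inputs with known ground truth for the whole pipeline.

Three layers are simulated:

* **Sequences** — a paralog family assembled from tryptic building blocks
  (each block ends in K or R, contains no internal K/R): blocks shared by
  every member produce non-discriminating peptides, private blocks produce
  ground-truth discriminating peptides, and an optional exact-duplicate
  member reproduces the situation where two gene products share every
  tryptic peptide and must be quantified as one group.

* **Areas** — transition-level integrated areas under a multiplicative
  (log-normal) error model. On the Ln scale, the area of transition t of
  peptide p in the sample of donor d under condition c is

      base + ln(fold_g) * 1[c = capacitated] + shift(sample)
           + u_d + pi_p + ln(f_t) + eps

  with a donor effect u_d ~ N(0, sigma_donor^2) shared across that donor's
  conditions (this is what makes the paired design informative), a fixed
  peptide response pi_p ~ N(0, sigma_peptide^2), deterministic decreasing
  transition fractions f_t, and residual noise eps ~ N(0, sigma_residual^2).
  The loading control always has fold 1 and no shift.

* **Chromatograms** (optional) — each transition rendered as a Gaussian
  peak whose continuous integral equals the requested area, plus baseline
  and additive noise, for exercising peak integration.

Everything is driven by a single integer seed; identical configuration and
seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ProteinRecord, SampleMeta
from .quantify import AREA_COLUMNS

#: Residues eligible for block interiors (no K/R: cleavage sites only at
#: block ends, so blocks are exactly the tryptic peptides).
_INTERIOR = "ACDEFGHILMNPQSTVWY"

CONTROL_GROUP = "CTRL"


@dataclass(frozen=True)
class ChromConfig:
    """Peak-shape parameters for rendered chromatograms (minutes/AU)."""

    rt_jitter_sd: float = 0.02
    peak_sigma_min: float = 0.05
    baseline_level: float = 0.0
    noise_sd: float = 0.0
    sampling_step_min: float = 0.005


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the area simulator.

    Defaults describe the reference paired design: 6 donors measured in
    both conditions, Ln-scale variance components sigma_donor = 0.2 (between
    donors), sigma_peptide = 0.3 (between peptide responses) and
    sigma_residual = 0.05 (measurement), and 5 transitions per peptide with
    fixed decreasing fractions.
    """

    seed: int = 0
    n_donors: int = 6
    sigma_donor: float = 0.2
    sigma_peptide: float = 0.3
    sigma_residual: float = 0.05
    base_level: float = 12.0
    n_transitions: int = 5
    chromatography: ChromConfig = field(default_factory=ChromConfig)


@dataclass
class GroundTruth:
    """Realized latent quantities of one simulation run."""

    true_fold_changes: dict[str, float]
    donor_effects: dict[str, float]
    peptide_offsets: dict[str, float]
    transition_fractions: dict[str, np.ndarray]
    config: SimConfig


def _random_block(rng: np.random.Generator, length_range=(7, 14)) -> str:
    n = int(rng.integers(length_range[0], length_range[1] + 1))
    body = "".join(rng.choice(list(_INTERIOR), size=n - 1))
    terminal = "K" if rng.random() < 0.5 else "R"
    return body + terminal


def _distinct_blocks(rng: np.random.Generator, count: int,
                     avoid: set[str]) -> list[str]:
    blocks: list[str] = []
    seen = set(avoid)
    while len(blocks) < count:
        b = _random_block(rng)
        if b not in seen:
            seen.add(b)
            blocks.append(b)
    return blocks


def generate_family(
    n_isoforms: int,
    n_shared_blocks: int = 4,
    n_unique_blocks: int = 2,
    include_indistinguishable_pair: bool = False,
    seed: int = 0,
) -> tuple[list[ProteinRecord], dict[str, set[str]]]:
    """Build a paralog family with controlled peptide structure.

    Each isoform concatenates the same shared blocks with its own private
    blocks, so its ground-truth discriminating peptides are exactly its
    private blocks. With ``include_indistinguishable_pair`` the last
    isoform is an exact sequence duplicate of its predecessor under a new
    accession, so those two can only be quantified as a merged group.

    Returns (records, annotation) where annotation maps each accession to
    its private-block peptide set (shared between the two members of the
    duplicated pair).
    """
    if n_isoforms < 1:
        raise ValueError("n_isoforms must be >= 1")
    rng = np.random.default_rng(seed)
    n_distinct = n_isoforms - 1 if include_indistinguishable_pair else n_isoforms
    if include_indistinguishable_pair and n_distinct < 1:
        raise ValueError("need >= 2 isoforms to include a duplicate pair")
    shared = _distinct_blocks(rng, n_shared_blocks, set())
    used = set(shared)
    records: list[ProteinRecord] = []
    annotation: dict[str, set[str]] = {}
    for i in range(n_distinct):
        unique = _distinct_blocks(rng, n_unique_blocks, used)
        used.update(unique)
        # interleave shared and private blocks
        blocks: list[str] = []
        for j in range(max(n_shared_blocks, n_unique_blocks)):
            if j < n_shared_blocks:
                blocks.append(shared[j])
            if j < n_unique_blocks:
                blocks.append(unique[j])
        acc = f"ISO{i + 1:02d}"
        records.append(ProteinRecord(accession=acc, sequence="".join(blocks),
                                     label=acc, role="family_target"))
        annotation[acc] = set(unique)
    if include_indistinguishable_pair:
        twin_of = records[-1]
        acc = f"ISO{n_isoforms:02d}"
        records.append(ProteinRecord(accession=acc,
                                     sequence=twin_of.sequence,
                                     label=acc, role="family_target"))
        annotation[acc] = set(annotation[twin_of.accession])
    return records, annotation


def generate_control_protein(
    accession: str = "CTRL",
    label: str = CONTROL_GROUP,
    n_peptides: int = 3,
    avoid: set[str] | None = None,
    seed: int = 1,
) -> tuple[ProteinRecord, list[str]]:
    """A loading-control protein whose peptides collide with nothing in
    ``avoid`` (pass the family's digest peptides)."""
    rng = np.random.default_rng(seed)
    blocks = _distinct_blocks(rng, n_peptides, set(avoid or ()))
    rec = ProteinRecord(accession=accession, sequence="".join(blocks),
                        label=label, role="control")
    return rec, blocks


def generate_capacitation_design(n_donors: int = 6) -> list[SampleMeta]:
    """Paired design: each donor measured non-capacitated and capacitated."""
    samples = []
    for d in range(1, n_donors + 1):
        donor = f"D{d:02d}"
        samples.append(SampleMeta(sample_id=f"{donor}_NC", donor_id=donor,
                                  condition="non_capacitated"))
        samples.append(SampleMeta(sample_id=f"{donor}_C", donor_id=donor,
                                  condition="capacitated"))
    return samples


def generate_motility_design(
    n_samples: int = 20,
    motility_range: tuple[float, float] = (20.0, 90.0),
    association: float = 0.0,
    group_sizes: tuple[int, int, int] | None = None,
    seed: int = 0,
) -> tuple[list[SampleMeta], dict[str, float]]:
    """One-sample-per-donor design with measured motilities.

    Total motility is uniform over ``motility_range``; progressive motility
    is a random fraction (0.6-0.9) of it. ``association`` is the Ln-scale
    abundance shift per 100 percentage points of total motility, centred on
    the range midpoint; 0 makes abundance independent of motility (the null
    of the correlation analysis). With ``group_sizes = (a, n, t)`` the a
    lowest-motility samples are labelled astheno-terato and the rest split
    into normo and terato, reproducing an unbalanced three-group contrast.

    Returns (samples, shifts) with shifts keyed by sample_id.
    """
    if n_samples < 4:
        raise ValueError("need n_samples >= 4")
    rng = np.random.default_rng(seed)
    lo, hi = motility_range
    total = rng.uniform(lo, hi, size=n_samples)
    progressive = total * rng.uniform(0.6, 0.9, size=n_samples)
    labels = ["none"] * n_samples
    if group_sizes is not None:
        a, n, t = group_sizes
        if a + n + t > n_samples:
            raise ValueError("group sizes exceed n_samples")
        # the low-motility tail defines the astheno group; normo/terato
        # split the high-motility remainder (samples beyond a+n+t stay
        # unlabelled, as in a cohort where only a subset fits a category)
        order = np.argsort(total)
        for idx in order[:a]:
            labels[idx] = "asthenoterato"
        rest = order[a:].copy()
        rng.shuffle(rest)
        for idx in rest[:n]:
            labels[idx] = "normo"
        for idx in rest[n:n + t]:
            labels[idx] = "terato"
    mid = (lo + hi) / 2
    samples = []
    shifts: dict[str, float] = {}
    for i in range(n_samples):
        sid = f"S{i + 1:02d}"
        samples.append(SampleMeta(
            sample_id=sid, donor_id=sid, condition="none",
            total_motility=float(total[i]),
            progressive_motility=float(progressive[i]),
            group_label=labels[i]))
        shifts[sid] = association * (float(total[i]) - mid) / 100.0
    return samples, shifts


def transition_fractions(n: int) -> np.ndarray:
    """Fixed decreasing fractions f_k proportional to n+1-k, summing to 1."""
    w = np.arange(n, 0, -1, dtype=float)
    return w / w.sum()


def simulate_areas(
    group_peptides: Mapping[str, Sequence[str]],
    control_peptides: Sequence[str],
    design: Sequence[SampleMeta],
    config: SimConfig = SimConfig(),
    true_fold_changes: Mapping[str, float] | None = None,
    sample_shifts: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a long-format transition-area table.

    ``true_fold_changes`` maps group labels to the capacitated /
    non-capacitated ratio (default 1 everywhere); the loading control is
    appended as its own group with fold pinned to 1. ``sample_shifts``
    adds a per-sample Ln offset to every target group (used to encode a
    motility association); the control is unshifted so normalization must
    not remove a real association.
    """
    folds = {g: 1.0 for g in group_peptides}
    if true_fold_changes:
        unknown = set(true_fold_changes) - set(group_peptides)
        if unknown:
            raise ValueError(f"fold changes for unknown groups {sorted(unknown)}")
        for g, f in true_fold_changes.items():
            if f <= 0:
                raise ValueError(f"fold change for {g} must be > 0")
            folds[g] = float(f)
    if any(f != 1.0 for f in folds.values()):
        conds = {s.condition for s in design}
        if "capacitated" not in conds or "non_capacitated" not in conds:
            warnings.warn("fold changes != 1 requested but the design has "
                          "no paired conditions; effects will be unobservable")

    all_groups = dict(group_peptides)
    all_groups[CONTROL_GROUP] = list(control_peptides)
    folds[CONTROL_GROUP] = 1.0

    rng = np.random.default_rng(config.seed)
    donors = sorted({s.donor_id for s in design})
    donor_eff = {d: float(rng.normal(0.0, config.sigma_donor))
                 for d in donors}
    peptides = [p for peps in all_groups.values() for p in peps]
    if len(set(peptides)) != len(peptides):
        raise ValueError("a peptide appears in more than one group")
    pep_off = {p: float(rng.normal(0.0, config.sigma_peptide))
               for p in peptides}
    fracs = transition_fractions(config.n_transitions)
    frac_by_pep = {p: fracs for p in peptides}

    rows = []
    for s in design:
        shift = (sample_shifts or {}).get(s.sample_id, 0.0)
        for g, peps in all_groups.items():
            g_shift = 0.0 if g == CONTROL_GROUP else shift
            ln_fold = (math.log(folds[g])
                       if s.condition == "capacitated" else 0.0)
            for p in peps:
                eps = rng.normal(0.0, config.sigma_residual,
                                 size=config.n_transitions)
                for k in range(config.n_transitions):
                    ln_area = (config.base_level + ln_fold + g_shift
                               + donor_eff[s.donor_id] + pep_off[p]
                               + math.log(fracs[k]) + eps[k])
                    rows.append((s.sample_id, p, "y", k + 2, 1,
                                 math.exp(ln_area)))
    areas = pd.DataFrame(rows, columns=AREA_COLUMNS)
    truth = GroundTruth(true_fold_changes=dict(folds),
                        donor_effects=donor_eff,
                        peptide_offsets=pep_off,
                        transition_fractions=frac_by_pep,
                        config=config)
    return areas, truth


def render_chromatograms(
    areas: pd.DataFrame,
    rt_by_peptide: Mapping[str, float],
    chrom: ChromConfig = ChromConfig(),
    seed: int = 0,
) -> pd.DataFrame:
    """Render each transition area as a sampled Gaussian peak.

    Amplitude is chosen so the continuous integral equals the requested
    area; the peak centre is the peptide's nominal retention time plus a
    per-(sample, peptide) jitter shared by co-eluting transitions. Sampling
    extends 4 peak-sigmas either side of the centre. A sampling step at or
    above the peak sigma would undersample the peak and is rejected.
    """
    if chrom.sampling_step_min >= chrom.peak_sigma_min:
        raise ValueError("sampling step must be finer than the peak sigma")
    rng = np.random.default_rng(seed)
    jitter: dict[tuple[str, str], float] = {}
    rows = []
    sigma = chrom.peak_sigma_min
    for r in areas.itertuples(index=False):
        if r.area <= 0:
            raise ValueError("areas must be positive to render peaks")
        key = (r.sample_id, r.peptide)
        if key not in jitter:
            jitter[key] = float(rng.normal(0.0, chrom.rt_jitter_sd))
        center = rt_by_peptide[r.peptide] + jitter[key]
        t = np.arange(center - 4 * sigma, center + 4 * sigma,
                      chrom.sampling_step_min)
        amp = r.area / (sigma * math.sqrt(2 * math.pi))
        y = amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)
        y = y + chrom.baseline_level
        if chrom.noise_sd > 0:
            y = y + rng.normal(0.0, chrom.noise_sd, size=t.size)
        y = np.maximum(y, 0.0)
        for ti, yi in zip(t, y):
            rows.append((r.sample_id, r.peptide, r.ion_type, r.ordinal,
                         r.fragment_charge, float(ti), float(yi)))
    return pd.DataFrame(rows, columns=["sample_id", "peptide", "ion_type",
                                       "ordinal", "fragment_charge",
                                       "time_min", "intensity"])
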