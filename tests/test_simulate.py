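"""Synthetic-data generator: construction, determinism, noiseless limits."""

import numpy as np
import pandas as pd
import pytest

from isomrm.digest import build_peptide_index, digest_peptide_set, \
    merge_indistinguishable
from isomrm.quantify import integrate
from isomrm.simulate import (ChromConfig, SimConfig,
                             generate_capacitation_design, generate_family,
                             generate_motility_design, render_chromatograms,
                             simulate_areas, transition_fractions)


class TestGenerateFamily:
    def test_unique_blocks_are_the_discriminating_peptides(self):
        records, annotation = generate_family(2, n_shared_blocks=1,
                                              n_unique_blocks=1, seed=5)
        for rec in records:
            own = annotation[rec.accession]
            assert len(own) == 1
            assert own <= digest_peptide_set(rec.sequence)
        assert annotation["ISO01"].isdisjoint(annotation["ISO02"])

    def test_indistinguishable_pair_merges(self):
        records, _ = generate_family(4, include_indistinguishable_pair=True,
                                     seed=7)
        assert records[-1].sequence == records[-2].sequence
        index = build_peptide_index(records)
        groups = merge_indistinguishable(records, index)
        assert len(groups) == 3

    def test_seed_determinism(self):
        a, _ = generate_family(5, seed=11)
        b, _ = generate_family(5, seed=11)
        assert [(r.accession, r.sequence) for r in a] == \
               [(r.accession, r.sequence) for r in b]

    def test_blocks_are_tryptic(self):
        records, annotation = generate_family(3, seed=2)
        for peps in annotation.values():
            for pep in peps:
                assert pep[-1] in "KR"
                assert not any(c in "KR" for c in pep[:-1])


def _tiny_setup(**cfg_kwargs):
    groups = {"G1": ["AAAGGGK", "CCCDDDK"]}
    control = ["EEEFFFK"]
    design = generate_capacitation_design(n_donors=4)
    cfg = SimConfig(**cfg_kwargs)
    return groups, control, design, cfg


class TestSimulateAreas:
    def test_noiseless_null_gives_exact_unit_folds(self):
        groups, control, design, cfg = _tiny_setup(
            seed=1, n_donors=4, sigma_donor=0.0, sigma_peptide=0.0,
            sigma_residual=0.0)
        areas, _ = simulate_areas(groups, control, design, cfg)
        pivot = areas.groupby("sample_id")["area"].sum()
        assert pivot.nunique() == 1  # all samples identical

    def test_noiseless_fold_two_exact(self):
        groups, control, design, cfg = _tiny_setup(
            seed=1, n_donors=4, sigma_donor=0.0, sigma_peptide=0.0,
            sigma_residual=0.0)
        areas, _ = simulate_areas(groups, control, design, cfg,
                                  true_fold_changes={"G1": 2.0})
        by = areas[areas["peptide"] == "AAAGGGK"].groupby(
            "sample_id")["area"].sum()
        assert by["D01_C"] / by["D01_NC"] == pytest.approx(2.0, abs=1e-12)

    def test_control_unaffected_by_fold(self):
        groups, control, design, cfg = _tiny_setup(
            seed=1, n_donors=4, sigma_donor=0.0, sigma_peptide=0.0,
            sigma_residual=0.0)
        areas, _ = simulate_areas(groups, control, design, cfg,
                                  true_fold_changes={"G1": 3.0})
        ctrl = areas[areas["peptide"] == "EEEFFFK"].groupby(
            "sample_id")["area"].sum()
        assert ctrl.nunique() == 1

    def test_seed_determinism_byte_identical(self):
        groups, control, design, cfg = _tiny_setup(seed=42, n_donors=4)
        a1, _ = simulate_areas(groups, control, design, cfg)
        a2, _ = simulate_areas(groups, control, design, cfg)
        assert a1.to_csv(index=False) == a2.to_csv(index=False)

    def test_unknown_group_fold_rejected(self):
        groups, control, design, cfg = _tiny_setup(seed=0, n_donors=4)
        with pytest.raises(ValueError):
            simulate_areas(groups, control, design, cfg,
                           true_fold_changes={"NOPE": 2.0})

    def test_unpaired_design_with_fold_warns(self):
        groups, control, _, cfg = _tiny_setup(seed=0, n_donors=4)
        design, _ = generate_motility_design(n_samples=4, seed=0)
        with pytest.warns(UserWarning, match="paired"):
            simulate_areas(groups, control, design, cfg,
                           true_fold_changes={"G1": 2.0})

    def test_transition_fractions_decreasing_and_normalized(self):
        f = transition_fractions(5)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(f) < 0)

    def test_mean_fold_centred_on_truth_under_noise(self):
        # residual-only noise, null fold: replicate means scatter around 1
        groups = {"G1": ["AAAGGGK", "CCCDDDK"]}
        control = ["EEEFFFK"]
        design = generate_capacitation_design(n_donors=6)
        means = []
        for i in range(100):
            cfg = SimConfig(seed=1000 + i, n_donors=6, sigma_donor=0.0,
                            sigma_peptide=0.0, sigma_residual=0.1)
            areas, _ = simulate_areas(groups, control, design, cfg)
            pep = areas.groupby(["sample_id", "peptide"])["area"].sum()
            folds = []
            for d in range(1, 7):
                nc = pep[f"D{d:02d}_NC"]
                c = pep[f"D{d:02d}_C"]
                ab_nc = np.log(nc[["AAAGGGK", "CCCDDDK"]]).mean() \
                    - np.log(nc["EEEFFFK"])
                ab_c = np.log(c[["AAAGGGK", "CCCDDDK"]]).mean() \
                    - np.log(c["EEEFFFK"])
                folds.append(np.exp(ab_c - ab_nc))
            means.append(np.mean(folds))
        assert np.mean(means) == pytest.approx(1.0, abs=0.02)


class TestMotilityDesign:
    def test_group_sizes_and_low_motility_labelling(self):
        samples, _ = generate_motility_design(20, group_sizes=(3, 7, 3),
                                              seed=3)
        labels = [s.group_label for s in samples]
        assert labels.count("asthenoterato") == 3
        assert labels.count("normo") == 7
        assert labels.count("terato") == 3
        astheno = [s.total_motility for s in samples
                   if s.group_label == "asthenoterato"]
        others = [s.total_motility for s in samples
                  if s.group_label != "asthenoterato"]
        assert max(astheno) <= min(others)

    def test_no_association_means_zero_shifts(self):
        _, shifts = generate_motility_design(10, association=0.0, seed=1)
        assert all(v == 0.0 for v in shifts.values())

    def test_association_shifts_track_motility(self):
        samples, shifts = generate_motility_design(10, association=1.0,
                                                   seed=1)
        for s in samples:
            assert shifts[s.sample_id] == pytest.approx(
                (s.total_motility - 55.0) / 100.0)

    def test_minimum_samples(self):
        with pytest.raises(ValueError):
            generate_motility_design(3)


class TestRenderChromatograms:
    def _areas(self):
        return pd.DataFrame(
            [("s1", "AAAGGGK", "y", 2, 1, 120.0),
             ("s1", "AAAGGGK", "y", 3, 1, 60.0)],
            columns=["sample_id", "peptide", "ion_type", "ordinal",
                     "fragment_charge", "area"])

    def test_noiseless_peak_reintegrates_to_requested_area(self):
        chrom = ChromConfig(rt_jitter_sd=0.0, noise_sd=0.0,
                            baseline_level=0.0)
        traces = render_chromatograms(self._areas(), {"AAAGGGK": 10.0},
                                      chrom, seed=0)
        first = traces[traces["ordinal"] == 2]
        area = integrate(first["time_min"].to_numpy(),
                         first["intensity"].to_numpy(),
                         (first["time_min"].min(), first["time_min"].max()))
        assert area == pytest.approx(120.0, rel=0.01)

    def test_doubling_area_doubles_integral(self):
        chrom = ChromConfig(rt_jitter_sd=0.0, noise_sd=0.0)
        base = self._areas()
        doubled = base.assign(area=base["area"] * 2)
        t1 = render_chromatograms(base, {"AAAGGGK": 10.0}, chrom, seed=0)
        t2 = render_chromatograms(doubled, {"AAAGGGK": 10.0}, chrom, seed=0)
        assert np.allclose(t2["intensity"], 2 * t1["intensity"])

    def test_seed_determinism(self):
        chrom = ChromConfig(noise_sd=5.0)
        t1 = render_chromatograms(self._areas(), {"AAAGGGK": 10.0}, chrom, 9)
        t2 = render_chromatograms(self._areas(), {"AAAGGGK": 10.0}, chrom, 9)
        assert t1.to_csv(index=False) == t2.to_csv(index=False)

    def test_undersampling_rejected(self):
        chrom = ChromConfig(peak_sigma_min=0.01, sampling_step_min=0.02)
        with pytest.raises(ValueError, match="sampling step"):
            render_chromatograms(self._areas(), {"AAAGGGK": 10.0}, chrom, 0)
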