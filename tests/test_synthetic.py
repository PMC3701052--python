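"""Synthetic cohort generator: reproducibility, programmed effects, ground
truth bookkeeping."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import cytoscreen as cs
from cytoscreen.lattice import Phenotype, POS, NEG, NEUTRAL


def _mean_truth_frequency(samples, metadata, truth, phenotype, group):
    ids = metadata.loc[metadata["group"] == group, "sample_id"]
    return float(np.mean([truth.truth_frequency(s, phenotype) for s in ids]))


class TestReproducibility:
    def test_same_spec_same_seed_identical(self):
        spec = cs.CohortSpec(n_donors=2, n_replicates=2,
                             n_events_per_sample=500, seed=5)
        s1, m1, t1 = cs.generate_cohort(spec)
        s2, m2, t2 = cs.generate_cohort(spec)
        assert [e.sample_id for e in s1] == [e.sample_id for e in s2]
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.values, b.values)
        pd.testing.assert_frame_equal(m1, m2)
        for sid in t1.events:
            pd.testing.assert_frame_equal(t1.events[sid], t2.events[sid])

    def test_different_seed_differs(self):
        spec = cs.CohortSpec(n_donors=1, n_replicates=1,
                             n_events_per_sample=500, seed=5)
        s1, *_ = cs.generate_cohort(spec)
        s2, *_ = cs.generate_cohort(dataclasses.replace(spec, seed=6))
        assert not np.array_equal(s1[0].values, s2[0].values)


class TestProgrammedEffects:
    def test_null_platform_effects_give_unit_ratio(self):
        spec = cs.CohortSpec(n_donors=8, n_replicates=1,
                             n_events_per_sample=12_000,
                             platform_effects={}, seed=13)
        samples, meta, truth = cs.generate_cohort(spec)
        panel = spec.panel
        for marker in ("IL10", "IFNg", "CD25"):
            ph = Phenotype.root(panel).with_state(marker, POS)
            fa = _mean_truth_frequency(samples, meta, truth, ph, "CFP")
            fb = _mean_truth_frequency(samples, meta, truth, ph, "LFP")
            assert fa / fb == pytest.approx(1.0, abs=0.12)

    def test_il10_effect_ratio_recovered(self):
        # programmed: group A (CFP) reads IL-10+ 44% lower, ratio A/B = 0.56
        spec = cs.CohortSpec(n_donors=12, n_replicates=1,
                             n_events_per_sample=20_000, seed=17)
        samples, meta, truth = cs.generate_cohort(spec)
        ph = Phenotype.root(spec.panel).with_state("IL10", POS)
        fa = _mean_truth_frequency(samples, meta, truth, ph, "CFP")
        fb = _mean_truth_frequency(samples, meta, truth, ph, "LFP")
        assert fa / fb == pytest.approx(0.56, abs=0.05)

    def test_overfull_frequencies_rejected_with_sample_name(self):
        spec_kwargs = dict(
            n_donors=1, n_replicates=1, n_events_per_sample=100,
            populations=(
                cs.PopulationSpec("big", {"CD4": True, "CD8": False},
                                  frequency=0.9, donor_sd=0.0,
                                  replicate_cv=0.0),
            ),
            platform_effects={"CD4": 1.5},
            seed=1,
        )
        with pytest.raises(ValueError, match="D01_LFP_r1"):
            cs.generate_cohort(cs.CohortSpec(**spec_kwargs))


@pytest.fixture(scope="module")
def tiny():
    spec = cs.CohortSpec(n_donors=2, n_replicates=1,
                         n_events_per_sample=4000, seed=23)
    return spec, *cs.generate_cohort(spec)


class TestGroundTruth:
    def test_root_phenotype_frequency_is_one(self, tiny):
        spec, samples, meta, truth = tiny
        sid = samples[0].sample_id
        assert truth.truth_frequency(sid, Phenotype.root(spec.panel)) == 1.0

    def test_complement_pair_sums_to_one(self, tiny):
        spec, samples, meta, truth = tiny
        sid = samples[0].sample_id
        root = Phenotype.root(spec.panel)
        for marker in spec.panel:
            pos = truth.truth_frequency(sid, root.with_state(marker, POS))
            neg = truth.truth_frequency(sid, root.with_state(marker, NEG))
            assert pos + neg == 1.0

    def test_population_pattern_matches_label_recount(self, tiny):
        # cd4_t is defined by CD4+CD8-; background fixes both negative, so
        # the phenotype count equals the label count exactly
        spec, samples, meta, truth = tiny
        ph = Phenotype.from_code("CD4+CD8-", spec.panel)
        for em in samples:
            assert truth.truth_frequency(em.sample_id, ph) == \
                truth.population_frequency(em.sample_id, "cd4_t")

    def test_unknown_marker_rejected(self, tiny):
        spec, samples, meta, truth = tiny
        ph = Phenotype(("XX",), (POS,))
        with pytest.raises(KeyError, match="XX"):
            truth.truth_frequency(samples[0].sample_id, ph)

    def test_summary_counts_consistent(self, tiny):
        spec, samples, meta, truth = tiny
        sid = samples[0].sample_id
        summary = truth.summary()[sid]
        assert summary["denominator"] == truth.denominator(sid)
        assert sum(summary["population_counts"].values()) == \
            summary["denominator"]


class TestSpecValidation:
    def test_bad_event_count(self):
        with pytest.raises(ValueError, match="n_events"):
            cs.CohortSpec(n_events_per_sample=0)

    def test_bad_effect_ratio(self):
        with pytest.raises(ValueError, match="> 0"):
            cs.CohortSpec(platform_effects={"IL10": -1.0})

    def test_unknown_population_marker(self):
        with pytest.raises(ValueError, match="unknown marker"):
            cs.CohortSpec(populations=(
                cs.PopulationSpec("p", {"NOPE": True}, 0.1),
            ))

    def test_frequencies_must_not_exceed_one(self):
        with pytest.raises(ValueError, match="sum"):
            cs.CohortSpec(populations=(
                cs.PopulationSpec("p1", {"CD4": True}, 0.7),
                cs.PopulationSpec("p2", {"CD8": True}, 0.6),
            ))


class TestCohortOutput:
    def test_write_cohort_artifacts(self, tmp_path):
        spec = cs.CohortSpec(n_donors=1, n_replicates=1,
                             n_events_per_sample=200, seed=2)
        samples, meta, truth = cs.generate_cohort(spec)
        cs.write_cohort(samples, meta, truth, tmp_path, provenance="t")
        fcs_files = sorted(tmp_path.glob("*.fcs"))
        assert len(fcs_files) == len(samples)
        back = cs.read_events(fcs_files[0])
        orig = next(s for s in samples if s.sample_id == back.sample_id)
        np.testing.assert_allclose(back.values, orig.values, rtol=1e-4,
                                   atol=1e-4)
        assert (tmp_path / "metadata.csv").exists()
        assert (tmp_path / "truth.json").exists()

    def test_replication_spec_drops_named_effects(self):
        spec = cs.CohortSpec()
        rep = cs.replication_spec(spec, n_donors=6, drop_effects=("IFNg",))
        assert rep.platform_effects["IFNg"] == 1.0
        assert rep.platform_effects["IL10"] == spec.platform_effects["IL10"]
        assert rep.n_donors == 6
        assert rep.seed != spec.seed
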