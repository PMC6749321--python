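"""Synthetic study generator: determinism, truth structure, recovery."""

import statistics

import pytest

from aromaprofiler.errors import ValidationError
from aromaprofiler.kovats import compute_ki, identify_peaks, rt_for_ki
from aromaprofiler.library import AgeClass, ChemicalFamily, Variety
from aromaprofiler.semiquant import replicate_rsd, semi_quantify
from aromaprofiler.odor_activity import screen_impact_odorants
from aromaprofiler.simulate import (
    build_truth,
    default_design,
    generate_ladder,
    generate_sample,
    generate_study,
)


class TestDesign:
    def test_default_is_22_wines(self):
        design = default_design()
        assert len(design.wines) == 22
        assert {m.variety for m in design.wines} == set(Variety)

    def test_each_variety_has_young_and_old(self):
        design = default_design()
        for variety in Variety:
            classes = {
                m.age_class for m in design.wines if m.variety == variety
            }
            assert classes == {AgeClass.YOUNG, AgeClass.OLD}

    def test_tinta_negra_covers_all_types(self):
        design = default_design()
        types = {m.wine_type for m in design.wines
                 if m.variety is Variety.TINTA_NEGRA}
        assert len(types) == 4


class TestLadderGeneration:
    def test_anchor_identity(self, ladder):
        anchors = dict(ladder.anchors)
        assert compute_ki(ladder, anchors[15]) == pytest.approx(1500)

    def test_extended_range_covers_library(self, ladder, library):
        max_ki = max(r.ki_calc_published for r in library)
        assert 100 * ladder.anchors[-1][0] >= max_ki

    def test_same_seed_identical(self, library):
        assert generate_ladder(library, seed=3) == generate_ladder(library, seed=3)

    def test_infeasible_span_is_error(self, library):
        with pytest.raises(ValidationError):
            generate_ladder(library, rt_span=(10.0, 20.0))


class TestTruthTable:
    def test_family_direction_signs(self, library):
        truth = build_truth(default_design(), library)
        for rec in library:
            sign = truth.aging_sign[rec.compound_id]
            if rec.family in (ChemicalFamily.FURANIC, ChemicalFamily.LACTONE,
                              ChemicalFamily.VOLATILE_PHENOL,
                              ChemicalFamily.ACETAL):
                assert sign == 1
            elif rec.family in (ChemicalFamily.TERPENIC,
                                ChemicalFamily.NORISOPRENOID,
                                ChemicalFamily.ESTER,
                                ChemicalFamily.HIGHER_ALCOHOL,
                                ChemicalFamily.SULPHUR):
                assert sign == -1

    def test_furanic_totals_rise_with_age(self, library):
        design = default_design()
        truth = build_truth(design, library)
        furanics = [r.compound_id for r in library
                    if r.family is ChemicalFamily.FURANIC]

        def total(age_class):
            wines = [m for m in design.wines if m.age_class == age_class]
            return sum(
                truth.conc(m.sample_id, cid) for m in wines for cid in furanics
            ) / len(wines)

        assert total(AgeClass.OLD) > total(AgeClass.YOUNG)

    def test_terpenic_totals_fall_with_age(self, library):
        design = default_design()
        truth = build_truth(design, library)
        terpenics = [r.compound_id for r in library
                     if r.family is ChemicalFamily.TERPENIC]

        def total(age_class):
            wines = [m for m in design.wines if m.age_class == age_class]
            return sum(
                truth.conc(m.sample_id, cid) for m in wines for cid in terpenics
            ) / len(wines)

        assert total(AgeClass.OLD) < total(AgeClass.YOUNG)

    def test_ethyl_pyruvate_elevated_in_verdelho(self, library):
        design = default_design()
        truth = build_truth(design, library)
        verdelho = [
            truth.conc(m.sample_id, "ethyl_pyruvate")
            for m in design.wines if m.variety is Variety.VERDELHO
        ]
        others = [
            truth.conc(m.sample_id, "ethyl_pyruvate")
            for m in design.wines if m.variety is not Variety.VERDELHO
        ]
        assert statistics.fmean(verdelho) == pytest.approx(3.54)
        assert statistics.fmean(others) == pytest.approx(1.49)

    def test_concentrations_positive(self, library):
        truth = build_truth(default_design(), library)
        assert all(c > 0 for c in truth.concentrations.values())


class TestGenerateStudy:
    def test_default_yields_66_peak_tables(self, noiseless_study):
        tables, _, _ = noiseless_study
        assert len(tables) == 66

    def test_same_seed_identical_outputs(self, library):
        design = default_design(seed=5)
        t1, _, _ = generate_study(design, library=library, noise_cv=0.05)
        t2, _, _ = generate_study(design, library=library, noise_cv=0.05)
        for a, b in zip(t1, t2):
            assert a.peaks == b.peaks
            assert a.is_peak == b.is_peak

    def test_different_seed_differs(self, library):
        t1, _, _ = generate_study(default_design(seed=5), library=library)
        t2, _, _ = generate_study(default_design(seed=6), library=library)
        assert t1[0].peaks != t2[0].peaks


class TestEndToEndRecovery:
    def test_noiseless_recovery_is_exact(self, library, noiseless_study):
        """Zero noise, no decoys: identification has precision = recall = 1
        and concentrations round-trip to floating-point accuracy."""
        tables, truth, ladder = noiseless_study
        for table in tables:
            idents = identify_peaks(table, ladder, library)
            accepted = {i.compound_id for i in idents if i.accepted}
            assert accepted == {r.compound_id for r in library}  # recall & precision
            quant = semi_quantify(table, idents)
            for cid, conc in quant.entries.items():
                assert conc == pytest.approx(
                    truth.conc(table.meta.sample_id, cid), rel=1e-12
                )

    def test_noiseless_screen_matches_truth_exceedance(
        self, library, noiseless_study
    ):
        tables, truth, ladder = noiseless_study
        for table in tables[:6]:
            quant = semi_quantify(
                table, identify_peaks(table, ladder, library)
            )
            screened = {
                r.compound_id for r in screen_impact_odorants(quant, library)
                if r.is_impact
            }
            expected = {
                r.compound_id for r in library
                if r.odor_threshold_ug_per_L is not None
                and truth.conc(table.meta.sample_id, r.compound_id)
                > r.odor_threshold_ug_per_L
            }
            assert screened == expected

    def test_decoys_cause_no_false_identifications(self, library, ladder):
        design = default_design(seed=13)
        truth = build_truth(design, library, noise_cv=0.0)
        meta = design.wines[0]
        table = generate_sample(
            meta, truth, ladder, seed=13, library=library, n_decoys=25
        )
        assert len(table.peaks) == 82 + 25
        idents = identify_peaks(table, ladder, library)
        accepted = [i for i in idents if i.accepted]
        assert len(accepted) == 82
        # every accepted peak is a true peak (resemblance >= 80)
        assert all(i.resemblance_pct >= 80 for i in accepted)

    def test_rsd_calibration_band(self, library, ladder):
        """Median recovered RSD within [0.7c, 1.3c] of the generating CV."""
        design = default_design(seed=29, replicates=3)
        tables, truth, _ = generate_study(
            design, library=library, noise_cv=0.08
        )
        wine = design.wines[3].sample_id
        quants = [
            semi_quantify(t, identify_peaks(t, ladder, library))
            for t in tables if t.meta.sample_id.startswith(wine + "_rep")
        ]
        rsds = [v for v in replicate_rsd(quants).values() if v is not None]
        median = statistics.median(rsds)
        assert 0.7 * 8.0 <= median <= 1.3 * 8.0
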