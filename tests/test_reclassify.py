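"""Residual-WT binning, ACMG splice-assay criteria, cohort summaries."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from minisplice.events import AberrantTranscript, SpliceEvent
from minisplice.intake import VariantRecord
from minisplice.model import classify_variant_site
from minisplice.reclassify import (AssayError, QuantifiedAssay,
                                   assign_criteria, baseline_adjust,
                                   bin_residual, parse_identity_text,
                                   summarize_cohort)


def _assay(wt, vtype="NCSS", prior="VUS", scores=(0.5, 0, 0, 0),
           aberrant=(), construct="WT-3", c="c.643+5G>A"):
    var = VariantRecord(c_notation=c, variant_type=vtype, acmg_prior=prior,
                        scores=scores, positions=(1, 0, 0, 0),
                        construct=construct)
    return QuantifiedAssay(variant=var, wt_fraction=wt,
                           aberrant=tuple(aberrant), construct=construct,
                           aberrant_total_reported=100.0 - wt)


# ----------------------------------------------------------------------
# binning
# ----------------------------------------------------------------------

@pytest.mark.parametrize("wt,expected", [
    (0, "none"), (0.5, "sub5"), (4.99, "sub5"), (5, "low"), (7, "low"),
    (19.99, "low"), (20, "high"), (100, "high"),
])
def test_bin_residual(wt, expected):
    assert bin_residual(wt) == expected


@pytest.mark.parametrize("wt", [-1, 101])
def test_bin_residual_range(wt):
    with pytest.raises(AssayError):
        bin_residual(wt)


@given(wt=st.floats(0, 100, allow_nan=False))
@settings(max_examples=300, derandomize=True)
def test_bins_partition_the_range(wt):
    assert bin_residual(wt) in ("none", "sub5", "low", "high")


# ----------------------------------------------------------------------
# criteria
# ----------------------------------------------------------------------

def test_zero_residual_is_pvs1_very_strong():
    a = assign_criteria(_assay(0.0, c="c.999-3C>G"), "NCSS")
    assert a.has("PVS1", "very_strong")
    assert a.final_class == "P"


def test_sub5_residual_is_pvs1_strong():
    a = assign_criteria(_assay(3.0), "NCSS")
    assert a.has("PVS1", "strong") and not a.has("PVS1", "very_strong")
    assert a.final_class == "LP"


def test_splice_silent_ncss_is_bp7_strong():
    a = assign_criteria(_assay(100.0, c="c.353+4A>T"), "NCSS")
    assert a.has("BP7", "strong")
    assert a.final_class == "B"


def test_splice_silent_missense_keeps_class():
    a = assign_criteria(_assay(100.0, vtype="Missense", c="c.425A>T",
                               scores=(0.15, 0, 0, 0)), "exonic")
    assert not a.criteria
    assert a.final_class == "VUS"


def test_partial_effect_keeps_class():
    a = assign_criteria(_assay(40.0), "NCSS")
    assert not a.has("PVS1") and not a.has("BP7")
    assert a.final_class == "VUS"


def test_pp3_recorded_but_never_classifying():
    a = assign_criteria(_assay(40.0, scores=(0.9, 0, 0, 0)), "NCSS")
    assert a.has("PP3", "supporting")
    assert a.final_class == "VUS"


def test_inconsistent_input_rejected():
    bad = _assay(100.0, aberrant=[AberrantTranscript(
        events=(SpliceEvent.exon_skip(7),), fraction=0.0)])
    with pytest.raises(AssayError):
        assign_criteria(bad, "NCSS")


def test_criteria_exclusivity_and_monotonicity():
    strength = {("PVS1", "very_strong"): 2, ("PVS1", "strong"): 1}

    def pvs1_strength(a):
        return max((strength.get(c, 0) for c in a.criteria), default=0)

    wts = [0, 1, 3, 4.9, 5, 10, 30, 70, 100]
    prev = None
    for wt in wts:
        a = assign_criteria(_assay(float(wt)), "NCSS")
        assert not (a.has("PVS1", "very_strong") and a.has("PVS1",
                                                           "strong"))
        assert not (a.has("BP7") and a.has("PVS1"))
        s = pvs1_strength(a)
        if prev is not None:
            assert s <= prev
        prev = s


def test_assignment_is_deterministic():
    a1 = assign_criteria(_assay(0.0), "NCSS")
    a2 = assign_criteria(_assay(0.0), "NCSS")
    assert a1 == a2


# ----------------------------------------------------------------------
# cohort summary on the packaged tables
# ----------------------------------------------------------------------

@pytest.fixture(scope="module")
def cohort_assignments(model, assays):
    out = []
    for assay in assays:
        site = classify_variant_site(assay.variant.c_notation, model)
        out.append(assign_criteria(assay, site))
    return out


def test_cohort_bins(cohort_assignments):
    s = summarize_cohort(cohort_assignments)
    assert s["bins"] == {"none": 7, "sub5": 0, "low": 11, "high": 41}


def test_cohort_no_effect_count(cohort_assignments):
    assert summarize_cohort(cohort_assignments)["no_effect"] == 15


def test_cohort_pvs1(cohort_assignments):
    very_strong = [a for a in cohort_assignments
                   if a.has("PVS1", "very_strong")]
    assert len(very_strong) == 7
    assert all(a.final_class == "P" for a in very_strong)
    assert all(a.wt_fraction == 0.0 for a in very_strong)
    assert not any(a.has("PVS1", "strong") for a in cohort_assignments)


def test_single_assay_summary():
    s = summarize_cohort([assign_criteria(_assay(0.0), "NCSS")])
    assert s["bins"]["none"] == 1 and s["n"] == 1


def test_summary_requires_input():
    with pytest.raises(AssayError):
        summarize_cohort([])


# ----------------------------------------------------------------------
# baseline adjustment
# ----------------------------------------------------------------------

def _wt3_assay(skip7_fraction):
    ab = AberrantTranscript(events=(SpliceEvent.exon_skip(7),),
                            fraction=skip7_fraction)
    return _assay(100.0 - skip7_fraction, aberrant=[ab])


def test_baseline_consistent_species_flagged(model):
    wt3 = model.construct_by_name("WT-3")
    adjusted = baseline_adjust(_wt3_assay(39.0), wt3, tolerance=10.0)
    assert adjusted.aberrant[0].baseline_consistent
    assert adjusted.effective_wt_fraction == pytest.approx(100.0)


def test_strong_effect_not_baseline_consistent(model):
    wt3 = model.construct_by_name("WT-3")
    adjusted = baseline_adjust(_wt3_assay(92.0), wt3, tolerance=10.0)
    assert not adjusted.aberrant[0].baseline_consistent
    assert adjusted.effective_wt_fraction == pytest.approx(8.0)


def test_baseline_adjust_without_baseline_is_identity(model):
    wt2 = model.construct_by_name("WT-2")
    assay = _wt3_assay(30.0)
    assert baseline_adjust(assay, wt2) is assay


def test_raw_fractions_untouched(model):
    wt3 = model.construct_by_name("WT-3")
    adjusted = baseline_adjust(_wt3_assay(39.0), wt3)
    assert adjusted.wt_fraction == 61.0
    assert adjusted.aberrant[0].fraction == 39.0


# ----------------------------------------------------------------------
# identity-text parsing (quantification-table dialect)
# ----------------------------------------------------------------------

def _kinds(species):
    return [("unidentified" if t.unidentified and not t.artefact else
             "artefact" if t.artefact else
             tuple(e.kind for e in t.events)) for t in species]


def test_identity_multi_species(model):
    text = ("Exon 6 and 7 skipping (83%), exon 6 skipping (8%), exon 7 "
            "skipping (3%), and unidentified transcript (6%)")
    species = parse_identity_text(text, 100.0, model)
    assert [t.fraction for t in species] == [83.0, 8.0, 3.0, 6.0]
    assert species[0].events[0].exons == (6, 7)


def test_identity_single_species_takes_whole_aberrant_total(model):
    species = parse_identity_text("Exon 7 skipping", 100.0, model)
    assert len(species) == 1
    assert species[0].fraction == 100.0
    assert species[0].events[0].exons == (7,)


def test_identity_noncontiguous_compound(model):
    species = parse_identity_text("exon 7 + 10 skipping (46%)", 100.0,
                                  model)
    assert _kinds(species) == [("exon_skip", "exon_skip")]
    assert [e.exons for e in species[0].events] == [(7,), (10,)]


def test_identity_artefact_remainder(model):
    species = parse_identity_text("Exon 12 skipping (3% artefact)", 100.0,
                                  model)
    kinds = _kinds(species)
    assert "artefact" in kinds
    skip = next(t for t in species if t.events)
    assert skip.fraction == 97.0  # unaccounted remainder of the total


def test_identity_truncation_and_artefact_pe(model):
    text = ("5 basepair 3′ truncation of exon 12 (87%) "
            "(13% is a PE identified as artefact)")
    species = parse_identity_text(text, 100.0, model)
    trunc = next(t for t in species if t.events)
    assert trunc.events[0].kind == "exon_truncation"
    assert trunc.fraction == 87.0
    art = next(t for t in species if t.artefact)
    assert art.fraction == 13.0


def test_identity_elongation_and_retention(model):
    text = ("2 basepair 5′ elongation of exon 13 (34%), exon 12 + 13 "
            "skipping (41%), and exon 12 skipping (21%) (4% artefact)")
    species = parse_identity_text(text, 100.0, model)
    elong = species[0]
    assert elong.events[0].kind == "exon_elongation"
    assert elong.fraction == 34.0
    text2 = "Exon 7 and 8 skipping (88%) and intron 7 retention (3%)"
    species2 = parse_identity_text(text2, 91.0, model)
    assert species2[1].events[0].kind == "intron_retention"


def test_identity_two_unidentified(model):
    text = ("Exon 5 skipping (37%), intron 4 retention (14%), exon 4 + 5 "
            "skipping (8%), and two unidentified transcripts "
            "(8% and 6%, resp.)")
    species = parse_identity_text(text, 72.0, model)
    unid = [t for t in species if t.unidentified]
    assert sorted(t.fraction for t in unid) == [6.0, 8.0]


def test_identity_elongation_until(model):
    text = ("Exon 13 elongation until 1450 + 48 (15%) and exon 12 + 13 "
            "skipping (37%)")
    species = parse_identity_text(text, 51.0, model)
    assert species[0].events[0].kind == "exon_elongation"
    assert species[0].events[0].end.serialize() == "1450+48"
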