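"""Format/conceptual detectors, name resolution, and rollup invariants."""

import pytest

from taxonvet.dwc_io import NameRecord
from taxonvet.issue_detection import (
    DetectionConfig,
    assess_record,
    assess_table,
    detect_conceptual_issues,
    detect_format_issues,
    resolve_name,
)
from taxonvet.synthetic import GeneratorConfig, generate_dataset


def rec(**kw):
    return NameRecord(id="x", **kw)


class TestFormatDetector:
    def test_extra_whitespace_and_normalization(self):
        flags, norm = detect_format_issues(rec(scientificName="Parus  major"))
        assert flags["extra_whitespace"]
        assert norm["scientificName"] == "Parus major"

    def test_capitalization_flags(self):
        flags, _ = detect_format_issues(rec(genus="parus", specificEpithet="Major"))
        assert flags["genus_uncapitalized"]
        assert flags["epithet_capitalized"]

    def test_capitalized_epithet_inside_scientificname(self):
        flags, _ = detect_format_issues(rec(scientificName="Parus Major"))
        assert flags["epithet_capitalized"]

    def test_authorship_miscapitalization(self):
        flags, _ = detect_format_issues(
            rec(scientificNameAuthorship="linnaeus, 1758")
        )
        assert flags["con_authcap"]

    def test_abbreviated_genus(self):
        flags, _ = detect_format_issues(rec(scientificName="P. major"))
        assert flags["abbreviation_present"]

    def test_clean_record_has_no_flags(self, clean_binomial_record):
        flags, _ = detect_format_issues(clean_binomial_record)
        assert not any(flags.values())

    def test_verbatim_record_not_mutated(self):
        record = rec(scientificName="Parus  major")
        detect_format_issues(record)
        assert record.scientificName == "Parus  major"


class TestConceptualDetector:
    def test_qualifier_in_scientificname(self):
        flags = detect_conceptual_issues(rec(scientificName="Parus sp."))
        assert flags["qualifier_present"]

    def test_question_mark_qualifier(self):
        flags = detect_conceptual_issues(rec(scientificName="Parus major ?"))
        assert flags["qualifier_present"]

    def test_author_in_epithet_field(self):
        flags = detect_conceptual_issues(rec(specificEpithet="major Linnaeus"))
        assert flags["con_autherr"]

    def test_binomial_only_scientificname_with_infraspecific(self):
        flags = detect_conceptual_issues(
            rec(scientificName="Motacilla alba", infraspecificEpithet="yarrellii")
        )
        assert flags["sn_inf_missing"]

    def test_only_infraspecific_populated(self):
        flags = detect_conceptual_issues(rec(infraspecificEpithet="yarrellii"))
        assert flags["only_infraspecific"]

    def test_malformed_subgenus(self):
        flags = detect_conceptual_issues(rec(subgenus="parus major"))
        assert flags["con_sgerror"]

    def test_clean_record_has_no_flags(self, clean_binomial_record):
        flags = detect_conceptual_issues(clean_binomial_record)
        assert not any(flags.values())


class TestResolveName:
    def test_exact_accepted_hit(self, tit_authority):
        res = resolve_name("Cyanistes caeruleus", "", tit_authority)
        assert res.valid_canonical == "Cyanistes caeruleus"
        assert res.is_synonym == "no"
        assert not res.has_misspelling

    def test_exact_synonym_resolves_one_hop(self, tit_authority):
        res = resolve_name("Parus caeruleus", "", tit_authority)
        assert res.is_synonym == "yes"
        assert res.valid_canonical == "Cyanistes caeruleus"

    def test_misspelled_junior_synonym_sets_both_flags(self, tit_authority):
        res = resolve_name("Parus caerulues", "", tit_authority)
        assert res.has_misspelling
        assert res.is_synonym == "yes"
        assert res.valid_canonical == "Cyanistes caeruleus"

    def test_unresolvable_is_indeterminate(self, tit_authority):
        res = resolve_name("Xxxxxx zzzzzz", "", tit_authority)
        assert res.valid_canonical == ""
        assert res.is_synonym == "indeterminate"

    def test_authorship_stripped_before_matching(self, tit_authority):
        res = resolve_name("Parus major Linnaeus, 1758", "", tit_authority)
        assert res.valid_canonical == "Parus major"
        assert not res.has_misspelling

    def test_qualifier_stripped_before_matching(self, tit_authority):
        res = resolve_name("Parus major sp.", "", tit_authority)
        assert res.valid_canonical == "Parus major"

    def test_abbreviated_genus_expanded(self, tit_authority):
        res = resolve_name("M. alba", "", tit_authority)
        assert res.valid_canonical == "Motacilla alba"
        assert not res.has_misspelling

    def test_fewer_corrections_wins_disagreement(self, tit_authority):
        # constructed needs one edit, scientificnameplus is exact: the
        # exact candidate wins and the disagreement is logged
        res = resolve_name("Parus majox", "Cyanistes caeruleus", tit_authority)
        assert res.valid_canonical == "Cyanistes caeruleus"
        assert res.corrections == 0
        assert any("disagree" in c for c in res.comments)


class TestAssessRecord:
    def test_clean_record_all_clear(self, tit_authority, clean_binomial_record):
        a = assess_record(clean_binomial_record, tit_authority)
        assert not a.hasIssue and not a.hasError
        assert a.isSynonym == "no"
        assert a.validCanonical == "Parus major"

    def test_whitespace_plus_synonym_compose(self, tit_authority):
        a = assess_record(
            rec(genus="Parus", specificEpithet="caeruleus",
                scientificName="Parus  caeruleus"),
            tit_authority,
        )
        assert a.hasFormatError and a.isSynonym == "yes"
        assert a.hasIssue and a.hasError
        assert a.validCanonical == "Cyanistes caeruleus"

    def test_gibberish_keeps_remaining_flags(self, tit_authority):
        a = assess_record(rec(scientificName="Qqqq  wwww"), tit_authority)
        assert a.isSynonym == "indeterminate"
        assert a.validCanonical == ""
        assert a.hasFormatError  # whitespace problem still reported
        assert a.hasIssue

    def test_synonym_without_error_is_issue_not_error(self, tit_authority):
        a = assess_record(
            rec(genus="Parus", specificEpithet="caeruleus"), tit_authority
        )
        assert a.isSynonym == "yes"
        assert a.hasIssue and not a.hasError

    def test_authorship_only_constructed_name_not_invalid(self, tit_authority):
        a = assess_record(
            rec(scientificName="Parus major",
                scientificNameAuthorship="Linnaeus, 1758"),
            tit_authority,
        )
        assert not a.hasIssue
        assert a.validCanonical == "Parus major"

    def test_assessing_resolved_output_yields_no_flags(self, tit_authority):
        first = assess_record(
            rec(genus="parus", specificEpithet="caerulues"), tit_authority
        )
        resolved = first.validCanonical.split()
        again = assess_record(
            rec(genus=resolved[0], specificEpithet=resolved[1],
                scientificName=first.validCanonical),
            tit_authority,
        )
        assert not again.hasIssue


class TestDetectionConfig:
    def test_from_yaml_file(self, tmp_path):
        p = tmp_path / "detect.yaml"
        p.write_text(
            "max_dist_binomial: 1\nqualifier_tokens: ['sp.', 'cf.']\n",
            encoding="utf-8",
        )
        config = DetectionConfig.from_file(p)
        assert config.max_dist_binomial == 1
        assert config.qualifier_tokens == ("sp.", "cf.")
        assert config.max_dist_trinomial == 3  # untouched default

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "detect.yaml"
        p.write_text("max_dist_binomal: 1\n", encoding="utf-8")
        with pytest.raises(ValueError, match="unknown"):
            DetectionConfig.from_file(p)


class TestRollupInvariants:
    def test_rollups_hold_on_synthetic_corpus(self):
        bundle = generate_dataset(GeneratorConfig(seed=11, n_names=300,
                                                  mean_occurrences_per_name=0))
        assessments = assess_table(bundle.names, bundle.authority)
        assert len(assessments) == len(bundle.names)
        for a in assessments:
            has_any = (
                a.hasMisspelling
                or a.hasFormatError
                or a.hasConceptualError
                or a.isSynonym == "yes"
            )
            assert a.hasIssue == has_any
            assert a.hasError == (
                a.hasMisspelling or a.hasFormatError or a.hasConceptualError
            )
            if a.hasError:
                assert a.hasIssue
            assert (a.validCanonical == "") == (a.isSynonym == "indeterminate")
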