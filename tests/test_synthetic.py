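"""Synthetic-data generator: determinism, rates, truth-consistency."""

import numpy as np
import pytest

from taxonvet.authority import Authority, damerau_levenshtein
from taxonvet.issue_detection import (
    assess_record,
    detect_conceptual_issues,
    detect_format_issues,
)
from taxonvet.name_assembly import Rank, build_constructed_name
from taxonvet.synthetic import (
    GeneratorConfig,
    corrupt_name,
    generate_authority,
    generate_dataset,
    simulate_covariates,
    simulate_issue_outcomes,
)


def binom_band(p, n, z=2.576):
    """99% normal-approximation band for a binomial proportion."""
    half = z * np.sqrt(p * (1 - p) / n)
    return p - half, p + half


class TestGenerateAuthority:
    def test_shape_without_synonyms(self):
        config = GeneratorConfig(seed=1, n_genera=10, species_per_genus=5,
                                 subspecies_rate=0.0, synonym_rate=0.0)
        authority, _ = generate_authority(config)
        accepted = [e for e in authority if e.status == "accepted"]
        species = [e for e in accepted if e.rank is Rank.SPECIES]
        assert len(species) == 50
        assert not [e for e in authority if e.status == "synonym"]

    def test_seeded_reproducibility(self):
        config = GeneratorConfig(seed=42, n_genera=20, synonym_rate=0.2)
        a1, _ = generate_authority(config)
        a2, _ = generate_authority(config)
        assert [e.canonical for e in a1] == [e.canonical for e in a2]

    def test_closure_by_construction(self):
        config = GeneratorConfig(seed=3, synonym_rate=0.5)
        authority, _ = generate_authority(config)
        # re-building from the entry list re-runs the closure check
        Authority(authority.entries)
        for e in authority:
            if e.status == "synonym":
                assert authority.lookup_exact(e.accepted_canonical).status == (
                    "accepted"
                )


class TestCorruptName:
    def test_misspelling_at_exact_distance(self, tit_authority, rng):
        rec, label = corrupt_name(
            "Parus major", "Linnaeus, 1758", {"misspelling"},
            tit_authority, rng,
        )
        name = build_constructed_name(rec) or rec.scientificName
        # reconstruct the corrupted canonical from whichever fields were used
        corrupted = " ".join(
            t for t in name.split() if "," not in t and not t[0].isdigit()
        )
        assert damerau_levenshtein(corrupted, "Parus major") == label.n_edits
        assert 1 <= label.n_edits <= 2

    def test_empty_issue_spec_reconstructs_clean_name(self, tit_authority, rng):
        rec, label = corrupt_name(
            "Parus major", "Linnaeus, 1758", set(), tit_authority, rng
        )
        assert label.issues == frozenset()
        candidates = [rec.scientificName, build_constructed_name(rec)]
        assert any("Parus major" in c for c in candidates if c)

    def test_qualifier_injection_recorded_and_detectable(self, tit_authority, rng):
        for _ in range(10):
            rec, label = corrupt_name(
                "Parus major", "Linnaeus, 1758", {"conceptual"},
                tit_authority, rng,
            )
            if label.conceptual_kind == "qualifier":
                flags = detect_conceptual_issues(rec)
                assert flags["qualifier_present"]
                return
        pytest.skip("qualifier kind not drawn in 10 tries")

    def test_synonym_requires_availability(self, tit_authority, rng):
        with pytest.raises(ValueError, match="no junior synonym"):
            corrupt_name("Parus major", "Linnaeus, 1758", {"synonym"},
                         tit_authority, rng)

    def test_synonym_swap_uses_authority(self, tit_authority, rng):
        rec, label = corrupt_name(
            "Cyanistes caeruleus", "(Linnaeus, 1758)", {"synonym"},
            tit_authority, rng,
        )
        assert label.synonym_used == "Parus caeruleus"


class TestSimulateIssueOutcomes:
    def test_intercept_zero_gives_half(self, rng):
        X = np.ones((10000, 1))
        y = simulate_issue_outcomes(X, [0.0], rng)
        assert abs(y.mean() - 0.5) < 3 * np.sqrt(0.25 / 10000)

    def test_intercept_logit_quarter(self, rng):
        from scipy.special import logit

        X = np.ones((10000, 1))
        y = simulate_issue_outcomes(X, [float(logit(0.25))], rng)
        lo, hi = binom_band(0.25, 10000)
        assert lo < y.mean() < hi

    def test_same_seed_identical(self):
        X = np.ones((500, 1))
        y1 = simulate_issue_outcomes(X, [0.3], np.random.default_rng(7))
        y2 = simulate_issue_outcomes(X, [0.3], np.random.default_rng(7))
        assert (y1 == y2).all()

    def test_nonconformable_is_error(self, rng):
        with pytest.raises(ValueError, match="conformable"):
            simulate_issue_outcomes(np.ones((10, 2)), [0.1], rng)


class TestGenerateDataset:
    def test_realized_rates_within_binomial_band(self):
        bundle = generate_dataset(GeneratorConfig(seed=101))
        n = len(bundle.names)
        for cls, rate in [
            ("misspelling", 0.129),
            ("format", 0.089),
            ("conceptual", 0.137),
            ("synonym", 0.27),
        ]:
            realized = sum(cls in l.issues for l in bundle.truth.values()) / n
            lo, hi = binom_band(rate, n)
            assert lo < realized < hi, (cls, realized)

    def test_zero_names_gives_empty_valid_tables(self):
        bundle = generate_dataset(GeneratorConfig(seed=1, n_names=0))
        assert bundle.names == []
        assert bundle.occurrences == []

    def test_bitwise_determinism(self):
        b1 = generate_dataset(GeneratorConfig(seed=55, n_names=150))
        b2 = generate_dataset(GeneratorConfig(seed=55, n_names=150))
        assert [vars(r) for r in b1.names] == [vars(r) for r in b2.names]
        assert [vars(o) for o in b1.occurrences] == [
            vars(o) for o in b2.occurrences
        ]

    def test_occurrences_share_name_keys(self):
        from taxonvet.occurrence_link import link_occurrences

        bundle = generate_dataset(GeneratorConfig(seed=77, n_names=100))
        result = link_occurrences(bundle.names, bundle.occurrences)
        assert len(result.unmatched_occurrence_ids) == 0
        assert sum(result.counts.values()) == len(bundle.occurrences)

    def test_truth_consistency_each_label_redetectable(self):
        bundle = generate_dataset(
            GeneratorConfig(seed=31, n_names=200, mean_occurrences_per_name=0)
        )
        by_id = {r.id: r for r in bundle.names}
        for label in bundle.truth.values():
            record = by_id[label.id]
            if "format" in label.issues:
                flags, _ = detect_format_issues(record)
                assert any(flags.values()), label
            if "conceptual" in label.issues:
                flags = detect_conceptual_issues(record)
                assert any(flags.values()), label
            if "misspelling" in label.issues:
                a = assess_record(record, bundle.authority)
                assert a.hasMisspelling, label

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError, match="rates"):
            GeneratorConfig(rate_misspelling=1.5)


class TestSimulateCovariates:
    def test_columns_and_ranges(self, rng):
        df = simulate_covariates(2000, rng)
        assert set(df.columns) >= {
            "basisOfRecord", "region", "clade", "year", "institutionRecords",
        }
        assert df["year"].between(1900, 2015).all()
        assert (df["institutionRecords"] >= 1).all()
        assert set(df["basisOfRecord"]) == {"PreservedSpecimen", "FossilSpecimen"}
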