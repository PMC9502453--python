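import pytest

from ms2fp.curation import (
    CurationConfig,
    check_precursor,
    cure,
    metadata_filter,
    spectrum_filter,
    strict_filter,
)
from tests.conftest import make_record


class TestCheckPrecursor:
    def test_consistent_protonated(self):
        rec = make_record(molecular_weight=180.063, precursor_mz=181.071,
                          precursor_type="[M+H]+")
        assert check_precursor(rec, tolerance=0.01) == "consistent"

    def test_inconsistent_when_delta_missing(self):
        rec = make_record(molecular_weight=180.063, precursor_mz=180.063,
                          precursor_type="[M+H]+")
        assert check_precursor(rec, tolerance=0.01) == "inconsistent"

    def test_unknown_when_mw_absent(self):
        rec = make_record(molecular_weight=None)
        assert check_precursor(rec) == "unknown"

    def test_unknown_adduct(self):
        rec = make_record(precursor_type="[M+Cl]-")
        assert check_precursor(rec) == "unknown"

    @pytest.mark.parametrize(
        "adduct, delta",
        [("[M+H]+", 1.00728), ("[M+Na]+", 22.98922),
         ("[M+K]+", 38.96316), ("[M+NH4]+", 18.03383)],
    )
    def test_all_adduct_deltas(self, adduct, delta):
        rec = make_record(molecular_weight=300.0, precursor_mz=300.0 + delta,
                          precursor_type=adduct)
        assert check_precursor(rec) == "consistent"


class TestMetadataFilter:
    def test_ce_out_of_range_discarded(self):
        recs = [make_record(collision_energy_value=80.0)]
        kept, report = metadata_filter(recs)
        assert kept == []
        assert report.discards == {"ce_out_of_range": 1}

    def test_ce_boundaries_kept(self):
        recs = [make_record(record_id="lo", collision_energy_value=5.0),
                make_record(record_id="hi", collision_energy_value=70.0)]
        kept, _ = metadata_filter(recs)
        assert len(kept) == 2

    def test_uncommon_adduct_discarded_under_adduct_rule(self):
        rec = make_record(precursor_type="[M+Cl]-", precursor_mz=None,
                          molecular_weight=None)
        kept, report = metadata_filter([rec])
        assert kept == []
        assert report.discards == {"adduct_not_allowed": 1}

    def test_good_record_kept(self, good_record):
        kept, report = metadata_filter([good_record])
        assert kept == [good_record]
        assert report.n_kept == 1 and report.discards == {}

    def test_missing_metadata_first_rule(self):
        rec = make_record(instrument_type=None, collision_energy_value=80.0)
        _, report = metadata_filter([rec])
        assert report.discards == {"missing_instrument_or_ce": 1}

    def test_negative_mode_discarded(self):
        rec = make_record(ionisation_mode="negative")
        _, report = metadata_filter([rec])
        assert report.discards == {"ionisation_mode": 1}

    def test_unknown_mode_discarded_under_mode_rule(self):
        rec = make_record(ionisation_mode="unknown")
        _, report = metadata_filter([rec])
        assert report.discards == {"ionisation_mode": 1}

    def test_inconsistent_precursor_discarded(self):
        rec = make_record(precursor_mz=300.5)
        _, report = metadata_filter([rec])
        assert report.discards == {"precursor_inconsistent": 1}

    @pytest.mark.parametrize("instrument", ["ESI-ITFT (ion trap)", "APCI-QTOF",
                                            "LC-APPI-QQ", "ESI-LT", "Orbitrap Elite"])
    def test_excluded_instruments(self, instrument):
        rec = make_record(instrument_type=instrument)
        _, report = metadata_filter([rec])
        assert report.discards == {"excluded_instrument": 1}

    def test_itft_not_caught_by_lt_token(self):
        kept, _ = metadata_filter([make_record(instrument_type="LC-ESI-ITFT")])
        assert len(kept) == 1

    def test_percent_ce_without_hcd_discarded(self):
        rec = make_record(collision_energy_unit="%")
        _, report = metadata_filter([rec])
        assert report.discards == {"ce_unit_incompatible": 1}

    def test_conservation(self, small_dataset):
        recs = small_dataset.records + [make_record(collision_energy_value=99.0)]
        kept, report = metadata_filter(recs)
        assert report.n_input == len(recs)
        assert report.n_kept + report.n_discarded == report.n_input


class TestSpectrumFilter:
    def test_single_peak_discarded(self):
        rec = make_record(peaks=((100.0, 100.0),))
        kept, report = spectrum_filter([rec])
        assert kept == []
        assert report.discards == {"too_few_peaks": 1}

    def test_peaks_above_precursor_removed(self):
        rec = make_record(peaks=((150.0, 50.0), (299.9, 100.0), (310.2, 30.0)),
                          precursor_mz=300.1)
        kept, _ = spectrum_filter([rec])
        assert len(kept) == 1
        assert [p.mz for p in kept[0].peaks] == [150.0, 299.9]

    def test_all_peaks_above_precursor_discards(self):
        rec = make_record(peaks=((310.2, 50.0), (320.5, 100.0)), precursor_mz=300.1)
        kept, report = spectrum_filter([rec])
        assert kept == []
        assert report.discards == {"too_few_peaks": 1}

    def test_peak_equal_to_precursor_retained(self):
        rec = make_record(peaks=((150.0, 50.0), (300.1, 100.0)), precursor_mz=300.1)
        kept, _ = spectrum_filter([rec])
        assert len(kept[0].peaks) == 2


class TestStrictFilter:
    def test_sodiated_discarded(self):
        rec = make_record(precursor_type="[M+Na]+",
                          peaks=tuple((100.0 + i, 10.0) for i in range(20)))
        kept, report = strict_filter([rec])
        assert kept == []
        assert report.discards == {"adduct_not_strict": 1}

    def test_four_peaks_discarded_five_kept(self):
        four = make_record(record_id="r4",
                           peaks=tuple((100.0 + i, 10.0) for i in range(4)))
        five = make_record(record_id="r5",
                           peaks=tuple((100.0 + i, 10.0) for i in range(5)))
        kept, report = strict_filter([four, five])
        assert [r.record_id for r in kept] == ["r5"]
        assert report.discards == {"too_few_peaks_strict": 1}


class TestCascade:
    def test_idempotent(self, small_dataset):
        kept1, _ = cure(small_dataset.records)
        kept2, reports = cure(kept1)
        assert [r.record_id for r in kept2] == [r.record_id for r in kept1]
        assert all(rep.n_discarded == 0 for rep in reports)

    def test_strict_is_subset(self, small_dataset):
        kept, _ = cure(small_dataset.records)
        strict_kept, _ = cure(small_dataset.records, strict=True)
        assert set(r.record_id for r in strict_kept) <= set(r.record_id for r in kept)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            CurationConfig(ce_min=70, ce_max=5)
        with pytest.raises(ValueError):
            CurationConfig(min_peaks=5, strict_min_peaks=2)
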