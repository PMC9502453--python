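"""Two-stage record-filter cascade with per-rule accounting.

Library spectra are heterogeneous: metadata may be missing, collision
energies are free text, and precursor annotations sometimes contradict the
stated molecular weight.  The cascade first filters on metadata alone
(instrument and collision energy present and mutually compatible, positive
ionisation, precursor m/z consistent with MW under the adduct, instrument
not in an excluded family, collision energy within a voltage window, adduct
among the common positive-mode ones), then on the spectra themselves
(drop peaks above the precursor, require a minimum surviving peak count).
A further *strict* pass keeps only protonated-molecule records with a
higher peak count, trading dataset size for spectral information content.

Every discarded record is attributed to its *first* failing rule, so the
report is a partition: kept + per-rule discards == input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .records import SpectrumRecord

logger = logging.getLogger(__name__)

# proton / cation mass deltas for [M+X]+ adducts, Da
ADDUCT_DELTAS: dict[str, float] = {
    "[M+H]+": 1.00728,
    "[M+Na]+": 22.98922,
    "[M+K]+": 38.96316,
    "[M+NH4]+": 18.03383,
}

# instrument families excluded for scarcity of entries; matched as
# case-insensitive substrings ("lt" as a whole token to avoid e.g. "ITFT")
DEFAULT_EXCLUDED_INSTRUMENTS = frozenset(
    {"ion trap", "appi", "apci", "lt", "orbitrap"}
)

METADATA_RULES = (
    "missing_instrument_or_ce",
    "ce_unit_incompatible",
    "ionisation_mode",
    "precursor_inconsistent",
    "excluded_instrument",
    "ce_out_of_range",
    "adduct_not_allowed",
)


@dataclass
class CurationConfig:
    """Thresholds and vocabularies for the filter cascade."""

    ce_min: float = 5.0
    ce_max: float = 70.0
    allowed_adducts: frozenset[str] = frozenset(ADDUCT_DELTAS)
    strict_adducts: frozenset[str] = frozenset({"[M+H]+"})
    min_peaks: int = 2
    strict_min_peaks: int = 5
    excluded_instruments: frozenset[str] = DEFAULT_EXCLUDED_INSTRUMENTS
    precursor_tolerance: float = 0.01

    def __post_init__(self) -> None:
        if not self.ce_min < self.ce_max:
            raise ValueError("ce_min must be < ce_max")
        if self.min_peaks < 1:
            raise ValueError("min_peaks must be >= 1")
        if self.strict_min_peaks < self.min_peaks:
            raise ValueError("strict_min_peaks must be >= min_peaks")


@dataclass
class CurationReport:
    """Per-rule discard accounting for one filter stage."""

    stage: str
    n_input: int = 0
    n_kept: int = 0
    discards: dict[str, int] = field(default_factory=dict)
    first_failure: dict[str, str] = field(default_factory=dict)  # record_id -> rule

    def record_discard(self, record_id: str, rule: str) -> None:
        self.discards[rule] = self.discards.get(rule, 0) + 1
        self.first_failure[record_id] = rule

    @property
    def n_discarded(self) -> int:
        return sum(self.discards.values())

    def check_conservation(self) -> None:
        if self.n_kept + self.n_discarded != self.n_input:
            raise AssertionError(
                f"{self.stage}: kept {self.n_kept} + discarded {self.n_discarded} "
                f"!= input {self.n_input}"
            )

    def to_tsv(self) -> str:
        lines = ["stage\trule\tcount"]
        lines.append(f"{self.stage}\tkept\t{self.n_kept}")
        for rule, n in sorted(self.discards.items()):
            lines.append(f"{self.stage}\t{rule}\t{n}")
        return "\n".join(lines) + "\n"


def check_precursor(
    record: SpectrumRecord, tolerance: float = 0.01
) -> str:
    """Check precursor m/z against MW + adduct mass delta.

    Returns ``"consistent"`` when |precursor_mz - (MW + delta)| <= tolerance,
    ``"inconsistent"`` when the difference exceeds the tolerance, and
    ``"unknown"`` when MW or precursor m/z is absent or the adduct is not
    recognised.
    """
    if record.molecular_weight is None or record.precursor_mz is None:
        return "unknown"
    delta = ADDUCT_DELTAS.get((record.precursor_type or "").strip())
    if delta is None:
        return "unknown"
    expected = record.molecular_weight + delta
    if abs(record.precursor_mz - expected) <= tolerance:
        return "consistent"
    return "inconsistent"


def _instrument_excluded(label: str, excluded: frozenset[str]) -> bool:
    low = label.lower()
    tokens = [t for t in _split_tokens(low)]
    for pat in excluded:
        if len(pat) <= 2:
            if pat in tokens:
                return True
        elif pat in low:
            return True
    return False


def _split_tokens(label: str) -> list[str]:
    import re

    return re.split(r"[^a-z0-9]+", label)


def _ce_unit_compatible(record: SpectrumRecord) -> bool:
    """Percent collision energies are only meaningful for HCD/Orbitrap-class
    instruments (normalised collision energy); volt-scale units are accepted
    for any beam-type collision cell.  A missing unit is treated as volts."""
    unit = record.collision_energy_unit
    if unit in (None, "V", "eV"):
        return True
    instrument = (record.instrument_type or "").lower()
    if unit in ("%", "NCE"):
        return "hcd" in instrument or "orbitrap" in instrument
    return False


def _first_failing_rule(record: SpectrumRecord, config: CurationConfig) -> Optional[str]:
    if record.instrument_type is None or record.collision_energy_value is None:
        return "missing_instrument_or_ce"
    if not _ce_unit_compatible(record):
        return "ce_unit_incompatible"
    if record.ionisation_mode != "positive":
        return "ionisation_mode"
    if check_precursor(record, config.precursor_tolerance) == "inconsistent":
        return "precursor_inconsistent"
    if _instrument_excluded(record.instrument_type, config.excluded_instruments):
        return "excluded_instrument"
    ce = record.collision_energy_value
    if ce < config.ce_min or ce > config.ce_max:
        return "ce_out_of_range"
    if (record.precursor_type or "").strip() not in config.allowed_adducts:
        return "adduct_not_allowed"
    return None


def metadata_filter(
    records: Sequence[SpectrumRecord], config: Optional[CurationConfig] = None
) -> tuple[list[SpectrumRecord], CurationReport]:
    """Keep records passing every metadata rule; attribute discards to the
    first failing rule (fixed rule order, see :data:`METADATA_RULES`)."""
    config = config or CurationConfig()
    report = CurationReport(stage="metadata", n_input=len(records))
    kept: list[SpectrumRecord] = []
    for rec in records:
        rule = _first_failing_rule(rec, config)
        if rule is None:
            kept.append(rec)
        else:
            report.record_discard(rec.record_id, rule)
    report.n_kept = len(kept)
    report.check_conservation()
    return kept, report


def spectrum_filter(
    records: Sequence[SpectrumRecord], config: Optional[CurationConfig] = None
) -> tuple[list[SpectrumRecord], CurationReport]:
    """Remove peaks above the precursor m/z, then drop records left with
    fewer than ``min_peaks`` peaks.

    Peaks exactly at the precursor m/z are retained (strict inequality).
    Records without a precursor m/z keep their full peak list.
    """
    config = config or CurationConfig()
    report = CurationReport(stage="spectrum", n_input=len(records))
    kept: list[SpectrumRecord] = []
    for rec in records:
        if rec.precursor_mz is not None:
            peaks = [p for p in rec.peaks if p.mz <= rec.precursor_mz]
        else:
            peaks = list(rec.peaks)
        if len(peaks) < config.min_peaks:
            report.record_discard(rec.record_id, "too_few_peaks")
            continue
        kept.append(rec.with_peaks(peaks) if len(peaks) != len(rec.peaks) else rec)
    report.n_kept = len(kept)
    report.check_conservation()
    return kept, report


def strict_filter(
    records: Sequence[SpectrumRecord], config: Optional[CurationConfig] = None
) -> tuple[list[SpectrumRecord], CurationReport]:
    """Deep-curing pass: keep only records with a strict adduct (default
    [M+H]+) and at least ``strict_min_peaks`` peaks."""
    config = config or CurationConfig()
    report = CurationReport(stage="strict", n_input=len(records))
    kept: list[SpectrumRecord] = []
    for rec in records:
        if (rec.precursor_type or "").strip() not in config.strict_adducts:
            report.record_discard(rec.record_id, "adduct_not_strict")
        elif len(rec.peaks) < config.strict_min_peaks:
            report.record_discard(rec.record_id, "too_few_peaks_strict")
        else:
            kept.append(rec)
    report.n_kept = len(kept)
    report.check_conservation()
    return kept, report


def cure(
    records: Sequence[SpectrumRecord],
    config: Optional[CurationConfig] = None,
    strict: bool = False,
) -> tuple[list[SpectrumRecord], list[CurationReport]]:
    """Run the full cascade: metadata -> spectrum (-> strict)."""
    config = config or CurationConfig()
    kept, rep1 = metadata_filter(records, config)
    kept, rep2 = spectrum_filter(kept, config)
    reports = [rep1, rep2]
    if strict:
        kept, rep3 = strict_filter(kept, config)
        reports.append(rep3)
    return kept, reports
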