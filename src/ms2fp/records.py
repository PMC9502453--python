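"""Core domain types: peaks and spectral-library records.

A :class:`SpectrumRecord` is one MS/MS acquisition from a spectral library:
a centroided peak list plus the metadata needed for curation (instrument,
ionisation mode, adduct, precursor m/z, molecular weight, collision energy)
and, when known, the compound structure.  Several records usually share one
compound: libraries hold many spectra of the same molecule acquired at
different collision energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional


@dataclass(frozen=True)
class Peak:
    """A single centroided fragment peak.

    Parameters
    ----------
    mz : float
        Mass-to-charge ratio in Da (thomson). Must be positive.
    intensity : float
        Relative abundance, arbitrary units, non-negative.
    """

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass
class SpectrumRecord:
    """One MS/MS library entry: peak list + metadata + optional structure.

    Invariants: ``peaks`` sorted by ascending m/z; metadata strings stripped;
    ``compound_id`` identical for records of identical structures (derived
    from InChIKey, else canonical SMILES, else lower-cased compound name).
    """

    record_id: str
    compound_id: str
    peaks: list[Peak] = field(default_factory=list)
    smiles: Optional[str] = None
    name: Optional[str] = None
    inchikey: Optional[str] = None
    instrument_type: Optional[str] = None
    ionisation_mode: str = "unknown"  # {"positive", "negative", "unknown"}
    precursor_type: Optional[str] = None
    precursor_mz: Optional[float] = None
    molecular_weight: Optional[float] = None
    collision_energy_value: Optional[float] = None
    collision_energy_unit: Optional[str] = None

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)
        if self.ionisation_mode not in ("positive", "negative", "unknown"):
            raise ValueError(f"bad ionisation mode {self.ionisation_mode!r}")

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def with_peaks(self, peaks: list[Peak]) -> "SpectrumRecord":
        """Return a copy of this record with a replaced peak list."""
        return replace(self, peaks=sorted(peaks, key=lambda p: p.mz))
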