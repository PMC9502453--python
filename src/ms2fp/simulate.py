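"""Synthetic spectrum–fingerprint datasets with a known, learnable mapping.

The generator plants the statistical structure the prediction task relies
on, without attempting fragmentation chemistry: each fingerprint bit owns a
small set of characteristic m/z bins, and a compound's spectra contain the
union of the characteristic peaks of its active bits, corrupted by
per-spectrum peak dropout, log-normal intensity noise and spurious uniform
noise peaks.  Fingerprints are independent Bernoulli bits at ~23% activity,
matching the sparsity of real substructure keys; records carry
library-style metadata chosen to pass the default curation rules
(protonated adduct, positive mode, in-range collision energy, precursor
consistent with the molecular weight).

An adversarial variant generates spectra independently of the fingerprints;
any model trained on it can only reach the random baseline, which makes it
a negative control for the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .binning import BinGrid, make_grid
from .records import Peak, SpectrumRecord


@dataclass
class SynthConfig:
    """Study conditions for the generator.

    ``active_bit_probability`` defaults to 0.23 (real MACCS fingerprints are
    ~77% zeros); ``spectra_per_compound`` emulates repeated acquisitions at
    different collision energies; ``bit_dropout`` is the probability that an
    active bit's characteristic peaks are missing from a given spectrum.
    ``mz_signal_max`` keeps characteristic peaks below every precursor so
    the spectrum filter never removes signal.
    """

    n_compounds: int = 300
    spectra_per_compound: tuple[int, int] = (2, 8)
    n_bits: int = 166
    active_bit_probability: float = 0.23
    peaks_per_active_bit: int = 3
    noise_peaks: tuple[int, int] = (0, 10)
    intensity_noise_cv: float = 0.3
    bit_dropout: float = 0.1
    bit_block_size: int = 0  # >1 turns on block-correlated bits
    mz_signal_max: float = 600.0
    mw_range: tuple[float, float] = (620.0, 690.0)
    grid: BinGrid = dc_field(default_factory=make_grid)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.active_bit_probability, self.bit_dropout):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_bits < 1:
            raise ValueError("n_bits must be >= 1")
        if self.intensity_noise_cv < 0:
            raise ValueError("intensity_noise_cv must be >= 0")


@dataclass
class SynthDataset:
    """Records + ground-truth fingerprints + the planted bit→peak map."""

    records: list[SpectrumRecord]
    fingerprints: dict[str, np.ndarray]
    bit_peak_map: dict[int, tuple[float, ...]]
    config: SynthConfig


def make_bit_peak_map(config: SynthConfig) -> dict[int, tuple[float, ...]]:
    """Sample characteristic bins per bit (deterministic under the seed).

    The grid must offer at least ``n_bits * peaks_per_active_bit`` usable
    bins; bins are then drawn without replacement globally, so no two bits
    share a characteristic bin and every bit is identified by its peak set.
    """
    grid = config.grid
    centers = grid.centers()
    signal_bins = np.nonzero(centers <= config.mz_signal_max)[0]
    need = config.n_bits * config.peaks_per_active_bit
    if len(signal_bins) < need:
        raise ValueError(
            f"grid has {len(signal_bins)} usable bins, need {need}"
        )
    rng = np.random.default_rng(config.seed)
    # disjoint-leaning: one global draw without replacement, so bits never
    # share a characteristic bin when the grid is large enough (always, given
    # the precondition above)
    pool = rng.permutation(signal_bins)[:need]
    bit_map: dict[int, tuple[float, ...]] = {}
    for bit in range(config.n_bits):
        bins = pool[
            bit * config.peaks_per_active_bit : (bit + 1) * config.peaks_per_active_bit
        ]
        bit_map[bit] = tuple(round(float(centers[b]), 6) for b in sorted(bins))
    return bit_map


def _draw_fingerprints(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    p = config.active_bit_probability
    if config.bit_block_size > 1:
        # block-correlated bits: a latent per-block state drives its bits,
        # each bit copying the state with a 10% flip probability
        n_blocks = -(-config.n_bits // config.bit_block_size)
        latent = rng.random((config.n_compounds, n_blocks)) < p
        bits = np.repeat(latent, config.bit_block_size, axis=1)[:, : config.n_bits]
        flips = rng.random(bits.shape) < 0.1
        return (bits ^ flips).astype(np.uint8)
    return (rng.random((config.n_compounds, config.n_bits)) < p).astype(np.uint8)


def _lognormal_factors(
    rng: np.random.Generator, cv: float, size: int
) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def generate(config: Optional[SynthConfig] = None) -> SynthDataset:
    """Generate the default signal-bearing dataset.

    Per spectrum: the characteristic peaks of the compound's active bits
    (each bit surviving with probability 1 - ``bit_dropout``), log-normal
    intensity noise at the configured CV, plus spurious noise peaks below
    the precursor; intensities rescaled so the base peak is 100.  Every
    record passes the default metadata and spectrum filters.
    """
    return _generate(config or SynthConfig(), adversarial=False)


def generate_adversarial(config: Optional[SynthConfig] = None) -> SynthDataset:
    """Negative control: spectra independent of the fingerprints.

    Metadata and fingerprints are produced exactly as in :func:`generate`,
    but peak lists are pure noise, so no model can beat the random baseline.
    """
    return _generate(config or SynthConfig(), adversarial=True)


def _generate(config: SynthConfig, adversarial: bool) -> SynthDataset:
    rng = np.random.default_rng(config.seed)
    bit_map = make_bit_peak_map(config)
    # per-(bit, peak) base intensities, fixed across spectra
    base_intensity = {
        bit: rng.uniform(30.0, 100.0, size=config.peaks_per_active_bit)
        for bit in range(config.n_bits)
    }
    fps = _draw_fingerprints(config, rng)
    centers = config.grid.centers()
    noise_bins = np.nonzero(centers <= config.mw_range[0])[0]

    records: list[SpectrumRecord] = []
    fingerprints: dict[str, np.ndarray] = {}
    lo_s, hi_s = config.spectra_per_compound
    lo_n, hi_n = config.noise_peaks
    rec_idx = 0
    for ci in range(config.n_compounds):
        # lower-case id reused as the compound name so that the id derivation
        # rule (name, for structure-less records) round-trips through MSP
        cid = f"cpd{ci:05d}"
        fingerprints[cid] = fps[ci]
        mw = rng.uniform(*config.mw_range)
        precursor = mw + 1.00728
        n_spectra = int(rng.integers(lo_s, hi_s + 1))
        active_bits = np.nonzero(fps[ci])[0]
        for _ in range(n_spectra):
            peaks: dict[float, float] = {}
            if not adversarial:
                for bit in active_bits:
                    if rng.random() < config.bit_dropout:
                        continue
                    factors = _lognormal_factors(
                        rng, config.intensity_noise_cv, config.peaks_per_active_bit
                    )
                    for mz, inten in zip(
                        bit_map[bit], base_intensity[bit] * factors
                    ):
                        peaks[mz] = max(peaks.get(mz, 0.0), float(inten))
                n_noise = int(rng.integers(lo_n, hi_n + 1))
            else:
                n_noise = int(rng.integers(30, 121))
            # spurious peaks: uniform bins below the precursor, low intensity
            n_noise = max(n_noise, 2 - len(peaks))  # curation needs >= 2 peaks
            for b in rng.choice(noise_bins, size=n_noise, replace=False):
                mz = round(float(centers[b]), 6)
                inten = float(rng.uniform(1.0, 20.0))
                peaks[mz] = max(peaks.get(mz, 0.0), inten)
            scale = 100.0 / max(peaks.values())
            peak_list = [Peak(mz, inten * scale) for mz, inten in peaks.items()]
            records.append(
                SpectrumRecord(
                    record_id=f"SYN{rec_idx:06d}",
                    compound_id=cid,
                    peaks=peak_list,
                    name=cid,
                    instrument_type="LC-ESI-QFT",
                    ionisation_mode="positive",
                    precursor_type="[M+H]+",
                    precursor_mz=round(precursor, 5),
                    molecular_weight=round(mw, 5),
                    collision_energy_value=float(np.round(rng.uniform(10, 60), 1)),
                    collision_energy_unit="V",
                )
            )
            rec_idx += 1
    return SynthDataset(
        records=records,
        fingerprints=fingerprints,
        bit_peak_map=bit_map,
        config=config,
    )
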