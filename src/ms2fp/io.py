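"""Reading and writing spectral-library records, structures and matrices.

Supports an MSP-like dialect as exported by open spectral repositories
(MassBank of North America style): entries separated by blank lines, metadata
as ``Key: value`` or ``KEY=value`` lines, a ``Num Peaks`` count and one
``mz intensity`` pair per line (whitespace- or tab-separated).  A ``tabular``
dialect (one TSV row per record with an inline peak string) is provided for
round-tripping processed data.

Parsing is conservative: unparseable fields are stored as absent, never
guessed; a malformed entry is skipped and logged, never aborts the batch.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .records import Peak, SpectrumRecord

logger = logging.getLogger(__name__)

# Canonical instrument vocabulary: library exports mix bare and LC-prefixed
# labels for the same platform.
INSTRUMENT_SYNONYMS: dict[str, str] = {
    "ESI-QFT": "LC-ESI-QFT",
    "ESI-QTOF": "LC-ESI-QTOF",
    "ESI-QQ": "LC-ESI-QQ",
    "ESI-QQQ": "LC-ESI-QQQ",
    "ESI-ITFT": "LC-ESI-ITFT",
    "ESI-ITTOF": "LC-ESI-ITTOF",
    "ESI-TOF": "LC-ESI-TOF",
    "Q-TOF": "LC-ESI-QTOF",
    "QTOF": "LC-ESI-QTOF",
}

KNOWN_INSTRUMENTS: frozenset[str] = frozenset(INSTRUMENT_SYNONYMS) | frozenset(
    INSTRUMENT_SYNONYMS.values()
)


def standardize_instrument(label: str, flags: Optional[list[str]] = None) -> str:
    """Map an instrument-type label onto the canonical vocabulary.

    Unknown labels are returned unchanged and flagged (appended to ``flags``
    when given, and logged).  Idempotent: canonical labels map to themselves.
    """
    if not label or not label.strip():
        raise ValueError("instrument label must be non-empty")
    label = label.strip()
    if label in INSTRUMENT_SYNONYMS:
        return INSTRUMENT_SYNONYMS[label]
    if label not in KNOWN_INSTRUMENTS:
        if flags is not None:
            flags.append(label)
        logger.debug("unknown instrument label kept as-is: %r", label)
    return label


# --------------------------------------------------------------------------
# collision energy

_CE_RE = re.compile(
    r"""(?P<num>[-+]?\d+(?:\.\d+)?)\s*(?P<unit>%|eV|V|NCE)?""",
    re.IGNORECASE,
)


def parse_collision_energy(text: str) -> tuple[Optional[float], Optional[str]]:
    """Extract (value, unit) from a free-text collision-energy field.

    ``"35"``, ``"35 V"``, ``"35V"``, ``"35 eV"`` all give value 35 with the
    unit recorded (or absent); ``"HCD 35%"`` gives (35, "%").  Returns
    (None, None) when no number is found.
    """
    if text is None:
        return None, None
    m = _CE_RE.search(text.strip())
    if m is None or m.group("num") is None:
        return None, None
    value = float(m.group("num"))
    unit = m.group("unit")
    if unit is not None:
        unit = unit if unit == "%" else unit.strip()
        # normalise case: "ev" -> "eV", "v" -> "V"
        low = unit.lower()
        unit = {"ev": "eV", "v": "V", "%": "%", "nce": "NCE"}.get(low, unit)
    return value, unit


# --------------------------------------------------------------------------
# compound identity


def derive_compound_id(
    inchikey: Optional[str], smiles: Optional[str], name: Optional[str]
) -> Optional[str]:
    """Stable per-molecule key: InChIKey, else canonical SMILES, else name.

    Spectra of the same molecule must share one key so that train/test
    partitioning can keep them together.
    """
    if inchikey:
        return inchikey.strip()
    if smiles:
        canon = canonical_smiles(smiles)
        if canon is not None:
            return canon
        return smiles.strip()
    if name:
        return name.strip().lower()
    return None


def canonical_smiles(smiles: str) -> Optional[str]:
    """RDKit-canonicalised SMILES, or None if the string does not parse."""
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles.strip())
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


# --------------------------------------------------------------------------
# MSP / tabular record I/O

# metadata key synonyms, lower-cased with spaces/underscores removed
_KEY_ALIASES = {
    "name": "name",
    "compoundname": "name",
    "smiles": "smiles",
    "inchikey": "inchikey",
    "instrumenttype": "instrument_type",
    "instrument": "instrument_type",
    "ionmode": "ionisation_mode",
    "ionizationmode": "ionisation_mode",
    "ionisationmode": "ionisation_mode",
    "precursortype": "precursor_type",
    "adduct": "precursor_type",
    "precursormz": "precursor_mz",
    "mw": "molecular_weight",
    "molecularweight": "molecular_weight",
    "exactmass": "molecular_weight",
    "collisionenergy": "collision_energy",
    "ce": "collision_energy",
    "db#": "record_id",
    "id": "record_id",
    "recordid": "record_id",
    "numpeaks": "num_peaks",
}


@dataclass
class ParseReport:
    """Per-file parse accounting: record/skip counts and missing-field tallies."""

    n_entries: int = 0
    n_records: int = 0
    n_skipped: int = 0
    missing_fields: dict[str, int] = field(default_factory=dict)
    skipped_entries: list[str] = field(default_factory=list)
    unknown_instruments: list[str] = field(default_factory=list)

    def tally_missing(self, record: SpectrumRecord) -> None:
        for fld in (
            "smiles",
            "instrument_type",
            "precursor_mz",
            "molecular_weight",
            "collision_energy_value",
        ):
            if getattr(record, fld) is None:
                self.missing_fields[fld] = self.missing_fields.get(fld, 0) + 1


def _normalise_key(key: str) -> Optional[str]:
    return _KEY_ALIASES.get(re.sub(r"[\s_]+", "", key.strip().lower()))


def _entry_to_record(
    meta: dict[str, str], peak_lines: list[str], fallback_id: str
) -> SpectrumRecord:
    peaks = []
    for line in peak_lines:
        parts = line.replace(";", " ").split()
        if len(parts) < 2:
            raise ValueError(f"malformed peak line: {line!r}")
        try:
            mz, inten = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ValueError(f"malformed peak line: {line!r}") from exc
        peaks.append(Peak(mz, inten))

    def _float_or_none(key: str) -> Optional[float]:
        raw = meta.get(key)
        if raw is None:
            return None
        try:
            return float(raw)
        except ValueError:
            return None

    ce_value, ce_unit = parse_collision_energy(meta.get("collision_energy"))
    mode = (meta.get("ionisation_mode") or "").strip().lower()
    if mode in ("positive", "p", "pos", "+"):
        mode = "positive"
    elif mode in ("negative", "n", "neg", "-"):
        mode = "negative"
    else:
        mode = "unknown"

    name = meta.get("name")
    smiles = meta.get("smiles")
    inchikey = meta.get("inchikey")
    compound_id = derive_compound_id(inchikey, smiles, name) or fallback_id

    return SpectrumRecord(
        record_id=meta.get("record_id", fallback_id).strip(),
        compound_id=compound_id,
        peaks=peaks,
        smiles=smiles.strip() if smiles else None,
        name=name.strip() if name else None,
        inchikey=inchikey.strip() if inchikey else None,
        instrument_type=(
            meta["instrument_type"].strip() if meta.get("instrument_type") else None
        ),
        ionisation_mode=mode,
        precursor_type=(
            meta["precursor_type"].strip() if meta.get("precursor_type") else None
        ),
        precursor_mz=_float_or_none("precursor_mz"),
        molecular_weight=_float_or_none("molecular_weight"),
        collision_energy_value=ce_value,
        collision_energy_unit=ce_unit,
    )


def _iter_msp_entries(lines: Iterable[str]):
    meta: dict[str, str] = {}
    peak_lines: list[str] = []
    in_peaks = False
    for line in lines:
        stripped = line.strip()
        if not stripped:
            if meta or peak_lines:
                yield meta, peak_lines
            meta, peak_lines, in_peaks = {}, [], False
            continue
        if in_peaks:
            peak_lines.append(stripped)
            continue
        # metadata: "Key: value" or "KEY=value"
        m = re.match(r"^([^:=]+?)\s*[:=]\s*(.*)$", stripped)
        if m:
            key = _normalise_key(m.group(1))
            if key == "num_peaks":
                in_peaks = True
            elif key is not None:
                meta[key] = m.group(2)
            continue
        # a bare line before Num Peaks that looks like a peak pair
        peak_lines.append(stripped)
    if meta or peak_lines:
        yield meta, peak_lines


def read_records(
    path: str | Path, dialect: str = "msp"
) -> tuple[list[SpectrumRecord], ParseReport]:
    """Read spectral-library records from ``path``.

    Parameters
    ----------
    path : str or Path
        Input file; an unreadable file raises.
    dialect : {"msp", "tabular"}
        ``msp`` for MSP-like library exports, ``tabular`` for the TSV
        round-trip format written by :func:`write_records_tabular`.

    Returns
    -------
    (records, report)
        Records in file order; a :class:`ParseReport` with skip/missing
        accounting.  A malformed single entry is skipped and logged.
    """
    path = Path(path)
    if dialect == "msp":
        return _read_msp(path)
    if dialect == "tabular":
        return _read_tabular(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_msp(path: Path) -> tuple[list[SpectrumRecord], ParseReport]:
    report = ParseReport()
    records: list[SpectrumRecord] = []
    with open(path) as fh:
        for idx, (meta, peak_lines) in enumerate(_iter_msp_entries(fh)):
            report.n_entries += 1
            fallback = f"{path.stem}:{idx}"
            try:
                rec = _entry_to_record(meta, peak_lines, fallback)
            except ValueError as exc:
                report.n_skipped += 1
                report.skipped_entries.append(fallback)
                logger.warning("skipping entry %s: %s", fallback, exc)
                continue
            if rec.instrument_type is not None:
                rec.instrument_type = standardize_instrument(
                    rec.instrument_type, report.unknown_instruments
                )
            report.n_records += 1
            report.tally_missing(rec)
            records.append(rec)
    return records, report


_TAB_COLUMNS = [
    "record_id",
    "compound_id",
    "name",
    "smiles",
    "inchikey",
    "instrument_type",
    "ionisation_mode",
    "precursor_type",
    "precursor_mz",
    "molecular_weight",
    "collision_energy_value",
    "collision_energy_unit",
    "peaks",
]


def _read_tabular(path: Path) -> tuple[list[SpectrumRecord], ParseReport]:
    report = ParseReport()
    records: list[SpectrumRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for lineno, line in enumerate(fh):
            if not line.strip():
                continue
            report.n_entries += 1
            parts = line.rstrip("\n").split("\t")

            def get(name: str) -> Optional[str]:
                i = col.get(name)
                if i is None or i >= len(parts) or parts[i] == "":
                    return None
                return parts[i]

            try:
                peaks = [
                    Peak(float(p.split(":")[0]), float(p.split(":")[1]))
                    for p in (get("peaks") or "").split()
                ]
                rec = SpectrumRecord(
                    record_id=get("record_id") or f"{path.stem}:{lineno}",
                    compound_id=get("compound_id") or f"{path.stem}:{lineno}",
                    peaks=peaks,
                    smiles=get("smiles"),
                    name=get("name"),
                    inchikey=get("inchikey"),
                    instrument_type=get("instrument_type"),
                    ionisation_mode=get("ionisation_mode") or "unknown",
                    precursor_type=get("precursor_type"),
                    precursor_mz=(
                        float(get("precursor_mz")) if get("precursor_mz") else None
                    ),
                    molecular_weight=(
                        float(get("molecular_weight"))
                        if get("molecular_weight")
                        else None
                    ),
                    collision_energy_value=(
                        float(get("collision_energy_value"))
                        if get("collision_energy_value")
                        else None
                    ),
                    collision_energy_unit=get("collision_energy_unit"),
                )
            except (ValueError, IndexError) as exc:
                report.n_skipped += 1
                report.skipped_entries.append(f"{path.stem}:{lineno}")
                logger.warning("skipping row %d: %s", lineno, exc)
                continue
            report.n_records += 1
            report.tally_missing(rec)
            records.append(rec)
    return records, report


def write_records(records: Sequence[SpectrumRecord], path: str | Path) -> None:
    """Write records as an MSP-dialect library file (``Key: value`` lines)."""
    with open(path, "w") as fh:
        for rec in records:
            if rec.name:
                fh.write(f"Name: {rec.name}\n")
            fh.write(f"DB#: {rec.record_id}\n")
            if rec.smiles:
                fh.write(f"SMILES: {rec.smiles}\n")
            if rec.inchikey:
                fh.write(f"InChIKey: {rec.inchikey}\n")
            if rec.instrument_type:
                fh.write(f"Instrument_type: {rec.instrument_type}\n")
            fh.write(f"Ion_mode: {rec.ionisation_mode}\n")
            if rec.precursor_type:
                fh.write(f"Precursor_type: {rec.precursor_type}\n")
            if rec.precursor_mz is not None:
                fh.write(f"PrecursorMZ: {rec.precursor_mz!r}\n")
            if rec.molecular_weight is not None:
                fh.write(f"MW: {rec.molecular_weight!r}\n")
            if rec.collision_energy_value is not None:
                unit = rec.collision_energy_unit or ""
                fh.write(f"Collision_energy: {rec.collision_energy_value!r} {unit}".rstrip() + "\n")
            fh.write(f"Num Peaks: {len(rec.peaks)}\n")
            for p in rec.peaks:
                fh.write(f"{p.mz!r} {p.intensity!r}\n")
            fh.write("\n")


def write_records_tabular(records: Sequence[SpectrumRecord], path: str | Path) -> None:
    """Write records as one TSV row each (peaks inline as ``mz:intensity``)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TAB_COLUMNS) + "\n")
        for rec in records:
            peaks = " ".join(f"{p.mz!r}:{p.intensity!r}" for p in rec.peaks)
            row = [
                rec.record_id,
                rec.compound_id,
                rec.name or "",
                rec.smiles or "",
                rec.inchikey or "",
                rec.instrument_type or "",
                rec.ionisation_mode,
                rec.precursor_type or "",
                repr(rec.precursor_mz) if rec.precursor_mz is not None else "",
                repr(rec.molecular_weight) if rec.molecular_weight is not None else "",
                (
                    repr(rec.collision_energy_value)
                    if rec.collision_energy_value is not None
                    else ""
                ),
                rec.collision_energy_unit or "",
                peaks,
            ]
            fh.write("\t".join(row) + "\n")


# --------------------------------------------------------------------------
# spectral matrix


@dataclass
class SpectralMatrix:
    """Spectra-by-feature matrix with row ids and column labels.

    ``X`` is CSR sparse; values lie in [0, 1] after binning (each nonempty
    row's maximum is exactly 1).  Column labels are bin-centre m/z values
    (or component names after dimensionality reduction).
    """

    row_ids: list[str]
    col_labels: list[str]
    X: sp.csr_matrix

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        if self.X.shape != (len(self.row_ids), len(self.col_labels)):
            raise ValueError(
                f"shape {self.X.shape} does not match "
                f"{len(self.row_ids)} row ids x {len(self.col_labels)} labels"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def to_dense(self) -> np.ndarray:
        return self.X.toarray()


def write_matrix(matrix: SpectralMatrix, path: str | Path) -> None:
    """Write a spectral matrix as a sparse triplet TSV (bit-exact round-trip).

    Layout: a header block with shape, row ids and column labels, then one
    ``row<TAB>col<TAB>value`` line per stored element, with values in
    ``repr`` form so that read(write(M)) == M exactly.
    """
    coo = matrix.X.tocoo()
    if not np.all(np.isfinite(coo.data)):
        raise ValueError("matrix must be finite")
    with open(path, "w") as fh:
        fh.write(f"#shape\t{matrix.shape[0]}\t{matrix.shape[1]}\n")
        fh.write("#rows\t" + "\t".join(matrix.row_ids) + "\n")
        fh.write("#cols\t" + "\t".join(matrix.col_labels) + "\n")
        fh.write("row\tcol\tvalue\n")
        order = np.lexsort((coo.col, coo.row))
        for i, j, v in zip(coo.row[order], coo.col[order], coo.data[order]):
            fh.write(f"{i}\t{j}\t{float(v)!r}\n")


def read_matrix(path: str | Path) -> SpectralMatrix:
    """Read a sparse triplet TSV written by :func:`write_matrix`."""
    with open(path) as fh:
        shape_line = fh.readline().rstrip("\n").split("\t")
        if shape_line[0] != "#shape":
            raise ValueError(f"{path}: not a matrix file")
        n_rows, n_cols = int(shape_line[1]), int(shape_line[2])
        rows_line = fh.readline().rstrip("\n").split("\t")
        cols_line = fh.readline().rstrip("\n").split("\t")
        row_ids = rows_line[1 : 1 + n_rows]
        col_labels = cols_line[1 : 1 + n_cols]
        fh.readline()  # triplet header
        ii, jj, vv = [], [], []
        for line in fh:
            if not line.strip():
                continue
            i, j, v = line.rstrip("\n").split("\t")
            ii.append(int(i))
            jj.append(int(j))
            vv.append(float(v))
    X = sp.coo_matrix(
        (np.array(vv, dtype=float), (np.array(ii, dtype=int), np.array(jj, dtype=int))),
        shape=(n_rows, n_cols),
    ).tocsr()
    return SpectralMatrix(row_ids=row_ids, col_labels=col_labels, X=X)
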